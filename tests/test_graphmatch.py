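"""Window sampling, subgraph construction, RRWM matching and LPM filtering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from cellalign.geometry import RigidTransform
from cellalign.graphmatch import (
    CellGraph,
    ConfigurationError,
    GraphMatchConfig,
    RefinementFailedError,
    affinity_matrix,
    build_subgraph,
    discretize,
    kde_density,
    lpm_filter,
    map_window_center,
    match_cells,
    node_affinity,
    refine_transform,
    rrwm_match,
    sample_windows,
)
from cellalign.io_tables import CellTable


def _graph(xy, feats=None, edge_threshold=15.0):
    xy = np.asarray(xy, float)
    feats = np.asarray(feats, float) if feats is not None else np.zeros((len(xy), 0))
    if len(xy) >= 2:
        pairs = cKDTree(xy).query_pairs(r=edge_threshold, output_type="ndarray")
    else:
        pairs = np.zeros((0, 2), dtype=int)
    lens = (
        np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        if len(pairs)
        else np.zeros(0)
    )
    return CellGraph(np.arange(len(xy)), xy, feats, pairs, lens)


class TestKdeDensity:
    def test_matches_bruteforce_gaussian_sum(self):
        xy = np.array([[0, 0], [10, 0], [0, 10], [25, 25], [40, 5]], dtype=float)
        bw = 10.0
        d = kde_density(xy, bandwidth=bw)
        raw = np.array(
            [
                sum(math.exp(-np.sum((p - q) ** 2) / (2 * bw**2)) for q in xy)
                for p in xy
            ]
        )
        expected = (raw - raw.min()) / (raw.max() - raw.min())
        assert np.allclose(d, expected, atol=1e-9)

    def test_grid_interior_denser_than_corners(self):
        gx, gy = np.meshgrid(np.arange(10) * 10.0, np.arange(10) * 10.0)
        xy = np.column_stack([gx.ravel(), gy.ravel()])
        d = kde_density(xy, bandwidth=15.0)
        corner = d[0]
        interior = d[np.argmin(np.linalg.norm(xy - [45, 45], axis=1))]
        assert interior > corner

    def test_isolated_point_has_minimum(self, rng):
        cluster = rng.normal(0, 5, (40, 2))
        xy = np.vstack([cluster, [[200.0, 200.0]]])
        d = kde_density(xy, bandwidth=10.0)
        assert d[-1] == 0.0


class TestSampleWindows:
    def test_deterministic_under_seed(self, rng):
        xy = rng.uniform(0, 300, (200, 2))
        dens = kde_density(xy, 25.0)
        cfg = GraphMatchConfig(n_windows=5)
        a = sample_windows(xy, dens, cfg, np.random.default_rng(3))
        b = sample_windows(xy, dens, cfg, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_zero_cutoff_allows_any_cell(self, rng):
        xy = rng.uniform(0, 300, (50, 2))
        cfg = GraphMatchConfig(n_windows=50, kde_density_cutoff=0.0)
        centers = sample_windows(xy, np.zeros(50), cfg, rng)
        assert len(centers) == 50

    def test_fallback_when_nothing_passes(self, rng):
        xy = rng.uniform(0, 300, (50, 2))
        dens = np.full(50, 0.1)
        cfg = GraphMatchConfig(n_windows=4, kde_density_cutoff=0.99)
        centers = sample_windows(xy, dens, cfg, rng)
        assert len(centers) > 0


class TestBuildSubgraph:
    def test_edge_threshold_rule(self):
        # mutual distances 10, 10, 20: exactly 2 edges below 15 um
        xy = np.array([[0, 0], [10, 0], [-10, 0]], dtype=float)
        g = build_subgraph(xy, np.array([0.0, 0.0]), window=100, edge_threshold=15)
        assert g.n_nodes == 3 and len(g.edges) == 2

    def test_zero_threshold_no_edges(self):
        xy = np.array([[0, 0], [1, 0]], dtype=float)
        g = build_subgraph(xy, np.array([0.0, 0.0]), window=100, edge_threshold=0)
        assert len(g.edges) == 0

    def test_node_cap_seeded(self, rng):
        xy = rng.uniform(-10, 10, (200, 2))
        a = build_subgraph(xy, np.zeros(2), 50, 15, max_nodes=50, rng=np.random.default_rng(1))
        b = build_subgraph(xy, np.zeros(2), 50, 15, max_nodes=50, rng=np.random.default_rng(1))
        assert a.n_nodes == 50
        assert np.array_equal(a.node_indices, b.node_indices)

    def test_missing_feature_errors(self, rng):
        t = CellTable(
            ids=np.arange(4), xy=rng.uniform(0, 5, (4, 2)),
            features=pd.DataFrame({"area": np.ones(4)}),
        )
        with pytest.raises(ConfigurationError, match="perimeter"):
            build_subgraph(t, np.zeros(2), 50, 15, feature_names=("perimeter",))


class TestMapWindowCenter:
    @pytest.mark.parametrize(
        "tf,center,expected",
        [
            (RigidTransform(), (3.0, 4.0), (3.0, 4.0)),
            (RigidTransform(dx=10.0), (3.0, 4.0), (13.0, 4.0)),
            (RigidTransform(theta=math.pi / 2), (1.0, 0.0), (0.0, 1.0)),
        ],
    )
    def test_mapping(self, tf, center, expected):
        assert np.allclose(map_window_center(np.array(center), tf), expected, atol=1e-12)


class TestAffinity:
    def test_identical_graphs_unit_diagonal(self, rng):
        xy = rng.uniform(0, 30, (6, 2))
        f = rng.normal(0, 1, (6, 2))
        g = _graph(xy, f)
        K = affinity_matrix(g, g)
        diag = K.diagonal().reshape(6, 6)
        assert np.allclose(np.diag(diag), 1.0)

    def test_equal_edge_lengths_unit_affinity(self):
        xy = np.array([[0, 0], [10, 0]], dtype=float)
        g1 = _graph(xy, np.array([[1.0], [2.0]]))
        g2 = _graph(xy + 100 * 0, np.array([[1.0], [2.0]]))
        K = affinity_matrix(g1, g2).toarray()
        # entry pairing edge (0,1) in both graphs under the identity assignment
        a, b = 0 * 2 + 0, 1 * 2 + 1
        assert K[a, b] == pytest.approx(1.0)

    def test_one_scale_unit_difference_kernel(self):
        assert node_affinity(np.array([1.0]), scale=1.0) == pytest.approx(math.exp(-0.5))

    def test_entries_bounded(self, rng):
        g1 = _graph(rng.uniform(0, 30, (5, 2)), rng.normal(0, 1, (5, 2)))
        g2 = _graph(rng.uniform(0, 30, (7, 2)), rng.normal(0, 1, (7, 2)))
        K = affinity_matrix(g1, g2)
        assert K.min() >= 0 and K.max() <= 1 + 1e-12

    def test_spatial_gate_zeroes_far_assignments(self, rng):
        g1 = _graph(np.array([[0.0, 0.0]]), np.array([[1.0]]))
        g2 = _graph(np.array([[0.0, 0.0], [200.0, 0.0]]), np.array([[1.0], [1.0]]))
        K = affinity_matrix(
            g1, g2, spatial_scale=15.0, source_xy_mapped=np.array([[0.0, 0.0]])
        ).toarray()
        assert K[0, 0] > 0  # near candidate
        assert K[1, 1] == 0  # 200 um away: gated out


def _score(K, pairs, nt):
    x = np.zeros(K.shape[0])
    for i, j in pairs:
        x[i * nt + j] = 1
    return float(x @ (K @ x))


def _oracle_best(Kd, ns, nt):
    best = -1.0
    for perm in itertools.permutations(range(nt), ns):
        x = np.zeros(ns * nt)
        for i, j in enumerate(perm):
            x[i * nt + j] = 1
        best = max(best, float(x @ Kd @ x))
    return best


class TestRrwmMatch:
    def test_identical_path_graphs_identity_assignment(self):
        xy = np.array([[0, 0], [10, 0], [20, 0]], dtype=float)
        f = np.array([[0.0], [1.0], [2.0]])
        g = _graph(xy, f)
        K = affinity_matrix(g, g)
        soft = rrwm_match(K, 3, 3)
        pairs = discretize(soft)
        assert _score(K, pairs, 3) >= _oracle_best(K.toarray(), 3, 3) - 1e-9
        assert np.array_equal(pairs, [[0, 0], [1, 1], [2, 2]])

    def test_single_node_graphs(self):
        g = _graph(np.array([[0.0, 0.0]]), np.array([[1.0]]))
        soft = rrwm_match(affinity_matrix(g, g), 1, 1)
        assert soft.shape == (1, 1) and soft[0, 0] == 1.0

    def test_recovers_known_permutation(self, rng):
        xy = rng.uniform(0, 30, (4, 2))
        f = rng.normal(0, 1, (4, 2))
        perm = rng.permutation(4)
        g1 = _graph(xy, f)
        g2 = _graph(xy[perm], f[perm])
        K = affinity_matrix(g1, g2)
        pairs = discretize(rrwm_match(K, 4, 4))
        inv = np.argsort(perm)
        assert np.array_equal(pairs[:, 1], inv[pairs[:, 0]])

    def test_matches_bruteforce_on_small_windowed_pairs(self, rng):
        hits = 0
        for _ in range(10):
            ns = int(rng.integers(2, 7))
            nt = int(rng.integers(ns, 7))
            xy = rng.uniform(0, 40, (ns, 2))
            f = np.column_stack(
                [rng.lognormal(np.log(23), 0.25, ns), rng.beta(18, 2, ns)]
            )
            txy = xy + rng.normal(0, 1, (ns, 2))
            extra = nt - ns
            txy = np.vstack([txy, rng.uniform(0, 40, (extra, 2))])
            tf = np.vstack(
                [f * rng.lognormal(0, 0.05, (ns, 2)),
                 np.column_stack([rng.lognormal(np.log(23), 0.25, extra), rng.beta(18, 2, extra)])]
            )
            shuffle = rng.permutation(nt)
            g1, g2 = _graph(xy, f), _graph(txy[shuffle], tf[shuffle])
            K = affinity_matrix(g1, g2, spatial_scale=15.0, source_xy_mapped=xy)
            pairs = discretize(rrwm_match(K, ns, nt))
            hits += _score(K, pairs, nt) >= _oracle_best(K.toarray(), ns, nt) - 1e-9
        assert hits == 10


class TestDiscretize:
    def test_bruteforce_2x2(self):
        pairs = discretize(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert np.array_equal(pairs, [[0, 1], [1, 0]])

    def test_identity_matrix(self):
        pairs = discretize(np.eye(3))
        assert np.array_equal(pairs, [[0, 0], [1, 1], [2, 2]])

    def test_rectangular_leaves_surplus_unmatched(self, rng):
        pairs = discretize(rng.uniform(size=(2, 3)))
        assert len(pairs) == 2
        assert len(set(pairs[:, 1])) == 2


class TestLpmFilter:
    def test_global_similarity_keeps_all(self, rng):
        xy = rng.uniform(0, 400, (80, 2))
        tf = RigidTransform(theta=0.3, dx=25.0, dy=-40.0)
        assert lpm_filter(xy, tf.apply(xy)).all()

    def test_scrambled_pair_dropped(self, rng):
        xy = rng.uniform(0, 400, (60, 2))
        tgt = xy + np.array([10.0, 5.0])
        tgt[17] = tgt[17] + np.array([150.0, -120.0])  # one gross mismatch
        kept = lpm_filter(xy, tgt)
        assert not kept[17]
        assert kept.sum() >= 55

    def test_too_few_pairs_keeps_all(self, rng):
        xy = rng.uniform(0, 50, (5, 2))
        kept = lpm_filter(xy, xy, k=8)
        assert kept.all()


class TestRefineTransform:
    def test_exact_recovery(self, rng):
        truth = RigidTransform(theta=0.1, dx=12.0, dy=-7.0)
        src = rng.uniform(0, 300, (40, 2))
        fit = refine_transform(src, truth.apply(src))
        assert np.allclose(fit.transform.matrix, truth.matrix, atol=1e-9)

    def test_coincident_pairs_degenerate(self):
        src = np.zeros((5, 2)) + 3.0
        src += np.arange(5)[:, None] * 1e-13
        with pytest.raises((RefinementFailedError, ValueError)):
            refine_transform(src, src)

    def test_outliers_trimmed(self, rng):
        truth = RigidTransform(theta=0.05, dx=8.0, dy=2.0)
        src = rng.uniform(0, 300, (100, 2))
        tgt = truth.apply(src)
        bad = rng.choice(100, 5, replace=False)
        tgt[bad] += rng.uniform(20, 60, (5, 2))
        fit = refine_transform(src, tgt)
        assert abs(math.degrees(fit.transform.theta - truth.theta)) < 0.1
        assert np.hypot(fit.transform.dx - truth.dx, fit.transform.dy - truth.dy) < 1.0


class TestMatchCells:
    def test_reproducible_under_seed(self, degraded_pair):
        src, tgt, _, _ = degraded_pair
        from cellalign.cpd import cpd_align

        cpd_tf, _ = cpd_align(src, tgt)
        cfg = GraphMatchConfig(n_windows=6)
        a = match_cells(src, tgt, cpd_tf, cfg, np.random.default_rng(9))
        b = match_cells(src, tgt, cpd_tf, cfg, np.random.default_rng(9))
        assert np.array_equal(a.source_index, b.source_index)
        assert np.array_equal(a.target_index, b.target_index)
        assert np.array_equal(a.kept, b.kept)
        assert a.n_kept <= len(a)

    def test_one_to_one_pairs(self, degraded_pair):
        src, tgt, _, _ = degraded_pair
        from cellalign.cpd import cpd_align

        cpd_tf, _ = cpd_align(src, tgt)
        m = match_cells(src, tgt, cpd_tf, GraphMatchConfig(n_windows=6), np.random.default_rng(2))
        assert len(np.unique(m.source_index)) == len(m)
        assert len(np.unique(m.target_index)) == len(m)
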