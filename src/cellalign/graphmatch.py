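"""Graph-matching refinement of a coarse centroid alignment.

CPD aligns the two clouds through a density model, so its correspondence is
soft; this module establishes explicit one-to-one cell correspondences and
re-estimates the transform from them. The procedure:

1. Rank source cells by local density (Gaussian KDE, min-max normalised) and
   sample window centers from cells with density ≥ 0.5 — dense subregions
   carry tissue architecture, sparse ones mostly segmentation noise.
2. For each sampled center, build a source subgraph from the cells inside a
   50 μm square window; map the center through the CPD transform and build
   the target subgraph from a 150 μm window (wider, to tolerate residual CPD
   error). Edges join cells closer than 15 μm.
3. Score all source-node × target-node assignments with a Lawler-form
   association (affinity) matrix: node affinity from morphology (perimeter,
   solidity), edge affinity from edge-length agreement; solve the resulting
   quadratic assignment relaxation with Reweighted Random Walks Matching
   (RRWM) and discretise the soft assignment with the Hungarian algorithm.
4. Pool matched pairs over all windows, drop pairs that break the spatial
   neighbourhood structure with Locality Preserving Matching (LPM), and fit
   the final similarity transform on the survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from sklearn.neighbors import KernelDensity

from .geometry import FitResult, LandmarkPairs, RigidTransform, fit_similarity
from .io_tables import CellTable

logger = logging.getLogger(__name__)

__all__ = [
    "GraphMatchConfig",
    "CellGraph",
    "MatchSet",
    "ConfigurationError",
    "RefinementFailedError",
    "kde_density",
    "sample_windows",
    "build_subgraph",
    "map_window_center",
    "affinity_matrix",
    "node_affinity",
    "rrwm_match",
    "discretize",
    "lpm_filter",
    "refine_transform",
    "match_cells",
]


class ConfigurationError(ValueError):
    """A required feature or setting is missing."""


class RefinementFailedError(RuntimeError):
    """Too few reliable pairs survived to fit a transform."""


@dataclass
class GraphMatchConfig:
    """Windowing, affinity and filtering controls (lengths in μm)."""

    source_window: float = 50.0
    target_window: float = 150.0
    edge_threshold: float = 15.0
    kde_bandwidth: float = 25.0
    kde_density_cutoff: float = 0.5
    n_windows: int = 32
    max_nodes_per_window: int = 300
    min_affinity: float = 0.2  # matches scoring below this are discarded
    node_features: tuple[str, ...] = ("perimeter", "solidity")
    node_feature_scale: float = 1.0
    edge_length_scale: float = 5.0
    spatial_scale: float = 15.0  # μm; prior on CPD-mapped position residual
    lpm_neighbors: int = 8
    lpm_lambda1: float = 6.0
    lpm_lambda2: float = 4.0
    rrwm_alpha: float = 0.2  # restart/jump probability
    rrwm_beta: float = 30.0  # reweighting inflation
    rrwm_max_iter: int = 300
    rrwm_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.target_window < self.source_window:
            raise ValueError("target_window must be >= source_window")
        for name in ("source_window", "target_window", "edge_threshold", "kde_bandwidth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lpm_neighbors < 1:
            raise ValueError("lpm_neighbors must be >= 1")


@dataclass
class CellGraph:
    """Proximity subgraph over a window of cells.

    ``node_indices`` index into the originating CellTable; ``xy`` are μm
    coordinates, ``node_features`` the raw (unstandardised) feature matrix,
    ``edges`` an (E, 2) array of node-index pairs with ``edge_lengths`` μm.
    """

    node_indices: np.ndarray
    xy: np.ndarray
    node_features: np.ndarray
    edges: np.ndarray
    edge_lengths: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_indices)


@dataclass
class MatchSet:
    """Putative one-to-one cell pairs with affinities and LPM keep-flags."""

    source_index: np.ndarray
    target_index: np.ndarray
    affinity: np.ndarray
    kept: np.ndarray

    def __post_init__(self) -> None:
        self.source_index = np.asarray(self.source_index, dtype=int)
        self.target_index = np.asarray(self.target_index, dtype=int)
        self.affinity = np.asarray(self.affinity, dtype=float)
        self.kept = np.asarray(self.kept, dtype=bool)
        n = len(self.source_index)
        if not (len(self.target_index) == len(self.affinity) == len(self.kept) == n):
            raise ValueError("MatchSet arrays must have equal length")

    def __len__(self) -> int:
        return len(self.source_index)

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


def kde_density(cells, bandwidth: float = 25.0) -> np.ndarray:
    """Per-cell local density by Gaussian KDE, min-max normalised to [0, 1]."""
    xy = cells.xy if isinstance(cells, CellTable) else np.asarray(cells, dtype=float)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if len(xy) < 2:
        logger.warning("kde_density: fewer than 2 cells; returning all-ones")
        return np.ones(len(xy))
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth).fit(xy)
    dens = np.exp(kde.score_samples(xy))
    lo, hi = dens.min(), dens.max()
    if hi - lo < 1e-300:
        return np.ones(len(xy))
    return (dens - lo) / (hi - lo)


def sample_windows(
    cells,
    densities: np.ndarray,
    config: GraphMatchConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw window centers (without replacement) from dense cells.

    Eligible cells have normalised density ≥ ``kde_density_cutoff``; if none
    qualify the top density decile is used instead (with a warning). Returns
    an (k, 2) array of centers, k = min(n_windows, eligible).
    """
    xy = cells.xy if isinstance(cells, CellTable) else np.asarray(cells, dtype=float)
    densities = np.asarray(densities, dtype=float)
    eligible = np.flatnonzero(densities >= config.kde_density_cutoff)
    if len(eligible) == 0:
        cutoff = np.quantile(densities, 0.9)
        eligible = np.flatnonzero(densities >= cutoff)
        logger.warning(
            "sample_windows: no cell reaches density %.2f; falling back to top decile (%d cells)",
            config.kde_density_cutoff,
            len(eligible),
        )
    k = min(config.n_windows, len(eligible))
    chosen = rng.choice(eligible, size=k, replace=False)
    return xy[np.sort(chosen)]


def build_subgraph(
    cells,
    center: np.ndarray,
    window: float,
    edge_threshold: float,
    max_nodes: int | None = None,
    rng: np.random.Generator | None = None,
    feature_names: tuple[str, ...] = (),
) -> CellGraph:
    """Cells inside the axis-aligned square window become a proximity graph.

    The window square has side ``window`` centered at ``center``; if more
    than ``max_nodes`` cells fall inside, a seeded random subset is kept.
    Edges join node pairs strictly closer than ``edge_threshold`` μm.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    is_table = isinstance(cells, CellTable)
    xy = cells.xy if is_table else np.asarray(cells, dtype=float)
    center = np.asarray(center, dtype=float)
    half = window / 2.0
    inside = np.flatnonzero(
        (np.abs(xy[:, 0] - center[0]) <= half) & (np.abs(xy[:, 1] - center[1]) <= half)
    )
    if max_nodes is not None and len(inside) > max_nodes:
        if rng is None:
            rng = np.random.default_rng(0)
        inside = np.sort(rng.choice(inside, size=max_nodes, replace=False))
    sub_xy = xy[inside]
    if feature_names:
        if not is_table:
            raise ConfigurationError("feature_names requires a CellTable input")
        missing = [f for f in feature_names if f not in cells.features.columns]
        if missing:
            raise ConfigurationError(f"cell table lacks required node feature(s): {missing}")
        feats = cells.features.iloc[inside][list(feature_names)].to_numpy(float)
    else:
        feats = np.zeros((len(inside), 0))
    if len(inside) >= 2 and edge_threshold > 0:
        pairs = cKDTree(sub_xy).query_pairs(r=edge_threshold, output_type="ndarray")
        if len(pairs):
            lengths = np.linalg.norm(sub_xy[pairs[:, 0]] - sub_xy[pairs[:, 1]], axis=1)
            strict = lengths < edge_threshold
            pairs, lengths = pairs[strict], lengths[strict]
        else:
            lengths = np.zeros(0)
    else:
        pairs = np.zeros((0, 2), dtype=int)
        lengths = np.zeros(0)
    return CellGraph(
        node_indices=inside,
        xy=sub_xy,
        node_features=feats,
        edges=pairs,
        edge_lengths=lengths,
    )


def map_window_center(center: np.ndarray, cpd_transform: RigidTransform) -> np.ndarray:
    """Map a source-window center into target space through the CPD transform."""
    return cpd_transform.apply(np.asarray(center, dtype=float))


def node_affinity(delta: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Gaussian kernel on (standardised) node-feature difference vectors."""
    delta = np.asarray(delta, dtype=float)
    sq = (delta**2).sum(axis=-1) if delta.ndim > 1 else delta**2
    return np.exp(-sq / (2.0 * scale**2))


def _standardise(feats: np.ndarray) -> np.ndarray:
    """Per-graph feature standardisation; constant features map to 0."""
    if feats.size == 0:
        return feats
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (feats - mu) / sd


def affinity_matrix(
    source: CellGraph,
    target: CellGraph,
    node_feature_scale: float = 1.0,
    edge_length_scale: float = 5.0,
    spatial_scale: float | None = None,
    source_xy_mapped: np.ndarray | None = None,
) -> sparse.csr_matrix:
    """Lawler-form association matrix K over candidate assignments.

    Assignment (i→j) indexes row/column a = i·n_target + j. Diagonal entries
    hold node affinities exp(−‖Δf‖²/2s²) on per-graph standardised features;
    off-diagonal entries, present only where source edge (i,k) pairs with
    target edge (j,l), hold edge affinities exp(−(len_ik − len_jl)²/2s_e²).
    All entries lie in [0, 1].

    When ``source_xy_mapped`` (source node coordinates mapped into target
    space by the coarse transform) and ``spatial_scale`` are given, node
    affinities are additionally damped by a Gaussian on the mapped-position
    residual. Morphology and edge lengths alone cannot disambiguate a small
    window against the much larger target window; the coarse alignment that
    placed the window is the prior that makes the assignment identifiable.
    """
    ns, nt = source.n_nodes, target.n_nodes
    if ns == 0 or nt == 0:
        raise ValueError("both graphs must be non-empty")
    if source.node_features.shape[1] != target.node_features.shape[1]:
        raise ConfigurationError("source and target graphs carry different feature sets")
    fs = _standardise(source.node_features)
    ft = _standardise(target.node_features)
    if fs.shape[1]:
        diffs = fs[:, None, :] - ft[None, :, :]
        node_aff = node_affinity(diffs, node_feature_scale)
    else:
        node_aff = np.ones((ns, nt))
    gate = None
    if source_xy_mapped is not None and spatial_scale is not None:
        mapped = np.asarray(source_xy_mapped, dtype=float)
        if mapped.shape != (ns, 2):
            raise ValueError("source_xy_mapped must be (n_source, 2)")
        d2 = ((mapped[:, None, :] - target.xy[None, :, :]) ** 2).sum(axis=2)
        node_aff = node_aff * np.exp(-d2 / (2.0 * spatial_scale**2))
        # assignments beyond 3 spatial scales are implausible outright: their
        # whole association row/column is zeroed so edge agreements cannot
        # resurrect a spatially impossible embedding
        gate = (d2 <= (3.0 * spatial_scale) ** 2).ravel()
        node_aff = node_aff * gate.reshape(ns, nt)

    rows: list[np.ndarray] = [np.arange(ns * nt)]
    cols: list[np.ndarray] = [np.arange(ns * nt)]
    vals: list[np.ndarray] = [node_aff.ravel()]

    Es, Et = len(source.edges), len(target.edges)
    if Es and Et:
        # all source-edge x target-edge combinations, both orientations
        si = np.repeat(source.edges[:, 0], Et)
        sk = np.repeat(source.edges[:, 1], Et)
        ls = np.repeat(source.edge_lengths, Et)
        tj = np.tile(target.edges[:, 0], Es)
        tl = np.tile(target.edges[:, 1], Es)
        lt = np.tile(target.edge_lengths, Es)
        eaff = np.exp(-((ls - lt) ** 2) / (2.0 * edge_length_scale**2))
        for a_i, a_k, b_j, b_l in ((si, sk, tj, tl), (si, sk, tl, tj)):
            r = a_i * nt + b_j
            c = a_k * nt + b_l
            # edge agreement is only as credible as its endpoint assignments:
            # modulate by the geometric mean of the two node affinities
            v = eaff * np.sqrt(node_aff.ravel()[r] * node_aff.ravel()[c])
            rows.extend([r, c])
            cols.extend([c, r])
            vals.extend([v, v])
    K = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ns * nt, ns * nt),
    ).tocsr()
    if gate is not None:
        D = sparse.diags(gate.astype(float))
        K = D @ K @ D
    return K


def _sinkhorn(mat: np.ndarray, n_iter: int = 10) -> np.ndarray:
    """Alternating normalisation towards a (rectangular) doubly-stochastic matrix.

    Rows are normalised to sum 1; column sums are only capped at 1 (full
    column normalisation is infeasible when the sides differ in size and
    washes out the signal on strongly rectangular problems).
    """
    m = mat.copy()
    for _ in range(n_iter):
        rs = m.sum(axis=1, keepdims=True)
        m = np.divide(m, rs, out=np.zeros_like(m), where=rs > 0)
        cs = m.sum(axis=0, keepdims=True)
        m = np.divide(m, cs, out=m, where=cs > 1)
    return m


def _rrwm_run(
    K: sparse.spmatrix,
    n_source: int,
    n_target: int,
    alpha: float,
    beta: float,
    x0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, bool]:
    """One reweighted-random-walk iteration to (near) convergence."""
    x = x0.copy()
    for _ in range(max_iter):
        y = K @ x
        tot = y.sum()
        if tot <= 0:
            return x, True  # no affinity mass anywhere; nothing to walk on
        y = y / tot
        q = np.exp(beta * (y / y.max())).reshape(n_source, n_target)
        q = _sinkhorn(q).ravel()
        qsum = q.sum()
        if qsum > 0:
            q = q / qsum
        x_new = (1.0 - alpha) * y + alpha * q
        x_new = x_new / x_new.sum()
        if np.abs(x_new - x).sum() < tol:
            return x_new, True
        x = x_new
    return x, False


def _assignment_score(K: sparse.spmatrix, pairs: np.ndarray, n_target: int) -> float:
    """Quadratic objective x'Kx of a hard assignment."""
    idx = pairs[:, 0] * n_target + pairs[:, 1]
    sub = K[idx][:, idx]
    return float(sub.sum())


def rrwm_match(
    K: sparse.spmatrix,
    n_source: int,
    n_target: int,
    config: GraphMatchConfig | None = None,
) -> np.ndarray:
    """Reweighted Random Walks Matching: soft assignment from the affinity matrix.

    Power iteration on the association graph (random walk step K·x) is
    interleaved with an inflation + Sinkhorn bistochastic reweighting, mixed
    in with jump probability ``rrwm_alpha``, until the assignment vector
    stabilises. The walk is restarted from several initial distributions and
    inflation strengths (a dense grid for small problems, where restarts are
    nearly free, two restarts at production sizes) and the converged iterate
    whose Hungarian discretisation scores highest on the quadratic objective
    is returned, as an (n_source, n_target) soft matrix scaled to [0, 1].
    """
    config = config or GraphMatchConfig()
    n = n_source * n_target
    if K.shape != (n, n):
        raise ValueError(f"affinity matrix shape {K.shape} != ({n}, {n})")
    if n == 1:
        return np.ones((1, 1))

    uniform = np.full(n, 1.0 / n)
    diag = np.asarray(K.diagonal(), dtype=float)
    inits: list[np.ndarray] = [uniform]
    if diag.sum() > 0:
        inits.append(diag / diag.sum())
        # seed concentrated on the node-affinity-only assignment
        x0 = np.full(n, 0.1 / n)
        for i, j in discretize(diag.reshape(n_source, n_target)):
            x0[i * n_target + j] += 1.0
        inits.append(x0 / x0.sum())
    if n <= 120:
        grid = [(a, b) for a in (config.rrwm_alpha, 0.5) for b in (3.0, 10.0, config.rrwm_beta, 100.0)]
        if n <= 36:
            # tiny association spaces: also seed the walk in every single
            # assignment's basin — near-ties between permutations are then
            # resolved by the quadratic score, not by walk dynamics
            for a_idx in range(n):
                x0 = np.full(n, 0.5 / n)
                x0[a_idx] += 0.5
                inits.append(x0 / x0.sum())
    else:
        grid = [(config.rrwm_alpha, config.rrwm_beta)]
        inits = inits[:2]

    best_soft: np.ndarray | None = None
    best_score = -np.inf
    best_converged = True
    for x0 in inits:
        for alpha, beta in grid:
            x, conv = _rrwm_run(
                K, n_source, n_target, alpha, beta, x0,
                config.rrwm_max_iter, config.rrwm_tol,
            )
            soft = x.reshape(n_source, n_target)
            score = _assignment_score(K, discretize(soft), n_target)
            if score > best_score:
                best_score, best_soft, best_converged = score, soft, conv
    if not best_converged:
        logger.warning("rrwm_match: iteration cap reached before convergence")
    mx = best_soft.max()
    return best_soft / mx if mx > 0 else best_soft


def discretize(soft: np.ndarray) -> np.ndarray:
    """Hungarian discretisation of a soft assignment: max-total-score one-to-one pairs.

    Rectangular matrices are allowed; surplus nodes on the larger side stay
    unmatched. Returns an (k, 2) array of (source, target) index pairs sorted
    by source index (ties resolved deterministically by the solver).
    """
    soft = np.asarray(soft, dtype=float)
    if not np.isfinite(soft).all():
        raise ValueError("assignment scores must be finite")
    rows, cols = linear_sum_assignment(-soft)
    order = np.argsort(rows, kind="stable")
    return np.column_stack([rows[order], cols[order]])


def lpm_filter(
    source_xy: np.ndarray,
    target_xy: np.ndarray,
    k: int = 8,
    lambda1: float = 6.0,
    lambda2: float = 4.0,
) -> np.ndarray:
    """Locality Preserving Matching: keep pairs whose neighbourhoods agree.

    For each putative pair, the cost counts how many of its ``k`` nearest
    neighbours among the pairs (by source-side position) are not also among
    its ``k`` nearest neighbours by target-side position. Correct matches
    under any similarity transform preserve neighbour sets exactly (cost 0);
    mismatches land in foreign neighbourhoods on the target side and incur
    a high cost. Two passes: a permissive first pass (cost ≤ lambda1) over
    all pairs, then a strict second pass (cost ≤ lambda2) with
    neighbourhoods recomputed among first-pass survivors. Returns a boolean
    keep-mask over the input pairs.
    """
    source_xy = np.asarray(source_xy, dtype=float)
    target_xy = np.asarray(target_xy, dtype=float)
    n = len(source_xy)
    if len(target_xy) != n:
        raise ValueError("source and target pair coordinates must align")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k + 2:
        logger.warning("lpm_filter: only %d pairs for k=%d; keeping all", n, k)
        return np.ones(n, dtype=bool)

    def costs(idx: np.ndarray, kk: int) -> np.ndarray:
        s = source_xy[idx]
        t = target_xy[idx]
        _, ns_ = cKDTree(s).query(s, k=kk + 1)
        _, nt_ = cKDTree(t).query(t, k=kk + 1)
        out = np.empty(len(idx))
        for i in range(len(idx)):
            a = set(ns_[i][ns_[i] != i][:kk].tolist())
            b = set(nt_[i][nt_[i] != i][:kk].tolist())
            out[i] = kk - len(a & b)
        return out

    all_idx = np.arange(n)
    c1 = costs(all_idx, k)
    pass1 = c1 <= lambda1
    survivors = all_idx[pass1]
    if len(survivors) < 3:
        logger.warning("lpm_filter: first pass left %d pairs; keeping first-pass result", len(survivors))
        return pass1
    k2 = min(k, len(survivors) - 1)
    c2 = costs(survivors, k2)
    lam2 = lambda2 * (k2 / k) if k2 < k else lambda2
    kept = np.zeros(n, dtype=bool)
    kept[survivors[c2 <= lam2]] = True
    return kept


def refine_transform(
    source_xy: np.ndarray,
    target_xy: np.ndarray,
    trim_rounds: int = 2,
) -> FitResult:
    """Final similarity fit (scale clamped to 1) on LPM-surviving cell pairs.

    The least-squares fit is made robust by ``trim_rounds`` rounds of
    residual trimming: after each fit, pairs whose residual exceeds
    3 × the MAD-based robust scale are dropped and the fit repeated.
    Residual mismatches that slip through LPM sit at cell-spacing offsets,
    an order of magnitude above centroid noise, so they separate cleanly
    in residual space. Set ``trim_rounds=0`` for a plain fit.
    """
    source_xy = np.asarray(source_xy, dtype=float)
    target_xy = np.asarray(target_xy, dtype=float)
    if len(source_xy) < 2:
        raise RefinementFailedError("fewer than 2 kept pairs; cannot fit a transform")
    try:
        fit = fit_similarity(
            LandmarkPairs(source=source_xy, target=target_xy), fix_scale=True
        )
        for _ in range(trim_rounds):
            resid = np.linalg.norm(target_xy - fit.transform.apply(source_xy), axis=1)
            scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            cut = 3.0 * max(scale, 0.5)  # floor keeps zero-noise data intact
            keep = resid <= max(cut, np.median(resid))
            if keep.sum() < max(3, 0.2 * len(source_xy)) or keep.all():
                break
            source_xy, target_xy = source_xy[keep], target_xy[keep]
            fit = fit_similarity(
                LandmarkPairs(source=source_xy, target=target_xy), fix_scale=True
            )
        return fit
    except ValueError as exc:
        raise RefinementFailedError(str(exc)) from exc


def match_cells(
    source: CellTable,
    target: CellTable,
    cpd_transform: RigidTransform,
    config: GraphMatchConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MatchSet:
    """Run the full windowed matching chain and return pooled, LPM-flagged pairs.

    Windows are sampled in the source (H&E) table, matched against CPD-mapped
    windows in the target (MxIF) table, pairs pooled across windows (a source
    cell matched in several overlapping windows keeps its highest-affinity
    pairing), then LPM flags unreliable pairs.
    """
    config = config or GraphMatchConfig()
    rng = rng or np.random.default_rng(0)
    for feat in config.node_features:
        for tab, name in ((source, "source"), (target, "target")):
            if feat not in tab.features.columns:
                raise ConfigurationError(f"{name} table lacks required node feature {feat!r}")

    densities = kde_density(source, config.kde_bandwidth)
    centers = sample_windows(source, densities, config, rng)

    pooled: dict[tuple[int, int], float] = {}
    for center in centers:
        sg = build_subgraph(
            source, center, config.source_window, config.edge_threshold,
            config.max_nodes_per_window, rng, config.node_features,
        )
        if sg.n_nodes == 0:
            continue
        tg = build_subgraph(
            target, map_window_center(center, cpd_transform), config.target_window,
            config.edge_threshold, config.max_nodes_per_window, rng, config.node_features,
        )
        if tg.n_nodes == 0:
            continue
        K = affinity_matrix(
            sg, tg, config.node_feature_scale, config.edge_length_scale,
            spatial_scale=config.spatial_scale,
            source_xy_mapped=cpd_transform.apply(sg.xy),
        )
        soft = rrwm_match(K, sg.n_nodes, tg.n_nodes, config)
        for i, j in discretize(soft):
            aff = float(soft[i, j])
            if aff < config.min_affinity:
                continue  # no credible candidate for this node in this window
            key = (int(sg.node_indices[i]), int(tg.node_indices[j]))
            pooled[key] = max(pooled.get(key, 0.0), aff)

    if not pooled:
        return MatchSet(
            source_index=np.array([], dtype=int),
            target_index=np.array([], dtype=int),
            affinity=np.array([], dtype=float),
            kept=np.array([], dtype=bool),
        )
    # enforce one-to-one across windows: best target per source, then best
    # source per target (overlapping target windows can double-claim a cell)
    best_s: dict[int, tuple[int, float]] = {}
    for (s_i, t_i), a in sorted(pooled.items()):
        if s_i not in best_s or a > best_s[s_i][1]:
            best_s[s_i] = (t_i, a)
    best_t: dict[int, tuple[int, float]] = {}
    for s_i, (t_i, a) in sorted(best_s.items()):
        if t_i not in best_t or a > best_t[t_i][1]:
            best_t[t_i] = (s_i, a)
    triples = sorted((s_i, t_i, a) for t_i, (s_i, a) in best_t.items())
    si = np.array([t[0] for t in triples], dtype=int)
    ti = np.array([t[1] for t in triples], dtype=int)
    aff = np.array([t[2] for t in triples], dtype=float)
    kept = lpm_filter(
        source.xy[si], target.xy[ti],
        k=config.lpm_neighbors, lambda1=config.lpm_lambda1, lambda2=config.lpm_lambda2,
    )
    return MatchSet(source_index=si, target_index=ti, affinity=aff, kept=kept)
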