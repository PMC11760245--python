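"""Synthetic TMA-core generator with known ground truth.

Emulates a pair of cell-segmentation exports of the same tissue-microarray
core seen through two modalities (H&E as the moving/source side, MxIF as the
fixed/target side): a disc of cell centroids with density hotspots, a known
similarity transform between the sides, and the segmentation failure modes
that make real multimodal tables disagree — centroid jitter, cell dropout
(tissue washed off or missed by the segmenter), over-segmentation (one cell
detected as two) and under-segmentation (two neighbours merged into one).

Per-cell morphology features (area, perimeter, solidity, mean stain
intensity) are drawn once per base cell and shared by both sides before
perturbation, so cross-modal feature concordance is high by construction
for surviving one-to-one cells. Landmark pairs are taken post-transform but
pre-jitter, so the returned ground-truth transform maps each source landmark
exactly onto its target landmark.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import LandmarkPairs, RigidTransform
from .io_tables import CellTable

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "generate_core_pair",
    "restained_like",
    "serial_like",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one virtual core pair.

    Defaults are the package's reference conditions: a 400 μm-radius core of
    1,000 cells, true transform θ=5°, t=(20, −10) μm, 1 μm centroid jitter,
    20% dropout per side and 2% split/merge rates.
    """

    n_cells: int = 1000
    core_radius: float = 400.0  # μm
    n_clusters: int = 6
    cluster_sd: float = 40.0  # μm
    cluster_fraction: float = 0.5
    true_transform: RigidTransform = field(
        default_factory=lambda: RigidTransform(theta=math.radians(5.0), dx=20.0, dy=-10.0)
    )
    jitter_sd: float = 1.0  # μm, per side
    dropout_rate: float = 0.2  # per side
    split_rate: float = 0.02
    merge_rate: float = 0.02
    feature_jitter: float = 0.05  # multiplicative log-sd per side
    n_landmarks: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 10:
            raise ValueError("n_cells must be >= 10")
        for name in ("dropout_rate", "split_rate", "merge_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.core_radius <= 0 or self.cluster_sd <= 0:
            raise ValueError("core_radius and cluster_sd must be positive")


def restained_like(seed: int = 0, **overrides) -> SyntheticConfig:
    """Conditions emulating a restained section: same physical cells in both
    modalities, so low dropout and tightly shared features."""
    base = SyntheticConfig(
        jitter_sd=0.5, dropout_rate=0.05, split_rate=0.01, merge_rate=0.01,
        feature_jitter=0.05, seed=seed,
    )
    return replace(base, **overrides)


def serial_like(seed: int = 0, **overrides) -> SyntheticConfig:
    """Conditions emulating an adjacent serial section: different physical
    cells, so heavy dropout and largely decorrelated features."""
    base = SyntheticConfig(
        jitter_sd=2.0, dropout_rate=0.4, split_rate=0.05, merge_rate=0.05,
        feature_jitter=0.6, seed=seed,
    )
    return replace(base, **overrides)


def _base_centroids(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform-in-disc background plus Gaussian density hotspots, clipped to the core."""
    R = config.core_radius
    center = np.array([R, R])  # keep coordinates positive (image convention)
    n_clustered = int(round(config.n_cells * config.cluster_fraction))
    n_bg = config.n_cells - n_clustered

    phi = rng.uniform(0, 2 * math.pi, n_bg)
    rad = R * np.sqrt(rng.uniform(0, 1, n_bg))
    bg = center + np.column_stack([rad * np.cos(phi), rad * np.sin(phi)])

    k = max(config.n_clusters, 1)
    cphi = rng.uniform(0, 2 * math.pi, k)
    crad = 0.7 * R * np.sqrt(rng.uniform(0, 1, k))
    cc = center + np.column_stack([crad * np.cos(cphi), crad * np.sin(cphi)])
    assign = rng.integers(0, k, n_clustered)
    cl = cc[assign] + rng.normal(0, config.cluster_sd, (n_clustered, 2))
    pts = np.vstack([bg, cl])
    # re-draw the rare points that escaped the core disc
    for _ in range(20):
        out = np.linalg.norm(pts - center, axis=1) > R
        if not out.any():
            break
        m = int(out.sum())
        phi = rng.uniform(0, 2 * math.pi, m)
        rad = R * np.sqrt(rng.uniform(0, 1, m))
        pts[out] = center + np.column_stack([rad * np.cos(phi), rad * np.sin(phi)])
    return pts


def _base_features(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Morphology/intensity features from lognormal/beta families.

    Nuclear area ~35 μm² median; perimeter tracks √area with a lognormal
    shape factor; solidity ~Beta peaked near 0.9; stain intensity arbitrary
    units.
    """
    area = rng.lognormal(mean=math.log(35.0), sigma=0.35, size=n)
    shape = rng.lognormal(mean=math.log(1.1), sigma=0.08, size=n)
    perimeter = 2.0 * np.sqrt(math.pi * area) * shape
    solidity = rng.beta(18.0, 2.0, size=n)
    intensity = rng.lognormal(mean=math.log(100.0), sigma=0.4, size=n)
    return pd.DataFrame(
        {"area": area, "perimeter": perimeter, "solidity": solidity, "intensity": intensity}
    )


def _perturb_side(
    xy: np.ndarray,
    features: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Apply dropout, splits, merges and jitter to one side.

    Returns (xy, features, origin) where origin[i] is the base-cell index a
    surviving unsplit/unmerged cell came from, or −1 for split/merge products.
    """
    n = len(xy)
    keep = rng.uniform(size=n) >= config.dropout_rate
    idx = np.flatnonzero(keep)
    xy = xy[idx].copy()
    feats = features.iloc[idx].reset_index(drop=True).copy()
    origin = idx.copy()

    # over-segmentation: one cell -> two children offset ±2 μm on a random axis
    split = rng.uniform(size=len(xy)) < config.split_rate
    if split.any():
        s = np.flatnonzero(split)
        ang = rng.uniform(0, 2 * math.pi, len(s))
        off = 2.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        child_a = xy[s] + off
        child_b = xy[s] - off
        child_feats = feats.iloc[s].copy()
        child_feats["area"] = child_feats["area"] / 2.0
        child_feats["perimeter"] = child_feats["perimeter"] / math.sqrt(2.0)
        xy = np.vstack([xy[~split], child_a, child_b])
        feats = pd.concat(
            [feats.iloc[~split], child_feats, child_feats], ignore_index=True
        )
        origin = np.concatenate(
            [origin[~split], np.full(2 * len(s), -1, dtype=int)]
        )

    # under-segmentation: a cell absorbs its nearest neighbour
    if config.merge_rate > 0 and len(xy) >= 4:
        merged = np.zeros(len(xy), dtype=bool)
        tree = cKDTree(xy)
        _, nn = tree.query(xy, k=2)
        candidates = np.flatnonzero(rng.uniform(size=len(xy)) < config.merge_rate)
        for i in candidates:
            j = nn[i, 1]
            if merged[i] or merged[j] or i == j:
                continue
            xy[i] = (xy[i] + xy[j]) / 2.0
            feats.iloc[i, feats.columns.get_loc("area")] += feats.iloc[j]["area"]
            merged[j] = True
            origin[i] = -1
        if merged.any():
            keep2 = ~merged
            xy = xy[keep2]
            feats = feats.iloc[keep2].reset_index(drop=True)
            origin = origin[keep2]

    xy = xy + rng.normal(0, config.jitter_sd, xy.shape) if config.jitter_sd > 0 else xy
    if config.feature_jitter > 0:
        noise = rng.lognormal(mean=0.0, sigma=config.feature_jitter, size=(len(feats), feats.shape[1]))
        feats = feats * noise
        feats["solidity"] = feats["solidity"].clip(upper=1.0)
    return xy, feats, origin


def _pick_landmarks(
    base_xy: np.ndarray,
    shared: np.ndarray,
    n_landmarks: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Greedy farthest-point selection of landmark base cells among survivors."""
    cand = np.flatnonzero(shared)
    first = cand[rng.integers(0, len(cand))]
    chosen = [first]
    d = np.linalg.norm(base_xy[cand] - base_xy[first], axis=1)
    while len(chosen) < n_landmarks:
        nxt = cand[int(np.argmax(d))]
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(base_xy[cand] - base_xy[nxt], axis=1))
    return np.array(chosen)


def generate_core_pair(
    config: SyntheticConfig | None = None,
) -> tuple[CellTable, CellTable, LandmarkPairs, RigidTransform]:
    """Generate (source, target, landmarks, ground-truth transform).

    The source table plays the H&E role, the target the MxIF role; the
    returned transform maps source→target. Landmarks are base cells that
    survived unperturbed on both sides, placed at their pre-jitter positions,
    so the ground-truth transform maps them exactly. If a configuration
    leaves fewer shared survivors than landmarks requested, generation is
    retried (new sub-seed) up to 5 times before raising.
    """
    config = config or SyntheticConfig()
    for attempt in range(5):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, attempt]))
        base_xy = _base_centroids(config, rng)
        base_feats = _base_features(config.n_cells, rng)

        src_xy, src_feats, src_origin = _perturb_side(base_xy, base_feats, config, rng)
        tgt_base = config.true_transform.apply(base_xy)
        tgt_xy, tgt_feats, tgt_origin = _perturb_side(tgt_base, base_feats, config, rng)

        shared = np.zeros(config.n_cells, dtype=bool)
        src_ok = src_origin[src_origin >= 0]
        tgt_ok = tgt_origin[tgt_origin >= 0]
        shared[np.intersect1d(src_ok, tgt_ok)] = True
        if shared.sum() >= config.n_landmarks:
            break
        logger.warning(
            "generate_core_pair: only %d shared survivors (< %d landmarks); retrying",
            shared.sum(), config.n_landmarks,
        )
    else:
        raise RuntimeError("could not generate enough shared surviving cells for landmarks")

    lm_base = _pick_landmarks(base_xy, shared, config.n_landmarks, rng)
    landmarks = LandmarkPairs(source=base_xy[lm_base], target=tgt_base[lm_base])

    source = CellTable(
        ids=np.array([f"s{i:05d}" for i in range(len(src_xy))]),
        xy=src_xy, features=src_feats, modality="HE",
    )
    target = CellTable(
        ids=np.array([f"t{i:05d}" for i in range(len(tgt_xy))]),
        xy=tgt_xy, features=tgt_feats, modality="MxIF",
    )
    return source, target, landmarks, config.true_transform
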