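"""Post-alignment cross-modal concordance statistics.

Once the two modalities share a coordinate frame, each source (H&E) cell is
paired with its nearest target (MxIF) cell and the pairing is triaged by how
many source cells claim each target: N=1 (clean one-to-one correspondence),
N=0 (no counterpart within the pairing radius — cell washed off, missed, or
outside the section), N>1 (several H&E cells map onto one MxIF cell, the
over/under-segmentation signature). Feature concordance (Pearson r) is then
computed on the clean N=1 pairs only, and coarse-grid density / tumor-
composition maps compare the two modalities region by region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .io_tables import CellTable

logger = logging.getLogger(__name__)

__all__ = [
    "PairedFeatures",
    "UndefinedCorrelationError",
    "nearest_pairing",
    "feature_correlation",
    "regional_density",
    "composition_similarity",
]


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (too few pairs or zero variance)."""


@dataclass
class PairedFeatures:
    """Nearest-cell pairing of aligned source cells onto target cells.

    One row per source cell: its nearest target index (−1 when nothing lies
    within the pairing radius), the pair distance in μm, and the
    correspondence class ``"N=0"`` / ``"N=1"`` / ``"N>1"``.
    """

    source_index: np.ndarray
    target_index: np.ndarray
    distance: np.ndarray
    n_class: np.ndarray

    def __len__(self) -> int:
        return len(self.source_index)

    @property
    def n1_mask(self) -> np.ndarray:
        return self.n_class == "N=1"

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.n_class, return_counts=True)
        out = {"N=0": 0, "N=1": 0, "N>1": 0}
        out.update(dict(zip(vals.tolist(), counts.tolist())))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source_index": self.source_index,
                "target_index": self.target_index,
                "distance_um": self.distance,
                "n_class": self.n_class,
            }
        )


def nearest_pairing(
    source_xy_aligned: np.ndarray,
    target_xy: np.ndarray,
    radius: float = 10.0,
) -> PairedFeatures:
    """Pair each aligned source cell with its nearest target cell within ``radius``.

    Classes: a target claimed by exactly one source, with the claim mutually
    nearest, yields N=1; a source with no target within the radius is N=0;
    targets claimed by several sources (or ambiguous non-mutual claims) are
    N>1 for every claiming source.
    """
    src = np.atleast_2d(np.asarray(source_xy_aligned, dtype=float))
    tgt = np.atleast_2d(np.asarray(target_xy, dtype=float))
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = len(src)
    if n == 0 or len(tgt) == 0:
        return PairedFeatures(
            source_index=np.arange(n),
            target_index=np.full(n, -1),
            distance=np.full(n, np.inf),
            n_class=np.full(n, "N=0", dtype=object),
        )
    tree = cKDTree(tgt)
    dist, nearest = tree.query(src, k=1)
    within = dist <= radius
    target_index = np.where(within, nearest, -1)

    claims = np.bincount(nearest[within], minlength=len(tgt))
    # mutual-nearest check for singleton claims
    src_tree = cKDTree(src)
    _, tgt_nearest_src = src_tree.query(tgt, k=1)

    n_class = np.full(n, "N=0", dtype=object)
    for i in np.flatnonzero(within):
        t = nearest[i]
        if claims[t] > 1:
            n_class[i] = "N>1"
        elif tgt_nearest_src[t] == i:
            n_class[i] = "N=1"
        else:
            n_class[i] = "N>1"  # claimed once but not mutually nearest: ambiguous
    return PairedFeatures(
        source_index=np.arange(n),
        target_index=target_index,
        distance=np.where(within, dist, np.inf),
        n_class=n_class,
    )


def feature_correlation(
    paired: PairedFeatures,
    source: CellTable,
    target: CellTable,
    feature: str,
) -> tuple[float, float, int]:
    """Pearson r (with two-sided p) of a feature across N=1 pairs.

    Returns (r, p, n) where n is the number of N=1 pairs used.
    """
    for tab, name in ((source, "source"), (target, "target")):
        if feature not in tab.features.columns:
            raise KeyError(f"feature {feature!r} missing from {name} table")
    m = paired.n1_mask
    si = paired.source_index[m]
    ti = paired.target_index[m]
    x = source.features[feature].to_numpy(float)[si]
    y = target.features[feature].to_numpy(float)[ti]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise UndefinedCorrelationError(f"only {len(x)} N=1 pairs with feature {feature!r}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError(f"zero variance in feature {feature!r}")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(len(x))


def _grid_edges(bounds: tuple[float, float, float, float], grid_size: float):
    xmin, ymin, xmax, ymax = bounds
    nx = max(1, int(np.ceil((xmax - xmin) / grid_size)))
    ny = max(1, int(np.ceil((ymax - ymin) / grid_size)))
    return (
        xmin + grid_size * np.arange(nx + 1),
        ymin + grid_size * np.arange(ny + 1),
    )


def regional_density(
    xy: np.ndarray,
    grid_size: float,
    bounds: tuple[float, float, float, float] | None = None,
) -> np.ndarray:
    """Cell counts over an axis-aligned grid (rows = y bins, cols = x bins).

    ``bounds`` = (xmin, ymin, xmax, ymax); defaults to the data bounding box.
    The grid sum always equals the number of cells inside the bounds.
    """
    if grid_size <= 0:
        raise ValueError("grid_size must be positive")
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if bounds is None:
        if len(xy) == 0:
            return np.zeros((1, 1))
        bounds = (xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max())
    xe, ye = _grid_edges(bounds, grid_size)
    # nudge the top edges so boundary points are counted
    xe = xe.copy(); ye = ye.copy()
    xe[-1] = max(xe[-1], bounds[2] + 1e-9)
    ye[-1] = max(ye[-1], bounds[3] + 1e-9)
    H, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=[ye, xe])
    return H


def composition_similarity(
    source_xy: np.ndarray,
    source_labels: np.ndarray,
    target_xy: np.ndarray,
    target_labels: np.ndarray,
    grid_size: float,
    min_cells: int = 5,
    bounds: tuple[float, float, float, float] | None = None,
) -> np.ndarray:
    """Region-by-region agreement of tumor proportions between modalities.

    Labels are binary (1 = tumor) per cell, supplied by upstream classifiers.
    Per grid region the similarity is 1 − |p_source − p_target| where p is
    the tumor proportion; regions with fewer than ``min_cells`` cells on
    either side are masked (NaN). Returns a masked similarity grid.
    """
    source_xy = np.atleast_2d(np.asarray(source_xy, dtype=float))
    target_xy = np.atleast_2d(np.asarray(target_xy, dtype=float))
    source_labels = np.asarray(source_labels)
    target_labels = np.asarray(target_labels)
    if len(source_labels) != len(source_xy) or len(target_labels) != len(target_xy):
        raise ValueError("labels must align with coordinates")
    if source_labels.size and not np.isin(source_labels, [0, 1]).all():
        raise ValueError("labels must be binary (0/1)")
    if target_labels.size and not np.isin(target_labels, [0, 1]).all():
        raise ValueError("labels must be binary (0/1)")
    if bounds is None:
        allxy = np.vstack([source_xy, target_xy])
        bounds = (allxy[:, 0].min(), allxy[:, 1].min(), allxy[:, 0].max(), allxy[:, 1].max())
    n_src = regional_density(source_xy, grid_size, bounds)
    n_tgt = regional_density(target_xy, grid_size, bounds)
    t_src = regional_density(source_xy[source_labels == 1], grid_size, bounds)
    t_tgt = regional_density(target_xy[target_labels == 1], grid_size, bounds)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_src = np.where(n_src > 0, t_src / n_src, np.nan)
        p_tgt = np.where(n_tgt > 0, t_tgt / n_tgt, np.nan)
    sim = 1.0 - np.abs(p_src - p_tgt)
    sim[(n_src < min_cells) | (n_tgt < min_cells)] = np.nan
    return sim
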