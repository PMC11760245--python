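"""Rigid Coherent Point Drift (CPD) for cell-centroid clouds.

One centroid cloud (the moving set, here H&E) is modelled as the centroids of
an isotropic Gaussian mixture; the other (fixed, here MxIF) as data drawn from
it, with a uniform component of weight ``w`` absorbing outliers — cells present
in one modality only. EM alternates soft correspondence (E-step) with a
closed-form similarity update (M-step): rotation from the SVD of the
posterior-weighted cross-covariance with a determinant correction that
excludes reflections, translation from weighted centroids, and a variance
update. Because both clouds are in micrometers the physical scale is 1, so by
default the scale is clamped (``fixed_scale=True``) and only rotation and
translation are estimated.

EM is a local optimiser and TMA cores may sit at arbitrary orientations, so
by default the fit is restarted from four coarse initial rotations
(0°/90°/180°/270°) and the restart with the lowest final negative
log-likelihood wins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .geometry import DegenerateConfigurationError, RigidTransform
from .io_tables import CellTable

logger = logging.getLogger(__name__)

__all__ = ["CpdConfig", "CpdState", "cpd_align", "supercell_reduce"]

_SIGMA2_FLOOR = 1e-10  # μm²; below this the clouds coincide to machine precision


@dataclass
class CpdConfig:
    """EM controls for rigid CPD.

    w : expected outlier fraction in [0, 1); cells without a counterpart.
    tolerance : relative change of the negative log-likelihood that stops EM.
    fixed_scale : clamp S=1 (valid once both clouds are in μm).
    orientation_restarts : also start EM at 90/180/270° and keep the best.
    """

    w: float = 0.1
    max_iterations: int = 150
    tolerance: float = 1e-6
    fixed_scale: bool = True
    orientation_restarts: bool = True
    probe_iterations: int = 40  # short probe per orientation before committing
    supercell_cap: int = 20_000

    def __post_init__(self) -> None:
        if not 0 <= self.w < 1:
            raise ValueError(f"w must be in [0, 1), got {self.w}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class CpdState:
    """Final EM state: selected transform, variance and objective trace."""

    transform: RigidTransform
    sigma2: float
    iterations: int
    objective: float  # final negative log-likelihood
    objective_history: list[float]
    converged: bool
    restart_angle_deg: float = 0.0
    all_histories: list[list[float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _as_xy(points) -> np.ndarray:
    xy = points.xy if isinstance(points, CellTable) else np.asarray(points, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected an (n, 2) coordinate array or CellTable")
    return xy


def _em_run(
    X: np.ndarray,
    Y: np.ndarray,
    R: np.ndarray,
    s: float,
    t: np.ndarray | None,
    sigma2: float | None,
    config: CpdConfig,
    max_iter: int,
) -> tuple[np.ndarray, float, np.ndarray, float, list[float], bool, list[str]]:
    """EM from the given state (t/sigma2 None → centroid shift / pooled variance init).

    Returns (R, s, t, sigma2, nll_history, converged, warnings); resumable —
    feeding the returned state back in continues the same monotone EM trace.
    """
    N, M = len(X), len(Y)
    D = 2
    warnings: list[str] = []
    if t is None:
        t = X.mean(axis=0) - s * R @ Y.mean(axis=0)
    if sigma2 is None:
        TY = s * Y @ R.T + t
        sigma2 = max(float(cdist(X, TY, "sqeuclidean").mean()) / D, _SIGMA2_FLOOR)
    w = config.w

    nll_history: list[float] = []
    converged = False
    nll_prev = np.inf
    for it in range(max_iter):
        TY = s * Y @ R.T + t
        D2 = cdist(X, TY, "sqeuclidean")
        c = (2 * math.pi * sigma2) ** (D / 2) * w / max(1 - w, 1e-300) * M / N
        G = np.exp(-D2 / (2 * sigma2))
        den = G.sum(axis=1) + c
        # p(x_n) = (1-w)/(M (2πσ²)^{D/2}) (Σ_m G + c); guard log(0)
        nll = float(
            -np.log(np.maximum(den, 1e-300)).sum()
            + N * (math.log(M) + (D / 2) * math.log(2 * math.pi * sigma2) - math.log(1 - w))
        )
        nll_history.append(nll)
        if abs(nll_prev - nll) < config.tolerance * max(1.0, abs(nll)):
            converged = True
            break
        nll_prev = nll

        P = G / den[:, None]  # (N, M) posterior over mixture components
        Np = float(P.sum())
        if Np <= 0:
            warnings.append("all points classified as outliers; stopping")
            break
        Pt1 = P.sum(axis=1)
        P1 = P.sum(axis=0)
        mu_x = X.T @ Pt1 / Np
        mu_y = Y.T @ P1 / Np
        Xc = X - mu_x
        Yc = Y - mu_y
        A = Xc.T @ (P @ Yc)
        U, S, Vt = np.linalg.svd(A)
        d = np.sign(np.linalg.det(U @ Vt)) or 1.0
        C = np.diag([1.0, d])
        R = U @ C @ Vt
        yPy = float((P1 * (Yc**2).sum(axis=1)).sum())
        if config.fixed_scale:
            s = 1.0
        else:
            s = float(np.trace(np.diag(S) @ C)) / yPy
            if s <= 0:
                raise DegenerateConfigurationError("non-positive scale in CPD M-step")
        t = mu_x - s * R @ mu_y
        xPx = float((Pt1 * (Xc**2).sum(axis=1)).sum())
        trAR = float(np.trace(np.diag(S) @ C))
        sigma2 = (xPx - 2 * s * trAR + s**2 * yPy) / (Np * D)
        if sigma2 < _SIGMA2_FLOOR:
            sigma2 = _SIGMA2_FLOOR
            warnings.append("sigma2 collapsed to floor; clouds aligned to machine precision")
            converged = True
            break
    return R, s, t, sigma2, nll_history, converged, warnings


def cpd_align(
    moving, fixed, config: CpdConfig | None = None
) -> tuple[RigidTransform, CpdState]:
    """Align the moving centroid cloud onto the fixed one by rigid CPD.

    Accepts CellTables or (n, 2) μm coordinate arrays; returns the transform
    mapping moving→fixed and the final EM state (objective trace included, one
    per orientation restart).
    """
    config = config or CpdConfig()
    Y = _as_xy(moving)  # GMM centroids
    X = _as_xy(fixed)  # data
    if len(X) < 2 or len(Y) < 2:
        raise DegenerateConfigurationError("CPD needs at least 2 points in each set")

    angles = [0.0, 90.0, 180.0, 270.0] if config.orientation_restarts else [0.0]
    probe = min(config.probe_iterations, config.max_iterations)
    candidates = []
    for ang in angles:
        a = math.radians(ang)
        R0 = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        state = _em_run(X, Y, R0, 1.0, None, None, config, probe)
        candidates.append((state[4][-1], ang, state))
    candidates.sort(key=lambda c: c[0])
    # continue only orientations whose probe objective is competitive: the
    # correct basin separates decisively within a few tens of EM iterations
    # (its objective falls by percents while wrong basins plateau)
    margin = 0.005 * max(1.0, abs(candidates[0][0]))
    remaining = config.max_iterations - probe
    best = None
    all_histories: list[list[float]] = []
    for rank, (nll_probe, ang, state) in enumerate(candidates):
        R, s, t, sigma2, hist, conv, warns = state
        if remaining > 0 and not conv and (rank == 0 or nll_probe <= candidates[0][0] + margin):
            R, s, t, sigma2, hist2, conv, warns2 = _em_run(
                X, Y, R, s, t, sigma2, config, remaining
            )
            hist = hist + hist2
            warns = warns + warns2
        all_histories.append(hist)
        if best is None or hist[-1] < best[0]:
            best = (hist[-1], R, s, t, sigma2, hist, conv, warns, ang)
    nll, R, s, t, sigma2, hist, conv, warns, ang = best
    transform = RigidTransform(
        theta=math.atan2(R[1, 0], R[0, 0]), scale=s, dx=float(t[0]), dy=float(t[1])
    )
    if not conv:
        warns = warns + ["EM reached max_iterations without meeting tolerance"]
        logger.warning("CPD: %s", warns[-1])
    state = CpdState(
        transform=transform,
        sigma2=sigma2,
        iterations=len(hist),
        objective=nll,
        objective_history=hist,
        converged=conv,
        restart_angle_deg=ang,
        all_histories=all_histories,
        warnings=warns,
    )
    return transform, state


def supercell_reduce(cells: CellTable, linkage_distance: float) -> CellTable:
    """Collapse proximity clusters of cells into pseudo-cells ("super-cells").

    Single-linkage clustering at the given distance (clusters are the
    connected components of the graph joining centroids within
    ``linkage_distance`` μm), iterated to a fixed point: if merged pseudo-cell
    centroids themselves fall within the linkage distance they are merged
    again, so re-reducing the output is a no-op. Each cluster becomes one
    pseudo-cell at the mean of its original member centroids; numeric
    features are averaged and a ``member_count`` feature is attached. Used to
    scale registration to whole-slide-sized inputs.
    """
    if linkage_distance <= 0:
        raise ValueError("linkage_distance must be positive")
    n = len(cells)
    if n == 0:
        return CellTable(
            ids=np.array([], dtype=object),
            xy=np.zeros((0, 2)),
            features=cells.features.iloc[:0].assign(member_count=np.array([], dtype=int)),
            modality=cells.modality,
        )
    labels = np.arange(n)  # original cell -> cluster
    xy_c = cells.xy
    weight = np.ones(len(xy_c))
    while True:
        m = len(xy_c)
        pairs = cKDTree(xy_c).query_pairs(r=linkage_distance, output_type="ndarray")
        if len(pairs) == 0:
            break
        adj = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
        )
        n_comp, lab2 = connected_components(adj, directed=False)
        if n_comp == m:
            break
        labels = lab2[labels]
        new_xy = np.zeros((n_comp, 2))
        np.add.at(new_xy, lab2, xy_c * weight[:, None])
        new_w = np.bincount(lab2, weights=weight, minlength=n_comp)
        xy_c = new_xy / new_w[:, None]
        weight = new_w
    n_comp = len(xy_c)
    counts = np.bincount(labels, minlength=n_comp)
    xy = xy_c

    numeric = cells.features.select_dtypes(include=[np.number])
    agg = numeric.groupby(labels).mean() if len(numeric.columns) else pd.DataFrame(index=range(n_comp))
    agg = agg.reindex(range(n_comp))
    agg["member_count"] = counts
    # singleton clusters keep their original id; merged clusters get a fresh one
    first_member = np.full(n_comp, -1, dtype=int)
    for idx in reversed(range(n)):
        first_member[labels[idx]] = idx
    ids = np.array(
        [
            str(cells.ids[first_member[k]]) if counts[k] == 1 else f"sc{k}"
            for k in range(n_comp)
        ],
        dtype=object,
    )
    return CellTable(
        ids=ids, xy=xy, features=agg.reset_index(drop=True), modality=cells.modality
    )
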