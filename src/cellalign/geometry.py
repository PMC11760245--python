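"""Similarity transforms, landmark-based fitting and alignment-error metrics.

The registration model throughout the package is a 4-degree-of-freedom
similarity transform acting on cell centroids expressed in micrometers:

    M = | S·cosθ  −S·sinθ  dx |
        | S·sinθ   S·cosθ  dy |
        |   0        0      1 |

with rotation ``theta`` (radians, counter-clockwise in the image frame:
origin top-left, x rightward, y downward), isotropic scale ``S > 0`` and
translation ``(dx, dy)`` in μm. Once both modalities' centroids have been
converted from pixels to micrometers the physical scale between them is 1,
so the pipeline runs the transform with the scale clamped to unity and only
θ, dx, dy are free.

Alignment quality against annotated landmark pairs is summarised by three
numbers: ΔD, the mean distance between each target landmark and the mapped
source landmark; ΔT, the difference in translation magnitude T = √(dx²+dy²)
between the estimated and the landmark-derived transform; and Δθ, the
absolute rotation-angle difference in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "RigidTransform",
    "LandmarkPairs",
    "AlignmentMetrics",
    "FitResult",
    "NotASimilarityError",
    "DegenerateConfigurationError",
    "matrix_from_params",
    "params_from_matrix",
    "pixels_to_microns",
    "fit_similarity",
    "evaluate_alignment",
]


class NotASimilarityError(ValueError):
    """The 2×2 linear block is not a positively-scaled rotation."""


class DegenerateConfigurationError(ValueError):
    """Landmark/point configuration does not determine a transform."""


def matrix_from_params(theta: float, scale: float, dx: float, dy: float) -> np.ndarray:
    """Assemble the 3×3 homogeneous similarity matrix from (θ, S, dx, dy)."""
    if not np.isfinite([theta, scale, dx, dy]).all():
        raise ValueError("transform parameters must be finite")
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    c, s = math.cos(theta), math.sin(theta)
    return np.array(
        [
            [scale * c, -scale * s, dx],
            [scale * s, scale * c, dy],
            [0.0, 0.0, 1.0],
        ]
    )


def params_from_matrix(M: np.ndarray, *, rtol: float = 1e-6) -> tuple[float, float, float, float]:
    """Recover (θ, S, dx, dy) from a homogeneous similarity matrix.

    θ is returned in (−π, π]. Reflections (negative determinant) and
    anisotropic linear blocks are rejected with :class:`NotASimilarityError`.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {M.shape}")
    A = M[:2, :2]
    det = float(np.linalg.det(A))
    if det <= 0:
        raise NotASimilarityError("linear block has non-positive determinant (reflection?)")
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[0] - sv[1] > rtol * sv[0]:
        raise NotASimilarityError("linear block is anisotropic, not a similarity")
    scale = math.sqrt(det)
    theta = math.atan2(A[1, 0], A[0, 0])
    return theta, scale, float(M[0, 2]), float(M[1, 2])


@dataclass(frozen=True)
class RigidTransform:
    """Similarity transform (θ, S, dx, dy); lengths in μm, θ in radians."""

    theta: float = 0.0
    scale: float = 1.0
    dx: float = 0.0
    dy: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.theta, self.scale, self.dx, self.dy]).all():
            raise ValueError("transform parameters must be finite")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @property
    def matrix(self) -> np.ndarray:
        return matrix_from_params(self.theta, self.scale, self.dx, self.dy)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.dx, self.dy])

    @property
    def translation_magnitude(self) -> float:
        """T = sqrt(dx² + dy²), μm."""
        return math.hypot(self.dx, self.dy)

    @property
    def theta_degrees(self) -> float:
        return math.degrees(self.theta)

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        theta, scale, dx, dy = params_from_matrix(M)
        return cls(theta=theta, scale=scale, dx=dx, dy=dy)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array (or a single (2,) point) through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c, s = math.cos(self.theta), math.sin(self.theta)
        R = np.array([[c, -s], [s, c]])
        out = self.scale * pts @ R.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` first, then `self`."""
        return RigidTransform.from_matrix(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix))

    def to_dict(self) -> dict:
        return {
            "theta_rad": self.theta,
            "scale": self.scale,
            "dx_um": self.dx,
            "dy_um": self.dy,
            "matrix": self.matrix.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            theta=float(d["theta_rad"]),
            scale=float(d["scale"]),
            dx=float(d["dx_um"]),
            dy=float(d["dy_um"]),
        )


@dataclass(frozen=True)
class LandmarkPairs:
    """Index-paired corresponding points annotated in both modalities (μm)."""

    source: np.ndarray  # (n, 2)
    target: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        src = np.atleast_2d(np.asarray(self.source, dtype=float))
        tgt = np.atleast_2d(np.asarray(self.target, dtype=float))
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "target", tgt)
        if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 2:
            raise ValueError("source and target must be (n, 2) arrays of equal length")
        if len(src) < 2:
            raise ValueError("at least 2 landmark pairs are required")
        if not (np.isfinite(src).all() and np.isfinite(tgt).all()):
            raise ValueError("landmark coordinates must be finite")
        # duplicate source points make the pairing ambiguous
        if len(np.unique(src.round(9), axis=0)) != len(src):
            raise ValueError("duplicate source landmarks")

    def __len__(self) -> int:
        return len(self.source)


@dataclass(frozen=True)
class AlignmentMetrics:
    """Landmark-based alignment errors: ΔD, ΔT in μm; Δθ in degrees."""

    delta_D: float
    delta_T: float
    delta_theta: float

    def to_dict(self) -> dict:
        return {
            "delta_D_um": self.delta_D,
            "delta_T_um": self.delta_T,
            "delta_theta_deg": self.delta_theta,
        }


class FitResult(NamedTuple):
    transform: RigidTransform
    rms_residual: float


def pixels_to_microns(points: np.ndarray, pixel_size: float) -> np.ndarray:
    """Convert pixel coordinates to μm by multiplying with the pixel size (μm/px)."""
    if not (np.isfinite(pixel_size) and pixel_size > 0):
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    return np.asarray(points, dtype=float) * float(pixel_size)


def fit_similarity(landmarks: LandmarkPairs, fix_scale: bool = False) -> FitResult:
    """Least-squares similarity transform mapping source landmarks onto targets.

    Minimises Σ‖target_i − M·source_i‖² over (θ, S, dx, dy) by the
    SVD/Procrustes closed form; with ``fix_scale`` the scale is clamped to 1
    and only θ, dx, dy are estimated (the pipeline's operating mode after
    micron conversion). The returned rotation never contains a reflection.
    """
    src = landmarks.source
    tgt = landmarks.target
    n = len(src)
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    sc = src - mu_s
    tc = tgt - mu_t
    var_s = float((sc**2).sum()) / n
    if var_s <= 1e-18:
        raise DegenerateConfigurationError("all source landmarks coincide")
    # cross-covariance target <- source
    A = tc.T @ sc / n
    U, S, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    C = np.diag([1.0, d if d != 0 else 1.0])
    R = U @ C @ Vt
    if fix_scale:
        scale = 1.0
    else:
        scale = float(np.trace(np.diag(S) @ C)) / var_s
        if scale <= 0:
            raise DegenerateConfigurationError("degenerate landmark configuration")
    t = mu_t - scale * R @ mu_s
    tf = RigidTransform(
        theta=math.atan2(R[1, 0], R[0, 0]), scale=scale, dx=float(t[0]), dy=float(t[1])
    )
    resid = tgt - tf.apply(src)
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return FitResult(tf, rms)


def evaluate_alignment(
    estimated: RigidTransform,
    ground_truth: RigidTransform,
    landmarks: LandmarkPairs,
) -> AlignmentMetrics:
    """Compute ΔD/ΔT/Δθ of an estimated transform against the ground truth.

    ΔD is the mean Euclidean distance between each target landmark and the
    corresponding source landmark mapped through the *estimated* transform.
    ΔT compares the translation magnitudes of the two transforms, and Δθ is
    the absolute angle difference wrapped to [0°, 180°].
    """
    if len(landmarks) == 0:
        raise ValueError("landmarks must be non-empty")
    mapped = estimated.apply(landmarks.source)
    delta_D = float(np.linalg.norm(landmarks.target - mapped, axis=1).mean())
    delta_T = abs(estimated.translation_magnitude - ground_truth.translation_magnitude)
    dtheta = math.degrees(estimated.theta - ground_truth.theta)
    dtheta = abs((dtheta + 180.0) % 360.0 - 180.0)
    return AlignmentMetrics(delta_D=delta_D, delta_T=delta_T, delta_theta=dtheta)
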