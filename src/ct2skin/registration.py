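"""Evaluation procedures: unique-point counting, trimmed ICP, coverage fields.

Three questions are answered about a reconstructed cloud:

* how many of its points are *unique* relative to another cloud (no neighbour
  within a radius — quantifies what the sagittal/coronal views add over the
  axial view alone);
* how well it registers rigidly onto a ground-truth surface (trimmed
  point-to-point ICP with farthest-point removal, reporting the RMS residual);
* which ground-truth regions it fails to cover (one-sided distance field with
  a cutoff flagging missing areas).

All neighbour searches run on a k-d tree (:class:`scipy.spatial.cKDTree`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "ICPParams",
    "unique_points",
    "icp_register",
    "coverage_field",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R x + t`` (R orthonormal, det +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not math.isclose(
            float(np.linalg.det(R)), 1.0, abs_tol=1e-9
        ):
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis: np.ndarray, angle_rad: float, translation: np.ndarray | None = None
    ) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(axis * angle_rad).as_matrix()
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return cls(rotation=R, translation=t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            rotation=self.rotation.T, translation=-self.rotation.T @ self.translation
        )

    def angle_rad(self) -> float:
        """Rotation magnitude."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass(frozen=True)
class ICPParams:
    """ICP settings: convergence on RMS improvement, per-iteration trimming to
    the closest ``overlap_fraction`` of correspondences (farthest-point
    removal), and a seeded cap on the number of source points used."""

    rms_delta_mm: float = 1e-4
    overlap_fraction: float = 0.90
    max_samples: Optional[int] = None
    max_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in (0, 1]")
        if self.max_iterations <= 0:
            raise ValueError("max_iterations must be positive")


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    rms_mm: float
    iterations: int
    converged: bool
    rms_history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.rms_mm < 0:
            raise ValueError("rms_mm must be non-negative")


def unique_points(
    query: PointCloud, reference: PointCloud, radius_mm: float = 1.0
) -> tuple[int, PointCloud]:
    """Count query points with no reference point within ``radius_mm``.

    The ball is closed: a reference point at exactly ``radius_mm`` means the
    query point is *not* unique.  Returns the count and the unique subset;
    the unique percentage is ``count / len(query)``.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("both clouds must be nonempty")
    tree = cKDTree(reference.points)
    dists, _ = tree.query(query.points, k=1)
    mask = dists > radius_mm
    subset = PointCloud(points=query.points[mask], source_plane=query.source_plane)
    return int(mask.sum()), subset


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid motion mapping ``src`` onto ``dst`` (orthogonal
    Procrustes with reflection guard)."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, S, Vt = np.linalg.svd(H)
    if S[-1] < 1e-12 * max(S[0], 1.0):
        raise ValueError("degenerate geometry: rank-deficient cross-covariance")
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ D @ U.T
    t = mu_d - R @ mu_s
    return RigidTransform(rotation=R, translation=t)


def icp_register(
    source: PointCloud,
    target: PointCloud,
    params: ICPParams = ICPParams(),
    init: RigidTransform | None = None,
) -> RegistrationResult:
    """Trimmed point-to-point ICP registering ``source`` onto ``target``.

    Each iteration finds nearest-neighbour correspondences, keeps the closest
    ``overlap_fraction`` of them (farthest-point removal), and solves the
    closed-form least-squares rigid update.  Iteration stops when the RMS of
    the retained correspondences improves by less than ``rms_delta_mm`` or
    after ``max_iterations``.  When ``max_samples`` caps the source, the
    subsample is drawn with the seeded RNG and is reproducible.

    ``init`` stands in for the coarse manual alignment that precedes fine
    registration; identity when omitted.
    """
    if len(source) < 3 or len(target) < 3:
        raise ValueError("both clouds need at least 3 points")
    init = init or RigidTransform.identity()

    src = source.points
    if params.max_samples is not None and len(src) > params.max_samples:
        rng = np.random.default_rng(params.seed)
        src = src[rng.choice(len(src), size=params.max_samples, replace=False)]

    tree = cKDTree(target.points)
    transform = init
    current = transform.apply(src)
    n_keep = max(3, int(math.ceil(params.overlap_fraction * len(src))))

    rms_history: list[float] = []
    prev_rms = math.inf
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        dists, idx = tree.query(current)
        keep = np.argsort(dists)[:n_keep]
        rms = float(np.sqrt(np.mean(dists[keep] ** 2)))
        rms_history.append(rms)
        if prev_rms - rms < params.rms_delta_mm:
            converged = True
            break
        prev_rms = rms
        update = _kabsch(current[keep], target.points[idx[keep]])
        transform = update.compose(transform)
        current = transform.apply(src)

    dists, _ = tree.query(current)
    final_rms = float(np.sqrt(np.mean(np.sort(dists)[:n_keep] ** 2)))
    return RegistrationResult(
        transform=transform,
        rms_mm=final_rms,
        iterations=iterations,
        converged=converged,
        rms_history=tuple(rms_history),
    )


def coverage_field(
    gt_cloud: PointCloud, test_cloud: PointCloud, cutoff_mm: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided distance field from ground truth to a reconstructed cloud.

    For each GT point, the distance to the nearest test point; points at least
    ``cutoff_mm`` away are flagged as *uncovered*.  Returns the distance array
    and the boolean flag array (flagged fraction = ``flags.mean()``).  An
    empty test cloud flags everything at infinite distance.
    """
    if len(gt_cloud) == 0:
        raise ValueError("ground-truth cloud must be nonempty")
    if len(test_cloud) == 0:
        dists = np.full(len(gt_cloud), np.inf)
        return dists, np.ones(len(gt_cloud), dtype=bool)
    tree = cKDTree(test_cloud.points)
    dists, _ = tree.query(gt_cloud.points)
    return dists, dists >= cutoff_mm
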