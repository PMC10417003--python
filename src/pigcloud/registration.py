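"""Rigid point-cloud registration and cloud-similarity scoring.

Point-to-point ICP with nearest-neighbour correspondences (cKDTree) and a
closed-form Kabsch/SVD rigid fit per iteration. After alignment, agreement
between a lifted cloud and a reference (e.g. manually annotated) cloud is
summarised as the fraction of points whose nearest neighbour in the other
cloud lies within a distance ``tau`` — reported in the source→target
direction and as the symmetric mean of both directions.

The similarity score is this package's own documented choice of agreement
metric; it is configurable via ``tau`` (default 1 cm, commensurate with
animal-scale geometry viewed from ~3 m).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, EmptyCloudError
from .geometry import PointCloud

__all__ = [
    "RigidTransform",
    "AlignmentReport",
    "SimilarityScore",
    "kabsch_align",
    "icp",
    "cloud_similarity",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p -> R p + t`` (rotation + translation, no scale)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rotation", np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        )
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=np.float64).reshape(3)
        )
        r = self.rotation
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            rotation=self.rotation.T, translation=-self.rotation.T @ self.translation
        )

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


class SimilarityScore(NamedTuple):
    """Inlier-fraction agreement between two aligned clouds at threshold tau."""

    directed: float
    reverse: float
    symmetric: float
    tau: float


@dataclass
class AlignmentReport:
    """Outcome of an ICP run: transform, fit quality and similarity."""

    transform: RigidTransform
    rmsd: float
    iterations: int
    converged: bool
    similarity: float
    rmsd_history: list[float]

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError("similarity must lie in [0, 1]")


def kabsch_align(
    src: PointCloud | np.ndarray,
    dst: PointCloud | np.ndarray,
    correspondences: np.ndarray | list[tuple[int, int]] | None = None,
) -> RigidTransform:
    """Closed-form least-squares rigid fit over corresponded point pairs.

    Minimises sum ||R s_i + t - d_i||^2 via SVD of the cross-covariance
    (Kabsch). With ``correspondences=None`` the clouds are paired by index.

    Raises
    ------
    DegenerateGeometryError
        With fewer than 3 pairs, or when the paired source points are
        collinear (the rotation about their axis is unobservable).
    """
    s = src.points if isinstance(src, PointCloud) else np.asarray(src, dtype=np.float64)
    d = dst.points if isinstance(dst, PointCloud) else np.asarray(dst, dtype=np.float64)
    if correspondences is not None:
        pairs = np.asarray(correspondences, dtype=np.intp).reshape(-1, 2)
        s = s[pairs[:, 0]]
        d = d[pairs[:, 1]]
    if len(s) != len(d):
        raise DegenerateGeometryError("source and target pair counts differ")
    if len(s) < 3:
        raise DegenerateGeometryError(f"need >=3 correspondences, got {len(s)}")
    s_mean = s.mean(axis=0)
    d_mean = d.mean(axis=0)
    s0 = s - s_mean
    d0 = d - d_mean
    # Collinear source points leave one rotational degree of freedom free.
    sv = np.linalg.svd(s0, compute_uv=False)
    if sv[1] <= max(1e-12, 1e-9 * sv[0]):
        raise DegenerateGeometryError("correspondences are collinear")
    h = s0.T @ d0
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, sign if sign != 0 else 1.0])
    r = vt.T @ diag @ u.T
    t = d_mean - r @ s_mean
    return RigidTransform(rotation=r, translation=t)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def icp(
    src: PointCloud,
    dst: PointCloud,
    max_iterations: int = 50,
    tol: float = 1e-6,
    max_corr_dist: float = 0.05,
    tau: float = 0.01,
) -> AlignmentReport:
    """Point-to-point ICP aligning ``src`` onto ``dst``.

    Alternates nearest-neighbour correspondence (rejecting pairs farther
    than ``max_corr_dist``) with a Kabsch rigid fit until the correspondence
    RMSD improves by less than ``tol`` metres or ``max_iterations`` is hit.
    The RMSD over matched pairs is non-increasing across iterations; the
    report carries the per-iteration history.

    The report's ``similarity`` is the directed inlier fraction at ``tau``
    after alignment (see :func:`cloud_similarity`); it is 0 when no
    correspondences ever formed within ``max_corr_dist``.
    """
    if len(src) == 0 or len(dst) == 0:
        raise EmptyCloudError("ICP requires two non-empty clouds")
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    tree = cKDTree(dst.points)
    transform = RigidTransform.identity()
    moved = src.points.copy()
    history: list[float] = []
    converged = False
    prev_rmsd: float | None = None
    iterations = 0
    matched_any = False
    for _ in range(max_iterations):
        dist, idx = tree.query(moved, distance_upper_bound=max_corr_dist)
        keep = np.isfinite(dist)
        if keep.sum() < 3:
            break
        matched_any = True
        iterations += 1
        pairs_src = moved[keep]
        pairs_dst = dst.points[idx[keep]]
        current = _rmsd(pairs_src, pairs_dst)
        try:
            step = kabsch_align(pairs_src, pairs_dst)
        except DegenerateGeometryError:
            history.append(current)
            break
        moved = step.apply(moved)
        transform = step.compose(transform)
        new_rmsd = _rmsd(step.apply(pairs_src), pairs_dst)
        # The Kabsch step minimises over fixed pairs, so it cannot worsen.
        rmsd = min(new_rmsd, current)
        history.append(rmsd)
        if prev_rmsd is not None and prev_rmsd - rmsd < tol:
            converged = True
            break
        if rmsd < tol:
            converged = True
            break
        prev_rmsd = rmsd
    if not matched_any:
        return AlignmentReport(
            transform=RigidTransform.identity(),
            rmsd=0.0,
            iterations=0,
            converged=False,
            similarity=0.0,
            rmsd_history=[],
        )
    aligned = PointCloud(points=moved)
    sim = cloud_similarity(aligned, dst, tau=tau)
    return AlignmentReport(
        transform=transform,
        rmsd=history[-1] if history else 0.0,
        iterations=iterations,
        converged=converged,
        similarity=sim.directed,
        rmsd_history=history,
    )


def cloud_similarity(
    src: PointCloud, dst: PointCloud, tau: float = 0.01
) -> SimilarityScore:
    """Inlier-fraction agreement between two already-aligned clouds.

    Directed score: fraction of ``src`` points whose nearest ``dst``
    neighbour lies within ``tau`` metres. The symmetric score is the mean of
    the two directed scores. Call after :func:`icp` (or on clouds sharing a
    camera frame).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if len(src) == 0 or len(dst) == 0:
        raise EmptyCloudError("similarity requires two non-empty clouds")
    d_fwd, _ = cKDTree(dst.points).query(src.points)
    d_rev, _ = cKDTree(src.points).query(dst.points)
    directed = float(np.mean(d_fwd <= tau))
    reverse = float(np.mean(d_rev <= tau))
    return SimilarityScore(
        directed=directed,
        reverse=reverse,
        symmetric=(directed + reverse) / 2.0,
        tau=tau,
    )
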