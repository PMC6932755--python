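"""Rigid chewing kinematics of the mandibular block.

The chewing stroke is a quasi-static rigid rotation of the mandibular block
about a single fixed center C_ROT located r mm above the midpoint of the
occlusal interface, C_ROT = (width/2, r).  The stroke runs posterior →
anterior (left → right): it starts with the block overhanging the maxilla
posteriorly by ``start_overhang`` mm (θ_0 = −asin(start_overhang/r)) and
ends overhanging anteriorly (θ_N = +asin(end_overhang/r)), so the interface
midpoint travels ≈ start+end overhang mm horizontally and lifts by
r(1−cosθ) at the stroke ends.  The return stroke is instantaneous and
unloaded (no contact, no wear).

Per-increment sliding at a surface point is the exact arc length
|p − C_ROT|·Δθ.  A degenerate :class:`TranslationPath` provides the
C_ROT → ∞ limit used in tests: identity poses with the per-increment slide
r·Δθ held fixed, i.e. uniform grinding without pose change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class RigidTransform:
    """Rotation by ``angle`` about ``center`` plus an optional translation."""

    angle: float
    center: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float))

    @property
    def is_identity(self) -> bool:
        return self.angle == 0.0 and not self.translation.any()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 2) array (or a single 2-vector) of points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c, s = np.cos(self.angle), np.sin(self.angle)
        rel = pts - self.center
        out = np.column_stack([c * rel[:, 0] - s * rel[:, 1],
                               s * rel[:, 0] + c * rel[:, 1]])
        out += self.center + self.translation
        return out.reshape(np.shape(points))


@dataclass(frozen=True)
class KinematicPath:
    """Discretized rotation stroke: angles θ_0 < … < θ_N about C_ROT."""

    c_rot: np.ndarray
    radius: float
    thetas: np.ndarray
    dtheta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "c_rot", np.asarray(self.c_rot, dtype=float))
        object.__setattr__(self, "thetas", np.asarray(self.thetas, dtype=float))

    @property
    def n_increments(self) -> int:
        return len(self.thetas) - 1

    def pose_at(self, i: int) -> RigidTransform:
        if not 0 <= i <= self.n_increments:
            raise IndexError(f"pose index {i} outside [0, {self.n_increments}]")
        return RigidTransform(float(self.thetas[i]), self.c_rot)

    def midpose_at(self, i: int) -> RigidTransform:
        """Pose at the midpoint of increment i (between θ_{i−1} and θ_i)."""
        if not 1 <= i <= self.n_increments:
            raise IndexError(f"increment index {i} outside [1, {self.n_increments}]")
        return RigidTransform(0.5 * float(self.thetas[i - 1] + self.thetas[i]),
                              self.c_rot)

    def sliding_increments(self, points: np.ndarray, i: int) -> np.ndarray:
        """Arc length |p − C_ROT|·Δθ for each point, exact for rigid rotation."""
        if i < 1:
            raise IndexError("sliding increments are defined for i >= 1")
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.linalg.norm(pts - self.c_rot, axis=1) * self.dtheta

    @property
    def stroke_slide(self) -> float:
        """Total slide of the interface midpoint over one stroke (mm)."""
        return self.radius * float(self.thetas[-1] - self.thetas[0])


@dataclass(frozen=True)
class TranslationPath:
    """Degenerate C_ROT → ∞ grinding path: identity poses, uniform sliding.

    The r → ∞ limit of the rotation stroke taken with the per-increment
    slide r·Δθ held fixed: poses collapse to the identity while every
    surface point accrues the same sliding distance per increment.  Flat
    surfaces are a fixed point of wear under this path, which is what makes
    it the degenerate reference case for testing.
    """

    total_slide: float
    n_increments: int

    def __post_init__(self) -> None:
        if self.total_slide < 0:
            raise ConfigurationError("total_slide must be >= 0")
        if self.n_increments < 1:
            raise ConfigurationError("n_increments must be >= 1")

    def pose_at(self, i: int) -> RigidTransform:
        if not 0 <= i <= self.n_increments:
            raise IndexError(f"pose index {i} outside [0, {self.n_increments}]")
        return RigidTransform(0.0, np.zeros(2))

    midpose_at = pose_at

    def sliding_increments(self, points: np.ndarray, i: int) -> np.ndarray:
        if i < 1:
            raise IndexError("sliding increments are defined for i >= 1")
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.full(pts.shape[0], self.total_slide / self.n_increments)

    @property
    def stroke_slide(self) -> float:
        return self.total_slide


def make_path(
    r: float,
    width: float,
    start_overhang: float,
    end_overhang: float,
    n_increments: int,
) -> KinematicPath:
    """Build the rotation stroke from the two overhangs.

    θ_0 = −asin(start_overhang/r) and θ_N = +asin(end_overhang/r), so the
    horizontal travel of the interface midpoint at θ_0 is exactly
    −start_overhang.  Δθ is uniform.
    """
    if r <= width / 2:
        raise ConfigurationError("rotation radius must exceed half the block width")
    for name, ov in (("start_overhang", start_overhang),
                     ("end_overhang", end_overhang)):
        if not 0 < ov < width:
            raise ConfigurationError(f"{name} must lie in (0, width)")
        if ov >= r:
            raise ConfigurationError(f"{name} must be smaller than the radius")
    if n_increments < 2:
        raise ConfigurationError("n_increments must be >= 2")

    theta0 = -float(np.arcsin(start_overhang / r))
    theta_n = float(np.arcsin(end_overhang / r))
    thetas = np.linspace(theta0, theta_n, n_increments + 1)
    dtheta = (theta_n - theta0) / n_increments
    return KinematicPath(np.array([width / 2.0, r]), float(r), thetas, dtheta)


# spec-style free-function surface -----------------------------------------

def pose_at(path, i: int) -> RigidTransform:
    return path.pose_at(i)


def sliding_increment(path, node_position, i: int) -> float:
    """Sliding distance of a single surface point over increment i."""
    return float(path.sliding_increments(np.asarray(node_position, float), i)[0])
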