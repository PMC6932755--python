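"""Quantify emergent occlusal curvature.

The simulator's qualitative output is a pair of worn surface profiles.  This
module turns them into numbers: a least-squares circle fit (center, radius,
RMS radial residual), the signed sagitta depth of a profile relative to its
endpoint chord, the residual conformity gap between the two surfaces at the
centered pose, and a comparison table across rotation radii.

Sign convention (fixed here, used package-wide): sagitta depth is positive
when the profile deviates *downward* from its chord.  For the mandibular
block (occlusal surface on top, opposing block above) a downward mid-profile
dip is a concavity opening toward the maxilla — the curve-of-Spee sense.
For the maxillary block (occlusal surface on the bottom) a downward dip is a
convexity protruding toward the mandible — the compensating-curve sense.
Both developing curves therefore have positive depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

#: Fitted curvature (1/mm) below which a profile is reported as flat.
FLAT_CURVATURE = 1e-6

#: Cumulative wear (mm) above which a surface node counts as "ever contacted".
CONTACT_WEAR_EPS = 1e-9


@dataclass(frozen=True)
class SurfaceProfile:
    """Ordered (x, y) occlusal-surface polyline of one block, in mm.

    ``x`` must be strictly increasing (surface nodes keep their column
    alignment for the whole simulation).
    """

    points: np.ndarray
    role: str = "mandibular"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise DataError(f"profile points must be (n, 2), got {pts.shape}")
        if pts.shape[0] >= 2 and not np.all(np.diff(pts[:, 0]) > 0):
            raise DataError("profile x-coordinates must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class CurveFit:
    """Circle fit of a surface profile.

    ``flat`` is set when the fitted curvature falls below
    :data:`FLAT_CURVATURE` (or the points are collinear); ``radius`` is then
    ``inf`` and ``center`` is ``None``.
    """

    center: np.ndarray | None
    radius: float
    rms_residual: float
    sagitta: float
    chord_length: float
    flat: bool = False


def _chord_deviation(points: np.ndarray) -> np.ndarray:
    """Signed perpendicular deviation from the endpoint chord.

    Positive values are *downward* (toward −y) for a left-to-right chord.
    """
    p0, p1 = points[0], points[-1]
    chord = p1 - p0
    norm = float(np.hypot(*chord))
    if norm == 0.0:
        raise DataError("degenerate chord: identical endpoints")
    rel = points - p0
    # z-component of chord × rel: positive when the point lies above the
    # chord direction; negate so that downward deviation is positive.
    return -(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / norm


def sagitta_depth(profile: SurfaceProfile) -> float:
    """Signed sagitta: extreme perpendicular deviation from the endpoint chord.

    Positive = deviation toward the opposing block (downward for both block
    roles, see module docstring).  A flat profile returns 0.
    """
    if len(profile) < 2:
        raise DataError("sagitta needs at least 2 points")
    dev = _chord_deviation(profile.points)
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def _kasa_fit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Algebraic (Kåsa) circle fit; None if the system is rank deficient."""
    a = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 3:
        return None
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx * cx + cy * cy
    if r2 <= 0.0:
        return None
    return np.array([cx, cy]), float(np.sqrt(r2))


def _gauss_newton_step(
    pts: np.ndarray, center: np.ndarray, radius: float
) -> tuple[np.ndarray, float]:
    """One geometric (Gauss–Newton) refinement pass on (cx, cy, R)."""
    d = np.linalg.norm(pts - center, axis=1)
    d = np.where(d == 0.0, 1e-300, d)
    res = d - radius
    jac = np.empty((pts.shape[0], 3))
    jac[:, 0] = -(pts[:, 0] - center[0]) / d
    jac[:, 1] = -(pts[:, 1] - center[1]) / d
    jac[:, 2] = -1.0
    try:
        step, *_ = np.linalg.lstsq(jac, -res, rcond=None)
    except np.linalg.LinAlgError:
        return center, radius
    return center + step[:2], radius + float(step[2])


def fit_circle(profile: SurfaceProfile) -> CurveFit:
    """Least-squares circle through a profile.

    Algebraic (Kåsa) fit followed by a single Gauss–Newton geometric
    refinement pass — robust on the shallow arcs this simulation produces,
    where purely geometric iteration from a poor seed is ill-conditioned.
    Collinear input sets the ``flat`` flag rather than raising.
    """
    if len(profile) < 3:
        raise DataError("circle fit needs at least 3 points")
    pts = profile.points
    sag = sagitta_depth(profile)
    chord = float(np.linalg.norm(pts[-1] - pts[0]))

    seed = _kasa_fit(pts[:, 0], pts[:, 1])
    if seed is None:
        return CurveFit(None, np.inf, 0.0, sag, chord, flat=True)
    center, radius = _gauss_newton_step(pts, *seed)
    if radius <= 0.0 or not np.isfinite(radius):
        center, radius = seed
    if 1.0 / radius < FLAT_CURVATURE:
        rms = float(np.sqrt(np.mean(_chord_deviation(pts) ** 2)))
        return CurveFit(None, np.inf, rms, sag, chord, flat=True)
    res = np.linalg.norm(pts - center, axis=1) - radius
    rms = float(np.sqrt(np.mean(res * res)))
    return CurveFit(center, float(radius), rms, sag, chord, flat=False)


# ---------------------------------------------------------------------------
# Simulation-result analysis
# ---------------------------------------------------------------------------

def _contact_span(profile: SurfaceProfile, wear: np.ndarray) -> SurfaceProfile:
    """Trim end nodes that never carried load (cumulative wear ≈ 0)."""
    idx = np.nonzero(wear > CONTACT_WEAR_EPS)[0]
    if idx.size < 3:
        return profile
    lo, hi = int(idx[0]), int(idx[-1])
    if lo == 0 and hi == len(profile) - 1:
        return profile
    return SurfaceProfile(profile.points[lo : hi + 1], role=profile.role)


def steady_profiles(result: Any) -> tuple[SurfaceProfile, SurfaceProfile]:
    """(mandibular, maxillary) steady-state profiles over the contacted span."""
    from .mesh import occlusal_profile  # local import: mesh imports this module

    state = result.state
    mand = _contact_span(occlusal_profile(state.mand_mesh), state.ledger.wear_mand)
    maxp = _contact_span(occlusal_profile(state.max_mesh), state.ledger.wear_max)
    return mand, maxp


def conformity_gap(result: Any) -> float:
    """Max vertical separation between the two surfaces at the centered pose.

    Evaluated at θ = 0 (identity pose) over the x-overlap of the two
    profiles; interpenetration counts as zero gap.  A non-converged result
    triggers a warning but is still evaluated.
    """
    if not getattr(result, "converged", True):
        warnings.warn("conformity_gap evaluated on a non-converged result",
                      stacklevel=2)
    from .mesh import occlusal_profile

    mand = occlusal_profile(result.state.mand_mesh)
    maxp = occlusal_profile(result.state.max_mesh)
    lo = max(mand.x[0], maxp.x[0])
    hi = min(mand.x[-1], maxp.x[-1])
    if hi <= lo:
        raise DataError("profiles do not overlap in x")
    stations = maxp.x[(maxp.x >= lo) & (maxp.x <= hi)]
    y_mand = np.interp(stations, mand.x, mand.y)
    y_max = np.interp(stations, maxp.x, maxp.y)
    gap = y_max - y_mand
    return float(max(gap.max(), 0.0))


def _result_row(r: float, result: Any) -> dict[str, float]:
    mand, maxp = steady_profiles(result)
    fit = fit_circle(mand)
    return {
        "c_rot_radius_mm": float(r),
        "depth_mand_mm": sagitta_depth(mand),
        "depth_max_mm": sagitta_depth(maxp),
        "fitted_radius_mm": fit.radius,
        "rms_residual_mm": fit.rms_residual,
        "radius_ratio": fit.radius / float(r),
    }


_KINEMATIC_KEYS = {"c_rot_radius_mm", "start_overhang_mm", "end_overhang_mm",
                   "out_dir", "wear_coefficient"}


def compare_radii(results: Mapping[float, Any] | Iterable[Any]) -> pd.DataFrame:
    """Comparison table across rotation radii.

    Accepts a mapping ``{r: SimulationResult}`` or an iterable of results
    (radius then read from each result's config).  With two or more rows the
    sagitta depths must decrease strictly with increasing r — the simulator's
    headline dependence — otherwise a :class:`DataError` is raised.  All
    non-kinematic config fields must agree across runs.
    """
    if isinstance(results, Mapping):
        items = [(float(r), res) for r, res in results.items()]
    else:
        items = [(float(res.config.c_rot_radius_mm), res) for res in results]
    if not items:
        raise DataError("no results to compare")
    items.sort(key=lambda kv: kv[0])

    base = None
    for _, res in items:
        cfg = {k: v for k, v in res.config.model_dump().items()
               if k not in _KINEMATIC_KEYS}
        if base is None:
            base = cfg
        elif cfg != base:
            raise DataError("results have differing non-kinematic configs")

    rows = [_result_row(r, res) for r, res in items]
    table = pd.DataFrame(rows)
    if len(rows) >= 2:
        for col in ("depth_mand_mm", "depth_max_mm"):
            if not np.all(np.diff(table[col].to_numpy()) < 0):
                raise DataError(
                    f"{col} is not strictly decreasing with rotation radius")
    return table
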