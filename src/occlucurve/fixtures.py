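"""Synthetic inputs with known ground truth.

Everything the analysis and contact layers consume can be generated here
without running a simulation: circular-arc surface profiles (optionally with
seeded Gaussian height noise) whose true radius and sagitta are returned
alongside, and flat/wedge interference pairs whose Winkler pressure field is
known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .curve_analysis import SurfaceProfile
from .errors import ConfigurationError
from .kinematics import RigidTransform


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic profile fixture."""

    kind: str = "arc"  # flat | arc | arc+noise | wedge
    radius_mm: float = 100.0
    chord_mm: float = 40.0
    noise_sigma_mm: float = 0.0
    n_points: int = 41
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma_mm < 0:
            raise ConfigurationError("noise sigma must be >= 0")
        if self.n_points < 3:
            raise ConfigurationError("need at least 3 points")


class ArcTruth(NamedTuple):
    radius: float
    sagitta: float
    center: tuple[float, float]


class InterferencePair(NamedTuple):
    mand: SurfaceProfile
    max: SurfaceProfile
    pose: RigidTransform
    pressure: np.ndarray  # closed-form Winkler pressure at the maxillary nodes


def closed_form_sagitta(radius: float, chord: float) -> float:
    """Sagitta of a circular arc: R − sqrt(R² − (L/2)²)."""
    return radius - float(np.sqrt(radius * radius - (chord / 2.0) ** 2))


def make_arc_profile(
    radius: float,
    chord: float,
    n: int = 41,
    noise_sigma: float = 0.0,
    seed: int = 0,
    role: str = "mandibular",
) -> tuple[SurfaceProfile, ArcTruth]:
    """Points on a circle centered above the chord midpoint, plus y-noise.

    The arc dips downward (occlusal-curve sense: positive sagitta depth for
    either block role); endpoints sit at y = 0.  Ground truth (radius,
    sagitta, center) is returned alongside the profile.
    """
    if radius <= chord / 2.0:
        raise ConfigurationError("radius must exceed half the chord")
    if n < 3:
        raise ConfigurationError("need at least 3 points")
    x = np.linspace(0.0, chord, n)
    h = float(np.sqrt(radius * radius - (chord / 2.0) ** 2))
    y = h - np.sqrt(radius * radius - (x - chord / 2.0) ** 2)
    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=n)
    truth = ArcTruth(radius, closed_form_sagitta(radius, chord),
                     (chord / 2.0, h))
    return SurfaceProfile(np.column_stack([x, y]), role=role), truth


def make_interference_pair(
    kind: str,
    magnitude: float,
    n: int = 41,
    width: float = 40.0,
    foundation_modulus: float = 2062.5,
) -> InterferencePair:
    """Flat/flat or wedge overlap pair with an analytic Winkler pressure field.

    ``flat``: uniform overlap = magnitude everywhere (pressure E_f·magnitude,
    20.625 MPa at the defaults for magnitude 0.01).  ``wedge``: overlap rising
    linearly from zero at x = 0 to magnitude at x = width (pressure linear,
    exactly zero at the hinge).
    """
    if magnitude < 0:
        raise ConfigurationError("interference magnitude must be >= 0")
    x = np.linspace(0.0, width, n)
    if kind == "flat":
        overlap = np.full(n, float(magnitude))
    elif kind == "wedge":
        overlap = magnitude * x / width
    else:
        raise ConfigurationError(f"unknown interference kind: {kind!r}")
    mand = SurfaceProfile(np.column_stack([x, overlap]), role="mandibular")
    maxp = SurfaceProfile(np.column_stack([x, np.zeros(n)]), role="maxillary")
    pose = RigidTransform(0.0, np.zeros(2))
    return InterferencePair(mand, maxp, pose, foundation_modulus * overlap)
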