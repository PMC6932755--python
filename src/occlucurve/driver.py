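"""Chew-cycle orchestration: eruption → loaded stroke → wear → relaxation.

One cycle applies the per-cycle eruption advance, sweeps the mandibular
block through the discretized rotation stroke accumulating Archard wear
increments on both occlusal surfaces (pressure solve at each mid-increment
pose), applies the accumulated wear, re-relaxes the mesh interiors, and
updates the eruption ledger.  :func:`run_until_steady` iterates cycles until
the per-cycle surface change stays below tolerance, which is where wear
balances eruption at every contacting node and the surfaces have become
conjugate arcs about C_ROT.

Wear-update stability.  The explicit once-per-cycle wear update behaves
like a fixed-point iteration on the surface height field: a node protruding
by δ gains extra per-cycle wear k_w·k_c·δ·S (k_c = contact stiffness seen
by the perturbation in MPa/mm, S = slide per cycle), i.e. a feedback gain
G = k_w·k_c·S.  G must stay below 1 for smooth monotone decay; larger
values chatter and never reach the steady tolerance.  The "auto" wear
coefficient is therefore resolved once per run as k_w = G*/(k_c·S) with
target gain G* = 0.5:

* winkler — perturbations of every wavelength see the foundation modulus,
  k_c = E/(2h), so G ≈ G* uniformly;
* fe — short-wavelength perturbations see the much stiffer elastic
  sinusoidal-indentation response k(λ) ≈ πE/(2λ).  The per-cycle wear field
  is smoothed with a 3-point binomial filter (kills the 2Δx mode entirely)
  and k_c is taken at the shortest surviving wavelength 4Δx including the
  filter's ½ attenuation: k_c = πE/(16Δx).  This bounds G ≲ G* across the
  spectrum at the cost of a slower (large-wavelength) transient.

The steady-state *shape* is rate-independent (k_w and e_c set the
timescale, not the attractor), so these choices affect only cycle counts.
The core loop is deterministic: identical configs give bit-identical
histories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io_config, kinematics
from .curve_analysis import SurfaceProfile, sagitta_depth
from .errors import DataError, SolverError, StabilityError
from .mesh import BlockMesh, MaterialProps, build_block_mesh, occlusal_profile
from .pressure import (FEContactSolver, foundation_modulus, winkler_pressures)
from .wear_eruption import (EruptionLedger, apply_eruption, apply_wear,
                            archard_increment, update_ledger)

logger = logging.getLogger("occlucurve")

#: Target per-node feedback gain of the explicit wear update.
WEAR_GAIN_TARGET = 0.5


@dataclass
class SimState:
    """Full mutable simulation state between cycles."""

    mand_mesh: BlockMesh
    max_mesh: BlockMesh
    ledger: EruptionLedger
    cycle: int = 0
    k_w: float | None = None
    last_contact: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    _active_hint: np.ndarray | None = None


@dataclass
class SimulationResult:
    """Outcome of a run: final state, per-cycle history, convergence flag."""

    state: SimState
    history: pd.DataFrame
    converged: bool
    cycles: int
    config: Any


def make_stroke_path(config) -> kinematics.KinematicPath:
    return kinematics.make_path(
        config.c_rot_radius_mm, config.width_mm,
        config.start_overhang_mm, config.end_overhang_mm,
        config.increments_per_stroke)


def resolve_wear_coefficient(config, path=None) -> float:
    """Stability-based auto wear coefficient (see module docstring)."""
    if config.wear_coefficient != "auto":
        return float(config.wear_coefficient)
    if path is None:
        path = make_stroke_path(config)
    slide = path.stroke_slide
    e_f = foundation_modulus(config.modulus_mpa, config.height_mm)
    if config.engine == "winkler":
        k_c = e_f
    else:
        dx = config.width_mm / config.nx
        k_fe = np.pi * config.modulus_mpa / (16.0 * dx)
        penalty = config.penalty_factor * e_f
        k_c = 1.0 / (1.0 / penalty + 1.0 / k_fe)
    return WEAR_GAIN_TARGET / (k_c * slide)


def initial_state(config) -> SimState:
    """Fresh flat-block state; the wear coefficient is resolved and frozen."""
    mand = build_block_mesh(config.width_mm, config.height_mm, config.nx,
                            config.ny, "mandibular", config.thickness_mm)
    maxb = build_block_mesh(config.width_mm, config.height_mm, config.nx,
                            config.ny, "maxillary", config.thickness_mm,
                            y_offset=config.initial_gap_mm)
    ledger = EruptionLedger.empty(config.nx + 1, config.nx + 1)
    return SimState(mand, maxb, ledger, k_w=resolve_wear_coefficient(config),
                    seed=config.seed)


def _smooth_wear(depths: np.ndarray) -> np.ndarray:
    """3-point binomial filter; constant fields (and totals) are preserved."""
    if depths.size < 3:
        return depths
    out = depths.copy()
    out[1:-1] = 0.25 * depths[:-2] + 0.5 * depths[1:-1] + 0.25 * depths[2:]
    out[0] = 0.75 * depths[0] + 0.25 * depths[1]
    out[-1] = 0.25 * depths[-2] + 0.75 * depths[-1]
    return out


def run_cycle(state: SimState, config, path=None) -> SimState:
    """Advance the simulation by one full chew cycle (in place)."""
    if path is None:
        path = make_stroke_path(config)
    apply_eruption(state, config.eruption_mm_per_cycle, config.eruption_split)

    mand_prof = occlusal_profile(state.mand_mesh)
    max_prof = occlusal_profile(state.max_mesh)
    mat = MaterialProps(config.modulus_mpa, config.poisson)
    e_f = foundation_modulus(config.modulus_mpa, config.height_mm)
    penalty = config.penalty_factor * e_f
    k_w = state.k_w if state.k_w is not None else resolve_wear_coefficient(
        config, path)
    state.k_w = k_w

    n_mand = len(mand_prof)
    depths_mand = np.zeros(n_mand)
    depths_max = np.zeros(len(max_prof))
    peak_force = 0.0
    peak_pressure = 0.0
    loaded = 0

    fe_solver = None
    if config.engine == "fe":
        fe_solver = FEContactSolver(state.mand_mesh, state.max_mesh, mat,
                                    penalty, config.max_contact_iters,
                                    tol=config.contact_tol_mm)

    for i in range(1, path.n_increments + 1):
        pose = path.midpose_at(i)
        if fe_solver is None:
            cs = winkler_pressures(mand_prof, max_prof, pose, e_f,
                                   config.thickness_mm, pose_index=i)
        else:
            cs = fe_solver.solve(pose, pose_index=i,
                                 active_hint=state._active_hint)
            state._active_hint = cs.active_mand
        if k_w > 0:
            ds_mand = path.sliding_increments(mand_prof.points, i)
            ds_max = path.sliding_increments(max_prof.points, i)
            depths_mand += archard_increment(cs.pressure_mand, ds_mand, k_w)
            depths_max += archard_increment(cs.pressure_max, ds_max, k_w)
        if cs.total_force > 0:
            loaded += 1
            peak_force = max(peak_force, cs.total_force)
            peak_pressure = max(peak_pressure, float(cs.pressure_max.max()))

    if config.engine == "fe":
        depths_mand = _smooth_wear(depths_mand)
        depths_max = _smooth_wear(depths_max)

    worst = max(depths_mand.max(), depths_max.max(), 0.0)
    if worst >= config.max_wear_per_cycle_mm:
        raise StabilityError(
            f"per-cycle wear {worst:.4g} mm exceeds the safeguard "
            f"{config.max_wear_per_cycle_mm} mm at cycle {state.cycle + 1}; "
            "reduce the wear coefficient or increase increments_per_stroke")

    state.mand_mesh = apply_wear(state.mand_mesh, depths_mand,
                                 config.relax_sweeps)
    state.max_mesh = apply_wear(state.max_mesh, depths_max,
                                config.relax_sweeps)
    update_ledger(state.ledger, depths_mand, depths_max)
    state.cycle += 1
    state.last_contact = {
        "peak_total_force_n": peak_force,
        "peak_pressure_mpa": peak_pressure,
        "loaded_increments": float(loaded),
    }
    return state


def steady_metric(prev_profiles: tuple[SurfaceProfile, SurfaceProfile],
                  new_profiles: tuple[SurfaceProfile, SurfaceProfile]) -> float:
    """Max over blocks of the RMS per-node surface height change (mm)."""
    worst = 0.0
    for prev, new in zip(prev_profiles, new_profiles):
        if len(prev) != len(new) or not np.allclose(prev.x, new.x,
                                                    rtol=0.0, atol=1e-12):
            raise DataError("profiles are not column-aligned")
        rms = float(np.sqrt(np.mean((new.y - prev.y) ** 2)))
        worst = max(worst, rms)
    return worst


def _profiles(state: SimState) -> tuple[SurfaceProfile, SurfaceProfile]:
    return occlusal_profile(state.mand_mesh), occlusal_profile(state.max_mesh)


def _write_profiles(state: SimState, out: Path, cycle: int) -> None:
    mand, maxp = _profiles(state)
    io_config.write_profile_csv(out / "profiles" / f"cycle_{cycle:05d}.csv",
                                mand.x, mand.y, maxp.y)


def _write_checkpoint(state: SimState, out: Path, cycle: int) -> None:
    base = out / "checkpoints"
    io_config.export_vtk(state, base / f"cycle_{cycle:05d}.vtk")
    io_config.export_mesh_csv(state, base / f"cycle_{cycle:05d}_nodes.csv",
                              base / f"cycle_{cycle:05d}_elements.csv")


def run_until_steady(config) -> SimulationResult:
    """Iterate chew cycles until the surfaces stop changing.

    Stops when the steady metric stays below ``steady_tol_mm`` for
    ``patience`` consecutive cycles, or at ``max_cycles`` (convergence flag
    false — returned, not raised).  Checkpoints (VTK) and profile snapshots
    are written to ``config.out_dir`` when set; solver/stability failures
    write a final checkpoint before propagating.
    """
    path = make_stroke_path(config)
    state = initial_state(config)
    out = None
    if config.out_dir:
        out = Path(config.out_dir)
        (out / "profiles").mkdir(parents=True, exist_ok=True)
        (out / "checkpoints").mkdir(exist_ok=True)
        io_config.echo_config(config, out / "resolved.yaml")

    rows = []
    streak = 0
    converged = False
    for n in range(1, config.max_cycles + 1):
        prev = _profiles(state)
        try:
            run_cycle(state, config, path)
        except (SolverError, StabilityError):
            if out is not None:
                io_config.export_vtk(state,
                                     out / "checkpoints" / f"abort_{n:05d}.vtk")
            raise
        new = _profiles(state)
        metric = steady_metric(prev, new)
        depth_mand = sagitta_depth(new[0])
        depth_max = sagitta_depth(new[1])
        force = state.last_contact.get("peak_total_force_n", 0.0)
        rows.append((n, metric, depth_mand, depth_max, force))
        logger.info("cycle=%d metric=%.3e depth_mand=%.4f depth_max=%.4f "
                    "force=%.3f", n, metric, depth_mand, depth_max, force)

        if out is not None:
            if config.profile_every and n % config.profile_every == 0:
                _write_profiles(state, out, n)
            if config.checkpoint_every and n % config.checkpoint_every == 0:
                _write_checkpoint(state, out, n)

        streak = streak + 1 if metric < config.steady_tol_mm else 0
        if streak >= config.patience:
            converged = True
            break

    history = pd.DataFrame(rows, columns=["cycle", "metric_mm",
                                          "sagitta_mand_mm", "sagitta_max_mm",
                                          "total_force_n"])
    result = SimulationResult(state, history, converged, state.cycle, config)
    if out is not None:
        io_config.write_history_csv(history, out / "history.csv")
        _write_profiles(state, out, state.cycle)
        _write_checkpoint(state, out, state.cycle)
    logger.info("run finished: cycles=%d converged=%s k_w=%.4g",
                state.cycle, converged, state.k_w or float("nan"))
    return result
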