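"""Run configuration, structured logging, and artifact file readers/writers.

Units are fixed package-wide (mm, N, MPa) and never configurable; the enamel
modulus is stored in MPa (82.5 GPa → 82 500 MPa, converted once here at the
schema boundary).  The defaults reproduce the r = 100 mm reference run:
40 × 20 mm blocks at 40 × 20 elements, E = 82 500 MPa, ν = 0.33, 3 mm
overhangs on both ends of the stroke, 0.01 mm relative approach per cycle.

Config files are YAML, either flat ``key: value`` pairs or grouped into
sections (one level of nesting is flattened on load); unknown keys are
rejected by name.  All file writers are deterministic byte-for-byte given
identical inputs (fixed float formatting, sorted keys).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

from .errors import ConfigurationError, DataError

logger = logging.getLogger("occlucurve")

FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def configure_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.WARNING
    if verbose:
        level = logging.DEBUG
    elif not quiet:
        level = logging.INFO
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)


class RunConfig(BaseModel):
    """Validated flat configuration for one simulation run."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # geometry
    width_mm: float = 40.0
    height_mm: float = 20.0
    nx: int = 40
    ny: int = 20
    thickness_mm: float = 1.0
    initial_gap_mm: float = 0.0
    # material
    modulus_mpa: float = 82_500.0
    poisson: float = 0.33
    # kinematics
    c_rot_radius_mm: float = 100.0
    start_overhang_mm: float = 3.0
    end_overhang_mm: float = 3.0
    increments_per_stroke: int = 60
    # wear / eruption
    eruption_mm_per_cycle: float = 0.01
    eruption_split: float = 0.5
    wear_coefficient: float | Literal["auto"] = "auto"
    max_wear_per_cycle_mm: float = 0.2
    # contact engine
    engine: Literal["winkler", "fe"] = "winkler"
    penalty_factor: float = 100.0
    max_contact_iters: int = 40
    contact_tol_mm: float = 1e-9
    # stopping rule
    steady_tol_mm: float = 1e-4
    patience: int = 10
    max_cycles: int = 5000
    # run bookkeeping
    relax_sweeps: int = 25
    checkpoint_every: int = 500
    profile_every: int = 50
    out_dir: str | None = None
    seed: int = 0

    @field_validator("width_mm", "height_mm", "thickness_mm", "modulus_mpa",
                     "eruption_mm_per_cycle", "max_wear_per_cycle_mm",
                     "penalty_factor", "steady_tol_mm", "contact_tol_mm")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v

    @field_validator("nx", "ny", "patience", "max_cycles",
                     "max_contact_iters")
    @classmethod
    def _at_least_one(cls, v, info):
        if v < 1:
            raise ValueError(f"{info.field_name} must be >= 1")
        return v

    @field_validator("increments_per_stroke")
    @classmethod
    def _at_least_two(cls, v):
        if v < 2:
            raise ValueError("increments_per_stroke must be >= 2")
        return v

    @field_validator("poisson")
    @classmethod
    def _poisson_bounds(cls, v):
        if not 0.0 <= v < 0.5:
            raise ValueError("poisson must lie in [0, 0.5)")
        return v

    @field_validator("eruption_split")
    @classmethod
    def _split_bounds(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError("eruption_split must lie in [0, 1]")
        return v

    @field_validator("initial_gap_mm", "relax_sweeps", "checkpoint_every",
                     "profile_every")
    @classmethod
    def _non_negative(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0")
        return v

    @field_validator("wear_coefficient")
    @classmethod
    def _wear_coeff(cls, v):
        # 0 disables wear (degenerate eruption-only runs); negative is invalid
        if v != "auto" and v < 0:
            raise ValueError("wear_coefficient must be 'auto' or >= 0")
        return v

    @model_validator(mode="after")
    def _cross_field(self):
        if self.c_rot_radius_mm <= self.width_mm / 2:
            raise ValueError("c_rot_radius_mm must exceed width_mm / 2")
        for name in ("start_overhang_mm", "end_overhang_mm"):
            ov = getattr(self, name)
            if not 0 < ov < self.width_mm:
                raise ValueError(f"{name} must lie in (0, width_mm)")
            if ov >= self.c_rot_radius_mm:
                raise ValueError(f"{name} must be smaller than c_rot_radius_mm")
        return self


def _flatten(raw: dict[str, Any]) -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for key, value in raw.items():
        if isinstance(value, dict):
            for sub, subval in value.items():
                if sub in flat:
                    raise ConfigurationError(f"duplicate config key: {sub}")
                flat[sub] = subval
        else:
            if key in flat:
                raise ConfigurationError(f"duplicate config key: {key}")
            flat[key] = value
    return flat


def config_from_dict(raw: dict[str, Any] | None) -> RunConfig:
    try:
        return RunConfig(**_flatten(raw or {}))
    except ValidationError as exc:
        first = exc.errors()[0]
        name = ".".join(str(p) for p in first["loc"]) or "<config>"
        raise ConfigurationError(f"invalid config field '{name}': "
                                 f"{first['msg']}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and fully validate a YAML run config (empty file → all defaults)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise ConfigurationError(f"config file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping: {path}")
    return config_from_dict(raw)


def echo_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully-resolved config (deterministic key order)."""
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=True))


# ---------------------------------------------------------------------------
# Profile CSV (x_mm, y_mand_mm, y_max_mm)
# ---------------------------------------------------------------------------

PROFILE_HEADER = "x_mm,y_mand_mm,y_max_mm"


def write_profile_csv(path: str | Path, x: np.ndarray, y_mand: np.ndarray,
                      y_max: np.ndarray) -> None:
    x, y_mand, y_max = (np.asarray(a, dtype=float) for a in (x, y_mand, y_max))
    if not (x.shape == y_mand.shape == y_max.shape):
        raise DataError("profile columns must have equal length")
    lines = [PROFILE_HEADER]
    for xi, ym, yx in zip(x, y_mand, y_max):
        lines.append(",".join(FLOAT_FMT % v for v in (xi, ym, yx)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != PROFILE_HEADER:
        raise DataError(f"{path}:1: expected header '{PROFILE_HEADER}'")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise DataError(f"{path}:{lineno}: expected 3 columns")
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise DataError(f"{path}:{lineno}: non-numeric value") from None
    if not rows:
        raise DataError(f"{path}: no data rows")
    arr = np.asarray(rows)
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise DataError(f"{path}: x_mm must be strictly increasing")
    return arr[:, 0], arr[:, 1], arr[:, 2]


def write_history_csv(history, path: str | Path) -> None:
    """Per-cycle metrics table, deterministic formatting."""
    history.to_csv(path, index=False, float_format=FLOAT_FMT)


def export_mesh_csv(state, node_path: str | Path, element_path: str | Path) -> None:
    """Plain CSV node/element dump of both blocks (checkpoint companion)."""
    with open(node_path, "w") as fh:
        fh.write("block,node,x_mm,y_mm\n")
        for mesh in (state.mand_mesh, state.max_mesh):
            for i, (x, y) in enumerate(mesh.coords):
                fh.write(f"{mesh.role},{i},{FLOAT_FMT % x},{FLOAT_FMT % y}\n")
    with open(element_path, "w") as fh:
        fh.write("block,element,n0,n1,n2,n3\n")
        for mesh in (state.mand_mesh, state.max_mesh):
            for e, quad in enumerate(mesh.quads):
                fh.write(f"{mesh.role},{e}," + ",".join(map(str, quad)) + "\n")


# ---------------------------------------------------------------------------
# Legacy-text VTK export (unstructured grid, quad cells)
# ---------------------------------------------------------------------------

def export_vtk(state, path: str | Path) -> None:
    """Write both block meshes plus wear / E_TOTAL point fields.

    Legacy ASCII VTK dialect, quad cells (type 9); wear depth and net
    eruption are defined on occlusal nodes and zero elsewhere.
    """
    meshes = [state.mand_mesh, state.max_mesh]
    ledger = state.ledger
    wear = [ledger.wear_mand, ledger.wear_max]
    etot = [ledger.e_total_mand, ledger.e_total_max]

    points, cells, wear_field, etot_field = [], [], [], []
    offset = 0
    for mesh, w, e in zip(meshes, wear, etot):
        points.append(mesh.coords)
        cells.append(mesh.quads + offset)
        wf = np.zeros(mesh.n_nodes)
        ef = np.zeros(mesh.n_nodes)
        wf[mesh.occlusal_nodes] = w
        ef[mesh.occlusal_nodes] = e
        wear_field.append(wf)
        etot_field.append(ef)
        offset += mesh.n_nodes
    pts = np.vstack(points)
    quads = np.vstack(cells)

    out = ["# vtk DataFile Version 3.0",
           f"occlucurve state, cycle {state.cycle}",
           "ASCII",
           "DATASET UNSTRUCTURED_GRID",
           f"POINTS {len(pts)} double"]
    out += [f"{FLOAT_FMT % p[0]} {FLOAT_FMT % p[1]} 0" for p in pts]
    out.append(f"CELLS {len(quads)} {5 * len(quads)}")
    out += ["4 " + " ".join(str(int(n)) for n in q) for q in quads]
    out.append(f"CELL_TYPES {len(quads)}")
    out += ["9"] * len(quads)
    out.append(f"POINT_DATA {len(pts)}")
    for name, data in (("wear_depth_mm", np.concatenate(wear_field)),
                       ("e_total_mm", np.concatenate(etot_field))):
        out.append(f"SCALARS {name} double 1")
        out.append("LOOKUP_TABLE default")
        out += [FLOAT_FMT % v for v in data]
    Path(path).write_text("\n".join(out) + "\n")
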