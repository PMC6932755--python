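"""Continuous eruption and its load-dependent inhibition (Archard wear).

Two antagonistic height processes act on the occlusal surfaces each chewing
cycle:

* **Eruption** — the blocks rigidly advance toward each other by a total of
  ``e_c`` mm per cycle (default 0.01), split between the maxillary block
  (moving down by ``split``·e_c) and the mandibular block (moving up by
  (1−``split``)·e_c).

* **Eruption inhibition** — occlusal load suppresses eruption.  Following
  the Archard–Lancaster sliding-wear relationship, the depth removed at a
  surface node over one sliding increment is Δh = k_w · p · Δs (pressure ×
  sliding distance × wear coefficient).

The net height budget is tracked by :class:`EruptionLedger`.  The classical
inhibition integral ∫ k·F_n·dt (a force–time constant k) maps onto the
Archard sum Σ k_w·p·Δs as follows: with nodal contact area A and sliding
speed v, F_n = p·A and ds = v·dt, so ∫ k·F_n·dt = Σ k_w·p·Δs exactly when
k = k_w·v/A — the two constants describe the same inhibition process, one
per unit load-time, the other per unit pressure-distance (k_w in mm²/N).

At steady state the per-cycle wear depth at every node in sustained contact
equals that block's per-cycle eruption share, so the pair-level net budget
e_c·cycles − (wear_mand + wear_max) stops changing: the surfaces become
stationary while material keeps flowing through them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, StabilityError
from .mesh import BlockMesh, relax_interior


@dataclass
class EruptionLedger:
    """Cumulative per-node height bookkeeping for both blocks (mm).

    ``eruption_*`` holds each block's cumulative eruption advance (its share
    of the per-cycle approach), ``wear_*`` the cumulative inhibition realized
    as Archard wear depth.  Per block, E_TOTAL = eruption − wear; the
    pair-level ``e_total_relative`` uses the full approach rate e_c against
    the summed wear of the two facing surfaces and is the quantity whose
    per-cycle change vanishes at steady state.
    """

    eruption_mand: np.ndarray
    eruption_max: np.ndarray
    wear_mand: np.ndarray
    wear_max: np.ndarray

    @classmethod
    def empty(cls, n_mand: int, n_max: int) -> "EruptionLedger":
        return cls(np.zeros(n_mand), np.zeros(n_max),
                   np.zeros(n_mand), np.zeros(n_max))

    @property
    def e_total_mand(self) -> np.ndarray:
        return self.eruption_mand - self.wear_mand

    @property
    def e_total_max(self) -> np.ndarray:
        return self.eruption_max - self.wear_max

    @property
    def e_total_relative(self) -> np.ndarray:
        """Pair-level net eruption: e_c·cycles − (wear_mand + wear_max).

        Defined on the shared column stations (both blocks are discretized
        with the same nx, and surface nodes keep their x for the whole run).
        """
        if self.wear_mand.shape != self.wear_max.shape:
            raise DataError("pair-level ledger needs equal surface node counts")
        return (self.eruption_mand + self.eruption_max
                - self.wear_mand - self.wear_max)

    def check(self, atol: float = 1e-12) -> None:
        for w in (self.wear_mand, self.wear_max):
            if np.any(w < -atol):
                raise DataError("cumulative inhibition must be non-negative")


def archard_increment(p, delta_s, k_w: float):
    """Archard–Lancaster wear depth Δh = k_w · p · Δs (mm).

    ``p`` (MPa) and ``delta_s`` (mm) may be scalars or arrays; k_w is the
    dimensional wear coefficient in mm²/N.
    """
    p = np.asarray(p, dtype=float)
    delta_s = np.asarray(delta_s, dtype=float)
    if k_w <= 0:
        raise DataError("wear coefficient must be > 0")
    if np.any(p < 0) or np.any(delta_s < 0):
        raise DataError("pressure and sliding distance must be non-negative")
    out = k_w * p * delta_s
    return float(out) if out.ndim == 0 else out


def surface_element_heights(mesh: BlockMesh) -> np.ndarray:
    """Vertical extent of the element row adjacent to the occlusal surface."""
    grid = mesh.coords[:, 1].reshape(mesh.ny + 1, mesh.nx + 1)
    if mesh.role == "mandibular":
        return np.abs(grid[-1] - grid[-2])
    return np.abs(grid[1] - grid[0])


def apply_wear(mesh: BlockMesh, depth_per_node: np.ndarray,
               relax_sweeps: int = 25) -> BlockMesh:
    """Remove material at the occlusal surface and re-relax the interior.

    Each occlusal node moves vertically *into* its own block by its wear
    depth (mandibular top moves down, maxillary bottom moves up), so block
    area is strictly non-increasing.  Depths approaching the adjacent
    element height indicate an unstable per-cycle update and raise
    :class:`StabilityError` (use a smaller wear coefficient or more stroke
    increments).
    """
    depths = np.asarray(depth_per_node, dtype=float)
    surf = mesh.occlusal_nodes
    if depths.shape != surf.shape:
        raise DataError("wear depth array does not match occlusal node count")
    if np.any(depths < 0):
        raise DataError("wear depths must be non-negative")
    heights = surface_element_heights(mesh)
    if np.any(depths >= heights):
        raise StabilityError(
            f"per-cycle wear depth up to {depths.max():.4g} mm reaches the "
            f"adjacent element height ({heights.min():.4g} mm); reduce the "
            "wear coefficient or increase the stroke increment count")
    coords = mesh.coords.copy()
    direction = -1.0 if mesh.role == "mandibular" else 1.0
    coords[surf, 1] += direction * depths
    return relax_interior(mesh.with_coords(coords), relax_sweeps)


def apply_eruption(state, e_c: float, split: float = 0.5):
    """Advance the blocks toward each other by a total of e_c mm.

    The maxillary block translates down by split·e_c, the mandibular block
    up by (1−split)·e_c; the relative approach is exactly e_c.  The ledger's
    per-block eruption shares are updated here.
    """
    if not 0.0 <= split <= 1.0:
        raise DataError("eruption split must lie in [0, 1]")
    state.max_mesh = state.max_mesh.translated(dy=-split * e_c)
    state.mand_mesh = state.mand_mesh.translated(dy=(1.0 - split) * e_c)
    state.ledger.eruption_mand += (1.0 - split) * e_c
    state.ledger.eruption_max += split * e_c
    return state


def update_ledger(ledger: EruptionLedger, mand_depths: np.ndarray,
                  max_depths: np.ndarray) -> EruptionLedger:
    """Accumulate one cycle's wear depths (eruption is booked by apply_eruption)."""
    mand_depths = np.asarray(mand_depths, dtype=float)
    max_depths = np.asarray(max_depths, dtype=float)
    if np.any(mand_depths < 0) or np.any(max_depths < 0):
        raise DataError("wear depths must be non-negative")
    ledger.wear_mand += mand_depths
    ledger.wear_max += max_depths
    return ledger
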