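"""Structured quadrilateral meshes for the two dental blocks.

Each block (maxillary or mandibular) is a uniform nx × ny grid of 4-node
quadrilaterals in the sagittal plane.  Coordinates are in mm: x increases
anteriorly (rightward), y superiorly.  The shared occlusal interface sits at
y = 0 by default — the mandibular block spans y ∈ [−height, 0] with its
occlusal surface on top, the maxillary block spans y ∈ [0, height] with its
occlusal surface on the bottom.

Node (i, j) has index j·(nx+1) + i, i along x, j along y bottom-to-top.
Wear moves occlusal-surface nodes only vertically, so surface profiles stay
column-aligned across the whole run; the interior follows through Laplacian
relaxation (the remeshing analog).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .curve_analysis import SurfaceProfile
from .errors import ConfigurationError, SimulationIntegrityError

ROLES = ("maxillary", "mandibular")


@dataclass(frozen=True)
class MaterialProps:
    """Linear-elastic material: modulus in MPa, Poisson ratio dimensionless.

    Defaults are human enamel (82.5 GPa converted once to MPa, ν = 0.33).
    """

    modulus_mpa: float = 82_500.0
    poisson: float = 0.33

    def __post_init__(self) -> None:
        if self.modulus_mpa <= 0:
            raise ConfigurationError("elastic modulus must be > 0")
        if not 0.0 <= self.poisson < 0.5:
            raise ConfigurationError("Poisson ratio must be in [0, 0.5)")


@dataclass(frozen=True)
class BlockMesh:
    """One dental block as a structured quad mesh.

    coords: (n_nodes, 2) mm; quads: (n_el, 4) CCW node indices;
    thickness: out-of-plane depth (mm) for the plane-stress formulation.
    """

    coords: np.ndarray
    quads: np.ndarray
    role: str
    nx: int
    ny: int
    thickness: float = 1.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        quads = np.asarray(self.quads, dtype=np.intp)
        if self.role not in ROLES:
            raise ConfigurationError(f"role must be one of {ROLES}")
        if coords.shape != ((self.nx + 1) * (self.ny + 1), 2):
            raise ConfigurationError("coords shape inconsistent with nx, ny")
        if quads.shape != (self.nx * self.ny, 4):
            raise ConfigurationError("quads shape inconsistent with nx, ny")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "quads", quads)

    # -- indexing helpers ---------------------------------------------------
    def node_id(self, i: int, j: int) -> int:
        return j * (self.nx + 1) + i

    @property
    def n_nodes(self) -> int:
        return (self.nx + 1) * (self.ny + 1)

    @property
    def n_elements(self) -> int:
        return self.nx * self.ny

    @property
    def occlusal_nodes(self) -> np.ndarray:
        """Surface node indices ordered by increasing x.

        Top row for the mandibular block, bottom row for the maxillary one.
        """
        j = self.ny if self.role == "mandibular" else 0
        return np.arange(self.nx + 1, dtype=np.intp) + j * (self.nx + 1)

    @property
    def basal_nodes(self) -> np.ndarray:
        """Driven/fixed far-edge node indices (opposite the occlusal surface)."""
        j = 0 if self.role == "mandibular" else self.ny
        return np.arange(self.nx + 1, dtype=np.intp) + j * (self.nx + 1)

    # -- geometry -----------------------------------------------------------
    def signed_areas(self) -> np.ndarray:
        """Shoelace signed area per element (positive for CCW quads)."""
        p = self.coords[self.quads]  # (m, 4, 2)
        x, y = p[..., 0], p[..., 1]
        return 0.5 * np.sum(x * np.roll(y, -1, axis=1) - np.roll(x, -1, axis=1) * y,
                            axis=1)

    def area(self) -> float:
        return float(self.signed_areas().sum())

    def translated(self, dx: float = 0.0, dy: float = 0.0) -> "BlockMesh":
        return replace(self, coords=self.coords + np.array([dx, dy]))

    def with_coords(self, coords: np.ndarray) -> "BlockMesh":
        return replace(self, coords=coords)


def build_block_mesh(
    width: float,
    height: float,
    nx: int,
    ny: int,
    role: str,
    thickness: float = 1.0,
    y_offset: float = 0.0,
) -> BlockMesh:
    """Uniform structured block mesh with the occlusal interface at y = 0.

    The mandibular block spans y ∈ [−height, 0], the maxillary block
    y ∈ [0, height]; ``y_offset`` shifts the whole block (used to open an
    initial inter-block gap).
    """
    if width <= 0 or height <= 0 or thickness <= 0:
        raise ConfigurationError("block dimensions must be positive")
    if nx < 1 or ny < 1:
        raise ConfigurationError("element counts must be >= 1")
    if role not in ROLES:
        raise ConfigurationError(f"role must be one of {ROLES}")

    xs = np.linspace(0.0, width, nx + 1)
    y0, y1 = (-height, 0.0) if role == "mandibular" else (0.0, height)
    ys = np.linspace(y0, y1, ny + 1) + y_offset
    xg, yg = np.meshgrid(xs, ys)  # rows = j, cols = i
    coords = np.column_stack([xg.ravel(), yg.ravel()])

    i = np.arange(nx)
    j = np.arange(ny)
    ii, jj = np.meshgrid(i, j)
    n0 = (jj * (nx + 1) + ii).ravel()
    quads = np.column_stack([n0, n0 + 1, n0 + nx + 2, n0 + nx + 1])
    return BlockMesh(coords, quads, role, nx, ny, thickness)


def occlusal_profile(mesh: BlockMesh) -> SurfaceProfile:
    """Ordered (x, y) polyline of the occlusal surface (length nx+1)."""
    return SurfaceProfile(mesh.coords[mesh.occlusal_nodes].copy(), role=mesh.role)


def element_quality(mesh: BlockMesh) -> float:
    """Minimum scaled corner Jacobian over all elements (1 for rectangles).

    At each CCW corner the two emanating edges a, b give cross(a, b) /
    (|a||b|) = sin of the corner angle; degenerate edges score 0.
    """
    p = mesh.coords[mesh.quads]  # (m, 4, 2)
    a = np.roll(p, -1, axis=1) - p  # edge to next corner
    b = np.roll(p, 1, axis=1) - p   # edge to previous corner
    cross = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    norms = np.linalg.norm(a, axis=2) * np.linalg.norm(b, axis=2)
    scaled = np.divide(cross, norms, out=np.zeros_like(cross), where=norms > 0)
    return float(scaled.min())


def relax_interior(mesh: BlockMesh, n_sweeps: int) -> BlockMesh:
    """Fixed-corner Laplacian relaxation — the remeshing analog.

    Interior nodes are replaced by the mean of their four grid neighbors
    (Jacobi sweeps).  Lateral-edge nodes slide along their (vertical) edge by
    a 1D Laplacian in y so the near-surface element rows do not collapse
    under sustained wear; corners and the occlusal/basal edges never move.
    A uniform grid is a fixed point.
    """
    if n_sweeps < 0:
        raise ConfigurationError("n_sweeps must be >= 0")
    if element_quality(mesh) <= 0.0:
        raise SimulationIntegrityError(
            "inverted or degenerate element before relaxation")
    if n_sweeps == 0 or mesh.nx < 2 and mesh.ny < 2:
        return mesh

    grid = mesh.coords.reshape(mesh.ny + 1, mesh.nx + 1, 2).copy()
    for _ in range(n_sweeps):
        new = grid.copy()
        if mesh.nx >= 2 and mesh.ny >= 2:
            new[1:-1, 1:-1] = 0.25 * (grid[:-2, 1:-1] + grid[2:, 1:-1]
                                      + grid[1:-1, :-2] + grid[1:-1, 2:])
        if mesh.ny >= 2:
            # lateral edges: y only, x pinned to the edge line
            new[1:-1, 0, 1] = 0.5 * (grid[:-2, 0, 1] + grid[2:, 0, 1])
            new[1:-1, -1, 1] = 0.5 * (grid[:-2, -1, 1] + grid[2:, -1, 1])
        grid = new
    return mesh.with_coords(grid.reshape(-1, 2))
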