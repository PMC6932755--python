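"""Occlusal contact pressures: Winkler surrogate and plane-stress FE engine.

Two interchangeable engines compute the per-node contact state for a given
mandibular pose:

* ``winkler`` — an elastic-foundation (bed-of-springs) surrogate.  The two
  blocks in series behave, for smooth near-conformal contact, like a
  foundation of modulus E_f = E / (2h) (two h-tall columns of modulus E in
  series), so pressure is simply E_f × local vertical overlap.  It is the
  default driver engine: orders of magnitude faster than the FE solve and,
  because the steady-state surface shape is set by kinematics and the wear
  law rather than by the elastic details, it reaches the same attractor.

* ``fe`` — a full 2D plane-stress finite-element solve (bilinear quads,
  2×2 Gauss quadrature) of both blocks with node-on-segment penalty contact
  between the occlusal surfaces: the maxillary far (top) edge is fixed, the
  mandibular far (bottom) edge is rigidly driven by the pose, and
  penetration of mandibular surface nodes into maxillary surface segments is
  resisted by stiff vertical springs (penalty stiffness, default 100 × E_f,
  keeping the penetration error ≈ 1 % of the interference).

Units: mm, N, MPa throughout.  Contact is frictionless — the wear law needs
only the normal pressure and the kinematic sliding distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .curve_analysis import SurfaceProfile
from .errors import DataError, SimulationIntegrityError, SolverError
from .kinematics import RigidTransform
from .mesh import BlockMesh, MaterialProps

#: Default ratio of penalty stiffness to the series foundation modulus.
DEFAULT_PENALTY_FACTOR = 100.0


def foundation_modulus(modulus_mpa: float, height_mm: float) -> float:
    """Series-column Winkler modulus E_f = E / (2h), in MPa/mm."""
    return modulus_mpa / (2.0 * height_mm)


def tributary_widths(x: np.ndarray) -> np.ndarray:
    """Per-node tributary width: half the sum of adjacent segment lengths."""
    x = np.asarray(x, dtype=float)
    if x.size == 1:
        raise DataError("tributary widths need at least 2 nodes")
    w = np.empty_like(x)
    dx = np.diff(x)
    w[0] = dx[0] / 2.0
    w[-1] = dx[-1] / 2.0
    w[1:-1] = (dx[:-1] + dx[1:]) / 2.0
    return w


@dataclass
class ContactState:
    """Per-node contact fields for one pose, on both occlusal surfaces.

    Maxillary fields live on the (static) maxillary surface node stations;
    mandibular fields on the mandibular surface nodes.  Invariants: open
    contact carries no force (g = 0 ⇒ F_n = p = 0), F_n ≥ 0 (no adhesion),
    and total_force = Σ F_n.
    """

    pose_index: int
    x_max: np.ndarray
    penetration_max: np.ndarray
    pressure_max: np.ndarray
    force_max: np.ndarray
    x_mand: np.ndarray
    penetration_mand: np.ndarray
    pressure_mand: np.ndarray
    force_mand: np.ndarray
    total_force: float
    sliding_max: np.ndarray | None = None
    sliding_mand: np.ndarray | None = None
    reaction_force: float | None = None
    active_mand: np.ndarray | None = None

    def check(self, atol: float = 1e-9) -> None:
        """Assert the no-adhesion / open-contact / force-sum invariants."""
        for g, f, p in ((self.penetration_max, self.force_max, self.pressure_max),
                        (self.penetration_mand, self.force_mand,
                         self.pressure_mand)):
            if np.any(f < -atol) or np.any(p < -atol):
                raise SimulationIntegrityError("adhesive (negative) contact force")
            open_nodes = g <= 0
            if np.any(np.abs(f[open_nodes]) > atol):
                raise SimulationIntegrityError("open contact carries force")
        if abs(self.force_max.sum() - self.total_force) > max(atol, 1e-9):
            raise SimulationIntegrityError("total force != sum of nodal forces")


# ---------------------------------------------------------------------------
# Winkler elastic-foundation engine
# ---------------------------------------------------------------------------

def _surface_interp(x: np.ndarray, y: np.ndarray):
    """Cubic-spline interpolant of a smooth surface (linear below 4 points)."""
    if x.size < 4:
        return lambda xq: np.interp(xq, x, y)
    from scipy.interpolate import CubicSpline

    return CubicSpline(x, y, bc_type="not-a-knot", extrapolate=True)


def winkler_pressures(
    mand_profile: SurfaceProfile,
    max_profile: SurfaceProfile,
    pose: RigidTransform,
    foundation_modulus: float,
    thickness: float = 1.0,
    pose_index: int = 0,
) -> ContactState:
    """Bed-of-springs contact: p = E_f · overlap, F_n = p · tributary area.

    The overlap g(x) = max(0, y_mand(x) − y_max(x)) is evaluated on *both*
    sets of surface node stations, each time reading the opposing (smooth)
    surface through a cubic-spline interpolant.  The symmetric construction
    matters: sampling a linearly-interpolated field is biased at curved
    surfaces by O(Δx²), which makes the two blocks wear at slightly unequal
    rates and the conforming pair drift instead of reaching a fixed point;
    the spline reduces the bias to O(Δx⁴).  Flat and wedge profiles are
    reproduced exactly.
    """
    posed = pose.apply(mand_profile.points)
    xm, ym = posed[:, 0], posed[:, 1]
    if np.any(np.diff(xm) <= 0):
        raise DataError("posed mandibular profile x not strictly increasing")
    xs, ys = max_profile.x, max_profile.y
    if np.any(np.diff(xs) <= 0):
        raise DataError("maxillary profile x not strictly increasing")

    y_mand_at = _surface_interp(xm, ym)(xs)
    covered = (xs >= xm[0]) & (xs <= xm[-1])
    g_max = np.clip(np.where(covered, y_mand_at - ys, 0.0), 0.0, None)
    p_max = foundation_modulus * g_max
    f_max = p_max * tributary_widths(xs) * thickness

    y_max_at = _surface_interp(xs, ys)(xm)
    facing = (xm >= xs[0]) & (xm <= xs[-1])
    g_mand = np.clip(np.where(facing, ym - y_max_at, 0.0), 0.0, None)
    p_mand = foundation_modulus * g_mand
    f_mand = p_mand * tributary_widths(xm) * thickness

    return ContactState(
        pose_index=pose_index,
        x_max=xs.copy(), penetration_max=g_max, pressure_max=p_max,
        force_max=f_max,
        x_mand=xm, penetration_mand=g_mand, pressure_mand=p_mand,
        force_mand=f_mand,
        total_force=float(f_max.sum()),
    )


# ---------------------------------------------------------------------------
# Plane-stress FE engine
# ---------------------------------------------------------------------------

_GAUSS = 1.0 / np.sqrt(3.0)
_GPTS = [(-_GAUSS, -_GAUSS), (_GAUSS, -_GAUSS), (_GAUSS, _GAUSS), (-_GAUSS, _GAUSS)]


def _dshape(xi: float, eta: float) -> np.ndarray:
    """Bilinear shape-function derivatives dN/d(ξ,η), shape (4, 2)."""
    return 0.25 * np.array([
        [-(1 - eta), -(1 - xi)],
        [(1 - eta), -(1 + xi)],
        [(1 + eta), (1 + xi)],
        [-(1 + eta), (1 - xi)],
    ])


def _dmatrix(mat: MaterialProps) -> np.ndarray:
    e, nu = mat.modulus_mpa, mat.poisson
    return e / (1 - nu * nu) * np.array([
        [1.0, nu, 0.0],
        [nu, 1.0, 0.0],
        [0.0, 0.0, (1 - nu) / 2.0],
    ])


def assemble_plane_stress(mesh: BlockMesh, mat: MaterialProps) -> sp.csr_matrix:
    """Global stiffness of one block: bilinear Q4, plane stress, 2×2 Gauss.

    Returns a symmetric positive-semidefinite (2·n_nodes)² sparse operator,
    dof ordering (ux_0, uy_0, ux_1, uy_1, …).
    """
    if np.any(mesh.signed_areas() <= 0):
        raise SimulationIntegrityError("inverted element during assembly")
    d = _dmatrix(mat)
    xe = mesh.coords[mesh.quads]  # (m, 4, 2)
    m = xe.shape[0]
    ke = np.zeros((m, 8, 8))
    for xi, eta in _GPTS:
        dn = _dshape(xi, eta)  # (4, 2)
        jac = np.einsum("ka,mkb->mab", dn, xe)  # d(x)/d(ξ): (m, 2, 2)
        det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
        if np.any(det <= 0):
            raise SimulationIntegrityError("non-positive Jacobian at Gauss point")
        inv = np.empty_like(jac)
        inv[:, 0, 0] = jac[:, 1, 1]
        inv[:, 1, 1] = jac[:, 0, 0]
        inv[:, 0, 1] = -jac[:, 0, 1]
        inv[:, 1, 0] = -jac[:, 1, 0]
        inv /= det[:, None, None]
        dndx = np.einsum("ka,mba->mkb", dn, inv)  # (J^-1)^T: jac[a,b] = dx_b/dxi_a
        b = np.zeros((m, 3, 8))
        b[:, 0, 0::2] = dndx[:, :, 0]
        b[:, 1, 1::2] = dndx[:, :, 1]
        b[:, 2, 0::2] = dndx[:, :, 1]
        b[:, 2, 1::2] = dndx[:, :, 0]
        ke += np.einsum("mia,ij,mjb->mab", b, d, b) * det[:, None, None]
    ke *= mesh.thickness

    dofs = np.empty((m, 8), dtype=np.intp)
    dofs[:, 0::2] = 2 * mesh.quads
    dofs[:, 1::2] = 2 * mesh.quads + 1
    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    n = 2 * mesh.n_nodes
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return k


def element_stresses(mesh: BlockMesh, mat: MaterialProps,
                     u: np.ndarray) -> np.ndarray:
    """Centroid stress (σxx, σyy, τxy) per element for a displacement field."""
    d = _dmatrix(mat)
    xe = mesh.coords[mesh.quads]
    dn = _dshape(0.0, 0.0)
    jac = np.einsum("ka,mkb->mab", dn, xe)
    det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
    inv = np.empty_like(jac)
    inv[:, 0, 0] = jac[:, 1, 1]
    inv[:, 1, 1] = jac[:, 0, 0]
    inv[:, 0, 1] = -jac[:, 0, 1]
    inv[:, 1, 0] = -jac[:, 1, 0]
    inv /= det[:, None, None]
    dndx = np.einsum("ka,mba->mkb", dn, inv)  # (J^-1)^T: jac[a,b] = dx_b/dxi_a
    ue = u.reshape(-1, 2)[mesh.quads]  # (m, 4, 2)
    strain = np.empty((xe.shape[0], 3))
    strain[:, 0] = np.einsum("mk,mk->m", dndx[:, :, 0], ue[:, :, 0])
    strain[:, 1] = np.einsum("mk,mk->m", dndx[:, :, 1], ue[:, :, 1])
    strain[:, 2] = (np.einsum("mk,mk->m", dndx[:, :, 1], ue[:, :, 0])
                    + np.einsum("mk,mk->m", dndx[:, :, 0], ue[:, :, 1]))
    return strain @ d.T


def nodal_force_to_pressure(forces: np.ndarray, mesh: BlockMesh) -> np.ndarray:
    """Convert occlusal nodal forces (N) to pressures (MPa) via tributary areas."""
    surf = mesh.coords[mesh.occlusal_nodes]
    seg = np.linalg.norm(np.diff(surf, axis=0), axis=1)
    trib = np.empty(len(surf))
    trib[0] = seg[0] / 2.0
    trib[-1] = seg[-1] / 2.0
    trib[1:-1] = (seg[:-1] + seg[1:]) / 2.0
    area = trib * mesh.thickness
    if np.any(area <= 0):
        raise DataError("zero tributary area on the occlusal surface")
    forces = np.asarray(forces, dtype=float)
    if forces.shape != area.shape:
        raise DataError("force array does not match occlusal node count")
    return forces / area


class FEContactSolver:
    """Cached two-block penalty-contact solver for one mesh configuration.

    Assembly and sparse factorization are done once per (worn) mesh pair;
    each pose then costs only a multi-right-hand-side triangular solve plus
    dense algebra of the contact size (Woodbury low-rank update), which is
    what makes the FE engine usable inside the cycle loop.  The mandibular
    stiffness is assembled in the body frame and the rigid pose is applied
    exactly through per-node rotation of the contact incidence vectors
    (K_world = T K_body T^T for an isotropic material under rigid rotation).
    """

    def __init__(self, mand_mesh: BlockMesh, max_mesh: BlockMesh,
                 mat: MaterialProps, penalty_stiffness: float,
                 max_iters: int = 40, tol: float = 0.0) -> None:
        self.mand_mesh = mand_mesh
        self.max_mesh = max_mesh
        self.penalty = penalty_stiffness
        self.max_iters = max_iters
        self.tol = tol  # penetration threshold (mm) for the active set
        k1 = assemble_plane_stress(mand_mesh, mat)
        k2 = assemble_plane_stress(max_mesh, mat)
        self.n1 = mand_mesh.n_nodes
        self.k = sp.block_diag([k1, k2], format="csr")
        ndof = self.k.shape[0]
        fixed = np.zeros(ndof, dtype=bool)
        # mandibular bottom edge rigidly driven, maxillary top edge fixed
        fixed[2 * mand_mesh.basal_nodes] = True
        fixed[2 * mand_mesh.basal_nodes + 1] = True
        fixed[2 * (self.n1 + max_mesh.basal_nodes)] = True
        fixed[2 * (self.n1 + max_mesh.basal_nodes) + 1] = True
        self.free = np.nonzero(~fixed)[0]
        self.dof_pos = -np.ones(ndof, dtype=np.intp)
        self.dof_pos[self.free] = np.arange(len(self.free))
        self.lu = spla.splu(self.k[self.free][:, self.free].tocsc())

        self.slaves = mand_mesh.occlusal_nodes
        self.slave_xy = mand_mesh.coords[self.slaves]
        self.masters = max_mesh.occlusal_nodes
        self.mx = max_mesh.coords[self.masters, 0]
        self.my = max_mesh.coords[self.masters, 1]
        if np.any(np.diff(self.mx) <= 0):
            raise DataError("maxillary surface x not strictly increasing")

    def _trib(self, pts: np.ndarray) -> np.ndarray:
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        t = np.empty(len(pts))
        t[0], t[-1] = seg[0] / 2.0, seg[-1] / 2.0
        t[1:-1] = (seg[:-1] + seg[1:]) / 2.0
        return t

    def solve(self, pose: RigidTransform, pose_index: int = 0,
              active_hint: np.ndarray | None = None) -> ContactState:
        sxy = pose.apply(self.slave_xy)
        if np.any(np.diff(sxy[:, 0]) <= 0):
            raise DataError("posed mandibular surface x not strictly increasing")
        mx, my = self.mx, self.my
        ns = len(self.slaves)
        in_range = (sxy[:, 0] >= mx[0]) & (sxy[:, 0] <= mx[-1])
        seg = np.clip(np.searchsorted(mx, sxy[:, 0]) - 1, 0, len(mx) - 2)
        w = np.where(in_range,
                     (sxy[:, 0] - mx[seg]) / (mx[seg + 1] - mx[seg]), 0.0)
        g0 = np.where(in_range,
                      sxy[:, 1] - ((1 - w) * my[seg] + w * my[seg + 1]), -1.0)
        kspring = (self.penalty * self._trib(sxy)
                   * self.mand_mesh.thickness)  # N/mm per node

        # contact incidence in body dofs: world slave u_y = sinθ·u_bx + cosθ·u_by
        c, s = np.cos(pose.angle), np.sin(pose.angle)
        rows = np.concatenate([np.arange(ns)] * 4)
        cols = np.concatenate([
            self.dof_pos[2 * self.slaves],
            self.dof_pos[2 * self.slaves + 1],
            self.dof_pos[2 * (self.n1 + self.masters[seg]) + 1],
            self.dof_pos[2 * (self.n1 + self.masters[seg + 1]) + 1]])
        vals = np.concatenate([np.full(ns, s), np.full(ns, c), -(1 - w), -w])
        keep = cols >= 0
        cmat = sp.coo_matrix((vals[keep], (rows[keep], cols[keep])),
                             shape=(ns, len(self.free))).tocsr()
        v = self.lu.solve(cmat.T.toarray())          # (nfree, ns)
        gmat = cmat @ v                               # (ns, ns) dense

        if active_hint is not None and active_hint.shape == (ns,):
            active = active_hint & in_range
        else:
            active = (g0 > self.tol) & in_range
        pen = np.where(g0 > 0, g0, 0.0)
        coef = np.zeros(ns)  # b + z on the active set, zero elsewhere
        for _ in range(self.max_iters):
            a = np.nonzero(active)[0]
            if a.size == 0:
                coef = np.zeros(ns)
                pen = g0.copy()
            else:
                b = kspring[a] * g0[a]
                ckf = -gmat[:, a] @ b
                m = np.diag(1.0 / kspring[a]) + gmat[np.ix_(a, a)]
                z = np.linalg.solve(m, ckf[a])
                coef = np.zeros(ns)
                coef[a] = b + z
                pen = g0 - gmat[:, a] @ coef[a]
            new_active = (pen > self.tol) & in_range
            if np.array_equal(new_active, active):
                break
            active = new_active
        else:
            raise SolverError(
                f"penalty contact did not settle in {self.max_iters} "
                f"iterations (pose {pose_index}, {int(active.sum())} active "
                f"nodes, max penetration {pen.max():.3e} mm)")

        f_slave = np.where(active, kspring * np.clip(pen, 0.0, None), 0.0)
        g_slave = np.where(active, np.clip(pen, 0.0, None), 0.0)

        f_master = np.zeros(len(self.masters))
        np.add.at(f_master, seg, (1 - w) * f_slave)
        np.add.at(f_master, seg + 1, w * f_slave)
        g_master = np.clip(np.interp(mx, sxy[:, 0], g_slave,
                                     left=0.0, right=0.0), 0.0, None)
        g_master[f_master <= 0] = 0.0

        p_slave = f_slave / (self._trib(sxy) * self.mand_mesh.thickness)
        p_master = f_master / (self._trib(np.column_stack([mx, my]))
                               * self.max_mesh.thickness)

        # full body-frame displacement and top-edge vertical reactions
        u = np.zeros(self.k.shape[0])
        a = np.nonzero(active)[0]
        if a.size:
            u[self.free] = -v[:, a] @ coef[a]
        r = self.k @ u
        top = 2 * (self.n1 + self.max_mesh.basal_nodes) + 1
        reaction = float(r[top].sum())

        return ContactState(
            pose_index=pose_index,
            x_max=mx.copy(), penetration_max=g_master, pressure_max=p_master,
            force_max=f_master,
            x_mand=sxy[:, 0].copy(), penetration_mand=g_slave,
            pressure_mand=p_slave, force_mand=f_slave,
            total_force=float(f_slave.sum()),
            reaction_force=reaction,
            active_mand=active,
        )


def solve_contact_fe(
    mand_mesh: BlockMesh,
    max_mesh: BlockMesh,
    pose: RigidTransform,
    mat: MaterialProps,
    penalty_stiffness: float,
    max_iters: int = 40,
    pose_index: int = 0,
    active_hint: np.ndarray | None = None,
    tol: float = 0.0,
) -> ContactState:
    """Quasi-static penalty-contact solve of the posed two-block system.

    One-shot convenience wrapper over :class:`FEContactSolver`: the
    maxillary top edge is fully fixed, the mandibular bottom edge is rigidly
    driven by the pose, and node-on-segment penalty contact couples the two
    occlusal surfaces.  Action–reaction holds: the vertical reactions on the
    fixed maxillary edge balance the total contact force.
    """
    return FEContactSolver(mand_mesh, max_mesh, mat, penalty_stiffness,
                           max_iters, tol).solve(pose, pose_index, active_hint)
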