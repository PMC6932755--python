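"""Contact pressure engines: Winkler surrogate and plane-stress FE solve."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import occlucurve as oc
from occlucurve.errors import DataError
from occlucurve.pressure import _dmatrix

E_F = oc.foundation_modulus(82_500.0, 20.0)  # 2062.5 MPa/mm
SERIES_PRESSURE = E_F * 0.01  # 20.625 MPa for 0.01 mm interference


def test_foundation_modulus_series_columns():
    assert E_F == pytest.approx(2062.5)


class TestWinkler:
    def test_separated_profiles_carry_no_force(self, identity_pose):
        mand = oc.SurfaceProfile(np.column_stack([np.linspace(0, 40, 21),
                                                  np.full(21, -0.5)]))
        maxp = oc.SurfaceProfile(np.column_stack([np.linspace(0, 40, 21),
                                                  np.zeros(21)]),
                                 role="maxillary")
        cs = oc.winkler_pressures(mand, maxp, identity_pose, E_F)
        assert cs.total_force == 0.0
        assert np.all(cs.force_max == 0.0) and np.all(cs.force_mand == 0.0)
        cs.check()

    def test_uniform_interference_gives_series_column_pressure(self):
        """0.01 mm uniform overlap → exactly E·g/(2h) = 20.625 MPa."""
        pair = oc.make_interference_pair("flat", 0.01)
        cs = oc.winkler_pressures(pair.mand, pair.max, pair.pose, E_F)
        assert cs.pressure_max == pytest.approx(np.full(41, SERIES_PRESSURE),
                                                abs=1e-12)
        assert cs.pressure_mand == pytest.approx(np.full(41, SERIES_PRESSURE),
                                                 abs=1e-12)
        # F = p · tributary width · thickness; total = p · width · t
        assert cs.total_force == pytest.approx(SERIES_PRESSURE * 40.0)
        cs.check()

    def test_wedge_pressure_linear_and_zero_at_hinge(self):
        pair = oc.make_interference_pair("wedge", 0.01)
        cs = oc.winkler_pressures(pair.mand, pair.max, pair.pose, E_F)
        assert cs.pressure_max[0] == 0.0
        assert cs.pressure_max == pytest.approx(pair.pressure, abs=1e-9)
        assert np.all(np.diff(cs.pressure_max) > 0)

    def test_non_monotone_profile_rejected(self, identity_pose):
        x = np.array([0.0, 1.0, 0.5, 2.0])
        with pytest.raises(DataError):
            oc.SurfaceProfile(np.column_stack([x, np.zeros(4)]))
        # a pose large enough to fold x over is caught at solve time
        mand = oc.SurfaceProfile(np.column_stack([[0, 1e-4], [0, 0]]))
        maxp = oc.SurfaceProfile(np.column_stack([[0, 1], [0, 0]]),
                                 role="maxillary")
        fold = oc.RigidTransform(np.pi, np.zeros(2))
        with pytest.raises(DataError):
            oc.winkler_pressures(mand, maxp, fold, E_F)


class TestPlaneStressOperator:
    def test_single_element_has_three_rigid_body_modes(self):
        mesh = oc.build_block_mesh(1, 1, 1, 1, "mandibular")
        k = oc.assemble_plane_stress(mesh, oc.MaterialProps()).toarray()
        w = np.linalg.eigvalsh(k)
        assert np.sum(np.abs(w) < 1e-9 * w.max()) == 3
        assert np.all(w > -1e-9 * w.max())  # positive semi-definite

    def test_operator_symmetry(self):
        mesh = oc.build_block_mesh(40, 20, 10, 5, "maxillary")
        k = oc.assemble_plane_stress(mesh, oc.MaterialProps())
        assert abs(k - k.T).max() < 1e-9 * abs(k).max()

    def test_patch_uniform_stress(self):
        """Uniform top traction on a vertically-supported block reproduces a
        uniform stress state in every element to machine-level accuracy."""
        import scipy.sparse.linalg as spla

        mesh = oc.build_block_mesh(40, 20, 40, 20, "maxillary")
        mat = oc.MaterialProps()
        k = oc.assemble_plane_stress(mesh, mat)
        n = mesh.n_nodes
        f = np.zeros(2 * n)
        top = mesh.basal_nodes
        trib = oc.tributary_widths(mesh.coords[top, 0])
        f[2 * top + 1] = 10.0 * trib * mesh.thickness
        fixed = np.zeros(2 * n, dtype=bool)
        bottom = mesh.occlusal_nodes
        fixed[2 * bottom + 1] = True
        fixed[2 * bottom[0]] = True  # pin one horizontal dof
        free = ~fixed
        u = np.zeros(2 * n)
        u[free] = spla.spsolve(k[free][:, free].tocsc(), f[free])
        s = oc.element_stresses(mesh, mat, u)
        assert np.abs(s[:, 1] - 10.0).max() < 1e-6 * 10.0
        assert np.abs(s[:, 0]).max() < 1e-6 * 10.0

    def test_plane_stress_constitutive_matrix(self):
        d = _dmatrix(oc.MaterialProps(1000.0, 0.25))
        expect = 1000.0 / (1 - 0.0625) * np.array([[1, 0.25, 0],
                                                   [0.25, 1, 0],
                                                   [0, 0, 0.375]])
        assert d == pytest.approx(expect)


class TestContactFE:
    def test_separated_blocks_zero_everything(self, identity_pose):
        mand = oc.build_block_mesh(10, 5, 5, 3, "mandibular")
        maxb = oc.build_block_mesh(10, 5, 5, 3, "maxillary", y_offset=0.5)
        cs = oc.solve_contact_fe(mand, maxb, identity_pose, oc.MaterialProps(),
                                 100 * E_F)
        assert cs.total_force == 0.0
        assert np.all(cs.force_mand == 0.0)
        cs.check()

    def test_flat_interference_matches_series_column_oracle(
            self, flat_pair, identity_pose):
        """Mean FE pressure within 5 % of the 20.625 MPa closed form."""
        mand, maxb = flat_pair
        cs = oc.solve_contact_fe(mand, maxb, identity_pose, oc.MaterialProps(),
                                 100 * E_F)
        mean_p = cs.total_force / 40.0
        assert mean_p == pytest.approx(SERIES_PRESSURE, rel=0.05)
        cs.check()

    def test_action_reaction_balance(self, flat_pair, identity_pose):
        mand, maxb = flat_pair
        cs = oc.solve_contact_fe(mand, maxb, identity_pose, oc.MaterialProps(),
                                 100 * E_F)
        assert abs(cs.reaction_force) == pytest.approx(cs.total_force,
                                                       rel=1e-3)
        assert cs.force_max.sum() == pytest.approx(cs.total_force, abs=1e-9)

    def test_penalty_insensitivity(self, flat_pair, identity_pose):
        """Doubling the penalty changes total force < 2 % at the default."""
        mand, maxb = flat_pair
        f1 = oc.solve_contact_fe(mand, maxb, identity_pose, oc.MaterialProps(),
                                 100 * E_F).total_force
        f2 = oc.solve_contact_fe(mand, maxb, identity_pose, oc.MaterialProps(),
                                 200 * E_F).total_force
        assert abs(f2 - f1) / f1 < 0.02

    def test_wedge_profiles_rank_correlate_with_winkler(self, identity_pose):
        mand = oc.build_block_mesh(40, 20, 40, 20, "mandibular")
        coords = mand.coords.copy()
        surf = mand.occlusal_nodes
        coords[surf, 1] += 0.01 * coords[surf, 0] / 40.0
        mand = mand.with_coords(coords)
        maxb = oc.build_block_mesh(40, 20, 40, 20, "maxillary")
        fe = oc.solve_contact_fe(mand, maxb, identity_pose, oc.MaterialProps(),
                                 100 * E_F)
        wk = oc.winkler_pressures(oc.occlusal_profile(mand),
                                  oc.occlusal_profile(maxb),
                                  identity_pose, E_F)
        mask = (fe.pressure_max > 0) | (wk.pressure_max > 0)
        rho = spearmanr(fe.pressure_max[mask], wk.pressure_max[mask]).statistic
        assert rho == pytest.approx(1.0)


class TestNodalForceToPressure:
    def test_interior_and_end_tributaries(self):
        mesh = oc.build_block_mesh(40, 20, 40, 20, "mandibular")  # 1 mm pitch
        forces = np.zeros(41)
        forces[[0, 20]] = 5.0
        p = oc.nodal_force_to_pressure(forces, mesh)
        assert p[20] == pytest.approx(5.0)   # 1 mm tributary × 1 mm thickness
        assert p[0] == pytest.approx(10.0)   # half tributary at the end
        assert np.all(p[forces == 0.0] == 0.0)

    def test_shape_mismatch_rejected(self):
        mesh = oc.build_block_mesh(40, 20, 10, 5, "mandibular")
        with pytest.raises(DataError):
            oc.nodal_force_to_pressure(np.zeros(7), mesh)
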