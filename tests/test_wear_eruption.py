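"""Archard wear, eruption advance, and the net-eruption ledger."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import occlucurve as oc
from occlucurve.errors import DataError, StabilityError
from occlucurve.pressure import tributary_widths
from occlucurve.wear_eruption import surface_element_heights


class TestArchardIncrement:
    def test_worked_value(self):
        assert oc.archard_increment(10.0, 0.1, 1e-4) == pytest.approx(1e-4)

    def test_zero_pressure_wears_nothing(self):
        assert oc.archard_increment(0.0, 5.0, 1e-4) == 0.0

    @given(p=st.floats(0, 1e3), ds=st.floats(0, 10), k=st.floats(1e-8, 1e-2))
    def test_linearity_in_sliding(self, p, ds, k):
        assert oc.archard_increment(p, 2 * ds, k) == pytest.approx(
            2 * oc.archard_increment(p, ds, k))

    def test_negative_inputs_rejected(self):
        with pytest.raises(DataError):
            oc.archard_increment(-1.0, 0.1, 1e-4)
        with pytest.raises(DataError):
            oc.archard_increment(1.0, -0.1, 1e-4)
        with pytest.raises(DataError):
            oc.archard_increment(1.0, 0.1, 0.0)


class TestApplyWear:
    def test_zero_depths_leave_mesh_unchanged(self):
        mesh = oc.build_block_mesh(40, 20, 10, 5, "mandibular")
        worn = oc.apply_wear(mesh, np.zeros(11))
        assert np.abs(worn.coords - mesh.coords).max() < 1e-12

    @pytest.mark.parametrize("role, direction", [("mandibular", -1.0),
                                                 ("maxillary", +1.0)])
    def test_uniform_wear_moves_surface_into_block(self, role, direction):
        mesh = oc.build_block_mesh(40, 20, 40, 20, role)
        worn = oc.apply_wear(mesh, np.full(41, 0.01))
        prof = oc.occlusal_profile(worn)
        assert prof.y == pytest.approx(np.full(41, direction * 0.01), abs=1e-12)
        assert worn.area() == pytest.approx(mesh.area() - 0.01 * 40.0)

    def test_single_node_wear_area_matches_polygon_oracle(self):
        """Area loss for one lowered node equals depth × tributary width."""
        mesh = oc.build_block_mesh(40, 20, 20, 10, "mandibular")  # 2 mm pitch
        depths = np.zeros(21)
        depths[7] = 0.02
        worn = oc.apply_wear(mesh, depths, relax_sweeps=0)
        trib = tributary_widths(oc.occlusal_profile(mesh).x)
        assert mesh.area() - worn.area() == pytest.approx(0.02 * trib[7])

    def test_area_monotone_under_relaxation_too(self):
        mesh = oc.build_block_mesh(40, 20, 20, 10, "maxillary")
        rng = np.random.default_rng(7)
        depths = rng.uniform(0, 0.05, size=21)
        worn = oc.apply_wear(mesh, depths, relax_sweeps=25)
        assert worn.area() < mesh.area()

    def test_excessive_depth_raises_stability_error(self):
        mesh = oc.build_block_mesh(40, 20, 20, 10, "mandibular")
        depths = np.zeros(21)
        depths[3] = surface_element_heights(mesh)[3] + 0.1
        with pytest.raises(StabilityError):
            oc.apply_wear(mesh, depths)

    def test_negative_depths_rejected(self):
        mesh = oc.build_block_mesh(40, 20, 10, 5, "mandibular")
        with pytest.raises(DataError):
            oc.apply_wear(mesh, np.full(11, -1e-6))


class TestApplyEruption:
    def _state(self, gap=0.0, nx=10, ny=5):
        cfg = oc.config_from_dict({"nx": nx, "ny": ny, "initial_gap_mm": gap})
        return oc.initial_state(cfg)

    def test_relative_approach_is_exactly_e_c(self):
        state = self._state(gap=0.1)
        y_mand = state.mand_mesh.coords[:, 1].copy()
        y_max = state.max_mesh.coords[:, 1].copy()
        oc.apply_eruption(state, 0.01, 0.5)
        d_mand = state.mand_mesh.coords[:, 1] - y_mand
        d_max = state.max_mesh.coords[:, 1] - y_max
        assert np.all(d_mand == pytest.approx(0.005, abs=1e-15))
        assert np.all(d_max == pytest.approx(-0.005, abs=1e-15))

    def test_zero_eruption_is_identity(self):
        state = self._state()
        before = state.mand_mesh.coords.copy()
        oc.apply_eruption(state, 0.0, 0.5)
        assert np.array_equal(state.mand_mesh.coords, before)

    def test_full_split_moves_only_maxilla(self):
        state = self._state(gap=0.1)
        y_mand = state.mand_mesh.coords[:, 1].copy()
        y_max = state.max_mesh.coords[:, 1].copy()
        oc.apply_eruption(state, 0.01, 1.0)
        assert np.array_equal(state.mand_mesh.coords[:, 1], y_mand)
        assert y_max - state.max_mesh.coords[:, 1] == pytest.approx(
            np.full_like(y_max, 0.01), abs=1e-12)


class TestLedger:
    def test_unloaded_cycles_accumulate_full_relative_rate(self):
        """No contact: pair-level net eruption grows by e_c per cycle."""
        cfg = oc.config_from_dict({"nx": 10, "ny": 5, "initial_gap_mm": 1.0,
                                   "wear_coefficient": 0})
        state = oc.initial_state(cfg)
        for _ in range(3):
            oc.run_cycle(state, cfg)
        assert state.ledger.e_total_relative == pytest.approx(
            np.full(11, 3 * 0.01), abs=1e-12)
        assert state.ledger.e_total_mand == pytest.approx(
            np.full(11, 3 * 0.005), abs=1e-12)

    def test_zero_wear_coefficient_ignores_contact(self):
        cfg = oc.config_from_dict({"nx": 10, "ny": 5, "wear_coefficient": 0})
        state = oc.initial_state(cfg)
        for _ in range(4):
            oc.run_cycle(state, cfg)
        assert np.all(state.ledger.wear_mand == 0.0)
        assert state.ledger.e_total_relative == pytest.approx(
            np.full(11, 4 * 0.01), abs=1e-12)

    def test_ledger_identity_and_monotone_inhibition(self):
        led = oc.EruptionLedger.empty(5, 5)
        oc.update_ledger(led, np.full(5, 1e-3), np.full(5, 2e-3))
        oc.update_ledger(led, np.full(5, 1e-3), np.zeros(5))
        assert led.wear_mand == pytest.approx(np.full(5, 2e-3))
        assert np.all(np.diff([0, *led.wear_max]) >= 0)
        assert led.e_total_max == pytest.approx(led.eruption_max - led.wear_max,
                                                abs=1e-15)
        with pytest.raises(DataError):
            oc.update_ledger(led, np.full(5, -1e-3), np.zeros(5))


class TestSteadyStateWearBalance:
    def test_bilateral_wear_volumes_match(self, run_r100):
        """Equal-rate inhibition: per-cycle wear volume equal on both blocks."""
        import copy

        state = copy.deepcopy(run_r100.state)
        cfg = run_r100.config
        w_m = state.ledger.wear_mand.copy()
        w_x = state.ledger.wear_max.copy()
        oc.run_cycle(state, cfg)
        trib_m = tributary_widths(oc.occlusal_profile(state.mand_mesh).x)
        trib_x = tributary_widths(oc.occlusal_profile(state.max_mesh).x)
        vol_m = np.sum((state.ledger.wear_mand - w_m) * trib_m)
        vol_x = np.sum((state.ledger.wear_max - w_x) * trib_x)
        assert vol_m == pytest.approx(vol_x, rel=0.01)

    def test_per_cycle_net_eruption_vanishes_at_steady_state(self, run_r100):
        """ΔE_TOTAL ≈ 0 per cycle at contacting nodes (< 5 % of e_c)."""
        import copy

        state = copy.deepcopy(run_r100.state)
        cfg = run_r100.config
        before = state.ledger.e_total_relative.copy()
        oc.run_cycle(state, cfg)
        delta = state.ledger.e_total_relative - before
        assert np.abs(delta).max() < 0.05 * cfg.eruption_mm_per_cycle

    def test_rate_independent_attractor(self, run_r100, run_r100_half_kw):
        """Halving k_w leaves the steady-state profiles (sagitta) unchanged."""
        d_full = oc.sagitta_depth(oc.steady_profiles(run_r100)[0])
        d_half = oc.sagitta_depth(oc.steady_profiles(run_r100_half_kw)[0])
        assert d_half == pytest.approx(d_full, rel=0.02)
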