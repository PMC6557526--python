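"""Unit and property tests for the core kinetic definitions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dmt1flux as dx
from dmt1flux.model_core import MUCOSAL_BLOCK_FACTOR, RHO_GAIN

from conftest import random_state


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


class TestGeometry:
    def test_enterocyte_area_nominal(self):
        # lateral wall + two caps of a 29.6 x 6.2 um cylinder
        assert dx.enterocyte_area(29.6, 6.2) == pytest.approx(636.93, abs=0.01)

    def test_enterocyte_area_unit_cylinder(self):
        # h=1, d=2 -> 2*pi*1*1 + 2*pi*1 = 4*pi
        assert dx.enterocyte_area(1.0, 2.0) == pytest.approx(4 * math.pi, rel=1e-12)

    def test_enterocyte_area_flat_disk(self):
        # zero height leaves only the two caps
        assert dx.enterocyte_area(0.0, 2.0) == pytest.approx(2 * math.pi, rel=1e-12)

    def test_enterocyte_area_rejects_negative(self):
        with pytest.raises(ValueError):
            dx.enterocyte_area(-1.0, 2.0)

    def test_vesicle_volume_default(self, geometry):
        assert dx.vesicle_volume(geometry) == pytest.approx(2.5e-10, rel=0.02)

    def test_vesicle_volume_scales_with_release_fraction(self, geometry):
        doubled = dx.CellGeometry(release_fraction=0.02)
        assert dx.vesicle_volume(doubled) == pytest.approx(
            2 * dx.vesicle_volume(geometry), rel=1e-12
        )

    def test_gamma_default(self, geometry):
        assert geometry.gamma == pytest.approx(2.548e-13, rel=1e-3)
        assert geometry.gamma == dx.volume_correction_factor(geometry)

    def test_release_fraction_range_enforced(self):
        with pytest.raises(ValueError):
            dx.CellGeometry(release_fraction=0.06)

    @given(
        h=st.floats(0.1, 100, allow_nan=False),
        d=st.floats(0.1, 100, allow_nan=False),
    )
    def test_area_positive_and_monotone_in_height(self, h, d):
        a = dx.enterocyte_area(h, d)
        assert a > 0
        assert dx.enterocyte_area(h * 2, d) > a


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------


class TestParameters:
    def test_switch_defaults_published(self, switch_params):
        assert switch_params.k12 == 5.31e-6
        assert switch_params.k54 == 0.6492
        assert switch_params.DMT1_E == 566.10
        assert switch_params.alpha_E == 0.9890
        assert switch_params.alpha_M == 0.9780
        assert len(switch_params.PARAM_ORDER) == 10

    def test_swing_defaults_published(self, swing_params):
        assert swing_params.k12 == 1.68e-7
        assert swing_params.k56 == 3.2082
        assert swing_params.DMT1_E == 46156.25
        assert len(swing_params.PARAM_ORDER) == 9

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            dx.SwitchParameters(k23=-0.1)
        with pytest.raises(ValueError):
            dx.SwingParameters(k56=-1.0)

    def test_replace_returns_new_frozen_instance(self, swing_params):
        other = swing_params.replace(k12=1e-6)
        assert other.k12 == 1e-6
        assert swing_params.k12 == 1.68e-7

    def test_effectiveness_ratio(self, switch_params, swing_params):
        # Phi_switch / Phi_swing = DMT1_E(swing) / DMT1_E(switch)
        ratio = dx.effectiveness_ratio(switch_params, swing_params)
        assert ratio == pytest.approx(46156.25 / 566.10, rel=1e-12)
        assert dx.effectiveness_ratio(swing_params, switch_params) == pytest.approx(
            1 / ratio, rel=1e-12
        )

    def test_yaml_round_trip(self, tmp_path, switch_params, swing_params, geometry):
        for obj, kind in ((switch_params, "switch"), (swing_params, "swing"),
                          (geometry, "geometry")):
            p = tmp_path / f"{kind}.yaml"
            dx.save_parameters(obj, p)
            loaded = dx.load_parameters(p)
            assert loaded == obj

    def test_packaged_defaults_match_code_defaults(self, switch_params, swing_params,
                                                   geometry):
        from dmt1flux.model_core import _DATA_DIR

        assert dx.load_parameters(_DATA_DIR / "switch_params.yaml") == switch_params
        assert dx.load_parameters(_DATA_DIR / "swing_params.yaml") == swing_params
        assert dx.load_parameters(_DATA_DIR / "geometry.yaml") == geometry


# ---------------------------------------------------------------------------
# Protocol and state
# ---------------------------------------------------------------------------


class TestProtocolAndState:
    def test_default_protocol_shape(self, protocol):
        assert len(protocol) == 2
        for ch in protocol:
            assert ch.fe_chg == 20.0
            assert ch.duration == 15.0
            assert ch.sampling_times == (3.0, 6.0, 9.0, 12.0, 15.0)

    def test_bad_sampling_grid_rejected(self):
        with pytest.raises(ValueError):
            dx.Challenge(fe_chg=20, duration=15, sampling_times=(3, 2))
        with pytest.raises(ValueError):
            dx.Challenge(fe_chg=20, duration=15, sampling_times=(3, 20))

    def test_initial_state_switch(self):
        s = dx.initial_state("switch")
        assert s.P[0] == 1.0 and s.P[1:].sum() == 0.0
        assert s.mode is dx.Mode.ENDOCYTIC
        assert s.FeOUT == 20.0 and s.FeIN == 0.0
        s.validate()

    def test_initial_state_swing(self):
        s = dx.initial_state("swing")
        assert s.P[0] == pytest.approx(0.98)
        assert s.P[4] == s.P[5] == 0.01
        assert s.mode is None
        s.validate()

    def test_initial_state_unknown_model(self):
        with pytest.raises(ValueError):
            dx.initial_state("sliding")

    def test_state_validation_catches_bad_sum(self):
        s = dx.initial_state("switch")
        s.P[0] = 0.5
        with pytest.raises(ValueError):
            s.validate()


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------


class TestSwitchRHS:
    def test_hand_evaluated_initial_derivative(self, switch_params, geometry):
        # At P1=1, FeOUT=20, endocytic: dP1 = -k12*20 - k14; dP2 = k12*20;
        # dP4 = k14; dFeIN = 0 (P3 = P5 = 0).
        s = dx.initial_state("switch")
        d = dx.switch_rhs(s, switch_params, geometry)
        assert d.dP[0] == pytest.approx(-5.31e-6 * 20 - 11.2703, rel=1e-12)
        assert d.dP[1] == pytest.approx(5.31e-6 * 20, rel=1e-12)
        assert d.dP[3] == pytest.approx(11.2703, rel=1e-12)
        assert d.dFeIN == 0.0
        assert d.dFeOUT == 0.0

    def test_mode_gates_k45_k54(self, switch_params, geometry):
        s = dx.initial_state("switch")
        s.P = np.array([0.2, 0.1, 0.1, 0.3, 0.3, 0.0])
        endo = dx.switch_rhs(s, switch_params, geometry, mode=dx.Mode.ENDOCYTIC)
        exo = dx.switch_rhs(s, switch_params, geometry, mode=dx.Mode.EXOCYTIC)
        # endocytic: P5 can only grow; exocytic: P5 can only shrink
        assert endo.dP[4] == pytest.approx(switch_params.k45 * 20 * 0.3, rel=1e-12)
        assert exo.dP[4] == pytest.approx(-switch_params.k54 * 0.3, rel=1e-12)
        # vesicular release contributes to dFeIN only in exocytic mode
        assert exo.dFeIN > endo.dFeIN

    def test_missing_mode_rejected(self, switch_params, geometry):
        s = dx.initial_state("switch")
        s.mode = None
        with pytest.raises(ValueError):
            dx.switch_rhs(s, switch_params, geometry)


class TestSwingRHS:
    def test_hand_evaluated_initial_derivative(self, swing_params, geometry):
        # At P1=0.98, P5=P6=0.01: conv = k56*1e-4; dP1 = -k12*20*0.98 - k14*0.98
        s = dx.initial_state("swing")
        d = dx.swing_rhs(s, swing_params, geometry, rho=1.0)
        conv = 3.2082e-4
        assert d.dP[4] == pytest.approx(-conv, rel=1e-12)  # endo term is 0 (P4=0)
        assert d.dP[5] == pytest.approx(conv, rel=1e-12)  # exo term is 0 (P4=0)
        assert d.dP[0] == pytest.approx(-(1.68e-7 * 20 + 30.7036) * 0.98, rel=1e-12)
        assert d.dFeIN == pytest.approx(
            geometry.gamma * swing_params.k64 * swing_params.DMT1_E * 0.01, rel=1e-12
        )

    def test_rho_scales_only_trafficking_terms(self, swing_params, geometry):
        s = dx.initial_state("swing")
        s.P = np.array([0.5, 0.1, 0.1, 0.1, 0.1, 0.1])
        d1 = dx.swing_rhs(s, swing_params, geometry, rho=1.0)
        d2 = dx.swing_rhs(s, swing_params, geometry, rho=2.0)
        # iron flux does not see rho directly
        assert d2.dFeIN == d1.dFeIN
        # the P4<->P5/P6 exchange does
        assert d2.dP[4] != d1.dP[4]

    def test_nonfinite_rho_rejected(self, swing_params, geometry):
        s = dx.initial_state("swing")
        with pytest.raises(ValueError):
            dx.swing_rhs(s, swing_params, geometry, rho=float("nan"))


class TestRHSProperties:
    @pytest.mark.parametrize("model", ["switch", "swing"])
    def test_transporter_conservation_random_states(self, model, switch_params,
                                                    swing_params, geometry):
        rng = np.random.default_rng(7)
        for _ in range(200):
            s = random_state(rng, model)
            if model == "switch":
                mode = dx.Mode.ENDOCYTIC if rng.random() < 0.5 else dx.Mode.EXOCYTIC
                d = dx.switch_rhs(s, switch_params, geometry, mode=mode)
            else:
                d = dx.swing_rhs(s, swing_params, geometry, rho=float(rng.uniform(-2, 3)))
            assert abs(d.dP.sum()) < 1e-12
            # iron mass balance: V_a*dFeOUT + V_cb*dFeIN = 0 exactly
            assert geometry.V_a * d.dFeOUT + geometry.V_cb * d.dFeIN == pytest.approx(
                0.0, abs=1e-12 * max(1.0, abs(d.dFeIN) * geometry.V_cb)
            )
            # uptake flux non-negative for non-negative states
            assert d.dFeIN >= 0.0


# ---------------------------------------------------------------------------
# Kinetic correction factor
# ---------------------------------------------------------------------------


class TestRhoFactor:
    def test_identity_during_first_challenge(self):
        for fe_in in (0.0, 0.1, 5.0):
            assert dx.rho_factor(fe_in, 1, [0.0], [20.0]) == 1.0

    def test_second_challenge_start_equal_doses(self):
        # at the start of challenge 2, FeIN equals the recorded FeUP, so
        # rho = 1 - 2.8*(1 - 1.67) = 2.876 for equal concentrations
        fe_up = 0.3
        rho = dx.rho_factor(fe_up, 2, [0.0, fe_up], [20.0, 20.0])
        assert rho == pytest.approx(1 - RHO_GAIN * (1 - MUCOSAL_BLOCK_FACTOR), rel=1e-12)
        assert rho == pytest.approx(2.876, abs=1e-12)

    def test_decays_as_iron_accumulates(self):
        fe_up = 0.3
        hist_up, hist_chg = [0.0, fe_up], [20.0, 20.0]
        rhos = [dx.rho_factor(f, 2, hist_up, hist_chg) for f in (0.3, 0.5, 1.0, 5.0)]
        assert all(a > b for a, b in zip(rhos, rhos[1:]))

    def test_unequal_concentrations_scale(self):
        # halving the current challenge concentration doubles the damping term
        fe_up = 0.3
        r_eq = dx.rho_factor(0.6, 2, [0.0, fe_up], [20.0, 20.0])
        r_half = dx.rho_factor(0.6, 2, [0.0, fe_up], [20.0, 10.0])
        assert (1 - r_half) == pytest.approx(2 * (1 - r_eq), rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            dx.rho_factor(1.0, 0, [], [])
        with pytest.raises(ValueError):
            dx.rho_factor(0.0, 2, [0.0, 0.3], [20.0, 20.0])  # FeIN=0 after challenge 1
        with pytest.raises(ValueError):
            dx.rho_factor(1.0, 2, [0.0], [20.0])  # history too short


# ---------------------------------------------------------------------------
# Mode update rule
# ---------------------------------------------------------------------------


class TestModeUpdate:
    def _state_with(self, p5):
        s = dx.initial_state("switch")
        s.P = np.array([1 - p5, 0, 0, 0, p5, 0.0])
        return s

    def test_endocytic_flips_at_alpha_E(self, switch_params):
        below = self._state_with(0.98)
        at = self._state_with(switch_params.alpha_E)
        assert dx.update_switch_mode(below, switch_params, dx.Mode.ENDOCYTIC) is dx.Mode.ENDOCYTIC
        # ties resolve toward switching (closed comparison)
        assert dx.update_switch_mode(at, switch_params, dx.Mode.ENDOCYTIC) is dx.Mode.EXOCYTIC

    def test_exocytic_flips_at_alpha_M(self, switch_params):
        low_membrane = self._state_with(0.5)
        high_membrane = self._state_with(1 - switch_params.alpha_M)
        assert dx.update_switch_mode(low_membrane, switch_params, dx.Mode.EXOCYTIC) is dx.Mode.EXOCYTIC
        assert dx.update_switch_mode(high_membrane, switch_params, dx.Mode.EXOCYTIC) is dx.Mode.ENDOCYTIC

    def test_unreachable_threshold_pins_mode(self, switch_params):
        # thresholds above 1 (admissible for sensitivity scans) never trip
        pinned = switch_params.replace(alpha_E=1.1)
        s = self._state_with(1.0)
        assert dx.update_switch_mode(s, pinned, dx.Mode.ENDOCYTIC) is dx.Mode.ENDOCYTIC
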