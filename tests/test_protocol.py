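"""Forcing functions: gastric emptying, volumes, pH, bile, secretion split."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gastrosim as gs
from gastrosim.protocol import bile_profile_slope

FED_BILE = [(0.0, 3.0), (15.0, 3.0), (25.0, 15.4), (65.0, 15.4), (100.0, 3.0)]


class TestGastricEmptying:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (0.0, math.log(2) / 19 * 20 + 2.5),  # 3.229 mL/min
            (1e6, 2.5),  # only secretion compensation remains
        ],
    )
    def test_fasted_flow(self, sporanox_nowater, t, expected):
        assert gs.gastric_emptying_flow(t, sporanox_nowater) == pytest.approx(
            expected, rel=1e-6
        )

    def test_fed_flow_lag_then_linear(self, indinavir_fed_protein):
        assert gs.gastric_emptying_flow(10.0, indinavir_fed_protein) == 0.0
        # secretion compensation + linear dose emptying (650 mL over 240 min)
        assert gs.gastric_emptying_flow(120.0, indinavir_fed_protein) == pytest.approx(
            2.5 + 650.0 / 240.0
        )

    def test_negative_time_rejected(self, sporanox_nowater):
        with pytest.raises(ValueError):
            gs.gastric_emptying_flow(-1.0, sporanox_nowater)

    def test_fasted_volume_derivative_is_secretion_minus_emptying(
        self, sporanox_water
    ):
        h = 1e-4
        for t in np.linspace(1.0, 170.0, 23):
            dv = (
                gs.stomach_volume(t + h, sporanox_water)
                - gs.stomach_volume(t - h, sporanox_water)
            ) / (2 * h)
            expected = sporanox_water.F1 - gs.gastric_emptying_flow(t, sporanox_water)
            assert dv == pytest.approx(expected, rel=1e-6, abs=1e-9)

    def test_fed_emptied_volume_equals_dose(self, indinavir_fed_protein):
        # with the emptying window equal to duration - lag, the dose volume
        # leaves the stomach exactly once over [lag, duration]
        p = indinavir_fed_protein.model_copy(update={"dose_empty_minutes": 225.0})
        from scipy.integrate import quad

        emptied, _ = quad(
            lambda t: gs.gastric_emptying_flow(t, p) - p.F1, p.lag, p.duration
        )
        assert emptied == pytest.approx(p.V_dose, rel=1e-6)


class TestStomachVolume:
    def test_fasted_initial_and_limit(self, sporanox_nowater):
        assert gs.stomach_volume(0.0, sporanox_nowater) == pytest.approx(75.0)
        assert gs.stomach_volume(1e6, sporanox_nowater) == pytest.approx(55.0)

    def test_fed_volume_constant_during_lag(self, indinavir_fed_protein):
        assert gs.stomach_volume(7.0, indinavir_fed_protein) == pytest.approx(705.0)

    def test_fed_volume_never_below_basal(self, indinavir_fed_protein):
        p = indinavir_fed_protein.model_copy(update={"dose_empty_minutes": 60.0})
        assert gs.stomach_volume(200.0, p) == pytest.approx(p.V_fast)


class TestStomachPH:
    def test_fasted_constant_setpoint(self, sporanox_nowater):
        for t in (0.0, 90.0, 180.0):
            assert gs.stomach_pH(t, sporanox_nowater) == 1.6

    def test_fed_sigmoid_endpoints_and_midpoint(self, indinavir_fed_protein):
        p = indinavir_fed_protein
        assert gs.stomach_pH(0.0, p) == pytest.approx(4.6, rel=0.01)
        assert gs.stomach_pH(240.0, p) == pytest.approx(1.6, rel=0.01)
        assert gs.stomach_pH(120.0, p) == pytest.approx(3.1, abs=1e-9)

    def test_fed_sigmoid_monotone_decreasing(self, indinavir_fed_protein):
        ts = np.linspace(0, 240, 97)
        vals = [gs.stomach_pH(t, indinavir_fed_protein) for t in ts]
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestBileProfile:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (7.0, 3.0),
            (25.0, 15.4),
            (45.0, 15.4),
            (82.5, 9.2),  # midway on the decline from (65, 15.4) to (100, 3)
            (150.0, 3.0),  # constant extrapolation after the last node
        ],
    )
    def test_fed_profile_values(self, t, expected):
        assert gs.bile_salt_concentration(t, FED_BILE) == pytest.approx(expected)

    def test_nodes_reproduced_exactly(self):
        for t, c in FED_BILE:
            assert gs.bile_salt_concentration(t, FED_BILE) == c

    @given(t=st.floats(min_value=0.0, max_value=160.0))
    @settings(max_examples=50, deadline=None)
    def test_piecewise_linear_continuity(self, t):
        h = 1e-7
        left = gs.bile_salt_concentration(max(t - h, 0.0), FED_BILE)
        right = gs.bile_salt_concentration(t + h, FED_BILE)
        assert abs(right - left) < 1e-4

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            gs.bile_salt_concentration(10.0, [])
        with pytest.raises(ValueError):
            bile_profile_slope(10.0, [])


class TestSecretionSplit:
    def test_fasted_split_is_all_secretion(self, sporanox_nowater):
        assert gs.duodenal_secretion_split(30.0, sporanox_nowater) == (2.5, 0.0)

    def test_reduced_bile_fed_split_constant(self):
        p = gs.load_protocol("indinavir_fed_carb_lowbile")
        assert gs.duodenal_secretion_split(30.0, p) == (8.0, 0.0)

    def test_target_equal_to_stock_clamps_to_full_secretion(
        self, indinavir_fed_protein
    ):
        stock = indinavir_fed_protein.bile_stock_mM
        p = indinavir_fed_protein.model_copy(
            update={"bile_profile": [(0.0, stock)], "bile_init_mM": stock}
        )
        with pytest.warns(RuntimeWarning, match="unreachable"):
            split = gs.duodenal_secretion_split(30.0, p)
        assert split == (p.F3_total, 0.0)

    def test_split_tracks_profile_within_bounds(self, indinavir_fed_protein):
        p = indinavir_fed_protein
        for t in np.linspace(15.0, 240.0, 46):
            f31, f32 = gs.duodenal_secretion_split(t, p)
            assert 0.0 <= f31 <= p.F3_total
            assert f31 + f32 == pytest.approx(p.F3_total)

    def test_flow_state_sums(self, indinavir_fed_protein, sporanox_nowater):
        for p in (indinavir_fed_protein, sporanox_nowater):
            for t in np.linspace(0.0, p.duration, 25):
                fl = gs.flow_state(t, p)
                assert fl.F4 == fl.F2 + fl.F3_1 + fl.F3_2

    def test_fed_flows_pause_during_lag(self, indinavir_fed_protein):
        fl = gs.flow_state(10.0, indinavir_fed_protein)
        assert (fl.F2, fl.F3_1, fl.F3_2) == (0.0, 0.0, 0.0)


class TestProtocolValidation:
    def test_unsorted_sampling_times_rejected(self, sporanox_nowater):
        raw = sporanox_nowater.model_dump()
        raw["sampling_times"] = [7, 30, 15]
        with pytest.raises(ValueError, match="strictly increasing"):
            gs.Protocol.model_validate(raw)

    def test_fasted_requires_half_time(self, sporanox_nowater):
        raw = sporanox_nowater.model_dump()
        raw["T_half"] = None
        with pytest.raises(ValueError, match="T_half"):
            gs.Protocol.model_validate(raw)

    def test_sample_volume_must_fit_compartments(self, sporanox_nowater):
        raw = sporanox_nowater.model_dump()
        raw["sample_volume"] = 40.0
        with pytest.raises(ValueError, match="sample_volume"):
            gs.Protocol.model_validate(raw)
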