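"""Simulator: oracles, mass ledger, sampling events, limiting behavior.

The pure-dilution stomach has an independent quadrature solution
(dC/dt = −C·F1/V(t) between sampling events, times (1 − v/V) per event),
used as the oracle for the ODE path.
"""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import gastrosim as gs
from gastrosim.simulate import CompartmentState


def dilution_oracle(protocol, C0_uM, t):
    """Quadrature solution of the stomach pure-dilution balance at time t
    (pre-sampling value), including earlier sampling-replacement dilution."""
    integral, _ = quad(
        lambda u: protocol.F1 / gs.stomach_volume(u, protocol), 0.0, t, limit=200
    )
    c = C0_uM * math.exp(-integral)
    for ti in protocol.sampling_times:
        if ti < t:
            c *= 1.0 - protocol.sample_volume / gs.stomach_volume(ti, protocol)
    return c


def constant_volume_protocol(**overrides):
    base = dict(
        name="const_volume",
        prandial_state="fasted",
        V_fast=55.0,
        V_dose=0.0,
        dose_umol=55.0,  # 1000 μM in 55 mL
        dose_form="solution",
        F1=2.5,
        T_half=19.0,
        F3_total=2.5,
        bile_stock_mM=6.0,
        sampling_times=[],
        sample_volume=0.0,
        duration=120.0,
    )
    base.update(overrides)
    return gs.Protocol.model_validate(base)


class TestDilutionOracles:
    def test_constant_volume_limit_matches_closed_form(self):
        p = constant_volume_protocol()
        res = gs.inert_marker_run(p, dense_step=5.0)
        st = res.dense[res.dense.compartment == "stomach"]
        C0 = p.dose_umol / p.V_fast * 1e3
        expected = C0 * np.exp(-p.F1 * st.time_min.to_numpy() / p.V_fast)
        np.testing.assert_allclose(
            st.conc_total_uM.to_numpy(), expected, rtol=1e-6
        )

    @pytest.mark.parametrize(
        "fixture_name", ["sporanox_fasted_nowater", "sporanox_fasted_water"]
    )
    def test_stomach_matches_quadrature_oracle(self, fixture_name, itraconazole):
        protocol = gs.load_protocol(fixture_name)
        res = gs.run(protocol, itraconazole, dense_step=None)
        C0 = protocol.dose_umol / (protocol.V_fast + protocol.V_dose) * 1e3
        for _, row in res.sampled_table.iterrows():
            expected = dilution_oracle(protocol, C0, row.time_min)
            assert row.stomach_total_uM == pytest.approx(expected, rel=1e-3)

    def test_duodenal_marker_steady_state(self):
        # near-constant stomach feed: huge reservoir, constant flows
        p = constant_volume_protocol(V_fast=1e6, dose_umol=1e6, duration=200.0)
        res = gs.inert_marker_run(p, dense_step=None)
        st = res.dense[res.dense.compartment == "stomach"]
        du = res.dense[res.dense.compartment == "duodenum"]
        c_in = st.conc_total_uM.iloc[-1]
        expected = c_in * p.F1 / (p.F1 + p.F3_total)
        assert du.conc_total_uM.iloc[-1] == pytest.approx(expected, rel=1e-3)

    def test_duodenal_peak_lags_stomach_peak(self, fasted_marker_run):
        res = fasted_marker_run
        st = res.dense[res.dense.compartment == "stomach"]
        du = res.dense[res.dense.compartment == "duodenum"]
        t_st = st.time_min.iloc[int(np.argmax(st.conc_total_uM.to_numpy()))]
        t_du = du.time_min.iloc[int(np.argmax(du.conc_total_uM.to_numpy()))]
        assert t_du > t_st


class TestMassLedger:
    def test_ledger_closes_for_drug_runs(self, sporanox_nowater, itraconazole,
                                         indinavir_fasted, indinavir):
        for p, d in ((sporanox_nowater, itraconazole), (indinavir_fasted, indinavir)):
            res = gs.run(p, d, dense_step=None)
            assert res.mass_balance_error().max() <= 1e-6

    def test_no_permeability_means_empty_acceptor(self, fasted_marker_run):
        assert np.all(fasted_marker_run.permeated_umol == 0.0)

    def test_solution_without_precipitation_keeps_solute_equal_total(
        self, sporanox_nowater, itraconazole
    ):
        d = itraconazole.model_copy(update={"k_prec": 0.0})
        res = gs.run(sporanox_nowater, d, dense_step=None)
        np.testing.assert_allclose(
            res.dense.conc_solute_uM.to_numpy(),
            res.dense.conc_total_uM.to_numpy(),
            rtol=1e-9,
            atol=1e-12,
        )


class TestSamplingEvents:
    def test_event_removes_proportional_share(self):
        state = CompartmentState(
            V=300.0, pH=6.5, bile_mM=0.0, binder_mM=2.0,
            drug_solid=0.0, drug_bound=0.0, drug_free=30.0,
        )
        new, removed = gs.apply_sampling_event(state, 1.0)
        assert removed == pytest.approx(30.0 / 300.0)
        assert new.V == 300.0
        assert new.drug_free == pytest.approx(30.0 * (1 - 1 / 300.0))
        assert new.binder_mM == pytest.approx(2.0 * (1 - 1 / 300.0))

    def test_zero_volume_event_is_identity(self):
        state = CompartmentState(
            V=30.0, pH=6.5, bile_mM=3.0, binder_mM=0.0,
            drug_solid=1.0, drug_bound=0.0, drug_free=2.0,
        )
        new, removed = gs.apply_sampling_event(state, 0.0)
        assert removed == 0.0
        assert new == state

    def test_oversized_sample_rejected(self):
        state = CompartmentState(
            V=30.0, pH=6.5, bile_mM=0.0, binder_mM=0.0,
            drug_solid=0.0, drug_bound=0.0, drug_free=1.0,
        )
        with pytest.raises(ValueError):
            gs.apply_sampling_event(state, 30.0)

    def test_schedule_lengths_match_protocols(
        self, sporanox_nowater, itraconazole, indinavir_fasted, indinavir
    ):
        res_itra = gs.run(sporanox_nowater, itraconazole, dense_step=None)
        res_indi = gs.run(indinavir_fasted, indinavir, dense_step=None)
        assert len(res_itra.sampled_table) == 13
        assert len(res_indi.sampled_table) == 17


class TestFedLagPhase:
    def test_stomach_concentration_is_initial_dilution_at_first_sample(
        self, indinavir_fed_protein, indinavir
    ):
        res = gs.run(indinavir_fed_protein, indinavir, dense_step=None)
        p = indinavir_fed_protein
        expected = p.dose_umol / (p.V_fast + p.V_dose) * 1e3
        assert res.sampled_table.stomach_total_uM.iloc[0] == pytest.approx(
            expected, rel=1e-6
        )


class TestMonotonicity:
    def test_permeated_amount_increases_with_permeability(
        self, indinavir_fasted, indinavir
    ):
        finals = []
        for scale in (0.5, 1.0, 2.0):
            d = indinavir.model_copy(update={"P_eff": indinavir.P_eff * scale})
            res = gs.run(indinavir_fasted, d, dense_step=None)
            finals.append(res.permeated_umol[-1])
        assert finals[0] < finals[1] < finals[2]

    def test_duodenal_solute_auc_decreases_with_precipitation_rate(
        self, indinavir_fasted, indinavir
    ):
        aucs = []
        for scale in (0.5, 1.0, 2.0):
            d = indinavir.model_copy(update={"k_prec": indinavir.k_prec * scale})
            res = gs.run(indinavir_fasted, d, dense_step=None)
            st = res.sampled_table
            aucs.append(
                gs.auc_trapezoid(st.time_min, st.duodenum_solute_uM, 0.0, 240.0)
            )
        assert aucs[0] > aucs[1] > aucs[2]
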