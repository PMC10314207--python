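"""Three-compartment mass-balance simulator with sampling events.

The apparatus is modeled as a stomach of time-varying volume emptying into
a constant-volume duodenal donor compartment, which is continuously diluted
by secretions, emptied to waste, and coupled to a constant-volume acceptor
sink across a dialysis membrane.  Drug exists as suspended solid, dissolved
(colloid-bound + free) and permeated species; the co-dosed binder
(e.g. cyclodextrin) and the duodenal bile salts are advected by the same
flow schedules, so intraluminal dilution of the solubilizer emerges
mechanistically.

Integration is piecewise between breakpoints (fed lag start/end, bile
profile nodes) and sampling events; each 1 mL sample removes a
proportional share of every suspended and dissolved species and is
replaced by blank medium, mirroring the wet-lab sampling-with-replacement
design.  The mass ledger (stomach + duodenum + acceptor + waste + sampled)
closes to solver tolerance at every output time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .drug import (
    DrugProperties,
    apparent_solubility,
    dissolution_precipitation_rate,
    free_fraction,
    permeation_flux,
)
from .protocol import (
    Protocol,
    flow_state,
    stomach_pH,
    stomach_volume,
)

__all__ = [
    "CompartmentState",
    "SimulationResult",
    "SimulationError",
    "run",
    "inert_marker_run",
    "apply_sampling_event",
    "marker_drug",
]

# state vector layout
_S_SOLID, _S_DISS, _S_BINDER = 0, 1, 2
_D_SOLID, _D_DISS, _D_BINDER, _D_BILE = 3, 4, 5, 6
_A_DRUG, _W_DRUG = 7, 8
_NSTATE = 9


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or produces unphysical state."""


@dataclass
class CompartmentState:
    """Instantaneous snapshot of one compartment (amounts in μmol, V in mL)."""

    V: float
    pH: float
    bile_mM: float
    binder_mM: float
    drug_solid: float
    drug_bound: float
    drug_free: float

    @property
    def solute_uM(self) -> float:
        return (self.drug_bound + self.drug_free) / self.V * 1e3

    @property
    def total_uM(self) -> float:
        return self.solute_uM + self.drug_solid / self.V * 1e3


def apply_sampling_event(
    state: CompartmentState, sample_volume: float
) -> tuple[CompartmentState, float]:
    """Withdraw ``sample_volume`` mL and replace it with blank medium.

    Removes the proportional share of every dissolved and suspended species
    (drug, binder, bile); the volume is restored so V is unchanged.
    Returns the post-event state and the drug amount removed.
    """
    if sample_volume >= state.V:
        raise ValueError("sample volume must be smaller than the compartment")
    if sample_volume < 0:
        raise ValueError("sample volume must be nonnegative")
    f = 1.0 - sample_volume / state.V
    removed = (1.0 - f) * (state.drug_solid + state.drug_bound + state.drug_free)
    new = CompartmentState(
        V=state.V,
        pH=state.pH,
        bile_mM=state.bile_mM * f,
        binder_mM=state.binder_mM * f,
        drug_solid=state.drug_solid * f,
        drug_bound=state.drug_bound * f,
        drug_free=state.drug_free * f,
    )
    return new, removed


@dataclass
class SimulationResult:
    """Dense and sampled output of one run."""

    protocol: Protocol
    drug: DrugProperties
    times: np.ndarray  # min, dense grid
    dense: pd.DataFrame  # long format, one row per (time, compartment)
    sampled_table: pd.DataFrame  # wide, one row per sampling time
    permeated_umol: np.ndarray
    waste_umol: np.ndarray
    sampled_umol: np.ndarray  # cumulative, on the dense grid
    dose_umol: float

    def mass_balance_error(self) -> np.ndarray:
        """Relative ledger error |dose − Σ compartments| / dose per time."""
        st = self.dense[self.dense.compartment == "stomach"]
        du = self.dense[self.dense.compartment == "duodenum"]
        total = (
            st.amount_umol.to_numpy()
            + du.amount_umol.to_numpy()
            + self.permeated_umol
            + self.waste_umol
            + self.sampled_umol
        )
        return np.abs(total - self.dose_umol) / self.dose_umol

    def compartment_series(self, compartment: str, column: str) -> np.ndarray:
        sub = self.dense[self.dense.compartment == compartment]
        return sub[column].to_numpy()

    def to_dense_csv(self, path) -> None:
        self.dense.to_csv(path, index=False)

    def to_sampled_csv(self, path) -> None:
        self.sampled_table.to_csv(path, index=False)


def marker_drug(name: str = "inert_marker", MW: float = 615.6) -> DrugProperties:
    """A fully soluble, non-permeating, non-binding transfer marker."""
    return DrugProperties(
        name=name, MW=MW, pKa=[], S0=1e9, S_salt_cap=1e9, P_eff=0.0, A=65.0
    )


def _bile_factors(protocol: Protocol) -> tuple[float, float]:
    return protocol.bile_solub_factor, protocol.bile_entrapment_factor


def _rhs(t, y, protocol: Protocol, drug: DrugProperties):
    V_S = stomach_volume(t, protocol)
    fl = flow_state(t, protocol)
    F2, F4 = fl.F2, fl.F4
    pH_S = stomach_pH(t, protocol)
    solub_f, entrap_f = _bile_factors(protocol)

    s_solid = max(y[_S_SOLID], 0.0)
    s_diss = max(y[_S_DISS], 0.0)
    s_binder = max(y[_S_BINDER], 0.0)
    d_solid = max(y[_D_SOLID], 0.0)
    d_diss = max(y[_D_DISS], 0.0)
    d_binder = max(y[_D_BINDER], 0.0)
    d_bile = max(y[_D_BILE], 0.0)

    # smooth gate on the remaining solid: regularizes the hard `solid > 0`
    # switch of the dissolution law so the RHS stays continuous when the
    # solid depletes (scale ~1e-6 of the dose, far below assay resolution)
    gate_scale = 1e-6 * max(protocol.dose_umol, 1.0)

    def gated(rate: float, solid: float) -> float:
        if rate > 0:
            return rate * solid / (solid + gate_scale)
        return rate

    # stomach: dissolution at gastric pH, no bile micelles, binder present
    b_s = s_binder / V_S  # μmol/mL == mM
    C_s = s_diss / V_S * 1e3  # μM
    S_app_s = apparent_solubility(drug, pH_S, bile_mM=0.0, binder_mM=b_s)
    r_s = gated(
        dissolution_precipitation_rate(
            C_s, max(s_solid, gate_scale), S_app_s, V_S, drug, smooth_onset=0.05
        ),
        s_solid,
    )

    # duodenum: dissolution/precipitation, solubilization, permeation
    V_D = protocol.V_duo
    b_d = d_binder / V_D
    bile_d = d_bile / V_D
    C_d = d_diss / V_D * 1e3
    S_app_d = apparent_solubility(
        drug, protocol.duodenal_pH, bile_mM=bile_d, binder_mM=b_d, bile_factor=solub_f
    )
    r_d = gated(
        dissolution_precipitation_rate(
            C_d, max(d_solid, gate_scale), S_app_d, V_D, drug, smooth_onset=0.05
        ),
        d_solid,
    )
    f_free = free_fraction(
        C_d,
        b_d,
        drug.binder,
        bile_mM=bile_d,
        SR_bile=drug.SR_bile,
        bile_entrapment=entrap_f,
    )
    # acceptor treated as a perfect sink (surfactant keeps free conc ~ 0)
    J = permeation_flux(C_d * f_free, 0.0, drug)

    dy = np.zeros(_NSTATE)
    out_s = F2 / V_S
    dy[_S_SOLID] = -r_s - s_solid * out_s
    dy[_S_DISS] = r_s - s_diss * out_s
    dy[_S_BINDER] = -s_binder * out_s

    out_d = F4 / V_D
    dy[_D_SOLID] = s_solid * out_s - d_solid * out_d - r_d
    dy[_D_DISS] = s_diss * out_s + r_d - d_diss * out_d - J
    dy[_D_BINDER] = s_binder * out_s - d_binder * out_d
    dy[_D_BILE] = fl.F3_1 * protocol.bile_stock_mM - d_bile * out_d
    dy[_A_DRUG] = J
    dy[_W_DRUG] = (d_solid + d_diss) * out_d
    return dy


def _segment_points(protocol: Protocol, dense_step: Optional[float]):
    """Breakpoints (flow/bile discontinuities + sampling times) and grid."""
    brk = {0.0, protocol.duration}
    brk.update(protocol.sampling_times)
    if protocol.prandial_state == "fed":
        brk.add(protocol.lag)
        brk.add(min(protocol.lag + protocol.dose_empty_minutes, protocol.duration))
    for t, _ in protocol.bile_profile:
        if 0.0 < t < protocol.duration:
            brk.add(t)
    breakpoints = sorted(b for b in brk if 0.0 <= b <= protocol.duration)
    if dense_step is None:
        grid = np.array(sorted({0.0, *protocol.sampling_times, protocol.duration}))
    else:
        grid = np.union1d(
            np.arange(0.0, protocol.duration + dense_step / 2, dense_step),
            np.array(breakpoints),
        )
    return breakpoints, grid


def run(
    protocol: Protocol,
    drug: DrugProperties,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    dense_step: Optional[float] = 0.5,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate one scenario and return dense plus sampled time series.

    ``dense_step`` sets the output grid spacing in minutes (``None``:
    output only at sampling times).  Deterministic for fixed inputs.
    """
    y = np.zeros(_NSTATE)
    if protocol.dose_form == "solution":
        y[_S_DISS] = protocol.dose_umol
    else:
        y[_S_SOLID] = protocol.dose_umol
    y[_S_BINDER] = protocol.binder_dose_umol
    y[_D_BILE] = protocol.bile_init_mM * protocol.V_duo

    breakpoints, grid = _segment_points(protocol, dense_step)
    sampling = set(protocol.sampling_times)
    solub_f, entrap_f = _bile_factors(protocol)

    times: list[float] = []
    states: list[np.ndarray] = []
    sampled_cum: list[float] = []
    sampled_rows: list[dict] = []
    cum_sampled = 0.0

    def record(t: float, yv: np.ndarray) -> None:
        times.append(t)
        states.append(yv.copy())
        sampled_cum.append(cum_sampled)

    record(0.0, y)
    for t0, t1 in zip(breakpoints, breakpoints[1:]):
        t_eval = grid[(grid > t0) & (grid <= t1)]
        if t_eval.size == 0 or t_eval[-1] < t1:
            t_eval = np.append(t_eval, t1)
        sol = solve_ivp(
            _rhs,
            (t0, t1),
            y,
            t_eval=t_eval,
            args=(protocol, drug),
            method=method,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(
                f"solver failed in [{t0:.2f}, {t1:.2f}] min: {sol.message}"
            )
        for tt, yy in zip(sol.t, sol.y.T):
            record(float(tt), yy)
        y = sol.y[:, -1].copy()
        if np.min(y) < -1e-6 * max(protocol.dose_umol, 1.0):
            raise SimulationError(f"negative state at t={t1:.2f} min: {y}")
        y = np.maximum(y, 0.0)

        if t1 in sampling:
            row = _measure(t1, y, protocol, drug, solub_f, entrap_f)
            sampled_rows.append(row)
            y, removed = _sample_all(t1, y, protocol)
            cum_sampled += removed

    return _assemble_result(
        protocol, drug, times, states, sampled_cum, sampled_rows, solub_f, entrap_f
    )


def _sample_all(
    t: float, y: np.ndarray, protocol: Protocol
) -> tuple[np.ndarray, float]:
    """Apply the sampling-with-replacement event to all three compartments.

    The withdrawn volume is replaced with blank medium, so every
    compartment volume (and the closed-form stomach volume) is unchanged.
    """
    v = protocol.sample_volume
    y = y.copy()
    removed = 0.0
    if v <= 0:
        return y, removed
    f_s = 1.0 - v / stomach_volume(t, protocol)
    for idx in (_S_SOLID, _S_DISS, _S_BINDER):
        if idx in (_S_SOLID, _S_DISS):
            removed += y[idx] * (1.0 - f_s)
        y[idx] *= f_s
    f_d = 1.0 - v / protocol.V_duo
    for idx in (_D_SOLID, _D_DISS, _D_BINDER, _D_BILE):
        if idx in (_D_SOLID, _D_DISS):
            removed += y[idx] * (1.0 - f_d)
        y[idx] *= f_d
    f_a = 1.0 - v / protocol.V_sink
    removed += y[_A_DRUG] * (1.0 - f_a)
    y[_A_DRUG] *= f_a
    return y, removed


def _measure(
    t: float,
    y: np.ndarray,
    protocol: Protocol,
    drug: DrugProperties,
    solub_f: float,
    entrap_f: float,
) -> dict:
    """Pre-event concentrations at a sampling time (what the assay reports)."""
    V_S = stomach_volume(t, protocol)
    V_D, V_A = protocol.V_duo, protocol.V_sink
    bile_d = y[_D_BILE] / V_D
    b_d = y[_D_BINDER] / V_D
    C_d = y[_D_DISS] / V_D * 1e3
    S_app_d = apparent_solubility(
        drug, protocol.duodenal_pH, bile_mM=bile_d, binder_mM=b_d, bile_factor=solub_f
    )
    f_free = free_fraction(
        C_d, b_d, drug.binder, bile_mM=bile_d, SR_bile=drug.SR_bile,
        bile_entrapment=entrap_f,
    )
    return {
        "time_min": t,
        "stomach_total_uM": (y[_S_SOLID] + y[_S_DISS]) / V_S * 1e3,
        "stomach_solute_uM": y[_S_DISS] / V_S * 1e3,
        "duodenum_total_uM": (y[_D_SOLID] + y[_D_DISS]) / V_D * 1e3,
        "duodenum_solute_uM": C_d,
        "duodenum_free_uM": C_d * f_free,
        "duodenum_thermo_solubility_uM": S_app_d,
        "duodenum_bile_mM": bile_d,
        "permeate_total_uM": y[_A_DRUG] / V_A * 1e3,
    }


def _assemble_result(
    protocol, drug, times, states, sampled_cum, sampled_rows, solub_f, entrap_f
) -> SimulationResult:
    t_arr = np.asarray(times)
    Y = np.vstack(states)
    samp = np.asarray(sampled_cum)

    rows = []
    for i, t in enumerate(t_arr):
        y = Y[i]
        V_S = stomach_volume(t, protocol)
        bile_d = y[_D_BILE] / protocol.V_duo
        b_d = y[_D_BINDER] / protocol.V_duo
        C_d = y[_D_DISS] / protocol.V_duo * 1e3
        f_free = free_fraction(
            C_d, b_d, drug.binder, bile_mM=bile_d, SR_bile=drug.SR_bile,
            bile_entrapment=entrap_f,
        )
        rows.append(
            (t, "stomach", (y[_S_SOLID] + y[_S_DISS]) / V_S * 1e3,
             y[_S_DISS] / V_S * 1e3, y[_S_DISS] / V_S * 1e3,
             y[_S_SOLID] + y[_S_DISS], 0.0, stomach_pH(t, protocol))
        )
        rows.append(
            (t, "duodenum", (y[_D_SOLID] + y[_D_DISS]) / protocol.V_duo * 1e3,
             C_d, C_d * f_free, y[_D_SOLID] + y[_D_DISS], bile_d,
             protocol.duodenal_pH)
        )
        rows.append(
            (t, "acceptor", y[_A_DRUG] / protocol.V_sink * 1e3,
             y[_A_DRUG] / protocol.V_sink * 1e3,
             y[_A_DRUG] / protocol.V_sink * 1e3, y[_A_DRUG], 0.0, 6.5)
        )
    dense = pd.DataFrame(
        rows,
        columns=[
            "time_min", "compartment", "conc_total_uM", "conc_solute_uM",
            "conc_free_uM", "amount_umol", "bile_mM", "pH",
        ],
    )
    sampled_table = pd.DataFrame(sampled_rows)
    if not sampled_table.empty:
        thermo = sampled_table["duodenum_thermo_solubility_uM"].to_numpy()
        sampled_table["duodenum_DS"] = np.where(
            thermo > 0, sampled_table["duodenum_solute_uM"] / thermo, np.nan
        )
    return SimulationResult(
        protocol=protocol,
        drug=drug,
        times=t_arr,
        dense=dense,
        sampled_table=sampled_table,
        permeated_umol=Y[:, _A_DRUG],
        waste_umol=Y[:, _W_DRUG],
        sampled_umol=samp,
        dose_umol=protocol.dose_umol,
    )


def inert_marker_run(
    protocol: Protocol,
    C0_uM: Optional[float] = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    dense_step: Optional[float] = 0.5,
) -> SimulationResult:
    """Run the full simulator with a non-permeating, fully soluble marker.

    ``C0_uM`` sets the initial stomach concentration (dose dissolved in
    V_fast + V_dose); default keeps the protocol's dose amount.
    """
    p = protocol.model_copy(deep=True)
    if C0_uM is not None:
        p.dose_umol = C0_uM * (p.V_fast + p.V_dose) * 1e-3
    p.dose_form = "solution"
    p.binder_dose_umol = 0.0
    return run(p, marker_drug(), rtol=rtol, atol=atol, dense_step=dense_step)
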