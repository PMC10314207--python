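"""Scenario description and deterministic forcing functions.

A :class:`Protocol` captures everything the bench apparatus would be
programmed with for one run: compartment volumes, the administered dose,
gastric secretion and emptying schedules, duodenal secretion rates, the
stomach pH trajectory, the duodenal bile-salt target profile and the
sampling schedule.  The functions in this module evaluate the resulting
flow rates, volumes, pH and bile concentrations at any time point; they
are pure functions of ``(t, protocol)`` and carry no state.

Units: time min, volume mL, flow mL/min, concentration mM (bile) or
pH units, drug amounts μmol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Protocol",
    "SigmoidPH",
    "FlowState",
    "gastric_emptying_flow",
    "stomach_volume",
    "stomach_pH",
    "bile_salt_concentration",
    "bile_profile_slope",
    "duodenal_secretion_split",
    "flow_state",
]


class SigmoidPH(BaseModel):
    """Logistic stomach-pH program, pH(t) = end + (start-end)/(1+exp(k(t-mid))).

    With the default steepness the curve sits within 1% of both asymptotes
    at t=0 and t=duration for a 240 min run, and passes through the
    arithmetic midpoint of the two levels at ``midpoint_min``.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["sigmoid"] = "sigmoid"
    start: float = 4.6
    end: float = 1.6
    midpoint_min: Optional[float] = None  # default: duration / 2
    steepness: float = 0.045  # 1/min; keeps both ends within 1% over 240 min

    def value(self, t: float, duration: float) -> float:
        mid = self.midpoint_min if self.midpoint_min is not None else duration / 2.0
        return self.end + (self.start - self.end) / (
            1.0 + math.exp(self.steepness * (t - mid))
        )


class ConstantPH(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["constant"] = "constant"
    value_pH: float = 1.6

    def value(self, t: float, duration: float) -> float:
        return self.value_pH


class Protocol(BaseModel):
    """Full description of one transfer-and-permeation run."""

    model_config = ConfigDict(extra="forbid")

    name: str
    prandial_state: Literal["fasted", "fed"]
    # volumes (mL)
    V_fast: float = Field(gt=0, description="basal stomach volume")
    V_dose: float = Field(ge=0, description="administered volume")
    V_duo: float = Field(default=30.0, gt=0)
    V_sink: float = Field(default=300.0, gt=0)
    # dose
    dose_umol: float = Field(ge=0)
    dose_form: Literal["solution", "suspension"] = "solution"
    binder_dose_umol: float = Field(default=0.0, ge=0)
    # gastric flows
    F1: float = Field(gt=0, description="gastric secretion rate, mL/min")
    T_half: Optional[float] = Field(default=None, description="fasted emptying half-time, min")
    lag: float = Field(default=0.0, ge=0, description="fed gastric lag, min")
    dose_empty_minutes: Optional[float] = Field(
        default=None, gt=0, description="fed: window over which V_dose empties linearly"
    )
    # duodenal secretions
    F3_total: float = Field(gt=0)
    bile_stock_mM: float = Field(gt=0, description="bile molarity of the secretion medium")
    bile_init_mM: float = Field(default=3.0, ge=0)
    bile_profile: list[tuple[float, float]] = Field(
        default=[(0.0, 3.0)], description="target duodenal bile, (min, mM) nodes"
    )
    bile_tracking: bool = Field(
        default=False,
        description="split F3 between secretion and buffer to track bile_profile",
    )
    # pH
    stomach_pH_schedule: ConstantPH | SigmoidPH = Field(default_factory=ConstantPH)
    duodenal_pH: float = 6.5
    # food-dependent bile effects (dimensionless multipliers on the drug's SR_bile)
    bile_solub_factor: float = Field(default=1.0, ge=0)
    bile_entrapment_factor: float = Field(default=0.0, ge=0)
    # flows during the fed lag phase (apparatus starts all pumps at t=lag)
    secretions_during_lag: bool = False
    # sampling
    sampling_times: list[float]
    sample_volume: float = Field(default=1.0, ge=0)
    duration: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "Protocol":
        if self.prandial_state == "fasted":
            if self.T_half is None or self.T_half <= 0:
                raise ValueError("fasted protocol requires T_half > 0")
        else:
            if self.dose_empty_minutes is None:
                raise ValueError("fed protocol requires dose_empty_minutes")
        ts = list(self.sampling_times)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("sampling_times must be strictly increasing")
        if ts and ts[-1] > self.duration:
            raise ValueError("sampling_times must not exceed duration")
        if self.sample_volume >= min(self.V_fast, self.V_duo, self.V_sink):
            raise ValueError("sample_volume must be smaller than every compartment")
        nodes = [t for t, _ in self.bile_profile]
        if any(b <= a for a, b in zip(nodes, nodes[1:])):
            raise ValueError("bile_profile nodes must be ordered in time")
        if not self.bile_profile:
            raise ValueError("bile_profile must not be empty")
        return self

    # -- derived quantities ------------------------------------------------
    @property
    def emptying_rate_constant(self) -> float:
        """First-order gastric emptying constant k = ln2 / T_half (fasted)."""
        if self.T_half is None:
            raise ValueError("no T_half in fed mode")
        return math.log(2.0) / self.T_half

    @property
    def F_dose_linear(self) -> float:
        """Fed linear dose-emptying rate, V_dose / emptying window (mL/min)."""
        if self.dose_empty_minutes is None:
            raise ValueError("no linear emptying window in fasted mode")
        return self.V_dose / self.dose_empty_minutes


@dataclass(frozen=True)
class FlowState:
    """Instantaneous pump rates (mL/min); F4 = F2 + F3_1 + F3_2 always."""

    F2: float
    F3_1: float
    F3_2: float

    @property
    def F4(self) -> float:
        return self.F2 + self.F3_1 + self.F3_2


def _require_nonnegative_time(t: float) -> None:
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")


def gastric_emptying_flow(t: float, protocol: Protocol) -> float:
    """Gastric emptying rate F2(t) in mL/min.

    Fasted mode: first-order emptying of the dose volume plus a constant
    term compensating the gastric secretions,
    ``F2 = k V_dose exp(-k t) + F1`` with ``k = ln2/T_half``.

    Fed mode: zero during the lag phase, then secretion compensation plus
    the linear dose-emptying rate until the dose volume is gone, then F1.
    """
    _require_nonnegative_time(t)
    if protocol.prandial_state == "fasted":
        k = protocol.emptying_rate_constant
        return k * protocol.V_dose * math.exp(-k * t) + protocol.F1
    if t < protocol.lag:
        return 0.0
    if t < protocol.lag + protocol.dose_empty_minutes:
        return protocol.F1 + protocol.F_dose_linear
    return protocol.F1


def stomach_volume(t: float, protocol: Protocol) -> float:
    """Stomach volume (mL): monoexponential decline (fasted) or
    lag-then-linear decline (fed); never below the basal volume V_fast."""
    _require_nonnegative_time(t)
    if protocol.prandial_state == "fasted":
        k = protocol.emptying_rate_constant
        return protocol.V_fast + protocol.V_dose * math.exp(-k * t)
    if t <= protocol.lag:
        return protocol.V_fast + protocol.V_dose
    remaining = protocol.V_dose - protocol.F_dose_linear * (t - protocol.lag)
    return protocol.V_fast + max(0.0, remaining)


def stomach_pH(t: float, protocol: Protocol) -> float:
    """Stomach pH under the protocol's schedule (constant or sigmoidal)."""
    _require_nonnegative_time(t)
    return protocol.stomach_pH_schedule.value(t, protocol.duration)


def bile_salt_concentration(t: float, profile: list[tuple[float, float]]) -> float:
    """Piecewise-linear bile target (mM); constant extrapolation outside nodes."""
    if not profile:
        raise ValueError("empty bile profile")
    ts = np.asarray([p[0] for p in profile], dtype=float)
    cs = np.asarray([p[1] for p in profile], dtype=float)
    return float(np.interp(t, ts, cs))


def bile_profile_slope(t: float, profile: list[tuple[float, float]]) -> float:
    """d(target)/dt of the piecewise-linear bile profile (mM/min)."""
    if not profile:
        raise ValueError("empty bile profile")
    for (t0, c0), (t1, c1) in zip(profile, profile[1:]):
        if t0 <= t < t1:
            return (c1 - c0) / (t1 - t0)
    return 0.0


def duodenal_secretion_split(
    t: float, protocol: Protocol, stock_bile: Optional[float] = None
) -> tuple[float, float]:
    """Split of the total duodenal secretion rate into (F3_1, F3_2).

    F3_1 carries the bile-bearing secretion medium (``stock_bile`` mM),
    F3_2 the bile-free buffer.  Without bile tracking the whole flow is
    secretion medium, ``(F3_total, 0)`` (the fasted and reduced-bile fed
    modes).  With tracking, the split is the quasi-steady-state inversion
    of the duodenal bile balance

        F3_1 · stock = F4 · target(t) + V_duo · d target/dt

    clamped to [0, F3_total].
    """
    stock = protocol.bile_stock_mM if stock_bile is None else stock_bile
    if stock <= 0:
        raise ValueError("stock bile concentration must be positive")
    if not protocol.bile_tracking:
        return (protocol.F3_total, 0.0)
    target = bile_salt_concentration(t, protocol.bile_profile)
    slope = bile_profile_slope(t, protocol.bile_profile)
    F2 = gastric_emptying_flow(t, protocol)
    # F4 depends on the split only through F3_total (F3_1 + F3_2 fixed)
    F4 = F2 + protocol.F3_total
    needed = (F4 * target + protocol.V_duo * slope) / stock
    F3_1 = min(max(needed, 0.0), protocol.F3_total)
    if needed > protocol.F3_total:
        import warnings

        warnings.warn(
            f"bile target {target:.2f} mM unreachable at t={t:.1f} min "
            f"(needs F3_1={needed:.2f} > F3_total={protocol.F3_total}); clamped",
            RuntimeWarning,
            stacklevel=2,
        )
    return (F3_1, protocol.F3_total - F3_1)


def flow_state(t: float, protocol: Protocol) -> FlowState:
    """All pump rates at time t; duodenal pumps pause with the gastric ones
    during the fed lag unless ``secretions_during_lag`` is set."""
    F2 = gastric_emptying_flow(t, protocol)
    if (
        protocol.prandial_state == "fed"
        and t < protocol.lag
        and not protocol.secretions_during_lag
    ):
        return FlowState(F2=0.0, F3_1=0.0, F3_2=0.0)
    F3_1, F3_2 = duodenal_secretion_split(t, protocol)
    return FlowState(F2=F2, F3_1=F3_1, F3_2=F3_2)
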