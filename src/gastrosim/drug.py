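"""Drug-state model: pH-dependent solubility, solubilization, free fraction,
dissolution/precipitation kinetics and membrane permeation flux.

The solubility of a polyprotic weak base follows Henderson-Hasselbalch,
capped at a salt-limited ceiling at low pH.  Apparent solubility adds
micellar (bile) and excipient (binder, e.g. cyclodextrin) solubilization.
The binder isotherm doubles as the free-fraction model: complexed drug adds
solubilization capacity exactly in proportion to the bound/free ratio, so a
single binding constant controls both sides of the solubility-permeability
interplay.

Units: concentrations μM (binder and bile in mM where noted), amounts μmol,
volumes mL, rates μmol/min, permeability cm/min, area cm².
"""

from __future__ import annotations

import math
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "BinderIsotherm",
    "DrugProperties",
    "solubility_at_pH",
    "apparent_solubility",
    "free_fraction",
    "dissolution_precipitation_rate",
    "permeation_flux",
]


class BinderIsotherm(BaseModel):
    """Drug-binder complexation model.

    ``linear``: bound/free = K·B (1:1 complexes, dilute regime).
    ``hill``: bound/free = (K·B)^n, capturing cooperative higher-order
    complexes (one drug molecule bound by n excipient molecules).
    ``langmuir``: capacity-limited 1:1 binding, bound = B·C_free/(Kd+C_free).
    B is the binder concentration in mM.
    """

    model_config = ConfigDict(extra="forbid")

    type: Literal["none", "linear", "langmuir", "hill"] = "none"
    K_per_mM: float = Field(default=0.0, ge=0)
    n: float = Field(default=1.0, gt=0)
    Kd_uM: float = Field(default=1.0, gt=0)  # langmuir only
    capacity_umol_per_umol: float = Field(default=1.0, gt=0)  # langmuir only

    def bound_over_free(self, binder_mM: float) -> float:
        """Concentration-independent bound/free ratio (linear and hill)."""
        if self.type == "none" or binder_mM <= 0:
            return 0.0
        if self.type == "linear":
            return self.K_per_mM * binder_mM
        if self.type == "hill":
            return (self.K_per_mM * binder_mM) ** self.n
        raise ValueError("langmuir isotherm is concentration dependent")


class DrugProperties(BaseModel):
    """Physicochemical and kinetic parameters of one compound."""

    model_config = ConfigDict(extra="forbid")

    name: str
    MW: float = Field(gt=0, description="g/mol")
    pKa: list[float] = Field(default=[], description="basic pKa's")
    S0: float = Field(gt=0, description="intrinsic (neutral form) solubility, μM")
    S_salt_cap: float = Field(gt=0, description="salt-limited solubility ceiling, μM")
    SR_bile: float = Field(default=0.0, ge=0, description="solubilization ratio per mM bile")
    binder: BinderIsotherm = Field(default_factory=BinderIsotherm)
    k_diss: float = Field(default=0.0, ge=0, description="dissolution rate constant, 1/min")
    k_prec: float = Field(default=0.0, ge=0, description="precipitation rate constant, 1/min")
    DS_crit: float = Field(default=1.0, ge=1.0, description="precipitation induction threshold")
    P_eff: float = Field(default=0.0, ge=0, description="effective permeability, cm/min")
    A: float = Field(default=65.0, gt=0, description="permeation area, cm²")

    @model_validator(mode="after")
    def _check(self) -> "DrugProperties":
        if self.S_salt_cap < self.S0:
            raise ValueError("S_salt_cap must be >= S0")
        return self


def solubility_at_pH(drug: DrugProperties, pH: float) -> float:
    """Equilibrium solubility (μM) of a polyprotic weak base at a given pH.

    Henderson-Hasselbalch: S = S0 (1 + Σ_j 10^(Σ_{i<=j} pKa_i − j·pH)),
    with pKa's taken in descending order (first protonation first), capped
    at the salt-limited ceiling S_salt_cap.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH out of range: {pH}")
    total = 1.0
    cum = 0.0
    for j, pka in enumerate(sorted(drug.pKa, reverse=True), start=1):
        cum += pka
        exponent = cum - j * pH
        # guard overflow: the cap applies long before 10**300
        total += 10.0 ** min(exponent, 300.0)
        if drug.S0 * total >= drug.S_salt_cap:
            return drug.S_salt_cap
    return min(drug.S0 * total, drug.S_salt_cap)


def apparent_solubility(
    drug: DrugProperties,
    pH: float,
    bile_mM: float = 0.0,
    binder_mM: float = 0.0,
    bile_factor: float = 1.0,
) -> float:
    """Apparent (total dissolved) solubility in μM.

    S_app = S(pH) · (1 + SR_bile·bile·bile_factor + bound/free(binder)).
    ``bile_factor`` is the protocol-level food-dependence multiplier on the
    per-mM bile solubilization ratio (1 for fasted fluids).
    Monotone nondecreasing in bile and binder concentration.
    """
    if bile_mM < 0 or binder_mM < 0:
        raise ValueError("bile and binder concentrations must be nonnegative")
    s = solubility_at_pH(drug, pH)
    enh = 1.0 + drug.SR_bile * bile_mM * bile_factor
    if drug.binder.type in ("linear", "hill"):
        enh += drug.binder.bound_over_free(binder_mM)
    elif drug.binder.type == "langmuir":
        # capacity-limited: solubilized amount saturates at the binder capacity
        sites_uM = drug.binder.capacity_umol_per_umol * binder_mM * 1e3
        enh += sites_uM / (drug.binder.Kd_uM + max(s, 1e-12))
    return s * enh


def free_fraction(
    C_solute: float,
    binder_mM: float,
    isotherm: BinderIsotherm,
    bile_mM: float = 0.0,
    SR_bile: float = 0.0,
    bile_entrapment: float = 0.0,
) -> float:
    """Fraction of solute that is molecularly (free) dissolved, in [0, 1].

    Binder complexes (isotherm) and, when food components are present,
    bile-salt colloids (``bile_entrapment`` > 0) both sequester drug that
    cannot cross the membrane:

        f = 1 / (1 + bound/free(binder) + SR_bile·bile·entrapment).

    Monotone nonincreasing in binder and bile concentration.
    """
    if C_solute < 0:
        raise ValueError("solute concentration must be nonnegative")
    denom = 1.0 + SR_bile * max(bile_mM, 0.0) * bile_entrapment
    if isotherm.type in ("linear", "hill"):
        denom += isotherm.bound_over_free(binder_mM)
    elif isotherm.type == "langmuir":
        # solve C_solute = C_free + B_t·C_free/(Kd+C_free) for C_free
        bt = isotherm.capacity_umol_per_umol * binder_mM * 1e3  # μM of sites
        if bt > 0 and C_solute > 0:
            kd = isotherm.Kd_uM
            # C_free^2 + (Kd + Bt - C)·C_free - Kd·C = 0
            b = kd + bt - C_solute
            c_free = (-b + math.sqrt(b * b + 4.0 * kd * C_solute)) / 2.0
            return min(max(c_free / C_solute, 0.0), 1.0)
    return 1.0 / denom


def dissolution_precipitation_rate(
    C_solute: float,
    solid_umol: float,
    S_app: float,
    V_mL: float,
    drug: DrugProperties,
    ds_crit: Optional[float] = None,
    smooth_onset: float = 0.0,
) -> float:
    """Signed interconversion rate between solid and dissolved drug, μmol/min.

    Positive = dissolving.  First-order in the deviation from apparent
    solubility:

        C < S_app and solid > 0 :  +k_diss · (S_app − C) · V · 1e-3
        C > DS_crit · S_app     :  −k_prec · (C − S_app) · V · 1e-3

    ``DS_crit ≥ 1`` is an optional supersaturation induction threshold
    below which no nucleation occurs (default: the drug's setting).
    ``smooth_onset`` > 0 ramps the induction switch linearly over that
    relative width around DS_crit·S_app instead of a hard jump — a
    numerical regularization used by the ODE integrator.
    """
    if min(C_solute, solid_umol, S_app, V_mL) < 0:
        raise ValueError("all inputs must be nonnegative")
    crit = drug.DS_crit if ds_crit is None else ds_crit
    if C_solute < S_app and solid_umol > 0:
        return drug.k_diss * (S_app - C_solute) * V_mL * 1e-3
    onset = crit * S_app
    if C_solute > onset:
        rate = -drug.k_prec * (C_solute - S_app) * V_mL * 1e-3
        if smooth_onset > 0 and crit > 1.0 and onset > 0:
            width = smooth_onset * onset
            rate *= min((C_solute - onset) / width, 1.0)
        return rate
    return 0.0


def permeation_flux(
    C_free_donor: float, C_free_acceptor: float, drug: DrugProperties
) -> float:
    """Transmembrane flux J = P_eff · A · (C_free,donor − C_free,acceptor) · 1e-3.

    Concentrations in μM give μmol/min (the 1e-3 converts cm³ to L).
    Antisymmetric in its two concentration arguments.
    """
    if C_free_donor < 0 or C_free_acceptor < 0:
        raise ValueError("free concentrations must be nonnegative")
    return drug.P_eff * drug.A * (C_free_donor - C_free_acceptor) * 1e-3
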