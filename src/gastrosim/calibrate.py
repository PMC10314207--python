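"""Least-squares estimation of transfer and drug parameters.

Transfer parameters (gastric emptying half-time, secretion rates, lag) are
fitted against inert-marker concentration curves, whose shape depends only
on volumes and flows.  Drug parameters (effective permeability,
precipitation rate constant, binder affinity) are fitted against
drug concentration-time tables pooled across compartments.

Residuals are taken in log-concentration by default to balance series
spanning several orders of magnitude.  The optimizer is bounded
least-squares (trust region reflective via lmfit) with a small number of
seeded multi-starts, since the objectives are cheap but can be mildly
multimodal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

from .drug import DrugProperties
from .protocol import Protocol
from .simulate import inert_marker_run, run

__all__ = ["FitResult", "fit_transfer_params", "fit_drug_params"]

_TRANSFER_PARAMS = {
    "T_half": (1.0, 120.0),
    "F1": (0.1, 20.0),
    "F3_total": (0.1, 30.0),
    "lag": (0.0, 60.0),
    "dose_empty_minutes": (30.0, 600.0),
}
_DRUG_PARAMS = {
    "P_eff": (1e-5, 1.0),
    "k_prec": (1e-4, 10.0),
    "K_bind": (1e-4, 100.0),
}

# default series used in each fit
_MARKER_COLUMNS = ["stomach_total_uM", "duodenum_total_uM"]
_DRUG_COLUMNS = [
    "stomach_total_uM",
    "duodenum_total_uM",
    "duodenum_solute_uM",
    "permeate_total_uM",
]

_EPS = 1e-9  # μM floor inside the log residual


@dataclass
class FitResult:
    """Outcome of one parameter fit."""

    estimates: dict[str, float]
    residual_sse: float
    n_obs: int
    success: bool
    message: str
    stderr: dict[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residual_sse < 0:
            raise ValueError("residual SSE cannot be negative")


def _as_replicates(observed) -> list[pd.DataFrame]:
    if isinstance(observed, pd.DataFrame):
        return [observed]
    if hasattr(observed, "replicates"):
        return list(observed.replicates)
    return list(observed)


def _stack_observations(
    replicates: Sequence[pd.DataFrame], columns: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    used = [c for c in columns if c in replicates[0].columns]
    if not used:
        raise ValueError(f"no usable observation columns among {list(columns)}")
    obs = np.concatenate(
        [rep[c].to_numpy(dtype=float) for rep in replicates for c in used]
    )
    return obs, used


def _log_residuals(pred: np.ndarray, obs: np.ndarray, weights=None) -> np.ndarray:
    r = np.log(np.maximum(pred, _EPS)) - np.log(np.maximum(obs, _EPS))
    return r if weights is None else r * weights


def _multistart(
    params: lmfit.Parameters,
    residual_fn: Callable[[lmfit.Parameters], np.ndarray],
    n_starts: int,
    seed: int,
) -> lmfit.minimizer.MinimizerResult:
    """Run bounded least-squares from the nominal start plus perturbed ones."""
    rng = np.random.default_rng(seed)
    best = None
    for i in range(max(1, n_starts)):
        p = params.copy()
        if i > 0:
            for name in p:
                if p[name].vary:
                    lo, hi = p[name].min, p[name].max
                    factor = rng.uniform(0.5, 2.0)
                    p[name].value = float(np.clip(p[name].value * factor, lo, hi))
        try:
            res = lmfit.minimize(
                residual_fn, p, method="least_squares", nan_policy="omit"
            )
        except Exception as exc:  # pragma: no cover - solver blow-up
            warnings.warn(f"fit start {i} failed: {exc}", RuntimeWarning)
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("all optimization starts failed")
    return best


def _to_fit_result(res, free_params: Sequence[str], n_obs: int) -> FitResult:
    estimates = {k: float(res.params[k].value) for k in free_params}
    stderr = {
        k: (float(res.params[k].stderr) if res.params[k].stderr else None)
        for k in free_params
    }
    if not res.success:
        warnings.warn(
            f"fit did not converge: {res.message}", RuntimeWarning, stacklevel=3
        )
    return FitResult(
        estimates=estimates,
        residual_sse=float(res.chisqr),
        n_obs=n_obs,
        success=bool(res.success),
        message=str(res.message),
        stderr=stderr,
    )


def fit_transfer_params(
    observed,
    protocol_template: Protocol,
    free_params: Sequence[str],
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    *,
    columns: Sequence[str] = _MARKER_COLUMNS,
    n_starts: int = 3,
    seed: int = 0,
    rtol: float = 1e-6,
) -> FitResult:
    """Fit flow/transfer parameters to inert-marker sampled tables.

    ``observed`` is a sampled table, a list of replicate tables, or a
    :class:`~gastrosim.synth.SyntheticDataset`.  ``free_params`` is a
    nonempty subset of {T_half, F1, F3_total, lag, dose_empty_minutes}.
    """
    free_params = list(free_params)
    if not free_params:
        raise ValueError("free_params must be nonempty")
    unknown = set(free_params) - set(_TRANSFER_PARAMS)
    if unknown:
        raise ValueError(f"unknown transfer parameters: {sorted(unknown)}")
    replicates = _as_replicates(observed)
    if len(replicates[0]) < 5:
        raise ValueError("need at least 5 observed timepoints")
    obs, used = _stack_observations(replicates, columns)
    bounds = bounds or {}

    params = lmfit.Parameters()
    for name in free_params:
        lo, hi = bounds.get(name, _TRANSFER_PARAMS[name])
        start = getattr(protocol_template, name, None)
        if start is None or not (lo <= float(start) <= hi):
            start = np.sqrt(lo * hi) if lo > 0 else (lo + hi) / 2
        params.add(name, value=float(start), min=lo, max=hi)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        proto = protocol_template.model_copy(
            update={k: float(p[k].value) for k in free_params}
        )
        sim = inert_marker_run(proto, dense_step=None, rtol=rtol, atol=1e-8)
        pred_one = np.concatenate(
            [sim.sampled_table[c].to_numpy(dtype=float) for c in used]
        )
        pred = np.tile(pred_one, len(replicates))
        return _log_residuals(pred, obs)

    res = _multistart(params, residual, n_starts, seed)
    return _to_fit_result(res, free_params, obs.size)


def fit_drug_params(
    observed,
    protocol: Protocol,
    drug_template: DrugProperties,
    free_params: Sequence[str],
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    *,
    columns: Sequence[str] = _DRUG_COLUMNS,
    compartment_weights: Optional[dict[str, float]] = None,
    n_starts: int = 3,
    seed: int = 0,
    rtol: float = 1e-6,
) -> FitResult:
    """Fit drug kinetic parameters ({P_eff, k_prec, K_bind}) to sampled tables.

    Residuals are pooled across the stomach, duodenum and permeate series;
    ``compartment_weights`` rescales residuals by column prefix.  Fitting
    P_eff without a permeate series raises an identifiability warning.
    """
    free_params = list(free_params)
    if not free_params:
        raise ValueError("free_params must be nonempty")
    unknown = set(free_params) - set(_DRUG_PARAMS)
    if unknown:
        raise ValueError(f"unknown drug parameters: {sorted(unknown)}")
    replicates = _as_replicates(observed)
    obs, used = _stack_observations(replicates, columns)
    if "P_eff" in free_params and not any(c.startswith("permeate") for c in used):
        warnings.warn(
            "fitting P_eff without a permeate series is structurally "
            "non-identifiable",
            UserWarning,
        )
    bounds = bounds or {}

    def template_value(name: str) -> float:
        if name == "K_bind":
            return drug_template.binder.K_per_mM
        return getattr(drug_template, name)

    params = lmfit.Parameters()
    for name in free_params:
        lo, hi = bounds.get(name, _DRUG_PARAMS[name])
        start = template_value(name)
        if not (lo <= start <= hi) or start == 0:
            start = np.sqrt(lo * hi)
        params.add(name, value=float(start), min=lo, max=hi)

    weights = None
    if compartment_weights:
        n_t = len(replicates[0])
        w_one = np.concatenate(
            [
                np.full(n_t, compartment_weights.get(c.split("_")[0], 1.0))
                for c in used
            ]
        )
        weights = np.tile(w_one, len(replicates))

    def residual(p: lmfit.Parameters) -> np.ndarray:
        upd = {k: float(p[k].value) for k in free_params if k != "K_bind"}
        d = drug_template.model_copy(update=upd)
        if "K_bind" in free_params:
            d.binder = drug_template.binder.model_copy(
                update={"K_per_mM": float(p["K_bind"].value)}
            )
        sim = run(protocol, d, dense_step=None, rtol=rtol, atol=1e-8)
        pred_one = np.concatenate(
            [sim.sampled_table[c].to_numpy(dtype=float) for c in used]
        )
        pred = np.tile(pred_one, len(replicates))
        return _log_residuals(pred, obs, weights)

    res = _multistart(params, residual, n_starts, seed)
    return _to_fit_result(res, free_params, obs.size)
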