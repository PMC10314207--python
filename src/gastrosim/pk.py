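"""Noncompartmental statistics on concentration-time tables.

Linear-trapezoid AUC over a stated window, Cmax/Tmax, the degree of
supersaturation (solute concentration over thermodynamic solubility in the
same matrix), and the percent/fold scenario-comparison arithmetic used to
summarize transfer experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "PKMetrics",
    "auc_trapezoid",
    "cmax_tmax",
    "degree_of_supersaturation",
    "percent_change",
    "fold_change",
    "metrics_from_sampled_table",
    "compare_auc_table",
    "compare_scenarios",
]

AnchorPolicy = Literal["carry_back", "zero", "none"]


@dataclass
class PKMetrics:
    auc: float  # μM·min
    window: tuple[float, float]
    cmax: float  # μM
    tmax: float  # min
    ds_series: Optional[pd.Series] = None


def auc_trapezoid(
    times: Iterable[float],
    conc: Iterable[float],
    t_start: float = 0.0,
    t_end: Optional[float] = None,
    anchor: AnchorPolicy = "carry_back",
) -> float:
    """Linear trapezoidal AUC (μM·min) of a sampled series over a window.

    Measured tables usually start after t=0 (first sample at 7 min); the
    ``anchor`` policy supplies C(t_start): ``carry_back`` repeats the first
    observation, ``zero`` anchors at 0, ``none`` requires the window to lie
    within the observed range.
    """
    t = np.asarray(list(times), dtype=float)
    c = np.asarray(list(conc), dtype=float)
    if t.ndim != 1 or t.shape != c.shape or t.size == 0:
        raise ValueError("times and conc must be equal-length 1-D sequences")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t_end is None:
        t_end = float(t[-1])
    if t_end <= t_start:
        raise ValueError("empty integration window")
    if t_start < t[0]:
        if anchor == "carry_back":
            t = np.concatenate(([t_start], t))
            c = np.concatenate(([c[0]], c))
        elif anchor == "zero":
            t = np.concatenate(([t_start], t))
            c = np.concatenate(([0.0], c))
        else:
            raise ValueError(
                f"window start {t_start} precedes first observation {t[0]}"
            )
    if t_start < t[0] or t_end > t[-1]:
        raise ValueError("integration window outside the data range")
    # clip to the window, interpolating at the edges
    grid = np.union1d(t, [t_start, t_end])
    grid = grid[(grid >= t_start) & (grid <= t_end)]
    vals = np.interp(grid, t, c)
    return float(np.trapezoid(vals, grid))


def cmax_tmax(times: Iterable[float], conc: Iterable[float]) -> tuple[float, float]:
    """Maximum observed concentration and its time (first occurrence)."""
    t = np.asarray(list(times), dtype=float)
    c = np.asarray(list(conc), dtype=float)
    i = int(np.argmax(c))
    return float(c[i]), float(t[i])


def degree_of_supersaturation(solute_uM: float, thermo_solubility_uM: float) -> float:
    """DS = solute / thermodynamic solubility; DS > 1 marks supersaturation."""
    if thermo_solubility_uM <= 0:
        raise ValueError("thermodynamic solubility must be positive")
    return solute_uM / thermo_solubility_uM


def percent_change(reference: float, alternative: float) -> float:
    """Decrease of ``alternative`` relative to ``reference`` in percent,
    100·(reference − alternative)/reference (negative for an increase)."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (reference - alternative) / reference


def fold_change(a: float, b: float) -> float:
    """Ratio a/b (reported to one decimal in summaries)."""
    if b == 0:
        raise ValueError("denominator must be nonzero")
    return a / b


def metrics_from_sampled_table(
    table: pd.DataFrame,
    column: str,
    t_start: float = 0.0,
    t_end: Optional[float] = None,
    anchor: AnchorPolicy = "carry_back",
) -> PKMetrics:
    """AUC/Cmax/Tmax (and DS if present) for one measured series."""
    if table.empty:
        raise ValueError("empty sampled table")
    t = table["time_min"].to_numpy(dtype=float)
    c = table[column].to_numpy(dtype=float)
    end = float(t[-1]) if t_end is None else t_end
    auc = auc_trapezoid(t, c, t_start, end, anchor=anchor)
    cmax, tmax = cmax_tmax(t, c)
    ds = table["duodenum_DS"] if "duodenum_DS" in table.columns else None
    return PKMetrics(auc=auc, window=(t_start, end), cmax=cmax, tmax=tmax, ds_series=ds)


def compare_auc_table(
    aucs: pd.DataFrame, reference: Optional[str] = None
) -> pd.DataFrame:
    """Pairwise percent/fold changes of AUC summaries between scenarios.

    ``aucs`` has columns scenario, compartment, measure, auc (one row per
    series).  Every non-reference scenario is compared to ``reference``
    (default: the first scenario in the table) series-by-series.
    """
    required = {"scenario", "compartment", "measure", "auc"}
    if not required.issubset(aucs.columns):
        raise ValueError(f"AUC table must have columns {sorted(required)}")
    scenarios = list(dict.fromkeys(aucs["scenario"]))
    if len(scenarios) < 2:
        raise ValueError("need at least two scenarios to compare")
    ref = scenarios[0] if reference is None else reference
    ref_tab = aucs[aucs.scenario == ref].set_index(["compartment", "measure"])
    rows = []
    for sc in scenarios:
        if sc == ref:
            continue
        alt_tab = aucs[aucs.scenario == sc].set_index(["compartment", "measure"])
        for key in ref_tab.index:
            if key not in alt_tab.index:
                continue
            a = float(ref_tab.loc[key, "auc"])
            b = float(alt_tab.loc[key, "auc"])
            rows.append(
                {
                    "reference": ref,
                    "scenario": sc,
                    "compartment": key[0],
                    "measure": key[1],
                    "auc_reference": a,
                    "auc_scenario": b,
                    "pct_decrease": round(percent_change(a, b), 1),
                    "fold_change": round(fold_change(max(a, b), min(a, b)), 1),
                }
            )
    return pd.DataFrame(rows)


_SERIES = [
    ("stomach", "total", "stomach_total_uM"),
    ("stomach", "solute", "stomach_solute_uM"),
    ("duodenum", "total", "duodenum_total_uM"),
    ("duodenum", "solute", "duodenum_solute_uM"),
    ("permeate", "total", "permeate_total_uM"),
]


def compare_scenarios(
    results: list[tuple[str, pd.DataFrame]],
    t_start: float = 0.0,
    t_end: Optional[float] = None,
    anchor: AnchorPolicy = "carry_back",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-scenario AUC/Cmax/Tmax table plus pairwise comparisons.

    ``results`` pairs a scenario name with its sampled table (replicate
    means or a single deterministic run).  Returns (metrics, comparisons).
    """
    if len(results) < 2:
        raise ValueError("need at least two scenarios")
    windows = {
        (df["time_min"].iloc[0], df["time_min"].iloc[-1]) for _, df in results
    }
    if len(windows) > 1:
        raise ValueError(f"sampling windows differ between scenarios: {windows}")
    met_rows = []
    for name, df in results:
        for compartment, measure, col in _SERIES:
            if col not in df.columns:
                continue
            m = metrics_from_sampled_table(df, col, t_start, t_end, anchor)
            met_rows.append(
                {
                    "scenario": name,
                    "compartment": compartment,
                    "measure": measure,
                    "auc": m.auc,
                    "cmax": m.cmax,
                    "tmax": m.tmax,
                }
            )
    metrics = pd.DataFrame(met_rows)
    comparisons = compare_auc_table(metrics[["scenario", "compartment", "measure", "auc"]])
    return metrics, comparisons
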