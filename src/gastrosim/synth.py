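"""Synthetic wet-lab datasets emulating the bench measurement design.

Runs the deterministic simulator, evaluates the assayed series at the
protocol sampling times (pre-replacement, as sampled in the apparatus) and
applies independent multiplicative lognormal noise per observation to
produce replicate tables (biological triplicate by default).  The noise is
mean-one, so replicate averages converge to the deterministic trajectory.
Values below the assay's limit of quantification can be censored to a
"<LOQ" marker on export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .drug import DrugProperties
from .protocol import Protocol
from .simulate import SimulationResult, inert_marker_run, marker_drug, run

__all__ = ["SyntheticDataset", "generate_replicates", "paromomycin_reference"]

_NOISED_COLUMNS = [
    "stomach_total_uM",
    "stomach_solute_uM",
    "duodenum_total_uM",
    "duodenum_solute_uM",
    "permeate_total_uM",
]


@dataclass
class SyntheticDataset:
    """Replicate sampled tables for one scenario, with provenance."""

    scenario: str
    drug: str
    replicates: list[pd.DataFrame]
    noise_cv: float
    seed: int
    loq_uM: Optional[float] = None
    truth: Optional[pd.DataFrame] = None  # noise-free sampled table

    @property
    def n(self) -> int:
        return len(self.replicates)

    def mean_table(self) -> pd.DataFrame:
        """Across-replicate mean of every measured column."""
        stacked = pd.concat(self.replicates).groupby("time_min", sort=True)
        return stacked.mean().reset_index()

    def wide_table(self) -> pd.DataFrame:
        """One row per time, replicate columns like stomach_total_uM_r1."""
        out = self.replicates[0][["time_min"]].copy()
        for r, df in enumerate(self.replicates, start=1):
            for col in _NOISED_COLUMNS:
                if col in df.columns:
                    out[f"{col}_r{r}"] = df[col].to_numpy()
        return out

    def write(self, out_dir: str | Path) -> None:
        """Write replicate CSVs (LOQ-censored) and a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for r, df in enumerate(self.replicates, start=1):
            export = df.copy()
            if self.loq_uM is not None:
                for col in _NOISED_COLUMNS:
                    if col in export.columns:
                        vals = export[col].astype(object)
                        vals[export[col] < self.loq_uM] = "<LOQ"
                        export[col] = vals
            export.to_csv(out / f"{self.scenario}_rep{r}.csv", index=False)
        manifest = {
            "scenario": self.scenario,
            "drug": self.drug,
            "n_replicates": self.n,
            "noise_cv": self.noise_cv,
            "seed": self.seed,
            "loq_uM": self.loq_uM,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _apply_noise(
    truth: pd.DataFrame, noise_cv: float, n: int, rng: np.random.Generator
) -> list[pd.DataFrame]:
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if n < 1:
        raise ValueError("need at least one replicate")
    reps = []
    sigma = np.sqrt(np.log1p(noise_cv**2))
    for _ in range(n):
        df = truth.copy()
        if noise_cv > 0:
            for col in _NOISED_COLUMNS:
                if col in df.columns:
                    mult = rng.lognormal(
                        mean=-0.5 * sigma**2, sigma=sigma, size=len(df)
                    )
                    df[col] = np.maximum(df[col].to_numpy() * mult, 0.0)
        reps.append(df)
    return reps


def generate_replicates(
    protocol: Protocol,
    drug: DrugProperties,
    noise_cv: float = 0.05,
    n: int = 3,
    seed: int = 0,
    loq_uM: Optional[float] = None,
    result: Optional[SimulationResult] = None,
) -> SyntheticDataset:
    """Simulate a scenario and emit ``n`` noisy replicate sampled tables.

    Reproducible for a fixed seed; ``noise_cv=0`` returns replicates
    identical to the deterministic simulation.  ``result`` lets callers
    reuse an existing simulation instead of re-running it.
    """
    if result is None:
        result = run(protocol, drug, dense_step=None)
    truth = result.sampled_table
    rng = np.random.default_rng(seed)
    reps = _apply_noise(truth, noise_cv, n, rng)
    return SyntheticDataset(
        scenario=protocol.name,
        drug=drug.name,
        replicates=reps,
        noise_cv=noise_cv,
        seed=seed,
        loq_uM=loq_uM,
        truth=truth,
    )


def paromomycin_reference(
    protocol: Protocol,
    C0_uM: float,
    noise_cv: float = 0.05,
    n: int = 3,
    seed: int = 0,
) -> SyntheticDataset:
    """Inert-marker (paromomycin-like) reference curves for flow calibration.

    The marker is fully soluble and non-permeating, so its stomach and
    duodenal concentrations reflect only volumes and flows.
    """
    result = inert_marker_run(protocol, C0_uM, dense_step=None)
    truth = result.sampled_table
    rng = np.random.default_rng(seed)
    reps = _apply_noise(truth, noise_cv, n, rng)
    return SyntheticDataset(
        scenario=f"{protocol.name}_marker",
        drug=marker_drug().name,
        replicates=reps,
        noise_cv=noise_cv,
        seed=seed,
        truth=truth,
    )
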