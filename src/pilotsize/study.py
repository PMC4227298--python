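"""Full-study orchestration: run every grid cell, emit tidy summary tables.

``run_study`` executes three pipelines from one :class:`~pilotsize.config.StudyConfig`:

* **continuous** — one row per pilot size: mean pooled SD, bias, mean 95% CI
  width (Monte-Carlo and closed form), precision gain versus the previous
  size, and the inflation factor at the configured confidence;
* **planning** — one row per (effect size x pilot size x inflation flag):
  percentiles of true power, of the planned definitive-trial total, and of
  the grand total including the pilot, plus assurance at the power floor;
* **binary** — one row per (true rate x pilot size): mean observed rate,
  bias, mean Wilson width, precision gain versus n-5, and coverage.

The same simulated pilots feed the continuous and planning tables, as one
set of replicate pilot trials would in practice.  Re-running with the same
config byte-reproduces every numeric column.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binary_proportion import summarize_binomial_cell
from .config import StudyConfig
from .power_planning import plan_from_pilot, summarize_plans
from .sd_estimation import (
    _width_factor,
    inflation_factor,
    mean_ci_width_closed_form,
    pooled_sd,
    sd_bias,
)
from .simulate import required_reps_binary, simulate_normal_pilot

__all__ = ["StudyResultBundle", "run_study", "continuous_table", "planning_table", "binary_table"]

logger = logging.getLogger(__name__)


@dataclass
class StudyResultBundle:
    """All summary tables from one study run, with the resolved config."""

    config: StudyConfig
    continuous: pd.DataFrame
    planning: pd.DataFrame
    binary: pd.DataFrame

    def manifest(self) -> dict:
        return {
            "package": "pilotsize",
            "version": __version__,
            "config": self.config.to_dict(),
            "tables": {
                "continuous": len(self.continuous),
                "planning": len(self.planning),
                "binary": len(self.binary),
            },
        }

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.continuous.to_csv(outdir / "continuous_sd.csv", index=False)
        self.planning.to_csv(outdir / "planning.csv", index=False)
        self.binary.to_csv(outdir / "binary_proportion.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))
        return outdir


def _simulate_grid(config: StudyConfig) -> dict[int, np.ndarray]:
    """Pooled-SD arrays per pilot size, drawn independently per size."""
    out = {}
    for n in config.normal_group_sizes:
        reps = simulate_normal_pilot(
            n, config.normal_reps, config.true_mean, config.true_sd, config.seed
        )
        out[n] = np.asarray(pooled_sd(reps.s1_sq, reps.s2_sq))
        logger.info("continuous cell n=%d: %d replicates", n, config.normal_reps)
    return out


def continuous_table(
    config: StudyConfig, sd_by_size: dict[int, np.ndarray] | None = None
) -> pd.DataFrame:
    if sd_by_size is None:
        sd_by_size = _simulate_grid(config)
    rows = []
    prev_width = None
    for n in config.normal_group_sizes:
        sd_p = sd_by_size[n]
        df = 2 * (n - 1)
        mc_width = float(np.mean(sd_p)) * _width_factor(df, config.ci_level)
        rows.append(
            {
                "n_per_group": n,
                "n_total": 2 * n,
                "df": df,
                "n_reps": len(sd_p),
                "mean_sd_p": float(np.mean(sd_p)),
                "bias": sd_bias(sd_p, config.true_sd),
                "mean_ci_width_mc": mc_width,
                "mean_ci_width_closed": mean_ci_width_closed_form(
                    df, config.ci_level, config.true_sd
                ),
                "precision_gain_pct": (
                    np.nan
                    if prev_width is None
                    else 100.0 * (prev_width - mc_width) / prev_width
                ),
                "inflation_factor": inflation_factor(df, config.inflation_confidence),
            }
        )
        prev_width = mc_width
    return pd.DataFrame(rows)


def planning_table(
    config: StudyConfig, sd_by_size: dict[int, np.ndarray] | None = None
) -> pd.DataFrame:
    if sd_by_size is None:
        sd_by_size = _simulate_grid(config)
    rows = []
    for delta in config.effect_sizes:
        for n in config.normal_group_sizes:
            for inflate in (False, True):
                plans = plan_from_pilot(
                    sd_by_size[n],
                    2 * (n - 1),
                    delta,
                    config.alpha,
                    config.target_power,
                    inflate=inflate,
                    inflation_confidence=config.inflation_confidence,
                    true_sd=config.true_sd,
                )
                if plans.n_excluded:
                    logger.warning(
                        "planning cell delta=%s n=%d: %d degenerate pilots excluded",
                        delta, n, plans.n_excluded,
                    )
                summ = summarize_plans(plans, 2 * n, config.power_floor)
                row = {
                    "effect_size": delta,
                    "pilot_n_per_group": n,
                    "pilot_total": 2 * n,
                    "inflated": inflate,
                    "assurance_at_floor": summ.assurance_at_floor,
                    "power_floor": summ.power_floor,
                    "n_plans": summ.n_plans,
                    "n_excluded": summ.n_excluded,
                }
                for label, values in (
                    ("true_power", summ.true_power),
                    ("n_total", summ.n_total),
                    ("n_grand", summ.n_grand),
                ):
                    for q, v in zip(summ.percentiles, values):
                        row[f"{label}_p{q:g}"] = v
                rows.append(row)
    return pd.DataFrame(rows)


def binary_table(config: StudyConfig, method: str = "enumeration") -> pd.DataFrame:
    rows = []
    for theta in config.binary_thetas:
        n_reps = max(
            config.binary_min_reps,
            required_reps_binary(theta, config.binary_se_target),
        )
        prev_width = None
        for n in config.binary_sizes:
            cell = summarize_binomial_cell(
                theta,
                n,
                n_reps=n_reps if method == "simulation" else None,
                level=config.ci_level,
                seed=config.seed,
                method=method,
            )
            rows.append(
                {
                    "theta_true": theta,
                    "n": n,
                    "n_reps": cell.n_reps,
                    "method": cell.method,
                    "mean_theta_hat": cell.mean_theta_hat,
                    "bias": cell.bias,
                    "mean_width": cell.mean_width,
                    "precision_gain_pct": (
                        np.nan
                        if prev_width is None
                        else 100.0 * (prev_width - cell.mean_width) / prev_width
                    ),
                    "coverage": cell.coverage,
                }
            )
            prev_width = cell.mean_width
    return pd.DataFrame(rows)


def run_study(
    config: StudyConfig,
    outdir: str | Path | None = None,
    binary_method: str = "enumeration",
) -> StudyResultBundle:
    """Execute the full study; optionally write CSVs and a manifest to ``outdir``."""
    sd_by_size = _simulate_grid(config)
    bundle = StudyResultBundle(
        config=config,
        continuous=continuous_table(config, sd_by_size),
        planning=planning_table(config, sd_by_size),
        binary=binary_table(config, method=binary_method),
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle
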