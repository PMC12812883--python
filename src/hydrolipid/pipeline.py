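"""End-to-end two-scenario comparison: growth, lipids, photophysiology.

A scenario run generates (or loads) one static-control and one
hydrodynamically perturbed data set, pushes both through the stage
modules, and assembles a comparison report:

* per-replicate logistic fits, Welch two-sample t-tests of carrying
  capacity and doubling time, and the growth-index series IG(t);
* per-replicate lipid summaries from rendered micrographs, the lipid
  index IL, and a paired t-test of normalized lipid area by replicate;
* per-replicate PAM summaries (Fv/Fm, rETRmax, NPQ500) with paired
  t-tests.

Raw per-time-point p-values are reported (no multiple-testing
correction by default; Holm adjustment is available as a switch).  The
whole run is deterministic given the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io as hio
from .growth import (
    GrowthComparison,
    GrowthCurve,
    compare_growth,
    fit_logistic,
    growth_index,
)
from .lipids import SegmentationParams, measure_image_set, lipid_index, population_summary
from .pam import summarize_light_curve
from .synthetic import (
    SCENARIO_PRESETS,
    SyntheticGrowthSpec,
    SyntheticLightCurveSpec,
    cell_spec_for_total_volume,
    generate_cell_image_set,
    generate_growth_tables,
    generate_light_curve,
)

__all__ = [
    "ScenarioConfig",
    "ComparisonReport",
    "run_pipeline",
    "paired_ttest",
    "holm_adjust",
    "write_report",
]

CONDITIONS = ("static", "perturbed")
_SCENARIO_ONSET = {"0h_delay": 0.0, "120h_delay": 120.0}


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to run one scenario comparison."""

    scenario: str  # {"0h_delay", "120h_delay"}
    onset_time_h: float
    growth: dict  # condition -> {K_true, r_true, P0_true}
    lipid_total_volume: dict  # condition -> (mean µm³, sd µm³)
    strain_label: str = "HA452"
    n_replicates: int = 3
    n_cells_per_replicate: int = 60
    n_subsample: int = 20
    n_droplets_per_cell: int = 4
    growth_noise_cv: float = 0.1
    pam_noise_cv: float = 0.05
    master_seed: int = 0
    alpha: float = 0.05
    p_adjust: str = "none"  # {"none", "holm"}

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIO_ONSET:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.onset_time_h != _SCENARIO_ONSET[self.scenario]:
            raise ValueError(
                f"onset_time_h={self.onset_time_h} inconsistent with "
                f"scenario {self.scenario!r}"
            )
        for cond in CONDITIONS:
            if cond not in self.growth or cond not in self.lipid_total_volume:
                raise ValueError(f"missing stage parameters for condition {cond!r}")
        if self.p_adjust not in ("none", "holm"):
            raise ValueError("p_adjust must be 'none' or 'holm'")

    @classmethod
    def from_preset(cls, name: str, master_seed: int = 0, **overrides) -> "ScenarioConfig":
        """Build from a named preset ('scenario1' or 'scenario2')."""
        preset = SCENARIO_PRESETS[name]
        kwargs = dict(
            scenario=preset["scenario"],
            onset_time_h=preset["onset_time_h"],
            growth=preset["growth"],
            lipid_total_volume=preset["lipid_total_volume"],
            master_seed=master_seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "preset" in raw:
            name = raw.pop("preset")
            return cls.from_preset(name, **raw)
        raw["lipid_total_volume"] = {
            k: tuple(v) for k, v in raw["lipid_total_volume"].items()
        }
        return cls(**raw)


@dataclass(frozen=True)
class ComparisonReport:
    scenario: str
    strain_label: str
    master_seed: int
    alpha: float
    growth_timepoints: pd.DataFrame  # condition, time_h, mean, sd
    growth_fits: pd.DataFrame  # condition, replicate, K, r, P0, Td, sse
    growth_comparison: GrowthComparison
    ig_series: pd.DataFrame  # time_h, IG
    lipid_replicates: pd.DataFrame  # condition, replicate, means/sds
    lipid_index: float
    pam_replicates: pd.DataFrame  # condition, replicate, fvfm, retr_max, npq_500
    paired_tests: pd.DataFrame  # parameter, t, p, p_adjusted, significant


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test.

    Zero-variance differences use the degenerate conventions: all-zero
    differences give (0, 1); a constant nonzero difference gives
    (±inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = x - y
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, d[0]), 0.0
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def run_pipeline(
    config: ScenarioConfig, output_dir: str | Path | None = None
) -> ComparisonReport:
    """Run the full synthetic two-condition comparison.

    If ``output_dir`` is given, intermediate CSVs (growth tables,
    per-replicate lipid and PAM summaries) are written there.
    """
    root = np.random.SeedSequence(config.master_seed)
    seeds = {
        name: child
        for name, child in zip(
            ("growth_static", "growth_perturbed", "lipid", "pam", "subsample"),
            root.spawn(5),
        )
    }
    outdir = Path(output_dir) if output_dir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- growth ---------------------------------------------------------
    tables = {}
    for cond in CONDITIONS:
        spec = SyntheticGrowthSpec(
            **config.growth[cond],
            noise_cv=config.growth_noise_cv,
            n_replicates=config.n_replicates,
            seed=_child_seed(seeds[f"growth_{cond}"]),
        )
        tables[cond], _ = generate_growth_tables(spec, condition=cond)
    growth_table = pd.concat(tables.values(), ignore_index=True)
    if outdir is not None:
        hio.write_growth_csv(growth_table, outdir / "growth_tables.csv")

    tp = (
        growth_table.groupby(["condition", "time_h"])["concentration_cells_per_ml"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "mean_cells_per_ml", "std": "sd_cells_per_ml"})
    )

    fits = {cond: [] for cond in CONDITIONS}
    fit_rows = []
    for cond in CONDITIONS:
        for rep, grp in tables[cond].groupby("replicate"):
            fit = fit_logistic(
                GrowthCurve(
                    times=grp["time_h"].to_numpy(),
                    concentrations=grp["concentration_cells_per_ml"].to_numpy(),
                    replicate_id=rep,
                    condition=cond,
                    scenario=config.scenario,
                )
            )
            fits[cond].append(fit)
            fit_rows.append(
                {"condition": cond, "replicate": rep, "K": fit.K, "r": fit.r,
                 "P0": fit.P0, "Td": fit.Td, "sse": fit.residual_sse,
                 "converged": fit.converged}
            )
    growth_fits = pd.DataFrame(fit_rows)
    growth_cmp = compare_growth(fits["static"], fits["perturbed"])

    # IG(t) from fits of the replicate-mean trajectory of each condition
    mean_fits = {}
    for cond in CONDITIONS:
        mean_curve = (
            tables[cond].groupby("time_h")["concentration_cells_per_ml"].mean()
        )
        mean_fits[cond] = fit_logistic(
            GrowthCurve(times=mean_curve.index.to_numpy(),
                        concentrations=mean_curve.to_numpy(), condition=cond)
        )
    t_max = float(growth_table["time_h"].max())
    ig_times = np.linspace(0.0, t_max, 97)
    ig = growth_index(mean_fits["static"], mean_fits["perturbed"], ig_times)
    ig_series = pd.DataFrame({"time_h": ig.times, "IG": ig.IG})

    # --- lipids ---------------------------------------------------------
    lipid_children = seeds["lipid"].spawn(config.n_replicates * len(CONDITIONS))
    sub_children = seeds["subsample"].spawn(config.n_replicates * len(CONDITIONS))
    seg_params = SegmentationParams(pixel_size_um=0.1)
    lipid_rows = []
    summaries = {cond: [] for cond in CONDITIONS}
    for ci, cond in enumerate(CONDITIONS):
        mean_v, sd_v = config.lipid_total_volume[cond]
        for rep in range(config.n_replicates):
            k = ci * config.n_replicates + rep
            spec = cell_spec_for_total_volume(
                mean_v, sd_v,
                n_droplets=config.n_droplets_per_cell,
                n_cells=config.n_cells_per_replicate,
                seed=_child_seed(lipid_children[k]),
            )
            images, _truth = generate_cell_image_set(spec)
            cells = measure_image_set(images, seg_params)
            summary = population_summary(
                cells, n_subsample=config.n_subsample,
                seed=_child_seed(sub_children[k]),
            )
            summaries[cond].append(summary)
            lipid_rows.append(
                {
                    "condition": cond,
                    "replicate": rep,
                    "mean_normalized_area": summary.mean_normalized_area,
                    "sd_normalized_area": summary.sd_normalized_area,
                    "mean_total_volume_um3": summary.mean_total_volume_um3,
                    "sd_total_volume_um3": summary.sd_total_volume_um3,
                    "n_cells": summary.n_cells,
                }
            )
    lipid_reps = pd.DataFrame(lipid_rows)

    def _pooled(cond: str):
        cells = [m for s in summaries[cond] for m in s.measurements]
        return population_summary(cells, n_subsample=len(cells))

    il = lipid_index(_pooled("perturbed"), _pooled("static"))

    # --- photophysiology ------------------------------------------------
    pam_children = seeds["pam"].spawn(config.n_replicates * len(CONDITIONS))
    pam_rows = []
    for ci, cond in enumerate(CONDITIONS):
        for rep in range(config.n_replicates):
            k = ci * config.n_replicates + rep
            spec = SyntheticLightCurveSpec(
                noise_cv=config.pam_noise_cv,
                seed=_child_seed(pam_children[k]),
            )
            record, _truth = generate_light_curve(spec)
            s = summarize_light_curve(record)
            pam_rows.append(
                {"condition": cond, "replicate": rep, "fvfm": s.FvFm,
                 "retr_max": s.rETR_max, "npq_500": s.NPQ_500}
            )
    pam_reps = pd.DataFrame(pam_rows)

    # --- paired tests by replicate --------------------------------------
    paired_rows = []

    def _paired(frame: pd.DataFrame, column: str, parameter: str) -> None:
        pivot = frame.pivot(index="replicate", columns="condition", values=column)
        t, p = paired_ttest(pivot["perturbed"].to_numpy(), pivot["static"].to_numpy())
        paired_rows.append({"parameter": parameter, "t": t, "p": p})

    _paired(lipid_reps, "mean_normalized_area", "normalized_lipid_area")
    _paired(lipid_reps, "mean_total_volume_um3", "total_lipid_volume")
    for col in ("fvfm", "retr_max", "npq_500"):
        _paired(pam_reps, col, col)
    paired = pd.DataFrame(paired_rows)
    if config.p_adjust == "holm":
        paired["p_adjusted"] = holm_adjust(paired["p"].to_numpy())
    else:
        paired["p_adjusted"] = paired["p"]
    paired["significant"] = paired["p_adjusted"] < config.alpha

    if outdir is not None:
        lipid_reps.to_csv(outdir / "lipid_replicates.csv", index=False)
        pam_reps.to_csv(outdir / "pam_replicates.csv", index=False)
        growth_fits.to_csv(outdir / "growth_fits.csv", index=False)

    return ComparisonReport(
        scenario=config.scenario,
        strain_label=config.strain_label,
        master_seed=config.master_seed,
        alpha=config.alpha,
        growth_timepoints=tp,
        growth_fits=growth_fits,
        growth_comparison=growth_cmp,
        ig_series=ig_series,
        lipid_replicates=lipid_reps,
        lipid_index=il,
        pam_replicates=pam_reps,
        paired_tests=paired,
    )


def write_report(report: ComparisonReport, outdir: str | Path) -> list[Path]:
    """Write the report tables as CSV plus a plain-text summary.

    Output is byte-identical across repeated runs with the same seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    tables = {
        "growth_timepoints.csv": report.growth_timepoints,
        "growth_fits.csv": report.growth_fits,
        "ig_series.csv": report.ig_series,
        "lipid_replicates.csv": report.lipid_replicates,
        "pam_replicates.csv": report.pam_replicates,
        "paired_tests.csv": report.paired_tests,
    }
    for name, frame in tables.items():
        p = outdir / name
        frame.to_csv(p, index=False)
        paths.append(p)

    cmp = report.growth_comparison
    lines = [
        f"scenario: {report.scenario}  strain: {report.strain_label}  "
        f"seed: {report.master_seed}",
        f"alpha: {report.alpha}",
        "",
        "growth (Welch two-sample t-tests across replicate fits):",
        f"  K static    = {cmp.K_static[0]:.6g} +/- {cmp.K_static[1]:.3g}",
        f"  K perturbed = {cmp.K_perturbed[0]:.6g} +/- {cmp.K_perturbed[1]:.3g}",
        f"  K: t = {cmp.t_K:.4g}, p = {cmp.p_K:.4g}"
        f" -> {'significant' if cmp.K_significant else 'not significant'}",
        f"  Td static    = {cmp.Td_static[0]:.6g} +/- {cmp.Td_static[1]:.3g} h",
        f"  Td perturbed = {cmp.Td_perturbed[0]:.6g} +/- {cmp.Td_perturbed[1]:.3g} h",
        f"  Td: t = {cmp.t_Td:.4g}, p = {cmp.p_Td:.4g}"
        f" -> {'significant' if cmp.Td_significant else 'not significant'}",
        "",
        f"lipid index IL (perturbed/static mean normalized area): "
        f"{report.lipid_index:.4g}",
        f"growth index IG at {report.ig_series['time_h'].iloc[-1]:.0f} h: "
        f"{report.ig_series['IG'].iloc[-1]:.4g}",
        "",
        "paired t-tests by replicate (perturbed vs static):",
    ]
    for row in report.paired_tests.itertuples():
        lines.append(
            f"  {row.parameter}: t = {row.t:.4g}, p = {row.p:.4g}"
            f" -> {'significant' if row.significant else 'not significant'}"
        )
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    paths.append(summary)
    return paths
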