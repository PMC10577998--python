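"""End-to-end study orchestration.

ingest -> transforms -> nuisance estimation -> targeting -> contrasts ->
diagnostics, swept over the sensitivity grid (ratio trimming at
99.9/99/97.5 percentiles x outlier removal off/on), with deterministic
seeded output: a master contrast CSV, a JSON report and a forest plot.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diagnostics import weight_summary, positivity_report
from .ensemble import cv_performance
from .msm import contrasts_vs_reference, fit_saturated_msm
from .panel import CountryPanel, read_panel, remove_outcome_outliers
from .synthetic import SimConfig, generate_panel
from .tmle import (CategoricalTMLE, estimate_outcome_regression,
                   estimate_propensities)

__all__ = ["RunConfig", "StudyResult", "run_study", "run_multi_outcome",
           "export_report"]

DEFAULT_TRIMS = (99.9, 99.0, 97.5)


@dataclass
class RunConfig:
    """Validated, serializable configuration of one study run."""

    input_path: str | None = None          # CSV path, or None for synthetic
    scenario: str = "baseline"             # used when input_path is None
    n_countries: int = 87
    outcome_column: str = "outcome_raw"
    exposure_column: str = "exposure_index"
    learners: list | None = None           # None = full five-learner library
    folds: int = 10
    seed: int = 0
    trim_percentiles: tuple = DEFAULT_TRIMS
    outlier_removal: tuple = (False, True)
    outlier_percentiles: tuple = (1.0, 99.0)
    min_quality_stars: int = 3
    output_dir: str | None = None

    def __post_init__(self):
        for t in self.trim_percentiles:
            if not 0 < t <= 100:
                raise ValueError(f"trim percentile {t} out of (0, 100]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["trim_percentiles"] = list(self.trim_percentiles)
        d["outlier_removal"] = list(self.outlier_removal)
        d["outlier_percentiles"] = list(self.outlier_percentiles)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class StudyResult:
    """All grid cells of one run: contrast tables, diagnostics,
    ensemble performance."""

    config: RunConfig
    cells: dict = field(default_factory=dict)  # (trim, outliers) -> dict
    performance: dict = field(default_factory=dict)

    def master_table(self) -> pd.DataFrame:
        frames = []
        for (trim, outliers), cell in self.cells.items():
            t = cell["contrasts"].table.reset_index()
            t.insert(0, "trim_percentile", trim)
            t.insert(1, "outliers_removed", outliers)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def _load_panel(config: RunConfig) -> CountryPanel:
    if config.input_path is not None:
        schema = {"outcome": config.outcome_column,
                  "exposure": config.exposure_column}
        return read_panel(config.input_path, schema=schema,
                          min_quality_stars=config.min_quality_stars)
    panel, _ = generate_panel(SimConfig.for_scenario(
        config.scenario, n_countries=config.n_countries, seed=config.seed))
    return panel


def _fit_cells(panel: CountryPanel, config: RunConfig, result: StudyResult,
               variant: bool, g_cache: dict | None = None) -> None:
    sl_cfg = {"learners": config.learners, "folds": config.folds,
              "seed": config.seed}
    Q, q_model = estimate_outcome_regression(panel, sl_cfg)
    cache_key = ("g", variant)
    if g_cache is not None and cache_key in g_cache:
        g, g_model = g_cache[cache_key]
    else:
        g, g_model = estimate_propensities(panel, sl_cfg)
        if g_cache is not None:
            g_cache[cache_key] = (g, g_model)
    result.performance[variant] = {
        "cv_r2_outcome": cv_performance(q_model),
        "cv_auc_exposure": cv_performance(g_model),
    }
    for trim in config.trim_percentiles:
        tm = CategoricalTMLE(trim_percentile=trim).fit(
            panel.outcome_log, panel.levels, Q, g)
        est = tm.estimates_
        contrasts = contrasts_vs_reference(est)
        # saturated-MSM route must agree with the subtraction route
        lev_stack = np.repeat(np.arange(panel.n_levels), panel.n)
        pred_stack = est.Q_targeted.T.ravel()
        msm_coef = fit_saturated_msm(pred_stack, lev_stack)
        diag = weight_summary(tm.nuisance_)
        ok, narrative = positivity_report(diag)
        result.cells[(trim, variant)] = {
            "contrasts": contrasts,
            "msm_coefficients": msm_coef,
            "diagnostics": diag,
            "positivity": {"passed": ok, "narrative": narrative},
            "psi": est.psi,
            "se": est.se,
        }


def run_study(config: RunConfig, panel: CountryPanel | None = None
              ) -> StudyResult:
    """Run the full sensitivity grid; optionally on a pre-built panel."""
    panel = panel if panel is not None else _load_panel(config)
    result = StudyResult(config=config)
    for remove in config.outlier_removal:
        sub = panel
        if remove:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub = remove_outcome_outliers(panel,
                                              *config.outlier_percentiles)
        _fit_cells(sub, config, result, variant=bool(remove))
    if config.output_dir:
        export_report([result], config.output_dir)
    return result


def run_multi_outcome(config: RunConfig, outcome_columns: list[str],
                      panel: CountryPanel | None = None
                      ) -> dict[str, StudyResult]:
    """One bundle per outcome column; exposure-mechanism fits are shared
    across outcomes (the covariate set is identical)."""
    panel = panel if panel is not None else _load_panel(config)
    bundles: dict[str, StudyResult] = {}
    g_cache: dict = {}
    for col in outcome_columns:
        if col not in panel.df.columns:
            raise KeyError(f"outcome column {col!r} not in panel")
        df = panel.df.copy()
        df["outcome_raw"] = df[col]
        df["outcome_log"] = np.log(df[col])
        sub = panel.with_df(df)
        result = StudyResult(config=config)
        for remove in config.outlier_removal:
            cell_panel = sub
            if remove:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cell_panel = remove_outcome_outliers(
                        sub, *config.outlier_percentiles)
            # outlier filtering depends on the outcome, so g can only be
            # shared on the unfiltered variant
            _fit_cells(cell_panel, config, result, variant=bool(remove),
                       g_cache=g_cache if not remove else None)
        bundles[col] = result
    return bundles


def export_report(results: list[StudyResult], out_dir,
                  names: list[str] | None = None) -> dict:
    """Write master CSV, JSON diagnostics and a forest plot per bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    if not results:
        warnings.warn("no result bundles; writing empty report", stacklevel=2)
        (out / "report.json").write_text(json.dumps({"bundles": []}))
        return {"report": out / "report.json"}
    names = names or [f"bundle{i}" for i in range(len(results))]
    for name, res in zip(names, results):
        master = res.master_table()
        csv_path = out / f"{name}_contrasts.csv"
        master.to_csv(csv_path, index=False)
        diag = {
            f"trim{trim}_outliers{int(v)}": {
                **cell["diagnostics"].to_dict(),
                "positivity": cell["positivity"],
            }
            for (trim, v), cell in res.cells.items()
        }
        json_path = out / f"{name}_diagnostics.json"
        json_path.write_text(json.dumps(
            {"diagnostics": diag, "performance": {
                str(k): v for k, v in res.performance.items()}}, indent=2))
        fig_path = out / f"{name}_forest.png"
        _forest_plot(master, fig_path)
        res.config.to_yaml(out / f"{name}_config.yaml")
        written[name] = {"csv": csv_path, "json": json_path, "png": fig_path}
    return written


def _forest_plot(master: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    variants = sorted(master["trim_percentile"].unique(), reverse=True)
    markers = {v: m for v, m in zip(variants, "o^s")}
    contrasts = list(dict.fromkeys(master["contrast"]))
    fig, ax = plt.subplots(figsize=(7, 4))
    for vi, trim in enumerate(variants):
        sub = master[(master["trim_percentile"] == trim)
                     & (~master["outliers_removed"].astype(bool))]
        for ci, con in enumerate(contrasts):
            row = sub[sub["contrast"] == con]
            if row.empty:
                continue
            row = row.iloc[0]
            ypos = ci + 0.22 * (vi - (len(variants) - 1) / 2)
            sig = row["ci_low"] > 0 or row["ci_high"] < 0
            color = "crimson" if sig else "steelblue"
            ax.errorbar(row["beta"], ypos,
                        xerr=[[row["beta"] - row["ci_low"]],
                              [row["ci_high"] - row["beta"]]],
                        fmt=markers.get(trim, "o"), color=color, capsize=2,
                        label=f"trim {trim}" if ci == 0 else None)
    ax.axvline(0, color="gray", lw=0.8, ls=":")
    ax.set_yticks(range(len(contrasts)))
    ax.set_yticklabels(contrasts)
    ax.set_xlabel("Mean log difference (95% CI)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
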