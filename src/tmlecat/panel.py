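"""Country-level panel ingest, validation and description.

One row per country: a continuous globalization index (KOF 1-100 scale)
discretized into four ordinal levels, an age-standardized DALY outcome
(log-transformed for analysis), a pre-exposure baseline outcome, and the
confounder / precision-covariate set used by the causal analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LevelBins",
    "CountryPanel",
    "SchemaError",
    "PanelValidationError",
    "DEFAULT_SCHEMA",
    "read_panel",
    "panel_from_frame",
    "write_panel",
    "discretize_exposure",
    "log_transform_outcome",
    "remove_outcome_outliers",
    "descriptive_table",
    "one_way_anova",
    "kruskal_wallis",
    "load_country_roster",
]

#: confounders: jointly drive exposure level and log outcome
CONFOUNDERS = ["sdi", "unemployment", "inequality", "urbanization"]
#: precision covariates: predictive of the outcome only
PRECISION = ["sev", "quality_stars", "haq"]

#: default mapping from variable role to CSV column name (identity schema)
DEFAULT_SCHEMA = {
    "country": "country",
    "exposure": "exposure_index",
    "outcome": "outcome_raw",
    "baseline_outcome": "baseline_outcome_raw",
    "sdi": "sdi",
    "unemployment": "unemployment",
    "inequality": "inequality",
    "urbanization": "urbanization",
    "sev": "sev",
    "quality_stars": "quality_stars",
    "haq": "haq",
}

REQUIRED_ROLES = list(DEFAULT_SCHEMA)


class SchemaError(ValueError):
    """A required column is missing or the column mapping is incomplete."""


class PanelValidationError(ValueError):
    """Row-level validation failed; the message itemizes offending rows."""


@dataclass
class LevelBins:
    """Four contiguous intervals over the exposure scale.

    The first interval is closed on both ends; the rest are left-open,
    right-closed: [e0, e1], (e1, e2], (e2, e3], (e3, e4].
    """

    edges: tuple = (41.0, 64.0, 72.0, 82.5, 91.0)
    labels: tuple = ("Low", "Mid-Low", "Mid-High", "High")

    def __post_init__(self):
        if len(self.edges) != len(self.labels) + 1:
            raise ValueError("need len(labels)+1 edges")
        if list(self.edges) != sorted(self.edges):
            raise ValueError("edges must be increasing")

    @property
    def n_levels(self) -> int:
        return len(self.labels)


def discretize_exposure(index_values, bins: LevelBins | None = None,
                        country_ids=None) -> np.ndarray:
    """Assign each exposure-index value to an ordinal level (0..K-1).

    Boundary values fall in the lower-labeled interval: with the default
    bins, 64.0 -> Low, 64.01 -> Mid-Low, 82.5 -> Mid-High, 91.0 -> High.
    Values outside the covered range raise, naming the offending country.
    """
    bins = bins or LevelBins()
    x = np.asarray(index_values, dtype=float)
    lo, hi = bins.edges[0], bins.edges[-1]
    bad = (x < lo) | (x > hi) | ~np.isfinite(x)
    if bad.any():
        ids = (np.asarray(country_ids)[bad] if country_ids is not None
               else np.flatnonzero(bad))
        raise PanelValidationError(
            f"exposure index outside [{lo}, {hi}] for: {list(ids)}")
    # count of interior edges strictly below x; ties go to the lower level
    return np.searchsorted(np.asarray(bins.edges[1:]), x, side="left").astype(int)


@dataclass
class CountryPanel:
    """Validated analysis table: one row per country.

    ``df`` holds standardized columns: country, exposure_index,
    exposure_level, outcome_raw, outcome_log, baseline_outcome_raw,
    baseline_outcome_log, the four confounders and three precision
    covariates. Extra ``outcome_*`` columns (other disorders) are carried
    through untouched.
    """

    df: pd.DataFrame
    bins: LevelBins = field(default_factory=LevelBins)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def n_levels(self) -> int:
        return self.bins.n_levels

    @property
    def levels(self) -> np.ndarray:
        return self.df["exposure_level"].to_numpy(dtype=int)

    @property
    def outcome_log(self) -> np.ndarray:
        return self.df["outcome_log"].to_numpy(dtype=float)

    @property
    def country_ids(self) -> np.ndarray:
        return self.df["country"].to_numpy()

    def covariates(self, include_baseline: bool = True,
                   include_precision: bool = True) -> pd.DataFrame:
        cols = list(CONFOUNDERS)
        if include_baseline:
            cols.append("baseline_outcome_log")
        if include_precision:
            cols += PRECISION
        return self.df[cols].copy()

    def level_counts(self) -> np.ndarray:
        return np.bincount(self.levels, minlength=self.n_levels)

    def with_df(self, df: pd.DataFrame) -> "CountryPanel":
        return CountryPanel(df=df.reset_index(drop=True), bins=self.bins)


def panel_from_frame(df: pd.DataFrame, bins: LevelBins | None = None,
                     min_quality_stars: int = 0) -> CountryPanel:
    """Build a validated CountryPanel from a standardized raw frame.

    Expects the standardized column names (see DEFAULT_SCHEMA values);
    derives exposure_level and the log outcomes.
    """
    bins = bins or LevelBins()
    df = df.copy()

    numeric_roles = [r for r in REQUIRED_ROLES if r != "country"]
    colmap = {r: DEFAULT_SCHEMA[r] for r in REQUIRED_ROLES}
    missing_cols = [c for c in colmap.values() if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {missing_cols}")

    bad_rows = []
    for role in numeric_roles:
        col = colmap[role]
        coerced = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[coerced.isna()]:
            bad_rows.append((df.at[idx, "country"], col,
                             "missing" if pd.isna(df.at[idx, col]) else
                             f"non-numeric value {df.at[idx, col]!r}"))
        df[col] = coerced
    if bad_rows:
        items = "; ".join(f"{c}: {col} {why}" for c, col, why in bad_rows)
        raise PanelValidationError(f"invalid rows rejected -> {items}")

    n_before = len(df)
    df = df[df["quality_stars"] >= min_quality_stars]
    n_dropped = n_before - len(df)
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} row(s) below "
                      f"{min_quality_stars} quality stars", stacklevel=2)
    if df.empty:
        raise PanelValidationError("no rows retained after quality filtering")

    if (df["outcome_raw"] <= 0).any() or (df["baseline_outcome_raw"] <= 0).any():
        bad = df.loc[(df["outcome_raw"] <= 0)
                     | (df["baseline_outcome_raw"] <= 0), "country"]
        raise PanelValidationError(f"non-positive outcome for: {list(bad)}")

    df["exposure_level"] = discretize_exposure(
        df["exposure_index"], bins, country_ids=df["country"])
    df["outcome_log"] = np.log(df["outcome_raw"])
    df["baseline_outcome_log"] = np.log(df["baseline_outcome_raw"])
    return CountryPanel(df=df.reset_index(drop=True), bins=bins)


def read_panel(path, schema: dict | None = None, min_quality_stars: int = 3,
               bins: LevelBins | None = None) -> CountryPanel:
    """Read a country panel from CSV with schema validation.

    ``schema`` maps variable roles (see DEFAULT_SCHEMA keys) to the CSV's
    column names; roles omitted fall back to the standardized names. Rows
    with data-quality rating below ``min_quality_stars`` are excluded.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    unknown = set(schema) - set(REQUIRED_ROLES)
    if unknown:
        raise SchemaError(f"unknown schema role(s): {sorted(unknown)}")
    raw = pd.read_csv(path)
    missing = [schema[r] for r in REQUIRED_ROLES if schema[r] not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = raw.rename(columns={schema[r]: DEFAULT_SCHEMA[r] for r in REQUIRED_ROLES})
    return panel_from_frame(df, bins=bins, min_quality_stars=min_quality_stars)


def write_panel(panel: CountryPanel, path) -> None:
    """Write the raw columns back to CSV in the standardized schema
    (round-trips through :func:`read_panel`)."""
    cols = [DEFAULT_SCHEMA[r] for r in REQUIRED_ROLES]
    extra = [c for c in panel.df.columns if c.startswith("outcome_")
             and c not in ("outcome_raw", "outcome_log")]
    panel.df[cols + extra].to_csv(path, index=False)


def log_transform_outcome(panel: CountryPanel,
                          column: str = "outcome_raw") -> CountryPanel:
    """Natural-log transform of a positive outcome column; the raw values
    are preserved alongside."""
    vals = panel.df[column]
    if (vals <= 0).any():
        bad = panel.df.loc[vals <= 0, "country"]
        raise PanelValidationError(f"non-positive outcome for: {list(bad)}")
    df = panel.df.copy()
    df[column.replace("_raw", "") + "_log" if column.endswith("_raw")
       else column + "_log"] = np.log(vals)
    return panel.with_df(df)


def remove_outcome_outliers(panel: CountryPanel, lower_pct: float = 1.0,
                            upper_pct: float = 99.0,
                            column: str = "outcome_raw") -> CountryPanel:
    """Drop rows whose outcome lies strictly outside the sample percentile
    band (linear-interpolation quantiles). Removed ids are reported via a
    warning."""
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("percentile bounds out of order")
    if panel.n == 0:
        raise PanelValidationError("empty panel")
    y = panel.df[column].to_numpy(dtype=float)
    lo, hi = np.percentile(y, [lower_pct, upper_pct])
    keep = (y >= lo) & (y <= hi)
    removed = panel.df.loc[~keep, "country"]
    if len(removed):
        warnings.warn(f"outlier removal dropped: {list(removed)}", stacklevel=2)
    return panel.with_df(panel.df[keep])


def descriptive_table(panel: CountryPanel, variable: str) -> pd.DataFrame:
    """Per-level n / mean / SD / median / IQR plus an overall row.

    SD and IQR are reported as NaN for single-observation groups.
    """
    if variable not in panel.df.columns:
        raise KeyError(f"unknown variable {variable!r}")

    def _row(vals: np.ndarray) -> dict:
        n = len(vals)
        q75, q25 = (np.percentile(vals, [75, 25]) if n else (np.nan, np.nan))
        return {
            "n": n,
            "mean": np.mean(vals) if n else np.nan,
            "sd": np.std(vals, ddof=1) if n > 1 else np.nan,
            "median": np.median(vals) if n else np.nan,
            "iqr": q75 - q25 if n > 1 else np.nan,
        }

    rows = {}
    for k, label in enumerate(panel.bins.labels):
        rows[label] = _row(panel.df.loc[panel.levels == k, variable].to_numpy())
    rows["Overall"] = _row(panel.df[variable].to_numpy())
    return pd.DataFrame(rows).T


def one_way_anova(values, groups):
    """Classical one-way between-group ANOVA.

    Returns (F, df_between, df_within, p). Every group must have at least
    two observations.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in uniq]
    small = [g for g, s in zip(uniq, samples) if len(s) < 2]
    if small:
        raise ValueError(f"group(s) with <2 observations: {small}")
    F, _ = stats.f_oneway(*samples)
    df_b, df_w = len(uniq) - 1, len(values) - len(uniq)
    F = max(float(F), 0.0)  # guard the F ~ -1e-32 rounding case
    return F, int(df_b), int(df_w), float(stats.f.sf(F, df_b, df_w))


def kruskal_wallis(values, groups):
    """Rank-based Kruskal-Wallis H with tie correction; chi-square p.

    When every value is tied across all groups the test is vacuous:
    returns (0, 1) with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(values) == 0:
        warnings.warn("all values tied; H statistic degenerate", stacklevel=2)
        return 0.0, 1.0
    H, p = stats.kruskal(*[values[groups == g] for g in uniq])
    return float(H), float(p)


def group_comparison_table(panel: CountryPanel, variables: list[str],
                           test: str = "anova") -> pd.DataFrame:
    """Mean (SD) per exposure level plus a between-group test per
    variable — the layout of a burden-by-level descriptive table."""
    rows = []
    for var in variables:
        desc = descriptive_table(panel, var)
        row = {"variable": var}
        for label in panel.bins.labels:
            row[label] = f"{desc.loc[label, 'mean']:.3g} " \
                         f"({desc.loc[label, 'sd']:.3g})"
        vals = panel.df[var].to_numpy(dtype=float)
        if test == "anova":
            F, _, _, p = one_way_anova(vals, panel.levels)
            row["statistic"], row["p"] = F, p
        elif test == "kruskal":
            H, p = kruskal_wallis(vals, panel.levels)
            row["statistic"], row["p"] = H, p
        else:
            raise ValueError("test must be 'anova' or 'kruskal'")
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def load_country_roster() -> pd.DataFrame:
    """The 87 analysis countries with their 2018 KOF globalization level,
    parsed from the packaged roster file."""
    with resources.files("tmlecat.data").joinpath(
            "kof2018_country_levels.csv").open("r", encoding="utf-8") as fh:
        roster = pd.read_csv(fh)
    order = list(LevelBins().labels)
    roster["level"] = pd.Categorical(roster["level"], categories=order,
                                     ordered=True)
    return roster
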