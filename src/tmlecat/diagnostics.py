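"""Positivity diagnostics: weight summaries and implied exposure
probabilities.

The positivity assumption is verified descriptively, by inspecting the
mean and maximum of the (stabilized, trimmed) inverse-probability
weights: a maximum weight of w implies every country retained an
exposure probability of at least 1/w.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tmle import NuisanceFits

__all__ = ["WeightDiagnostics", "weight_summary", "implied_min_probability",
           "positivity_report"]


@dataclass
class WeightDiagnostics:
    max_weight: float
    mean_weight: float
    per_level: pd.DataFrame  # rows: level; cols: mean, max, n
    implied_min_probability: float
    implied_mean_probability: float

    def to_dict(self) -> dict:
        return {
            "max_weight": self.max_weight,
            "mean_weight": self.mean_weight,
            "implied_min_probability": self.implied_min_probability,
            "implied_mean_probability": self.implied_mean_probability,
            "per_level": self.per_level.to_dict(orient="index"),
        }


def implied_min_probability(max_weight: float) -> float:
    """Reciprocal reading of a weight extreme: max weight 50.1 means every
    unit kept at least a 1/50.1 ~ 2% probability of its exposure level."""
    if max_weight < 1:
        warnings.warn("max weight < 1 (stabilized ratios can fall below 1);"
                      " reciprocal returned as-is", stacklevel=2)
    return 1.0 / max_weight


def weight_summary(ratios: NuisanceFits, trimmed: bool = True
                   ) -> WeightDiagnostics:
    """Mean/max of positive (observed-cell) weights, overall and per
    level. Defaults to the stabilized, trimmed ratios the analysis
    reports; ``trimmed=False`` summarizes the raw stabilized ratios."""
    R = ratios.ratios_trimmed if trimmed else ratios.ratios
    pos = R[R > 0]
    if pos.size == 0:
        raise ValueError("no positive ratios to summarize")
    rows = []
    for k in range(R.shape[1]):
        col = R[:, k]
        colpos = col[col > 0]
        rows.append({"mean": float(colpos.mean()) if colpos.size else np.nan,
                     "max": float(colpos.max()) if colpos.size else np.nan,
                     "n": int(colpos.size)})
    per_level = pd.DataFrame(rows)
    per_level.index.name = "level"
    mx, mn = float(pos.max()), float(pos.mean())
    return WeightDiagnostics(
        max_weight=mx, mean_weight=mn, per_level=per_level,
        implied_min_probability=implied_min_probability(mx),
        implied_mean_probability=1.0 / mn)


def positivity_report(diag: WeightDiagnostics, threshold: float = 0.01
                      ) -> tuple[bool, str]:
    """Flag levels whose implied minimum exposure probability falls below
    ``threshold``; returns (passed, narrative)."""
    failing = []
    for k, row in diag.per_level.iterrows():
        if row["n"] and np.isfinite(row["max"]) and 1.0 / row["max"] < threshold:
            failing.append((int(k), 1.0 / row["max"]))
    passed = not failing
    if passed:
        # stabilized ratios can fall below 1; the probability reading is
        # capped at 100%
        p_min = min(1.0, diag.implied_min_probability)
        p_mean = min(1.0, diag.implied_mean_probability)
        text = (f"Positivity verified: maximum weight "
                f"{diag.max_weight:.1f} implies every country had a "
                f"probability of exposure of at least {100 * p_min:.0f}% "
                f"(1/{diag.max_weight:.1f}); mean weight "
                f"{diag.mean_weight:.1f} implies a mean probability of at "
                f"least {100 * p_mean:.0f}%.")
    else:
        named = ", ".join(f"level {k} (min prob {p:.2%})"
                          for k, p in failing)
        text = (f"Positivity concern: implied minimum exposure probability "
                f"below {threshold:.2%} at {named}.")
    return passed, text
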