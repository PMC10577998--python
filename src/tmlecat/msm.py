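"""Saturated marginal structural model over the four exposure levels.

With one dummy per non-reference level the MSM is saturated, so its OLS
coefficients on the targeted predictions equal the plain differences of
targeted level means; both routes are provided and must agree to
numerical precision. Contrasts are reported as mean log differences vs.
the Low reference with influence-curve Wald intervals, and as the
percent reading (log difference x 100, alongside the exact
exp(beta) - 1 factor).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .tmle import TargetedEstimates

__all__ = ["ContrastTable", "contrasts_vs_reference", "fit_saturated_msm",
           "percent_reading"]

Z95 = stats.norm.ppf(0.975)


class ContrastTable:
    """Mean log differences vs. the reference level with 95% CIs.

    ``table`` rows follow the reporting order High, Mid-High, Mid-Low;
    ``beta0`` is the reference (Low) targeted mean.
    """

    def __init__(self, beta0: float, table: pd.DataFrame):
        self.beta0 = beta0
        self.table = table

    def __repr__(self):
        return (f"ContrastTable(beta0={self.beta0:.3f})\n"
                + self.table.to_string())


def contrasts_vs_reference(est: TargetedEstimates, reference: int = 0,
                           labels=("Low", "Mid-Low", "Mid-High", "High")
                           ) -> ContrastTable:
    """Targeted-mean contrasts psi_k - psi_ref with IC-based inference.

    SE of each contrast is SD(IC_k - IC_ref)/sqrt(n); CIs are Wald
    beta +/- 1.96 se and p-values two-sided normal.
    """
    K = len(est.psi)
    if not 0 <= reference < K:
        raise ValueError(f"reference level {reference} absent")
    n = est.n
    rows = []
    for k in reversed([k for k in range(K) if k != reference]):
        beta = est.psi[k] - est.psi[reference]
        ic_diff = est.IC[:, k] - est.IC[:, reference]
        se = float(ic_diff.std(ddof=1) / np.sqrt(n))
        if se > 0:
            z = beta / se
            p = 2 * (1 - stats.norm.cdf(abs(z)))
        else:
            p = np.nan
        approx_pct, exact_pct = percent_reading(beta)
        rows.append({
            "contrast": f"{labels[k]} vs {labels[reference]}",
            "level": k,
            "beta": beta,
            "se": se,
            "ci_low": beta - Z95 * se,
            "ci_high": beta + Z95 * se,
            "p": p,
            "percent_approx": approx_pct,
            "percent_exact": exact_pct,
        })
    table = pd.DataFrame(rows).set_index("contrast")
    return ContrastTable(beta0=float(est.psi[reference]), table=table)


def fit_saturated_msm(targeted_predictions: np.ndarray,
                      levels_design: np.ndarray) -> np.ndarray:
    """OLS of stacked targeted predictions on level dummies.

    ``targeted_predictions`` is the length n*K stack of counterfactual
    predictions and ``levels_design`` the matching level index per row.
    Returns (beta0, beta_1..beta_{K-1}) where beta_k is the level-k
    contrast vs. level 0. Saturation makes these identical to the
    subtraction route.
    """
    y = np.asarray(targeted_predictions, dtype=float)
    lev = np.asarray(levels_design, dtype=int)
    K = int(lev.max()) + 1
    if K < 2:
        raise ValueError("rank-deficient dummy design (single level)")
    D = np.column_stack([(lev == k).astype(float) for k in range(1, K)])
    Xd = sm.add_constant(D)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("rank-deficient dummy design (level absent)")
    res = sm.OLS(y, Xd).fit()
    return np.asarray(res.params)


def percent_reading(beta: float) -> tuple[str, float]:
    """Render a log difference in the study's percent convention.

    Returns (approximate percent string, exact multiplicative percent):
    the approximation reads beta*100 directly as a percent (0.31 ->
    "31%"); the exact factor is 100*(exp(beta)-1).
    """
    approx = f"{round(beta * 100):.0f}%"
    exact = 100.0 * (np.exp(beta) - 1.0)
    return approx, exact
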