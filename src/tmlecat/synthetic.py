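"""Synthetic country panels with known causal truth.

The generator emulates the study's schema and statistical structure:
bounded confounders on realistic supports (development index, income
inequality, urbanization in [0,1]; unemployment positive; a baseline
log burden), a latent globalization score driven by the confounders
plus Gaussian noise (so true exposure-level propensities are analytic
normal-CDF differences), discretization of the score into four levels
at fixed quantile thresholds (splits resembling 23/23/19/22 of 87), and
additive level effects on the log-outcome scale. Default level effects
(0.13, 0.14, 0.31) mirror the magnitudes reported for this kind of
burden analysis — a simulation convention, not a reproduction claim.

Scenarios: ``baseline``, ``zero_effect``, ``strong_confounding``,
``nonlinear_Q`` (curved outcome surface with a level-dependent
modifier, so the causal truth needs the Monte-Carlo oracle) and
``misspecified_g`` (curved latent assignment score, so a multinomial
logit for the exposure mechanism is misspecified).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .panel import CountryPanel, LevelBins, panel_from_frame

__all__ = ["SimConfig", "SyntheticTruth", "generate_panel",
           "true_contrasts_oracle", "scenario_suite", "SCENARIOS"]

SCENARIOS = ("baseline", "zero_effect", "strong_confounding",
             "nonlinear_Q", "misspecified_g")

# cumulative level-share targets: 23/87, 46/87, 65/87
_DEFAULT_QUANTILES = (23 / 87, 46 / 87, 65 / 87)

# centering constants for the structural equations
_CENTERS = {"sdi": 0.75, "inequality": 0.41, "urbanization": 0.40,
            "sev": 6.0, "haq": 75.0, "unemployment": 6.5, "baseline": 4.2}

_OUTCOME_EFFECTS = {"sdi": 1.9, "inequality": 1.5, "urbanization": 0.45,
                    "sev": 0.03, "haq": 0.004, "unemployment": 0.012,
                    "baseline": 0.5}

_EXPOSURE_EFFECTS = {"sdi": 5.5, "inequality": -4.0, "urbanization": 0.9,
                     "haq": 0.012}

_POP_SEED = 987654321  # internal draw for thresholds / population means
_POP_SIZE = 200_000


@dataclass
class SimConfig:
    """Study-condition parameters for the generator."""

    n_countries: int = 87
    level_effects: tuple = (0.13, 0.14, 0.31)  # Mid-Low, Mid-High, High
    confounder_effects_on_outcome: dict = field(
        default_factory=lambda: dict(_OUTCOME_EFFECTS))
    confounder_effects_on_exposure: dict = field(
        default_factory=lambda: dict(_EXPOSURE_EFFECTS))
    noise_sd: float = 0.25          # outcome noise, log scale
    latent_noise_sd: float = 1.8    # assignment noise on the latent score
    exposure_bin_quantiles: tuple = _DEFAULT_QUANTILES
    intercept: float = 4.30         # log DALYs at Low with centered covariates
    seed: int = 0
    scenario: str = "baseline"
    extra_outcomes: int = 0         # additional null-effect outcome columns

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {SCENARIOS}")
        if self.noise_sd <= 0 or self.latent_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if not all(np.isfinite(self.level_effects)):
            raise ValueError("level effects must be finite")

    @classmethod
    def for_scenario(cls, scenario: str, n_countries: int = 87,
                     seed: int = 0, **kw) -> "SimConfig":
        cfg = cls(n_countries=n_countries, seed=seed, scenario=scenario, **kw)
        if scenario == "zero_effect":
            cfg = replace(cfg, level_effects=(0.0, 0.0, 0.0))
        elif scenario == "strong_confounding":
            # confounding is strengthened on the outcome side (effects
            # x2.2) while the assignment stays moderately predictive, so
            # the unadjusted contrast is badly biased (>0.2 log-units)
            # yet every unit keeps healthy exposure probabilities
            eff = {k: 2.2 * v
                   for k, v in cfg.confounder_effects_on_outcome.items()}
            cfg = replace(cfg, confounder_effects_on_outcome=eff,
                          latent_noise_sd=2.6)
        return cfg


@dataclass
class SyntheticTruth:
    """Known causal truth attached to a generated panel."""

    true_psi: np.ndarray        # (4,) counterfactual mean log outcomes
    true_contrasts: np.ndarray  # (3,) level k vs Low, k = 1..3
    generating_seed: int
    g_true: np.ndarray          # (n, 4) true propensities of sampled rows
    Q_true: np.ndarray          # (n, 4) true outcome means of sampled rows
    thresholds: np.ndarray      # latent-score cut points


def _draw_confounders(rng: np.random.Generator, n: int) -> pd.DataFrame:
    sdi = rng.beta(12, 4, n)
    df = pd.DataFrame({
        "sdi": sdi,
        "unemployment": rng.lognormal(np.log(6.0), 0.45, n),
        "inequality": rng.beta(20, 29, n),
        "urbanization": rng.beta(3.4, 5.1, n),
        "sev": rng.gamma(6.4, 0.94, n),
        "haq": np.clip(140 * sdi - 30 + rng.normal(0, 5, n), 5, 100),
        "quality_stars": 3 + rng.binomial(
            2, np.clip(1.2 * sdi - 0.45, 0.05, 0.95)),
    })
    df["baseline_outcome_log"] = (4.2 + 1.2 * (sdi - 0.75)
                                  + rng.normal(0, 0.45, n))
    return df


def _latent_mean(df: pd.DataFrame, cfg: SimConfig) -> np.ndarray:
    m = np.zeros(len(df))
    for name, coef in cfg.confounder_effects_on_exposure.items():
        m += coef * (df[name].to_numpy() - _CENTERS[name])
    if cfg.scenario == "misspecified_g":
        # curvature a multinomial logit in the raw covariates cannot match
        m = m + 4.5 * (df["sdi"].to_numpy() - 0.75) ** 2 \
            - 2.0 * np.abs(df["inequality"].to_numpy() - 0.41)
    return m


def _outcome_mean(df: pd.DataFrame, level, cfg: SimConfig) -> np.ndarray:
    level = np.broadcast_to(np.asarray(level, dtype=int), (len(df),))
    theta = np.concatenate([[0.0], np.asarray(cfg.level_effects)])
    mu = cfg.intercept + theta[level]
    for name, coef in cfg.confounder_effects_on_outcome.items():
        col = "baseline_outcome_log" if name == "baseline" else name
        mu = mu + coef * (df[col].to_numpy() - _CENTERS[name])
    if cfg.scenario == "nonlinear_Q":
        sdi = df["sdi"].to_numpy()
        mu = mu + 2.2 * (sdi - 0.75) ** 2 \
            + 0.8 * (df["inequality"].to_numpy() - 0.41) * (sdi - 0.75) \
            + 0.5 * (level == 3) * (sdi - 0.65)
    return mu


def _population(cfg: SimConfig):
    """Large fixed-seed draw defining thresholds and population means."""
    rng = np.random.default_rng(_POP_SEED)
    pop = _draw_confounders(rng, _POP_SIZE)
    m = _latent_mean(pop, cfg)
    s = m + cfg.latent_noise_sd * rng.standard_normal(_POP_SIZE)
    thr = np.quantile(s, cfg.exposure_bin_quantiles)
    lo = s.min() - 1e-9
    hi = s.max() + 1e-9
    return pop, thr, (lo, hi)


def _g_true(df: pd.DataFrame, thr: np.ndarray, cfg: SimConfig) -> np.ndarray:
    m = _latent_mean(df, cfg)
    z = stats.norm.cdf((thr[None, :] - m[:, None]) / cfg.latent_noise_sd)
    cdf = np.hstack([np.zeros((len(df), 1)), z, np.ones((len(df), 1))])
    return np.diff(cdf, axis=1)


def _index_from_latent(s, thr, span, bins: LevelBins) -> np.ndarray:
    lo, hi = span
    knots = np.concatenate([[lo], thr, [hi]])
    return np.interp(np.clip(s, lo, hi), knots, np.asarray(bins.edges))


def generate_panel(config: SimConfig, max_retries: int = 100
                   ) -> tuple[CountryPanel, SyntheticTruth]:
    """Draw one country panel plus its causal truth.

    Resamples (with a warning) if any exposure level comes up empty,
    which can happen at small n.
    """
    cfg = config
    bins = LevelBins()
    pop, thr, span = _population(cfg)

    # population truth: E[Y(k)] over the covariate distribution
    psi = np.array([_outcome_mean(pop, k, cfg).mean() for k in range(4)])
    if cfg.scenario == "nonlinear_Q":
        contrasts = psi[1:] - psi[0]
    else:  # additive: contrasts are the configured effects exactly
        contrasts = np.asarray(cfg.level_effects, dtype=float)

    rng = np.random.default_rng(cfg.seed)
    for attempt in range(max_retries):
        df = _draw_confounders(rng, cfg.n_countries)
        s = _latent_mean(df, cfg) \
            + cfg.latent_noise_sd * rng.standard_normal(cfg.n_countries)
        level = np.searchsorted(thr, s, side="left")
        if len(np.unique(level)) == 4:
            break
        warnings.warn(f"empty exposure level on draw {attempt}; resampling",
                      stacklevel=2)
    else:
        raise RuntimeError("could not populate all 4 levels; increase n")

    logy = _outcome_mean(df, level, cfg) \
        + cfg.noise_sd * rng.standard_normal(cfg.n_countries)
    raw = pd.DataFrame({
        "country": [f"C{i:04d}" for i in range(cfg.n_countries)],
        "exposure_index": _index_from_latent(s, thr, span, bins),
        "outcome_raw": np.exp(logy),
        "baseline_outcome_raw": np.exp(df["baseline_outcome_log"]),
    })
    for col in ("sdi", "unemployment", "inequality", "urbanization", "sev",
                "quality_stars", "haq"):
        raw[col] = df[col].to_numpy()
    for j in range(cfg.extra_outcomes):
        null_cfg = replace(cfg, level_effects=(0.0, 0.0, 0.0),
                           scenario="zero_effect")
        raw[f"outcome_alt{j + 1}_raw"] = np.exp(
            _outcome_mean(df, level, null_cfg)
            + cfg.noise_sd * rng.standard_normal(cfg.n_countries))

    panel = panel_from_frame(raw, bins=bins)
    assert np.array_equal(panel.levels, level), \
        "index discretization inconsistent with latent thresholds"
    truth = SyntheticTruth(
        true_psi=psi, true_contrasts=contrasts, generating_seed=cfg.seed,
        g_true=_g_true(df, thr, cfg),
        Q_true=np.column_stack([_outcome_mean(df, k, cfg) for k in range(4)]),
        thresholds=thr)
    return panel, truth


def true_contrasts_oracle(config: SimConfig, n_mc: int = 100_000
                          ) -> np.ndarray:
    """Monte-Carlo evaluation of E[Y(k)] - E[Y(0)] with exposure forced
    to each level over a fresh covariate draw."""
    if n_mc < 10_000:
        warnings.warn("n_mc < 10^4: oracle Monte-Carlo error may be large",
                      stacklevel=2)
    rng = np.random.default_rng((config.seed + 777) % (2 ** 31))
    df = _draw_confounders(rng, n_mc)
    means = np.array([_outcome_mean(df, k, config).mean() for k in range(4)])
    return means[1:] - means[0]


def scenario_suite(seed: int = 0, n_small: int = 87, n_large: int = 5000
                   ) -> dict:
    """One (panel, truth) fixture per scenario at a desk-scale n and a
    super-population n."""
    suite = {}
    for name in SCENARIOS:
        suite[name] = {
            "small": generate_panel(SimConfig.for_scenario(
                name, n_countries=n_small, seed=seed)),
            "large": generate_panel(SimConfig.for_scenario(
                name, n_countries=n_large, seed=seed + 1)),
        }
    return suite
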