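"""Meta-regression of divergence on evolvability, with derived quantities.

The response is ln(d) (log among-population variance) and the focal
predictor is ln(e) (log mean-scaled evolvability); observations are
weighted by the inverse sampling variance of ln(d), which by the delta
method is 2/(n_pop + 2) regardless of d.  Random intercepts for species
and divergence study capture heterogeneity in overall divergence; a
random slope for ln(e) per study quantifies heterogeneity of the
evolvability-divergence relationship itself.

Because the predictor is an estimated quantity, the fitted slope is
attenuated toward zero; :func:`attenuation_correct` divides it by the
reliability 1 - V_me/V, where V_me is the estimation-error variance among
repeated evolvability estimates and V the total predictor variance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import LMMFit, RandomTerm, WeightedLMM

logger = logging.getLogger(__name__)

__all__ = [
    "MetaDataset",
    "fit_weighted_lmm",
    "attenuation_correct",
    "estimate_reliability",
    "compare_aic",
    "r2_nakagawa",
    "slope_to_percent",
    "backtransform_log_ratio",
]

#: columns a meta-regression dataset must provide
META_COLUMNS = ["log_e", "log_d", "weight", "species", "study_id"]


@dataclass(frozen=True)
class MetaDataset:
    """Paired (log e, log d) rows with weights, covariates and groupings."""

    data: pd.DataFrame
    centered: bool = False

    def __post_init__(self):
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"meta dataset missing columns {missing}")
        w = self.data["weight"].to_numpy(dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be strictly positive and finite")

    def center_covariates(self, columns=("log_e", "log_npop", "log_dist")):
        """Mean-center covariates so the intercept refers to average
        predictor values (the reporting convention used throughout)."""
        data = self.data.copy()
        for col in columns:
            if col in data.columns:
                data[col] = data[col] - data[col].mean()
        return MetaDataset(data=data, centered=True)


def _design(
    data: pd.DataFrame,
    fixed: list[str],
    moderator: str | None,
    reference_level: str | None,
) -> pd.DataFrame:
    """Fixed-effects design matrix: intercept + terms (+ moderator and its
    interaction with log_e, treatment-coded against the reference level)."""
    X = pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)
    for term in fixed:
        X[term] = data[term].to_numpy(dtype=float)
    if moderator is not None:
        levels = sorted(data[moderator].astype(str).unique())
        ref = reference_level if reference_level is not None else levels[0]
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not among {levels}")
        for lev in levels:
            if lev == ref:
                continue
            ind = (data[moderator].astype(str) == lev).to_numpy(dtype=float)
            X[f"{moderator}[{lev}]"] = ind
            X[f"log_e:{moderator}[{lev}]"] = ind * data["log_e"].to_numpy(dtype=float)
    return X


def fit_weighted_lmm(
    dataset: MetaDataset,
    fixed: list[str] | None = None,
    random_intercepts: list[str] | None = None,
    random_slope: tuple[str, str] | None = ("log_e", "study_id"),
    moderator: str | None = None,
    reference_level: str | None = None,
    method: str = "ML",
) -> LMMFit:
    """Fit the weighted mixed-effects meta-regression.

    Parameters
    ----------
    fixed
        Continuous fixed-effect columns (default ``["log_e"]`` plus
        ``log_npop``/``log_dist`` when present in the data).
    random_intercepts
        Grouping columns for random intercepts (default species and
        study_id, each used only when it has >=2 levels).
    random_slope
        (covariate, grouping) pair for a random-slope term, or None.
    moderator
        Optional categorical column added as main effect plus its
        interaction with log_e (a slope-heterogeneity test).
    method
        "ML" (required for AIC comparison across fixed structures) or
        "REML" for final variance reporting.
    """
    data = dataset.data
    if fixed is None:
        fixed = ["log_e"]
        for c in ("log_npop", "log_dist"):
            if c not in data.columns:
                continue
            if data[c].nunique() < 2:
                logger.warning("covariate %s is constant; dropped", c)
                continue
            fixed.append(c)
    X = _design(data, fixed, moderator, reference_level)
    terms = []
    groups = random_intercepts
    if groups is None:
        groups = [g for g in ("species", "study_id") if data[g].nunique() >= 2]
    for g in groups:
        terms.append(RandomTerm(name=f"intercept|{g}", groups=data[g].to_numpy()))
    if random_slope is not None:
        cov, grp = random_slope
        if data[grp].nunique() >= 2:
            terms.append(
                RandomTerm(
                    name=f"{cov}|{grp}",
                    groups=data[grp].to_numpy(),
                    covariate=data[cov].to_numpy(dtype=float),
                )
            )
    model = WeightedLMM(
        y=data["log_d"].to_numpy(dtype=float),
        X=X,
        weights=data["weight"].to_numpy(dtype=float),
        random_terms=terms,
    )
    fit = model.fit(method=method)
    fit.r2_marginal, fit.r2_conditional = r2_nakagawa(fit)
    return fit


def attenuation_correct(
    raw_slope: float, V_me: float, V: float
) -> tuple[float, float]:
    """Correct a regression slope for attenuation by predictor noise.

    Estimation error in the predictor shrinks the fitted slope by the
    reliability 1 - V_me/V; dividing restores the error-free slope.

    Returns ``(corrected_slope, reliability)``.
    """
    if V_me < 0:
        raise ValueError("V_me must be >= 0")
    if V_me >= V:
        raise ValueError(
            f"measurement-error variance ({V_me}) >= predictor variance ({V}): "
            "predictor is all noise, correction undefined"
        )
    reliability = 1.0 - V_me / V
    return raw_slope / reliability, reliability


def estimate_reliability(
    estimates: pd.DataFrame,
    value_col: str = "evolvability",
    unit_cols: tuple[str, str] = ("species", "trait"),
    predictor: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Estimate (V_me, V, reliability) of the log-evolvability predictor.

    V_me is the mean within-(species, trait) variance among repeated log
    evolvability estimates — the estimation-error variance that survives
    in the per-pairing means.  V is the variance of the predictor actually
    entering the regression (the per-pairing mean log evolvabilities);
    pass it via ``predictor``, else it is computed from the per-unit means.
    """
    df = estimates.copy()
    df["_log_e"] = np.log(df[value_col].to_numpy(dtype=float))
    per_unit = df.groupby(list(unit_cols))["_log_e"]
    within = per_unit.var(ddof=1).dropna()
    counts = per_unit.count()
    if len(within) == 0:
        V_me = 0.0
    else:
        # error variance of a mean of n_i repeats is within-var / n_i
        n_per = counts.reindex(within.index)
        V_me = float(np.mean(within / n_per))
    if predictor is None:
        predictor = per_unit.mean().to_numpy()
    predictor = np.asarray(predictor, dtype=float)
    V = float(np.var(predictor, ddof=1))
    if V_me >= V:
        return V_me, V, float("nan")
    return V_me, V, 1.0 - V_me / V


def reliability_variance(
    estimates: pd.DataFrame,
    V: float,
    V_me: float,
    value_col: str = "evolvability",
    unit_cols: tuple[str, str] = ("species", "trait"),
    n_predictor: int | None = None,
) -> float:
    """Approximate sampling variance of the estimated reliability.

    Treats V_me (a mean of per-unit error-variance estimates) and V (a
    sample variance over the predictor values) as independent:
    var(rel) ~= var(V_me)/V^2 + V_me^2 var(V)/V^4, with
    var(V) ~= 2 V^2/(m-1) under approximate normality.
    """
    df = estimates.copy()
    df["_log_e"] = np.log(df[value_col].to_numpy(dtype=float))
    per_unit = df.groupby(list(unit_cols))["_log_e"]
    within = (per_unit.var(ddof=1) / per_unit.count()).dropna()
    m_units = len(within)
    var_Vme = float(within.var(ddof=1)) / m_units if m_units > 1 else 0.0
    m_pred = n_predictor if n_predictor is not None else m_units
    var_V = 2.0 * V * V / max(m_pred - 1, 1)
    return var_Vme / V**2 + (V_me**2) * var_V / V**4


def compare_aic(fit_baseline: LMMFit, fit_complex: LMMFit) -> tuple[float, str]:
    """AIC difference (complex - baseline); positive supports the baseline.

    |dAIC| > 2 is labeled a detectable difference.  Both fits must be ML
    fits on the same rows: REML likelihoods are not comparable across
    differing fixed-effects structures.
    """
    for f in (fit_baseline, fit_complex):
        if f.method != "ML":
            raise ValueError("AIC comparison across fixed effects requires ML fits")
    if fit_baseline.n_obs != fit_complex.n_obs:
        raise ValueError("fits use different numbers of observations")
    delta = fit_complex.aic - fit_baseline.aic
    if delta > 2:
        label = "baseline-supported"
    elif delta < -2:
        label = "complex-supported"
    else:
        label = "indistinguishable"
    return float(delta), label


def r2_nakagawa(fit: LMMFit) -> tuple[float, float]:
    """Marginal and conditional r^2 for a (weighted) Gaussian mixed model.

    r2_marginal = var_fixed / (var_fixed + var_random + var_resid) is the
    share of variance explained by the fixed effects; r2_conditional adds
    the random effects.  Random-slope contributions are evaluated at the
    observed covariate distribution (variance * mean squared covariate),
    and the weighted residual variance is summarized as sigma^2 * mean(1/w).
    """
    if fit._X is None:
        raise ValueError("fit does not retain its design matrix")
    if not fit.converged:
        logger.warning("computing r^2 from a non-converged fit")
    fitted = fit._X @ fit.fe_estimates
    var_fixed = float(np.var(fitted))
    var_random = sum(
        v * fit._re_mean_sq.get(name, 1.0)
        for name, v in fit.random_variances.items()
    )
    var_resid = fit.sigma2 * float(np.mean(1.0 / fit._weights))
    total = var_fixed + var_random + var_resid
    if total <= 0:
        raise ValueError("zero total variance; r^2 undefined")
    return var_fixed / total, (var_fixed + var_random) / total


def slope_to_percent(slope: float, pct_increase: float = 10.0) -> float:
    """Percent change in divergence for a given percent change in
    evolvability, under a log-log power law with the given slope."""
    if pct_increase <= -100:
        raise ValueError("percent increase must exceed -100")
    return 100.0 * ((1.0 + pct_increase / 100.0) ** slope - 1.0)


def backtransform_log_ratio(log_ratio: float) -> float:
    """Back-transform a mean log ratio to the ratio scale."""
    return math.exp(log_ratio)
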