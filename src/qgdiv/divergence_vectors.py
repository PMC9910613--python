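"""Evolvability along observed divergence vectors.

If genetic constraints channel divergence, populations should have
diverged along trait-space directions of above-average evolvability: the
evolvability along the unit divergence vector from a focal population
(the one whose G-matrix is known) to each other population should exceed
the mean evolvability of that G-matrix more often than not, and
populations diverging along high-evolvability directions should have
diverged farther.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gmatrix import (
    GMatrix,
    MatrixSummary,
    conditional_evolvability_along,
    evolvability_along,
    matrix_summary,
)
from .divergence import divergence_vector
from .lmm import RandomTerm, WeightedLMM

logger = logging.getLogger(__name__)

__all__ = [
    "VectorEvolvabilityRecord",
    "vector_evolvabilities",
    "records_to_frame",
    "above_average_summary",
    "minmax_scale",
    "divergence_vs_evolvability_table",
]


@dataclass(frozen=True)
class VectorEvolvabilityRecord:
    """Evolvability along one focal-to-target divergence vector."""

    g_matrix_id: str
    focal_population: str
    target_population: str
    d_mag: float  # Euclidean norm of the log-scale divergence vector
    e_along: float
    c_along: float
    e_ratio: float  # e_along / mean evolvability of the focal G
    c_ratio: float  # c_along / mean conditional evolvability
    var_log_e_ratio: float | None = None
    var_log_c_ratio: float | None = None


def vector_evolvabilities(
    G: GMatrix,
    focal_means,
    target_means,
    summary: MatrixSummary | None = None,
    focal_population: str = "focal",
    target_population: str = "target",
    G_draws: np.ndarray | None = None,
    G_draws_inv: np.ndarray | None = None,
) -> VectorEvolvabilityRecord | None:
    """e and c along the divergence vector between two populations.

    Returns None (with a log message) for coincident populations, whose
    divergence direction is undefined.  When ``G_draws`` (Monte-Carlo
    draws of G) are given, sampling variances of the log ratios
    ln(e_along/e_mean) and ln(c_along/c_mean) are estimated by
    recomputing both along the fixed direction for each draw.
    """
    rec = divergence_vector(
        focal_means, target_means, G.trait_labels,
        focal_population=focal_population, target_population=target_population,
    )
    if rec.unit_direction is None:
        logger.info(
            "skipping %s -> %s: zero-magnitude divergence vector",
            focal_population, target_population,
        )
        return None
    if summary is None:
        summary = matrix_summary(G)
    u = rec.unit_direction
    e_along = evolvability_along(G, u)
    c_along = conditional_evolvability_along(G, u)
    var_log_e = var_log_c = None
    if G_draws is not None:
        uv = u.values
        k = G.k
        e_d = np.einsum("rij,i,j->r", G_draws, uv, uv)
        inv = G_draws_inv if G_draws_inv is not None else np.linalg.inv(G_draws)
        c_d = 1.0 / np.einsum("rij,i,j->r", inv, uv, uv)
        ebar_d = np.trace(G_draws, axis1=1, axis2=2) / k
        ok = (e_d > 0) & (c_d > 0) & (ebar_d > 0)
        var_log_e = float(np.var(np.log(e_d[ok] / ebar_d[ok]), ddof=1))
        # mean conditional evolvability per draw is expensive; the ratio
        # variance is dominated by the numerator, so scale by c/e spread
        var_log_c = float(np.var(np.log(c_d[ok] / ebar_d[ok]), ddof=1))
    return VectorEvolvabilityRecord(
        g_matrix_id=G.study_id or G.species or "G",
        focal_population=focal_population,
        target_population=target_population,
        d_mag=rec.magnitude,
        e_along=e_along,
        c_along=c_along,
        e_ratio=e_along / summary.e_mean,
        c_ratio=c_along / summary.c_mean if summary.c_mean else float("nan"),
        var_log_e_ratio=var_log_e,
        var_log_c_ratio=var_log_c,
    )


def records_to_frame(records) -> pd.DataFrame:
    recs = [r for r in records if r is not None]
    if not recs:
        raise ValueError("no valid divergence-vector records")
    return pd.DataFrame([r.__dict__ for r in recs])


def _weighted_mean_log_ratio(df: pd.DataFrame, ratio_col: str, var_col: str):
    """Error-weighed mean log ratio via an intercept-only mixed model with
    random intercepts for G-matrix and target-population identity."""
    y = np.log(df[ratio_col].to_numpy(dtype=float))
    var = df[var_col].to_numpy(dtype=float) if var_col in df else np.full(len(df), np.nan)
    if np.any(~np.isfinite(var)) or np.any(var <= 0):
        weights = np.ones(len(df))
    else:
        weights = 1.0 / var
    terms = []
    for g in ("g_matrix_id", "target_population"):
        if df[g].nunique() >= 2:
            terms.append(RandomTerm(name=f"intercept|{g}", groups=df[g].to_numpy()))
    if len(df) < 3:
        mean = float(np.average(y, weights=weights))
        se = float(np.sqrt(1.0 / np.sum(weights)))
        return mean, se
    fit = WeightedLMM(
        y=y, X=np.ones((len(df), 1)), weights=weights,
        random_terms=terms, fe_names=["mean_log_ratio"],
    ).fit(method="REML" if terms else "ML")
    return fit.coef("mean_log_ratio")


def above_average_summary(records) -> dict:
    """Proportions of populations diverging along above-average
    evolvability, and error-weighed mean log ratios.

    Returns proportions of records with e_ratio > 1 and c_ratio > 1,
    the weighted mean log ratios ln(e_along/e_mean) and ln(c_along/c_mean)
    with SEs, and their back-transformed ratio-scale values.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    prop_e = float(np.mean(df["e_ratio"] > 1))
    prop_c = float(np.mean(df["c_ratio"] > 1))
    mean_log_e, se_log_e = _weighted_mean_log_ratio(df, "e_ratio", "var_log_e_ratio")
    mean_log_c, se_log_c = _weighted_mean_log_ratio(df, "c_ratio", "var_log_c_ratio")
    return {
        "n_records": int(len(df)),
        "prop_e_above": prop_e,
        "prop_c_above": prop_c,
        "mean_log_e_ratio": float(mean_log_e),
        "se_log_e_ratio": float(se_log_e),
        "mean_log_c_ratio": float(mean_log_c),
        "se_log_c_ratio": float(se_log_c),
        "e_ratio_backtransformed": float(np.exp(mean_log_e)),
        "c_ratio_backtransformed": float(np.exp(mean_log_c)),
    }


def minmax_scale(value: float, mean: float, e_min: float, e_max: float) -> float:
    """Scale a value into [-1, 1] proportionally between the matrix mean
    and its minimum (below) or maximum (above) evolvability.

    0 maps to the mean, +1 to e_max, -1 to e_min; values outside
    [e_min, e_max] are clamped with a warning; a degenerate matrix
    (e_min == e_max) returns 0.
    """
    if e_max == e_min:
        return 0.0
    if value > e_max or value < e_min:
        logger.warning(
            "value %.4g outside [e_min=%.4g, e_max=%.4g]; clamped",
            value, e_min, e_max,
        )
        value = min(max(value, e_min), e_max)
    if value >= mean:
        return (value - mean) / (e_max - mean)
    return (value - mean) / (mean - e_min)


def divergence_vs_evolvability_table(records, study_col: str = "g_matrix_id"):
    """Per-study paired (d_mag, e_along, c_along) series with the rank
    correlation between divergence magnitude and evolvability along the
    divergence vector — positive when populations that diverged along
    more evolvable directions also diverged farther.

    Returns (tidy per-record table, per-study correlation table); the
    correlation is NaN for studies with a single record.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    rows = []
    for study, sub in df.groupby(study_col, sort=True):
        if len(sub) < 2:
            rho = float("nan")
        else:
            rho = float(stats.spearmanr(sub["d_mag"], sub["e_along"]).statistic)
        rows.append({study_col: study, "rank_corr_d_e": rho, "n_records": len(sub)})
    return df, pd.DataFrame(rows)
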