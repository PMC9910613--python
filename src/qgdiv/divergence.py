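"""Per-trait and multivariate divergence statistics from population means.

Divergence of a trait among populations is measured on the proportional
scale as d = var(ln population means) (unbiased, n-1 denominator).  The
folded-normal back-transform d_P = exp(sqrt(2 d / pi)) expresses d as the
expected multiplicative deviation of an average population from the grand
mean: a d_P of 1.07 means the average population has evolved to be about
7% larger or smaller than the grand mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gmatrix import DirectionVector, DMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DivergenceEstimate",
    "DivergenceVectorRecord",
    "among_population_variance",
    "proportional_divergence",
    "proportional_divergence_inverse",
    "measurement_error_variance",
    "log_scale_error_variance",
    "estimate_D_matrix",
    "divergence_vector",
    "median_divergence_summary",
    "validate_population_means",
]

POPULATION_MEANS_COLUMNS = [
    "species",
    "study_id",
    "population_id",
    "trait",
    "mean",
    "environment",
    "lat",
    "lon",
]


@dataclass(frozen=True)
class DivergenceEstimate:
    """Divergence of one trait in one divergence study."""

    trait: str
    d: float  # variance of ln population means
    n_pop: int
    sigma2_m: float  # measurement-error variance of d, 2 d^2 / (n + 2)
    d_P: float  # proportional divergence factor, >= 1


@dataclass(frozen=True)
class DivergenceVectorRecord:
    """Realized log-scale displacement between two populations.

    ``delta`` = ln(target means) - ln(focal means); its Euclidean norm is
    the divergence magnitude and its unit direction is the direction in
    trait space along which the evolution actually occurred.
    ``unit_direction`` is None for coincident populations (magnitude 0).
    """

    focal_population: str
    target_population: str
    trait_labels: tuple[str, ...]
    delta: np.ndarray
    magnitude: float
    unit_direction: DirectionVector | None


def among_population_variance(means) -> float:
    """Variance of ln-transformed population means (n-1 denominator)."""
    means = np.asarray(means, dtype=float)
    if means.size < 2:
        raise ValueError("need at least 2 populations to estimate divergence")
    if np.any(means <= 0):
        bad = np.nonzero(means <= 0)[0].tolist()
        raise ValueError(f"non-positive population mean(s) at index {bad}")
    return float(np.var(np.log(means), ddof=1))


def proportional_divergence(d: float) -> float:
    """Folded-normal back-transform of d to the proportional scale.

    d_P = exp(sqrt(2 d / pi)): sqrt(2 d / pi) is the expected absolute
    deviation of a N(0, d) log-scale population effect, and exponentiation
    returns it to the arithmetic scale.  d_P >= 1, with d_P = 1 iff d = 0.
    """
    if d < 0:
        raise ValueError(f"negative among-population variance d={d}")
    return math.exp(math.sqrt(2.0 * d / math.pi))


def proportional_divergence_inverse(d_P: float) -> float:
    """Inverse of :func:`proportional_divergence` (d_P >= 1 -> d)."""
    if d_P < 1:
        raise ValueError(f"proportional divergence {d_P} < 1")
    return math.log(d_P) ** 2 * math.pi / 2.0


def measurement_error_variance(d: float, n_pop: int) -> float:
    """Sampling variance of d: sigma^2_m = 2 d^2 / (n_pop + 2)."""
    if n_pop < 2:
        raise ValueError("n_pop must be >= 2")
    if d < 0:
        raise ValueError("d must be >= 0")
    return 2.0 * d * d / (n_pop + 2)


def log_scale_error_variance(n_pop: int) -> float:
    """Delta-method sampling variance of ln(d): 2 / (n_pop + 2).

    var(ln d) ~= sigma2_m(d) / d^2, free of d itself; used as the default
    inverse-variance weighting basis when the response is ln(d).
    """
    if n_pop < 2:
        raise ValueError("n_pop must be >= 2")
    return 2.0 / (n_pop + 2)


def divergence_estimate(trait: str, means) -> DivergenceEstimate:
    """Full per-trait divergence summary from one study's population means."""
    means = np.asarray(means, dtype=float)
    d = among_population_variance(means)
    n = int(means.size)
    return DivergenceEstimate(
        trait=trait,
        d=d,
        n_pop=n,
        sigma2_m=measurement_error_variance(d, n),
        d_P=proportional_divergence(d),
    )


def validate_population_means(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format population-means table.

    Requires columns species, study_id, population_id, trait, mean;
    strictly positive means; unique (study_id, population_id, trait); and
    at least two populations per study.
    """
    required = ["species", "study_id", "population_id", "trait", "mean"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"population means table missing columns {missing}")
    nonpos = table[table["mean"] <= 0]
    if len(nonpos):
        rows = nonpos[["study_id", "population_id", "trait"]].to_dict("records")
        raise ValueError(f"non-positive trait means for {rows[:5]}")
    dup = table.duplicated(["study_id", "population_id", "trait"])
    if dup.any():
        raise ValueError(
            "duplicate (study_id, population_id, trait) rows: "
            f"{table[dup][['study_id', 'population_id', 'trait']].head().to_dict('records')}"
        )
    npop = table.groupby("study_id")["population_id"].nunique()
    small = npop[npop < 2]
    if len(small):
        raise ValueError(f"studies with <2 populations: {list(small.index)}")
    return table


def estimate_D_matrix(
    pop_means: pd.DataFrame,
    trait_subset=None,
    complete_cases: bool = True,
) -> DMatrix:
    """Sample covariance of ln population means across populations.

    ``pop_means`` must be restricted to a single study.  Populations with
    missing values for any selected trait are dropped (listwise deletion,
    logged) when ``complete_cases`` is true, otherwise an error lists them.
    """
    studies = pop_means["study_id"].unique()
    if len(studies) != 1:
        raise ValueError(f"expected a single study, got {list(studies)}")
    wide = pop_means.pivot(index="population_id", columns="trait", values="mean")
    if trait_subset is not None:
        wide = wide[list(trait_subset)]
    incomplete = wide.index[wide.isna().any(axis=1)].tolist()
    if incomplete:
        if not complete_cases:
            raise ValueError(
                f"populations with missing trait values: {incomplete}"
            )
        logger.info(
            "study %s: dropped %d incomplete population(s): %s",
            studies[0], len(incomplete), incomplete,
        )
        wide = wide.dropna()
    if len(wide) < 3:
        raise ValueError(
            f"study {studies[0]}: need >=3 complete populations, have {len(wide)}"
        )
    log_means = np.log(wide.to_numpy(dtype=float))
    cov = np.cov(log_means, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return DMatrix(
        trait_labels=tuple(str(t) for t in wide.columns),
        values=(cov + cov.T) / 2.0,
        n_pops=len(wide),
        study_id=str(studies[0]),
    )


def divergence_vector(
    focal_means,
    target_means,
    trait_labels,
    focal_population: str = "focal",
    target_population: str = "target",
) -> DivergenceVectorRecord:
    """Log-scale divergence vector from a focal to a target population."""
    focal = np.asarray(focal_means, dtype=float)
    target = np.asarray(target_means, dtype=float)
    if focal.shape != target.shape or focal.size != len(trait_labels):
        raise ValueError("mismatched trait sets between populations")
    if np.any(focal <= 0) or np.any(target <= 0):
        raise ValueError("population means must be strictly positive")
    delta = np.log(target) - np.log(focal)
    magnitude = float(np.linalg.norm(delta))
    unit = (
        DirectionVector(tuple(trait_labels), delta / magnitude)
        if magnitude > 0
        else None
    )
    return DivergenceVectorRecord(
        focal_population=focal_population,
        target_population=target_population,
        trait_labels=tuple(trait_labels),
        delta=delta,
        magnitude=magnitude,
        unit_direction=unit,
    )


def median_divergence_summary(
    d_P_values,
    group_labels,
    bootstrap_reps: int = 2000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-group median proportional divergence with bootstrap SEs.

    The SE of each median is the standard deviation of medians across
    seeded nonparametric bootstrap resamples; NaN for singleton groups.
    """
    df = pd.DataFrame({"d_P": np.asarray(d_P_values, dtype=float),
                       "group": list(group_labels)})
    if df.empty:
        raise ValueError("no divergence estimates supplied")
    rng = np.random.default_rng(seed)
    rows = []
    for group, sub in df.groupby("group", sort=True):
        x = sub["d_P"].to_numpy()
        if x.size == 1:
            rows.append({"group": group, "median_d_P": float(x[0]),
                         "se": float("nan"), "n": 1})
            continue
        boots = np.median(
            rng.choice(x, size=(bootstrap_reps, x.size), replace=True), axis=1
        )
        rows.append({
            "group": group,
            "median_d_P": float(np.median(x)),
            "se": float(np.std(boots, ddof=1)),
            "n": int(x.size),
        })
    return pd.DataFrame(rows)
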