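"""Per-case multivariate evolvability-divergence regressions.

A "case" pairs a G-matrix with a D-matrix (and optionally a P-matrix)
over the same trait set.  Evolvability e(v) and divergence d(v) are
projected onto a set of focal directions — the original trait axes or the
eigenvectors of G, D or P — and the log-log regression of d(v) on e(v)
estimates the scaling exponent of divergence with evolvability.

Sampling error in the matrices biases these slopes in opposite ways:
error in D inflates the spread of d(v) along D's own eigenvectors
(upward slope bias), while error in G inflates the spread of e(v) along
G's eigenvectors (classical regression-dilution, downward bias).
P-directions sidestep both because estimation error in P is independent
of G and D.  Slope standard errors come from regressions on randomly
paired Monte-Carlo draws of G and D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gmatrix import (
    DirectionVector,
    DMatrix,
    GMatrix,
    PMatrix,
    conditional_evolvability_along,
    eigen_directions,
    evolvability_along,
    project_divergence,
)
from .lmm import RandomTerm, WeightedLMM

logger = logging.getLogger(__name__)

__all__ = [
    "CaseStudy",
    "CaseSlopeResult",
    "direction_set",
    "case_regression",
    "resample_G",
    "resample_D",
    "slope_se",
    "meta_slope",
]

DIRECTION_SETS = ("original", "G_eigen", "D_eigen", "P_eigen")


@dataclass(frozen=True)
class CaseStudy:
    """Paired G- and D-matrices (optional P) over >=3 shared traits."""

    case_id: str
    G: GMatrix
    D: DMatrix
    P: PMatrix | None = None
    species: str = ""
    d_matrix_id: str = ""
    n_pops: int = 0

    def __post_init__(self):
        if self.G.trait_labels != self.D.trait_labels:
            raise ValueError(
                f"case {self.case_id}: G and D trait sets differ "
                f"({self.G.trait_labels} vs {self.D.trait_labels})"
            )
        if self.P is not None and self.P.trait_labels != self.G.trait_labels:
            raise ValueError(f"case {self.case_id}: P trait set differs from G")
        if self.G.k < 3:
            raise ValueError(
                f"case {self.case_id}: multivariate analysis needs >=3 traits, "
                f"has {self.G.k}"
            )


@dataclass(frozen=True)
class CaseSlopeResult:
    """Log-log regression of divergence on evolvability for one case."""

    case_id: str
    direction_set: str
    slope: float
    intercept: float
    r2: float
    n_directions: int
    n_dropped: int = 0
    slope_se: float | None = None
    conditional: bool = False


def direction_set(case: CaseStudy, which: str) -> list[DirectionVector]:
    """Focal directions: trait axes or eigenvectors of G, D or P.

    With ``which="original"`` the directions are the standard basis
    vectors, so e(v) and d(v) reduce to the matrix diagonals and the
    regression is equivalent to a univariate per-trait analysis.
    """
    labels = case.G.trait_labels
    if which == "original":
        return [
            DirectionVector(labels, np.eye(case.G.k)[i]) for i in range(case.G.k)
        ]
    if which == "G_eigen":
        return [v for _, v in eigen_directions(case.G)]
    if which == "D_eigen":
        return [v for _, v in eigen_directions(case.D)]
    if which == "P_eigen":
        if case.P is None:
            raise ValueError(f"case {case.case_id}: no P-matrix available")
        return [v for _, v in eigen_directions(case.P)]
    raise ValueError(f"unknown direction set {which!r}; choose from {DIRECTION_SETS}")


def _loglog_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS of ln y on ln x -> (slope, intercept, r2)."""
    lx, ly = np.log(x), np.log(y)
    vx = np.var(lx)
    if vx == 0:
        raise ValueError("no variation in evolvability across directions")
    slope = float(np.cov(lx, ly, ddof=0)[0, 1] / vx)
    intercept = float(np.mean(ly) - slope * np.mean(lx))
    vy = np.var(ly)
    r2 = 0.0 if vy == 0 else float(min(1.0, (slope**2) * vx / vy))
    return slope, intercept, r2


def _project_case(
    G: np.ndarray, D: np.ndarray, dirs: np.ndarray, conditional: bool
) -> tuple[np.ndarray, np.ndarray]:
    """(e or c, d) along each direction (rows of ``dirs``)."""
    d_vals = np.einsum("ij,jk,ik->i", dirs, D, dirs)
    if conditional:
        e_vals = 1.0 / np.einsum("ij,jk,ik->i", dirs, np.linalg.inv(G), dirs)
    else:
        e_vals = np.einsum("ij,jk,ik->i", dirs, G, dirs)
    return e_vals, d_vals


def case_regression(
    case: CaseStudy, which: str = "original", conditional: bool = False
) -> CaseSlopeResult:
    """OLS of ln d(v) on ln e(v) over a direction set.

    With ``conditional=True`` the predictor is the conditional
    evolvability c(v) instead of e(v).  Directions with non-positive
    projected variance (possible for indefinite sample matrices) are
    dropped with a logged count.
    """
    dirs = np.vstack([v.values for v in direction_set(case, which)])
    e_vals, d_vals = _project_case(case.G.values, case.D.values, dirs, conditional)
    ok = (e_vals > 0) & (d_vals > 0)
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        logger.warning(
            "case %s/%s: dropped %d direction(s) with non-positive projection",
            case.case_id, which, n_dropped,
        )
    if ok.sum() < 2:
        raise ValueError(
            f"case {case.case_id}/{which}: fewer than 2 usable directions"
        )
    slope, intercept, r2 = _loglog_ols(e_vals[ok], d_vals[ok])
    return CaseSlopeResult(
        case_id=case.case_id,
        direction_set=which,
        slope=slope,
        intercept=intercept,
        r2=r2,
        n_directions=case.G.k,
        n_dropped=n_dropped,
        conditional=conditional,
    )


def resample_G(
    G: GMatrix, iters: int = 1000, seed: int | None = 0, n_samples: int | None = None
) -> np.ndarray:
    """Monte-Carlo sampling distribution of G under its breeding design.

    Each iteration draws n_families observations from MVN(1, G) — means
    are 1 after mean-scaling — and returns the sample covariance, giving
    ``iters`` matrices of shape (k, k).  The draws reproduce the sampling
    noise of the original design, including the characteristic upward
    bias of the leading eigenvalue.
    """
    n = n_samples if n_samples is not None else G.n_families
    if n < 2:
        raise ValueError("need n_families >= 2 to resample G")
    if n < G.k + 1:
        logger.warning(
            "n_families=%d < k+1=%d: resampled G-matrices will be singular",
            n, G.k + 1,
        )
    eigvals = np.linalg.eigvalsh(G.values)
    if eigvals[0] < -1e-10 * max(eigvals[-1], 1e-300):
        raise ValueError("G must be positive semidefinite to resample")
    rng = np.random.default_rng(seed)
    root = np.linalg.cholesky(
        G.values + 1e-14 * np.eye(G.k) * max(eigvals[-1], 1e-30)
    )
    X = rng.standard_normal((iters, n, G.k)) @ root.T + 1.0
    Xc = X - X.mean(axis=1, keepdims=True)
    return np.einsum("rni,rnj->rij", Xc, Xc) / (n - 1)


def resample_D(
    D: DMatrix, iters: int = 1000, seed: int | None = 0, df: int | None = None
) -> np.ndarray:
    """Approximate sampling distribution of a point-estimate D-matrix.

    Draws follow a Wishart with effective degrees of freedom
    df = n_pops - 1 and scale D/df, the sampling distribution of a sample
    covariance from df+1 multivariate-normal populations.
    """
    df = df if df is not None else D.n_pops - 1
    if df < D.k:
        raise ValueError(
            f"Wishart degrees of freedom ({df}) below matrix dimension ({D.k})"
        )
    rng = np.random.default_rng(seed)
    eigvals = np.linalg.eigvalsh(D.values)
    if eigvals[0] <= 0:
        raise ValueError("D must be positive definite for Wishart resampling")
    root = np.linalg.cholesky(D.values / df)
    # Bartlett decomposition for speed and seeded determinism
    out = np.empty((iters, D.k, D.k))
    k = D.k
    for r in range(iters):
        A = np.zeros((k, k))
        A[np.tril_indices(k, -1)] = rng.standard_normal(k * (k - 1) // 2)
        A[np.diag_indices(k)] = np.sqrt(
            rng.chisquare(df - np.arange(k))
        )
        L = root @ A
        out[r] = L @ L.T
    return out


def slope_se(
    case: CaseStudy,
    which: str,
    G_draws: np.ndarray,
    D_draws: np.ndarray,
    pairings: int = 1000,
    seed: int | None = 0,
    conditional: bool = False,
    recompute_directions: bool = True,
) -> float:
    """Monte-Carlo SE of a case slope from randomly paired (G, D) draws.

    For each pairing one G draw and one D draw are combined; focal
    directions are recomputed from the drawn matrix that defines the
    direction set (G_eigen from the drawn G, D_eigen from the drawn D;
    original axes and P-directions are fixed).  The SE is the SD of the
    resulting slopes.  Pairings yielding fewer than two usable directions
    are dropped; more than 50% degenerate pairings is an error.
    """
    if len(G_draws) < 100 or len(D_draws) < 100:
        raise ValueError("need >=100 draws of each matrix for a stable SE")
    rng = np.random.default_rng(seed)
    gi = rng.integers(0, len(G_draws), size=pairings)
    di = rng.integers(0, len(D_draws), size=pairings)
    if not recompute_directions or which in ("original", "P_eigen"):
        fixed_dirs = np.vstack([v.values for v in direction_set(case, which)])
    else:
        fixed_dirs = None
    slopes = []
    for g_idx, d_idx in zip(gi, di):
        G, D = G_draws[g_idx], D_draws[d_idx]
        if fixed_dirs is not None:
            dirs = fixed_dirs
        else:
            M = G if which == "G_eigen" else D
            _, vecs = np.linalg.eigh((M + M.T) / 2.0)
            dirs = vecs.T
        try:
            e_vals, d_vals = _project_case(G, D, dirs, conditional)
        except np.linalg.LinAlgError:
            continue
        ok = (e_vals > 0) & (d_vals > 0)
        if ok.sum() < 2 or np.var(np.log(e_vals[ok])) == 0:
            continue
        s, _, _ = _loglog_ols(e_vals[ok], d_vals[ok])
        slopes.append(s)
    if len(slopes) < pairings / 2:
        raise ValueError(
            f"case {case.case_id}/{which}: {pairings - len(slopes)} of "
            f"{pairings} pairings degenerate"
        )
    return float(np.std(slopes, ddof=1))


def meta_slope(results: pd.DataFrame) -> pd.DataFrame:
    """Error-weighed grand slope per direction set across cases.

    ``results`` needs columns case_id, direction_set, slope, slope_se, r2,
    species, d_matrix_id.  Each direction set is summarized by a weighted
    mixed model (weights = inverse squared slope SE; random intercepts for
    species and D-matrix identity when each has >=2 levels), the grand
    slope with its SE, and the median r2.
    """
    rows = []
    for which, sub in results.groupby("direction_set", sort=True):
        sub = sub.reset_index(drop=True)
        if len(sub) < 2:
            raise ValueError(f"direction set {which}: need >=2 cases for a meta-slope")
        se = sub["slope_se"].to_numpy(dtype=float)
        if np.any(~np.isfinite(se)) or np.any(se <= 0):
            logger.warning(
                "direction set %s: missing slope SEs, falling back to equal weights",
                which,
            )
            weights = np.ones(len(sub))
        else:
            weights = 1.0 / se**2
        terms = []
        for g in ("species", "d_matrix_id"):
            if sub[g].nunique() >= 2:
                terms.append(RandomTerm(name=f"intercept|{g}",
                                        groups=sub[g].to_numpy()))
        model = WeightedLMM(
            y=sub["slope"].to_numpy(dtype=float),
            X=np.ones((len(sub), 1)),
            weights=weights,
            random_terms=terms,
            fe_names=["grand_slope"],
        )
        fit = model.fit(method="REML" if terms else "ML")
        est, se_est = fit.coef("grand_slope")
        rows.append({
            "direction_set": which,
            "grand_slope": est,
            "grand_slope_se": se_est,
            "median_r2": float(sub["r2"].median()),
            "n_cases": len(sub),
        })
    return pd.DataFrame(rows)
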