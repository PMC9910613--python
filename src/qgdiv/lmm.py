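"""Weighted Gaussian linear mixed models by profiled maximum likelihood.

The model is

    y = X beta + sum_q Z_q b_q + eps,
    b_q ~ N(0, psi_q I),   eps_i ~ N(0, sigma^2 / w_i),

with independent scalar-variance random terms (intercepts or slopes per
grouping factor) and known positive observation weights w_i entering as
inverse scaling of the residual variance — the meta-analytic convention
where w_i is the inverse sampling variance of observation i (up to the
common scale sigma^2).

Estimation profiles beta and sigma^2 out of the (RE)ML likelihood and
optimizes over the log variance ratios theta_q = psi_q / sigma^2.  All
linear algebra runs through the Woodbury identity on the q x q scale
(q = total number of random-effect levels), so fits with a few hundred
groups take milliseconds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import solve_triangular

logger = logging.getLogger(__name__)

__all__ = ["RandomTerm", "LMMFit", "WeightedLMM"]

_LOG_2PI = math.log(2.0 * math.pi)
_BOUNDARY_LOG_THETA = -12.0  # below this a variance ratio is effectively zero


@dataclass(frozen=True)
class RandomTerm:
    """One scalar-variance random term.

    ``groups`` assigns each observation to a level; ``covariate`` is the
    within-group regressor (None for a random intercept).
    """

    name: str
    groups: np.ndarray
    covariate: np.ndarray | None = None


@dataclass
class LMMFit:
    """A fitted weighted linear mixed model."""

    fe_names: list[str]
    fe_estimates: np.ndarray
    fe_se: np.ndarray
    fe_cov: np.ndarray
    random_variances: dict[str, float]
    sigma2: float
    log_likelihood: float
    aic: float
    n_obs: int
    n_params: int
    method: str  # "ML" or "REML"
    converged: bool
    boundary: bool = False
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    # retained design pieces (for r2 computation and predictions)
    _X: np.ndarray | None = field(default=None, repr=False)
    _weights: np.ndarray | None = field(default=None, repr=False)
    _re_mean_sq: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def fixed_effects(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.fe_estimates, "se": self.fe_se}, index=self.fe_names
        )

    def coef(self, name: str) -> tuple[float, float]:
        i = self.fe_names.index(name)
        return float(self.fe_estimates[i]), float(self.fe_se[i])


def _build_Z(terms: list[RandomTerm], n: int):
    """Dense random-effects design, with per-column term index."""
    blocks, col_term, level_names = [], [], []
    for t_idx, term in enumerate(terms):
        groups = np.asarray(term.groups)
        if len(groups) != n:
            raise ValueError(f"random term {term.name!r}: group labels wrong length")
        levels, codes = np.unique(groups, return_inverse=True)
        if len(levels) < 2:
            raise ValueError(
                f"random term {term.name!r} needs >=2 groups, has {len(levels)}"
            )
        Zt = np.zeros((n, len(levels)))
        Zt[np.arange(n), codes] = 1.0
        if term.covariate is not None:
            cov = np.asarray(term.covariate, dtype=float)
            if len(cov) != n:
                raise ValueError(f"random term {term.name!r}: covariate wrong length")
            Zt *= cov[:, None]
        blocks.append(Zt)
        col_term.extend([t_idx] * len(levels))
        level_names.append(levels)
    return np.hstack(blocks), np.asarray(col_term), level_names


class WeightedLMM:
    """Weighted Gaussian LMM with independent scalar random terms."""

    def __init__(
        self,
        y,
        X: pd.DataFrame | np.ndarray,
        weights=None,
        random_terms: list[RandomTerm] | None = None,
        fe_names: list[str] | None = None,
    ):
        self.y = np.asarray(y, dtype=float)
        n = len(self.y)
        if isinstance(X, pd.DataFrame):
            self.fe_names = [str(c) for c in X.columns]
            self.X = X.to_numpy(dtype=float)
        else:
            self.X = np.asarray(X, dtype=float)
            self.fe_names = fe_names or [f"x{i}" for i in range(self.X.shape[1])]
        if self.X.ndim != 2 or self.X.shape[0] != n:
            raise ValueError("X must be n x p")
        self.weights = (
            np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        )
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive and finite")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            aliased = self._aliased_columns()
            raise ValueError(f"rank-deficient fixed-effects design; aliased: {aliased}")
        self.terms = random_terms or []
        if self.terms:
            self.Z, self.col_term, self._levels = _build_Z(self.terms, n)
        else:
            self.Z = np.zeros((n, 0))
            self.col_term = np.asarray([], dtype=int)
        self._precompute()

    def _aliased_columns(self) -> list[str]:
        """Names of columns linearly dependent on earlier ones (via QR)."""
        _, R = np.linalg.qr(self.X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(self.X.shape) * np.finfo(float).eps
        return [nm for nm, d in zip(self.fe_names, diag) if d < tol]

    def _precompute(self):
        w = self.weights
        Xw = self.X * w[:, None]
        self._XtWX = self.X.T @ Xw
        self._XtWy = Xw.T @ self.y
        self._ytWy = float(self.y @ (w * self.y))
        self._sum_log_w = float(np.sum(np.log(w)))
        if self.Z.shape[1]:
            Zw = self.Z * w[:, None]
            self._ZtWZ = self.Z.T @ Zw
            self._ZtWX = Zw.T @ self.X
            self._ZtWy = Zw.T @ self.y

    # ---- profiled deviance ----------------------------------------------

    def _profile(self, log_theta: np.ndarray, reml: bool):
        """Return (-2 log likelihood, beta, sigma2, XtVinvX) at theta."""
        n, p = self.X.shape
        if self.Z.shape[1]:
            theta_col = np.exp(log_theta)[self.col_term]
            s = np.sqrt(theta_col)
            A = self._ZtWZ * np.outer(s, s)
            A[np.diag_indices_from(A)] += 1.0
            try:
                L = np.linalg.cholesky(A)
            except np.linalg.LinAlgError:
                return np.inf, None, None, None
            logdet_V0 = 2.0 * float(np.sum(np.log(np.diag(L)))) - self._sum_log_w
            U = solve_triangular(
                L,
                np.column_stack([s[:, None] * self._ZtWX, s * self._ZtWy]),
                lower=True, check_finite=False,
            )
            U_X, u_y = U[:, :-1], U[:, -1]
            XtVX = self._XtWX - U_X.T @ U_X
            XtVy = self._XtWy - U_X.T @ u_y
            ytVy = self._ytWy - float(u_y @ u_y)
        else:
            logdet_V0 = -self._sum_log_w
            XtVX, XtVy, ytVy = self._XtWX, self._XtWy, self._ytWy
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return np.inf, None, None, None
        qform = ytVy - float(beta @ XtVy)
        if qform <= 0:
            qform = 1e-12
        if reml:
            sigma2 = qform / (n - p)
            sign, logdet_XtVX = np.linalg.slogdet(XtVX)
            dev = (
                (n - p) * (_LOG_2PI + math.log(sigma2))
                + logdet_V0
                + logdet_XtVX
                + (n - p)
            )
        else:
            sigma2 = qform / n
            dev = n * (_LOG_2PI + math.log(sigma2)) + logdet_V0 + n
        return dev, beta, sigma2, XtVX

    def fit(self, method: str = "ML", start_log_theta=None) -> LMMFit:
        method = method.upper()
        if method not in ("ML", "REML"):
            raise ValueError("method must be 'ML' or 'REML'")
        reml = method == "REML"
        n, p = self.X.shape
        Q = len(self.terms)
        converged = True
        if Q:
            x0 = (
                np.zeros(Q)
                if start_log_theta is None
                else np.asarray(start_log_theta, dtype=float)
            )
            obj = lambda lt: self._profile(lt, reml)[0]
            opts = {"xatol": 1e-4, "fatol": 1e-7, "maxiter": 2000}
            res = optimize.minimize(obj, x0, method="Nelder-Mead", options=opts)
            # second start guards against a poor local optimum
            res2 = optimize.minimize(
                obj, np.full(Q, -3.0), method="Nelder-Mead", options=opts
            )
            if res2.fun < res.fun:
                res = res2
            converged = bool(res.success)
            if not converged:
                logger.warning("LMM variance optimization did not converge: %s",
                               res.message)
            log_theta = res.x
        else:
            log_theta = np.asarray([])
        dev, beta, sigma2, XtVX = self._profile(log_theta, reml)
        if beta is None:
            raise np.linalg.LinAlgError("LMM profile likelihood is degenerate")
        boundary = bool(Q and np.any(log_theta < _BOUNDARY_LOG_THETA))
        if boundary:
            logger.warning(
                "variance component(s) at boundary (near zero): %s",
                [t.name for t, lt in zip(self.terms, log_theta)
                 if lt < _BOUNDARY_LOG_THETA],
            )
        fe_cov = sigma2 * np.linalg.inv(XtVX)
        loglik = -0.5 * dev
        n_params = p + Q + 1
        random_variances = {
            t.name: float(np.exp(lt) * sigma2)
            for t, lt in zip(self.terms, log_theta)
        }
        re_mean_sq = {
            t.name: float(
                np.mean(t.covariate**2) if t.covariate is not None else 1.0
            )
            for t in self.terms
        }
        return LMMFit(
            fe_names=list(self.fe_names),
            fe_estimates=beta,
            fe_se=np.sqrt(np.diag(fe_cov)),
            fe_cov=fe_cov,
            random_variances=random_variances,
            sigma2=float(sigma2),
            log_likelihood=float(loglik),
            aic=float(dev + 2 * n_params),
            n_obs=n,
            n_params=n_params,
            method=method,
            converged=converged,
            boundary=boundary,
            _X=self.X,
            _weights=self.weights,
            _re_mean_sq=re_mean_sq,
        )
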