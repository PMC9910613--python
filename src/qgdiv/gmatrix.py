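"""Algebra of mean-scaled genetic (co)variance matrices.

The central objects are the G-matrix (mean-scaled additive genetic
variances and covariances within a population), the D-matrix
(among-population covariance of ln trait means) and the P-matrix (pooled
within-population phenotypic covariances).  Because all three are expressed
on the proportional (mean- or log-) scale they can be projected onto common
unit directions in trait space:

* evolvability           e(v) = v' G v   — predicted proportional response
  to a unit-strength selection gradient along v;
* conditional evolvability  c(v) = (v' G^-1 v)^-1 — the response along v
  when all orthogonal trait combinations are held constant by selection;
* divergence             d(v) = v' D v   — realized among-population
  variance along v.

For any unit vector, 0 <= c(v) <= e(v), with equality exactly at the
eigenvectors of G.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TraitMatrix",
    "GMatrix",
    "DMatrix",
    "PMatrix",
    "DirectionVector",
    "MatrixSummary",
    "mean_scale_covariance",
    "evolvability_along",
    "conditional_evolvability_along",
    "matrix_summary",
    "eigen_directions",
    "project_divergence",
    "read_matrix_csv",
    "write_matrix_csv",
]

_SYMMETRY_RTOL = 1e-10
_NORMALIZE_WARN_TOL = 1e-8


class SingularMatrixError(np.linalg.LinAlgError):
    """G cannot be inverted reliably; conditional evolvability undefined."""


@dataclass(frozen=True)
class TraitMatrix:
    """A labeled symmetric covariance matrix over an ordered trait set."""

    trait_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "trait_labels", tuple(self.trait_labels))
        k = len(self.trait_labels)
        if k < 1:
            raise ValueError("at least one trait is required")
        if len(set(self.trait_labels)) != k:
            raise ValueError(f"trait labels are not unique: {self.trait_labels}")
        if values.shape != (k, k):
            raise ValueError(
                f"matrix shape {values.shape} does not match {k} trait labels"
            )
        scale = max(np.max(np.abs(values)), 1.0e-300)
        if np.max(np.abs(values - values.T)) > _SYMMETRY_RTOL * scale:
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(values) < 0):
            bad = [t for t, v in zip(self.trait_labels, np.diag(values)) if v < 0]
            raise ValueError(f"negative variance for trait(s) {bad}")

    @property
    def k(self) -> int:
        return len(self.trait_labels)

    def subset(self, traits: Sequence[str]) -> "TraitMatrix":
        """Restrict to (and reorder by) the given traits."""
        idx = [self.trait_labels.index(t) for t in traits]
        return replace(
            self, trait_labels=tuple(traits), values=self.values[np.ix_(idx, idx)]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.trait_labels, columns=self.trait_labels
        )


@dataclass(frozen=True)
class GMatrix(TraitMatrix):
    """Mean-scaled additive genetic (co)variance matrix.

    Entries are dimensionless: G[i, j] = cov_A(i, j) / (mean_i * mean_j),
    so the diagonal holds per-trait evolvabilities I_A = V_A / mean^2.

    Parameters
    ----------
    n_families
        Effective sample size of the breeding design that produced the
        estimate; drives the Monte-Carlo resampling of G.
    """

    n_families: int = 0
    species: str = ""
    study_id: str = ""

    def __post_init__(self):
        super().__post_init__()
        if self.n_families < 0:
            raise ValueError("n_families must be non-negative")


@dataclass(frozen=True)
class DMatrix(TraitMatrix):
    """Among-population covariance matrix of ln population trait means."""

    n_pops: int = 0
    study_id: str = ""


@dataclass(frozen=True)
class PMatrix(TraitMatrix):
    """Pooled within-population phenotypic covariance matrix (mean-scaled)."""

    study_id: str = ""


@dataclass(frozen=True)
class DirectionVector:
    """A unit direction in trait space.

    Input coefficients are normalized to unit Euclidean length; a warning
    is logged when the supplied length deviates from 1 by more than 1e-8.
    """

    trait_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "trait_labels", tuple(self.trait_labels))
        if values.ndim != 1 or values.size != len(self.trait_labels):
            raise ValueError("direction length does not match trait labels")
        norm = float(np.linalg.norm(values))
        if norm == 0.0:
            raise ValueError("zero vector has no direction")
        if abs(norm - 1.0) > _NORMALIZE_WARN_TOL:
            logger.warning(
                "direction vector had length %.6g; normalized to unit length", norm
            )
        object.__setattr__(self, "values", values / norm)


@dataclass(frozen=True)
class MatrixSummary:
    """Summary evolvabilities of a G-matrix.

    ``e_mean`` is the average evolvability over uniform random directions,
    which equals trace(G)/k; ``e_min``/``e_max`` are the smallest/largest
    eigenvalues (evolvabilities along the trailing/leading eigenvectors);
    ``c_mean`` is the Monte-Carlo average conditional evolvability over
    uniform random unit directions (None when G is singular).
    """

    e_mean: float
    c_mean: float | None
    e_min: float
    e_max: float
    eigenvalues: tuple[float, ...] = field(default_factory=tuple)


def _check_labels(a, b, what: str = "vector") -> None:
    if tuple(a.trait_labels) != tuple(b.trait_labels):
        raise ValueError(
            f"trait labels of {what} {tuple(b.trait_labels)} do not match "
            f"matrix labels {tuple(a.trait_labels)}"
        )


def mean_scale_covariance(
    raw_cov: np.ndarray,
    means: Sequence[float],
    trait_labels: Sequence[str],
    **meta,
) -> GMatrix:
    """Convert a covariance matrix in trait units^2 to the mean-scaled scale.

    out[i, j] = raw_cov[i, j] / (means[i] * means[j]).  Mean-scaling is
    undefined for traits with non-positive means (ratio-scale traits only).
    """
    means = np.asarray(means, dtype=float)
    raw_cov = np.asarray(raw_cov, dtype=float)
    for label, m in zip(trait_labels, means):
        if m <= 0:
            raise ValueError(
                f"trait {label!r} has non-positive mean {m}; mean-scaling undefined"
            )
    scaled = raw_cov / np.outer(means, means)
    return GMatrix(trait_labels=tuple(trait_labels), values=scaled, **meta)


def evolvability_along(G: GMatrix, v: DirectionVector) -> float:
    """Evolvability e(v) = v' G v along a unit direction."""
    _check_labels(G, v)
    return float(v.values @ G.values @ v.values)


def conditional_evolvability_along(
    G: GMatrix, v: DirectionVector, rcond_threshold: float = 1e-12
) -> float:
    """Conditional evolvability c(v) = (v' G^-1 v)^-1.

    Raises
    ------
    SingularMatrixError
        When the reciprocal condition number of G falls below
        ``rcond_threshold``.  The inverse is then numerically meaningless
        and a silent pseudo-inverse would bias c downward invisibly;
        reduce the trait set instead.
    """
    _check_labels(G, v)
    eigvals = np.linalg.eigvalsh(G.values)
    if eigvals[0] <= 0 or eigvals[0] / eigvals[-1] < rcond_threshold:
        raise SingularMatrixError(
            "G-matrix is singular or ill-conditioned "
            f"(rcond={eigvals[0] / eigvals[-1]:.3g}); conditional evolvability "
            "is undefined — consider reducing the trait set"
        )
    return float(1.0 / (v.values @ np.linalg.solve(G.values, v.values)))


def random_unit_vectors(k: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform random unit vectors in k dimensions (rows)."""
    x = rng.standard_normal((n, k))
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def matrix_summary(
    G: GMatrix, mc_samples: int = 10_000, seed: int | None = 0
) -> MatrixSummary:
    """Mean, minimum, maximum and mean conditional evolvability of G.

    c_mean is the seeded Monte-Carlo average of c(v) over ``mc_samples``
    uniform random unit directions; it is None (undefined) when G is
    singular, in which case the other summaries are still returned.
    """
    eigvals = np.linalg.eigvalsh(G.values)[::-1]
    e_mean = float(np.trace(G.values)) / G.k
    e_min, e_max = float(eigvals[-1]), float(eigvals[0])
    c_mean: float | None
    if eigvals[-1] <= 0 or eigvals[-1] / eigvals[0] < 1e-12:
        logger.warning("singular G-matrix: mean conditional evolvability undefined")
        c_mean = None
    else:
        rng = np.random.default_rng(seed)
        V = random_unit_vectors(G.k, mc_samples, rng)
        quad = np.einsum("ij,jk,ik->i", V, np.linalg.inv(G.values), V)
        c_mean = float(np.mean(1.0 / quad))
    return MatrixSummary(
        e_mean=e_mean,
        c_mean=c_mean,
        e_min=e_min,
        e_max=e_max,
        eigenvalues=tuple(float(x) for x in eigvals),
    )


def eigen_directions(M: TraitMatrix) -> list[tuple[float, DirectionVector]]:
    """Eigen-decomposition with descending eigenvalues and fixed signs.

    Each eigenvector's sign is chosen so that its largest-magnitude
    coefficient is positive, making outputs reproducible across LAPACK
    implementations.
    """
    eigvals, eigvecs = np.linalg.eigh(M.values)
    order = np.argsort(eigvals)[::-1]
    out = []
    for idx in order:
        vec = eigvecs[:, idx]
        if vec[np.argmax(np.abs(vec))] < 0:
            vec = -vec
        out.append(
            (float(eigvals[idx]), DirectionVector(M.trait_labels, vec))
        )
    return out


def project_divergence(D: DMatrix | TraitMatrix, v: DirectionVector) -> float:
    """Among-population divergence d(v) = v' D v along a unit direction."""
    _check_labels(D, v)
    return float(v.values @ D.values @ v.values)


def read_matrix_csv(
    path: str | Path,
    kind: type[TraitMatrix] = GMatrix,
    symmetry_tol: float = 1e-8,
    **meta,
):
    """Read a square labeled covariance matrix from CSV.

    Format: first row and first column hold the trait labels.  Matrices
    asymmetric beyond ``symmetry_tol`` (relative) are rejected; smaller
    asymmetries (e.g. from printed rounding) are symmetrized by averaging
    the upper and lower triangles, logging the largest discrepancy.
    """
    df = pd.read_csv(path, index_col=0)
    labels = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != labels:
        raise ValueError(f"{path}: row and column trait labels differ")
    values = df.to_numpy(dtype=float)
    asym = float(np.max(np.abs(values - values.T)))
    scale = max(float(np.max(np.abs(values))), 1.0)
    if asym > symmetry_tol * scale:
        raise ValueError(f"{path}: matrix asymmetric beyond tolerance ({asym:.3g})")
    if asym > 0:
        logger.info("%s: symmetrized matrix (max asymmetry %.3g)", path, asym)
        values = (values + values.T) / 2.0
    return kind(trait_labels=labels, values=values, **meta)


def write_matrix_csv(M: TraitMatrix, path: str | Path) -> None:
    M.to_dataframe().to_csv(path)
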