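"""Seeded generator of synthetic evolvability-divergence databases.

The generator emulates the hierarchical structure of a comparative
quantitative-genetics compilation — species carry G-matrices, each species
contributes divergence studies, each study holds population trait means —
with known ground truth, so that every pipeline stage can be exercised and
its estimates checked against the generating parameters.

Two divergence models are available:

* ``neutral`` — log-scale population means drawn from MVN with
  among-population covariance (t/Ne) * G.  Under drift, divergence after t
  generations is d = 2 Vm t while equilibrium evolvability is
  e = 2 Vm Ne, so d/e = t/Ne along every direction and the true
  evolvability-divergence scaling exponent is exactly 1.
* ``ou`` — an optimum-tracking model in its stationary regime: the
  among-population covariance shares its eigenvectors with G but its
  eigenvalues follow a power law lambda_i^s (s in [0.5, 1]), the scaling
  produced by weak stabilizing selection around an optimum moving as an
  Ornstein-Uhlenbeck process.  s = 1 recovers the neutral scaling.

Per-population sampling noise (phenotypic variance over the number of
individuals measured) is added on the log scale, and evolvability
estimates are perturbed by multiplicative log-normal error so the
attenuation correction has real work to do.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gmatrix import DMatrix, GMatrix, PMatrix, write_matrix_csv

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SyntheticDatabase",
    "simulate_G",
    "simulate_population_means",
    "simulate_evolvability_estimates",
    "simulate_database",
]

ENVIRONMENTS = ("greenhouse", "common_garden", "field")
MATING_SYSTEMS = ("selfing", "mixed", "outcrossing")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic evolvability-divergence world.

    Defaults describe a plant-like comparative database: per-trait
    evolvabilities around 0.5% (mean-scaled), about ten populations per
    divergence study, divergence times comparable to effective population
    sizes (t/Ne = 1, giving d/e near unity and median proportional
    divergence around 1.06), and vegetative traits with five-fold larger
    among-population variance than floral traits (proportional divergence
    ~1.13 vs ~1.06).
    """

    n_species: int = 25
    studies_per_species: int = 2
    k_traits: int = 6
    n_pops: int = 10
    n_pops_jitter: int = 3  # per-study n_pops drawn from n_pops +- jitter
    n_families: int = 50
    n_individuals_per_pop: int = 30
    mean_evolvability_scale: float = 0.005
    wishart_df: int = 12
    divergence_model: str = "neutral"  # "neutral" | "ou"
    t_over_Ne: float = 1.0
    ou_exponent: float = 0.7  # eigenvalue power-law exponent s
    study_ratio_sd: float = 0.5  # SD of log study-level t/Ne multipliers
    measurement_noise: float = 0.3  # SD of log-evolvability estimation error
    n_evolvability_estimates: int = 3
    category_effects: dict = field(
        default_factory=lambda: {"floral": 1.0, "vegetative": 5.0}
    )
    floral_fraction: float = 0.7
    heritability: float = 1.0 / 3.0  # G = h^2 * P on the mean-scaled scale
    exact_matrices: bool = True  # write true G/P or estimates with sampling noise
    seed: int = 0

    def __post_init__(self):
        if self.n_pops < 3:
            raise ValueError("n_pops must be >= 3 (D-matrix estimation)")
        if self.k_traits < 3:
            raise ValueError("k_traits must be >= 3 for multivariate analyses")
        if self.wishart_df < self.k_traits:
            raise ValueError("wishart_df must be >= k_traits")
        if self.divergence_model not in ("neutral", "ou"):
            raise ValueError("divergence_model must be 'neutral' or 'ou'")


@dataclass
class SyntheticDatabase:
    """A complete generated input bundle with its ground truth."""

    evolvability: pd.DataFrame
    population_means: pd.DataFrame
    study_metadata: pd.DataFrame
    g_matrices: dict[str, GMatrix]  # by species
    p_matrices: dict[str, PMatrix]  # by species
    true_D: dict[str, DMatrix]  # by study_id
    ground_truth: dict
    config: SimConfig | None = None

    def write(self, outdir: str | Path) -> None:
        """Serialize every pipeline input (and the ground truth) as CSV/JSON."""
        outdir = Path(outdir)
        (outdir / "matrices").mkdir(parents=True, exist_ok=True)
        self.evolvability.to_csv(outdir / "evolvability.csv", index=False)
        self.population_means.to_csv(outdir / "population_means.csv", index=False)
        self.study_metadata.to_csv(outdir / "study_metadata.csv", index=False)
        for sp, G in self.g_matrices.items():
            write_matrix_csv(G, outdir / "matrices" / f"G_{sp}.csv")
        for sp, P in self.p_matrices.items():
            write_matrix_csv(P, outdir / "matrices" / f"P_{sp}.csv")
        gt = dict(self.ground_truth)
        gt.pop("true_G", None)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(gt, fh, indent=2, default=float)
        if self.config is not None:
            with open(outdir / "config.json", "w") as fh:
                json.dump(dataclasses.asdict(self.config), fh, indent=2)


def _base_structure(k: int, rho: float = 0.3) -> np.ndarray:
    """Compound-symmetry scale matrix giving G-matrices some anisotropy."""
    return (1 - rho) * np.eye(k) + rho * np.ones((k, k))


def simulate_G(
    k: int,
    scale: float,
    df: int,
    seed: int | np.random.Generator | None = 0,
    trait_labels=None,
    **meta,
) -> GMatrix:
    """Draw a Wishart-distributed G-matrix rescaled to trace/k = scale.

    Lower ``df`` gives noisier, more anisotropic matrices; the expected
    structure is compound-symmetric with correlation 0.3.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if df < k:
        raise ValueError("Wishart df must be >= k")
    root = np.linalg.cholesky(_base_structure(k) / df)
    X = rng.standard_normal((df, k)) @ root.T
    W = X.T @ X
    W *= scale * k / np.trace(W)
    labels = tuple(trait_labels) if trait_labels else tuple(f"t{i+1}" for i in range(k))
    return GMatrix(trait_labels=labels, values=(W + W.T) / 2.0, **meta)


def _among_population_covariance(
    G: GMatrix, model: str, t_over_Ne: float, ou_exponent: float,
    category_multipliers: np.ndarray | None,
) -> np.ndarray:
    eigvals, eigvecs = np.linalg.eigh(G.values)
    eigvals = np.clip(eigvals, 1e-14, None)
    if model == "neutral":
        omega = t_over_Ne * G.values
    else:
        lam = eigvals**ou_exponent
        lam *= t_over_Ne * eigvals.mean() / lam.mean()
        omega = eigvecs @ np.diag(lam) @ eigvecs.T
    if category_multipliers is not None:
        s = np.sqrt(category_multipliers)
        omega = omega * np.outer(s, s)
    return (omega + omega.T) / 2.0


def simulate_population_means(
    G: GMatrix,
    n_pops: int,
    model: str = "neutral",
    t_over_Ne: float = 1.0,
    ou_exponent: float = 0.7,
    category_multipliers=None,
    n_individuals: int = 30,
    heritability: float = 1.0 / 3.0,
    seed: int | np.random.Generator | None = 0,
) -> tuple[pd.DataFrame, DMatrix]:
    """Draw log-normal population means with known among-population
    covariance, plus per-population sampling noise.

    Returns a per-population trait-means table (wide: one row per
    population) and the true (noise-free) D-matrix.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    k = G.k
    omega = _among_population_covariance(
        G, model, t_over_Ne, ou_exponent,
        None if category_multipliers is None
        else np.asarray(category_multipliers, dtype=float),
    )
    # eigendecomposition root works for the t/Ne = 0 degenerate case too
    eigvals, eigvecs = np.linalg.eigh(omega)
    root = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None)))
    log_means = rng.standard_normal((n_pops, k)) @ root.T
    # sampling noise: mean-scaled phenotypic variance / individuals measured
    p_diag = np.diag(G.values) / heritability
    noise_sd = np.sqrt(p_diag / n_individuals)
    log_means += rng.standard_normal((n_pops, k)) * noise_sd
    means = pd.DataFrame(
        np.exp(log_means),
        columns=list(G.trait_labels),
        index=[f"p{i+1}" for i in range(n_pops)],
    )
    means.index.name = "population_id"
    true_D = DMatrix(trait_labels=G.trait_labels, values=omega, n_pops=n_pops)
    return means, true_D


def simulate_evolvability_estimates(
    G: GMatrix,
    noise_sd: float = 0.3,
    n_estimates: int = 3,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Repeated noisy evolvability estimates per trait.

    Estimates are log-normal perturbations of the true diagonal
    evolvabilities: e_hat = e * exp(N(0, noise_sd^2)).  The variance among
    repeated log estimates identifies the estimation-error variance that
    the attenuation correction removes downstream.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    rows = []
    for i, trait in enumerate(G.trait_labels):
        true_e = G.values[i, i]
        noise = rng.standard_normal(n_estimates) * noise_sd
        for j in range(n_estimates):
            rows.append({
                "species": G.species,
                "trait": trait,
                "estimate_id": j + 1,
                "evolvability": true_e * np.exp(noise[j]),
            })
    return pd.DataFrame(rows)


def _estimate_matrix(true_values: np.ndarray, n: int, rng) -> np.ndarray:
    """Sample covariance of n MVN(1, true) draws (matrix estimation noise)."""
    root = np.linalg.cholesky(true_values + 1e-14 * np.eye(len(true_values)))
    X = rng.standard_normal((n, len(true_values))) @ root.T
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc / (n - 1)


def simulate_database(config: SimConfig) -> SyntheticDatabase:
    """Generate a complete multi-species database with ground truth.

    Study-level divergence scale varies log-normally around the configured
    t/Ne (SD ``study_ratio_sd`` on the log scale), and the maximum
    geographic distance between a study's populations is generated to
    increase with that scale, making distance an informative covariate.
    With ``exact_matrices=False`` the stored G- and P-matrices are
    re-estimated from finite samples (n_families and pooled individuals),
    reproducing the eigenvalue biases of real matrix estimates.
    """
    rng = np.random.default_rng(config.seed)
    k = config.k_traits
    n_floral = max(1, min(k - 1, round(config.floral_fraction * k)))
    categories = ["floral"] * n_floral + ["vegetative"] * (k - n_floral)
    cat_mult = np.asarray(
        [config.category_effects.get(c, 1.0) for c in categories], dtype=float
    )

    evol_rows, mean_rows, meta_rows = [], [], []
    g_matrices, p_matrices, true_D = {}, {}, {}
    true_e, study_ratios = {}, {}

    for si in range(config.n_species):
        species = f"sp{si+1:02d}"
        mating = MATING_SYSTEMS[si % len(MATING_SYSTEMS)]
        G_true = simulate_G(
            k,
            config.mean_evolvability_scale,
            config.wishart_df,
            rng,
            species=species,
            study_id=f"{species}_G",
            n_families=config.n_families,
        )
        P_true_values = G_true.values / config.heritability
        if config.exact_matrices:
            G_store, P_store = G_true.values, P_true_values
        else:
            G_store = _estimate_matrix(G_true.values, config.n_families, rng)
            P_store = _estimate_matrix(
                P_true_values, config.n_individuals_per_pop * config.n_pops, rng
            )
        g_matrices[species] = GMatrix(
            trait_labels=G_true.trait_labels,
            values=G_store,
            n_families=config.n_families,
            species=species,
            study_id=f"{species}_G",
        )
        p_matrices[species] = PMatrix(
            trait_labels=G_true.trait_labels,
            values=P_store,
            study_id=f"{species}_P",
        )
        for i, trait in enumerate(G_true.trait_labels):
            true_e[(species, trait)] = float(G_true.values[i, i])

        est = simulate_evolvability_estimates(
            G_true, config.measurement_noise, config.n_evolvability_estimates, rng
        )
        evol_rows.append(est.assign(
            trait_category=[categories[list(G_true.trait_labels).index(t)]
                            for t in est["trait"]]
        ))

        for sj in range(config.studies_per_species):
            study_id = f"{species}_s{sj+1}"
            environment = ENVIRONMENTS[(si + sj) % len(ENVIRONMENTS)]
            # log-normal study multiplier, mean-centered so that the
            # expected study-level divergence scale is exactly t/Ne
            ratio = config.t_over_Ne * float(
                np.exp(rng.standard_normal() * config.study_ratio_sd
                       - config.study_ratio_sd**2 / 2.0)
            )
            study_ratios[study_id] = ratio
            n_pops = int(rng.integers(
                max(3, config.n_pops - config.n_pops_jitter),
                config.n_pops + config.n_pops_jitter + 1,
            ))
            means, D = simulate_population_means(
                G_true,
                n_pops,
                model=config.divergence_model,
                t_over_Ne=ratio,
                ou_exponent=config.ou_exponent,
                category_multipliers=cat_mult,
                n_individuals=config.n_individuals_per_pop,
                heritability=config.heritability,
                seed=rng,
            )
            true_D[study_id] = dataclasses.replace(D, study_id=study_id)
            # geography: spread scales with sqrt of the divergence ratio
            lat0 = float(rng.uniform(35, 65))
            lon0 = float(rng.uniform(-10, 30))
            spread = 2.0 * np.sqrt(ratio / config.t_over_Ne) if config.t_over_Ne else 1.0
            lats = lat0 + rng.standard_normal(n_pops) * spread
            lons = lon0 + rng.standard_normal(n_pops) * spread
            for pi, (pop, row) in enumerate(means.iterrows()):
                for trait, value in row.items():
                    mean_rows.append({
                        "species": species,
                        "study_id": study_id,
                        "population_id": f"{study_id}_{pop}",
                        "trait": trait,
                        "mean": float(value),
                        "environment": environment,
                        "lat": float(lats[pi]),
                        "lon": float(lons[pi]),
                    })
            meta_rows.append({
                "study_id": study_id,
                "species": species,
                "environment": environment,
                "n_pops": n_pops,
                "n_families": config.n_families,
                "mating_system": mating,
                "focal_population": f"{study_id}_p1",
                "max_dist_km": float("nan"),  # derived from coordinates
            })

    evolvability = pd.concat(evol_rows, ignore_index=True)
    population_means = pd.DataFrame(mean_rows)
    study_metadata = pd.DataFrame(meta_rows)

    diag_mult = {c: config.category_effects.get(c, 1.0) for c in set(categories)}
    ground_truth = {
        "true_slope": 1.0 if config.divergence_model == "neutral"
        else config.ou_exponent,
        "t_over_Ne": config.t_over_Ne,
        "study_t_over_Ne": study_ratios,
        "category_multipliers": diag_mult,
        "trait_categories": dict(zip([f"t{i+1}" for i in range(k)], categories)),
        "V_me_log": config.measurement_noise**2 / config.n_evolvability_estimates,
        "true_evolvability": {f"{sp}:{tr}": e for (sp, tr), e in true_e.items()},
    }
    return SyntheticDatabase(
        evolvability=evolvability,
        population_means=population_means,
        study_metadata=study_metadata,
        g_matrices=g_matrices,
        p_matrices=p_matrices,
        true_D=true_D,
        ground_truth=ground_truth,
        config=config,
    )
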