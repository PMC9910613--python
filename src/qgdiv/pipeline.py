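"""End-to-end analyses over an evolvability-divergence database.

A database bundles (i) a table of per-trait evolvability estimates with
species/trait-category labels, (ii) long-format population trait means per
divergence study, (iii) study metadata (environment, mating system,
geography) and (iv) per-species G- (and optionally P-) matrices.  The
:class:`~qgdiv.simulate.SyntheticDatabase` produced by the generator has
exactly this shape; :func:`load_database` reads the same bundle from CSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import divergence as dv
from . import divergence_vectors as dvec
from . import meta_regression as mr
from . import multivariate as mv
from .gmatrix import GMatrix, PMatrix, matrix_summary, read_matrix_csv

logger = logging.getLogger(__name__)

__all__ = [
    "Database",
    "load_database",
    "classify_mating_system",
    "max_great_circle_km",
    "build_meta_dataset",
    "run_patterns",
    "run_univariate",
    "run_multivariate",
    "run_divergence_vectors",
    "compute_de_ratio",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class Database:
    """Pipeline input bundle (see module docstring)."""

    evolvability: pd.DataFrame
    population_means: pd.DataFrame
    study_metadata: pd.DataFrame
    g_matrices: dict[str, GMatrix] = field(default_factory=dict)
    p_matrices: dict[str, PMatrix] = field(default_factory=dict)

    def __post_init__(self):
        dv.validate_population_means(self.population_means)


def load_database(indir: str | Path) -> Database:
    """Read a database bundle written by ``SyntheticDatabase.write`` (or
    assembled by hand in the same schema)."""
    indir = Path(indir)
    evol = pd.read_csv(indir / "evolvability.csv")
    means = pd.read_csv(indir / "population_means.csv")
    meta = pd.read_csv(indir / "study_metadata.csv")
    g_matrices, p_matrices = {}, {}
    mat_dir = indir / "matrices"
    if mat_dir.is_dir():
        for path in sorted(mat_dir.glob("G_*.csv")):
            species = path.stem[2:]
            n_fam = 0
            if "n_families" in meta.columns:
                sub = meta.loc[meta["species"] == species, "n_families"]
                n_fam = int(sub.iloc[0]) if len(sub) else 0
            g_matrices[species] = read_matrix_csv(
                path, GMatrix, species=species, n_families=n_fam
            )
        for path in sorted(mat_dir.glob("P_*.csv")):
            p_matrices[path.stem[2:]] = read_matrix_csv(path, PMatrix)
    return Database(
        evolvability=evol,
        population_means=means,
        study_metadata=meta,
        g_matrices=g_matrices,
        p_matrices=p_matrices,
    )


def classify_mating_system(outcrossing_rate: float) -> str:
    """Mating-system class from the outcrossing rate: < 0.2 selfing,
    0.2-0.8 mixed, > 0.8 outcrossing."""
    if not 0 <= outcrossing_rate <= 1:
        raise ValueError("outcrossing rate must be in [0, 1]")
    if outcrossing_rate < 0.2:
        return "selfing"
    if outcrossing_rate > 0.8:
        return "outcrossing"
    return "mixed"


def max_great_circle_km(lats, lons) -> float:
    """Maximum pairwise great-circle distance (haversine) in km."""
    lat = np.radians(np.asarray(lats, dtype=float))
    lon = np.radians(np.asarray(lons, dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2.0) ** 2
    )
    return float(np.max(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))))


def _study_distances(db: Database) -> pd.Series:
    """Per-study maximum distance: great-circle from coordinates when
    present, otherwise the metadata column max_dist_km."""
    out = {}
    meta = db.study_metadata.set_index("study_id")
    for study, sub in db.population_means.groupby("study_id"):
        pops = sub.drop_duplicates("population_id")
        if {"lat", "lon"} <= set(pops.columns) and pops[["lat", "lon"]].notna().all().all():
            out[study] = max_great_circle_km(pops["lat"], pops["lon"])
        elif "max_dist_km" in meta.columns and np.isfinite(
            meta.loc[study, "max_dist_km"]
        ):
            out[study] = float(meta.loc[study, "max_dist_km"])
        else:
            out[study] = float("nan")
    return pd.Series(out, name="max_dist_km")


def divergence_table(db: Database) -> pd.DataFrame:
    """Per (study, trait) divergence estimates d, sigma2_m and d_P."""
    rows = []
    for (study, trait), sub in db.population_means.groupby(["study_id", "trait"]):
        if len(sub) < 2:
            continue
        est = dv.divergence_estimate(str(trait), sub["mean"].to_numpy())
        rows.append({
            "study_id": study,
            "species": sub["species"].iloc[0],
            "trait": trait,
            "d": est.d,
            "n_pop": est.n_pop,
            "sigma2_m": est.sigma2_m,
            "d_P": est.d_P,
        })
    return pd.DataFrame(rows)


def build_meta_dataset(
    db: Database,
    weighting: str = "log",  # "log": 1/(2/(n+2)) on ln d; "raw": 1/sigma2_m(d)
    missing_distance: str = "drop",  # "drop" | "median"
) -> mr.MetaDataset:
    """Assemble the univariate meta-regression dataset.

    Each row pairs one study-trait divergence estimate (response ln d)
    with the mean evolvability estimate for that species-trait (predictor
    ln e).  Weights are inverse sampling variances — by default of ln(d),
    which by the delta method is 2/(n+2).  Covariates ln(npop) and
    ln(max distance) are attached and mean-centered.
    """
    div = divergence_table(db)
    div = div[div["d"] > 0]
    e_mean = (
        db.evolvability.groupby(["species", "trait"])["evolvability"]
        .mean()
        .rename("e")
        .reset_index()
    )
    data = div.merge(e_mean, on=["species", "trait"], how="inner")
    cat_cols = [c for c in ("trait_category",) if c in db.evolvability.columns]
    if cat_cols:
        cats = db.evolvability.drop_duplicates(["species", "trait"])[
            ["species", "trait"] + cat_cols
        ]
        data = data.merge(cats, on=["species", "trait"], how="left")
    meta_cols = [
        c for c in ("mating_system", "environment") if c in db.study_metadata.columns
    ]
    data = data.merge(
        db.study_metadata[["study_id"] + meta_cols], on="study_id", how="left"
    )
    dist = _study_distances(db)
    data["max_dist_km"] = data["study_id"].map(dist)
    n_missing = int((~np.isfinite(data["max_dist_km"])).sum()
                    + (data["max_dist_km"] <= 0).sum())
    if n_missing:
        if missing_distance == "median":
            med = float(data.loc[data["max_dist_km"] > 0, "max_dist_km"].median())
            logger.warning("imputed %d missing distances with median %.1f km",
                           n_missing, med)
            data.loc[~(data["max_dist_km"] > 0), "max_dist_km"] = med
        else:
            logger.warning("dropped %d rows lacking a usable distance", n_missing)
            data = data[data["max_dist_km"] > 0]
    data = data[data["e"] > 0].copy()
    data["log_e"] = np.log(data["e"])
    data["log_d"] = np.log(data["d"])
    data["log_npop"] = np.log(data["n_pop"])
    data["log_dist"] = np.log(data["max_dist_km"])
    if weighting == "log":
        data["weight"] = 1.0 / (2.0 / (data["n_pop"] + 2.0))
    elif weighting == "raw":
        data["weight"] = 1.0 / data["sigma2_m"]
    else:
        raise ValueError("weighting must be 'log' or 'raw'")
    dataset = mr.MetaDataset(data=data.reset_index(drop=True))
    return dataset.center_covariates()


def run_patterns(
    db: Database,
    groupings=("trait_category", "mating_system", "environment"),
    bootstrap_reps: int = 2000,
    seed: int | None = 0,
) -> dict[str, pd.DataFrame]:
    """Median proportional divergence d_P per group with bootstrap SEs."""
    div = divergence_table(db)
    cats = db.evolvability.drop_duplicates(["species", "trait"])
    if "trait_category" in cats.columns:
        div = div.merge(
            cats[["species", "trait", "trait_category"]],
            on=["species", "trait"], how="left",
        )
    div = div.merge(
        db.study_metadata[
            ["study_id"]
            + [c for c in ("mating_system", "environment")
               if c in db.study_metadata.columns]
        ],
        on="study_id", how="left",
    )
    out = {}
    for grouping in groupings:
        if grouping not in div.columns:
            continue
        sub = div.dropna(subset=[grouping])
        n_excluded = len(div) - len(sub)
        if n_excluded:
            logger.warning("%s: excluded %d rows without labels",
                           grouping, n_excluded)
        out[grouping] = dv.median_divergence_summary(
            sub["d_P"], sub[grouping], bootstrap_reps=bootstrap_reps, seed=seed
        )
    return out


def run_univariate(
    db: Database,
    moderators=("trait_category", "mating_system", "environment"),
    weighting: str = "log",
    missing_distance: str = "drop",
) -> dict:
    """Baseline weighted random-slope meta-regression plus moderator models.

    Returns the baseline ML fit, the attenuation-corrected overall slope
    with reliability, a dAIC table for slope-heterogeneity moderators, and
    the assembled dataset.
    """
    dataset = build_meta_dataset(db, weighting=weighting,
                                 missing_distance=missing_distance)
    baseline = mr.fit_weighted_lmm(dataset, method="ML")
    raw_slope, raw_se = baseline.coef("log_e")
    V_me, V, reliability = mr.estimate_reliability(
        db.evolvability,
        predictor=dataset.data["log_e"].to_numpy(),
    )
    if math.isnan(reliability):
        logger.warning("V_me >= V: attenuation correction unavailable")
        corrected, corrected_se = float("nan"), float("nan")
    else:
        corrected, reliability = mr.attenuation_correct(raw_slope, V_me, V)
        # delta-method SE: raw-slope noise scaled by 1/reliability plus the
        # contribution of the estimated reliability itself
        var_rel = mr.reliability_variance(db.evolvability, V, V_me)
        corrected_se = math.sqrt(
            (raw_se / reliability) ** 2
            + raw_slope**2 * var_rel / reliability**4
        )
    mod_rows = []
    for moderator in moderators:
        if moderator not in dataset.data.columns:
            continue
        if dataset.data[moderator].nunique() < 2:
            continue
        fit = mr.fit_weighted_lmm(dataset, moderator=moderator, method="ML")
        delta, label = mr.compare_aic(baseline, fit)
        mod_rows.append({
            "moderator": moderator,
            "delta_aic": delta,
            "support": label,
            "converged": fit.converged,
        })
    return {
        "dataset": dataset,
        "baseline": baseline,
        "raw_slope": raw_slope,
        "raw_slope_se": raw_se,
        "corrected_slope": corrected,
        "corrected_slope_se": corrected_se,
        "reliability": reliability,
        "V_me": V_me,
        "V": V,
        "moderators": pd.DataFrame(mod_rows),
        "r2_marginal": baseline.r2_marginal,
        "r2_conditional": baseline.r2_conditional,
        "random_slope_sd": math.sqrt(
            baseline.random_variances.get("log_e|study_id", 0.0)
        ),
    }


def build_cases(db: Database) -> list[mv.CaseStudy]:
    """One case per divergence study whose species has a G-matrix with >=3
    traits present in the study's population means."""
    cases = []
    for study, sub in db.population_means.groupby("study_id"):
        species = sub["species"].iloc[0]
        G = db.g_matrices.get(species)
        if G is None:
            continue
        traits = [t for t in G.trait_labels if t in set(sub["trait"])]
        if len(traits) < 3:
            logger.warning("study %s: <3 shared traits, skipped", study)
            continue
        try:
            D = dv.estimate_D_matrix(sub, trait_subset=traits)
        except ValueError as exc:
            logger.warning("study %s: %s", study, exc)
            continue
        P = db.p_matrices.get(species)
        cases.append(
            mv.CaseStudy(
                case_id=str(study),
                G=G.subset(traits) if traits != list(G.trait_labels) else G,
                D=D,
                P=P.subset(traits) if P is not None else None,
                species=species,
                d_matrix_id=str(study),
                n_pops=D.n_pops,
            )
        )
    return cases


def run_multivariate(
    db: Database,
    iters: int = 1000,
    pairings: int = 1000,
    seed: int | None = 0,
    conditional: bool = False,
    compute_se: bool = True,
) -> dict:
    """Per-case evolvability-divergence slopes for every direction set,
    Monte-Carlo slope SEs, and error-weighed grand slopes."""
    cases = build_cases(db)
    if not cases:
        raise ValueError("no usable cases (paired G and D with >=3 traits)")
    rng = np.random.default_rng(seed)
    rows = []
    for case in cases:
        sets = ["original", "G_eigen", "D_eigen"] + (
            ["P_eigen"] if case.P is not None else []
        )
        case_has_draws = False
        if compute_se:
            try:
                G_draws = mv.resample_G(
                    case.G, iters=iters, seed=int(rng.integers(2**31))
                )
                D_draws = mv.resample_D(
                    case.D, iters=iters, seed=int(rng.integers(2**31))
                )
                case_has_draws = True
            except ValueError as exc:
                logger.warning("case %s: no slope SEs (%s)", case.case_id, exc)
        for which in sets:
            try:
                res = mv.case_regression(case, which, conditional=conditional)
            except ValueError as exc:
                logger.warning("case %s/%s: %s", case.case_id, which, exc)
                continue
            se = None
            if case_has_draws:
                try:
                    se = mv.slope_se(
                        case, which, G_draws, D_draws,
                        pairings=pairings, seed=int(rng.integers(2**31)),
                        conditional=conditional,
                    )
                except ValueError as exc:
                    logger.warning("case %s/%s SE: %s", case.case_id, which, exc)
            rows.append({
                "case_id": case.case_id,
                "species": case.species,
                "d_matrix_id": case.d_matrix_id,
                "direction_set": which,
                "slope": res.slope,
                "intercept": res.intercept,
                "r2": res.r2,
                "n_directions": res.n_directions,
                "n_dropped": res.n_dropped,
                "slope_se": se if se is not None else float("nan"),
            })
    case_results = pd.DataFrame(rows)
    grand = mv.meta_slope(case_results)
    return {"cases": case_results, "grand_slopes": grand, "n_cases": len(cases)}


def run_divergence_vectors(
    db: Database,
    iters: int = 1000,
    seed: int | None = 0,
    with_sampling_variances: bool = True,
) -> dict:
    """Evolvability along observed divergence vectors for every study with
    a focal population and a species G-matrix."""
    rng = np.random.default_rng(seed)
    meta = db.study_metadata.set_index("study_id")
    records = []
    for study, sub in db.population_means.groupby("study_id"):
        species = sub["species"].iloc[0]
        G = db.g_matrices.get(species)
        if G is None:
            logger.warning("study %s: no G-matrix, skipped", study)
            continue
        wide = sub.pivot(index="population_id", columns="trait", values="mean")
        traits = [t for t in G.trait_labels if t in wide.columns]
        if len(traits) < 2:
            continue
        wide = wide[traits].dropna()
        Gs = G.subset(traits) if traits != list(G.trait_labels) else G
        if "focal_population" in meta.columns and study in meta.index:
            focal = meta.loc[study, "focal_population"]
        else:
            focal = wide.index[0]
        if focal not in wide.index:
            logger.warning("study %s: focal population %s missing, skipped",
                           study, focal)
            continue
        summary = matrix_summary(Gs, seed=int(rng.integers(2**31)))
        G_draws = (
            mv.resample_G(Gs, iters=iters, seed=int(rng.integers(2**31)))
            if with_sampling_variances and Gs.n_families >= Gs.k + 1
            else None
        )
        G_draws_inv = None if G_draws is None else np.linalg.inv(G_draws)
        for target in wide.index:
            if target == focal:
                continue
            rec = dvec.vector_evolvabilities(
                Gs,
                wide.loc[focal].to_numpy(),
                wide.loc[target].to_numpy(),
                summary=summary,
                focal_population=str(focal),
                target_population=str(target),
                G_draws=G_draws,
                G_draws_inv=G_draws_inv,
            )
            if rec is not None:
                records.append(
                    dvec.VectorEvolvabilityRecord(
                        **{**rec.__dict__, "g_matrix_id": str(study)}
                    )
                )
    frame = dvec.records_to_frame(records)
    summary = dvec.above_average_summary(frame)
    table, correlations = dvec.divergence_vs_evolvability_table(frame)
    return {"records": table, "summary": summary, "rank_correlations": correlations}


def compute_de_ratio(db: Database) -> dict:
    """Distribution of per-trait d/e ratios across paired estimates.

    Under neutral divergence d/e = t/Ne for every trait, so the mean ratio
    estimates the ratio of divergence time to effective population size.
    """
    div = divergence_table(db)
    e_mean = (
        db.evolvability.groupby(["species", "trait"])["evolvability"]
        .mean()
        .rename("e")
        .reset_index()
    )
    data = div.merge(e_mean, on=["species", "trait"], how="inner")
    n_zero = int((data["e"] <= 0).sum())
    if n_zero:
        logger.warning("dropped %d rows with non-positive evolvability", n_zero)
        data = data[data["e"] > 0]
    ratio = data["d"] / data["e"]
    return {
        "n": int(len(ratio)),
        "mean": float(ratio.mean()),
        "median": float(ratio.median()),
        "ratios": data.assign(de_ratio=ratio),
    }
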