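"""Readers, writers and the end-to-end pipeline.

The pipeline sequences: inclusion filter -> SRI + demographic/geographic
masks -> dyad table + ZIB GLMM -> community detection -> community
permutation tests -> closest-associate tests, with every stochastic
stage seeded and a machine-readable JSON result bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import (
    AssociationMatrix,
    compute_sri,
    demographic_mask,
    filter_individuals,
    geographic_mask,
)
from .closest import closest_associates, homophily_binomial_test
from .communities import detect_communities
from .dyadic import ZIBModelSpec, build_dyad_table, fit_zib_glmm, foraging_contrasts, vif_check
from .homerange import overlap_matrix
from .permtests import perm_depth_sd, perm_foraging, perm_haplotype, perm_relatedness

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_sightings",
    "read_attributes",
    "read_relatedness",
    "write_association",
    "run_pipeline",
]


class InputError(ValueError):
    pass


@dataclass
class PipelineConfig:
    sightings_path: str = ""
    attributes_path: str = ""
    relatedness_path: str = ""
    output_dir: str = "results"
    inclusion_mode: str = "in_association"
    min_sightings: int = 10
    overlap_threshold: float = 0.25
    use_home_range_mask: bool = True
    kde_bandwidth: str | float = "reference"
    chains: int = 4
    iterations: int = 4000
    standardize: bool = False
    n_perm: int = 10_000
    n_restarts: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inclusion_mode not in ("in_association", "any"):
            raise InputError(f"unknown inclusion mode {self.inclusion_mode!r}")
        if not (0.0 <= self.overlap_threshold <= 1.0):
            raise InputError("overlap_threshold must lie in [0, 1]")
        if self.min_sightings < 1 or self.n_perm < 1:
            raise InputError("min_sightings and n_perm must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def read_sightings(path: str | Path) -> pd.DataFrame:
    """Sighting table CSV: survey_id, date, group_id, individual_id, depth, x, y."""
    df = pd.read_csv(path)
    if df.empty:
        raise InputError(f"{path}: empty sighting table")
    required = {"survey_id", "date", "group_id", "individual_id", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    if (df["depth"] < 0).any():
        bad = df.index[df["depth"] < 0][0]
        raise InputError(f"{path}: negative depth at row {bad + 2}")
    dup = df.duplicated(subset=["survey_id", "individual_id"])
    if dup.any():
        raise InputError(
            f"{path}: duplicate (survey, individual) at row {df.index[dup][0] + 2}"
        )
    df["date"] = pd.to_datetime(df["date"])
    return df


def read_attributes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise InputError(f"{path}: empty attribute table")
    required = {"individual_id", "haplotype", "sponger", "mean_depth"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    n_missing_hap = int(df["haplotype"].isna().sum())
    if n_missing_hap:
        logger.info("%d individuals lack haplotype data", n_missing_hap)
    df["sponger"] = df["sponger"].astype(bool)
    return df


def read_relatedness(path: str | Path, tol: float = 1e-8) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise InputError(f"{path}: empty relatedness matrix")
    if list(df.index) != list(df.columns):
        raise InputError(f"{path}: relatedness matrix index/columns differ")
    arr = df.to_numpy(dtype=float)
    finite = np.isfinite(arr) & np.isfinite(arr.T)
    if np.nanmax(np.abs(np.where(finite, arr - arr.T, 0.0))) > tol:
        raise InputError(f"{path}: relatedness matrix asymmetric beyond {tol}")
    return df


def write_association(assoc: AssociationMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assoc.value_frame().to_csv(outdir / "sri.csv")
    assoc.mask_frame().to_csv(outdir / "sri_mask.csv")
    assoc.edge_list().to_csv(outdir / "sri_edges.csv", index=False)
    try:
        import igraph as ig

        g = ig.Graph.Weighted_Adjacency(
            assoc.masked_weights().tolist(), mode="undirected", attr="weight", loops=False
        )
        g.vs["name"] = assoc.ids
        g.write_graphml(str(outdir / "sri.graphml"))
    except Exception:  # pragma: no cover - GraphML export is best effort
        logger.exception("GraphML export failed")


@dataclass
class PipelineResult:
    assoc: AssociationMatrix
    dyads: pd.DataFrame
    fit: object
    partition: object
    perms: dict
    closest_report: object
    results: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    sightings: pd.DataFrame | None = None,
    attributes: pd.DataFrame | None = None,
    relatedness: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full analysis; inputs may be passed in memory or by path."""
    if sightings is None:
        sightings = read_sightings(config.sightings_path)
    if attributes is None:
        attributes = read_attributes(config.attributes_path)
    if relatedness is None:
        relatedness = read_relatedness(config.relatedness_path)

    logger.info("stage 1: inclusion filter (%s)", config.inclusion_mode)
    individuals = filter_individuals(
        sightings, mode=config.inclusion_mode, min_sightings=config.min_sightings
    )
    if len(individuals) < 2:
        raise InputError("fewer than two individuals pass the inclusion filter")

    logger.info("stage 2: SRI and masks over %d individuals", len(individuals))
    assoc = compute_sri(sightings, individuals)
    assoc = assoc.apply_mask(demographic_mask(sightings, individuals))
    if config.use_home_range_mask:
        overlap = overlap_matrix(sightings, individuals, bandwidth=config.kde_bandwidth)
        assoc = assoc.apply_mask(
            geographic_mask(overlap, individuals, config.overlap_threshold)
        )

    # attributes restricted to the network; mean depth recomputed from data
    attrs = attributes[attributes["individual_id"].isin(individuals)].copy()
    observed_depth = sightings.groupby("individual_id")["depth"].mean()
    attrs["mean_depth"] = attrs["individual_id"].map(observed_depth)

    logger.info("stage 3: dyadic ZIB GLMM")
    dyads = build_dyad_table(assoc, attrs, relatedness)
    spec = ZIBModelSpec(
        chains=config.chains,
        iterations=config.iterations,
        standardize=config.standardize,
    )
    fit = fit_zib_glmm(dyads, spec, seed=config.seed)
    vif = vif_check(dyads)
    contrasts = foraging_contrasts(fit)

    logger.info("stage 4: community detection")
    partition = detect_communities(
        assoc, seed=config.seed + 1, n_restarts=config.n_restarts
    )

    logger.info("stage 5: permutation tests (%d permutations)", config.n_perm)
    attrs_idx = attrs.set_index("individual_id")
    labels = partition.labels
    perms = {
        "relatedness": perm_relatedness(
            relatedness, labels, config.n_perm, seed=config.seed + 2
        ),
        "haplotype": perm_haplotype(
            attrs_idx["haplotype"], labels, config.n_perm, seed=config.seed + 3
        ),
        "foraging": perm_foraging(
            attrs_idx["sponger"], labels, config.n_perm, seed=config.seed + 4
        ),
        "depth_sd": perm_depth_sd(
            attrs_idx["mean_depth"], labels, config.n_perm, seed=config.seed + 5
        ),
    }

    logger.info("stage 6: closest associates")
    closest = closest_associates(assoc)
    closest_report = homophily_binomial_test(closest, attrs_idx["sponger"])

    results = {
        "n_individuals": len(individuals),
        "n_dyads_modelled": int(fit.n_dyads),
        "n_dyads_dropped_missing_genetics": int(fit.n_dropped),
        "odds_ratios": {
            row["effect"]: {
                "mean": row["odds_ratio"],
                "ci_low": row["ci_low"],
                "ci_high": row["ci_high"],
            }
            for _, row in fit.odds_ratios.iterrows()
        },
        "foraging_contrasts": {
            row["contrast"]: {
                "mean": row["odds_ratio"],
                "ci_low": row["ci_low"],
                "ci_high": row["ci_high"],
            }
            for _, row in contrasts.iterrows()
        },
        "bayes_r2": {"mean": fit.bayes_r2_mean, "ci": list(fit.bayes_r2_ci)},
        "zero_inflation": {
            "mean": fit.zero_inflation_mean,
            "ci": list(fit.zero_inflation_ci),
        },
        "max_rhat": fit.max_rhat,
        "converged": fit.converged,
        "vif": {k: float(v) for k, v in vif.items()},
        "modularity": partition.modularity,
        "n_communities": partition.n_communities,
        "modularity_meaningful": partition.meaningful,
        "permutation_tests": {k: v.to_dict() for k, v in perms.items()},
        "closest_associates": closest_report.to_dict(),
        "seed": config.seed,
    }

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True, default=_json_default)
    )
    write_association(assoc, outdir)
    dyads.to_csv(outdir / "dyads.csv", index=False)
    pd.Series(labels, name="community").rename_axis("individual_id").to_csv(
        outdir / "communities.csv"
    )
    logger.info("pipeline complete; results in %s", outdir)

    return PipelineResult(
        assoc=assoc,
        dyads=dyads,
        fit=fit,
        partition=partition,
        perms=perms,
        closest_report=closest_report,
        results=results,
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
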