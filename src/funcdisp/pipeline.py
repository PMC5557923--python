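"""End-to-end orchestration: data -> dendrograms -> SES -> scale/gradient tests.

`run_pipeline` executes the full analysis for one data set: builds the six
trait dendrograms, pools communities to each spatial scale, computes
observed and null dispersion metrics, standardizes them into SES values,
summarizes departure from zero per scale, partitions SES variance across
the nesting levels and fits the three scale-specific gradient trends
(water depth, water transparency, elevation). All outputs are written as
CSV next to a JSON run manifest that fully determines them (inputs, seed,
iteration count, library versions).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._errors import NumericalError, ValidationError
from .community import CommunityMatrix, SCALES, SpatialHierarchy, pool_to_scale
from .dendrogram import MULTI_TRAIT, TraitDendrogram, build_all_dendrograms
from .envscales import (
    bin_gradient,
    gradient_trend,
    pca_environment,
    variance_partition,
)
from .nullmodels import (
    DEFAULT_ITERATIONS,
    alpha_ses_table,
    beta_ses_table,
    derive_seed,
    ses_summary,
    significance_stars,
)
from .traits import TraitTable

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    traits_csv: str
    traits_config: str
    community_csv: str
    hierarchy_csv: str
    environment_csv: str
    out_dir: str
    seed: int
    n_iter: int = DEFAULT_ITERATIONS
    scales: Sequence[str] = SCALES
    linkage: str = "average"
    transparency_levels: int = 5
    log_transform_env: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.n_iter < 99:
            raise ValidationError("n_iter must be >= 99")
        for s in self.scales:
            if s not in SCALES:
                raise ValidationError(f"unknown scale {s!r}")
        for name in ("traits_csv", "traits_config", "community_csv",
                     "hierarchy_csv", "environment_csv"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ValidationError(f"{name}: file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class RunResult:
    """In-memory bundle of every table the pipeline produced."""

    dendrograms: dict[str, TraitDendrogram]
    alpha_ses: pd.DataFrame
    beta_ses: pd.DataFrame
    summary: pd.DataFrame
    varcomp: pd.DataFrame
    env_axes: pd.DataFrame
    env_loadings: pd.DataFrame
    trends: pd.DataFrame
    manifest: dict


def compute_alpha_ses(
    comm: CommunityMatrix,
    hier: SpatialHierarchy,
    dendrograms: Mapping[str, TraitDendrogram],
    scales: Sequence[str],
    n_iter: int,
    seed: int,
) -> pd.DataFrame:
    """Alpha SES (PW, NN) for every scale x trait metric."""
    parts = []
    for scale in scales:
        pooled = pool_to_scale(comm, hier, scale)
        for tm, dendro in dendrograms.items():
            t0 = time.perf_counter()
            tab = alpha_ses_table(
                pooled, dendro.cophenetic, n_iter=n_iter,
                rng=derive_seed(seed, "alpha", scale, tm),
            )
            tab.insert(0, "scale", scale)
            tab.insert(1, "trait_metric", tm)
            parts.append(tab)
            logger.info("alpha SES %s/%s: %.2fs", scale, tm, time.perf_counter() - t0)
    return pd.concat(parts, ignore_index=True)


def compute_beta_ses(
    comm: CommunityMatrix,
    hier: SpatialHierarchy,
    dendrograms: Mapping[str, TraitDendrogram],
    scales: Sequence[str],
    n_iter: int,
    seed: int,
) -> pd.DataFrame:
    """Beta SES (Dpw, Dnn) for all within-group pairs at every scale."""
    parts = []
    for scale in scales:
        for tm, dendro in dendrograms.items():
            t0 = time.perf_counter()
            tab = beta_ses_table(
                comm, hier, scale, dendro.cophenetic, n_iter=n_iter,
                rng=derive_seed(seed, "beta", scale, tm),
            )
            tab.insert(0, "scale", scale)
            tab.insert(1, "trait_metric", tm)
            parts.append(tab)
            logger.info("beta SES %s/%s: %.2fs", scale, tm, time.perf_counter() - t0)
    return pd.concat(parts, ignore_index=True)


def compute_varcomp(
    alpha_ses: pd.DataFrame, beta_ses: pd.DataFrame, hier: SpatialHierarchy
) -> pd.DataFrame:
    """Variance components of SES across the nesting levels.

    Alpha SES at the plot grain decomposes over region / lake / depth
    stratum with the plot-level remainder as the residual; beta SES of
    plot pairs (grouped by stratum) decomposes the same way with the
    within-stratum pair remainder as residual.
    """
    t = hier.table
    rows = []
    plot_alpha = alpha_ses[(alpha_ses["scale"] == "plot") & alpha_ses["defined"]]
    merged = plot_alpha.merge(
        t[["plot", "depth_stratum", "lake", "region"]],
        left_on="community", right_on="plot", how="left",
    )
    for (tm, metric), grp in merged.groupby(["trait_metric", "metric"]):
        try:
            vc = variance_partition(grp, ("region", "lake", "depth_stratum"), value="ses")
        except (ValidationError, NumericalError) as exc:
            logger.warning("varcomp skipped for alpha %s/%s: %s", tm, metric, exc)
            continue
        for level, pct in vc.percentages.items():
            rows.append(
                {"kind": "alpha", "trait_metric": tm, "metric": f"SES {metric}",
                 "level": level, "share_pct": pct}
            )
    plot_beta = beta_ses[(beta_ses["scale"] == "plot") & beta_ses["defined"]]
    if len(plot_beta):
        stratum_info = t.drop_duplicates("depth_stratum").set_index("depth_stratum")
        pb = plot_beta.copy()
        pb["lake"] = pb["group"].map(stratum_info["lake"])
        pb["region"] = pb["group"].map(stratum_info["region"])
        pb["depth_stratum"] = pb["group"]
        for (tm, metric), grp in pb.groupby(["trait_metric", "metric"]):
            try:
                vc = variance_partition(grp, ("region", "lake", "depth_stratum"), value="ses")
            except (ValidationError, NumericalError) as exc:
                logger.warning("varcomp skipped for beta %s/%s: %s", tm, metric, exc)
                continue
            for level, pct in vc.percentages.items():
                rows.append(
                    {"kind": "beta", "trait_metric": tm, "metric": f"SES {metric}",
                     "level": level, "share_pct": pct}
                )
    return pd.DataFrame(rows)


def compute_trends(
    alpha_ses: pd.DataFrame,
    beta_ses: pd.DataFrame,
    hier: SpatialHierarchy,
    env: pd.DataFrame,
    log_transform_env: bool = True,
    transparency_levels: int = 5,
) -> pd.DataFrame:
    """Gradient trends of SES at the three environment-bearing scales.

    depth scale  — SES vs. water depth, random intercept per lake (alpha:
    per-stratum values; beta: plot pairs within stratum, at the stratum's
    depth);
    lake scale   — SES vs. log water transparency (Secchi depth), random
    intercept per region for alpha, per lake for beta (strata pairs);
    region scale — two-level elevation contrast on per-lake values (alpha:
    lake-scale SES; beta: lake pairs within region), ordinary least squares
    since the contrast coincides with the enclosing unit.
    """
    t = hier.table
    stratum_info = t.drop_duplicates("depth_stratum").set_index("depth_stratum")
    lake_info = t.drop_duplicates("lake").set_index("lake")
    transparency = env["secchi_depth"].astype(float)
    if log_transform_env:
        transparency = np.log(transparency)
    bins = bin_gradient(transparency, transparency_levels)
    rows = []

    def fit(frame, scale, kind, tm, metric, gradient_name, group):
        try:
            res = gradient_trend(frame, value="ses", gradient="gradient", group=group)
        except (ValidationError, NumericalError) as exc:
            logger.warning("trend skipped (%s %s %s/%s): %s", scale, kind, tm, metric, exc)
            return
        rows.append(
            {
                "scale": scale, "kind": kind, "trait_metric": tm,
                "metric": f"SES {metric}", "gradient": gradient_name,
                "slope": res.slope, "pvalue": res.pvalue,
                "direction": res.direction, "stars": significance_stars(res.pvalue),
                "n": res.n, "method": res.method,
            }
        )

    # --- depth scale -------------------------------------------------------
    da = alpha_ses[(alpha_ses["scale"] == "depth") & alpha_ses["defined"]].copy()
    da["gradient"] = da["community"].map(stratum_info["water_depth_m"])
    da["group"] = da["community"].map(stratum_info["lake"])
    for (tm, metric), grp in da.groupby(["trait_metric", "metric"]):
        fit(grp, "depth", "alpha", tm, metric, "water_depth_m", "group")
    db = beta_ses[(beta_ses["scale"] == "plot") & beta_ses["defined"]].copy()
    db["gradient"] = db["group"].map(stratum_info["water_depth_m"])
    db["lake_group"] = db["group"].map(stratum_info["lake"])
    for (tm, metric), grp in db.groupby(["trait_metric", "metric"]):
        fit(grp.rename(columns={"lake_group": "grp"}), "depth", "beta", tm, metric,
            "water_depth_m", "grp")

    # --- lake scale --------------------------------------------------------
    la = alpha_ses[(alpha_ses["scale"] == "lake") & alpha_ses["defined"]].copy()
    la["gradient"] = la["community"].map(transparency)
    la["group"] = la["community"].map(lake_info["region"])
    for (tm, metric), grp in la.groupby(["trait_metric", "metric"]):
        fit(grp, "lake", "alpha", tm, metric, "log_transparency", "group")
    lb = beta_ses[(beta_ses["scale"] == "depth") & beta_ses["defined"]].copy()
    lb["gradient"] = lb["group"].map(transparency)
    lb["lake_group"] = lb["group"]
    for (tm, metric), grp in lb.groupby(["trait_metric", "metric"]):
        fit(grp.rename(columns={"lake_group": "grp"}), "lake", "beta", tm, metric,
            "log_transparency", "grp")

    # --- region scale (two-level elevation contrast) -----------------------
    ra = alpha_ses[(alpha_ses["scale"] == "lake") & alpha_ses["defined"]].copy()
    ra["gradient"] = ra["community"].map(lake_info["elevation_m"])
    for (tm, metric), grp in ra.groupby(["trait_metric", "metric"]):
        fit(grp, "region", "alpha", tm, metric, "elevation_m", None)
    rb = beta_ses[(beta_ses["scale"] == "lake") & beta_ses["defined"]].copy()
    rb["gradient"] = rb["group"].map(
        t.drop_duplicates("region").set_index("region")["elevation_m"]
    )
    for (tm, metric), grp in rb.groupby(["trait_metric", "metric"]):
        fit(grp, "region", "beta", tm, metric, "elevation_m", None)

    out = pd.DataFrame(
        rows,
        columns=["scale", "kind", "trait_metric", "metric", "gradient", "slope",
                 "pvalue", "direction", "stars", "n", "method"],
    )
    out.attrs["transparency_bins"] = bins.display_edges
    return out


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage and write all outputs under ``config.out_dir``."""
    t_start = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    current = stage("load")
    try:
        traits = TraitTable.from_csv(config.traits_csv, config.traits_config)
        comm = CommunityMatrix.from_csv(config.community_csv)
        hier = SpatialHierarchy.from_csv(config.hierarchy_csv)
        env = pd.read_csv(config.environment_csv, index_col=0)
        extra = set(comm.species) - set(traits.species)
        if extra:
            raise ValidationError(f"community species missing from trait table: {sorted(extra)[:5]}")

        current = stage("dendrograms")
        dendrograms = build_all_dendrograms(traits, method=config.linkage)
        (out / "dendrograms").mkdir(exist_ok=True)
        for tm, dendro in dendrograms.items():
            (out / "dendrograms" / f"{tm}.nwk").write_text(dendro.to_newick() + "\n")
            dendro.cophenetic.to_csv(out / "dendrograms" / f"{tm}_cophenetic.csv")

        current = stage("alpha_ses")
        alpha = compute_alpha_ses(comm, hier, dendrograms, config.scales,
                                  config.n_iter, config.seed)
        alpha.to_csv(out / "ses_alpha.csv", index=False)

        current = stage("beta_ses")
        beta = compute_beta_ses(comm, hier, dendrograms, config.scales,
                                config.n_iter, config.seed)
        beta.to_csv(out / "ses_beta.csv", index=False)

        current = stage("summary")
        alpha_s = ses_summary(alpha)
        alpha_s.insert(0, "kind", "alpha")
        beta_s = ses_summary(beta)
        beta_s.insert(0, "kind", "beta")
        summary = pd.concat([alpha_s, beta_s], ignore_index=True)
        summary.to_csv(out / "ses_summary.csv", index=False)

        current = stage("varcomp")
        varcomp = compute_varcomp(alpha, beta, hier)
        varcomp.to_csv(out / "variance_components.csv", index=False)

        current = stage("environment")
        axes = pca_environment(env, log_transform=config.log_transform_env)
        axes.scores.rename_axis("lake").to_csv(out / "env_axes.csv")
        axes.loadings.rename_axis("parameter").to_csv(out / "env_loadings.csv")

        current = stage("trends")
        trends = compute_trends(alpha, beta, hier, env,
                                log_transform_env=config.log_transform_env,
                                transparency_levels=config.transparency_levels)
        trends.to_csv(out / "gradient_trends.csv", index=False)
    except (ValidationError, NumericalError) as exc:
        raise type(exc)(f"stage {current!r}: {exc}") from exc

    import scipy
    import sklearn
    import statsmodels

    manifest = {
        "package": "funcdisp",
        "version": __import__("funcdisp").__version__,
        "seed": int(config.seed),
        "n_iter": int(config.n_iter),
        "scales": list(config.scales),
        "linkage": config.linkage,
        "counts": {
            "species_pool": len(traits.species),
            "plots": len(hier.plots),
            "depth_strata": len(hier.units("depth")),
            "lakes": len(hier.units("lake")),
            "regions": len(hier.units("region")),
        },
        "pca_axis1_explained_pct": float(100.0 * axes.explained_ratio[0]),
        "transparency_bins": trends.attrs.get("transparency_bins", []),
        "library_versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t_start)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResult(
        dendrograms=dendrograms, alpha_ses=alpha, beta_ses=beta, summary=summary,
        varcomp=varcomp, env_axes=axes.scores, env_loadings=axes.loadings,
        trends=trends, manifest=manifest,
    )
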