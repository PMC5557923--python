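"""Synthetic lake-macrophyte surveys with known ground truth.

The generator emulates the survey design the pipeline is built for: two
regions (a high plateau at ~1967 m and a lowland river basin at ~16 m),
twelve lakes per region, 0.5 m water-depth strata per lake, several 25 m^2
plots per stratum, and a 50-species regional pool carrying the five
canonical traits. Plot richness is kept within the observed 1-18 range
with a median around 4.

Community assembly follows a trait-filtering lottery: the occurrence
probability of species *i* at a site with environmental score *E* is
proportional to ``exp(-lambda * (z_i - opt(E))^2)`` averaged over
standardized trait axes, followed by a weighted lottery draw without
replacement and lognormal abundances. ``lambda = 0`` is the neutral
scenario (occurrence independent of traits); increasing ``lambda``
strengthens environmental filtering and drives the standardized effect
sizes of the dispersion metrics negative. Per-trait filter weights allow
trait-specific responses.

:func:`simulate_ses_table` bypasses the assembly model entirely and draws
SES values directly as sums of independent normal effects per nesting
level — the controlled input for variance-partition recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._errors import ValidationError
from .community import CommunityMatrix, SpatialHierarchy
from .nullmodels import derive_seed
from .traits import CONTINUOUS, TraitTable, default_definitions

ENV_PARAMETERS = (
    "secchi_depth",
    "total_nitrogen",
    "total_phosphorus",
    "chlorophyll_a",
    "ph",
    "water_temperature",
)


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic survey; defaults mirror the study design."""

    seed: int = 0
    n_regions: int = 2
    lakes_per_region: int = 12
    strata_per_lake: tuple[int, int] = (2, 9)  # uniform range, ~135 strata total
    plots_per_stratum: tuple[int, int] = (4, 11)  # ~1008 plots total
    pool_size: int = 50
    fraction_annual: float = 0.3
    sla_ldmc_correlation: float = -0.6  # leaf-economics trade-off
    filtering_strength: float = 0.0  # lambda; 0 = neutral assembly
    trait_filter_weights: dict[str, float] | None = None  # per-trait kappa
    gradient_weights: dict[str, float] = field(
        default_factory=lambda: {"region": 1.0, "lake": 1.0, "depth": 1.0}
    )
    mean_richness: float = 4.0
    richness_range: tuple[int, int] = (1, 18)
    abundance_sigma: float = 1.0
    depth_interval_m: float = 0.5
    elevations_m: tuple[float, float] = (16.3, 1967.4)
    max_retries: int = 1000

    def __post_init__(self):
        if self.n_regions < 1 or self.lakes_per_region < 1 or self.pool_size < 2:
            raise ValidationError("all design counts must be >= 1 (pool >= 2)")
        lo, hi = self.richness_range
        if lo < 1 or hi < lo:
            raise ValidationError("invalid richness range")
        if self.pool_size < hi and self.pool_size < lo:
            raise ValidationError("pool size must allow the minimum richness")
        if self.filtering_strength < 0:
            raise ValidationError("filtering strength must be >= 0")


@dataclass
class SyntheticSurvey:
    """Bundle of everything one scenario generates."""

    scenario: SyntheticScenario
    traits: TraitTable
    community: CommunityMatrix
    hierarchy: SpatialHierarchy
    environment: pd.DataFrame  # lakes x water parameters

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.traits.to_csv(out / "traits.csv")
        self.traits.config_to_yaml(out / "trait_config.yaml")
        self.community.to_csv(out / "communities.csv")
        self.hierarchy.to_csv(out / "hierarchy.csv")
        self.environment.rename_axis("lake").to_csv(out / "environment.csv")
        truth = asdict(self.scenario)
        with open(out / "ground_truth.yaml", "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=False)
        return {p.name: str(p) for p in sorted(out.iterdir())}


def generate_traits(scen: SyntheticScenario) -> TraitTable:
    """Species pool with the five canonical traits.

    Life history is a Bernoulli annual/perennial draw; shoot height and
    specific leaf area are lognormal; leaf dry mass content is generated
    jointly with specific leaf area on the log scale with the configured
    (negative by default) correlation; flowering duration is an integer
    month count in [1, 12].
    """
    rng = np.random.default_rng(derive_seed(scen.seed, "traits"))
    n = scen.pool_size
    species = [f"sp{i + 1:02d}" for i in range(n)]
    life = np.where(rng.random(n) < scen.fraction_annual, "annual", "perennial")
    height = np.exp(rng.normal(np.log(60.0), 0.8, n))
    rho = float(np.clip(scen.sla_ldmc_correlation, -0.99, 0.99))
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    sla = np.exp(3.0 + 0.5 * z[:, 0])
    ldmc = np.clip(0.15 * np.exp(0.4 * z[:, 1]), 0.02, 0.6)
    flowering = np.clip(np.rint(rng.normal(4.0, 2.0, n)), 1, 12)
    data = pd.DataFrame(
        {
            "life_history": life,
            "shoot_height": height,
            "specific_leaf_area": sla,
            "leaf_dry_mass_content": ldmc,
            "flowering_duration": flowering.astype(float),
        },
        index=pd.Index(species, name="species"),
    )
    return TraitTable(data, default_definitions())


def _standardized_trait_matrix(traits: TraitTable) -> np.ndarray:
    """Species x traits matrix of z-scores (binary categoricals coded 0/1)."""
    cols = []
    for t in traits.trait_names:
        if traits.kind(t) == CONTINUOUS:
            x = traits.values(t).to_numpy(float)
        else:
            levels = sorted(set(traits.values(t)))
            x = (traits.values(t).to_numpy(str) == levels[-1]).astype(float)
        sd = x.std(ddof=0)
        cols.append((x - x.mean()) / sd if sd > 0 else np.zeros_like(x))
    return np.column_stack(cols)


def _generate_environment(scen: SyntheticScenario, lakes, q, rng) -> pd.DataFrame:
    """Per-lake water parameters driven by a latent water-quality axis q.

    Higher q means clearer, less eutrophic water: Secchi depth rises while
    nitrogen, phosphorus and chlorophyll-a fall.
    """
    n = len(lakes)
    env = pd.DataFrame(
        {
            "secchi_depth": np.exp(0.7 + 0.35 * q + rng.normal(0, 0.05, n)),
            "total_nitrogen": np.exp(0.0 - 0.5 * q + rng.normal(0, 0.2, n)),
            "total_phosphorus": np.exp(-2.3 - 0.5 * q + rng.normal(0, 0.2, n)),
            "chlorophyll_a": np.exp(2.0 - 0.6 * q + rng.normal(0, 0.3, n)),
            "ph": np.exp(rng.normal(np.log(8.0), 0.04, n)),
            "water_temperature": np.exp(rng.normal(np.log(25.0), 0.06, n)),
        },
        index=pd.Index(lakes, name="lake"),
    )
    return env


def generate_survey(
    scen: SyntheticScenario, traits: TraitTable
) -> tuple[CommunityMatrix, SpatialHierarchy, pd.DataFrame]:
    """Hierarchy, per-lake environments and trait-filtered communities."""
    rng = np.random.default_rng(derive_seed(scen.seed, "survey"))
    Z = _standardized_trait_matrix(traits)
    kappa = np.ones(Z.shape[1])
    if scen.trait_filter_weights:
        for j, t in enumerate(traits.trait_names):
            kappa[j] = scen.trait_filter_weights.get(t, 1.0)
    if kappa.sum() <= 0:
        raise ValidationError("trait filter weights must have positive total")
    kappa = kappa / kappa.sum()

    # --- spatial design ---------------------------------------------------
    rows = []
    lake_region = {}
    for r in range(scen.n_regions):
        region = f"R{r + 1}"
        elev = scen.elevations_m[r % len(scen.elevations_m)]
        for l in range(scen.lakes_per_region):
            lake = f"{region}L{l + 1:02d}"
            lake_region[lake] = (region, elev)
            n_strata = int(rng.integers(scen.strata_per_lake[0], scen.strata_per_lake[1] + 1))
            for k in range(n_strata):
                depth = scen.depth_interval_m * (k + 1)
                stratum = f"{lake}D{depth:.1f}"
                n_plots = int(
                    rng.integers(scen.plots_per_stratum[0], scen.plots_per_stratum[1] + 1)
                )
                for p in range(n_plots):
                    rows.append(
                        {
                            "plot": f"{stratum}P{p + 1:02d}",
                            "depth_stratum": stratum,
                            "water_depth_m": depth,
                            "lake": lake,
                            "region": region,
                            "elevation_m": elev,
                        }
                    )
    hier_df = pd.DataFrame(rows)
    hier = SpatialHierarchy(hier_df)

    # --- environments and plot-level environmental scores ------------------
    lakes = list(lake_region)
    q = rng.normal(0.0, 1.0, len(lakes))
    env = _generate_environment(scen, lakes, q, rng)
    q_of_lake = dict(zip(lakes, (q - q.mean()) / (q.std() or 1.0)))
    region_sign = {f"R{r + 1}": (1.0 if r % 2 else -1.0) for r in range(scen.n_regions)}
    depths = hier_df["water_depth_m"].to_numpy()
    d_mu, d_sd = depths.mean(), depths.std() or 1.0
    w = scen.gradient_weights
    w_tot = sum(abs(w.get(k, 0.0)) for k in ("region", "lake", "depth")) or 1.0

    # --- assembly ----------------------------------------------------------
    lam = scen.filtering_strength
    lo, hi = scen.richness_range
    hi = min(hi, scen.pool_size)
    n_species = scen.pool_size
    abund = np.zeros((len(hier_df), n_species))
    for i, row in enumerate(hier_df.itertuples(index=False)):
        e = (
            w.get("region", 0.0) * region_sign[row.region]
            + w.get("lake", 0.0) * q_of_lake[row.lake]
            + w.get("depth", 0.0) * (row.water_depth_m - d_mu) / d_sd
        ) / w_tot
        opt = float(np.clip(e, -2.0, 2.0))
        weight = np.exp(-lam * ((Z - opt) ** 2 @ kappa))
        weight = weight / weight.sum()
        richness = int(np.clip(1 + rng.poisson(max(scen.mean_richness - 1.0, 0.0)), lo, hi))
        for _ in range(scen.max_retries):
            if richness <= np.count_nonzero(weight):
                break
            richness -= 1
        chosen = rng.choice(n_species, size=richness, replace=False, p=weight)
        abund[i, chosen] = np.exp(rng.normal(0.0, scen.abundance_sigma, size=richness))
    comm = CommunityMatrix(
        pd.DataFrame(abund, index=hier_df["plot"].to_numpy(), columns=traits.species)
    )
    return comm, hier, env


def simulate_scenario(scen: SyntheticScenario) -> SyntheticSurvey:
    """Generate a complete survey bundle from one scenario."""
    traits = generate_traits(scen)
    comm, hier, env = generate_survey(scen, traits)
    return SyntheticSurvey(scen, traits, comm, hier, env)


def simulate_ses_table(
    variances: Mapping[str, float],
    hier: SpatialHierarchy,
    n_obs_per_plot: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """SES values drawn directly from a nested random-effects model.

    ``variances`` maps levels (any of ``region``, ``lake``, ``depth``,
    ``plot``, ``residual``) to variance magnitudes; each observation is the
    sum of independent zero-mean normal effects at those levels. With
    ``n_obs_per_plot > 1`` the residual acts within plots (micro-habitat
    replication); ground truth for variance-partition recovery tests.
    """
    bad = {k: v for k, v in variances.items() if v < 0}
    if bad:
        raise ValidationError(f"negative variance(s): {bad}")
    rng = np.random.default_rng(seed)
    t = hier.table
    key_col = {"region": "region", "lake": "lake", "depth": "depth_stratum", "plot": "plot"}
    base = t.loc[t.index.repeat(n_obs_per_plot)].reset_index(drop=True)
    y = np.zeros(len(base))
    for level, col in key_col.items():
        var = float(variances.get(level, 0.0))
        if var == 0.0:
            continue
        units = pd.unique(base[col])
        eff = dict(zip(units, rng.normal(0.0, np.sqrt(var), len(units))))
        y += base[col].map(eff).to_numpy(float)
    y += rng.normal(0.0, np.sqrt(float(variances.get("residual", 0.0))), len(base))
    out = base[["region", "lake", "depth_stratum", "plot", "water_depth_m"]].copy()
    out["ses"] = y
    return out
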