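# Methods

## Trait space and dendrograms

Traits are declared as continuous or categorical. The canonical macrophyte
schema has five: life history (annual/perennial, binary categorical), shoot
height (cm), specific leaf area (mm² mg⁻¹), leaf dry mass content (mass
fraction) and flowering duration (months, treated as a continuous count).
Flowering duration is generated and stored as whole months but analyzed as
continuous; life history is a two-level factor.

Pairwise species distances come from two builders:

- **Gower distance** (categorical or mixed trait sets): per-trait
  contribution |xᵢ − xⱼ| / range for continuous traits, 0/1 mismatch for
  categorical ones; the distance is the *unweighted mean* of contributions
  (no trait weights — none are justified a priori), hence bounded in [0, 1].
  A trait that is constant across the pool contributes 0 to every pair and
  is reported in the log rather than raised, except when every selected
  trait is constant (the distance is then undefined and an error). Because
  contributions are range-normalized, Gower distances are invariant to
  affine rescaling of any continuous trait.
- **Euclidean distance on one z-standardized continuous trait**
  (sample SD, ddof = 1). Standardization puts single-trait dendrograms from
  different traits on a comparable height scale, so standardized effect
  sizes can be compared across traits.

Dendrograms are built by **UPGMA** (average linkage), the standard choice
for trait dendrograms in functional ecology; complete and single linkage
are available behind a flag for sensitivity checks, and all three produce
ultrametric cophenetic matrices (property-tested over all leaf triples).
Every dispersion metric consumes *cophenetic* distances, not raw trait
distances. Six dendrograms are built per analysis: one per single trait
(Gower for the categorical trait, Euclidean-on-standardized for the four
continuous ones) and one multi-trait Gower dendrogram. Newick export uses
branch lengths equal to merge-height differences, so tip-to-tip path
lengths reproduce the cophenetic distances.

## Communities, hierarchy and pooling

The sampling design is a strict tree: plot → 0.5 m depth stratum → lake →
region, with water depth attached to strata, water chemistry to lakes and
elevation to regions. Quadrat-level records are accepted at load and summed
into their plot; the plot is the canonical analysis unit. Pooling to any
coarser scale **sums** abundances (conserving totals exactly, matching how
quadrats aggregate physically); pooling is associative and never decreases
richness. All-zero samples are dropped with a log entry.

## Dispersion metrics

With fᵢ the relative abundances of the species present in a community and
dᵢⱼ cophenetic distances:

- alpha: PW = Σᵢ≠ⱼ fᵢfⱼdᵢⱼ / Σᵢ≠ⱼ fᵢfⱼ, NN = Σᵢ fᵢ · minⱼ≠ᵢ dᵢⱼ
- beta: Dpw = Σᵢ∈A Σⱼ∈B fᵢᴬ fⱼᴮ dᵢⱼ,
  Dnn = ½ [Σᵢ fᵢᴬ minⱼ∈B dᵢⱼ + Σⱼ fⱼᴮ minᵢ∈A dᵢⱼ]

These exact weighting forms are frozen as the package's reference
definitions and each is backed by an independent brute-force loop in the
test suite. Dnn is symmetrized as the mean of both directions so the value
is pair-symmetric (the one-directional variant is not). NN ≤ PW always
(each species' nearest neighbor is no farther than its weighted mean
neighbor); Dnn(A, A) = 0; all four metrics are invariant to uniform
abundance rescaling and to zero-abundance species.

Communities with fewer than two species present have *undefined* alpha
dispersion, flagged rather than zero-filled: coding them as 0 would read as
maximal clustering and bias downstream effect sizes. Beta groups are the
sub-units inside each enclosing unit (plots within a stratum, strata within
a lake, lakes within a region, and the regions as one global group); groups
with fewer than two sub-units are skipped with a log entry.

## Null model and standardized effect sizes

The null model relabels the dendrogram tips: one uniformly random
permutation applied jointly to rows and columns of the cophenetic matrix.
Community composition, abundances, occupancy and spatial structure are
untouched by construction; the multiset of distances is exactly preserved.
One permutation per iteration is shared by all communities, so
cross-community structure is preserved for the beta metrics (within a pair,
both communities must see the same relabeling). Default 999 iterations; a
seed is mandatory, and all pipeline stages derive named child seeds from it
(`derive_seed`), so reruns are byte-identical.

SES = (obs − null mean) / null SD, with the null SD computed over the
iterations only (ddof = 1; the observed value is not part of the null
sample). SES is undefined when the null SD is zero — e.g. a community
containing the whole pool with equal abundances, where every relabeling
yields the same value — or, at float precision, within 1e−12 of zero.
SES is invariant to multiplying all distances by a positive constant.

Departure of a group of SES values from zero uses a two-sided Wilcoxon
signed-rank test: zeros dropped, exact sign-flip distribution for n ≤ 25
(computed by a subset-sum count over doubled midranks, so ties are exact
too), normal approximation with continuity correction above. Significance
is labeled with the 0.05 / 0.01 / 0.001 star convention and no
multiple-testing correction by default (a Benjamini–Hochberg step would be
a trivial addition but changes the reporting convention).

**A calibration caveat worth knowing.** Per community, SES is exactly
calibrated under neutral assembly (mean 0, SD ≈ 1; verified by simulation).
But the null distribution of PW on an ultrametric dendrogram is
left-skewed, so neutral SES values have mean 0 and *median above 0*
(≈ +0.18 in our neutral scenario). The signed-rank test responds to the
median and to asymmetry, not the mean, so its rejection rate under neutral
assembly exceeds the nominal α and grows with group size (≈ 8.5% at α=0.05
with ~34 communities per group in our simulations). This is a property of
applying a signed-rank test to skewed effect sizes, inherited from standard
field practice, and it means small p-values near the threshold should be
read cautiously; strongly negative mean SES (the filtering signature) is
unaffected.

## Variance components

SES variance is decomposed over the nesting levels with a linear mixed
model holding one variance component per level (REML, non-negative by
construction, via statsmodels MixedLM), reported as percentage shares that
sum to 100. With SES at the plot grain the components are region /
lake-in-region / stratum-in-lake with the plot-level remainder as the
residual; the generator's `simulate_ses_table` can add within-plot
replication to separate a plot component from a micro-habitat residual.

The REML surface can have ridges and local optima when a level has very few
units (two regions). The implementation therefore fits from the default
start and from a method-of-moments start, and — only when those two
disagree — retries with a derivative-free Nelder–Mead search, keeping the
fit with the highest restricted likelihood. This was verified to matter: in
a degenerate region-only structure the default optimizer reported
convergence at a point ~140 log-likelihood units below the optimum.

## Environmental gradients

The lake-scale gradient is extracted by PCA of the six water parameters
(Secchi depth, total N, total P, chlorophyll-a, pH, water temperature), all
log-transformed (a config switch restricts the log set) and z-standardized.
Axis 1 is sign-oriented so Secchi depth loads positively, making "higher
axis-1 score = clearer water" a stable convention; transparency then serves
as the lake gradient. Equal-width binning of the log-transparency range
into five ordinal levels is provided for display (boundaries rounded
half-up to 2 decimals; assignment uses unrounded boundaries, interior
boundaries open to the right, maximum included in the last level).

Trends of SES along a gradient are linear mixed models with a random
intercept for the enclosing spatial unit: per-stratum SES vs. water depth
with lake intercepts (depth scale); per-lake SES vs. log-transparency with
region intercepts, and beta pairs within lakes with lake intercepts (lake
scale); at the region scale the gradient is a two-level elevation factor on
per-lake values, which coincides with the enclosing unit, so the model
reduces to ordinary least squares (the documented fallback whenever fewer
than two groups are available). The p-value is a likelihood-ratio test of
the slope (ML fits of slope vs. intercept-only, χ² with 1 df); the reported
slope comes from a REML refit. Direction labels follow the interpretive
rule: significant negative slope = "more clustered" along the gradient,
positive = "less clustered", otherwise "none". A constant response returns
slope 0, p = 1, "none" without fitting.

## Synthetic surveys

The generator emulates the nested survey the pipeline targets, and its
defaults are the study conditions used by the tests: 2 regions (elevations
16.3 m and 1967.4 m), 12 lakes per region, 2–9 depth strata per lake at
0.5 m intervals, 4–11 plots per stratum (~1000 plots in expectation), a
50-species pool, plot richness clamped to [1, 18] with a 1 + Poisson(3)
draw (median 4). Traits: Bernoulli life history (30% annual), lognormal
shoot height and specific leaf area, leaf dry mass content generated
jointly with SLA on the log scale with correlation −0.6 (the
leaf-economics trade-off), integer flowering months. Lake water chemistry
is driven by one latent water-quality axis: clearer water (higher Secchi)
goes with lower N, P and chlorophyll-a.

Assembly is a trait-filtering lottery: a plot's environmental score
combines its region sign, its lake's latent axis and its standardized
depth; occurrence weights are exp(−λ · mean-weighted squared distance of a
species' standardized traits from the site optimum), and species are drawn
without replacement with those weights, with lognormal abundances. λ = 0 is
the neutral limit (weights uniform; occupancy independent of traits —
verified); increasing λ monotonically depresses mean SES (verified at
λ = 0, 2, 8). Per-trait filter weights allow trait-specific responses. What
the generator does *not* emulate: real biomass units, intraspecific trait
variation, dispersal limitation, spatial autocorrelation within strata, or
depth-dependent richness. Passing tests therefore demonstrate the
statistical machinery under a known assembly model, not ecological realism.

## Problem sizes used by the checks

The calibration and recovery runs are sized to be informative yet quick:
null calibration uses 200 independent neutral surveys (~34 plots each, 999
iterations); filtering detection uses a reduced 2 regions × 4 lakes × 4
strata × 4 plots design at λ = 6; variance-component recovery uses 2 × 5 ×
3 × 3 plots with 3 within-plot observations and 50 replicates (mean shares
recovered to within a few points of the true 20%); trend recovery uses 12
lakes × 6 depths with slope −0.5, random-intercept SD 0.5 and residual SD
0.5, 50 replicates. At the Wilcoxon thresholds, note that an exact
signed-rank p-value with n groups cannot fall below 2/2ⁿ — with 8 lakes the
floor is 0.0078, and with 2 regions the test is undefined (fewer than 5
values) — so very small p-values are only reachable at the finer scales.

## Known limitations

- The signed-rank calibration caveat above: group-level tests on skewed SES
  are mildly anticonservative under neutrality.
- Variance-component estimates for a 2-unit level (region) are intrinsically
  noisy and biased toward 0; shares at that level should be read as rough.
- The full model-selection workflow for mixed-model error structures is
  deliberately reduced to one fixed, documented random-effects structure
  per scale.
- Beta SES values within a group share communities across pairs, so their
  group-level tests are not independent-sample tests; they are reported
  with the same machinery for comparability.
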