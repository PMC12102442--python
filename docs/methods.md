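# Methods

## Rate conversions

Bacterial production is taken as `BP = Leu × f` with the leucine-to-carbon
factor f = 0.37 kg C mol⁻¹ Leu, so a leucine incorporation rate in
nmol L⁻¹ d⁻¹ is numerically a production in µg C L⁻¹ d⁻¹ = mg C m⁻³ d⁻¹.
Community respiration comes from whole-water INT reduction through the
empirical power-law calibration `log₁₀ CR_O₂ = 0.72 log₁₀ INT_T + 0.44`,
applied with INT_T in µmol INT L⁻¹ d⁻¹ and yielding CR_O₂ in
µmol O₂ L⁻¹ d⁻¹ (the units of the source calibration; both are recorded in
output metadata and the constants are configurable). The bacterial share is
the 0.2–0.8 µm fraction, `BR_O₂ = CR_O₂ · INT₀.₂–₀.₈/INT_T`, converted to
carbon at a respiratory quotient of 1 mol C per mol O₂ and a carbon mass of
12.011 µg µmol⁻¹ (IUPAC; configurable — surveys sometimes use 12). Cell-
specific rates are reported in fg C cell⁻¹ d⁻¹ (`rate × 10⁶ / BA` with BA in
cells mL⁻¹).

Numerical conventions:

* Blank-corrected absorbances that come out negative (blanks can exceed
  samples through instrument noise) are clamped to 0 with a logged warning
  rather than raising.
* The log-log calibration is undefined at 0; `int_to_cr` refuses non-positive
  input, and the panel builder maps a measured zero explicitly to
  CR_O₂ = BR = 0 so the domain restriction is visible, never silent.
* Missing raw fields propagate as missing outputs, never as zeros; a
  bacterial INT fraction exceeding the total is a per-sample error that is
  reported and excludes only that sample.
* Leucine inputs are accepted as already-computed incorporation rates;
  scintillation-counter DPM processing is instrument-specific and out of
  scope.

## Community statistics

Lineage filtering removes ASVs whose lineage contains any banned label
(default "chloroplast", "mitochondria") by case-insensitive substring match
across all six ranks; ASVs missing from the taxonomy are retained and
reported. Rarefaction is seeded subsampling without replacement (one
multivariate-hypergeometric draw per sample) to an exact common depth;
samples below the depth are dropped and reported. Diversity is computed
after rarefaction. Shannon entropy uses natural log (base configurable).

PCoA is classical scaling of −½D² after double-centering; axes belong to
positive eigenvalues only, negative eigenvalues (non-Euclidean distances)
are reported but uncorrected (no Lingoes/Cailliez), and proportions explained
are relative to the positive part of the spectrum. PERMANOVA partitions the
squared-distance sum into among/within components; the p-value is
`(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` over seeded relabelings (default
999), with exhaustive enumeration available for n ≤ 9. The Wilcoxon rank-sum
test uses exact enumeration when both samples have n ≤ 8 without ties, and
otherwise the normal approximation with tie and continuity corrections.

## Co-occurrence networks

ASVs present in fewer than 5 samples are excluded; pairwise Spearman
correlations (average ranks for ties, two-sided t-approximation p-values)
are Benjamini–Hochberg adjusted over the upper triangle; an edge requires
|ρ| above the threshold **and** adjusted p below the threshold. The edge
criterion uses the absolute correlation, so strong negative associations are
edges with negative weight. The default p-threshold is 0.001 with 0.01
available as a config override (both appear in survey practice). Nodes with
no surviving edge are not part of the network, and the edge set is invariant
to sample/ASV ordering.

Module detection is seeded Louvain — greedy modularity maximization with
local moves — on the unweighted graph; module labels are assigned by
descending node count (module 1 = largest, ties broken by smallest member
name) so that "module 1" is stable across runs. Topology metrics are all on
the unweighted graph: Newman–Girvan modularity Q, mean local clustering
(degree-<2 nodes contribute 0), mean shortest-path length over connected
ordered pairs only (disconnected pairs are excluded rather than infinite),
mean degree 2E/N, and Freeman degree centralization
Σ(k_max − k_i)/((n−1)(n−2)), undefined below 3 nodes and then reported as
missing. Per-node degrees are exported alongside.

Module abundance per sample is the mean of member ASVs' z-scored relative
abundances, computed from the rarefied, lineage-filtered table; z-scores use
the population (n) denominator (configurable to n−1), and zero-variance
series contribute zeros.

## Linkage

The coupling panel defaults to Spearman (consistent with the network stage;
Pearson by config) with pairwise-complete handling of missing values and
stars at p < 0.05 / p < 0.01, uncorrected (a BH option exists but is off by
default, matching how such panels are conventionally reported). BR is scaled
by the global maximum of the season's analysis set before each per-module
OLS regression. PCA standardizes columns (correlation PCA) because the panel
mixes units; the sign convention makes each axis's largest-magnitude loading
positive. The coupled/decoupled verdict is a descriptive dichotomy at
α = 0.05, invariant to sample ordering, and explicitly not a causal claim.
Per-season PCAs run on a combined standardized matrix of BR, dominant
class-level relative abundances, and module abundances.

## Synthetic generator

Defaults are the study conditions of a two-season subtropical-gyre survey:
40 summer and 48 winter stations; temperature 29.8 ± 0.6 / 26.9 ± 1.4 °C,
salinity 34.7 ± 0.4 / 34.8 ± 0.5, Chl a 0.05 ± 0.02 / 0.10 ± 0.04 µg L⁻¹,
BA 6.95 ± 1.49 / 8.45 ± 1.13 × 10⁵ cells mL⁻¹ (summer/winter), giving BP and
BR levels near 0.06–0.07 and 4.6–4.9 mg C m⁻³ d⁻¹. Values are drawn from
seasonal normals clipped at 0.

Couplings are chosen once from those printed statistics:

* `ba_chl_slope = 3×10⁶ cells mL⁻¹ per µg Chl L⁻¹` — the seasonal ΔBA/ΔChl
  implied by the means above; residual BA noise is set so the seasonal BA SD
  stays near its target after the Chl-driven part is removed (floored at 20%
  of the target SD).
* `cs_bp = 0.085 fg C cell⁻¹ d⁻¹` with lognormal noise of log-SD 0.35 —
  the BP/BA ratio of the seasonal means; the noise level is the realism
  constraint that a survey of n ≈ 88 detects the BA–BP association clearly,
  as such surveys do, while keeping BP's coefficient of variation near the
  printed one.
* `BR = 4.7 + 1.0·z₁ + N(0, 1.2)` mg C m⁻³ d⁻¹, where z₁ is the realized
  mean z-scored relative abundance of planted module 1 — BR is independent
  of BP given the module, the planted decoupling. β = 1.0 with noise SD 1.2
  keeps the total BR SD near the printed 1.4–1.8 and gives the per-season
  regression (n ≈ 48) comfortable power.

The community is 120 ASVs with three planted modules of sizes 15/12/10:
log-abundance of ASV i in sample s is `base_i + λ F_{m(i),s} + ε`, with a
shared standard-normal latent factor per module per sample and
λ = √(ρ/(1−ρ))·σ_ε for target intra-module correlation ρ = 0.85. Rows become
proportions and are sampled multinomially at a uniform 50,000–120,000 depth.
A latent-factor scheme is used rather than Dirichlet-multinomial because the
analysis needs direct control of pairwise Spearman structure. 5% of ASVs
(background members) carry chloroplast/mitochondria lineages; removing their
reads pushes some samples below the 49,920 rarefaction depth, so the
sample-dropping path is exercised. Taxonomy labels are drawn from a fixed
pool of the classes and orders typical of these communities (SAR11_clade,
SAR86_clade, Flavobacteriales, Rhodobacterales, Synechococcales, …).

Raw tracer inputs are back-computed by exact inversion of the rate formulas
(leucine from BP; a per-sample bacterial fraction drawn in 0.4–0.8 fixes
INT₀.₂–₀.₈/INT_T, and CR_O₂ → INT_T inverts the calibration), so the rate
stage reproduces the true panel to floating-point precision.

What the generator does **not** emulate: seasonal turnover in community
composition (module factors are season-independent, so PERMANOVA between
seasons on synthetic data is a true null), spatial autocorrelation along
cruise tracks, compositional effects beyond the shared multinomial total,
read-level sequencing error, and any temperature dependence of rates.
Passing tests therefore demonstrate correctness of the statistical machinery
and recoverability of planted effects at survey-realistic sizes — not that
real communities satisfy the generator's assumptions.

## Pipeline

Seasons are analyzed as independent strata (separate networks, module
scores, regressions and PCAs), pooled only for the cross-season Wilcoxon
contrasts and the rate-coupling panel. All randomness flows from named
per-stage seeds; the manifest records the config snapshot, input checksums,
and per-stage counts, and omits timestamps so reruns with identical inputs
and seeds are byte-identical. A failing stage removes its partial outputs
and aborts with a stage-tagged error.

Problem sizes in the test suite and acceptance script — 88 stations,
120 ASVs, 20-seed recovery ensembles, 199–999 permutations — are the
generator's default survey scale, chosen to match the conditions the
analysis is meant for while keeping ensemble checks quick to run.

## Known limitations

* The INT→O₂ calibration is empirical and carried over from its source
  conditions; no uncertainty is propagated through the conversion chain.
* Rarefaction discards data; no variance-stabilizing alternative is offered.
* Hard correlation thresholding ignores edge uncertainty near the cutoff;
  compositional correlation bias (shared multinomial denominator) is not
  corrected (no CLR/SparCC-style treatment).
* Louvain is a heuristic: the partition is seed-deterministic but not
  guaranteed optimal.
* The coupled/decoupled verdict is threshold-based description, sensitive to
  n, and performs no multiplicity correction by default.
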