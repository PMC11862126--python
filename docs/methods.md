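# Methods

This note documents the models, estimators and design choices behind
`proteomelt`, and what the synthetic-data studies do and do not establish.

## Measurement model and preprocessing

One TMT 10-plex set is one melt curve: ten reporter channels correspond to
ten denaturation temperatures (default grid: ten points evenly spanning
37–67 °C; the channel→temperature map is configuration, never inferred from
headers). PSM reporter signals are summed to peptides within a set; missing
channels are treated as absent (a channel missing in all PSMs stays
missing — zero is a valid post-denaturation measurement and is never
conflated with missing).

**Variance-stabilizing normalization.** The VSN model is a per-sample
affine calibration followed by a generalized-log transform:
h(x) = arsinh((x/c_j)/b). Scale factors c_j are robust median-of-ratios
estimates (trimmed mean of log-ratios to a reference profile;
`trim_fraction`, default 0.25), making the transform exactly invariant to
per-sample rescaling. The shared glog parameter b is fitted by a bracketed
1-d search that equalizes mean feature standard deviation between the
bottom and top intensity tertiles — deterministic, no iterative ML. For
x ≫ b the transform behaves like log (flattening multiplicative noise);
near zero it is linear (not inflating additive noise). This is a
deliberate simplification of full maximum-likelihood VSN: it keeps the
variance-flattening contract the pipeline needs while remaining exactly
reproducible.

**Melt profiles.** Fold changes are formed on the ratio scale after
back-transforming to calibrated intensities: profile[t] =
value(t)/value(reference), so the reference channel is exactly 1 and the
downstream melt models operate on "fraction non-denatured". Curves with a
missing or zero reference are dropped with a logged warning. (Whether to
form fold changes on the transformed or ratio scale was an open choice;
the ratio scale is used because the sigmoid models are defined on
fractions.)

## Proteoform-group inference

Genes enter clustering only with ≥ 10 peptides and ≥ 2 peptides in every
sample; all other genes become single groups. Distances between peptides
are weighted Euclidean over the concatenation of all samples' fold-change
vectors (missing positions pairwise-excluded; pairs sharing < 3 positions
get no edge). Position weights are inversely proportional to the
cross-peptide variance at that position within the gene — this
down-weights the noisy high-temperature tail, where fold changes are small
and relative noise large. Weights are renormalized per pair to sum to the
number of shared positions so distances are comparable across missingness
patterns.

The distance→similarity kernel is Gaussian, exp(−d²/2h²), with per-gene
bandwidth h equal to the median pairwise distance. The kernel and weight
scheme are config-swappable; both were chosen as the simplest forms that
separate latent proteoforms at realistic noise while keeping
single-proteoform genes connected (near-uniform similarity graphs, where
modularity maximization correctly returns one community).

Leiden community detection maximizes weighted modularity at resolution 1
with a seeded RNG and a fixed iteration count, so assignments are
deterministic. Gates: modularity Q > 10⁻¹³ and ambiguity ratio r < 0.5
(strict inequalities; r = ambiguous/(specific + ambiguous) at the gene
level), and every community needs ≥ 3 supporting peptides. Communities
below that support are merged into the community with the highest mean
similarity rather than discarded — merging preserves the partition
property (every retained peptide belongs to exactly one group), which the
null-randomization machinery downstream relies on. Labels are
`gene_1, gene_2, …` by descending community size (ties broken by the
lexicographically smallest member peptide).

Group melt curves are built by summing **raw, non-normalized** member
intensities per set, then VSN-normalizing per temperature across groups,
then re-forming fold changes. Summing raw signal keeps the group curve an
intensity-weighted average of its members instead of an average of
per-peptide ratios.

## Differential melting (NPARC)

The melting model is the classic reciprocal-temperature sigmoid
f(T) = (1 − pl)/(1 + exp(b − a/T)) + pl, fitted by bounded least squares
from a small multi-start grid (Tm quantiles of the grid × two steepness
levels; plateau started at the minimum observed fraction). The null model
pools both arms; the alternative fits each arm separately, and each model
is additionally warm-started from the other's optimum so the nested pair
cannot land in inconsistent local minima. Only groups with complete curves
in every (condition × replicate) cell of a comparison scope are tested;
scopes are "all samples" and each cell line separately, with effective
degrees of freedom estimated per scope.

**Effective degrees of freedom and scales.** RSS₀ − RSS₁ and RSS₁ are
modelled as scaled chi-squares whose (dof, scale) are fitted by least
squares on the log-quantiles of the 0.05–0.8 body of their empirical
distributions across all tested groups (median-normalized first, so the
fit is exactly scale-invariant). Two details matter:

- *Per-component scales.* The two components' fitted scales differ in
  practice (the denominator is slightly overdispersed relative to the
  numerator), so the F statistic normalizes each component by its own
  fitted scale: F = ((RSS₀−RSS₁)/σ̂₁²d₁)/(RSS₁/σ̂₂²d₂). Ignoring the
  scale ratio shifts every p-value (simulated null type-I error drops to
  ~0.03 and uniformity fails); with it, null p-values are uniform and the
  type-I error sits at the nominal 5%.
- *Body-only fitting.* Plain method-of-moments is corrupted by true
  positives, which inflate the numerator's mean and variance and crush
  power; fitting only the quantile body identifies the null bulk, keeping
  calibration under the null and near-full power when up to ~20% of the
  screen is truly shifted. Method-of-moments (dof = 2·mean²/var) remains
  the degenerate-input fallback, and nominal counting dof are used (with a
  logged notice) below 50 tested groups.

Significance vocabulary: pAdj < 0.05 "likely thermally impacted",
p < 0.05 "plausibly thermally impacted". 4PL fits for reporting use
curve_fit with first-order error propagation for the 95% band
(t-quantile, residual dof); a singular covariance suppresses the band and
sets a flag.

## Enrichment, motifs, pulldown

ORA entities are proteoform-group IDs mapped to gene symbols: a gene with
k groups contributes k entries to both the hit list and the universe, so
the hypergeometric background reflects each gene's chance of random
identification across its measured proteoform contexts. p-values are
computed as exact rationals (integer binomials) and BH-adjusted; complexes
covering < 3 distinct universe genes are skipped.

Motif scoring is at sequence-presence level (does the protein contain
GCL/GSL/GTL/GYL at least once), because the proportion test compares
fractions of proteins; "any G*L" means G[STCY]L by default (the
phospho-capable and cysteine middle residues), with a fully general G.L
variant by flag. Proportions are compared with the 2-sample equality test
with Yates continuity correction. Pulldown hits require detection in ≥ 2
of 3 drug-probe preparations and zero vehicle detections.

## Cohort analysis

PSM values are VSN-calibrated per TMT set, then summed per grouping on the
calibrated natural scale, then log₂-transformed and median-centered per
patient. Summation on the natural scale (rather than on the glog scale)
keeps a multiplicative treatment effect multiplicative in the group total,
so log₂ abundances carry effects in log₂ units. Replicate samples of one
patient are averaged after normalization.

The null grouping permutes proteoform-group labels within each gene
(uniformly at random, seeded), preserving the peptide universe and each
gene's group-size multiset. The variance screen compares each real group's
across-patient variance to this null. Two constructions are implemented:

- **pooled** (default): the size-matched null groups' variances are
  modelled with the same robust scaled-chi-square body fit used for NPARC
  dof, and each real variance is referred to that parametric null's upper
  tail. This construction is used because (i) a shuffled group shares
  roughly half its peptides with its own real counterpart, so the paired
  per-gene ratio is underdispersed relative to any F distribution, and
  (ii) shuffled groups from genes with true effects inherit part of the
  signal, so a purely empirical pooled percentile loses its small-p
  resolution. The parametric body fit fixes both. Its main assumption is
  comparable measurement noise across same-size groups; under strong
  noise heterogeneity the paired variant is the safer screen.
- **paired**: F = var(real)/var(own null) against F(n−1, n−1), one-sided.

Treatment contrasts are two-sided Wilcoxon rank-sum tests (exact when both
arms ≤ 10 without ties, normal approximation with tie correction
otherwise), run on variance-screen survivors and BH-adjusted. Response
associations are Spearman correlations with Fisher-z confidence intervals
(variance 1.06/(n−3)) computed in three strata — all patients, a
designated subgroup, its complement — with BH within stratum.

## Synthetic-data generators

The TPP generator emulates the reference design: two cell lines × two
arms (drug/vehicle) × technical duplicates, one TMT set per melt curve;
200 genes × 12 peptides by default; 30% of genes carry two latent
proteoforms with baseline melting points 4 °C apart (each proteoform
supported by ≥ 3 peptides); 10% of proteoforms are drug targets shifted
+3 °C in the drug arm. Peptide base abundances are log-normal over ~3
orders of magnitude (to exercise VSN); reporter noise is multiplicative
log-normal (sd 0.05 on the log scale by default — chosen to represent a
clean TMT experiment; the paper-scale data carry no stated noise figure)
with an optional additive floor for low-intensity censoring. Ambiguous
peptides (default 5%) carry a second random gene symbol and are quantified
identically under both genes, as shared peptides are in real searches.

The cohort generator emulates a 68-patient study with 4 ibrutinib
treated/pretreated patients and a 12-patient biologically distinct
subgroup. Group log₂ abundance = gene baseline + treatment effect (1.5
log₂ units on designated groups for treated patients) + subgroup-specific
latent signal for response-correlated groups (target Spearman −0.65
against ex vivo viability) + iid PSM noise (sd 0.4 log₂). Sibling
proteoform groups of one gene share the baseline abundance by default
(`within_gene_base_sd = 0`): with a large between-sibling spread, the
randomized null group's natural-scale sum is dominated by the abundant
sibling's peptides and its noise variance is inflated, which biases the
variance screen conservative — a genuine limitation of
randomized-membership nulls that the parameter makes explorable. Peptide
ionization offsets (sd 0.5 log₂) give PSMs realistic within-group spread;
their effect on the variance screen cancels to first order.

**What the studies do not show.** The generators contain no co-eluting
interferences, missed cleavages, fraction-dependent missingness,
batch/set effects beyond per-channel scaling, or heteroscedastic
biological variance across genes. Passing the recovery and calibration
studies therefore demonstrates correctness of the estimators under the
stated noise models, not performance on raw instrument data; the
headline counts of the original screens (which depend on deposited raw
data and an external search pipeline) are out of desk-scale reach.

## Problem sizes and numerics

Validation studies use 200 simulated genes for clustering recovery, 2000
null screens and 200 targets + 800 null screens for the melting test's
calibration and power, 1000 no-effect groups for the cohort variance
screen, a 30-effect-group cohort for sensitivity, and 100 replicate fits
for 4PL recovery — sizes at which the binomial/KS assertions have
meaningful resolution while a full run stays at minutes on one CPU. All
randomness flows from one root seed through named substreams
(crc32-derived, < 2³¹); identical configurations reproduce byte-identical
result tables. Degenerate inputs are handled explicitly: constant curves
fit with RSS 0 and a degenerate flag, zero null variances give
conservative p = 1 with a flag, RSS₀ < RSS₁ clamps F at 0, and ties in
label ordering break lexicographically.
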