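# Methods

`fmena` implements the analysis chain used in functional-gene-array
(GeoChip-style) comparisons of microbial communities between two groups
of lakes at contrasting elevations: signal preprocessing, group
statistics, permutation tests on dissimilarity matrices, random-matrix-
theory (RMT) based co-occurrence network inference, and node-role /
module–environment analysis. A synthetic-data generator with a ground-
truth ledger exercises every stage without the original microarray
data. This note records the models, the parameters that matter, and the
design choices made where the construction was genuinely open.

## Preprocessing

Raw inputs are probe-by-sample fluorescence intensities with per-cell
signal-to-noise ratios (SNR) and flagged positive-control probes. The
pipeline applies, in enforced order:

1. **Quality filter.** A (probe, sample) cell is detected iff SNR > 2
   (strict; a cell at exactly 2 is removed).
2. **Prevalence filter.** A probe is kept iff detected in at least 2 of
   the 6 samples of at least one lake; for unequal lake sizes the
   threshold generalizes to ceil(30% of the lake's samples).
3. **Normalization.** Each detected cell becomes `ln(x + 1)` and is
   divided by the mean of the *transformed* positive-control values of
   its sample. Transform-then-divide keeps both operands on the same
   scale; the alternative order (divide raw intensities by the raw
   control mean, then `ln(x + 1)`) is available via
   `divide_before_log=True` because the upstream convention is not
   unambiguous. Undetected cells become 0 — richness and relative
   intensities need a complete matrix — and positive controls are
   dropped from the analysis matrix by default.
4. **Relative intensities.** Each sample column is divided by its
   total, so columns sum to 1.
5. **Group difference.** A gene family / subcategory / category is
   summarized as `(S_high / S_low) − 1`, where `S_g` totals the chosen
   intensity over the unit's probes and the group's samples; units with
   `S_low = 0` are flagged rather than divided.

Provenance flags on the matrix objects reject out-of-order composition
(e.g. relative intensities from an un-normalized matrix).

## Group statistics

Detection means "normalized value > 0". Richness counts detected
probes per sample and per group (detected in ≥ 1 group sample); overlap
is set algebra on the two groups' detected sets with percentages on the
union (per-group denominators are also reported, since the published
percentages do not state their denominator). Category, subcategory,
family, and lineage-within-category contrasts test per-sample summed
intensities with a two-sample t test — Welch by default, since group
variances have no reason to be equal; the pooled-variance variant is a
flag. Raw p-values are reported to mirror the source convention, with
optional Benjamini–Hochberg adjustment. Units carried entirely by one
group are reported as group-exclusive instead of tested.

## Dissimilarity tests

Euclidean, Bray–Curtis, and Morisita–Horn ("Horn") distances are
computed on sample profiles of relative intensities. Three permutation
tests run on the distance matrix with free whole-sample label
permutation and the add-observed convention
`p = (1 + #extreme) / (n_perm + 1)`, so p = 0.001 is attainable at 999
permutations:

- **PERMANOVA**: pseudo-F from distance-based sums of squares,
  `SS_total = Σ_{i<j} d²_ij / N`, within-group analogue per group,
  large F extreme. On Euclidean distances of a 1-D response this equals
  the classical one-way ANOVA F (asserted in tests).
- **ANOSIM**: R from mid-ranked distances,
  `R = (mean between-rank − mean within-rank) / (n(n−1)/4)`.
- **MRPP**: δ = Σ_g (n_g/N) · (mean within-group distance), small δ
  extreme.

Small designs can be evaluated by exhaustive enumeration of distinct
labelings (`exact=True`); the sampled and exhaustive paths are checked
against each other and against scikit-bio in the tests. A
lake-stratified permutation scheme is deliberately *not* the default:
the emulated study pooled 12 vs 12 samples across lakes, and the free
scheme reproduces that analysis; users worried about within-lake
pseudo-replication can permute externally.

## RMT network inference

Networks are built per elevation group over the "commonly detected"
genes: categories carbon, nitrogen, and phosphorus cycling plus stress
response, detected in ≥ ceil(0.5 × group samples) samples of that
group. Pearson correlations are computed across the group's samples;
remaining zeros count as true zeros (absence is signal on a functional
array), not missing data.

The similarity threshold *st* is chosen spectrally. For a candidate
*st*, the similarity matrix keeps |r| where |r| ≥ st (zero otherwise,
unit diagonal), restricted to genes with at least one retained
off-diagonal entry (isolated genes only add exact eigenvalue-1
degeneracies). Its eigenvalue nearest-neighbour spacing distribution
(NNSD) is compared to the Poisson law `P(s) = e^(−s)` (decoupled,
modular system) and the Wigner–Dyson/GOE law
`P(s) = (πs/2)·e^(−πs²/4)` (intrinsically correlated system) by a
one-sample Kolmogorov–Smirnov test at α = 0.05 (chi-square with
bin width 0.5 as an option). Verdict: *poisson* when the Poisson law is
not rejected while Wigner is; *goe* for the converse; *ambiguous*
otherwise. Fully decoupled spectra (no surviving genes, or too few
distinct eigenvalues) are classified *poisson* with a degeneracy flag.

**Unfolding.** Exact degeneracies are collapsed, then each level gap is
divided by the mean gap in a sliding window of ±5 levels ("local"
unfolding). Thresholded similarity matrices have sharply multimodal
spectral densities (near-degenerate clusters from many small
components); a global smooth unfolding cannot track them, while the
local rule keeps the mean spacing at 1 ± 0.05 on both GOE and
block-diagonal reference spectra. A Gaussian-broadened empirical
cumulative spectral function and a smoothing-spline fit of the
staircase are available as alternatives.

**Scan rule.** Thresholds are scanned ascending over 0.30–0.99 (step
0.01). The selected st is the smallest grid value with ≥ 50 surviving
genes whose verdict is Poisson, whose next three testable grid values
are also Poisson, and for which ≥ 90% of all higher testable grid
values remain Poisson. The tolerance absorbs isolated goodness-of-fit
fluctuations at single grid points, which would otherwise void every
candidate; requiring literally every successor to stay Poisson is not
robust for finite spectra. A matrix whose off-diagonal entries never
reach the grid minimum is decoupled everywhere and returns the grid
minimum; a matrix with no stable Poisson regime raises a scan error
with diagnostics.

Edges carry sign (from r) and weight |r|; isolated genes are excluded
from the network size n. At 24-sample scale with zero-inflated data the
strict KS criterion often finds no stable Poisson regime (co-absence
cliques distort the extreme-threshold tail); the pipeline then falls
back to a fixed threshold |r| ≥ 0.8 — the fixed-threshold construction
that co-occurrence studies use when spectral selection is impractical —
and records that it did so. RMT selection itself is validated on
planted-block fixtures, where it recovers the planted structure
(partition NMI ≥ 0.9 through threshold selection plus community
detection).

## Topology and null models

All indices are computed on the unweighted, unsigned graph; the sign is
kept only as an edge attribute. Average connectivity avgK = 2L/n;
harmonic geodesic distance HD is the harmonic mean of shortest-path
lengths with disconnected pairs contributing reciprocal 0 (finite HD on
fragmented graphs, matching how the index is used for sparse
co-occurrence networks); avgCC is the mean local clustering coefficient
(degree < 2 contributes 0); transitivity is 3 × triangles / triples.
Modules come from Clauset–Newman–Moore fast greedy modularity
maximization (networkx), deterministic for a given graph; the degree
distribution is summarized by the R² of an OLS fit of log10 frequency
on log10 degree.

Null ensembles (default 100 networks) are degree-preserving — repeated
double-edge swaps, ≥ 10·L successful swaps per network, no self-loops
or multi-edges, the convention of molecular-ecological-network
analysis — or uniform random graphs with the same n and L
(`size_links`). HD, avgCC, and modularity are contrasted by
`Z = (empirical − null mean) / null sd` with a two-sided normal p.

## Node roles and module eigengenes

Within-module degree z-score `Zi = (k_within − mean) / sd` (over the
node's module) and participation coefficient `Pi = 1 − Σ_s (k_is/k_i)²`
classify nodes: network hubs (Zi > 2.5 and Pi > 0.62), module hubs
(Zi > 2.5), connectors (Pi > 0.62), peripherals (neither). Boundary
values fall to the peripheral side (the published inequalities are
strict and leave the boundary unassigned); a module of size 1 or zero
spread gives Zi = 0 with a degeneracy flag. Zi uses within-module
degree, the standard construction of the role framework.

A module eigengene is the first principal component of the module
members' z-scored profiles across samples (SVD; unit-norm gene
loadings), oriented so its mean correlation with the member profiles is
positive; variance explained is reported. "Top modules" are the five
largest by node count (the source ranks modules without stating a
criterion). Eigengenes are correlated with each environmental variable
by Spearman rank correlation (mid-ranks, two-sided p); eigengenes are
computed from normalized (not relative) intensities by default, the
choice being configurable since the source does not state it.

## Synthetic data

The generator emulates the study design — 4 lakes × 6 samples, two
elevation groups — at reduced scale (600 probes + 20 positive
controls). Signals are lognormal (microarray intensities are positive
and right-skewed): probe baselines `mu_g ~ N(6.5, 0.8)` on the log
scale with within-probe noise sd 0.30. Planted structure, recorded in a
truth ledger:

- **Stress enrichment**: stress-response probes gain
  `ln(stress_effect)` in high-group samples; default fold-change 1.5,
  the magnitude of the study's headline single-gene enrichments.
- **Correlation modules**: 12 modules × 10 genes among the four
  network categories, latent-factor construction
  `gene = sqrt(w)·factor + sqrt(1−w)·noise` with per-gene loadings
  jittered ±0.05 around `within_module_r = 0.95`. Many small, strongly
  correlated modules mirror the modular scale of observed co-occurrence
  networks (~10 genes per module at similarity ~0.98); exactly
  equicorrelated blocks are avoided because their thresholded
  components have symmetry-degenerate spectra, an artifact rather than
  a study condition.
- **Group-exclusive probes**: ~7% of probes detectable only in the
  low-elevation group and ~12% only in the high group, with turnover
  balanced within categories and the excess high-group uniqueness
  placed in stress response. This presence/absence turnover is what
  separates the groups in the dissimilarity tests and puts the shared
  fraction in the reported 75–87% range.
- **Environmental driver**: module 1's latent factor is the z-scored
  temperature, so its eigengene should correlate with temperature.
- **Detection**: per-cell Bernoulli (p = 0.9) independent of intensity,
  plus a 10% chance that a detected cell's SNR falls at or below 2;
  positive controls are always detected with a common mean. The
  environment table contrasts temperature, DOC, Chl a, PO4-P, pH, DO,
  turbidity, ORP, and TP between groups in the directions expected
  between warm productive lowland lakes and cold oligotrophic
  high-elevation lakes.

What the generator does **not** emulate: probe cross-hybridization,
scanner artifacts, dye chemistry, ecologically structured (per-lake)
presence/absence, or compositional covariance between categories.
Passing tests therefore demonstrate that the statistical machinery
recovers planted structure under the stated noise model — not that it
would recover every feature of real microarray data. In particular,
random per-cell dropout combined with the zeros-as-true-zeros rule
creates shared-zero correlation cliques at extreme thresholds; this is
why mechanism-recovery tests for the eigengene–environment chain use a
full-detection generator configuration, and why the 24-sample scan
exercises the fixed-threshold fallback.

## Problem sizes and numerical choices

Tests and the acceptance script run at reduced scale chosen to keep the
statistical properties measurable: 600-probe datasets, 120-gene/8-block
correlation fixtures (100 samples for clean correlation estimates),
200-level spectra for NNSD discrimination, 20-seed detection-rate
estimates, and 1,000 null simulations (12 samples, 99 permutations) for
the type-I error of PERMANOVA. Permutation seeds derive from a single
run seed; all random draws use `numpy.random.default_rng`. Eigenvalue
degeneracy collapse uses tolerance 1e-8; tie-breaks (degree ranking) are
lexicographic by gene id; KS comparisons treat the observed statistic as
extreme under a 1e-12 tolerance to keep add-observed counts exact under
floating-point ties.

## Known limitations

- The spacing-based threshold scan is reliable on spectra with hundreds
  of distinct levels and many independent blocks; at 12 samples per
  group and strict KS criteria it frequently has no stable Poisson
  regime, which the pipeline reports rather than hides.
- MRPP is implemented with the unweighted group-size weighting
  `n_g / N`; other weightings exist in the literature.
- The power-law R² is the conventional log–log OLS summary, not a
  maximum-likelihood power-law fit; it is reported for comparability,
  not as evidence of scale-freeness.
- Module–environment correlations on 12 samples have wide sampling
  variability; the driver recovery property holds for the planted
  |rho| ≈ 1 driver, not for weak drivers.
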