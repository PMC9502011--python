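# Methods

`nitronet` implements the statistical chain used to analyse soil bacterial
communities under contrasting nitrogen fertilization regimes — a zero-N
control, controlled-release urea (CRU), and CRU combined with the organic
synergist fulvic acid (FA) — sampled over an incubation time course. This
note documents the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Count-table preprocessing

Samples are rarefied to a common depth by multivariate hypergeometric
subsampling — true subsampling of the observed reads without replacement,
not multinomial resampling — so rarefied tables stay integer-valued and
column sums equal the target depth exactly. Samples below the target depth
are dropped with a warning rather than scaled, because scaling would break
the integrality assumptions of downstream rank statistics. The default
depth is 20,000 reads per sample, the depth at which such amplicon data
sets typically retain Good's coverage above 99%.

Good's coverage is 1 − F1/N with F1 the number of singleton taxa and N the
sample total. Taxonomic aggregation sums counts over taxa sharing a rank
label and pools taxa unclassified at that rank into an explicit
`unclassified` bin, conserving per-sample totals exactly.

The network's node set is defined by a mean relative-abundance filter
(default 1%). "Mean abundance within treatments" is ambiguous between
three readings, all implemented: the default `union` rule keeps a taxon
whose mean exceeds the threshold in *at least one* treatment group, which
maximizes comparability of node sets when networks are contrasted between
treatments; `intersection` and `global` are available via a flag.

## Ordination and ANOSIM

Community dissimilarity is Bray–Curtis, d(i,j) = Σ|x_ik − x_jk| / Σ(x_ik +
x_jk). Principal coordinates analysis double-centers −d²/2 (Gower) and
eigendecomposes. Because Bray–Curtis is not Euclidean-embeddable, negative
eigenvalues can occur: they are retained in the reported eigenvalue list
as a diagnostic but excluded from the proportion-explained denominator,
and no Cailliez correction is applied — the simplest convention, flagged
in the output. Phylogeny-aware distances (UniFrac) are out of scope: the
package models no tree.

ANOSIM uses the rank statistic R = (mean between-group rank − mean
within-group rank)/(M/4), M = n(n−1)/2, with average ranks for ties, and a
seeded permutation p-value under the +1 convention (p is never zero). The
implementation is scikit-bio's, wrapped for seeding and validation; tests
verify it against an independent rank-formula oracle and exhaustive label
enumeration on small instances.

## Co-occurrence network inference

Pairwise associations are Spearman correlations across samples (average
ranks for ties, two-sided p from the t-approximation). Taxa with zero
variance have undefined correlations; these are recorded as missing and
excluded from any network. Edge-wise p-values are adjusted by
Benjamini–Hochberg step-up with a stringent default cutoff q ≤ 0.001
appropriate for the thousands of simultaneous pairs; the adjustment method
is pluggable (Benjamini–Yekutieli, Bonferroni).

### RMT threshold selection

The hard correlation cutoff is chosen by random-matrix-theory spectral
statistics. The principle: the nearest-neighbour spacing distribution
(NNSD) of unfolded eigenvalues of a dense noise-dominated correlation
matrix follows Wigner–Dyson (GOE) statistics with level repulsion, whereas
a matrix whose surviving entries form effectively independent diagonal
blocks — genuine modular structure — shows Poisson spacing P(s) = e^(−s).
Scanning the cutoff upward, the transition from GOE to Poisson marks the
point where random correlations have been removed.

Procedure per candidate cutoff t: zero |ρ| < t (unit diagonal kept),
eigendecompose, unfold, histogram the spacings into ⌈√m⌉ bins and test
against the exponential law by chi-square (degrees of freedom = bins − 2).
Numerical choices that matter:

- **Unfolding**: the cumulative spectral density is smoothed with a
  polynomial of configurable order (default 5) fit to the sorted
  eigenvalues; spacings are differences of the unfolded levels, normalized
  to mean 1. Nonpositive spacings from local non-monotonicity of the fit
  are discarded.
- **Degenerate levels**: numerically equal eigenvalues are collapsed
  before unfolding; a spectrum with too few distinct levels (fewer than 12)
  cannot be tested and the candidate is marked inconsistent.
- **Bulk statistics**: detached outlier eigenvalues (module and global
  factors far above the bulk) distort the polynomial fit badly. Outliers
  whose gap from the remaining spectrum exceeds 10× the median gap are
  trimmed from either end, capped at 20% of the spectrum, before
  unfolding. Spacing statistics are a property of the bulk.
- **Sustained transition**: the selected cutoff is the smallest t that is
  Poisson-consistent (chi-square p > 0.05) at t *and at the next two grid
  points*. On matrices of a few dozen taxa the chi-square test has limited
  power, and a single chance acceptance below the true transition would
  otherwise terminate the scan early; requiring a sustained run makes the
  scan stable across seeds without changing what it estimates.

If no candidate passes, the scan raises with an instruction to extend the
grid — an identity-like spectrum (no transition anywhere) lands here.

### Network construction and modules

Edges connect pairs with |ρ| ≥ threshold and q ≤ q_cut. Negative
correlations are kept as signed edges (the threshold applies to the
magnitude): disrupted and mutualistic linkages are both ecologically
informative. Isolated nodes are retained and flagged. Module detection is
Louvain modularity maximization on |ρ| weights (seeded; ties broken by
node identifier), with modules ranked by size and named Mod1..Modk.
Per-sample module abundance is the sum of member-taxon relative
abundances. The default pipeline builds one network on all samples
jointly — a single module partition is needed for module–environment
association — and additionally recomputes per-treatment edge statistics
(node/edge/sign counts, mean degree) at the same threshold for
between-treatment comparison.

## Association analyses

Module–environment relations are Pearson correlations between per-sample
module abundances and each environmental factor, starred at p < 0.05 /
0.01 / 0.001 (boundary values get the weaker star). Factor-by-factor
panels conventionally use Spearman; both are available via `method=`.

Differential taxa between two treatments are called per OTU by Welch's t
on log-transformed relative abundance with a pseudo-fraction of half the
smallest nonzero value, BH-adjusted within the tested set. With three
replicates per group a rank test cannot reach q ≤ 0.05 at all, which is
why a parametric test on log abundances is the default; the output table
carries −log10(p), module and phylum columns ready for Manhattan-style
display. Under a complete null the caller's empirical false-discovery
rate is verified to stay at or below the nominal α.

Mantel tests correlate vectorized off-diagonal distances, with a
one-sided seeded permutation p (+1 convention). The partial Mantel
statistic is the Pearson correlation of residuals after regressing both
vectorized matrices on the vectorized conditioning matrix; a conditioner
that explains either matrix completely yields a partial r of 0 by
convention. In a single-incubator time course there is no geography to
correct for, so the default conditioning matrix is the day-difference
matrix |d_i − d_j|. Guild-level community distances restrict the table to
the genera of one functional guild (ammonia oxidizers, nitrifiers,
denitrifiers, N-fixers) before computing Bray–Curtis; the genus→guild map
is user-supplied, with an example file
(`src/nitronet/data/guilds_example.tsv`) covering genera repeatedly
implicated in these processes. Environmental-factor distances are
Euclidean on the z-standardized single factor (population SD).

## Agronomic statistics

Fertilizer-efficiency indices from a pot experiment with a zero-N
control: NUE (%) = (AN − AN0)/SN × 100, NAE = (GN − GN0)/SN, NPE =
(YN − YN0)/(AN − AN0), with AN/AN0 plant N uptake with and without
fertilizer, SN the fertilizer N dose, GN/YN grain weight and yield. NPE
is reported missing when AN = AN0. Percent changes versus a reference
treatment are rounded half-up to one decimal, matching agronomic
reporting practice; raw values are kept alongside, and percent changes
are always computed on unrounded means.

Treatment means are separated by one-way ANOVA followed by Duncan's
multiple range test: groups ordered by mean, critical range for a span of
p means q*(α_p, p, df_error)·√(MSE/n_h) with protection level α_p = 1 −
(1 − α)^(p−1) and n_h the harmonic mean group size. Studentized-range
quantiles come from `scipy.stats.studentized_range`, not printed tables.
Letters mark maximal runs of mutually non-separated adjacent means;
groups sharing a letter are not separated. Duncan's test is less
conservative than Tukey's HSD at equal α, which the tests verify as a
coarsening property.

## Synthetic data generator

The generator emulates the study design — by default 3 treatments × 4
sampling days (1, 7, 30, 60) × 3 replicates = 36 samples of 20,000 reads,
300 taxa in 5 modules — with known ground truth. Taxon log-abundances
follow a module-factor model: z_t = √ρ_w·f_m + √(1−ρ_w)·ε_t with ρ_w the
target within-module latent correlation (default 0.8), and f_m a
unit-variance Gaussian per sample centered on a treatment-by-day shift
(modules alternate direction; the shift grows with day and treatment
intensity, scaled by `module_effect`, so 0 gives a null community).
Log-abundances are softmax-normalized, perturbed by a Dirichlet draw
(concentration = `dispersion` × expectation, default 2000, modelling
replicate-level compositional noise), and closed by a multinomial of
exactly `depth` reads. Environmental factors are linear combinations of
per-sample module relative abundances plus N(0, `env_noise_sd`) noise,
with a twelve-factor vocabulary (leachate, soil and pot NO3⁻/NH4⁺/pH,
NUE, yield). Agronomic records are Gaussian around stated treatment
means: yields and biomass follow a realistic winter-wheat pot experiment
(37.6/81.6/99.6 g pot⁻¹ grain for control/CRU/CRU+FA); the fertilizer
dose (6.3 g N pot⁻¹) and uptake means place NUE in the 30–50% and NAE in
the 7–10 kg kg⁻¹ range typical of such trials. Replicate noise defaults
to a 3% coefficient of variation; the study replicate variance is not
published, so this is a free parameter chosen once as realistic rather
than calibrated.

One integer seed drives everything through deterministic per-stage
substreams, so identical configurations reproduce byte-identical outputs.

What the generator does **not** emulate: sequence-level artifacts
(chimeras, denoising), phylogenetic signal, sparsity patterns of real OTU
tables (zero inflation beyond what the multinomial induces),
taxon-specific dispersion, or compositional effects stronger than the
Dirichlet closure. Passing recovery tests therefore demonstrate that the
inference chain is correct under its own model assumptions — not that
those assumptions hold for any particular real community.

## Problem sizes and determinism

Default problem sizes (36 samples, 300 taxa, depth 20,000, RMT grid
0.30–0.95 in steps of 0.01, 9,999 Mantel and 999 ANOSIM permutations)
complete in a few minutes on one CPU; the test suite uses scaled-down
variants of the same conditions. Every stochastic component takes an
explicit seed, and the pipeline manifest records the seed, parameter
values, package version and input checksums of each run.

## Known limitations

- Spearman co-occurrence on relative abundances is not
  compositional-aware; SparCC/SPIEC-EASI-style estimators are explicit
  non-goals.
- The RMT chi-square test has limited power below ~30 distinct
  eigenvalues; the scan requires at least 12 and refuses degenerate
  spectra rather than guessing.
- Welch's t on n = 3 log abundances is approximate; its null behaviour is
  verified empirically in the test suite, but heavy-tailed real data may
  deviate.
- Duncan's test controls the comparisonwise, not familywise, error rate —
  that is its definition, not a defect, but letters should be read
  accordingly.
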