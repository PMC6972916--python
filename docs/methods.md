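# Methods

This note documents the models and estimators implemented in `cfmarrow`,
the default parameters and why they were chosen, and what the synthetic
data do and do not emulate.

## The measurement model

A bulk cf-mRNA (or whole-blood, or buffy-coat) transcriptome is treated as
a non-negative mixture of cell-type expression profiles. With `S` the
cell-type × gene matrix of TPM-normalized profiles and `p` the vector of
cell-type proportions (p ≥ 0, Σp = 1), the expected sample is `x = Sᵀp`,
rescaled so that each sample sums to 10⁶ (TPM). All downstream estimators
are built against this model.

TPM is compositional: a lineage shutting down raises every other gene's
share even at constant absolute output. The time-course generator
deliberately renormalizes each day's mixture to TPM so that trajectory
summaries face the same compositional distortion real cf-mRNA data do.

## Synthetic data generators

The generators exist so that every pipeline stage can be tested against a
known ground truth. Their defaults define the study conditions used
throughout the test suite and the acceptance script.

**Reference profiles.** 1000 genes × 6 cell types; non-marker expression is
log-normal with median 30 (TPM scale) and σ = 0.5 on the natural-log scale
— a minimal model of the heavy-tailed expression distributions in atlas
data. Each cell type gets 30 planted markers whose expression in their own
type is exactly `marker_fold` (default 50) times the maximum over the other
types. The planted value is nudged down by at most a few ulps so the
*computed* ratio never exceeds `marker_fold` through floating-point
rounding; a boundary fold of exactly 20 therefore never passes the strict
">20" specificity rule.

**Mixtures.** Proportion-weighted sums of TPM-normalized profiles. Noise
models: `none` (the exact expectation), `multinomial` (read resampling at
`read_depth`, default 10⁶ — the dominant noise source in counting assays),
and `lognormal` (mean-one multiplicative noise, σ default 0.5). The
noiseless output is the exact expectation of the multinomial mode and, up
to a renormalization bias that is an order of magnitude below Monte-Carlo
error at the default sizes, of the log-normal mode.

**Lineage trajectories.** Per-lineage activity is piecewise: plateau at
`pre_level` until `ablation_day` (default −2, when conditioning
chemotherapy starts), log-linear decay to `nadir_level` at `recovery_day`,
then exponential recovery at `recovery_rate`/day capped at the pre-ablation
level. A nadir of exactly zero decays linearly to zero; recovery from zero
restarts from 10⁻³ × `pre_level`, standing in for graft reseeding of an
extinguished lineage (an exponential cannot leave an exact zero).

**Ig repertoires.** A planted clone takes `clone_fraction` of the read
mass (split equally over its segments); the remaining mass is spread
uniformly over *all* segments, clone included, so a clone at fraction 0 is
exactly one of `repertoire_size + n_clone` exchangeable segments. Counts
are multinomial at `total_reads` (default 10⁴) per day.

**SNP allele counts.** Reference-allele frequency at a SNP is
`(1−m)·f_host + m·f_donor` with f ∈ {1, 0.5, 0} for hom-ref/het/hom-alt and
`m` the donor fraction of marrow output; a symmetric per-read miscall
probability (default 0.01) shrinks frequencies toward 0.5; counts are
binomial at `depth` reads (default 200).

**Determinism.** One global seed expands into fixed per-operation
substreams (`SeedSequence([seed, crc32(op)])`), so identical configuration
and seed give bitwise-identical outputs and stages can be regenerated
independently.

What the generators do *not* emulate: fragment-level effects (length/GC
bias, degradation), batch effects, between-subject biological variability,
correlated noise across genes, RNA editing, or alignment artifacts.
Passing tests demonstrate correctness of the estimators under the stated
models, not performance on real cf-mRNA.

## Signature calling

A gene is specific to an entity when its expression there is strictly more
than `fold_threshold` (default 20) times its expression in every other
entity. Ties for the top entity yield no call (the rule needs a unique
top). `min_top_expression` (default 1 TPM) suppresses calls on genes
expressed at trace levels everywhere, where the ratio is numerically
unstable. Pairwise enrichment uses `(a + pc)/(b + pc) > 5` with a default
pseudocount of 0.1 TPM so the rule is defined at zero expression; setting
the pseudocount to 0 restores strict ratio behavior with infinite fold on
zero denominators.

## Deconvolution

**NMF route.** Genes below 20 TPM in every sample are removed; each
remaining gene is divided by its row maximum (every row peaks at 1), which
puts genes on a comparable scale so the factorization captures shared
patterns rather than absolute levels. The factorization uses
coordinate-descent NMF (scikit-learn) with the deterministic `nndsvda`
initialization. Coordinate descent was chosen over multiplicative updates
because it reaches near-exact factorizations of exactly low-rank input
(relative error < 10⁻⁶ within the default 20 000-iteration budget, ~1.5 s
at the default problem size) where multiplicative updates stall around
10⁻³; the Frobenius objective is non-increasing either way, and
non-convergence is reported via a flag, never raised. When the rank is not
known, `select_rank` scores each rank in the configured 8–12 window by
RMSE on a 10% held-out entry mask and reports all per-rank errors.

Components are annotated by majority vote of the specificity calls among
their `top_n` (default 25) highest-loading genes; the winning entity must
hold more than `min_fraction` (default 0.5) of `top_n`, else the component
stays "unannotated". Vote tallies are retained as evidence. Per-sample
contributions are the activity columns normalized to sum 1, aggregated by
annotation label.

**QP route.** Fractions solve min ‖x − Sᵀp‖² s.t. p ≥ 0, Σp = 1. The
implementation first runs an unconstrained NNLS to estimate the sample's
total mass in signature units and rescales the sample accordingly — this
makes the estimate invariant to rescaling the sample alone (a sub-vector
of a TPM profile is not itself TPM-complete). The simplex constraint is
then imposed through an augmented row with weight 10³ × the mean signature
magnitude inside a second NNLS solve, and the result is renormalized to
sum exactly 1. On noiseless identifiable mixtures this recovers the true
proportions to machine precision; rank-deficient signatures are flagged
with a warning but still solved. The gene set for QP should be the
specific-gene signature restricted to genes detected in the sample.

## Time-course analysis

Selection keeps genes with max > 50 TPM across days and
(max + pc)/(min + pc) > 5 with pseudocount 1 TPM (the ratio is undefined at
min = 0 without it; `ratio_pseudocount=0` gives strict behavior with zeros
treated as infinite ratio). Max-normalized profiles are clustered with
seeded k-means (default k = 8, 10 restarts) or average-linkage hierarchical
clustering on Euclidean distance, cut to the same k.

Lineage trajectories express each gene relative to its own level at
`reference_day` (ratio, or 100 × (ratio − 1) percent change) and average
arithmetically across genes; the arithmetic mean of per-gene ratios was
chosen over the ratio of means so each gene contributes equally regardless
of abundance (a geometric-mean option exists since the conventions differ
across figures in the field). Genes undetected at the reference day are
excluded and logged by default (optionally floored at 1 TPM); an optional
cap (preset 5000 TPM) excludes very abundant transcripts so a handful of
hemoglobin-scale genes cannot dominate the average.

## Repertoire analysis

Relative abundance is reads on a segment over total Ig reads in scope;
the default scope normalizes within each Ig class (heavy-variable
separately from kappa-variable, etc.), matching how repertoire panels are
drawn. Zero-read scopes yield NaN fractions, never silent zeros.

"Dominant" is not standardized in the literature, so the call is an
explicit dual criterion: fraction > 0.5 OR > 5 × the second-ranked segment
of the class, with at least 100 reads in the class (below that, a single
stray read can fake dominance). Both triggers are recorded per call so the
evidence is reviewable. Clone tracking sums the clone's segment fractions
per day; the loss-of-dominance day is the first day after which dominance
never recurs within the series.

## Chimerism analysis

Genotypes are called from reference-allele frequency with an inclusive
0.9 threshold (≥ 0.9 hom-ref; alt-frequency ≥ 0.9 hom-alt; otherwise het)
and a minimum depth of 10 informative reads, below which calls are
"ambiguous". The hom-alt comparison is written as `1 − f ≥ threshold`
rather than `f ≤ 1 − threshold` so the two homozygous boundaries are
exactly symmetric in floating point (3/30 reads must classify like
27/30). At depth 30 and 1% miscall error the exact per-draw
misclassification probability is ≈ 2 × 10⁻⁴ for homozygotes and ≈ 10⁻⁵
for heterozygotes, so thousands of draws typically classify without error.

The pre-transplant consensus is the majority non-ambiguous call over
pre-transplant days (ties → indeterminate). The post-transplant consensus
is the call held over the final run of ≥ 2 consecutive informative days,
and the transition day is the first post-transplant day starting such a
run — the two-day persistence requirement suppresses single-day flips from
variable cf-mRNA depth. Averaged trajectories are arithmetic means over
SNPs with defined frequency per day, with days lacking informative SNPs
flagged rather than imputed.

## Rank-sum test

For groups both ≤ 8 the test enumerates all C(n₁+n₂, n₁) assignments of
the pooled mid-ranked observations — a permutation-exact two-sided
p-value that handles ties. Larger groups use the normal approximation
with tie-corrected variance and a continuity correction. The headline
statistic is the signed standardized z = (U − n₁n₂/2)/σ (positive when
group 1 tends larger), reported alongside the raw U, since published
"U" values in this area are typically of z-score magnitude. Calibration:
empirical type-I error at nominal 0.05 sits within [0.03, 0.07] in the
acceptance run's 2000 null simulations.

## Problem sizes

The test suite and acceptance script run at the generators' default sizes:
1000-gene references with 6 cell types, 24-sample mixture panels, 21-day
time grids, 10⁴-read Ig repertoires over ~13 days, and 50-SNP panels at
depth 200 over 21 days; Monte-Carlo stages use 20–250 replicates. These
sizes keep every stage's sampling error well below the tested tolerances
while completing in seconds.

## Known limitations

- Component annotation automates only the expression-evidence criterion;
  ontology-based evidence integration is out of scope and annotation of
  components lacking marker genes will return "unannotated".
- The QP estimator assumes the signature spans the sample; material
  contributions from cell types absent in the signature inflate the
  residual and bias fractions upward for correlated signatures.
- Fold-change trajectories on TPM confound absolute lineage activity with
  compositional renormalization; interpretation should lean on relative
  timing (nadir, recovery onset) rather than absolute fold values.
- Genotype transition detection assumes a stable post-transplant state is
  reached within the observed series; incomplete chimerism with m
  fluctuating near a call boundary can defer the transition day or return
  "indeterminate".
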