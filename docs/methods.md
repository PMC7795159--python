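# Methods

This note records the models, conventions and numerical choices behind
`tepomics`, in the spirit of a statistical methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort model

The generator emulates a two-group platelet profiling study: group `A`
(PDAC-like) and group `B` (benign-like), 11 samples per group, with the
protein layer restricted to 8 of the group-A samples to mirror a proteomics
subset.  Per layer:

* **Library sizes** are log-normal, `log L ~ N(lib_size_log_mean,
  lib_size_log_sd)`; defaults log(1e5) and 0.3.
* **Counts** are negative binomial via a gamma–Poisson mixture: feature `f`
  in sample `s` is `Poisson(L_s · rel_f · mult_{f,s} · G_{f,s})` with
  `G ~ Gamma(1/φ, φ)` (so variance is `μ + φμ²`); the common dispersion
  default is φ = 0.1, a typical bulk-RNA-seq value.  Relative abundances
  `rel_f` are normalized log-normals (SD 1 on the log scale).
* **Planted fold changes**: a fraction `frac_de` (default 0.1) of features
  per layer multiplies the group-B mean by `2^(±planted_lfc)` (default
  magnitude 2).  Ground truth stores the signed log2FC in the A-over-B
  convention.
* **miRNA → mRNA repression.** A module of `n_regulators = 8` miRNAs shares
  a correlated biological factor (Gaussian copula on the gamma mixing
  variables, equicorrelation 0.8 — a co-regulated miRNA cluster).  The hub
  transcript's mean is damped by `exp(-β · z̄)` where `z̄` is the
  standardized mean log biological factor of the module and β =
  `repression_beta` (default 1.5).  Four further solo repressor miRNAs each
  damp two targets of their own through their individual `z`.  Coupling
  acts on the *within-cohort biological variation* (the gamma factors); the
  *between-group* consequence of repression is planted separately as an
  explicit fold change on the targets (hub down in A, solo targets opposite
  to their repressor).  Conflating the two — standardizing `z` over a
  vector that already contains the planted group shift — leaves almost no
  within-group variance for the correlation analysis to detect, so the two
  mechanisms are kept orthogonal by construction.  Couplings are planted on
  transcripts from the upper half of relative abundance: repression of a
  transcript observed at a handful of counts is invisible to sample-wise
  correlation, and a truth object that cannot be recovered even in
  principle is useless for testing.
* **mRNA → protein coupling**: protein log-means are
  `protein_coupling · z_g + ε`, with `z_g` the standardized log biological
  abundance of the cognate mRNA and `ε ~ N(0, 0.5)`; default coupling 0.7.
* **isomiR features** (expression layer) share their parent's biological
  factor and fold change, with log-normal relative weights; four isomiR
  features per miRNA, classes drawn from the average of the group mixtures.
* **Reads.** Small-RNA reads draw a miRNA uniformly and a class from the
  group's mixture, then apply the class's modification (templated
  trims/extensions, uniform non-templated tails, internal substitutions,
  trim-plus-tail for `mv`).  When a class is impossible on the drawn miRNA
  (e.g. `nta#G` against a 3′ flank starting with G, which would read as a
  templated extension) the *miRNA* is redrawn and the class kept, so class
  fractions track the mixture exactly.  Default mixtures encode the
  qualitative group difference — benign-like reads rich in `nta#G`,
  PDAC-like reads rich in `lv3p` and `nta#T` — and are fully configurable;
  no quantitative mixture is published, so these are design choices.

**What the generator does not emulate**: sequencing error and quality
strings, adapter contamination, mapping ambiguity beyond sequence identity,
multi-isoform gene structure, batch effects, covariates (age/sex/stage),
and the compositional artifacts of real spectral counting.  Tests passing
on this generator therefore demonstrate correctness of the pipeline's
statistics and bookkeeping under its stated model, not robustness to
real-data pathologies.

## IsomiR classification

A read is anchored against `mature ± flanks` over all 5′/3′ offsets within
`max_offset` (default 3 nt).  Candidate anchorings are scored by the
lexicographic cost `(tail length, substitutions, |o5|+|o3|, o5, o3)` —
templated explanations always beat non-templated ones, fewer substitutions
beat more, smaller shifts beat larger, and the final two components make
ties deterministic.  Substitutions (≤ `max_subs`, default 1) are admissible
only strictly inside the mature body: core ends and flank-templated
positions must match the template exactly, otherwise a mismatched templated
extension would masquerade as a cheaper explanation of a non-templated
tail.  Classes follow the priority: exact → `canonical`; substitutions
only → `nve`; uniform-base tail on canonical ends → `nta#X` (tail reported
in DNA alphabet); single-end shift → `lv5p`/`lv3p`; both ends →
`mlv5p` if |o5| ≥ |o3| else `mlv3p` (ties to 5′); anything else → `mv`.
Reads under 15 nt or without an admissible anchoring are no-calls, tallied
per sample, never forced into `mv`.  Multi-parent reads go to the parent
with the lowest cost, ties broken lexicographically by name, with the
ambiguity counted.  An 8-mer index prefilters candidate parents; reads with
no k-mer hit fall back to a full scan, so the index cannot cause missed
calls.

Class frequencies are abundance-weighted (CPM mass per class among the
isomiRs of the chosen DE miRNAs, per group); heatmap-style expression values
are `log2(mean CPM + 1)` — the pseudo-count avoids −∞ on absent classes.

## Filtering and TMM

The presence filter keeps a feature with CPM ≥ `min_cpm` (1) in strictly
more than `min_frac` (0.40) of all samples.  The black-and-white rescue is
read strictly: the non-expressing group must be all zero and the expressing
("positive") group may contain at most `bw_max_zero_frac` (0.18) zero
samples; a switch (`require_other_all_zero=False`) relaxes the first clause
for data where a stray sub-threshold count should not veto the rescue.

TMM follows the standard construction: reference sample = closest 75th
CPM percentile to the mean percentile; per sample, over features nonzero in
both, M = log2 ratio of library proportions and A = mean log2 proportion
are doubly trimmed (30 % per M tail, 5 % per A tail, rank-based) and
averaged with inverse asymptotic-variance weights
`1/((N−y)/(Ny)_sample + (N−y)/(Ny)_ref)`; factors are rescaled to geometric
mean 1 so CPMs stay comparable.  Fewer than `min_features` (default 10)
usable features yields factor 1 with a warning; the parameter is exposed
because deliberately tiny matrices (oracle toys) are legitimate inputs.
The protein layer bypasses CPM/TMM — its test conditions on per-sample
totals — and gets a median-scaling helper for reporting only.

## Differential expression

*Count layers.* The common NB dispersion is estimated by the method of
moments on counts rescaled to the geometric-mean effective library:
`φ̂ = max(0, mean_f,g (s² − μ)/μ²)` over within-group statistics.  This
replaces conditional-ML/empirical-Bayes machinery deliberately: it is
simple, transparent, and accurate at the feature counts used here; there is
no per-feature moderation.  The exact test rescales counts linearly to the
common library and rounds (a simplification of quantile-adjusted
pseudo-counts, documented as an approximation), then computes the
conditional two-sided p-value: given total S, the group sums are NB with
sizes `n_g/φ` and proportional means, and p sums the probabilities of all
splits no more likely than the observed one (minimum-likelihood ordering,
1e-10 log-tolerance for float ties; φ = 0 reduces to the conditional
binomial).  log2FC uses group-mean normalized CPM with a 0.5 pseudo-count.
Flags: p < 0.05 and |log2FC| > 1, on raw p-values; a Benjamini–Hochberg
column is emitted for reference only.

*Protein layer.* Unpaired beta-binomial likelihood ratio: H0 one success
probability μ for all samples, H1 group-specific μ with shared
overdispersion ρ, parametrized `a = μ(1−ρ)/ρ`, `b = (1−μ)(1−ρ)/ρ`; MLEs by
bounded L-BFGS-B (bounds 1e-8 away from the boundary) with a clipped
Nelder–Mead fallback; non-convergence yields NaN with a logged diagnostic,
never a silent value.  The LR statistic is referred to **F(1, N−3)** rather
than χ²(1): with ~19 samples and an estimated dispersion the χ² reference
is anticonservative, and the F reference on residual degrees of freedom
(the quasi-likelihood convention) restores the nominal level.  A paired
inverted-beta-binomial variant was not implemented because the 8-vs-11
design is unpaired.

## Expected-correlation networks

Correlations are Pearson (Spearman by config) on **log2(CPM + 1)** values:
Pearson on raw CPM of overdispersed counts is dominated by single outlying
samples.  Edges require p < α (0.05) from the t transform
`t = r√((n−2)/(1−r²))` and the expected sign (miRNA→gene negative,
gene→protein positive); gene–protein pairs use only samples present in both
layers; zero-variance features are skipped with a log entry.  Candidate
features default to each layer's DE set (networks built downstream of the
differential analysis); an all-filtered-features mode exists for
null-calibration and recovery studies where DE status is irrelevant or
absent.  Node degree counts incident edges; the top transcript breaks
degree ties by total |r| (a genuine hub carries stronger edges than a node
reaching the same degree through marginal correlations) and then by id.
The hub question for a group's isomiR networks is asked on degree pooled
over its two isomiR networks (`top_transcript_pooled`), since the hub's
regulators reach it through both gene layers; the per-network ranking is
also available.  The cross-network core is the strict intersection of
transcript node sets over the four same-group networks.  IsomiR nodes can
be collapsed to parent miRNAs for display while edges stay per-isomiR.

## Enrichment

Ranking statistic: `−log10(p) · sign(log2FC)` with p floored at 1e-300.
The enrichment score is the signed extremum of the weighted KS running sum
(member increments `|stat|^w / Σ|stat|^w` with w = 1, non-member decrements
`1/(N − n_set)`); extremes occur only at member positions, so the scan is
O(n_set) given positions, and a brute-force running sum serves as the test
oracle.  Permutation null: redraw set positions uniformly (gene-label
permutation preserving set size), `p = (1 + #{|ES_b| ≥ |ES|, same sign}) /
(1 + #{same-sign perms})`, `NES = ES / mean(|ES_b| same sign)`; n_perm
default 1000, seeded.  The miRNA layer uses the upper-tail hypergeometric
over-representation test; its significant terms carry a fixed NES of ±1.5
into the integration (the convention for injecting rank-free results into
an NES-based summary), signed by the mean log2FC of the hit miRNAs in the
set.  The cross-layer overlap keeps terms significant (raw p < 0.05 by
default; a BH switch exists) in every provided layer, annotated with
per-layer direction.

## Pipeline and problem sizes

Stages communicate through fixed file names in a working directory, every
TSV carries a provenance header (seed, config hash — the hash excludes the
output path), and the manifest is deterministic byte-for-byte under a fixed
seed.  The simulate-mode defaults (60 miRNAs, 4 isomiRs each, 300 mRNAs,
120 introns, 150 proteins, libraries ~1e5, 2 000 reads per sample) are the
package's desk-scale study conditions: large enough for calibrated tests
and stable recovery, small enough that the full workflow and the
reproduction script run in seconds to minutes on one core.  Recovery and
calibration analyses in the test suite use the same conditions at 30/80/40/40
features.

Estimator-quality measurements (sensitivity, direction accuracy) are made
on planted DE features that are *not* repression targets: targets carry
extra coupling variance by design, so their realized group difference is
not the clean planted fold change, and including them would conflate the
fold-change estimator with the coupling mechanism.

## Known limitations

* The common-dispersion exact test has no per-feature dispersion
  moderation; features with atypical dispersion are mis-calibrated in
  either direction.
* The beta-binomial F calibration is an approximation; at much smaller
  sample counts a parametric bootstrap would be preferable.
* Network edges use raw p < 0.05 per pair (by design, matching the
  workflow this implements); with thousands of candidate features the
  expected number of chance edges is substantial, and degree rankings at
  n = 11 samples have a heavy chance tail — the hub analyses here
  quantify, rather than eliminate, that behavior.
* GO-style sets are taken flat from GMT files; no ontology-graph
  propagation.
* 5′ non-templated additions are not a distinct class; such reads fall
  into `mv` or no-call.
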