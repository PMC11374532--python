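# Methods

## Study design being modelled

Two arms — control (C) and treatment (T) — sampled at days 0, 1, 2, 4, 8
with three biological replicates per (arm, day) cell and a single shared
baseline: day 0 exists only in the control arm, so both the natural (NS,
C_d vs C0) and treatment-induced (TS, T_d vs C0) contrast families compare
against the same C0 group.  With four post-baseline days that is 27 samples.

## Synthetic data generator

Counts are negative binomial with Var = μ + αμ² (default dispersion
α = 0.1), gene baseline means log-normal (location 4.0, scale 1.0 on the
natural-log scale, median ≈ 55 counts), and multiplicative library-size
factors log-normal(0, 0.15) recorded in the truth labels.  Genes are drawn
into five classes whose noise-free mean patterns land exactly in the Venn
regions the VDEG screen distinguishes (the class-separation test checks this
analytically on the generative means): `null` constant; `ns_equal` the same
post-baseline step in both arms (region d — must never be called);
`cppu_only` a step only in T (region f); `ns_suppressed` a step only in C
(region e); `both_diff` steps of +`effect_lfc` in C and +2·`effect_lfc` in T
(region g).  The default effect is 2.0 log2 units, the step applied at all
post-baseline days.  `both_diff` uses (+e, +2e) rather than a sub-threshold
C-arm effect so that membership in all three per-day DEG sets is guaranteed
at realistic power; otherwise class-g genes leak into class f whenever the
NS test misses a borderline effect.

TF genes (the first `n_tfs` ids) follow per-day Gaussian random walks
(σ = 1.0 log2 units per step) instead of a class pattern; about half walk
identically in both arms, the rest independently, so TFs are informative for
network inference and some become treatment-responsive.  Planted TF→target
edges set the target's per-sample log2 mean to an intercept plus
`coefficient` (default 3.0) times the TF's standardized log2 expression plus
N(0, 0.25) noise, then re-draw NB counts.

Promoters are 2000 bp of i.i.d. uniform ACGT ending immediately 5' of the
ATG.  Planted consensus motifs are written at recorded ATG-relative
coordinates and strands; every other occurrence of any library consensus (on
either strand) is removed by local resampling, so consensus scans recover
exactly the recorded sites with zero false positives.  What the generator
does **not** emulate: read-level artefacts, isoforms, GC/length bias, batch
effects, non-uniform promoter composition, motif degeneracy in the planted
sites.  Passing tests therefore demonstrate correctness of the algebra,
calibration of the statistics and recoverability under the stated model —
not robustness to those real-data complications.

## Differential expression

Median-of-ratios size factors use genes with nonzero counts in every sample.
Per-gene dispersion is a method-of-moments estimate on normalized counts,
pooled within replicate groups — α̂ = max(0, (s² − μ̄)/μ̄²) with s² the
within-group pooled variance — shrunk toward a prior with weight
n_prior/(n_prior + n_reps) (default n_prior = 5).  Two numerical choices
matter at three replicates and were validated on all-null simulations:

* the prior is the mean of the gene-wise estimates with only the **top 1%**
  trimmed.  The gene-wise estimator is clipped at zero and right-skewed, so
  a conventional symmetric trimmed mean sits well below the true dispersion
  (≈ 0.086 at a true 0.1) and makes the Wald test anticonservative;
* shrunken values are floored at the prior (one-sided shrinkage): at n = 3 a
  below-prior moment estimate is noise, not evidence of low dispersion, and
  trusting it inflates the type-I error (raw p < 0.05 fraction ≈ 0.062
  without the floor, ≈ 0.047 with it, across seeds at the 0.05 nominal
  level).  Genes may only look more dispersed than the consensus, never
  less.  Both behaviours are configurable.

The Wald test compares normalized group means with a pseudo-count of 0.5 per
group mean, the delta-method variance of the log ratio
(Var(m̂) = n⁻² Σᵢ (μ/sᵢ + αμ²) per group), and a two-sided normal p-value;
Benjamini–Hochberg runs over all genes tested in the contrast (genes with
zero counts in both groups are excluded and flagged).  There is no fold
change shrinkage — log2FC is biased away from zero at very low counts — and
no independent filtering or outlier refitting.  DEG calls use |log2FC| ≥ 1.0
(boundary inclusive) and padj < 0.05 (strict).

## VDEG screen

Pure set algebra per day: g = A∩B∩X, f = (B∩X)\A, e = (A∩X)\B over
A = NS_d, B = TS_d, X = TC_d DEG sets; the union equals X ∩ (A∪B) (verified
against brute-force pattern enumeration).  Direction is the sign of the
same-day TC log2FC — always defined for VDEGs since they are members of X.
Cross-period sharing counts up and down memberships independently per day
(a direction-flipping gene can in principle reach both shared lists); the
shared-up and shared-down sets at k ≥ 3 of 4 days feed enrichment, against a
default population of globally expressed genes (mean TPM ≥ 1 in ≥ 1 period;
the boundary counts as expressed).

## Profile clustering

Trajectories are (0, log2FC_d1 … log2FC_d4) vectors taken from the DE tables
regardless of significance.  Candidate templates start at 0 and change by at
most c (default 1) per transition — (2c+1)⁴ = 81 candidates at the defaults —
and m = 26 are kept by greedy max-min selection under distance 1 − Pearson,
seeded at the flat template, which by convention correlates 0 with
everything and serves as the catch-all for zero-variance trajectories.
Genes go to their best-correlated template (ties to the lowest id).
Significance compares each profile's observed size to its expected size
under within-gene permutation of the four post-baseline values — exhaustive
over all 24 orderings, hence fully deterministic — using an upper binomial
tail and Bonferroni across profiles (α = 0.05).  This is a simplified,
deterministic variant of the classic short-time-series permutation scheme;
no claim is made of matching any specific tool's output.

## Enrichment

Upper hypergeometric tail P(X ≥ k) for a study set of n genes in a
population of M with K term members.  GO-style results are BH-adjusted
within namespace (BP/MF/CC) by default; BIN-style results are conventionally
read at raw p ≤ 0.05 (BH also emitted); TF-family enrichment uses the TF
universe as its population.  Annotations are taken as given — no ontology
ancestor propagation.

## Regulatory modules

Per target, a 1000-tree random-forest regression (mtry = √#TFs, seeded per
target from the root seed) of the target's standardized log2(TPM+1) on all
TFs except itself; impurity importances, normalized to sum to 1 per target,
are edge weights, kept above 0.1.  Motif evidence comes from scanning
promoters on both strands: consensus motifs by exact IUPAC matching (an N in
the promoter never matches), PWMs by log-odds against a 0-order background
with an exact tail probability from dynamic programming over the
integer-discretized (×1000) score distribution, hit iff tail ≤ 1e-5.
Coordinates are ATG-relative with −1 the base immediately 5' of the ATG;
string offset i in a promoter of length L maps to start = i − L, spans
inclusive, so a 6-mer at −1594 ends at −1589.  Tiers: 1 = expression edge
only, 2 = the TF's motif hits the target promoter in exactly one library,
3 = in both.  Candidates are ranked by the mean of the eight per-day TC and
TS log2FC values, ties broken by the maximum single-day value; genes missing
from a table rank last and are flagged.

## Pipeline and problem sizes

Stages write plain-text artifacts into a run directory and re-read their
upstream artifacts, so re-running one stage from cache reproduces a full
run's outputs byte for byte; all randomness derives from a single root seed
through named substreams.  The test suite and the acceptance script run the
screen at 300–2000 genes, calibration at 5000 genes, and network recovery at
20 TFs × 10 planted edges × 5 seeds — sizes at which every statistical claim
is measurable with comfortable margins while a full run stays in the tens of
seconds.

## Known limitations

The Wald test is asymptotic; with three replicates its honest level
(~0.045–0.055) depends on the dispersion floor described above.  No
covariates, no time-as-continuous modelling, no isoform resolution.  The
permutation scheme for profiles assumes exchangeable post-baseline values
under the null.  Network importances are correlational; tier 3 is evidence
convergence, not causality.  Consensus scanning treats the motif as exact;
degenerate real-world sites require the PWM route.
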