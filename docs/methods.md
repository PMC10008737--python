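# Methods

## Copy-number data model

Profiles are per-sample lists of integer-CN segments with 1-based
inclusive coordinates (SEG convention); all interval arithmetic is done
half-open internally and converted at the boundary. Preprocessing
drops sex chromosomes whole, subtracts configured exclusion intervals
(the GRCh38 Ig loci IGH 14q32, IGK 2p11, IGL 22q11 are shipped as an
overridable default, since V(D)J recombination mimics somatic CN
change there), reverts CN-changed segments shorter than 50 kb to the
sample baseline, and merges contiguous equal-CN neighbours. Two choices
here were genuinely open and are fixed as follows: "changed" is judged
against the length-weighted median ploidy computed *before* filtering,
and the 50 kb threshold applies to individual segment length (not to
merged changed regions). Filtering is idempotent.

Tumor ploidy is the length-weighted median integer copy number over
autosomal segments — the median of the per-base CN multiset — with
ties resolved to the lower value (deterministic and conservative).

## Chromothripsis calling

Two of the published judgment criteria are visible in CN-only data and
are tested per chromosome:

- **Clustering (criterion A).** With `n` breakpoints on a chromosome of
  length `L`, the statistic is the maximum breakpoint count in any
  window of width `w` (default 50 Mb). Its null distribution under
  uniform placement is estimated by Monte Carlo (2000 draws, vectorised
  scan); the p-value uses the `(1 + hits)/(1 + draws)` estimator. The
  null stream is derived deterministically from `(n, w/L)`, so repeated
  calls reproduce without threading a seed. Because the statistic is
  discrete, null p-values form a step distribution; calibration means
  the empirical CDF equals the p-value at every attainable level, which
  the tests check directly.
- **Oscillation (criterion B).** Over the segments overlapping the
  densest window: the number of distinct CN states, the fraction of
  interior segments differing from both neighbours while the
  neighbours agree, and the longest run alternating between exactly
  two states.

A chromosome is flagged when the densest window holds ≥ 10 breakpoints,
the cluster p-value is ≤ 0.05, the region shows ≤ 3 CN states, and the
oscillation fraction is ≥ 0.5; the sample flag is the OR over
chromosomes. All thresholds live in `CTThresholds` and are echoed into
output. Chromosomes failing the count gate skip the Monte-Carlo test
(NaN p-value, never flagged), which keeps cohort-scale calling fast
without affecting any decision. Criteria that need SV orientation,
haplotype phase or fragment-join data (C–F) cannot be evaluated from
segmented CN input; they are documented as structurally unavailable
rather than approximated. Raising `min_breakpoints` can only shrink
the flagged set (tested monotonicity).

## CN signatures and the CPS

Six per-sample feature distributions are extracted from filtered
profiles: segment size (bp), absolute CN, |ΔCN| at breakpoints,
breakpoint count per chromosome arm, lengths (≥ 3) of maximal two-state
alternating segment runs, and breakpoint counts in 10 Mb bins tiled
from position 1 (terminal partial bins kept, counts not
length-normalised). Arm and bin counts include zeros for every
arm/bin of a covered chromosome.

Each feature is pooled across the cohort and fit with univariate
Gaussian mixtures — segment size on log10 scale because it spans
orders of magnitude — for 2–8 components in both equal-variance and
free-variance families; the BIC-best fit defines the categories and
every event is assigned to its maximum-posterior component. Constant
features collapse to a single forced category with a warning (at the
default generator settings |ΔCN| is constant at 1, so the warning is
expected there). The frozen mixture parameters travel with the model so
new samples are categorized without refitting.

Signature extraction is restarted multiplicative-update NMF under KL
divergence (10 restarts, best objective kept, seeded), giving
`counts ≈ exposures · signaturesᵀ` with simplex-normalised signature
columns. The engine slot is deliberately narrow (a count matrix in,
non-negative factors out) so an alternative sampler could be dropped
in. `K` defaults to 3 for the synthetic conditions; `K="auto"` selects
by a reconstruction-error elbow gated on restart stability (mean
matched cosine ≥ 0.85). Rank-1 extraction recovers the closed-form
outer product of the count marginals (tested numerically).

The CPS GLM is an unpenalized binomial/logit fit on NNLS exposures
against the frozen signatures — using NNLS projections for training as
well as scoring makes a training sample's score reproduce its fitted
probability exactly. On separation or non-convergence the fit falls
back to an L2-penalized logistic regression (C = 1.0) and records the
penalty in the model file; with a cleanly separable cohort (the
synthetic default) the fallback is the norm, not the exception.
Reported AUC is computed on pooled out-of-fold predictions from
stratified k-fold CV (folds derived from the seed; default 10).
Exposures enter the GLM raw (un-normalised). The whole model — mixture
parameters, category registry, signatures, coefficients, seed —
persists as a single JSON file that is byte-identical across reruns at
a fixed seed.

## Genomic covariates

Variant filtering keeps records that pass all three confidence rules:
coverage ≥ 5 **or** allele fraction > 0.05 (the disjunction is
deliberate and is flagged here because a conjunction would be the more
natural reading); classification among missense, nonsense, frameshift
and splice-site; and frequency < 0.005 in every provided population
database (rule skipped with a warning when no frequency columns
exist). TMB is qualifying mutations per Mb with a default 30 Mb exome.
CNA burden counts genes overlapping ≥ 1 bp of any segment above
(gain) or below (loss) ploidy, each gene at most once per direction.
wGII is the unweighted mean over covered autosomes of the fraction of
*covered* bases at CN ≠ ploidy — the covered-base denominator avoids
penalising sparse profiles. Key-gene Fisher tests are two-sided with
BH-adjusted q-values emitted alongside the raw p-values.

## Immune scoring

ssGSEA ranks genes per sample by decreasing expression and integrates
the difference between the weighted in-set ECDF (weights = ascending
rank^0.25, ties averaged) and the unweighted out-set ECDF; the integral
is divided by the range (max − min) of the running difference so
scores are comparable across samples. The unnormalised integral is
maximised when the set occupies the top ranks (tested exhaustively);
the normalised score trades that property for cross-sample
comparability. Because ssGSEA scores can be negative, cell-type and
cytokine ratios are computed from geometric-mean scores instead
(pseudocount 1 on linear-scale expression; log2-scale input is
exponentiated first). Group-level pathway differentials are Welch t
statistics on per-sample set scores, sign positive when the
non-chromothripsis group scores higher, BH-adjusted across sets; this
substitutes for kernel-CDF pathway-variation scoring while preserving
the scientific contract (direction and ranking of group-level
enrichment). The total-infiltration score is the mean (not sum) of the
28 per-set scores — configurable, since either convention only rescales.

## Survival analysis

Time is in months. Median grouping puts strictly-greater-than-median
samples in the high group (ties low). Kaplan–Meier and the two-group
log-rank test come from lifelines; median survival is the earliest
time with S(t) ≤ 0.5. Univariate Cox uses Efron tie handling (Breslow
available via statsmodels' PHReg), 95% Wald CIs, and by default the
binary high/low indicator so hazard ratios are comparable across
biomarkers (continuous fits are also exposed). The time-dependent AUC
is the IPCW cumulative-case / dynamic-control estimator: cases
(events by t) are weighted by the inverse left-limit of the censoring
Kaplan–Meier at their event time; the common control weight cancels.
Without censoring it reduces exactly to pairwise concordance (tested
against a quadratic oracle), and on censored data it agrees with
scikit-survival's independent implementation. RECIST responders are
CR, PR, or SD ≥ 6 months; objective responders are CR or PR; rates are
compared by two-sided Fisher tests.

## Synthetic cohort

The generator emulates the statistical structure the analyses assume,
with every stream derived from one root seed (fixed seed ⇒ byte-identical
outputs):

- **Genome**: 8 autosomes of 110–200 Mb (arm boundary at 40% of
  length) plus an X chromosome, ~1.35 Gb total — compact enough for
  fast cohorts while leaving chromosomes much longer than the scan
  window.
- **Profiles**: diploid baseline; background CNAs at 0.01 events/Mb
  (~13 per genome), single segments of ±1 CN and 1–10 Mb — the
  simplest null that still exercises the 50 kb filter and the
  specificity of the caller. A planted event places 20 breakpoints in
  a 30 Mb region of one random autosome, with deterministic
  alternation among the configured CN states (default 2: ploidy ↔
  ploidy+1) so the ground-truth label is unambiguous; background
  events never overlap the planted region for the same reason.
- **Mutations**: Poisson non-silent records at 2/Mb over a 30 Mb
  exome (plus silent records at half that rate); records pass the
  variant filters by construction so TMB recovers the planted rate.
- **Expression**: log2 values N(5, 1); 28 disjoint 10-gene cell-type
  sets, 6 pathway sets, 2 ICB-signature sets, the 8 cytokine panel
  genes and CD8A/CD274. Cytotoxic sets (CD8 T cells, NK cells,
  pathways, ICB signatures, pro-inflammatory cytokines, CD8A) are
  shifted up by 2 log2-units in samples *without* chromothripsis —
  effect sizes are free parameters of the generator, not estimates of
  any real cohort.
- **Outcomes**: exponential proportional hazards with baseline median
  24 months and log-HR log(1.9) per SD of the score; independent
  exponential censoring with its rate solved (Brent) so the expected
  censored fraction matches the target (default 20%); response labels
  logistic in the standardised score with a ~35% base rate (a
  plausible ICB response rate; any fixed value works for the tests).

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: allele-specific or
subclonal CN, purity, read-level noise, segmentation error, correlated
gene-gene expression structure, non-proportional hazards, and
informative censoring. Closure results (detector sensitivity/
specificity, CPS AUC) certify internal consistency of
generator + detector + model, not field performance.

## Problem sizes and determinism

The shipped test suite and acceptance script use: detector closure on
3 × 200 samples; CPS training on 400 samples with 10-fold CV;
signature recovery at n = 400, K = 3 over 5 seeds; Cox recovery over
200 replicates at n = 600 (mean HR) and 500 replicates (CI coverage —
500 rather than 200 because a true 95% coverage has ~1.5% binomial SE
at 200 replicates, too noisy for a ±2% band); log-rank type-I error
over 1000 replicates at n = 100. The full demo pipeline (200 samples)
completes in seconds on one CPU, and rerunning any pipeline with the
same config and seed reproduces every output table byte-identically
(SHA-256 manifest).
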