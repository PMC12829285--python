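# Methods

`methmark` implements a marker-discovery workflow for array-based blood
DNA methylation: given a beta-value matrix and phenotype-defined risk
cluster labels, it finds a compact consensus panel of CpG sites whose
methylation alone reproduces the cluster structure, and validates that
panel by unsupervised re-clustering in an independent cohort. This note
records the model, the choices that were genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Data model

Methylation is represented as beta values — the fraction of methylated
signal at a CpG, in [0, 1] — in a samples x CpGs matrix. Samples carry
a cohort tag (`discovery` / `replication`), a phenotype cluster label
(2 = low risk; 3 = low beta-cell function; 5 = insulin resistance /
fatty liver; 6 = high insulin secretion / visceral fat; the
replication design contains only the three high-risk clusters), and
numeric clinical traits. Upstream array processing (normalization,
batch and cell-composition correction) is assumed done; missing beta
values are tolerated on input but any CpG with a missing entry is
dropped, with a logged count, before analysis.

All randomness flows from one master seed through named substreams
(`SeedSequence([seed, crc32(stage), index])`), so the 1,000-split
resampling loop, the cross-validation folds and the random-CpG controls
are individually reproducible and independent of execution order.

## Pipeline stages

**Variance filter.** A CpG is removed when, within at least one cohort,
*all* of its values are below 0.05 or all are above 0.95 (strict
inequalities; boundary values stay). Flags are raised per cohort and
the union is removed so both cohorts keep a single shared feature
space. Whether the original workflow removed the union or the
intersection of per-cohort flags is not documented anywhere we could
find; the union is our choice, because the consensus markers must be
evaluable in the replication cohort.

**Differential methylation.** Every unordered pair of clusters is
tested CpG-wise with a moderated t statistic: per-CpG residual
variances are shrunk toward a prior (d0, s0²) estimated from the
marginal distribution of log-variances by moment matching (trigamma
inversion, Newton iteration, tolerance 1e-8, 50 iterations max;
verified against limma::eBayes to ~1e-11). If prior estimation fails
the ordinary pooled t is used and logged. p values are
Benjamini–Hochberg adjusted *within each pairwise contrast* — each
contrast is its own testing family — and the union of CpGs with
adjusted p < 0.05 in any contrast feeds feature selection. Analysis is
on beta values directly, not logit-transformed M-values, matching the
beta-scale reporting convention of the workflow this emulates.

**Consensus elastic-net selection.** The discovery cohort is split
1,000 times (default) into stratified 70/30 train/test partitions with
largest-remainder rounding, so every cluster appears in both parts; at
n = 187 this gives 131 training samples (round(130.9); a 132/55
convention differs by one sample and is immaterial). Stratification is
our choice — plain random splits risk losing a class from a training
set at ~42 samples per class. Per split, a multinomial logistic model
with the elastic-net penalty

    (1/n) Σᵢ NLL(yᵢ) + λ Σⱼₖ [ α·|βⱼₖ| + (1−α)/2·βⱼₖ² ]

is tuned: λ by 5-fold cross-validated deviance along a log-spaced path
from λ_max (smallest λ zeroing all coefficients) down by a factor of
0.01 (the glmnet convention for n < p; a 1e-4 tail adds only
near-saturated, slowly-converging fits), α over a grid (default
0.1…1.0 in steps of 0.1); ties go to the sparser model. Features are
standardized on the training samples only. The path is solved by
coordinate descent with partial Newton steps (weights p(1−p) clamped
at 1e-5, warm starts along the path, active-set sweeps, early stop
once 99.5% of the null deviance is explained); the solver is checked
against scikit-learn's saga solver by penalized-objective comparison
in the test suite. A model is *successful* if its held-out plain
accuracy exceeds 80% (the gate uses unbalanced accuracy; balanced
accuracy is recorded as well). The consensus set keeps every CpG with
a nonzero coefficient in any class in at least 10% of the successful
models; per-class selection frequencies are kept for the downstream
specificity calls.

**PAM validation.** The consensus CpGs are handed to partitioning
around medoids (classical BUILD + SWAP, Euclidean distance on raw beta
values, no standardization, deterministic with lowest-index
tie-breaks), with k equal to the number of phenotype clusters present
(4 in discovery, 3 in replication). PAM labels are arbitrary, so
agreement with the phenotype clusters is scored after an optimal
one-to-one assignment (Hungarian method on the confusion matrix;
rectangular allowed); *matched accuracy* is the fraction of samples
whose PAM cluster maps onto their phenotype cluster. A greedy matcher
would under-report agreement whenever two PAM clusters prefer the same
phenotype cluster. The specificity control repeats PAM on 15 random
draws of 1,500 post-filter CpGs.

Note that BUILD + SWAP is a best-improvement local search: it has
genuine single-swap local optima (observable at n = 5, k = 3), and on
such instances it returns the same suboptimal medoid set as the
reference R implementation (`cluster::pam`). Exhaustive-search
equality therefore holds on most, but provably not all, tiny
instances; the test suite documents both facts.

**Downstream characterisation.** Consensus CpGs are screened against
clinical traits with tie-corrected Spearman correlation (p from the t
approximation on n−2 df; |rho| = 1 maps to p = 0); significance uses
the *raw* p < 0.05, deliberately unadjusted — the screen is
descriptive. Pairs with fewer than 4 complete observations or a
constant variable are flagged and excluded from the per-trait counts.
Cluster membership of a CpG is the set of clusters whose per-class
selection frequency reaches the 10% threshold: singleton membership =
cluster-specific, larger sets = mixed (the Venn surface); a retained
CpG clearing no single class keeps its argmax class, flagged weak.
This derivation from per-class elastic-net support is our design: it
is the only class-resolved signal the workflow produces. Direction
calls compare the target-cluster mean with the pooled mean of all
other samples (cluster-vs-rest, not pairwise). Gene annotation uses
0-based half-open coordinates: promoter = within 2,000 bp of the
nearest TSS (ties to the alphabetically first gene; promoter takes
precedence), gene body = inside the first-to-last-exon span,
everything else intergenic and excluded from gene-level outputs.
Catalogue overlap is plain per-category set intersection, with a
per-cluster breakdown when specificity records are supplied.

## Synthetic cohorts

The generator emulates the two-cohort study design with recorded
ground truth. Defaults: discovery clusters 2/3/5/6 with 50/42/45/50
samples (n = 187), replication clusters 3/5/6 with 49/51/46 (n = 146);
5,000 CpGs of which 10% are informative. Each informative CpG marks
exactly one cluster: its baseline mean m₀ ~ U(0.2, 0.8) is shifted by
±0.25 (clipped to [0.02, 0.98]; if clipping absorbs the whole shift
the direction is flipped) in the target cluster only. Noise is
beta-distributed on the beta-value scale — bounded support with a
single concentration knob κ (default 60, i.e. sd ≈ 0.064 at
m₀ = 0.5) — rather than logit-normal. 2% of CpGs are detection
floor/ceiling probes (means in (0.005, 0.02) or (0.98, 0.995)) with a
much tighter concentration (κ = 1000), reflecting the strong variance
compression real arrays show near the bounds; this is what makes the
"all values below 5%" filter rule fire reliably at cohort size. The
replication panel keeps a random 95% of the discovery CpGs and
replaces the rest with fresh uninformative probes, emulating two array
generations. Ten quantitative traits are cluster-dependent Gaussians
plus 0.6 × the standardized mean methylation of a trait-specific
subset of informative CpGs, creating genuine CpG–trait correlations.
Age and sex are generated but never analysed (the real workflow
normalises for them upstream); they exercise the sample-sheet schema.

At δ = 0.25 and κ = 60 the planted effect is ≈ 4 noise standard
deviations — a deliberately strong-signal regime in which the workflow
should succeed essentially always. Passing benchmarks on these
cohorts therefore demonstrates correctness of the machinery, not
real-data power: real blood DMPs have far smaller effects (typically
Δβ < 0.05), real panels have ~0.3% informative sites rather than 10%,
and real CpGs are spatially correlated, none of which the generator
reproduces. One concrete consequence: a random draw of 1,500 CpGs
from a surrogate panel that is 10% informative still contains ~150
strong markers, so the random-CpG PAM control clusters essentially
perfectly here, whereas on real data (informative fraction ~0.35%) the
same control stays below 60% accuracy.

## Benchmark problem sizes

The packaged validation runs (`methmark.benchmark`,
`scripts/acceptance.py`) use a 2,000-CpG panel, 200 resampling splits,
an α grid of {0.1, 0.5, 1.0} and a 15-point λ path — sizes one CPU
core completes in minutes while leaving every scientific condition
(cohort sizes, effect size, noise, informative fraction, 5-fold CV,
70/30 splits, 80% gate, 10% consensus) at its default. The
random-control surrogate uses a 20,000-CpG panel so that 1,500-CpG
draws are a small fraction of it.

## Numerical details and edge cases

- Beta-matrix validation tolerates 1e-9 beyond [0, 1] for rounding in
  external files; anything further is an error, never clipped.
- Zero-variance features inside a training split are dropped for that
  split only (logged). A zero-variance CpG under the plain (unshrunk)
  t test yields an undefined statistic and a flagged record; with the
  empirical-Bayes prior the shrunken variance is positive and the
  statistic is defined.
- λ_max for the multinomial model is max |(1/n) Xᵀ(Y − P₀)| / α with
  P₀ the training class frequencies; α is floored at 0.001 in this
  formula so a pure-ridge grid point still gets a finite path.
- `stratified_split` guarantees at least one sample per cluster in
  each partition, which can shift the train total by a seat at extreme
  fractions.
- BH adjustment uses the step-up formulation with a reverse cumulative
  minimum; equal p values receive equal adjusted values.
- PAM tie-breaks (equal-cost swaps, equidistant medoids) resolve to
  the lowest sample index, making results independent of execution
  environment.

## Known limitations

- The generator does not simulate probe chemistry, batch effects,
  cell-composition heterogeneity, spatially correlated CpGs, or
  realistic (small) effect sizes; see above for what that implies.
- The consensus denominator is the set of successful models; when many
  models fail the gate (weak data), selection frequencies are
  conditioned on an unrepresentative subset.
- BH within each contrast controls the FDR per contrast, not over the
  union of contrasts.
- PAM is O(n²) in samples and the SWAP phase O(k·n²) per iteration;
  fine at cohort scale, not intended for thousands of samples.
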