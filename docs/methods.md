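# Methods

## Scope and shape

The package is a staged pipeline, not a single fitted model: read-level
stages (simulation, demultiplexing, reference building, counting, QC) feed
cohort-level statistics (differential expression, stability selection,
repeated-partition classification). Stage boundaries follow the data flow;
the DE and classification stages return result objects
(`DEResults.summary()`, `ModelReport`) so their estimates, uncertainties and
diagnostics travel together.

## The synthetic-data generator

The generator is first-class, tested code; it defines the study conditions
for every downstream check.

**Reads.** Parent transcripts are random {A,C,G,T} sequences with the
lengths of the human rRNA (28S 5070, 18S 1869, 5.8S 157, 5S 121 nt) and
Y RNA (RNY1 112, RNY3 102, RNY4 96, RNY5 83 nt) parents. Fragments are
sense-only substrings with lengths drawn from Gamma(shape α = 10.22,
rate β = 0.24) — the shape/rate parameterisation, mean α/β ≈ 42.6 nt, the
values fitted to plasma mRNA fragments — clipped to [15, parent length] and
to the read frame. R1 is `insert + poly(A) + barcode(8) + adapter`, padded
with G to 150 nt; R2 is `barcode + poly(T)`. Read length (150 nt) and the
poly-A tail range (10–30 nt) are free assay parameters with those defaults;
quality strings are constant Q40 unless `low_quality_fraction` injects Q10
reads to exercise the quality filter.

**Count matrices.** Per-feature baselines are log-normal (median 60,
σ_log = 1.2); library sizes are uniform in [5×10^5, 2×10^6] and become true
size factors; counts are NB(μ = base·sf·2^lfc, dispersion 0.2). The default
dispersion and baseline spread are typical of bulk count data at moderate
depth. Planted features (default 5% of features at log2FC +1.5, upregulated
in the case class, emulating the tumor-shedding direction) are disjoint per
case class; `n_common_features` plants a shared pan-cancer signal.
`GroundTruth` records sample classes, planted sets, per-read origins and
the true size factors, enabling oracle checks downstream.

**What the generator does not emulate.** Sequencing error beyond uniform
substitution, UMI structure, real human reference sequences, batch or
site effects, correlated features, and the extreme rsRNA dominance of real
plasma libraries. Passing tests therefore demonstrate the correctness and
calibration of the *algorithms* under the stated statistical model, not
performance on real plasma data.

## Preprocessing decisions

Barcode matching is exact (no mismatch tolerance): with 8-nt barcodes this
maximises specificity and is the only convention that is testable without a
stated tolerance. Adapter location uses an exact 10-nt seed; a ≥ 6-nt
adapter prefix at the read end is also trimmed (a partial adapter running
off the read). When no adapter evidence exists, the read is left intact —
this makes trimming idempotent on already-clean inserts. The trailing
A-homopolymer is removed only when ≥ 4 nt (`polyA_min`), so genuine short
3'-A inserts survive; an insert that truly ends in A is indistinguishable
from the tail, and its trailing A's are lost — the round-trip tests
condition on this known ambiguity. "Low quality" is mean Phred < 20 over
the trimmed insert; windowed trimming is deliberately not implemented.
N bases never match anything.

## Reference and counting

Derived entries are named `{type}-{parent}-{start}-{length}` with 0-based
half-open coordinates, ordered by (parent, start, length); a fragment
present in several parents is assigned to the lexicographically first
(parent, start) — the choice is arbitrary but deterministic. Counting for
the fragment classes requires full-length identity (a hash-map lookup);
transcript-class counting uses exact sense containment with length gates
(19 nt miRNA, 23 nt mRNA/lncRNA/snRNA/snoRNA, none for piRNA) and drops
reads contained in more than one feature, mirroring the default
multi-overlap discard of feature-level counters. Genome alignment is
replaced by this containment rule at desk scale — a documented fidelity
deviation: soft-clipped alignments that a genome aligner would rescue are
not counted here. A read may count in more than one RNA-type workflow;
cross-type deduplication is intentionally not performed, matching
independent per-reference alignment passes.

## QC

The four exclusion predicates use strict inequalities, so a sample sitting
exactly on a threshold is retained. The 2-million clean-read floor is a
sequencing-scale constant; it is a configurable threshold
(`QCThresholds.clean_reads_min`) and the bundled pipeline scales it to
synthetic depth. "Mappable reads" at desk scale means reads assigned by any
counting workflow. The Gamma fit solves the shape equation
log(a) − ψ(a) = log(mean) − mean(log) by Newton iteration (Minka
initialisation, tolerance 1e-8, max 100 iterations) and reports the rate
β = shape/mean; kurtosis is the non-excess Pearson moment ratio m4/m2²,
the convention consistent with the magnitudes reported for heavy-tailed
fragment data.

## Differential expression

Counts are modelled as K_fs ~ NB(μ_fs = s_s·q_fg, α_f). Size factors are
median-of-ratios: the median over all-nonzero features of
counts/geometric-mean, with a positive-counts fallback when no feature is
nonzero everywhere. (The median is taken on the ratio scale as stated; the
common reference implementation medians log-ratios, which differs only for
even feature counts.) Dispersions are per-feature method-of-moments on
normalized counts, pooled within groups so planted effects do not inflate
them, floored at 1e-8; empirical-Bayes shrinkage and independent filtering
are deliberately not reproduced — acceptance is by simulation calibration.
Group log-means are fitted by vectorized Fisher scoring (50 iterations,
step clipping at ±2); a group with all-zero counts uses a half-count
initialisation, giving a finite, conservative estimate. Wald
z = log2FC/SE with SE from the Fisher information; all-zero features get
p = NA and are excluded from BH.

**Known calibration limits.** Null rejection at α = 0.05 is calibrated
(0.048–0.052 at n = 50+50 over 3000 features). Two limits remain, both
verified against the reference NB-Wald implementation on identical
matrices: (1) one-sided planted effects bias median-of-ratios size factors
between groups (≈ 2.4% at 5% planted features), shifting every null log2FC
by ≈ −0.07 — the reference implementation reproduces this bias to four
decimals; (2) unshrunken per-feature dispersions leave the far tail of the
null ≈ 1.8× heavier than nominal. Together these push the empirical FDR of
the BH < 0.1 discovery set to ≈ 0.16–0.25 on one-sided mixed simulations
(the reference implementation: 0.24). Downstream stages consume only the
upregulated candidate set (q < 0.1, log2FC > 0.8, mean raw counts > 10,
strict), which is far cleaner because the normalization bias points the
other way.

The cumulative-sum comparison sums normalized reads over the upregulated
DE set per sample and applies Welch's two-sided t-test (Satterthwaite
degrees of freedom) to each group pair.

## Stability selection

Partitions are stratified 80/20 and shared across strategies where pairing
matters. Top-N fixes one partition bank for all N so AUC comparisons are
paired; ties keep the smaller set (parsimony). Boruta's decision rule is
the canonical one: a hit when a feature's RF importance exceeds the maximum
shadow importance; confirmation/rejection by two-sided binomial test at
α = 0.01 after ≥ 5 rounds, capped at `boruta_max_runs`. LASSO uses
z-scored log2-RPM features, a λ grid from the data-derived λ_max down by
factor 1e-4 (1e-2 when n < p, the glmnet convention), 10-fold CV binomial
deviance, and the 1-SE rule; liblinear fits are seeded for exact
reproducibility. Degenerate single-class training splits are skipped with
a warning.

On a raw feature pool with very strong planted signal, the lambda.1se model
retains cohort-level chance correlates alongside the planted features —
behavior reproduced exactly by the R glmnet implementation — so selection
precision is evaluated where the pipeline actually applies it: on the
upregulated DE candidate pool, where both LASSO and Boruta reach precision
1.0 at the 10/20 frequency floor in the bundled simulations.

## Classification

Risk scores are out-of-fold only: a sample's score list comes solely from
iterations where it was held out, because in-fold scoring would leak
training labels; the median drives the ≥ 0.5 high-risk call. Ridge LR
chooses its penalty by internal cross-validated log-loss (7 candidate
strengths); RF uses 500 trees at full scale (tests and the pipeline scale
this down); the linear SVM uses C = 1 and contributes decision values to
AUC but no probabilities, so risk scores come from the probabilistic
models. AUC is the Mann–Whitney concordance with half-credit ties.
Combination panels refit jointly on the concatenated feature set.
A partition missing a class is redrawn with the next seed and logged.

## Numerical and reproducibility choices

All randomness flows from per-stage seeds derived from one master seed;
reruns are bit-identical (asserted in tests down to artifact bytes). TSVs
are written with LF endings and integer counts for exact round-trips.
Sampling without replacement (optional read subsampling) sorts selected
indices so output order is stable.

## Known limitations

Desk-scale problem sizes throughout (thousands of features, tens of
samples, tens of repeats) — chosen as the smallest sizes at which the
statistical checks are stable; exact-match counting is stricter than
alignment-based counting for the transcript classes; the FDR of the
two-sided DE discovery set under one-sided effect mixtures is inflated by
normalization composition bias (see above); and nothing here speaks to
performance on real plasma cohorts, only to the correctness and calibration
of the algorithms under the generator's model.
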