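# Methods

## Scope and model

The package evaluates RNA-seq *quantification pipelines* (a trimming,
alignment, counting and normalization chain, represented here only by the
expression matrix it emits plus its step labels) and *differential
expression (DE) methods* (represented by their per-gene adjusted
p-values). It never runs the external tools themselves: panels and DE
result tables are inputs, and a synthetic generator provides
ground-truthed stand-ins so the scoring machinery can be validated.

### Precision

For gene g, pipeline p and one cell line, the non-parametric coefficient
of variation over the control (vehicle-treated) replicates is

    CoV(g, p) = MAD / median,   MAD = median(|X_i − median(X)|),

with the raw MAD (no 1.4826 consistency factor). CoV is unit-free, so
pipelines whose normalizations emit different units remain comparable.
Pipelines are ranked per gene ascending in CoV with average (fractional)
ranks on ties; the precision index of a pipeline is the median of its
gene ranks. A gene whose CoV is undefined (zero median) in *any* pipeline
is removed from the ranking universe and logged, never imputed, because a
rank against an undefined competitor is meaningless.

### Accuracy

Per gene and pipeline, the Pearson correlation r between the pipeline's
expression values and duplicate-averaged qRT-PCR Ct values over the same
control samples. Ct is inversely proportional to log template abundance,
so a faithful pipeline shows strongly negative r; rank 1 therefore goes to
the most negative r (ranking ascending in r). The equivalent convention —
correlating against −Ct and ranking descending — yields identical indices
and is pinned by a test. An undefined r (constant vector) ranks last
within its gene; genes with no defined r in any pipeline are dropped with
a log message. The accuracy index is again the median gene rank.

The published procedure never states whether good accuracy means large
positive or large negative r, nor whether "a median rank for each gene"
is aggregated per gene or per pipeline; we read it as the per-pipeline
median of gene ranks (a per-gene median cannot order pipelines) and
declare the sign convention above.

### Overall ranking

overall(p) = Σ over cell lines of (precision index + accuracy index),
giving both axes equal weight. With exactly two cell lines the reported
medians across cell lines satisfy overall = 2 × (median precision +
median accuracy) — an identity the acceptance suite checks against the
published top-10 table. Final ranks ascend in overall; ties break by
median accuracy, then pipeline id, so output order is deterministic.

## Housekeeping set and qRT-PCR candidates

`filter_expressed` keeps genes with ≥ `min_units` (default 4 expression
units) in every control sample of every panel. The published rule states
only the removal side ("< 4 removed"); we implement keep-if ≥ 4, so a
value of exactly 4 survives. The filter is monotone in the threshold and
anti-monotone in the panel collection (more pipelines can only shrink the
set), both property-tested.

`select_candidates` takes the n_high largest and n_low smallest median
CoV genes (medians across pipelines), then draws n_mid genes uniformly
(seeded) from the remaining middle stratum — defined simply as everything
eligible not already chosen, since no stratum bounds are published —
and appends the designated control genes regardless of their CoV,
excluding them from the draws. Ties in median CoV at group boundaries
break lexicographically by gene id. Defaults 10 + 10 + 10 + 2 controls
give the canonical 32-gene candidate list.

## ΔCt normalization

ΔCt = Ct(reference) − Ct(target), computed after arithmetic averaging of
technical duplicates on the Ct scale; larger ΔCt = more expressed. Three
references:

* **endogenous control** — the per-sample mean Ct of designated control
  genes;
* **global median** — the per-sample median Ct over genes with
  Ct strictly below the 35-cycle ceiling (near-background amplification
  excluded); a sample with no gene under the ceiling is a hard error
  naming the sample;
* **most stable gene** — a single reference chosen by the stability
  consensus below.

All three schemes are equivariant under adding a per-sample constant:
between-gene ΔCt differences are preserved.

## Reference-gene stability

All four estimators run on duplicate-averaged Ct values directly. Ct is
already a log-scale quantity, so methods built on standard deviations of
pairwise Ct differences (geNorm, comparative ΔCt) are identical to their
formulations on log-transformed relative quantities; for BestKeeper we
rank on the SD of Ct and report (but do not rank on) its index
correlation, since which BestKeeper statistic enters the published
consensus is not documented.

* **geNorm**: V_jk = SD over samples of (Ct_j − Ct_k); M_j = mean of
  V_jk over k ≠ j. The highest-M gene is excluded (ties broken
  lexicographically) and M recomputed until two genes remain; a gene's
  stability value is its M from its exclusion round, the final pair
  sharing the last M. geNorm's round-1 M equals the comparative-ΔCt value
  for every gene — asserted exactly as a cross-method identity.
* **comparative ΔCt**: mean pairwise SD without pruning.
* **BestKeeper**: per-gene sample SD of Ct (lower = more stable); the
  Pearson correlation of each gene with the BestKeeper index (per-sample
  mean Ct across genes) is reported in `extras`, NaN when either side is
  constant.
* **NormFinder**: a model-based decomposition. Ct values are centred per
  sample by the mean over genes (removing the sample loading); for gene g
  and group i (groups default to cell line), a_ig and s²_ig are the mean
  and sample variance of the centred values and
  d_ig = a_ig − mean_i(a_ig) the inter-group bias. Stability is
  ρ_g = mean_i |d_ig| + mean_i √(s²_ig / n_i) — absolute group bias plus
  averaged intra-group standard error. The exact published estimator is
  not specified; this documented variant is pinned by an independent
  brute-force oracle test, is invariant to permuting samples within
  groups, and attains exactly 0 for a gene with no bias and no
  within-group variation.

**Consensus**: each estimator ranks genes (average ranks on ties); the
consensus value is the geometric mean of the four ranks, ordered
ascending with lexicographic tie-breaks. The top gene is the most-stable
ΔCt reference.

## Group statistics

Kruskal–Wallis uses the tie-corrected H with a chi-square reference
distribution regardless of sample size (no exact permutation p); when
every observation is identical the tie correction degenerates and H is
defined as 0 with p = 1. Dunn's pairwise test uses

    z_ij = (R̄_i − R̄_j) / √((N(N+1)/12 − ΣT/(12(N−1))) (1/n_i + 1/n_j)),

T = t³ − t per tie group, with **two-sided** normal p-values (half of
these equal the one-sided values some R implementations report) adjusted
by Benjamini–Hochberg across the C(k, 2) comparisons. For by-step
comparisons the overall indices are min–max scaled to [1, 100] across the
included pipelines (a constant vector maps to the midpoint), and the
analysis can be re-run after excluding pipelines by normalization label
(e.g. the raw-count-like normalizations that bimodalize the score
distribution), reporting both results.

Note the full BH step-up procedure is not idempotent in general;
re-applying it to an already adjusted vector inflates values again. The
tested fixed point is a fully tied adjusted vector.

## DE evaluation

Truth labels per contrast come from Welch (unequal-variance) two-sample
t-tests on global-median ΔCt between the contrast's groups — the
published account says only "two-sample t-test"; Welch is the safer
default — BH-adjusted across genes; a gene constant in both groups gets
p = 1 when the group means agree, 0 otherwise. By default the truth
cut-off matches the evaluation cut-off at each FDR level
(`truth_cutoff_mode="matched"`); a fixed truth level is available via
configuration since the published choice is not stated.

Diagnostics from the confusion table (method adjusted p < cutoff vs
truth): TPR, TNR, PPV, NPV, ACC as their standard ratios (NaN on empty
denominators), MCC with the 0-on-zero-denominator convention, and AUC as
the midrank Mann–Whitney statistic of the DE-evidence score
1 − adjusted p (NaN when truth holds a single class). Method similarity
uses binary call vectors at the cut-off (adjusted-p vectors optional) with
Euclidean distance and unweighted group-average (UPGMA) linkage; trees
serialize to Newick. Performance aggregation ranks methods per scenario
(per contrast, metrics averaged over cut-offs, mean rank across the seven
parameters), per cut-off (symmetric), and overall (mean of the two,
re-ranked); NaN cells are excluded pairwise with a warning.

The DE method registry enumerates the 17 evaluated methods: 11
algorithms, of which edgeR exact, edgeR GLM and NOISeq contribute three
internal normalization variants each (TMM, UQ, FPKM).

## Synthetic data

The generator emulates the study conditions, not real biology:

* **design** — 18 samples: 2 cell lines × 3 treatments (T0 = vehicle
  control) × 3 replicates; configurable.
* **truth** — per-gene baseline log2 expression ~ N(8, 1.5²) (a
  mid-dynamic-range bulk signal); a seeded fraction of genes per contrast
  (default 10%) receives a ±`effect_size` log2 shift (default 2, a
  clearly detectable 4-fold change; 3 cycles ≈ 8-fold where a stronger
  planted effect is wanted). Treated-vs-control contrasts shift only the
  treated condition; the between-cell-line contrast shifts every
  condition of the second line so its within-line contrasts stay clean.
  Non-DE genes have identical means across treatments within a cell line
  by construction.
* **panels** — value = s_p · 2^(bias_p(g) + μ + ε), ε ~ N(0, σ_p²):
  log-normal expression noise, a per-pipeline global scale (pipelines
  disagreeing in units) and an optional per-gene log2 bias drawn once per
  pipeline (default sd 0). No published characterization of
  pipeline-specific error exists; this distortion model is a stand-in
  chosen for analytic tractability of the recovery tests.
* **Ct table** — Ct = α − β(μ + ε) with α = 40 cycles (no-template
  intercept), β = 1 cycle per log2 unit (one cycle per doubling),
  duplicate noise sd 0.25 cycles by default; one planted gene carries a
  3× smaller noise multiplier and is the recovery target for the
  stability consensus.
* **DE stand-ins** — per method, a pseudo statistic
  t = q·log2fc/2 + N(0, 1) gives two-sided normal p-values (uniform for
  null genes), BH-adjusted per contrast; the quality q grades fidelity,
  q = 0 being pure noise.

One global seed splits into fixed per-operation substreams
(`default_rng([seed, stream, …])`), so adding one generator call never
shifts another's stream and every output is a pure function of
(arguments, seed).

What the generator does **not** emulate: read-level artefacts, library
size and gene length effects, count discreteness and overdispersion
structure, amplification-efficiency differences, correlated gene modules,
or realistic tail behaviour of DE p-values. Passing recovery tests
therefore demonstrate that the scoring machinery identifies planted
signal under its own noise model — they are internal-consistency
evidence, not evidence about how real pipelines rank.

## Problem sizes and numerical choices

Recovery checks run at 500 genes × 6 pipelines × 50 seeds (pipeline
ranking), 10 genes × 100 seeds (stability consensus), 40 genes × 100
seeds (truth power) and 1000 replicates (Kruskal–Wallis calibration) —
sizes chosen so the whole suite and the acceptance script each finish in
well under a minute while keeping Monte-Carlo error small relative to the
asserted margins. Sample SDs use ddof = 1 throughout. All file exchange
is UTF-8 TSV with '.' decimals (comma decimals are rejected), long-format
Ct tables, and JSON for sets/summaries.

## Known limitations

* The distortion and Ct models are generative conveniences; conclusions
  about real pipeline rankings require real panels.
* NormFinder and the consensus rule implement documented, oracle-pinned
  variants of tools whose exact published internals are unavailable.
* Kruskal–Wallis p-values rely on the chi-square approximation, which is
  anti-conservative for very small groups.
* AUC treats 1 − adjusted p as a continuous score; methods that emit
  heavily tied adjusted p-values get midrank credit only.
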