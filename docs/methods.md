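# Methods

`cropscreen` implements the statistical core of a pooled single-cell
CRISPRi (CROP-seq) screen analysis: cells carry lentivirally delivered
guide RNAs (gRNAs) targeting transcription start sites (TSSs) and
candidate regulatory elements, the transcriptome and the gRNA repertoire
of each cell are read out together, and the task is to decide which
perturbed element changes which nearby gene — an element-to-gene (E2G)
map. This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Guide assignment

For cell *c* with total guide-library UMI count
N<sub>c</sub> = Σ<sub>g</sub> x<sub>gc</sub>, each observed guide count
x<sub>gc</sub> is tested against Binomial(N<sub>c</sub>, p<sub>g</sub>),
where p<sub>g</sub> is the guide's proportion in the plasmid library.
The upper tail is inclusive, P[X ≥ x], computed with a numerically
stable survival function (validated against term-by-term summation to
1e-10 relative error for n ≤ 10^6 in the test suite). Conditioning on
N<sub>c</sub> absorbs cell-to-cell differences in guide-transcript
recovery; p<sub>g</sub> absorbs abundance-driven ambient background.

* **Multiple testing.** Bonferroni within each cell over *all* guides in
  the library (not only observed guides, not pooled across cells). The
  per-cell × library-size family is the most conservative reading that
  keeps cells independent; it is configurable via `alpha` and the
  library size.
* **UMI floor.** Applied *after* significance: a guide is assigned iff
  its adjusted p < 0.001 **and** x > 3 UMIs. Calls supported by three or
  fewer molecules are treated as PCR/ambient artifacts regardless of
  significance.
* A cell may be assigned any number of guides; cells are classed
  unassigned / single / multi.

## Quality control

Per cell: total UMIs, genes detected, mitochondrial fraction. Within
each batch ("experiment"), a cell is removed when it deviates by more
than `n_mads` (default 3) median absolute deviations from the batch
median: totals and gene counts on the log1p scale, low side only;
mitochondrial fraction on the natural scale, both sides — the high tail
catches dying cells, the low tail catches stripped nuclei. Details that
make the tests exact: the MAD uses the 1.4826 normal-consistency
constant; deviations of exactly `n_mads` MADs are kept (the rule is
strict); a metric with MAD = 0 in a batch filters nothing there.
Doublets are flagged (not removed unless asked) when a cell is both
multi-gRNA and above its batch's 95th percentile of total UMIs — a
deliberate heuristic stand-in for neighborhood-based doublet callers,
exposed as a pipeline option.

## Differential expression: the hurdle model

For each target, the model is fit on cells carrying any of its four
guides plus a fixed background of 5,000 cells whose only assigned guide
is non-targeting (sampled once per run, reused for every target). Cells
with multiple assigned guides are excluded — exposure must be
unambiguous, and at low MOI this discards few cells. Genes tested are
those detected in ≥ 5% of QC-passing cells whose TSS lies within
± 1 Mb (closed interval) of the target.

Expression is library-size normalized (size factor
s<sub>c</sub> = total<sub>c</sub>/median total; a simple, deterministic
replacement for pool-based deconvolution factors — the factor definition
is isolated in `normalize_log` and swappable) and transformed to
log2(1 + count/s<sub>c</sub>).

The two-part hurdle likelihood factorizes exactly into:

1. a **detection** component: logistic regression of (count > 0) on
   per-guide indicators + batch + CDR (cellular detection rate: the
   fraction of tested genes detected in the cell, standardized);
2. a **continuous** component: Gaussian regression of the
   log-normalized values among detected cells on the same design.

Each guide is tested by a likelihood-ratio test refitting both
components without that guide's indicator (its cells fold into the
baseline); the statistic is the sum of the two component LR statistics,
referred to χ² with one degree of freedom per estimable component.
LRT-by-refit was chosen over a Wald contrast because it is invariant to
coefficient scaling and directly checkable against an independent
maximum-likelihood oracle (the test suite matches a generic-optimizer
fit to 1e-6 on a hand-coded fixture).

Numerical choices: the logistic fits carry a ridge penalty λ = 1e-6 on
the guide coefficients so that perfect separation stays finite; fits
with |coef| > 15 are flagged degenerate. Reduced fits are cold-started
(warm starts can stall in the flat region separation creates). The
continuous component requires ≥ 3 detected cells in the dropped group
and ≥ 3 in the remainder; otherwise the test is detection-only with
df = 1 and flagged. Guides with zero recovered cells yield NA rows.
log2FC = mean(log-normalized | guide cells) − mean(log-normalized | NT
cells), zeros included; negative means downregulation. BH adjustment of
gRNA-level p-values spans all (guide, gene) tests of the run.

A stratified Wilcoxon backend (van Elteren weights 1/(m+n+1) per batch,
normal approximation with tie correction) provides a nonparametric
cross-check with the same output schema.

## Target-level aggregation

Per (target, gene) pair, raw per-guide p-values are combined with
Fisher's method (−2Σln p ~ χ²(2k)); guides with no recovered cells are
dropped with the degrees of freedom reduced rather than imputed at
p = 1, which would bias toward non-significance. Combined p-values are
BH-corrected across all pairs of the run. Significant pairs
(FDR < 0.05) are tiered by support — the number of guides with raw
p < 0.05 whose log2FC sign matches the majority sign among those guides
(ties broken by the cell-weighted mean): 3–4 high, 2 medium, 1 low.
Low-tier rows are kept but excluded from headline summaries. The
summary log2FC is the cell-count-weighted mean of per-guide log2FCs;
distances are measured from the target interval midpoint to the gene
TSS; the nearest-expressed-gene flag is computed among detection-
filtered genes on the same chromosome.

## Null calibration

Non-targeting guides are partitioned into pseudo-targets of four
(35 NT guides → 8 disjoint groups, 3 guides unused — leftovers are
excluded rather than recycled so groups stay disjoint) and pushed
through the *same* DE entry point as real targets. Lacking a genomic
position, each pseudo-target is tested against the union of all real
targets' window genes (optionally subsampled, seeded, to bound
compute); background cells carrying the pseudo-target's own guides are
dropped from the background for that pseudo-target. The report gives a
KS statistic against U(0,1), empirical type-I rates at 0.05/0.01, and
an inflation factor (median observed −log10 p over median expected).

## The synthetic screen generator

The generator is first-class, tested code; it is the ground-truth
instrument for every stage. It emulates:

* the reference library: 80 targets (35 TSS, 28 enhancer, 11 intronic +
  3 intergenic cCRE, 3 LCR) × 4 guides + 35 NT = 355 guides;
* plasmid abundance: lognormal (σ = 0.5), normalized to proportions;
* transduction: Poisson(MOI = 0.3) integrations per cell, identities
  drawn ∝ plasmid proportion without replacement within a cell;
* guide capture: Poisson(25 · capture<sub>c</sub>) UMIs per present
  guide with capture<sub>c</sub> ~ lognormal(0, 0.3) — the
  recovery-efficiency bias the assignment test is meant to absorb —
  plus ambient UMIs at 5% of the per-cell capture rate, allocated
  multinomially by plasmid proportion (the ambient model is an
  interpretation; assignment is tested against it, not tuned to it);
* expression: NB(μ<sub>g</sub>·s<sub>c</sub>·b<sub>g,batch</sub>,
  θ = 10) over a toy genome of uniformly spaced gene TSSs (default one
  250 Mb chromosome, genes every 50 kb), two batches with lognormal
  (σ = 0.1) per-gene batch factors, lognormal(0, 0.25) size factors;
* effects: per-target knockdown ~ Normal(class mean, 0.05) truncated to
  [0.08, 0.60] with class means 0.31 (TSS), 0.29 (LCR), 0.20
  (enhancer/cCRE); per-guide efficiency ~ Beta(5, 1) (mean 0.83). The
  expected gene's NB mean is multiplied by (1 − effect·efficiency) in
  cells truly carrying the guide. Expected-gene baseline means are
  log-uniform on [0.2, 8] UMIs/cell so recovery can be profiled across
  the expression range; bystanders are lognormal(ln 0.25, 1.0);
* nuisance structure: mitochondrial genes on a separate contig hitting
  per-cell Beta-distributed mito fractions with batch-specific means
  (0.06/0.08), a 1% "stripped nuclei" tail (near-zero mito, reduced
  size factor), and 5% doublets formed by summing a phantom cell's gene
  and guide columns into a host cell of the same batch.

It does **not** emulate: read-level artifacts (PCR duplication,
sequencing error), cell-state or cell-cycle heterogeneity, correlated
gene programs, chromatin-context-dependent CRISPRi efficacy, or
off-target effects. Passing tests therefore demonstrate the
*statistical* behaviour of the pipeline under the stated noise model,
not robustness to every failure mode of real data.

## Reference evaluation sizes

The package's headline evaluations (tests/test_acceptance.py and
scripts/acceptance.py) use a compact study scale chosen to keep a full
run in minutes on one CPU while preserving the quantities that drive
power: a 170 Mb toy chromosome with genes every 200 kb (~10 genes per
testing window), the full 355-guide library, 480,000 cells for the
power screen (mean ~300 single-assigned cells per guide at MOI 0.3,
5,000-cell NT background) and 200,000 cells for the no-effect
calibration screen, whose pseudo-target gene universe is subsampled to
reach ≥ 10,000 gRNA-level null tests.

## Known limitations

* Library-size factors under-correct composition effects that
  deconvolution factors would catch; with ≤ a few percent of cells per
  perturbation the effect on DE is negligible in simulation.
* The Gaussian continuous component is a working approximation for
  log-normalized NB counts; its null calibration is verified
  empirically (KS < 0.02 over 10^4 tests) rather than guaranteed.
* The doublet heuristic only sees doublets that show two guides and
  high depth; same-guide doublets pass through (they mostly act as
  slightly deeper singlets).
* With MAD-based gates, batches with pathological (near-constant) QC
  metric distributions filter nothing on that metric by construction.
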