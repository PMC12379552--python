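# Methods

## Problem setting

Given gene-by-cell UMI counts and VDJ contig tables for CD8+
tumor-infiltrating lymphocytes, and a table mapping experimentally
validated clonotypes to `reactive`/`nonreactive`, the pipeline learns a
per-cell probability of tumor reactivity and characterizes the TCR
repertoire of each compartment. Labels propagate by clonotype: all cells
sharing a canonical clonotype key (sorted α CDR3 set + `|` + sorted β CDR3
set) inherit the validated label; everything else stays `unknown` and is
excluded from supervision.

## Quality control

Defaults: cells need ≥ 200 total UMIs and ≤ 15% mitochondrial counts;
genes must be detected (count > 0) in > 3 cells. The thresholds are read
as strict exclusions — "fewer than 200" and "more than 15%" remove, so a
cell at exactly 200 UMIs or exactly 15% mito is retained, and a gene in
exactly 3 cells is removed. Mitochondrial content is the fraction of raw
counts from genes with the case-sensitive prefix `MT-` (configurable),
computed before any gene filtering. Doublet removal is a pluggable boolean
column supplied upstream; no doublet detector is bundled.

CD8 gating requires evidence from both marker pairs: (CD3D > 0 or
CD3G > 0) and (CD8A > 0 or CD8B > 0). This demands both lineage and
co-receptor evidence without requiring all four genes, which drop out
frequently at typical depths. If a pair is entirely absent from the matrix
the gate treats it as "no evidence against"; if all four markers are
missing the call is a configuration error.

Subtype annotation is deliberately simple: score(subtype) = mean
normalized expression of that subtype's markers, assign the argmax,
`Unassigned` on an exact top-two tie or when no subtype scores positive.
The classifier needs only a categorical covariate, not an atlas; the
default marker table (GZMK for GZMK+Tem; HAVCR2/CTLA4/CXCL13 for Tex;
MKI67/TOP2A for Proliferative; CX3CR1/GZMB for Temra; ZNF683/ITGAE for
Trm; KLRD1/NKG7 for NK-like; CCR7/SELL/LEF1 for Tn; IL7R/CD44 for Tm) is a
replaceable default, not a claim about the one true taxonomy.

## Variance-stabilizing normalization

Counts are modeled as negative-binomial with mean μ_gc = p_g · d_c, where
p_g is gene g's fraction of all counts and d_c is cell c's total depth.
The Pearson residual r = (x − μ)/√(μ + μ²/θ) is the variance-stabilized
value. Per-gene dispersion θ_g is estimated by method of moments
(Var(x) ≈ E[μ] + E[μ²]/θ across cells) and regularized by Nadaraya–Watson
kernel regression of log10 θ on log10 gene mean (Gaussian kernel,
Silverman bandwidth), which shrinks noisy per-gene estimates toward the
mean-dispersion trend. This is a simplified instance of the
regularized-NB approach used by variance-stabilizing scRNA-seq
normalizers; the full Poisson-GLM machinery is not reproduced, only the
variance-stabilization contract (residual means near 0, comparable
variances across expression strata, Poisson limit (x − μ)/√μ as θ → ∞).
Residuals are clipped at ±√n_cells to bound outlier leverage. A gene with
zero total count has no defined residual and must be removed by the gene
filter first.

## Feature engineering

Genes are ranked by residual variance; the top 10,000 per dataset form
that dataset's HVG set. Sets are intersected across datasets (ordered by
mean rank, alphabetical tie-break), then genes matching the blacklist are
removed. The shipped blacklist combines the TCR segment regex
`^TR[ABDG][VDJC]` — TCR genes would let the classifier memorize clonotypes
rather than programs — with a curated dissociation-stress list (FOS/JUN
family, heat-shock, immediate-early genes), and is user-replaceable.

Z-scoring uses the population SD and is computed **within each sample** by
default, so per-sample depth and batch offsets cancel; scaling one
sample's residuals by any constant leaves its z-scores unchanged. The
scope (`per_sample` or `global`) is recorded in provenance. Zero-variance
genes map to zeros.

Panel selection fits a random forest (500 trees, unlimited depth, √p
features per split, class-balanced weights, fixed seed) of reactive vs
nonreactive cells on the z-scores and keeps genes whose normalized
mean-impurity-decrease importance is **strictly** greater than 0.0025.
Impurity importances sum to 1, which makes the absolute cut meaningful
across panel sizes; permutation importance is available behind a flag.
Cells are canonically sorted by barcode before fitting so importances do
not depend on input row order. The resulting panel is ordered by
decreasing weight (alphabetical ties) and that order is part of the
trained model's contract — convolution is order-sensitive — so it is
serialized with the model.

## The classifier

Input per cell: the z-scored panel vector as a 1-channel signal plus a
one-hot subtype. Architecture defaults: two convolution blocks (32 then
64 channels, kernel 9, stride 2, GELU), linear projection of the token
sequence to embed_dim = 64 with a learned positional embedding, two
pre-norm transformer encoder layers (4 heads, feed-forward 2×embed,
residual connections, layer norm), mean pooling over tokens, a 16-d linear
subtype embedding fused through a block-linear first head layer
(equivalent to concatenation), and an MLP head 64→32→1 emitting a logit.
Panels shorter than the kernel-9 receptive field (< ~25 genes) get
proportionally smaller kernels via `ModelConfig.for_panel`; a config that
does not fit the panel is an error.

Training: binary cross-entropy on logits with optional class-balanced
weights, Adam at 1e−3, batch 128, up to 50 epochs with early stopping on
held-out test loss (patience 10, best weights restored). The default
holdout groups by clonotype — clonal copies of one TCR are expression-wise
near-duplicates, so a random split would leak labels; a `patient` mode
groups by sample for patient-level validation, and `random` is available
for null experiments. The decision threshold is fixed at 0.5 and never
tuned on test data. Both held-out and resubstitution metrics are reported,
clearly separated.

Metrics: ROC AUC is the midrank Mann–Whitney statistic (ties get half
credit) and equals brute-force concordant-pair counting exactly; PR AUC is
the step-interpolated precision sum (the average-precision rule).

The network runs on a purpose-built numpy reverse-mode autodiff engine
(`trseek.nn`): broadcast arithmetic, batched matmul, reductions,
GELU/sigmoid/softmax, 1D unfolding for convolution, layer norm, dropout,
Adam. All operations and the full network are gradient-checked against
central finite differences in the test suite. Everything is seeded from
`ModelConfig.seed`; identical seed + data reproduce the loss history and
metrics to numerical precision, and inference is deterministic (dropout
off).

## TCR repertoire

Clonotypes use productive, high-confidence contigs only, deduplicated by
(chain, CDR3, V, J) within a cell. The primary chain per locus is the
highest-UMI chain (tie: lexicographically smallest CDR3), giving
deterministic combined α+β CDR3 lengths; cells lacking either chain are
excluded from the length histogram, and each clonotype contributes once.
`multi_ab` flags > 1 distinct α or β CDR3; the cohort fraction is reported
alongside the ~6% droplet pairing error as interpretive context, not a
test. Expansion bins follow right-closed frequency edges (Rare ≤ 1e−4 <
Small ≤ 1e−3 < Medium ≤ 1e−2 < Large ≤ 0.1 < Hyperexpanded ≤ 1), so a
clone at exactly 0.1 is Large; frequencies are computed within a declared
cell universe (e.g. one patient's TR compartment). Diversity indices are
the standard closed forms (Shannon −Σp ln p, inverse Simpson 1/Σp²,
Gini-Simpson 1 − Σp², bias-corrected Chao1 S + f1(f1−1)/(2(f2+1)), Pielou
H/ln S) on clone frequencies over cells; they are cross-checked against
scikit-bio in the tests. Viral bystander matching defaults to exact β-CDR3
string equality against the reference (a V-gene-restricted mode exists);
the shipped reference is a synthetic stand-in with the VDJdb column layout
and should be replaced by a real VDJdb export for real data.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes.
Counts are gamma-Poisson (NB) with the same mean-dispersion
parameterization the normalizer fits, so the residual contract is directly
testable. Defaults, chosen once as the study conditions: 4 samples ×
1,000 cells, 2,000 genes, 25% TR fraction; per-cell depth lognormal
(ln 2000, 0.35); per-sample batch factors lognormal(0, 0.15); dispersion
θ = 2; 20 effect genes — 10 exhaustion-program genes up at log2FC +2 and
10 mitochondrial genes down at log2FC −1 (the mitochondrial baseline is
8% of counts, so TR cells drop to ≈ 4%, comfortably inside the 15% QC
ceiling); subtype marker programs at log2FC +3; 3% deliberately
low-quality cells (half under the UMI floor, half above the mito ceiling)
so QC always has work to do. TR clonotypes draw from a power law with
exponent 1.5 over ~n/8 clones per sample, producing per-sample
hyperexpanded clones; non-TR clones hold 1–3 cells each. 8% of cells gain
an extra productive α chain (above the 6% platform reference); 5% of
non-TR cells carry a β CDR3 from the shipped viral reference. CDR3s are
random amino-acid strings with per-chain length ~N(14, 1.5) truncated to
[8, 22], spanning the biologically typical 23–33 combined window and
beyond it for multi-chain cells. The gene universe always contains the
marker, effect, `MT-`, and TCR-segment symbols so every filter has live
targets.

What the generator does **not** emulate: gene–gene correlation beyond the
planted programs, ambient RNA, empty droplets, realistic doublets, V(D)J
germline sequence structure, or batch effects beyond a multiplicative
depth factor. Passing tests therefore demonstrate that the implementation
honors its contracts under the assumed model — not that the classifier's
near-perfect synthetic AUCs transfer to real tumors, where effect sizes
are smaller and covariate structure richer.

## Numerical and design notes

- All tie-breaks are deterministic (alphabetical, mean-rank, smallest
  CDR3) and all randomness flows from explicit seeds; outputs are
  byte-identical across processes.
- Problem sizes in the shipped tests and the acceptance script (cohorts of
  2,000–5,000 cells, 2,000 genes, 100–500-tree forests) are the package's
  chosen desk-scale study conditions; all scale linearly upward.
- z-scoring per sample vs globally is a genuine design fork; per-sample is
  the default because cross-sample depth/batch invariance is the stated
  goal, and the choice is recorded in provenance.
- The reported head is probabilistic binary classification (sigmoid +
  BCE): reactivity labels are binary, and classification metrics are what
  the evaluation reports.
- Whether the 0.0025 importance cut refers to normalized impurity
  importances is a modeling decision here (they sum to 1, making the
  constant comparable across runs); permutation importance is offered as
  an alternative but not the default.
- Known limitations: no batch integration (the z-score scope is the only
  batch handling); the subtype annotator is marker-score argmax, not
  clustering; diversity indices are reported without significance tests;
  the shipped viral reference and blacklist are replaceable defaults, and
  real analyses should substitute curated versions.
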