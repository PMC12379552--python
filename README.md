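# trseek

Identification of **tumor-reactive (TR) CD8+ tumor-infiltrating
lymphocytes** from paired single-cell RNA and TCR sequencing.

Tumor-reactive T cells — the small fraction of TILs whose receptors actually
recognize autologous tumor — are the raw material for TCR-T therapies, but
finding them normally requires slow, expensive co-culture killing assays.
`trseek` implements a supervised alternative: cells whose TCRs have been
experimentally validated label their clonal siblings (every cell sharing the
same α/β CDR3 pair inherits the label), and a deep network learns to
recognize the transcriptional program of reactivity — elevated exhaustion
genes (*CTLA4*, *CXCL13*, *HAVCR2*), depressed mitochondrial
respiratory-chain genes (*MT-ATP6*, *MT-ND1*, *MT-ND3*) — so that
reactivity can be predicted for cells with no validation data at all.

The package is aimed at computational immunologists working with 10x
Genomics Gene Expression + VDJ output (MatrixMarket count triplets and
filtered contig annotation CSVs).

## The pipeline

1. **QC & gating** (`trseek.qc_gating`) — drop cells with < 200 UMIs or
   > 15% mitochondrial counts (boundary values retained), keep genes
   detected in > 3 cells, gate CD8+ T cells on (CD3D ∨ CD3G) ∧ (CD8A ∨
   CD8B), annotate subtypes by marker score.
2. **Feature engineering** (`trseek.normalize_features`) — counts are
   variance-stabilized to negative-binomial Pearson residuals
   r = (x − μ)/√(μ + μ²/θ) with a regularized per-gene dispersion θ; the
   top 10,000 genes by residual variance are selected per dataset,
   intersected across datasets, stripped of TCR-segment and
   dissociation-stress genes (the blacklist), and z-scored within each
   sample.
3. **Panel selection** (`trseek.feature_selection`) — a random forest of
   reactive vs non-reactive cells scores every candidate gene; genes with
   normalized importance strictly greater than 0.0025 form the ordered
   feature panel.
4. **Classifier** (`trseek.tr_classifier`) — a Transformer joint 1D-CNN:
   the z-scored panel vector passes through convolution blocks, transformer
   encoder layers with residual connections, mean pooling, fusion with a
   subtype embedding, and a fully connected head emitting P(reactive).
   Trained with binary cross-entropy/Adam under a clonotype-grouped holdout
   (cells sharing a TCR never straddle the split), monitoring train and
   test loss per epoch.
5. **Repertoire** (`trseek.tcr_repertoire`) — clonotype construction,
   clonal-expansion bins (Rare … Hyperexpanded, right-closed at 1e−4,
   1e−3, 1e−2, 0.1), Shannon / inverse-Simpson / Gini-Simpson / Chao1 /
   Pielou diversity, combined αβ CDR3 length histograms, multi-α/β
   detection (against the ~6% droplet-platform pairing error), and viral
   bystander flagging by exact β-CDR3 match against a VDJdb-style table.
6. **Synthetic cohorts** (`trseek.synthetic_data`) — negative-binomial
   cohorts with planted TR/subtype programs, clonally expanded TCRs, and
   full truth tables, so the entire pipeline runs and is tested without any
   download.

The network is built on a small numpy reverse-mode autodiff engine
(`trseek.nn`), gradient-checked against finite differences in the test
suite; no deep-learning framework is required.

## Worked example

`examples/` contains one short script per capability. Training on a
simulated cohort (`examples/04_train_classifier.py`, 1,200 cells, 20-gene
panel of the planted effect genes):

```
epochs run: 18 (first/last test loss: 0.054 / 0.043)
held-out metrics: {'roc_auc': 1.0, 'pr_auc': 1.0, 'accuracy': 1.0,
                   'precision': 1.0, 'recall': 1.0, 'decision_threshold': 0.5}
          barcode  probability  call
S1-GTCAGCTAATGC-0     0.000183     0
S1-CGATCTTATGTG-1     0.999162     1
```

`probability` is the modeled P(tumor-reactive) for each cell; `call`
applies the fixed 0.5 threshold. Repertoire comparison
(`examples/05_tcr_repertoire.py`) shows the planted biology: the reactive
compartment is oligoclonal (Shannon 2.86 vs 5.99; 3 hyperexpanded clones
vs 0) while non-reactive cells stay near-uniform.

The same stages are scriptable from a shell via the thin `trseek` CLI
(`simulate`, `qc`, `features`, `select`, `train`, `predict`, `tcr`); every
run writes a JSON manifest with config, input checksums, and seed.

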