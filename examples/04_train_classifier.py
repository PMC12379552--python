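"""Train and evaluate the Transformer joint 1D-CNN classifier.

Cells sharing a clonotype never straddle the train/test split (clonal
copies would leak labels).  Training monitors train and held-out test loss
per epoch and early-stops on the test loss.
"""

from trseek.feature_selection import FeaturePanel
from trseek.normalize_features import vst_normalize, zscore
from trseek.qc_gating import filter_cells, filter_genes
from trseek.sc_data import SUBTYPES
from trseek.synthetic_data import SyntheticSpec, generate
from trseek.tr_classifier import ModelConfig, build_model, predict, train

counts, cells, _contigs, truth = generate(
    SyntheticSpec(n_samples=2, cells_per_sample=600, n_genes=800, seed=7)
)
m = filter_genes(filter_cells(counts)[0])
panel = FeaturePanel(truth["genes"]["tr_up"] + truth["genes"]["tr_down"])
z = zscore(vst_normalize(m), panel.genes)
kept = set(z.barcodes)
cells_kept = [c for c in cells if c.barcode in kept]

cfg = ModelConfig.for_panel(len(panel.genes), seed=7, holdout="clonotype")
net = build_model(cfg, len(panel.genes), len(SUBTYPES))
clf = train(net, z, cells_kept, panel, cfg)

print(f"epochs run: {len(clf.history)} "
      f"(first/last test loss: {clf.history[0]['test_loss']:.3f} / "
      f"{clf.history[-1]['test_loss']:.3f})")
print("held-out metrics:", clf.metrics.as_dict())
scores = predict(clf, z, cells_kept)
print(scores.head().to_string(index=False))
# probability is P(tumor-reactive); call applies the fixed 0.5 threshold.
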