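"""Staged feature engineering: NB Pearson residuals -> per-sample HVGs ->
intersection -> blacklist -> per-sample z-scores -> random-forest panel.

The final panel keeps genes whose normalized random-forest importance
against the reactive/nonreactive labels exceeds 0.0025 (strictly).
"""

import numpy as np

from trseek.feature_selection import RfConfig, rf_importance, threshold_features
from trseek.normalize_features import (
    ResidualMatrix, apply_blacklist, intersect_hvgs, select_hvg, vst_normalize,
    zscore,
)
from trseek.qc_gating import filter_cells, filter_genes
from trseek.sc_data import default_blacklist
from trseek.synthetic_data import SyntheticSpec, generate

counts, cells, _contigs, truth = generate(
    SyntheticSpec(n_samples=2, cells_per_sample=500, n_genes=800, seed=11)
)
m = filter_genes(filter_cells(counts)[0])
residuals = vst_normalize(m)

hvg_sets = []
for sid in dict.fromkeys(m.sample_ids):
    cols = np.asarray([s == sid for s in m.sample_ids])
    sub = ResidualMatrix(
        residuals.values[:, cols], residuals.gene_symbols,
        [b for b, c in zip(residuals.barcodes, cols) if c],
        [sid] * int(cols.sum()),
    )
    hvg_sets.append(select_hvg(sub, 10_000, dataset_id=sid))

common = intersect_hvgs(hvg_sets)
candidates = apply_blacklist(common, default_blacklist())
z = zscore(residuals, candidates)

labels = {c.barcode: c.tr_label for c in cells}
fi = rf_importance(z, [labels[b] for b in z.barcodes], RfConfig(seed=11))
panel = threshold_features(fi, 0.0025)

planted = set(truth["genes"]["tr_up"]) | set(truth["genes"]["tr_down"])
print(f"HVG intersection: {len(common)} genes; after blacklist: {len(candidates)}")
print(f"panel above the 0.0025 cut: {len(panel.genes)} genes")
print(f"planted effect genes recovered: "
      f"{len(planted & set(panel.genes))}/{len(planted)}")
print("top 10 panel genes:", panel.genes[:10])
# The panel order (decreasing importance) defines the classifier's input
# layout and is serialized with any trained model.
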