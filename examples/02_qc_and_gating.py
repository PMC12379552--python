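"""Quality control and CD8+ gating.

Cells with fewer than 200 UMIs or more than 15% mitochondrial counts are
excluded (boundary values are retained); genes must be detected in more
than 3 cells.  CD8+ T cells require evidence from both the CD3 lineage pair
(CD3D/CD3G) and the CD8 pair (CD8A/CD8B).
"""

from trseek.qc_gating import QcThresholds, filter_cells, filter_genes, gate_cd8
from trseek.synthetic_data import SyntheticSpec, generate

counts, cells, contigs, truth = generate(
    SyntheticSpec(n_samples=2, cells_per_sample=400, n_genes=800, seed=7)
)

filtered, audit = filter_cells(counts, QcThresholds())
filtered = filter_genes(filtered)
cd8_mask = gate_cd8(filtered)

print(f"input: {counts.n_cells} cells; removed by QC: {len(audit)}")
print(audit["reason"].value_counts().to_string())
print(f"genes surviving detection filter: {filtered.n_genes}/{counts.n_genes}")
print(f"CD8+ cells after gating: {int(cd8_mask.sum())}/{filtered.n_cells}")
# The audit table names each removed barcode and why, so QC decisions are
# traceable sample by sample.
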