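"""TCR repertoire characterization of reactive vs non-reactive cells.

Builds clonotypes from VDJ contigs, flags viral bystanders by exact beta
CDR3 match, and compares clonal expansion, diversity, combined CDR3
lengths, and the multi alpha/beta fraction between compartments.
"""

from trseek.sc_data import default_viral_reference
from trseek.synthetic_data import SyntheticSpec, generate
from trseek.tcr_repertoire import (
    PLATFORM_MULTIPLET_ERROR, build_clonotypes, match_viral, repertoire_stats,
)

_counts, cells, contigs, _truth = generate(
    SyntheticSpec(n_samples=2, cells_per_sample=500, n_genes=800, seed=3)
)
clonotypes = build_clonotypes(contigs)
match_viral(clonotypes, default_viral_reference())

reactive = {c.barcode for c in cells if c.tr_label == "reactive"}
for name, subset in (
    ("tumor-reactive", [c for c in clonotypes if c.barcode in reactive]),
    ("non-reactive", [c for c in clonotypes if c.barcode not in reactive]),
):
    stats = repertoire_stats(subset)
    modal = max(stats.length_hist.items(), key=lambda kv: kv[1])[0]
    print(f"{name}: {len(stats.clone_table)} clones over {len(subset)} cells")
    print(f"  expansion bins: {stats.expansion_bins}")
    print(f"  shannon {stats.diversity['shannon']:.3f}, "
          f"inverse Simpson {stats.diversity['inv_simpson']:.2f}")
    print(f"  modal combined CDR3 length: {modal} aa; "
          f"multi-ab fraction {stats.multi_ab_fraction:.1%} "
          f"(platform error ~{PLATFORM_MULTIPLET_ERROR:.0%})")
n_bystanders = sum(c.bystander for c in clonotypes)
print(f"viral bystander cells: {n_bystanders}")
# Lower diversity and more hyperexpanded bins in the reactive compartment
# reflect the planted clonal expansion of tumor-reactive T cells.
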