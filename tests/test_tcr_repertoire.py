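"""Clonotype construction, viral matching, expansion bins, diversity
indices (cross-checked against scikit-bio), and CDR3 length statistics."""

import numpy as np
import pytest

from trseek._exceptions import ValidationError
from trseek.sc_data import ContigRecord, ViralReference
from trseek.tcr_repertoire import (
    build_clonotypes,
    cdr3_length_distribution,
    clone_frequencies,
    diversity,
    expansion_categories,
    match_viral,
    repertoire_stats,
)


def contig(barcode, chain, cdr3, v="TRAV1", j="TRAJ1", productive=True,
           high_conf=True, umis=5):
    return ContigRecord(barcode, chain, cdr3, v, j, productive, high_conf, umis)


class TestBuildClonotypes:
    def test_single_pair_is_not_multi(self):
        out = build_clonotypes(
            [contig("BC1", "TRA", "CAVRF"), contig("BC1", "TRB", "CASSF")]
        )
        assert len(out) == 1 and not out[0].multi_ab
        assert out[0].clonotype_key == "CAVRF|CASSF"

    def test_two_alphas_flag_multi(self):
        out = build_clonotypes(
            [
                contig("BC1", "TRA", "CAVRF"),
                contig("BC1", "TRA", "CAXYF"),
                contig("BC1", "TRB", "CASSF"),
            ]
        )
        assert out[0].multi_ab
        assert out[0].clonotype_key == "CAVRF;CAXYF|CASSF"

    def test_nonproductive_and_low_confidence_ignored(self):
        out = build_clonotypes(
            [
                contig("BC1", "TRA", "CAVRF"),
                contig("BC1", "TRA", "CAXYF", productive=False),
                contig("BC1", "TRB", "CASSF", high_conf=False),
            ]
        )
        assert out[0].alpha_cdr3s == ["CAVRF"] and out[0].beta_cdr3s == []

    def test_planted_multiplet_tally(self):
        contigs = []
        for i in range(50):
            contigs.append(contig(f"BC{i:02d}", "TRA", f"CAV{i:02d}F"))
            contigs.append(contig(f"BC{i:02d}", "TRB", f"CASS{i:02d}F"))
        for i in range(8):  # plant 8 dual-alpha cells
            contigs.append(contig(f"BC{i:02d}", "TRA", f"CAEXTRA{i}F"))
        out = build_clonotypes(contigs)
        assert sum(c.multi_ab for c in out) == 8
        assert sum(c.multi_ab for c in out) / len(out) == pytest.approx(0.16)

    def test_keys_invariant_to_contig_order(self):
        rng = np.random.default_rng(0)
        contigs = []
        for i in range(20):
            contigs.append(contig(f"BC{i}", "TRA", f"CAV{i}F", umis=int(rng.integers(1, 30))))
            contigs.append(contig(f"BC{i}", "TRB", f"CASS{i}F", umis=int(rng.integers(1, 30))))
        keys = {c.barcode: c.clonotype_key for c in build_clonotypes(contigs)}
        shuffled = list(contigs)
        rng.shuffle(shuffled)
        keys2 = {c.barcode: c.clonotype_key for c in build_clonotypes(shuffled)}
        assert keys == keys2

    def test_primary_chain_is_highest_umi(self):
        out = build_clonotypes(
            [
                contig("BC1", "TRA", "CAVLONGERF", umis=3),
                contig("BC1", "TRA", "CAVRF", umis=9),
                contig("BC1", "TRB", "CASSF", umis=5),
            ]
        )
        assert out[0].primary_alpha == "CAVRF"


class TestMatchViral:
    def ref(self, cdr3s):
        return ViralReference([(c, None, "CMV") for c in cdr3s])

    def test_exact_beta_match_flags_bystander(self):
        cells = build_clonotypes(
            [contig("BC1", "TRA", "CAVRF"), contig("BC1", "TRB", "CASSVIRF")]
        )
        match_viral(cells, self.ref(["CASSVIRF"]))
        assert cells[0].bystander and cells[0].bystander_species == "CMV"

    def test_empty_reference_flags_nothing(self):
        cells = build_clonotypes([contig("BC1", "TRB", "CASSF")])
        match_viral(cells, ViralReference([]))
        assert not cells[0].bystander

    def test_planted_viral_count_recovered(self):
        contigs = []
        for i in range(100):
            beta = f"CASSVIRAL{i:02d}F" if i < 12 else f"CASS{i:02d}F"
            contigs.append(contig(f"BC{i:03d}", "TRA", f"CAV{i}F"))
            contigs.append(contig(f"BC{i:03d}", "TRB", beta))
        cells = build_clonotypes(contigs)
        match_viral(cells, self.ref([f"CASSVIRAL{i:02d}F" for i in range(12)]))
        assert sum(c.bystander for c in cells) == 12


class TestExpansionCategories:
    def test_hyperexpanded_above_ten_percent(self):
        cats = expansion_categories({"A": (2, 0.2), "B": (8, 0.8)})
        assert cats["A"] == "Hyperexpanded"

    def test_boundary_frequency_falls_in_lower_bin(self):
        cats = expansion_categories({"A": (1, 0.1), "B": (9, 0.9)})
        assert cats["A"] == "Large"  # right-closed bins

    def test_partition_every_clone_exactly_once(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 50, size=30)
        freqs = counts / counts.sum()
        table = {f"C{i}": (int(c), float(f)) for i, (c, f) in enumerate(zip(counts, freqs))}
        cats = expansion_categories(table)
        assert set(cats) == set(table)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValidationError, match="frequency"):
            expansion_categories({"A": (1, 1.5)})


class TestDiversity:
    def test_uniform_four_clone_closed_forms(self):
        table = {f"C{i}": (25, 0.25) for i in range(4)}
        d = diversity(table)
        assert d["shannon"] == pytest.approx(np.log(4), abs=1e-12)
        assert d["inv_simpson"] == pytest.approx(4.0, abs=1e-12)
        assert d["pielou_evenness"] == pytest.approx(1.0, abs=1e-12)

    def test_single_clone(self):
        d = diversity({"C": (10, 1.0)})
        assert d["shannon"] == 0.0 and d["inv_simpson"] == 1.0

    def test_chao1_singleton_doubleton_formula(self):
        # S=5 with f1=3 singletons and f2=1 doubleton -> 5 + 3*2/(2*2) = 6.5
        table = clone_frequencies_from_counts([1, 1, 1, 2, 5])
        assert diversity(table)["chao1"] == pytest.approx(6.5)

    def test_matches_scikit_bio(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 40, size=25)
        table = clone_frequencies_from_counts(counts.tolist())
        d = diversity(table)
        assert d["shannon"] == pytest.approx(skbio_alpha.shannon(counts, base=np.e))
        assert d["inv_simpson"] == pytest.approx(skbio_alpha.enspie(counts))
        assert d["chao1"] == pytest.approx(skbio_alpha.chao1(counts, bias_corrected=True))
        assert d["pielou_evenness"] == pytest.approx(skbio_alpha.pielou_e(counts))

    def test_shannon_maximal_iff_uniform(self):
        uniform = diversity(clone_frequencies_from_counts([5, 5, 5]))
        skewed = diversity(clone_frequencies_from_counts([13, 1, 1]))
        assert uniform["shannon"] == pytest.approx(np.log(3))
        assert skewed["shannon"] < uniform["shannon"]
        # duplicating a cell of an existing clone breaks uniformity
        bumped = diversity(clone_frequencies_from_counts([6, 5, 5]))
        assert bumped["shannon"] <= uniform["shannon"]

    def test_inv_simpson_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            counts = rng.integers(1, 30, size=int(rng.integers(1, 15))).tolist()
            d = diversity(clone_frequencies_from_counts(counts))
            assert 1.0 - 1e-12 <= d["inv_simpson"] <= len(counts) + 1e-12


def clone_frequencies_from_counts(counts):
    total = sum(counts)
    return {f"C{i}": (c, c / total) for i, c in enumerate(counts)}


class TestLengthDistribution:
    def test_combined_length_is_sum_of_primaries(self):
        cells = build_clonotypes(
            [
                contig("BC1", "TRA", "C" * 13),
                contig("BC1", "TRB", "C" * 15),
            ]
        )
        assert cdr3_length_distribution(cells) == {28: 1}

    def test_cells_missing_a_chain_excluded(self):
        cells = build_clonotypes([contig("BC1", "TRB", "CASSF")])
        assert cdr3_length_distribution(cells) == {}

    def test_histogram_matches_brute_force_tally(self):
        rng = np.random.default_rng(4)
        lengths = []
        contigs = []
        for i in range(30):
            la, lb = int(rng.integers(8, 20)), int(rng.integers(8, 20))
            lengths.append(la + lb)
            # unique CDR3s so each cell is its own clone
            contigs.append(contig(f"BC{i:02d}", "TRA", f"{i:02d}" + "A" * (la - 2)))
            contigs.append(contig(f"BC{i:02d}", "TRB", f"{i:02d}" + "B" * (lb - 2)))
        hist = cdr3_length_distribution(build_clonotypes(contigs))
        expected = {}
        for L in lengths:
            expected[L] = expected.get(L, 0) + 1
        assert hist == expected


def test_repertoire_stats_frequencies_partition(tiny_cohort):
    _cm, _cells, contigs, truth = tiny_cohort
    cells = build_clonotypes(contigs)
    stats = repertoire_stats(cells)
    assert sum(f for _n, f in stats.clone_table.values()) == pytest.approx(1.0)
    assert sum(stats.expansion_bins.values()) == len(stats.clone_table)
    planted_multi = sum(v["multi_ab"] for v in truth["cells"].values())
    assert sum(c.multi_ab for c in cells) == planted_multi
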