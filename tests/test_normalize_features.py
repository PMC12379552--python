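"""Variance-stabilizing normalization, HVG selection/intersection,
blacklist application, and z-scoring contracts."""

import numpy as np
import pytest

from trseek._exceptions import ValidationError
from trseek.normalize_features import (
    HvgSet,
    ResidualMatrix,
    apply_blacklist,
    intersect_hvgs,
    select_hvg,
    vst_normalize,
    zscore,
)
from trseek.sc_data import GeneBlacklist

from conftest import make_counts


def residual_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    barcodes = [f"BC{i}" for i in range(values.shape[1])]
    samples = samples or ["S1"] * values.shape[1]
    return ResidualMatrix(values, genes, barcodes, samples)


class TestVstNormalize:
    def test_poisson_limit_matches_closed_form(self):
        rng = np.random.default_rng(0)
        n_cells = 100
        counts = rng.poisson(5.0, size=(4, n_cells)) + 1  # keep totals positive
        m = make_counts(counts)
        r = vst_normalize(m, theta=np.inf)
        X = counts.astype(float)
        depth = X.sum(axis=0)
        p = X.sum(axis=1) / X.sum()
        mu = p[:, None] * depth[None, :]
        expected = np.clip((X - mu) / np.sqrt(mu), -np.sqrt(n_cells), np.sqrt(n_cells))
        assert np.abs(r.values - expected).max() < 1e-6

    def test_nb_residual_means_near_zero(self):
        # counts simulated from the NB model the residuals assume
        rng = np.random.default_rng(1)
        n_genes, n_cells, theta = 50, 500, 2.0
        base = rng.lognormal(0.5, 0.8, size=n_genes)
        depth_factor = rng.lognormal(0.0, 0.3, size=n_cells)
        mu = np.outer(base, depth_factor)
        counts = rng.poisson(rng.gamma(theta, mu / theta))
        counts[:, 0] += 1  # guard against an all-zero gene
        keep = counts.sum(axis=1) > 0
        m = make_counts(counts[keep])
        r = vst_normalize(m)
        assert np.abs(r.values.mean(axis=1)).max() < 0.1

    def test_residuals_respect_clipping_bound(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 50, size=(20, 30))
        counts[0, 0] = 100000  # extreme outlier
        counts[:, 1] += 1
        keep = counts.sum(axis=1) > 0
        m = make_counts(counts[keep])
        r = vst_normalize(m)
        assert np.abs(r.values).max() <= np.sqrt(m.n_cells) + 1e-12

    def test_zero_total_gene_rejected(self):
        m = make_counts([[0, 0], [1, 2]])
        with pytest.raises(ValidationError, match="zero total"):
            vst_normalize(m)


class TestSelectHvg:
    def test_fewer_genes_than_requested_returns_all(self):
        rng = np.random.default_rng(3)
        r = residual_matrix(rng.normal(size=(50, 10)))
        assert len(select_hvg(r, 10_000).genes) == 50

    def test_recovers_planted_high_dispersion_genes(self):
        rng = np.random.default_rng(4)
        n_genes, n_cells = 2000, 200
        values = rng.normal(0, 1.0, size=(n_genes, n_cells))
        planted = rng.choice(n_genes, size=100, replace=False)
        values[planted] *= 3.0  # high residual variance
        r = residual_matrix(values)
        top = set(select_hvg(r, 200).genes)
        recovered = sum(f"G{i}" in top for i in planted)
        assert recovered >= 95

    def test_variance_tie_broken_alphabetically(self):
        r = residual_matrix([[1.0, -1.0], [1.0, -1.0]], genes=["ZZZ", "AAA"])
        assert select_hvg(r, 2).genes == ["AAA", "ZZZ"]


class TestIntersectHvgs:
    def test_identity_on_identical_sets(self):
        s = HvgSet("a", ["X", "Y", "Z"])
        assert intersect_hvgs([s, HvgSet("b", ["X", "Y", "Z"])]) == ["X", "Y", "Z"]

    def test_disjoint_sets_yield_empty(self):
        out = intersect_hvgs([HvgSet("a", ["X"]), HvgSet("b", ["Y"])])
        assert out == []

    def test_constructed_overlap_matches_set_intersection(self):
        rng = np.random.default_rng(5)
        shared = [f"S{i}" for i in range(7)]
        sets = []
        for d in range(3):
            private = [f"P{d}_{i}" for i in range(20)]
            genes = shared + private
            rng.shuffle(genes)
            sets.append(HvgSet(str(d), genes))
        out = intersect_hvgs(sets)
        assert set(out) == set(shared)  # brute-force set intersection
        # ordered by mean rank across sets
        rank = {g: np.mean([s.genes.index(g) for s in sets]) for g in shared}
        assert out == sorted(shared, key=lambda g: (rank[g], g))


class TestApplyBlacklist:
    def test_tcr_segment_regex_removal(self):
        bl = GeneBlacklist(regex_patterns=("^TR[ABDG][VDJC]",))
        assert apply_blacklist(["TRBV7-2", "GZMK"], bl) == ["GZMK"]

    def test_empty_blacklist_is_identity(self):
        assert apply_blacklist(["A", "B"], GeneBlacklist()) == ["A", "B"]

    def test_fully_blacklisted_panel_is_empty(self):
        bl = GeneBlacklist(literal_symbols=frozenset({"A", "B"}))
        assert apply_blacklist(["A", "B"], bl) == []


class TestZscore:
    def test_three_point_gene_standardized(self):
        r = residual_matrix([[1.0, 2.0, 3.0]])
        out = zscore(r)
        np.testing.assert_allclose(
            out.values[0], [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )

    def test_constant_gene_maps_to_zeros(self):
        out = zscore(residual_matrix([[5.0, 5.0, 5.0]]))
        assert (out.values == 0).all()

    def test_per_sample_mean_zero_sd_one(self):
        rng = np.random.default_rng(6)
        samples = ["S1"] * 30 + ["S2"] * 20
        out = zscore(residual_matrix(rng.normal(2, 3, size=(10, 50)), samples=samples))
        for sid in ("S1", "S2"):
            cols = [i for i, s in enumerate(samples) if s == sid]
            block = out.values[:, cols]
            assert np.abs(block.mean(axis=1)).max() < 1e-8
            assert np.abs(block.std(axis=1) - 1).max() < 1e-6

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        r = residual_matrix(rng.normal(size=(5, 40)), samples=["S1"] * 20 + ["S2"] * 20)
        once = zscore(r)
        twice = zscore(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-6)

    def test_removes_per_sample_scale_offsets(self):
        rng = np.random.default_rng(8)
        samples = ["S1"] * 25 + ["S2"] * 25
        base = rng.normal(size=(6, 50))
        scaled = base.copy()
        scaled[:, 25:] *= 7.5  # one sample's residuals rescaled
        a = zscore(residual_matrix(base, samples=samples))
        b = zscore(residual_matrix(scaled, samples=samples))
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)


def test_pipeline_panel_contained_in_every_hvg_set(tiny_cohort):
    """The staged order ends with a panel inside every per-dataset HVG set
    and disjoint from the blacklist."""
    from trseek.qc_gating import filter_cells, filter_genes
    from trseek.sc_data import default_blacklist

    cm, _cells, _contigs, _truth = tiny_cohort
    m = filter_genes(filter_cells(cm)[0])
    r = vst_normalize(m)
    sets = []
    for sid in dict.fromkeys(m.sample_ids):
        cols = np.asarray([s == sid for s in m.sample_ids])
        sub = ResidualMatrix(
            r.values[:, cols], r.gene_symbols,
            [b for b, c in zip(r.barcodes, cols) if c], [sid] * int(cols.sum()),
        )
        sets.append(select_hvg(sub, 200, dataset_id=sid))
    common = intersect_hvgs(sets)
    bl = default_blacklist()
    panel = apply_blacklist(common, bl)
    for s in sets:
        assert set(panel) <= set(s.genes)
    assert not any(g in bl for g in panel)
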