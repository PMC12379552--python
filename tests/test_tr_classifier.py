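"""Training behaviour, grouped holdout, prediction contracts, and the
evaluation metrics against brute-force oracles."""

import numpy as np
import pytest

from trseek._exceptions import ValidationError
from trseek.feature_selection import FeaturePanel
from trseek.normalize_features import ResidualMatrix
from trseek.sc_data import SUBTYPES, CellRecord
from trseek.tr_classifier import (
    ModelConfig,
    _grouped_split,
    assemble_inputs,
    build_model,
    evaluate,
    pr_auc,
    predict,
    roc_auc,
    train,
)

FAST_CFG = dict(
    conv_blocks=[(8, 3, 1), (16, 3, 2)], n_transformer_layers=1, n_heads=2,
    embed_dim=16, mlp_dims=[16], subtype_embed_dim=4, dropout=0.0,
    epochs=8, patience=8, batch_size=64,
)


def separable_data(n_cells=300, n_genes=12, seed=0, effect=2.0, n_clones=40):
    """Small z-matrix where reactive cells shift the first half of genes."""
    rng = np.random.default_rng(seed)
    y = rng.random(n_cells) < 0.4
    values = rng.normal(size=(n_genes, n_cells))
    values[: n_genes // 2, y] += effect
    z = ResidualMatrix(
        values,
        [f"G{i}" for i in range(n_genes)],
        [f"BC{i}" for i in range(n_cells)],
        ["S1"] * n_cells,
    )
    clones = rng.integers(0, n_clones, size=n_cells)
    cells = [
        CellRecord(
            barcode=f"BC{i}", sample_id="S1", total_umi=500, mito_fraction=0.05,
            subtype="Tex" if y[i] else "Tn",
            tr_label="reactive" if y[i] else "nonreactive",
            clonotype_key=f"CLONE{'R' if y[i] else 'N'}{clones[i]}",
        )
        for i in range(n_cells)
    ]
    panel = FeaturePanel([f"G{i}" for i in range(n_genes)])
    return z, cells, panel


class TestTrain:
    def test_learns_separable_data(self):
        z, cells, panel = separable_data(seed=1)
        cfg = ModelConfig(seed=1, **FAST_CFG)
        tc = train(build_model(cfg, len(panel), len(SUBTYPES)), z, cells, panel, cfg)
        assert tc.history[-1]["test_loss"] < tc.history[0]["test_loss"]
        assert len(tc.history) <= cfg.epochs

    def test_clonotype_grouping_contract(self):
        # one clonotype spanning 10 cells must land entirely on one side
        groups = ["BIG"] * 10 + [f"g{i}" for i in range(40)]
        y = np.array([1] * 10 + [0, 1] * 20)
        tr, te = _grouped_split(groups, y, 0.3, np.random.default_rng(0))
        big = set(np.flatnonzero(np.asarray(groups) == "BIG"))
        assert big <= set(tr) or big <= set(te)

    def test_degenerate_labels_rejected(self):
        z, cells, panel = separable_data(seed=2)
        for c in cells:
            c.tr_label = "reactive"
        cfg = ModelConfig(seed=2, **FAST_CFG)
        with pytest.raises(ValidationError, match="degenerate"):
            train(build_model(cfg, len(panel), len(SUBTYPES)), z, cells, panel, cfg)

    def test_training_reproducible(self):
        z, cells, panel = separable_data(seed=3, n_cells=150)
        results = []
        for _ in range(2):
            cfg = ModelConfig(seed=3, **FAST_CFG)
            tc = train(build_model(cfg, len(panel), len(SUBTYPES)), z, cells, panel, cfg)
            results.append(tc)
        a, b = results
        assert len(a.history) == len(b.history)
        for ha, hb in zip(a.history, b.history):
            assert abs(ha["train_loss"] - hb["train_loss"]) < 1e-6
        assert abs(a.metrics.roc_auc - b.metrics.roc_auc) < 1e-6


class TestPredict:
    def test_training_cells_rescore_identically(self):
        z, cells, panel = separable_data(seed=4, n_cells=150)
        cfg = ModelConfig(seed=4, **FAST_CFG)
        tc = train(build_model(cfg, len(panel), len(SUBTYPES)), z, cells, panel, cfg)
        out = predict(tc, z, cells)
        scored = dict(zip(out["barcode"], out["probability"]))
        for bc, p in tc.train_probabilities.items():
            assert abs(scored[bc] - p) < 1e-6

    def test_insufficient_panel_coverage_rejected(self):
        z, cells, panel = separable_data(seed=5)
        wide = FeaturePanel(panel.genes + [f"MISSING{i}" for i in range(20)])
        with pytest.raises(ValidationError, match="insufficient panel coverage"):
            assemble_inputs(z, wide, cells)

    def test_missing_panel_genes_zero_filled(self):
        z, cells, panel = separable_data(seed=6)
        wide = FeaturePanel(panel.genes + ["MISSING0"])
        X, _onehot, _y = assemble_inputs(z, wide, cells)
        assert (X[:, -1] == 0).all()

    def test_planted_reactive_cells_score_higher(self):
        z, cells, panel = separable_data(seed=7)
        cfg = ModelConfig(seed=7, **FAST_CFG)
        tc = train(build_model(cfg, len(panel), len(SUBTYPES)), z, cells, panel, cfg)
        out = predict(tc, z, cells)
        probs = dict(zip(out["barcode"], out["probability"]))
        tr = [probs[c.barcode] for c in cells if c.tr_label == "reactive"]
        non = [probs[c.barcode] for c in cells if c.tr_label == "nonreactive"]
        assert np.mean(tr) > np.mean(non)


def brute_force_roc_auc(probs, labels):
    """Concordant-pair fraction over all positive-negative pairs with
    half-credit ties: the independent oracle."""
    pos = [p for p, l in zip(probs, labels) if l == 1]
    neg = [p for p, l in zip(probs, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestEvaluate:
    def test_perfect_classifier(self):
        m = evaluate(np.array([1.0, 0.0, 1.0, 0.0]), np.array([1, 0, 1, 0]))
        assert (m.roc_auc, m.pr_auc, m.accuracy, m.precision, m.recall) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_worked_pair_counting_example(self):
        m = evaluate(np.array([0.9, 0.8, 0.4, 0.3]), np.array([1, 0, 1, 0]))
        assert m.roc_auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="single-class"):
            evaluate(np.array([0.5, 0.6]), np.array([1, 1]))

    def test_roc_auc_equals_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(5, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            probs = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert abs(
                roc_auc(probs, labels) - brute_force_roc_auc(probs, labels)
            ) < 1e-12

    def test_pr_auc_matches_step_interpolation_oracle(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(10, 100))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            probs = np.round(rng.random(n), 2)
            assert abs(
                pr_auc(probs, labels) - average_precision_score(labels, probs)
            ) < 1e-10
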