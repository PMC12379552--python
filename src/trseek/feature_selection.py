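"""Random-forest importance scoring of candidate genes against
tumor-reactivity labels, and hard thresholding into the classifier's feature
panel.

Importances are normalized mean-impurity-decrease weights (they sum to 1),
and the panel keeps genes whose weight is strictly greater than the threshold
(default 0.0025).  Cells are sorted canonically by barcode before fitting so
the result is invariant to input row order under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from ._exceptions import ValidationError
from .normalize_features import ResidualMatrix

logger = logging.getLogger(__name__)


@dataclass
class RfConfig:
    """Random forest hyperparameters (the field-standard defaults)."""

    n_trees: int = 500
    max_depth: int | None = None
    seed: int = 0
    class_balanced: bool = True
    importance: str = "impurity"  # or "permutation"


@dataclass
class FeatureImportance:
    """Per-gene importance weights with the fit configuration recorded."""

    weights: dict[str, float]
    rf_config: RfConfig
    label_counts: tuple[int, int]  # (n_reactive, n_nonreactive)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("negative importance weight")


@dataclass
class FeaturePanel:
    """Ordered gene list defining the classifier input layout.

    The order (decreasing importance, alphabetical tie-break) is part of the
    trained model's contract and is serialized with it.
    """

    genes: list[str]
    threshold: float = 0.0025
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def rf_importance(
    z: ResidualMatrix,
    tr_labels: list[str],
    cfg: RfConfig | None = None,
) -> FeatureImportance:
    """Fit a random forest of reactive vs nonreactive cells and return
    per-gene importance weights.

    Cells labelled ``unknown`` are excluded.  Raises on single-class labels.
    """
    cfg = cfg or RfConfig()
    if len(tr_labels) != len(z.barcodes):
        raise ValidationError("tr_labels length != number of cells")
    labels = np.asarray(tr_labels)
    use = np.isin(labels, ("reactive", "nonreactive"))
    labels = labels[use]
    if len(set(labels)) < 2:
        raise ValidationError("degenerate labels: need both reactive and nonreactive cells")

    X = z.values[:, use].T  # cells x genes
    y = (labels == "reactive").astype(int)
    barcodes = [b for b, u in zip(z.barcodes, use) if u]
    order = np.argsort(barcodes, kind="stable")  # canonical order: by barcode
    X, y = X[order], y[order]

    rf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        max_features="sqrt",
        class_weight="balanced" if cfg.class_balanced else None,
        random_state=cfg.seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    if cfg.importance == "permutation":
        imp = permutation_importance(
            rf, X, y, n_repeats=5, random_state=cfg.seed, n_jobs=1
        ).importances_mean
        imp = np.maximum(imp, 0.0)
        if imp.sum() > 0:
            imp = imp / imp.sum()
    else:
        imp = rf.feature_importances_  # normalized impurity decrease, sums to 1
    weights = {g: float(w) for g, w in zip(z.gene_symbols, imp)}
    n_pos = int(y.sum())
    return FeatureImportance(weights, cfg, (n_pos, len(y) - n_pos))


def threshold_features(
    fi: FeatureImportance, threshold: float = 0.0025
) -> FeaturePanel:
    """Keep genes whose weight is strictly greater than ``threshold``,
    ordered by decreasing weight (ties alphabetical)."""
    if not fi.weights:
        raise ValidationError("empty feature importance table")
    kept = [(g, w) for g, w in fi.weights.items() if w > threshold]
    if not kept:
        raise ValidationError(
            f"threshold {threshold} removes all {len(fi.weights)} features"
        )
    kept.sort(key=lambda gw: (-gw[1], gw[0]))
    logger.info(
        "threshold_features: %d of %d genes above %g",
        len(kept), len(fi.weights), threshold,
    )
    return FeaturePanel(
        genes=[g for g, _ in kept],
        threshold=threshold,
        provenance={
            "rf_config": fi.rf_config,
            "label_counts": fi.label_counts,
        },
    )
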