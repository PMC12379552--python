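"""The Transformer joint 1D-CNN tumor-reactivity classifier.

Each cell is represented by its z-scored expression over the feature panel
(a 1 x panel_len signal) plus a categorical subtype covariate.  Convolution
blocks extract local expression motifs, transformer encoder layers with
residual connections mix them globally, the token sequence is mean-pooled,
fused with a learned subtype embedding, and a fully connected head outputs
the probability that the cell is tumor-reactive.  Training minimizes binary
cross-entropy with Adam, monitors train and held-out test loss each epoch,
and early-stops on the test loss.

Holdout splitting is grouped by clonotype by default so cells sharing a TCR
never straddle the train/test boundary (clonal copies would otherwise leak
labels); a patient-level mode groups by sample instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from ._exceptions import ConfigError, ValidationError
from .feature_selection import FeaturePanel
from .nn import (
    Adam,
    Conv1d,
    LayerNorm,
    Linear,
    Module,
    Tensor,
    TransformerEncoderLayer,
    no_grad,
)
from .normalize_features import ResidualMatrix
from .sc_data import SUBTYPES, CellRecord

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``conv_blocks`` is a list of (channels, kernel, stride) tuples applied to
    the 1-channel panel signal; ``holdout`` selects the grouping used for the
    train/test split.
    """

    conv_blocks: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(32, 9, 2), (64, 9, 2)]
    )
    n_transformer_layers: int = 2
    n_heads: int = 4
    embed_dim: int = 64
    mlp_dims: list[int] = field(default_factory=lambda: [64, 32])
    subtype_embed_dim: int = 16
    dropout: float = 0.1
    loss: str = "binary-cross-entropy"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 128
    patience: int = 10
    seed: int = 0
    holdout: str = "clonotype"  # clonotype | patient | random
    test_fraction: float = 0.25
    class_weighting: bool = True

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ConfigError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.holdout not in ("clonotype", "patient", "random"):
            raise ConfigError(f"unknown holdout mode {self.holdout!r}")

    def receptive_ok(self, panel_len: int) -> bool:
        length = panel_len
        for _c, k, s in self.conv_blocks:
            if length < k:
                return False
            length = (length - k) // s + 1
        return length >= 1

    @classmethod
    def for_panel(cls, panel_len: int, **overrides) -> "ModelConfig":
        """Default config with conv kernels shrunk, if necessary, to fit a
        short panel (panels below ~25 genes cannot support two kernel-9
        blocks)."""
        cfg = cls(**overrides)
        if cfg.receptive_ok(panel_len):
            return cfg
        for k in (7, 5, 3):
            candidate = [(c, k, s) for c, _k, s in cfg.conv_blocks]
            trial = cls(**{**overrides, "conv_blocks": candidate})
            if trial.receptive_ok(panel_len):
                return trial
        trial = cls(**{**overrides, "conv_blocks": [(32, 3, 1)]})
        if trial.receptive_ok(panel_len):
            return trial
        raise ConfigError(f"panel of length {panel_len} is too short for any conv stack")


@dataclass
class EvalMetrics:
    roc_auc: float
    pr_auc: float
    accuracy: float
    precision: float
    recall: float
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("roc_auc", "pr_auc", "accuracy", "precision", "recall"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")

    def as_dict(self) -> dict:
        return asdict(self)


class TrNet(Module):
    """The network: conv blocks -> transformer encoder stack -> mean pool,
    fused with a subtype embedding, then an MLP head producing a logit."""

    def __init__(self, cfg: ModelConfig, panel_len: int, n_subtypes: int) -> None:
        super().__init__()
        if not cfg.receptive_ok(panel_len):
            raise ConfigError(
                f"panel_len {panel_len} shorter than the conv receptive field"
            )
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.panel_len = panel_len
        self.n_subtypes = n_subtypes

        self.convs: list[Conv1d] = []
        c_in, length = 1, panel_len
        for c_out, k, s in cfg.conv_blocks:
            conv = Conv1d(rng, c_in, c_out, k, s)
            self.convs.append(conv)
            length = conv.out_length(length)
            c_in = c_out
        self.n_tokens = length
        self.proj = Linear(rng, c_in, cfg.embed_dim)
        self.pos = Tensor(
            rng.normal(0.0, 0.02, size=(1, length, cfg.embed_dim)), requires_grad=True
        )
        self.encoder = [
            TransformerEncoderLayer(
                rng, cfg.embed_dim, cfg.n_heads, 2 * cfg.embed_dim, cfg.dropout
            )
            for _ in range(cfg.n_transformer_layers)
        ]
        self.final_norm = LayerNorm(cfg.embed_dim)
        self.subtype_embed = Linear(rng, n_subtypes, cfg.subtype_embed_dim)
        dims = [cfg.embed_dim + cfg.subtype_embed_dim] + list(cfg.mlp_dims) + [1]
        self.head = [Linear(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]

    def forward_logits(self, x: np.ndarray, subtype_onehot: np.ndarray) -> Tensor:
        """x: (B, panel_len) z-scores; subtype_onehot: (B, n_subtypes)."""
        B = x.shape[0]
        h = Tensor(x).reshape(B, 1, self.panel_len)
        for conv in self.convs:
            h = conv(h).gelu()
        tokens = self.proj(h.transpose(0, 2, 1)) + self.pos  # (B, T, E)
        for layer in self.encoder:
            tokens = layer(tokens)
        pooled = self.final_norm(tokens).mean(axis=1)  # (B, E)
        sub = self.subtype_embed(Tensor(subtype_onehot))  # (B, S_e)
        # concatenation expressed as a block-linear first head layer
        first = self.head[0]
        e = self.cfg.embed_dim
        h = pooled @ _view(first.weight, slice(0, e)) \
            + sub @ _view(first.weight, slice(e, None)) + first.bias
        h = h.gelu()
        for layer in self.head[1:-1]:
            h = layer(h).gelu()
        return self.head[-1](h).reshape(B)

    def predict_proba(self, x: np.ndarray, subtype_onehot: np.ndarray) -> np.ndarray:
        self.eval()
        with no_grad():
            logits = self.forward_logits(x, subtype_onehot)
        return expit(logits.data)


def _view(t: Tensor, rows: slice) -> Tensor:
    """A differentiable row-slice of a parameter matrix."""
    out = Tensor(t.data[rows])

    def backward(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            full[rows] = g
            t._accumulate(full)

    out.requires_grad = t.requires_grad
    if out.requires_grad:
        out._parents = (t,)
        out._backward = backward
    return out


@dataclass
class TrainedClassifier:
    """Trained weights plus everything needed to reproduce predictions:
    the feature panel (order is part of the contract), the subtype
    vocabulary, the config, the loss history, and held-out metrics."""

    net: TrNet
    panel: FeaturePanel
    subtype_vocab: list[str]
    config: ModelConfig
    history: list[dict]
    metrics: EvalMetrics | None
    resubstitution_metrics: EvalMetrics | None = None
    train_probabilities: dict[str, float] = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savez(out_dir / "weights.npz", *self.net.state_arrays())
        meta = {
            "panel": self.panel.genes,
            "panel_threshold": self.panel.threshold,
            "subtype_vocab": self.subtype_vocab,
            "config": _config_dict(self.config),
            "history": self.history,
            "metrics": self.metrics.as_dict() if self.metrics else None,
            "resubstitution_metrics": (
                self.resubstitution_metrics.as_dict()
                if self.resubstitution_metrics
                else None
            ),
        }
        (out_dir / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, out_dir: str | Path) -> "TrainedClassifier":
        out_dir = Path(out_dir)
        meta = json.loads((out_dir / "model.json").read_text())
        cfg_d = meta["config"]
        cfg_d["conv_blocks"] = [tuple(b) for b in cfg_d["conv_blocks"]]
        cfg = ModelConfig(**cfg_d)
        panel = FeaturePanel(meta["panel"], meta["panel_threshold"])
        net = TrNet(cfg, len(panel.genes), len(meta["subtype_vocab"]))
        with np.load(out_dir / "weights.npz") as z:
            net.load_state_arrays([z[k] for k in z.files])
        metrics = EvalMetrics(**meta["metrics"]) if meta["metrics"] else None
        resub = (
            EvalMetrics(**meta["resubstitution_metrics"])
            if meta.get("resubstitution_metrics")
            else None
        )
        return cls(net, panel, meta["subtype_vocab"], cfg, meta["history"], metrics, resub)


def _config_dict(cfg: ModelConfig) -> dict:
    d = asdict(cfg)
    d["conv_blocks"] = [list(b) for b in cfg.conv_blocks]
    return d


def build_model(cfg: ModelConfig, panel_len: int, n_subtypes: int) -> TrNet:
    """Construct the untrained network; logs the parameter count."""
    net = TrNet(cfg, panel_len, n_subtypes)
    logger.info(
        "built TrNet: panel_len=%d, %d tokens, %d parameters",
        panel_len, net.n_tokens, net.n_parameters(),
    )
    return net


def _subtype_onehot(subtypes: list[str], vocab: list[str]) -> np.ndarray:
    index = {s: i for i, s in enumerate(vocab)}
    unassigned = index.get("Unassigned")
    onehot = np.zeros((len(subtypes), len(vocab)))
    warned = False
    for i, s in enumerate(subtypes):
        j = index.get(s)
        if j is None:
            if not warned:
                logger.warning("subtype %r outside vocabulary; mapped to Unassigned", s)
                warned = True
            j = unassigned if unassigned is not None else 0
        onehot[i, j] = 1.0
    return onehot


def _grouped_split(
    groups: list[str],
    y: np.ndarray,
    test_fraction: float,
    rng: np.random.Generator,
    max_tries: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Split cell indices so no group straddles the boundary, with at least
    one cell of each class on each side."""
    unique = sorted(set(groups))
    group_arr = np.asarray(groups)
    n = len(groups)
    for _ in range(max_tries):
        perm = list(unique)
        rng.shuffle(perm)
        test_groups: set[str] = set()
        n_test = 0
        for g in perm:
            if n_test >= test_fraction * n:
                break
            test_groups.add(g)
            n_test += int((group_arr == g).sum())
        is_test = np.asarray([g in test_groups for g in groups])
        if (
            0 < y[is_test].sum() < is_test.sum()
            and 0 < y[~is_test].sum() < (~is_test).sum()
        ):
            return np.flatnonzero(~is_test), np.flatnonzero(is_test)
    raise ValidationError(
        "degenerate split: could not place both classes on both sides of the holdout"
    )


def assemble_inputs(
    z: ResidualMatrix,
    panel: FeaturePanel,
    cells: list[CellRecord],
    min_coverage: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (X, subtype one-hot, y) for the network from a z-scored matrix.

    Panel genes absent from the matrix are zero-filled with a warning; below
    ``min_coverage`` presence it is an error.  y is -1 for unknown labels.
    """
    idx = z.gene_index()
    present = [g for g in panel.genes if g in idx]
    coverage = len(present) / len(panel.genes)
    if coverage < min_coverage:
        raise ValidationError(
            f"insufficient panel coverage: {coverage:.0%} of panel genes present"
        )
    if len(present) < len(panel.genes):
        logger.warning(
            "zero-filling %d missing panel genes", len(panel.genes) - len(present)
        )
    X = np.zeros((len(z.barcodes), len(panel.genes)))
    for j, g in enumerate(panel.genes):
        if g in idx:
            X[:, j] = z.values[idx[g]]
    by_barcode = {c.barcode: c for c in cells}
    subtypes, y = [], []
    for b in z.barcodes:
        c = by_barcode.get(b)
        subtypes.append(c.subtype if c else "Unassigned")
        if c is None or c.tr_label == "unknown":
            y.append(-1)
        else:
            y.append(1 if c.tr_label == "reactive" else 0)
    onehot = _subtype_onehot(subtypes, list(SUBTYPES))
    return X, onehot, np.asarray(y)


def _bce_loss(logits: Tensor, y: np.ndarray, weights: np.ndarray) -> Tensor:
    """Weighted binary cross-entropy on logits, numerically stable.

    loss_i = w_i * (softplus(z_i) - y_i * z_i); softplus computed via a
    custom closed-form gradient (sigmoid(z) - y)."""
    z = logits.data
    sp = np.where(z > 0, z + np.log1p(np.exp(-z)), np.log1p(np.exp(z)))
    per = weights * (sp - y * z)
    out = Tensor(np.array(per.mean()))

    def backward(g):
        if logits.requires_grad:
            logits._accumulate(g * weights * (expit(z) - y) / z.size)

    out.requires_grad = logits.requires_grad
    if out.requires_grad:
        out._parents = (logits,)
        out._backward = backward
    return out


def train(
    net: TrNet,
    z: ResidualMatrix,
    cells: list[CellRecord],
    panel: FeaturePanel,
    cfg: ModelConfig | None = None,
) -> TrainedClassifier:
    """Train on labeled cells with a grouped holdout; returns the classifier
    with per-epoch train/test losses and held-out metrics."""
    cfg = cfg or net.cfg
    X, onehot, y_all = assemble_inputs(z, panel, cells)
    labeled = np.flatnonzero(y_all >= 0)
    if labeled.size == 0:
        raise ValidationError("no labeled cells")
    y = y_all[labeled]
    if len(set(y.tolist())) < 2:
        raise ValidationError("degenerate labels: need both classes to train")

    by_barcode = {c.barcode: c for c in cells}
    rng = np.random.default_rng(cfg.seed + 1)
    if cfg.holdout == "clonotype":
        groups = [
            (by_barcode[z.barcodes[i]].clonotype_key or f"__solo__{z.barcodes[i]}")
            for i in labeled
        ]
    elif cfg.holdout == "patient":
        groups = [z.sample_ids[i] for i in labeled]
    else:
        groups = [z.barcodes[i] for i in labeled]
    tr_rel, te_rel = _grouped_split(groups, y, cfg.test_fraction, rng)
    train_idx, test_idx = labeled[tr_rel], labeled[te_rel]

    y_tr, y_te = y_all[train_idx].astype(float), y_all[test_idx].astype(float)
    if cfg.class_weighting:
        n_pos, n_neg = y_tr.sum(), len(y_tr) - y_tr.sum()
        w_pos = len(y_tr) / (2.0 * max(n_pos, 1.0))
        w_neg = len(y_tr) / (2.0 * max(n_neg, 1.0))
    else:
        w_pos = w_neg = 1.0

    def weights_for(yv: np.ndarray) -> np.ndarray:
        return np.where(yv > 0.5, w_pos, w_neg)

    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    history: list[dict] = []
    best_loss, best_state, patience_left = np.inf, None, cfg.patience

    def eval_loss(idx: np.ndarray, yv: np.ndarray) -> float:
        net.eval()
        total, n = 0.0, 0
        with no_grad():
            for start in range(0, len(idx), cfg.batch_size):
                sl = idx[start : start + cfg.batch_size]
                logits = net.forward_logits(X[sl], onehot[sl])
                yb = yv[start : start + cfg.batch_size]
                loss = _bce_loss(logits, yb, weights_for(yb))
                total += float(loss.data) * len(sl)
                n += len(sl)
        return total / max(n, 1)

    for epoch in range(cfg.epochs):
        net.train()
        order = rng.permutation(len(train_idx))
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            sl = train_idx[order[start : start + cfg.batch_size]]
            yb = y_all[sl].astype(float)
            opt.zero_grad()
            logits = net.forward_logits(X[sl], onehot[sl])
            loss = _bce_loss(logits, yb, weights_for(yb))
            if not np.isfinite(loss.data):
                raise ValidationError(
                    f"NaN/inf loss at epoch {epoch}; lr={cfg.learning_rate}, "
                    f"batch={len(sl)}"
                )
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(sl)
            n_seen += len(sl)
        test_loss = eval_loss(test_idx, y_te)
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n_seen, "test_loss": test_loss}
        )
        if test_loss < best_loss - 1e-6:
            best_loss, best_state, patience_left = test_loss, net.state_arrays(), cfg.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                logger.info("early stopping at epoch %d", epoch)
                break
    if best_state is not None:
        net.load_state_arrays(best_state)

    probs_te = net.predict_proba(X[test_idx], onehot[test_idx])
    metrics = evaluate(probs_te, y_all[test_idx])
    probs_tr = net.predict_proba(X[train_idx], onehot[train_idx])
    resub = evaluate(probs_tr, y_all[train_idx])
    train_probs = {
        z.barcodes[i]: float(p) for i, p in zip(train_idx, probs_tr)
    }
    logger.info(
        "trained %d epochs; held-out ROC AUC %.3f, PR AUC %.3f",
        len(history), metrics.roc_auc, metrics.pr_auc,
    )
    return TrainedClassifier(
        net=net,
        panel=panel,
        subtype_vocab=list(SUBTYPES),
        config=cfg,
        history=history,
        metrics=metrics,
        resubstitution_metrics=resub,
        train_probabilities=train_probs,
    )


def predict(
    tc: TrainedClassifier,
    z: ResidualMatrix,
    cells: list[CellRecord] | None = None,
    decision_threshold: float = 0.5,
) -> "pd.DataFrame":
    """Score cells with a trained classifier.

    Returns a DataFrame (barcode, probability, call).  Panel genes missing
    from ``z`` are zero-filled (error below 50% coverage); subtypes outside
    the vocabulary map to Unassigned with a warning.
    """
    import pandas as pd

    cells = cells or []
    X, onehot, _ = assemble_inputs(z, tc.panel, cells)
    probs = np.concatenate(
        [
            tc.net.predict_proba(X[s : s + 512], onehot[s : s + 512])
            for s in range(0, X.shape[0], 512)
        ]
    ) if X.shape[0] else np.array([])
    return pd.DataFrame(
        {
            "barcode": z.barcodes,
            "probability": probs,
            "call": (probs >= decision_threshold).astype(int),
        }
    )


def roc_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the midrank Mann-Whitney statistic (ties get half credit)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("single-class labels")
    ranks = rankdata(probs)  # midranks
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def pr_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by the step-interpolation rule
    (sum over thresholds of delta-recall times precision)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValidationError("single-class labels")
    order = np.argsort(-probs, kind="stable")
    sorted_p, sorted_y = probs[order], labels[order]
    tp = np.cumsum(sorted_y)
    fp = np.cumsum(1 - sorted_y)
    # collapse tied probabilities to a single operating point
    distinct = np.flatnonzero(np.diff(sorted_p)).tolist() + [len(sorted_p) - 1]
    area, prev_recall = 0.0, 0.0
    for i in distinct:
        precision = tp[i] / (tp[i] + fp[i])
        recall = tp[i] / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return float(area)


def evaluate(
    probs: np.ndarray, labels: np.ndarray, decision_threshold: float = 0.5
) -> EvalMetrics:
    """ROC AUC, PR AUC, and threshold metrics for binary labels."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValidationError("single-class labels")
    calls = (probs >= decision_threshold).astype(int)
    tp = int(((calls == 1) & (labels == 1)).sum())
    fp = int(((calls == 1) & (labels == 0)).sum())
    fn = int(((calls == 0) & (labels == 1)).sum())
    accuracy = float((calls == labels).mean())
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    return EvalMetrics(
        roc_auc=float(roc_auc(probs, labels)),
        pr_auc=float(pr_auc(probs, labels)),
        accuracy=accuracy,
        precision=float(precision),
        recall=float(recall),
        decision_threshold=decision_threshold,
    )
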