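"""Staged feature engineering: variance-stabilizing normalization to
negative-binomial Pearson residuals, per-dataset highly-variable-gene (HVG)
selection, cross-dataset HVG intersection, blacklist removal, and per-sample
z-scoring.

The normalization models each count x_gc as NB with mean mu_gc = p_g * d_c
(gene fraction times cell depth) and gene-wise dispersion theta_g estimated by
method of moments and regularized toward a kernel-smoothed trend over
log-mean.  Pearson residuals r = (x - mu) / sqrt(mu + mu^2/theta) are clipped
at +/- sqrt(n_cells) to bound outlier leverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ValidationError
from .sc_data import CountMatrix, GeneBlacklist

logger = logging.getLogger(__name__)


@dataclass
class ResidualMatrix:
    """Real-valued genes x cells matrix with normalization provenance."""

    values: np.ndarray
    gene_symbols: list[str]
    barcodes: list[str]
    sample_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_symbols), len(self.barcodes)):
            raise ValidationError("residual matrix shape mismatch")
        if len(self.sample_ids) != len(self.barcodes):
            raise ValidationError("sample_ids length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite residual values")

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_symbols)}

    def subset_genes(self, genes: list[str]) -> "ResidualMatrix":
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ResidualMatrix(
            self.values[rows], list(genes), self.barcodes, self.sample_ids,
            dict(self.provenance),
        )


@dataclass
class HvgSet:
    """Ordered highly-variable-gene list for one dataset (decreasing residual
    variance)."""

    dataset_id: str
    genes: list[str]
    n_requested: int = 10_000


def _regularize_dispersion(log_mean: np.ndarray, log_theta_mom: np.ndarray) -> np.ndarray:
    """Nadaraya-Watson kernel regression of log theta on log gene mean.

    Bandwidth is Silverman's rule on the log means; returns the smoothed
    log-theta evaluated at every gene.
    """
    n = log_mean.size
    if n == 1:
        return log_theta_mom.copy()
    sd = np.std(log_mean)
    bw = max(0.9 * sd * n ** (-1 / 5), 1e-3)
    # pairwise Gaussian weights; n_genes is at most tens of thousands, but a
    # chunked evaluation keeps memory flat
    out = np.empty(n)
    chunk = 2048
    for start in range(0, n, chunk):
        d = (log_mean[start : start + chunk, None] - log_mean[None, :]) / bw
        w = np.exp(-0.5 * d * d)
        out[start : start + chunk] = (w @ log_theta_mom) / w.sum(axis=1)
    return out


def vst_normalize(
    m: CountMatrix,
    theta: float | None = None,
    clip: float | None = None,
) -> ResidualMatrix:
    """Variance-stabilize raw counts to NB Pearson residuals.

    Parameters
    ----------
    m
        QC-filtered counts; every gene must have a nonzero total (run
        ``filter_genes`` first).
    theta
        If given, a fixed dispersion shared by all genes (``np.inf`` gives
        the Poisson limit (x - mu)/sqrt(mu)).  Default: per-gene
        method-of-moments estimate regularized along the mean trend.
    clip
        Residual clipping bound; default sqrt(n_cells).
    """
    if m.n_cells < 2:
        raise ValidationError("vst_normalize needs at least 2 cells")
    X = m.values.toarray().astype(np.float64)
    gene_tot = X.sum(axis=1)
    if np.any(gene_tot == 0):
        bad = [m.gene_symbols[i] for i in np.flatnonzero(gene_tot == 0)[:5]]
        raise ValidationError(
            f"gene(s) with zero total count (run filter_genes first): {bad}"
        )
    depth = X.sum(axis=0)
    total = depth.sum()
    p = gene_tot / total  # gene fraction of all counts
    mu = p[:, None] * depth[None, :]

    if theta is None:
        # method-of-moments: Var(x) = E[mu] + E[mu^2]/theta across cells
        var_x = X.var(axis=1)
        mean_mu = mu.mean(axis=1)
        mean_mu2 = (mu * mu).mean(axis=1)
        excess = np.maximum(var_x - mean_mu, 1e-10)
        theta_mom = np.clip(mean_mu2 / excess, 1e-3, 1e6)
        log_mean = np.log10(np.maximum(gene_tot / m.n_cells, 1e-12))
        log_theta = _regularize_dispersion(log_mean, np.log10(theta_mom))
        theta_g = 10.0 ** log_theta
    else:
        theta_g = np.full(m.n_genes, float(theta))

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(mu + mu * mu / theta_g[:, None])
    resid = (X - mu) / denom
    bound = float(clip) if clip is not None else float(np.sqrt(m.n_cells))
    resid = np.clip(resid, -bound, bound)
    provenance = {
        "normalization": "nb_pearson_residuals",
        "theta": "regularized_mom" if theta is None else float(theta),
        "theta_per_gene": theta_g,
        "gene_fraction": p,
        "clip": bound,
    }
    return ResidualMatrix(resid, list(m.gene_symbols), list(m.barcodes),
                          list(m.sample_ids), provenance)


def select_hvg(r: ResidualMatrix, n: int = 10_000, dataset_id: str = "") -> HvgSet:
    """Rank genes by residual variance and keep the top ``n``.

    Ties are broken alphabetically by gene symbol so runs are reproducible.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    var = r.values.var(axis=1)
    order = sorted(range(len(r.gene_symbols)),
                   key=lambda i: (-var[i], r.gene_symbols[i]))
    top = order[: min(n, len(order))]
    return HvgSet(dataset_id or (r.sample_ids[0] if r.sample_ids else ""),
                  [r.gene_symbols[i] for i in top], n)


def intersect_hvgs(sets: list[HvgSet]) -> list[str]:
    """Genes present in every HVG set, ordered by mean rank across sets
    (tie: alphabetical)."""
    if not sets:
        raise ValidationError("need at least one HVG set")
    common = set(sets[0].genes)
    for s in sets[1:]:
        common &= set(s.genes)
    if not common:
        logger.warning("intersect_hvgs: empty intersection across %d sets", len(sets))
        return []
    rank_maps = [{g: i for i, g in enumerate(s.genes)} for s in sets]
    mean_rank = {g: float(np.mean([rm[g] for rm in rank_maps])) for g in common}
    return sorted(common, key=lambda g: (mean_rank[g], g))


def apply_blacklist(genes: list[str], bl: GeneBlacklist) -> list[str]:
    """Drop genes matching the blacklist (literals or regexes); order kept."""
    kept = [g for g in genes if g not in bl]
    removed = len(genes) - len(kept)
    if removed:
        logger.info("apply_blacklist: removed %d of %d genes", removed, len(genes))
    if genes and not kept:
        logger.warning("apply_blacklist: every gene was blacklisted")
    return kept


def zscore(
    r: ResidualMatrix,
    genes: list[str] | None = None,
    per_sample: bool = True,
) -> ResidualMatrix:
    """Standardize each gene to mean 0, population SD 1.

    By default standardization is computed within each sample (batch) so that
    per-sample depth and batch offsets are removed; ``per_sample=False`` gives
    a single global standardization.  Zero-variance genes map to all zeros.
    """
    sub = r.subset_genes(genes) if genes is not None else r
    X = sub.values.copy()
    samples = np.asarray(sub.sample_ids)
    groups = [np.flatnonzero(samples == s) for s in dict.fromkeys(sub.sample_ids)] \
        if per_sample else [np.arange(X.shape[1])]
    for cols in groups:
        block = X[:, cols]
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)  # population SD
        centered = block - mean
        X[:, cols] = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    prov = dict(sub.provenance)
    prov["zscore_scope"] = "per_sample" if per_sample else "global"
    return ResidualMatrix(X, sub.gene_symbols, sub.barcodes, sub.sample_ids, prov)
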