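"""Generator of labeled scRNA + scTCR datasets with the statistical
structure the pipeline assumes, so every stage runs without downloads.

Counts are negative-binomial (gamma-Poisson) with per-gene baseline means,
lognormal per-cell depths, and lognormal per-sample batch factors.  Planted
structure: tumor-reactive (TR) cells up-regulate an exhaustion program
(CTLA4/CXCL13/HAVCR2 and companions) and down-regulate mitochondrial
respiratory-chain genes (MT-*); each subtype up-regulates its marker
program; TR cells draw clonotypes from a power law (clonal expansion) while
non-TR clones stay near-uniform; a fraction of cells carries an extra
productive alpha chain (multi alpha/beta), and a fraction of non-TR cells
carries a beta CDR3 from the shipped viral reference (bystanders).  Truth
tables record every planted label.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._exceptions import ConfigError
from .qc_gating import default_markers
from .sc_data import (
    SUBTYPES,
    CellRecord,
    ContigRecord,
    CountMatrix,
    default_viral_reference,
    write_10x,
    write_contigs,
)

logger = logging.getLogger(__name__)

_AA = "ACDEFGHIKLMNPQRSTVWY"

_DEFAULT_SUBTYPE_PROPS = {
    "GZMK+Tem": 0.20,
    "Tex": 0.20,
    "Temra": 0.10,
    "Trm": 0.10,
    "NK-like": 0.10,
    "Tn": 0.10,
    "Tm": 0.10,
    "Proliferative": 0.10,
    "Unassigned": 0.0,
}

_DEFAULT_TR_UP = [
    "CTLA4", "CXCL13", "HAVCR2", "PDCD1", "LAG3",
    "TIGIT", "TNFRSF9", "ENTPD1", "TOX", "CD27",
]
_DEFAULT_TR_DOWN = [
    "MT-ATP6", "MT-ND1", "MT-ND3", "MT-CO1", "MT-CO2",
    "MT-CO3", "MT-ND2", "MT-ND4", "MT-CYB", "MT-ATP8",
]
_TCR_SEGMENT_GENES = ["TRBV7-2", "TRAV1-2", "TRBJ2-7", "TRAJ33", "TRBC2", "TRGV9"]


@dataclass
class SyntheticSpec:
    """Study conditions for one simulated cohort.

    Defaults give 4 samples x 1,000 cells over a 2,000-gene universe with a
    25% TR fraction and 20 planted effect genes (10 up, 10 down).
    """

    n_samples: int = 4
    cells_per_sample: int = 1000
    n_genes: int = 2000
    frac_tr: float = 0.25
    subtype_props: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SUBTYPE_PROPS)
    )
    tr_up_genes: list[str] = field(default_factory=lambda: list(_DEFAULT_TR_UP))
    tr_down_genes: list[str] = field(default_factory=lambda: list(_DEFAULT_TR_DOWN))
    lfc_up: float = 2.0
    lfc_down: float = -1.0
    subtype_lfc: float = 3.0
    nb_dispersion: float = 2.0
    batch_scale_sd: float = 0.15
    depth_lognormal_params: tuple[float, float] = (math.log(2000.0), 0.35)
    clonal_alpha: float = 1.5
    frac_multi_ab: float = 0.08
    frac_viral: float = 0.05
    frac_low_quality: float = 0.03
    mito_baseline_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.subtype_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"subtype_props sums to {total}, not 1")
        for name in self.subtype_props:
            if name not in SUBTYPES:
                raise ConfigError(f"unknown subtype {name!r}")
        for frac in (self.frac_tr, self.frac_multi_ab, self.frac_viral,
                     self.frac_low_quality):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.batch_scale_sd < 0:
            raise ConfigError("batch_scale_sd must be >= 0")


def _gene_universe(spec: SyntheticSpec) -> list[str]:
    markers = default_markers()
    named: list[str] = []
    for g in (
        markers.cd8_markers
        + [m for ms in markers.subtype_markers.values() for m in ms]
        + spec.tr_up_genes
        + spec.tr_down_genes
        + _TCR_SEGMENT_GENES
    ):
        if g not in named:
            named.append(g)
    if len(named) > spec.n_genes:
        raise ConfigError(
            f"n_genes={spec.n_genes} smaller than the {len(named)} named genes"
        )
    fillers = [f"GENE{i:04d}" for i in range(spec.n_genes - len(named))]
    return named + fillers


def _random_cdr3(rng: np.random.Generator, prefix: str = "CA") -> str:
    length = int(np.clip(round(rng.normal(14.0, 1.5)), 8, 22))
    core = "".join(rng.choice(list(_AA), size=max(length - len(prefix) - 1, 1)))
    return prefix + core + "F"


def generate(
    spec: SyntheticSpec | None = None,
) -> tuple[CountMatrix, list[CellRecord], list[ContigRecord], dict]:
    """Simulate one cohort.

    Returns the count matrix (genes x cells), per-cell records with planted
    subtype/TR labels and clonotype keys, the VDJ contig table, and a truth
    dictionary recording every planted label (including the clonotype ->
    label table used for supervised training).
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    genes = _gene_universe(spec)
    gene_idx = {g: i for i, g in enumerate(genes)}
    for g in spec.tr_up_genes + spec.tr_down_genes:
        if g not in gene_idx:
            raise ConfigError(f"effect gene {g!r} absent from the gene universe")
    markers = default_markers()
    n_genes = len(genes)
    n_cells = spec.n_samples * spec.cells_per_sample

    # --- baseline gene weights -------------------------------------------
    w = rng.lognormal(0.0, 1.0, size=n_genes)
    named_boost: list[str] = []
    for g in (
        markers.cd8_markers
        + [m for ms in markers.subtype_markers.values() for m in ms]
        + spec.tr_up_genes
    ):
        if g not in named_boost:
            named_boost.append(g)
    for g in named_boost:
        if g in gene_idx:
            w[gene_idx[g]] = rng.lognormal(1.2, 0.3)
    for g in markers.cd8_markers:
        w[gene_idx[g]] = rng.lognormal(2.0, 0.2)
    # mitochondrial genes get a fixed share of baseline expression
    mito_idx = [gene_idx[g] for g in genes if g.startswith("MT-")]
    if mito_idx:
        non_mito = np.ones(n_genes, bool)
        non_mito[mito_idx] = False
        w[mito_idx] = (
            spec.mito_baseline_fraction
            * w[non_mito].sum()
            / (1.0 - spec.mito_baseline_fraction)
            / len(mito_idx)
        )
    w = w / w.sum()

    # --- cell-level assignments ------------------------------------------
    sample_ids, barcodes = [], []
    subtype_names = [s for s, p in spec.subtype_props.items()]
    subtype_p = np.array([spec.subtype_props[s] for s in subtype_names])
    subtypes = np.empty(n_cells, dtype=object)
    is_tr = np.zeros(n_cells, bool)
    depth = np.empty(n_cells)
    low_quality = np.zeros(n_cells, bool)
    mu_d, sd_d = spec.depth_lognormal_params
    for s in range(spec.n_samples):
        sl = slice(s * spec.cells_per_sample, (s + 1) * spec.cells_per_sample)
        sid = f"S{s + 1}"
        sample_ids += [sid] * spec.cells_per_sample
        barcodes += [
            f"{sid}-{''.join(rng.choice(list('ACGT'), size=12))}-{i}"
            for i in range(spec.cells_per_sample)
        ]
        subtypes[sl] = rng.choice(subtype_names, size=spec.cells_per_sample, p=subtype_p)
        is_tr[sl] = rng.random(spec.cells_per_sample) < spec.frac_tr
        depth[sl] = rng.lognormal(mu_d, sd_d, size=spec.cells_per_sample)
    low = rng.random(n_cells) < spec.frac_low_quality
    low_quality[:] = low
    batch = rng.lognormal(0.0, spec.batch_scale_sd, size=spec.n_samples)

    # --- per-cell gene means + NB sampling --------------------------------
    up_idx = np.array([gene_idx[g] for g in spec.tr_up_genes])
    down_idx = np.array([gene_idx[g] for g in spec.tr_down_genes])
    marker_idx = {
        s: np.array([gene_idx[m] for m in ms if m in gene_idx])
        for s, ms in markers.subtype_markers.items()
    }
    theta = spec.nb_dispersion
    rows, cols, vals = [], [], []
    sample_of = np.repeat(np.arange(spec.n_samples), spec.cells_per_sample)
    for c in range(n_cells):
        wc = w.copy()
        if is_tr[c]:
            wc[up_idx] *= 2.0 ** spec.lfc_up
            wc[down_idx] *= 2.0 ** spec.lfc_down
        midx = marker_idx.get(subtypes[c])
        if midx is not None and midx.size:
            wc[midx] *= 2.0 ** spec.subtype_lfc
        d = depth[c]
        if low_quality[c]:
            if c % 2 == 0:
                d = rng.uniform(40.0, 180.0)  # fails the UMI floor
            else:
                wc[mito_idx] *= 6.0  # fails the mitochondrial ceiling
        mu = wc / wc.sum() * d * batch[sample_of[c]]
        lam = rng.gamma(theta, mu / theta)
        counts = rng.poisson(lam)
        nz = np.flatnonzero(counts)
        rows.append(nz)
        cols.append(np.full(nz.size, c))
        vals.append(counts[nz])
    matrix = sp.csr_matrix(
        (
            np.concatenate(vals),
            (np.concatenate(rows), np.concatenate(cols)),
        ),
        shape=(n_genes, n_cells),
    )
    cm = CountMatrix(matrix, genes, barcodes, sample_ids)

    # --- clonotypes and contigs ------------------------------------------
    viral_cdr3s = sorted(default_viral_reference().cdr3_set())
    clone_alpha: dict[int, str] = {}
    clone_beta: dict[int, str] = {}
    cell_clone = np.empty(n_cells, dtype=int)
    next_clone = 0
    for s in range(spec.n_samples):
        cells_s = np.arange(s * spec.cells_per_sample, (s + 1) * spec.cells_per_sample)
        tr_cells = cells_s[is_tr[cells_s]]
        nontr_cells = cells_s[~is_tr[cells_s]]
        # TR clones: power-law sizes (clonal expansion)
        k_tr = max(3, len(tr_cells) // 8)
        weights = np.arange(1, k_tr + 1, dtype=float) ** (-spec.clonal_alpha)
        weights /= weights.sum()
        assign = rng.choice(k_tr, size=len(tr_cells), p=weights)
        for local, cell in zip(assign, tr_cells):
            cell_clone[cell] = next_clone + int(local)
        next_clone += k_tr
        # non-TR clones: near-uniform, 1-3 cells each
        i = 0
        shuffled = rng.permutation(nontr_cells)
        while i < len(shuffled):
            size = int(rng.integers(1, 4))
            for cell in shuffled[i : i + size]:
                cell_clone[cell] = next_clone
            next_clone += 1
            i += size
    for clone in range(next_clone):
        clone_alpha[clone] = _random_cdr3(rng, "CAV")
        clone_beta[clone] = _random_cdr3(rng, "CASS")

    # bystanders: some non-TR cells get a viral beta CDR3 (their own clone)
    nontr_all = np.flatnonzero(~is_tr)
    n_viral = int(round(spec.frac_viral * len(nontr_all)))
    viral_cells = set(
        rng.choice(nontr_all, size=n_viral, replace=False).tolist()
    ) if n_viral else set()
    viral_beta = {}
    for j, cell in enumerate(sorted(viral_cells)):
        viral_beta[cell] = viral_cdr3s[j % len(viral_cdr3s)]

    multi_cells = set(
        np.flatnonzero(rng.random(n_cells) < spec.frac_multi_ab).tolist()
    )

    contigs: list[ContigRecord] = []
    cell_key: list[str] = []
    for c in range(n_cells):
        clone = int(cell_clone[c])
        alpha = clone_alpha[clone]
        beta = viral_beta.get(c, clone_beta[clone])
        alphas = [alpha]
        if c in multi_cells:
            extra = _random_cdr3(rng, "CAV")
            while extra == alpha:
                extra = _random_cdr3(rng, "CAV")
            alphas.append(extra)
        key = ";".join(sorted(alphas)) + "|" + beta
        cell_key.append(key)
        for a in alphas:
            contigs.append(
                ContigRecord(
                    barcode=barcodes[c], chain="TRA", cdr3_aa=a,
                    v_gene=f"TRAV{1 + clone % 40}", j_gene=f"TRAJ{1 + clone % 50}",
                    productive=True, high_confidence=True,
                    umis=int(1 + rng.poisson(15)),
                )
            )
        contigs.append(
            ContigRecord(
                barcode=barcodes[c], chain="TRB", cdr3_aa=beta,
                v_gene=f"TRBV{1 + clone % 30}", j_gene=f"TRBJ{1 + clone % 12}",
                productive=True, high_confidence=True,
                umis=int(1 + rng.poisson(20)),
            )
        )
        if rng.random() < 0.02:  # occasional non-productive contig
            contigs.append(
                ContigRecord(
                    barcode=barcodes[c], chain="TRA",
                    cdr3_aa=_random_cdr3(rng, "CAV"),
                    v_gene="TRAV2", j_gene="TRAJ3",
                    productive=False, high_confidence=True,
                    umis=int(1 + rng.poisson(2)),
                )
            )

    label_table = {
        cell_key[c]: ("reactive" if is_tr[c] else "nonreactive")
        for c in range(n_cells)
    }

    total = cm.total_umi()
    mito = cm.mito_fraction()
    cell_records = [
        CellRecord(
            barcode=barcodes[c],
            sample_id=sample_ids[c],
            total_umi=int(total[c]),
            mito_fraction=float(mito[c]),
            is_cd8=True,
            subtype=str(subtypes[c]),
            tr_label="reactive" if is_tr[c] else "nonreactive",
            clonotype_key=cell_key[c],
        )
        for c in range(n_cells)
    ]

    truth = {
        "spec": {**asdict(spec), "subtype_props": dict(spec.subtype_props)},
        "cells": {
            barcodes[c]: {
                "tr_label": "reactive" if is_tr[c] else "nonreactive",
                "subtype": str(subtypes[c]),
                "clonotype_key": cell_key[c],
                "multi_ab": c in multi_cells,
                "viral": c in viral_cells,
                "low_quality": bool(low_quality[c]),
            }
            for c in range(n_cells)
        },
        "genes": {"tr_up": list(spec.tr_up_genes), "tr_down": list(spec.tr_down_genes)},
        "clonotype_labels": label_table,
    }
    logger.info(
        "generated %d cells (%d TR), %d genes, %d contigs",
        n_cells, int(is_tr.sum()), n_genes, len(contigs),
    )
    return cm, cell_records, contigs, truth


_FIXTURE_SPECS = {
    "tiny": dict(n_samples=2, cells_per_sample=90, n_genes=300),
    "small": dict(n_samples=2, cells_per_sample=400, n_genes=800),
    "default": {},
}


def make_fixtures(out_dir: str | Path, size: str = "tiny", seed: int = 0) -> dict:
    """Write a simulated cohort to disk in the external formats.

    Creates one MatrixMarket triplet per sample under ``counts/<sample>/``,
    a contig CSV, a clonotype label CSV, and a truth JSON.  Returns the
    truth dictionary.
    """
    if size not in _FIXTURE_SPECS:
        raise ConfigError(f"size must be one of {sorted(_FIXTURE_SPECS)}")
    spec = SyntheticSpec(seed=seed, **_FIXTURE_SPECS[size])
    cm, cells, contigs, truth = generate(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid in dict.fromkeys(cm.sample_ids):
        mask = [s == sid for s in cm.sample_ids]
        write_10x(cm.subset_cells(np.asarray(mask)), out_dir / "counts" / sid)
    write_contigs(contigs, out_dir / "contigs.csv")
    pd.DataFrame(
        [{"clonotype_key": k, "label": v} for k, v in truth["clonotype_labels"].items()]
    ).to_csv(out_dir / "labels.csv", index=False)
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth
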