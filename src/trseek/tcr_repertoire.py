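"""TCR repertoire characterization: clonotype construction from VDJ contigs,
bystander (viral) CDR3 matching, clonal-expansion categories, diversity
indices, combined alpha-beta CDR3 length distribution, and multi-chain
(multi alpha/beta) detection.

A clonotype is the canonical string "sorted alpha CDR3 set | sorted beta
CDR3 set", so the key is invariant to contig input order.  Only productive,
high-confidence contigs contribute.  The multi-alpha/beta fraction is
reported alongside the ~6% systematic pairing error of droplet platforms as
context; cells exceeding one distinct chain per locus are flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ValidationError
from .sc_data import ContigRecord, ViralReference

logger = logging.getLogger(__name__)

#: Droplet-platform systematic alpha/beta pairing error rate, for context
#: when interpreting multi_ab_fraction.
PLATFORM_MULTIPLET_ERROR = 0.06

#: Right-closed clonal-expansion frequency bins (scRepertoire-style defaults).
EXPANSION_BINS: tuple[tuple[str, float, float], ...] = (
    ("Rare", 0.0, 1e-4),
    ("Small", 1e-4, 1e-3),
    ("Medium", 1e-3, 1e-2),
    ("Large", 1e-2, 0.1),
    ("Hyperexpanded", 0.1, 1.0),
)


@dataclass
class CellClonotype:
    """Per-cell TCR chain summary with the canonical clonotype key."""

    barcode: str
    alpha_cdr3s: list[str]
    beta_cdr3s: list[str]
    clonotype_key: str
    multi_ab: bool
    primary_alpha: str = ""
    primary_beta: str = ""
    bystander: bool = False
    bystander_species: str = ""


@dataclass
class RepertoireStats:
    """Clone table, expansion bins, diversity indices, CDR3 length
    histogram, and the multi alpha/beta fraction for one cell universe."""

    clone_table: dict[str, tuple[int, float]]
    expansion_bins: dict[str, int]
    diversity: dict[str, float]
    length_hist: dict[int, int]
    multi_ab_fraction: float

    def __post_init__(self) -> None:
        if self.clone_table:
            total = sum(freq for _n, freq in self.clone_table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"clone frequencies sum to {total}, not 1")
        if not 0.0 <= self.multi_ab_fraction <= 1.0:
            raise ValidationError("multi_ab_fraction outside [0, 1]")


def build_clonotypes(contigs: list[ContigRecord]) -> list[CellClonotype]:
    """Group contigs by barcode into per-cell clonotypes.

    Only productive AND high-confidence contigs are used; within a cell,
    chains are deduplicated by (chain, CDR3, V gene, J gene).  The primary
    chain per locus is the one with the highest UMI count (tie: smallest
    CDR3 lexicographically).  ``multi_ab`` flags cells with more than one
    distinct alpha or beta CDR3.
    """
    per_cell: dict[str, dict[tuple[str, str, str, str], int]] = {}
    for c in contigs:
        if not (c.productive and c.high_confidence):
            continue
        key = (c.chain, c.cdr3_aa, c.v_gene, c.j_gene)
        cell = per_cell.setdefault(c.barcode, {})
        cell[key] = cell.get(key, 0) + c.umis
    out: list[CellClonotype] = []
    for barcode in sorted(per_cell):
        chains = per_cell[barcode]
        alphas = {cdr3 for (chain, cdr3, _v, _j) in chains if chain == "TRA"}
        betas = {cdr3 for (chain, cdr3, _v, _j) in chains if chain == "TRB"}

        def primary(chain_name: str) -> str:
            candidates = [
                (umis, cdr3)
                for (chain, cdr3, _v, _j), umis in chains.items()
                if chain == chain_name
            ]
            if not candidates:
                return ""
            return min(candidates, key=lambda uc: (-uc[0], uc[1]))[1]

        key = ";".join(sorted(alphas)) + "|" + ";".join(sorted(betas))
        out.append(
            CellClonotype(
                barcode=barcode,
                alpha_cdr3s=sorted(alphas),
                beta_cdr3s=sorted(betas),
                clonotype_key=key,
                multi_ab=len(alphas) > 1 or len(betas) > 1,
                primary_alpha=primary("TRA"),
                primary_beta=primary("TRB"),
            )
        )
    return out


def match_viral(
    clonotypes: list[CellClonotype],
    ref: ViralReference,
    mode: str = "cdr3b_exact",
) -> list[CellClonotype]:
    """Flag bystander cells whose beta CDR3 exactly matches a viral
    reference entry.

    ``cdr3b_exact`` matches on the CDR3 amino-acid string alone;
    ``cdr3b_v_exact`` additionally requires the V gene recorded in the
    reference (entries without a V gene match on CDR3 alone).  Returns the
    same objects with ``bystander``/``bystander_species`` set.
    """
    if mode not in ("cdr3b_exact", "cdr3b_v_exact"):
        raise ValidationError(f"unknown viral matching mode {mode!r}")
    cdr3s = ref.cdr3_set()
    for cell in clonotypes:
        cell.bystander = False
        cell.bystander_species = ""
        for beta in cell.beta_cdr3s:
            if beta in cdr3s:
                cell.bystander = True
                cell.bystander_species = ref.species_of(beta) or ""
                break
    n = sum(c.bystander for c in clonotypes)
    if n:
        logger.info("match_viral: flagged %d of %d cells as bystanders", n, len(clonotypes))
    return clonotypes


def clone_frequencies(clonotypes: list[CellClonotype]) -> dict[str, tuple[int, float]]:
    """Clone table over a cell universe: key -> (cell count, frequency)."""
    counts: dict[str, int] = {}
    for c in clonotypes:
        counts[c.clonotype_key] = counts.get(c.clonotype_key, 0) + 1
    total = sum(counts.values())
    return {k: (n, n / total) for k, n in sorted(counts.items())}


def expansion_categories(
    clone_table: dict[str, tuple[int, float]],
    bins: tuple[tuple[str, float, float], ...] = EXPANSION_BINS,
) -> dict[str, str]:
    """Assign each clone its expansion category by frequency.

    Bins are right-closed: a frequency exactly on an edge falls in the lower
    bin (0.1 -> Large, not Hyperexpanded).
    """
    out: dict[str, str] = {}
    for key, (_n, freq) in clone_table.items():
        if not 0.0 < freq <= 1.0:
            raise ValidationError(f"clone frequency {freq} outside (0, 1]")
        for name, lo, hi in bins:
            if lo < freq <= hi:
                out[key] = name
                break
    return out


def diversity(clone_table: dict[str, tuple[int, float]]) -> dict[str, float]:
    """Diversity indices of the clone frequency distribution.

    shannon = -sum p ln p; inv_simpson = 1/sum p^2; gini_simpson =
    1 - sum p^2; chao1 = S + f1(f1-1)/(2(f2+1)) from singleton/doubleton
    counts; pielou = shannon / ln S (1.0 for a single clone).
    """
    if not clone_table:
        raise ValidationError("empty clone table")
    counts = np.array([n for n, _f in clone_table.values()], dtype=float)
    p = counts / counts.sum()
    shannon = float(-(p * np.log(p)).sum())
    sum_p2 = float((p * p).sum())
    S = len(counts)
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return {
        "shannon": shannon,
        "inv_simpson": 1.0 / sum_p2,
        "gini_simpson": 1.0 - sum_p2,
        "chao1": S + f1 * (f1 - 1) / (2.0 * (f2 + 1)),
        "pielou_evenness": shannon / math.log(S) if S > 1 else 1.0,
    }


def cdr3_length_distribution(clonotypes: list[CellClonotype]) -> dict[int, int]:
    """Histogram of combined alpha+beta CDR3 length over clones.

    Per clone, length = len(primary alpha CDR3) + len(primary beta CDR3);
    cells lacking either chain are excluded.  Each clonotype contributes
    once.
    """
    seen: dict[str, int] = {}
    for c in clonotypes:
        if not c.primary_alpha or not c.primary_beta:
            continue
        seen.setdefault(c.clonotype_key, len(c.primary_alpha) + len(c.primary_beta))
    hist: dict[int, int] = {}
    for length in seen.values():
        hist[length] = hist.get(length, 0) + 1
    return dict(sorted(hist.items()))


def repertoire_stats(clonotypes: list[CellClonotype]) -> RepertoireStats:
    """Full repertoire summary for one cell universe (e.g. the TR cells of
    one patient): clone table, expansion bin counts, diversity indices,
    combined CDR3 length histogram, and the multi alpha/beta fraction."""
    if not clonotypes:
        raise ValidationError("no clonotypes")
    table = clone_frequencies(clonotypes)
    categories = expansion_categories(table)
    bin_counts = {name: 0 for name, _lo, _hi in EXPANSION_BINS}
    for cat in categories.values():
        bin_counts[cat] += 1
    multi = sum(c.multi_ab for c in clonotypes) / len(clonotypes)
    return RepertoireStats(
        clone_table=table,
        expansion_bins=bin_counts,
        diversity=diversity(table),
        length_hist=cdr3_length_distribution(clonotypes),
        multi_ab_fraction=multi,
    )
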