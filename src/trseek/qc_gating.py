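"""Cell/gene quality control, CD8+ marker gating, marker-score subtype
annotation, and clonotype-based tumor-reactivity label propagation.

Boundary semantics are strict exclusions: a cell with *fewer than* ``min_umi``
UMIs or *more than* ``max_mito_fraction`` mitochondrial counts is removed, so
cells at exactly the threshold are retained; a gene detected in *more than*
``min_cells_per_gene`` cells is kept, so a gene in exactly that many cells is
removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, ValidationError
from .sc_data import SUBTYPES, CellRecord, CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    """QC cutoffs. Defaults: min 200 UMIs, max 15% mitochondrial counts,
    genes kept when detected in more than 3 cells."""

    min_umi: int = 200
    max_mito_fraction: float = 0.15
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if self.min_umi < 0:
            raise ConfigError("min_umi must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ConfigError("max_mito_fraction must be in [0, 1]")


@dataclass
class MarkerTable:
    """Subtype -> marker genes mapping plus the CD8 lineage marker list."""

    subtype_markers: dict[str, list[str]]
    cd8_markers: list[str] = field(
        default_factory=lambda: ["CD3D", "CD3G", "CD8A", "CD8B"]
    )

    def __post_init__(self) -> None:
        for subtype, markers in self.subtype_markers.items():
            if subtype not in SUBTYPES:
                raise ConfigError(f"unknown subtype {subtype!r} in marker table")
            if not markers:
                raise ConfigError(f"empty marker list for subtype {subtype!r}")
        if not self.cd8_markers:
            raise ConfigError("cd8_markers must be non-empty")


def read_markers(path: str | Path) -> MarkerTable:
    """Read a marker TSV with columns ``set`` (subtype name or ``CD8``) and
    ``gene``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    subtype_markers: dict[str, list[str]] = {}
    cd8: list[str] = []
    for row in df.itertuples(index=False):
        if row.set == "CD8":
            cd8.append(row.gene)
        else:
            subtype_markers.setdefault(row.set, []).append(row.gene)
    if not cd8:
        cd8 = ["CD3D", "CD3G", "CD8A", "CD8B"]
    return MarkerTable(subtype_markers, cd8)


def default_markers() -> MarkerTable:
    """The shipped default marker table (user-overridable)."""
    with resources.as_file(
        resources.files("trseek._resources") / "markers_default.tsv"
    ) as p:
        return read_markers(p)


def filter_cells(
    m: CountMatrix,
    thresholds: QcThresholds | None = None,
    mito_prefix: str = "MT-",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove cells with too few UMIs or too high a mitochondrial fraction.

    Returns the filtered matrix and an audit table listing each removed
    barcode with the reason (``low_umi`` and/or ``high_mito``).  The
    mitochondrial fraction is computed on raw counts before any gene
    filtering.
    """
    t = thresholds or QcThresholds()
    total = m.total_umi()
    mito = m.mito_fraction(mito_prefix)
    low_umi = total < t.min_umi
    high_mito = mito > t.max_mito_fraction
    keep = ~(low_umi | high_mito)

    audit_rows = []
    for i in np.flatnonzero(~keep):
        reasons = []
        if low_umi[i]:
            reasons.append("low_umi")
        if high_mito[i]:
            reasons.append("high_mito")
        audit_rows.append(
            {
                "barcode": m.barcodes[i],
                "reason": "+".join(reasons),
                "total_umi": int(total[i]),
                "mito_fraction": float(mito[i]),
            }
        )
    audit = pd.DataFrame(
        audit_rows, columns=["barcode", "reason", "total_umi", "mito_fraction"]
    )
    if not keep.any():
        logger.warning("filter_cells removed every cell")
    return m.subset_cells(keep), audit


def filter_genes(m: CountMatrix, thresholds: QcThresholds | None = None) -> CountMatrix:
    """Keep genes detected (count > 0) in strictly more than
    ``min_cells_per_gene`` cells."""
    t = thresholds or QcThresholds()
    detected_in = np.asarray((m.values > 0).sum(axis=1)).ravel()
    return m.subset_genes(detected_in > t.min_cells_per_gene)


def cell_qc_table(m: CountMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC statistics (barcode, sample, total UMIs, mito fraction)."""
    return pd.DataFrame(
        {
            "barcode": m.barcodes,
            "sample_id": m.sample_ids,
            "total_umi": m.total_umi(),
            "mito_fraction": m.mito_fraction(mito_prefix),
        }
    )


def gate_cd8(m: CountMatrix, markers: MarkerTable | None = None) -> np.ndarray:
    """Flag CD8+ T cells by marker expression.

    A cell is CD8+ iff it has nonzero counts for at least one CD3 lineage
    marker (CD3D or CD3G) AND at least one CD8 marker (CD8A or CD8B).  With a
    custom marker list, the first half is treated as the lineage pair and the
    second half as the CD8 pair.
    """
    mk = markers or default_markers()
    idx = m.gene_index()
    present = [g for g in mk.cd8_markers if g in idx]
    if not present:
        raise ConfigError(
            f"none of the CD8 gating markers {mk.cd8_markers} present in the matrix"
        )
    half = max(1, len(mk.cd8_markers) // 2)
    lineage = [g for g in mk.cd8_markers[:half] if g in idx]
    cd8 = [g for g in mk.cd8_markers[half:] if g in idx]

    def any_positive(genes: list[str]) -> np.ndarray:
        if not genes:
            # pair entirely absent from the matrix: no evidence against
            return np.ones(m.n_cells, dtype=bool)
        rows = m.values[[idx[g] for g in genes]]
        return np.asarray((rows > 0).sum(axis=0)).ravel() > 0

    return any_positive(lineage) & any_positive(cd8)


def annotate_subtypes(
    z_values: np.ndarray,
    gene_symbols: list[str],
    markers: MarkerTable | None = None,
) -> list[str]:
    """Assign each cell the subtype whose marker genes score highest.

    ``z_values`` is a normalized genes x cells matrix (z-scored residuals).
    score(subtype) = mean normalized expression of that subtype's markers
    present in the matrix; the argmax wins.  Exact ties and cells where no
    subtype scores positive are labelled ``Unassigned``.
    """
    mk = markers or default_markers()
    if not mk.subtype_markers:
        raise ConfigError("empty marker table")
    idx = {g: i for i, g in enumerate(gene_symbols)}
    names: list[str] = []
    scores = []
    for subtype, marker_genes in sorted(mk.subtype_markers.items()):
        rows = [idx[g] for g in marker_genes if g in idx]
        if not rows:
            continue
        names.append(subtype)
        scores.append(np.asarray(z_values[rows]).mean(axis=0))
    if len(names) < 2:
        raise ConfigError(
            "marker table covers fewer than 2 subtypes present in the matrix"
        )
    score_matrix = np.vstack(scores)  # subtypes x cells
    best = np.argmax(score_matrix, axis=0)
    best_score = score_matrix[best, np.arange(score_matrix.shape[1])]
    # a tie between the top two subtypes, or no positive evidence -> Unassigned
    sorted_scores = np.sort(score_matrix, axis=0)
    tie = sorted_scores[-1] == sorted_scores[-2] if score_matrix.shape[0] >= 2 else np.zeros_like(best_score, bool)
    out = []
    for c in range(score_matrix.shape[1]):
        if tie[c] or best_score[c] <= 0:
            out.append("Unassigned")
        else:
            out.append(names[best[c]])
    return out


def label_by_clonotype(
    cells: list[CellRecord], labels: dict[str, str]
) -> list[CellRecord]:
    """Propagate clonotype-level reactive/nonreactive labels to cells.

    Cells whose ``clonotype_key`` appears in the table receive its label; all
    others keep ``unknown``.  Returns new records (input not mutated).
    """
    for key, label in labels.items():
        if label not in ("reactive", "nonreactive"):
            raise ValidationError(f"invalid label {label!r} for clonotype {key!r}")
    out = []
    counts = {"reactive": 0, "nonreactive": 0, "unknown": 0}
    for cell in cells:
        label = labels.get(cell.clonotype_key, "unknown") if cell.clonotype_key else "unknown"
        counts[label] += 1
        out.append(
            CellRecord(
                barcode=cell.barcode,
                sample_id=cell.sample_id,
                total_umi=cell.total_umi,
                mito_fraction=cell.mito_fraction,
                doublet_flag=cell.doublet_flag,
                is_cd8=cell.is_cd8,
                subtype=cell.subtype,
                tr_label=label,
                clonotype_key=cell.clonotype_key,
            )
        )
    logger.info(
        "label_by_clonotype: %d reactive, %d nonreactive, %d unknown",
        counts["reactive"],
        counts["nonreactive"],
        counts["unknown"],
    )
    return out
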