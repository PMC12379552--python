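"""Core data model and I/O for single-cell count matrices, VDJ contig tables,
gene blacklists, viral CDR3 references, and clonotype label tables.

Conventions
-----------
Count matrices are stored genes x cells (the 10x MatrixMarket layout); every
reader converts to this orientation.  Gene symbols and cell barcodes are
unique within a matrix.  Mitochondrial genes are recognised by the
case-sensitive symbol prefix ``MT-`` unless overridden.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Closed vocabulary of CD8+ T cell subtypes used as the categorical covariate.
SUBTYPES: tuple[str, ...] = (
    "GZMK+Tem",
    "Temra",
    "Tex",
    "Trm",
    "NK-like",
    "Tn",
    "Tm",
    "Proliferative",
    "Unassigned",
)

#: Allowed tumor-reactivity labels.
TR_LABELS: tuple[str, ...] = ("reactive", "nonreactive", "unknown")

_TRUE_STRINGS = {"True", "TRUE", "true"}


@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI matrix, genes x cells.

    Parameters
    ----------
    values
        ``scipy.sparse`` matrix of shape (n_genes, n_cells) holding raw UMI
        counts.  Stored as CSR.
    gene_symbols
        Unique gene symbols, one per row.
    barcodes
        Unique cell barcodes, one per column.
    sample_ids
        Sample (batch) identifier per cell.
    """

    values: sp.spmatrix
    gene_symbols: list[str]
    barcodes: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_symbols = list(self.gene_symbols)
        self.barcodes = list(self.barcodes)
        self.sample_ids = list(self.sample_ids)
        n_genes, n_cells = self.values.shape
        if len(self.gene_symbols) != n_genes:
            raise ValidationError(
                f"gene symbol count {len(self.gene_symbols)} != matrix rows {n_genes}"
            )
        if len(self.barcodes) != n_cells:
            raise ValidationError(
                f"barcode count {len(self.barcodes)} != matrix columns {n_cells}"
            )
        if len(self.sample_ids) != n_cells:
            raise ValidationError(
                f"sample_ids length {len(self.sample_ids)} != number of cells {n_cells}"
            )
        if len(set(self.gene_symbols)) != n_genes:
            raise ValidationError("duplicate gene symbols")
        if len(set(self.barcodes)) != n_cells:
            raise ValidationError("duplicate barcodes")
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative count")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer count")
        self.values = self.values.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_symbols)}

    def total_umi(self) -> np.ndarray:
        """Per-cell total UMI counts."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def mito_fraction(self, prefix: str = "MT-") -> np.ndarray:
        """Per-cell fraction of counts from mitochondrial genes.

        Computed on raw counts.  Cells with zero total UMIs get fraction 0.
        """
        is_mito = np.array([g.startswith(prefix) for g in self.gene_symbols])
        total = self.total_umi().astype(float)
        if not is_mito.any():
            return np.zeros(self.n_cells)
        mito = np.asarray(self.values[is_mito].sum(axis=0)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1e-300), 0.0)
        return frac

    def subset_genes(self, mask_or_indices) -> "CountMatrix":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[idx],
            [self.gene_symbols[i] for i in idx],
            self.barcodes,
            self.sample_ids,
        )

    def subset_cells(self, mask_or_indices) -> "CountMatrix":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[:, idx],
            self.gene_symbols,
            [self.barcodes[i] for i in idx],
            [self.sample_ids[i] for i in idx],
        )


@dataclass
class CellRecord:
    """Per-cell QC statistics and labels carried through the pipeline."""

    barcode: str
    sample_id: str
    total_umi: int
    mito_fraction: float
    doublet_flag: bool = False
    is_cd8: bool = False
    subtype: str = "Unassigned"
    tr_label: str = "unknown"
    clonotype_key: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.mito_fraction <= 1.0:
            raise ValidationError(
                f"mito_fraction {self.mito_fraction} outside [0, 1] for {self.barcode}"
            )
        if self.subtype not in SUBTYPES:
            raise ValidationError(f"unknown subtype {self.subtype!r}")
        if self.tr_label not in TR_LABELS:
            raise ValidationError(f"unknown tr_label {self.tr_label!r}")


@dataclass
class GeneBlacklist:
    """Genes excluded from classifier features: literal symbols plus regexes.

    Default content covers TCR segment genes and dissociation-induced stress
    genes; membership testing is deterministic and order-independent.
    """

    literal_symbols: frozenset[str] = frozenset()
    regex_patterns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.literal_symbols = frozenset(self.literal_symbols)
        self.regex_patterns = tuple(self.regex_patterns)
        try:
            self._compiled = [re.compile(p) for p in self.regex_patterns]
        except re.error as exc:
            raise FormatError(f"invalid blacklist regex {exc.pattern!r}: {exc}") from exc

    def __contains__(self, symbol: str) -> bool:
        if symbol in self.literal_symbols:
            return True
        return any(p.search(symbol) for p in self._compiled)

    def __len__(self) -> int:
        return len(self.literal_symbols) + len(self.regex_patterns)


@dataclass
class ContigRecord:
    """One VDJ contig (one assembled TCR chain for one cell)."""

    barcode: str
    chain: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    productive: bool
    high_confidence: bool
    umis: int

    def __post_init__(self) -> None:
        if self.chain not in ("TRA", "TRB"):
            raise ValidationError(f"chain must be TRA or TRB, got {self.chain!r}")
        if self.productive and not self.cdr3_aa:
            raise ValidationError(f"productive contig with empty CDR3 for {self.barcode}")


@dataclass
class ViralReference:
    """Public viral-antigen-specific beta-chain CDR3 table (VDJdb-style)."""

    rows: list[tuple[str, str | None, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cdr3, _v, _species in self.rows:
            if not cdr3:
                raise ValidationError("empty CDR3 in viral reference")

    def cdr3_set(self) -> frozenset[str]:
        return frozenset(r[0] for r in self.rows)

    def species_of(self, cdr3: str) -> str | None:
        for row_cdr3, _v, species in self.rows:
            if row_cdr3 == cdr3:
                return species
        return None


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_lines(path: str | Path) -> list[str]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_10x(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    sample_id: str,
) -> CountMatrix:
    """Read a 10x-style MatrixMarket triplet into a :class:`CountMatrix`.

    ``features`` may have one column (symbol) or the Cell Ranger three-column
    layout (id, symbol, feature type); the symbol column is used.  All cells
    are assigned ``sample_id``.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"non-integer count in {matrix_path}")

    feature_lines = _read_lines(features_path)
    symbols = []
    for line in feature_lines:
        parts = line.split("\t")
        symbols.append(parts[1] if len(parts) >= 2 else parts[0])
    barcodes = [line.split("\t")[0] for line in _read_lines(barcodes_path)]

    if len(symbols) != mat.shape[0]:
        raise FormatError(
            f"feature count mismatch: {features_path} has {len(symbols)} entries "
            f"for a {mat.shape[0]}-row matrix"
        )
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"barcode count mismatch: {barcodes_path} has {len(barcodes)} entries "
            f"for a {mat.shape[1]}-column matrix"
        )
    return CountMatrix(mat, symbols, barcodes, [sample_id] * len(barcodes))


def write_10x(m: CountMatrix, out_dir: str | Path) -> None:
    """Write a MatrixMarket triplet (matrix.mtx, features.tsv, barcodes.tsv)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), sp.coo_matrix(m.values), field="integer")
    (out_dir / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in m.gene_symbols)
    )
    (out_dir / "barcodes.tsv").write_text("".join(b + "\n" for b in m.barcodes))


def read_dense_csv(path: str | Path, sample_id: str) -> CountMatrix:
    """Read a dense genes-x-cells CSV (gene symbols as index, barcodes as header)."""
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    if not np.allclose(values, np.round(values)) or (values < 0).any():
        raise FormatError(f"non-integer or negative count in {path}")
    return CountMatrix(
        sp.csr_matrix(values.astype(np.int64)),
        [str(g) for g in df.index],
        [str(b) for b in df.columns],
        [sample_id] * df.shape[1],
    )


_CONTIG_COLUMNS = (
    "barcode",
    "chain",
    "cdr3",
    "v_gene",
    "j_gene",
    "productive",
    "high_confidence",
    "umis",
)


def read_contigs(path: str | Path) -> list[ContigRecord]:
    """Parse a Cell Ranger VDJ filtered contig annotation CSV.

    Rows whose chain is not TRA/TRB (e.g. TRG, Multi) are dropped with a
    logged count.  ``productive``/``high_confidence`` accept the Cell Ranger
    dialect variants True/TRUE/true; anything else (including "None") is
    treated as false.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _CONTIG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"contig table {path} missing required column {col!r}")
    records: list[ContigRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        chain = row.chain
        if chain not in ("TRA", "TRB"):
            n_dropped += 1
            continue
        records.append(
            ContigRecord(
                barcode=row.barcode,
                chain=chain,
                cdr3_aa=row.cdr3,
                v_gene=row.v_gene,
                j_gene=row.j_gene,
                productive=row.productive in _TRUE_STRINGS,
                high_confidence=row.high_confidence in _TRUE_STRINGS,
                umis=int(float(row.umis)) if row.umis else 0,
            )
        )
    if n_dropped:
        logger.info("read_contigs: dropped %d non-TRA/TRB contigs from %s", n_dropped, path)
    return records


def write_contigs(records: Iterable[ContigRecord], path: str | Path) -> None:
    rows = [
        {
            "barcode": r.barcode,
            "chain": r.chain,
            "cdr3": r.cdr3_aa,
            "v_gene": r.v_gene,
            "j_gene": r.j_gene,
            "productive": "True" if r.productive else "None",
            "high_confidence": "True" if r.high_confidence else "False",
            "umis": r.umis,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_CONTIG_COLUMNS)).to_csv(path, index=False)


def read_blacklist(path: str | Path) -> GeneBlacklist:
    """Read a blacklist TSV with columns ``symbol_or_pattern`` and ``kind``.

    ``kind`` must be ``literal`` or ``regex``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("symbol_or_pattern", "kind"):
        if col not in df.columns:
            raise FormatError(f"blacklist {path} missing required column {col!r}")
    literals: set[str] = set()
    patterns: list[str] = []
    for row in df.itertuples(index=False):
        if row.kind == "literal":
            literals.add(row.symbol_or_pattern)
        elif row.kind == "regex":
            patterns.append(row.symbol_or_pattern)
        else:
            raise FormatError(
                f"blacklist {path}: kind must be 'literal' or 'regex', got {row.kind!r}"
            )
    return GeneBlacklist(frozenset(literals), tuple(patterns))


def default_blacklist() -> GeneBlacklist:
    """The shipped default blacklist: TCR segment regexes plus a curated
    dissociation-stress gene list.  User-replaceable via :func:`read_blacklist`.
    """
    with resources.as_file(
        resources.files("trseek._resources") / "blacklist_default.tsv"
    ) as p:
        return read_blacklist(p)


def read_viral_reference(path: str | Path) -> ViralReference:
    """Read a VDJdb-style TSV with columns ``cdr3``, ``v.segm``, ``antigen.species``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("cdr3", "antigen.species"):
        if col not in df.columns:
            raise FormatError(f"viral reference {path} missing required column {col!r}")
    v_col = df["v.segm"] if "v.segm" in df.columns else [""] * len(df)
    rows = [
        (cdr3, v or None, species)
        for cdr3, v, species in zip(df["cdr3"], v_col, df["antigen.species"])
    ]
    return ViralReference(rows)


def default_viral_reference() -> ViralReference:
    """The shipped synthetic stand-in for a VDJdb viral CDR3 export.

    The CDR3 sequences are generated, not curated from VDJdb; replace with a
    real export (same columns) for bystander detection on real data.
    """
    with resources.as_file(
        resources.files("trseek._resources") / "viral_reference_synthetic.tsv"
    ) as p:
        return read_viral_reference(p)


def read_clonotype_labels(path: str | Path) -> dict[str, str]:
    """Read a clonotype -> {reactive, nonreactive} label table (CSV)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("clonotype_key", "label"):
        if col not in df.columns:
            raise FormatError(f"label table {path} missing required column {col!r}")
    table: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.label not in ("reactive", "nonreactive"):
            raise ValidationError(f"label must be reactive/nonreactive, got {row.label!r}")
        if row.clonotype_key in table and table[row.clonotype_key] != row.label:
            raise ValidationError(
                f"clonotype {row.clonotype_key!r} mapped to both labels"
            )
        table[row.clonotype_key] = row.label
    return table
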