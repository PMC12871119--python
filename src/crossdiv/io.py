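"""Readers and writers for every external format the pipeline touches.

Covered formats: aligned FASTA codon pairs, TPM expression tables (TSV,
genes x tissues), structural similarity tables (TSV), PAML codeml pairwise
output, FATCAT text output, and the pipeline's own tab-separated result
tables.

Conventions shared by all writers: tab separation, a header row, missing
values serialized as ``NA``, floats rendered with six significant digits,
stable row and column order.  All readers validate and raise
:class:`~crossdiv.errors.FormatError` instead of silently coercing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

_VALID_NT = set("ACGTN-")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonAlignment:
    """A pairwise codon-aware alignment of two coding sequences.

    Sequences are upper-case nucleotide strings over ``{A,C,G,T,N,-}`` of
    equal length divisible by three; RNA input is accepted and stored with
    U mapped to T.
    """

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper().replace("U", "T"), self.seq_b.upper().replace("U", "T")
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise FormatError(
                f"aligned sequences differ in length: {self.id_a} has {len(a)}, "
                f"{self.id_b} has {len(b)}"
            )
        if len(a) % 3 != 0:
            raise FormatError(
                f"alignment length {len(a)} of {self.id_a}/{self.id_b} is not a codon multiple"
            )
        for sid, s in ((self.id_a, a), (self.id_b, b)):
            bad = set(s) - _VALID_NT
            if bad:
                raise FormatError(f"record {sid} contains invalid characters {sorted(bad)}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self):
        """Yield aligned codon pairs."""
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


class ExpressionMatrix:
    """A genes x tissues table of nonnegative TPM values.

    Thin wrapper around a pandas DataFrame (genes as index, tissues as
    columns) enforcing unique identifiers and nonnegativity.
    """

    def __init__(self, tpm: pd.DataFrame):
        if tpm.index.has_duplicates:
            dup = tpm.index[tpm.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dup}")
        if tpm.columns.has_duplicates:
            dup = tpm.columns[tpm.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate tissue ids: {dup}")
        values = tpm.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise FormatError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise FormatError("expression matrix contains negative TPM values")
        self._tpm = tpm.astype(float)

    @property
    def tpm(self) -> pd.DataFrame:
        return self._tpm

    @property
    def gene_ids(self) -> list[str]:
        return list(self._tpm.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self._tpm.columns)

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self._tpm.equals(other._tpm)


class StructuralSimilarityTable:
    """Per-gene structural similarity scores s in [0, 100] (percent)."""

    def __init__(self, similarities: Mapping[str, float]):
        clean: dict[str, float] = {}
        for gene, s in similarities.items():
            s = float(s)
            if not (0.0 <= s <= 100.0):
                raise FormatError(f"similarity {s} for gene {gene} outside [0, 100]")
            clean[str(gene)] = s
        self._scores = clean

    @property
    def scores(self) -> dict[str, float]:
        return dict(self._scores)

    def __len__(self) -> int:
        return len(self._scores)

    def __getitem__(self, gene: str) -> float:
        return self._scores[gene]

    def __iter__(self):
        return iter(self._scores)


@dataclass(frozen=True)
class CodemlRecord:
    """dN/dS estimates for one ortholog pair parsed from codeml output."""

    gene_id: str
    dn: float
    ds: float

    def __post_init__(self) -> None:
        for name, v in (("dN", self.dn), ("dS", self.ds)):
            if not math.isfinite(v) or v < 0:
                raise FormatError(f"{name}={v} for gene {self.gene_id} is not a finite nonnegative value")


@dataclass(frozen=True)
class FatcatRecord:
    """Fields extracted from FATCAT flexible structural alignment output."""

    gene_id: str
    similarity: float
    p_value: float | None = None
    rmsd: float | None = None
    twists: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.similarity <= 100.0):
            raise FormatError(
                f"similarity {self.similarity} for gene {self.gene_id} outside [0, 100]"
            )
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise FormatError(f"p-value {self.p_value} for gene {self.gene_id} outside [0, 1]")
        if self.rmsd is not None and self.rmsd < 0:
            raise FormatError(f"negative RMSD for gene {self.gene_id}")
        if self.twists is not None and self.twists < 0:
            raise FormatError(f"negative twist count for gene {self.gene_id}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_paired_fasta(source) -> CodonAlignment:
    """Read an aligned FASTA file containing exactly two records.

    Sequences are upper-cased and U is mapped to T.  Raises
    :class:`FormatError` when the file does not hold exactly two records of
    equal, codon-multiple length.
    """
    records = list(SeqIO.parse(_as_handle(source), "fasta"))
    if len(records) != 2:
        raise FormatError(f"expected exactly 2 FASTA records, found {len(records)}")
    a, b = records
    return CodonAlignment(id_a=a.id, id_b=b.id, seq_a=str(a.seq), seq_b=str(b.seq))


def write_paired_fasta(alignment: CodonAlignment, destination) -> None:
    records = [
        SeqRecord(Seq(alignment.seq_a), id=alignment.id_a, description=""),
        SeqRecord(Seq(alignment.seq_b), id=alignment.id_b, description=""),
    ]
    if hasattr(destination, "write"):
        SeqIO.write(records, destination, "fasta")
    else:
        with open(destination, "w") as fh:
            SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def read_expression_tsv(source) -> ExpressionMatrix:
    """Read a TSV with gene ids in the first column and tissues as columns."""
    lines = _read_lines(source)
    if not lines:
        raise FormatError("empty expression table")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError("expression table needs a gene column and at least one tissue")
    tissues = header[1:]
    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise FormatError(
                f"row {lineno}: expected {len(header)} fields, found {len(parts)}"
            )
        genes.append(parts[0])
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise FormatError(f"row {lineno}: non-numeric cell ({exc})") from None
    frame = pd.DataFrame(rows, index=genes, columns=tissues)
    try:
        return ExpressionMatrix(frame)
    except FormatError as exc:
        raise FormatError(f"invalid expression table: {exc}") from None


def write_expression_tsv(matrix: ExpressionMatrix, destination) -> None:
    frame = matrix.tpm
    out = ["gene\t" + "\t".join(map(str, frame.columns))]
    for gene, row in frame.iterrows():
        out.append(str(gene) + "\t" + "\t".join(_fmt(v) for v in row))
    _write_text("\n".join(out) + "\n", destination)


# ---------------------------------------------------------------------------
# structural similarity TSV
# ---------------------------------------------------------------------------

def read_similarity_tsv(source) -> StructuralSimilarityTable:
    """Read a two-column TSV of gene id and similarity percentage."""
    lines = _read_lines(source)
    if not lines:
        raise FormatError("empty similarity table")
    scores: dict[str, float] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"row {lineno}: expected 2 fields, found {len(parts)}")
        gene, raw = parts
        if gene in scores:
            raise FormatError(f"row {lineno}: duplicate gene id {gene}")
        try:
            s = float(raw)
        except ValueError:
            raise FormatError(f"row {lineno}: non-numeric similarity {raw!r}") from None
        if not (0.0 <= s <= 100.0):
            raise FormatError(f"row {lineno}: similarity {s} outside [0, 100]")
        scores[gene] = s
    return StructuralSimilarityTable(scores)


def write_similarity_tsv(table: StructuralSimilarityTable, destination) -> None:
    out = ["gene\tsimilarity"]
    for gene in sorted(table.scores):
        out.append(f"{gene}\t{_fmt(table[gene])}")
    _write_text("\n".join(out) + "\n", destination)


# ---------------------------------------------------------------------------
# codeml / FATCAT text scanners
# ---------------------------------------------------------------------------

_CODEML_DN = re.compile(r"dN\s*=\s*([-+0-9.eE]+)")
_CODEML_DS = re.compile(r"dS\s*=\s*([-+0-9.eE]+)")
# "dN/dS= 0.3" must not be read as "dN= ..."; strip the ratio token first.
_CODEML_RATIO = re.compile(r"dN/dS\s*=\s*[-+0-9.eE]+")


def parse_codeml_pairwise(text: str, gene_id: str) -> CodemlRecord:
    """Extract dN and dS from codeml pairwise (runmode -2) output.

    A tolerant token scanner: the numbers following the last ``dN =`` and
    ``dS =`` tokens win, whitespace optional around ``=``.
    """
    cleaned = _CODEML_RATIO.sub("", text)
    dn_matches = _CODEML_DN.findall(cleaned)
    ds_matches = _CODEML_DS.findall(cleaned)
    if not dn_matches:
        raise FormatError(f"no 'dN =' token found in codeml output for {gene_id}")
    if not ds_matches:
        raise FormatError(f"no 'dS =' token found in codeml output for {gene_id}")
    try:
        dn, ds = float(dn_matches[-1]), float(ds_matches[-1])
    except ValueError as exc:
        raise FormatError(f"unparseable dN/dS value for {gene_id}: {exc}") from None
    return CodemlRecord(gene_id=gene_id, dn=dn, ds=ds)


_FATCAT_SIM = re.compile(r"Similarity\s+([0-9.eE+-]+)\s*%?")
_FATCAT_P = re.compile(r"P-value\s+([0-9.eE+-]+)")
_FATCAT_RMSD = re.compile(r"RMSD\s+([0-9.eE+-]+)")
_FATCAT_TWISTS = re.compile(r"Twists?\s+(\d+)", re.IGNORECASE)


def parse_fatcat_output(text: str, gene_id: str) -> FatcatRecord:
    """Extract the similarity score (and optional fields) from FATCAT text."""
    sim = _FATCAT_SIM.search(text)
    if sim is None:
        raise FormatError(f"no 'Similarity' token found in FATCAT output for {gene_id}")
    similarity = float(sim.group(1))
    if not (0.0 <= similarity <= 100.0):
        raise FormatError(
            f"FATCAT similarity {similarity} for {gene_id} outside [0, 100]"
        )
    p = _FATCAT_P.search(text)
    rmsd = _FATCAT_RMSD.search(text)
    twists = _FATCAT_TWISTS.search(text)
    return FatcatRecord(
        gene_id=gene_id,
        similarity=similarity,
        p_value=float(p.group(1)) if p else None,
        rmsd=float(rmsd.group(1)) if rmsd else None,
        twists=int(twists.group(1)) if twists else None,
    )


# ---------------------------------------------------------------------------
# generic result tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableSchema:
    """Declared column names and kinds ('str', 'float', 'int') for a table."""

    columns: tuple[str, ...]
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.columns) != len(self.kinds):
            raise ValueError("columns and kinds differ in length")
        bad = set(self.kinds) - {"str", "float", "int"}
        if bad:
            raise ValueError(f"unknown column kinds {bad}")


def write_table(frame: pd.DataFrame, schema: TableSchema, destination) -> None:
    """Write a DataFrame as TSV under a declared schema.

    Floats are rendered with six significant digits, missing values as
    ``NA``; rows are written in the frame's order, columns in schema order.
    """
    missing = [c for c in schema.columns if c not in frame.columns]
    if missing:
        raise FormatError(f"frame lacks schema columns {missing}")
    out = ["\t".join(schema.columns)]
    for _, row in frame.iterrows():
        cells = []
        for col, kind in zip(schema.columns, schema.kinds):
            v = row[col]
            if v is None or (isinstance(v, float) and math.isnan(v)) or v is pd.NA:
                cells.append("NA")
            elif kind == "float":
                cells.append(_fmt(float(v)))
            elif kind == "int":
                cells.append(str(int(v)))
            else:
                cells.append(str(v))
        out.append("\t".join(cells))
    _write_text("\n".join(out) + "\n", destination)


def read_table(source, schema: TableSchema) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, validating the header."""
    lines = _read_lines(source)
    if not lines:
        raise FormatError("empty table")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != schema.columns:
        raise FormatError(f"header {header} does not match schema {schema.columns}")
    records: list[list] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(schema.columns):
            raise FormatError(
                f"row {lineno}: expected {len(schema.columns)} fields, found {len(parts)}"
            )
        row: list = []
        for raw, kind in zip(parts, schema.kinds):
            if raw == "NA":
                row.append(np.nan if kind in ("float", "int") else None)
            elif kind == "float":
                try:
                    row.append(float(raw))
                except ValueError:
                    raise FormatError(f"row {lineno}: non-numeric cell {raw!r}") from None
            elif kind == "int":
                try:
                    row.append(int(raw))
                except ValueError:
                    raise FormatError(f"row {lineno}: non-integer cell {raw!r}") from None
            else:
                row.append(raw)
        records.append(row)
    frame = pd.DataFrame(records, columns=list(schema.columns))
    if not records:  # preserve dtypes for an empty table
        for col, kind in zip(schema.columns, schema.kinds):
            frame[col] = frame[col].astype(float if kind in ("float", "int") else object)
    return frame


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    """Six significant digits, no exponent padding surprises."""
    if isinstance(v, float) and math.isnan(v):
        return "NA"
    return f"{v:.6g}"


def _as_handle(source):
    if hasattr(source, "read"):
        return source
    return str(source)


def _read_lines(source) -> list[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    return Path(source).read_text().splitlines()


def _write_text(text: str, destination) -> None:
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)
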