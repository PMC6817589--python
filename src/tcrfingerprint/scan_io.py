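"""Readers and writers for every external text format the pipeline touches.

Formats
-------
* measurement tables  — delimited text with columns
  ``peptide, assay, replicate_id, signal, background`` (signals are raw
  percent-positive-cells per replicate; the background column is the
  matched no-peptide control for the same replicate);
* FASTA proteomes (via Biopython);
* affinity tables — two columns ``peptide, ic50_nm`` of precomputed
  peptide→MHC IC50 predictions (nanomolar);
* expression tables — ``gene_symbol`` plus one TPM column per tissue
  (Human Protein Atlas RNA-consensus style);
* PWM files — a ``#``-prefixed metadata header followed by a TSV matrix
  (20 amino-acid rows × one column per scored position);
* ranked-hit reports and per-bin motif matrices.

The delimiter is auto-detected between tab and comma.  Column names are
matched case-sensitively by default (``strict=True``); a lenient mode maps
case-insensitively.  Readers never silently drop rows: every reject raises
or is counted and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .core import (
    AA_INDEX,
    AMINO_ACIDS,
    Assay,
    FormatError,
    ParseError,
    ValidationError,
    check_peptide,
)
from .fingerprint import PositionWeightMatrix

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ("peptide", "assay", "replicate_id", "signal", "background")


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementRecord:
    """One replicate read-out for one peptide in one assay."""

    peptide: str
    assay: Assay
    replicate_id: str
    signal: float
    background: float

    def __post_init__(self) -> None:
        check_peptide(self.peptide)
        object.__setattr__(self, "assay", Assay.coerce(self.assay))
        if not str(self.replicate_id):
            raise ValidationError(f"empty replicate_id for peptide {self.peptide}")
        for name in ("signal", "background"):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ValidationError(
                    f"non-finite {name} for peptide {self.peptide}"
                )

    @property
    def corrected(self) -> float:
        """Background-corrected signal for this replicate."""
        return float(self.signal) - float(self.background)


class MeasurementSet:
    """Replicate measurements grouped by (peptide, assay)."""

    def __init__(self, records: Iterable[MeasurementRecord]):
        self._records: list[MeasurementRecord] = list(records)
        self._groups: dict[tuple[str, Assay], list[MeasurementRecord]] = {}
        for rec in self._records:
            self._groups.setdefault((rec.peptide, rec.assay), []).append(rec)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def peptides(self, assay: Assay | str) -> tuple[str, ...]:
        """Distinct peptides measured in *assay*, sorted."""
        assay = Assay.coerce(assay)
        return tuple(sorted({p for (p, a) in self._groups if a is assay}))

    def replicates(self, peptide: str, assay: Assay | str) -> tuple[MeasurementRecord, ...]:
        assay = Assay.coerce(assay)
        return tuple(self._groups.get((peptide, assay), ()))

    def assays(self) -> tuple[Assay, ...]:
        return tuple(sorted({a for (_, a) in self._groups}, key=lambda a: a.value))


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_table(path: str | Path, required: Sequence[str], *, strict: bool = True) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    if strict:
        missing = [c for c in required if c not in df.columns]
    else:
        lower = {c.strip().lower(): c for c in df.columns}
        missing = [c for c in required if c not in lower]
        if not missing:
            df = df.rename(columns={lower[c]: c for c in required})
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def _numeric(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.index[values.isna()]
    if len(bad) > 0:
        # +2: header line plus 1-based numbering
        raise ParseError(
            f"{path}: non-numeric {column} value {df[column].iloc[bad[0]]!r} "
            f"at row {int(bad[0]) + 2}"
        )
    return values


def read_measurements(path: str | Path, *, strict: bool = True) -> MeasurementSet:
    """Read a replicate measurement table into a :class:`MeasurementSet`."""
    path = Path(path)
    df = _read_table(path, MEASUREMENT_COLUMNS, strict=strict)
    if len(df) == 0:
        return MeasurementSet([])
    signal = _numeric(df, "signal", path)
    background = _numeric(df, "background", path)
    records = [
        MeasurementRecord(
            peptide=row.peptide,
            assay=Assay.coerce(row.assay),
            replicate_id=row.replicate_id,
            signal=float(signal.iloc[i]),
            background=float(background.iloc[i]),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]
    ms = MeasurementSet(records)
    for assay in ms.assays():
        logger.info("%s: %d distinct peptides in %s assay", path.name,
                    len(ms.peptides(assay)), assay.value)
    return ms


def write_measurements(ms: MeasurementSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(MEASUREMENT_COLUMNS) + "\n")
        for rec in ms:
            fh.write(
                f"{rec.peptide}\t{rec.assay.value}\t{rec.replicate_id}\t"
                f"{rec.signal:.10g}\t{rec.background:.10g}\n"
            )


# ---------------------------------------------------------------------------
# FASTA proteomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier and (optional) gene symbol.

    The sequence may contain non-canonical letters (X, U, ...); those are
    handled downstream by the k-mer enumerator, which skips and counts
    windows containing them.
    """

    protein_id: str
    gene_symbol: str | None
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("empty protein_id")
        if not self.sequence:
            raise ValidationError(f"protein {self.protein_id}: empty sequence")


def _gene_from_description(description: str, dialect: str) -> str | None:
    tokens = description.split()
    if dialect in ("auto", "gene_key"):
        for tok in tokens[1:]:
            if tok.startswith("gene="):
                return tok[len("gene="):] or None
        if dialect == "gene_key":
            return None
    if dialect in ("auto", "second_token") and len(tokens) > 1:
        return tokens[1]
    return None


def read_fasta(path: str | Path, *, gene_dialect: str = "auto") -> list[ProteinRecord]:
    """Read a protein FASTA file in order.

    The first header token is the protein id; the gene symbol comes from a
    ``gene=`` key (or, under the default ``auto`` dialect, the second header
    token).  ``gene_dialect`` is one of ``auto``, ``gene_key``,
    ``second_token``, ``none``.
    """
    path = Path(path)
    if gene_dialect not in ("auto", "gene_key", "second_token", "none"):
        raise ValueError(f"unknown gene dialect {gene_dialect!r}")
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}: sequence data before first '>' header")
            break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate protein_id {rec.id!r}")
        seen.add(rec.id)
        gene = None if gene_dialect == "none" else _gene_from_description(rec.description, gene_dialect)
        records.append(
            ProteinRecord(protein_id=rec.id, gene_symbol=gene,
                          sequence=str(rec.seq).upper())
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            gene = f" gene={rec.gene_symbol}" if rec.gene_symbol else ""
            fh.write(f">{rec.protein_id}{gene}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# affinity tables
# ---------------------------------------------------------------------------

class AffinityMap:
    """Peptide → predicted MHC binding IC50 (nM, positive)."""

    def __init__(self, entries: Mapping[str, float]):
        self._entries: dict[str, float] = {}
        for pep, ic50 in entries.items():
            check_peptide(pep)
            ic50 = float(ic50)
            if not (ic50 > 0):
                raise ValidationError(f"non-positive IC50 {ic50} for {pep}")
            self._entries[pep] = ic50

    def __contains__(self, peptide: str) -> bool:
        return peptide in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def get(self, peptide: str) -> float | None:
        return self._entries.get(peptide)

    def items(self):
        return self._entries.items()


def read_affinity_table(path: str | Path, *, strict: bool = True) -> AffinityMap:
    """Read a two-column ``peptide, ic50_nm`` table.

    Duplicate peptide rows keep the minimum IC50 (a warning is logged).
    """
    path = Path(path)
    df = _read_table(path, ("peptide", "ic50_nm"), strict=strict)
    entries: dict[str, float] = {}
    n_dup = 0
    if len(df):
        ic50 = _numeric(df, "ic50_nm", path)
        for i, pep in enumerate(df["peptide"]):
            v = float(ic50.iloc[i])
            if pep in entries:
                n_dup += 1
                entries[pep] = min(entries[pep], v)
            else:
                entries[pep] = v
    if n_dup:
        logger.warning("%s: %d duplicate peptide rows; kept minimum IC50", path.name, n_dup)
    return AffinityMap(entries)


def write_affinity_table(affinity: AffinityMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("peptide\tic50_nm\n")
        for pep, ic50 in sorted(affinity.items()):
            fh.write(f"{pep}\t{ic50:.10g}\n")


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """Gene → per-tissue TPM, with a tissue list shared by all genes."""

    table: pd.DataFrame = field(repr=False)  # index: gene_symbol; columns: tissues

    def __post_init__(self) -> None:
        if (self.table.values < 0).any():
            raise ValidationError("negative TPM value in expression table")

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(self.table.columns)

    def genes(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index

    def tpm(self, gene: str) -> pd.Series | None:
        if gene not in self.table.index:
            return None
        return self.table.loc[gene]


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a gene × tissue TPM table (first column ``gene_symbol``)."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.columns[0] != "gene_symbol":
        raise FormatError(f"{path}: first column must be 'gene_symbol', got {df.columns[0]!r}")
    df = df.set_index("gene_symbol")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric TPM value ({exc})") from None
    return ExpressionTable(df)


def write_expression_table(expr: ExpressionTable, path: str | Path) -> None:
    expr.table.to_csv(path, sep="\t", index_label="gene_symbol", float_format="%.10g")


# ---------------------------------------------------------------------------
# PWM serialization
# ---------------------------------------------------------------------------

def write_pwm(pwm: PositionWeightMatrix, path: str | Path,
              extra_metadata: Mapping[str, str] | None = None) -> None:
    """Serialize a PWM as '#' metadata lines plus a TSV matrix.

    Entries are written with 12 significant digits so a round-trip
    reproduces them to that precision.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# epitope: {pwm.epitope}\n")
        fh.write(f"# anchors: {','.join(str(p) for p in sorted(pwm.anchor_positions))}\n")
        fh.write(f"# assay: {pwm.assay}\n")
        for key, value in (extra_metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("aa\t" + "\t".join(str(p) for p in pwm.scored_positions) + "\n")
        for aa in AMINO_ACIDS:
            row = [f"{pwm.weight(aa, p):.12g}" for p in pwm.scored_positions]
            fh.write(aa + "\t" + "\t".join(row) + "\n")


def read_pwm(path: str | Path) -> PositionWeightMatrix:
    path = Path(path)
    metadata: dict[str, str] = {}
    header: list[int] | None = None
    rows: dict[str, list[float]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    metadata[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if header is None:
                if fields[0] != "aa":
                    raise FormatError(f"{path}:{lineno}: expected matrix header starting with 'aa'")
                try:
                    header = [int(f) for f in fields[1:]]
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-integer position label") from None
                continue
            aa = fields[0]
            if aa not in AA_INDEX:
                raise FormatError(f"{path}:{lineno}: row label {aa!r} is not a canonical amino acid")
            if len(fields) - 1 != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} values, got {len(fields) - 1}")
            try:
                rows[aa] = [float(f) for f in fields[1:]]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric matrix entry") from None
    for key in ("epitope", "anchors", "assay"):
        if key not in metadata:
            raise FormatError(f"{path}: missing required metadata line '# {key}: ...'")
    if header is None:
        raise FormatError(f"{path}: no matrix found")
    missing_rows = [aa for aa in AMINO_ACIDS if aa not in rows]
    if missing_rows:
        raise FormatError(f"{path}: missing amino-acid rows {missing_rows}")
    import numpy as np

    weights = np.array([rows[aa] for aa in AMINO_ACIDS], dtype=float)
    anchors = frozenset(int(p) for p in metadata["anchors"].split(",") if p.strip())
    extra = {k: v for k, v in metadata.items() if k not in ("epitope", "anchors", "assay")}
    return PositionWeightMatrix(
        epitope=metadata["epitope"],
        anchor_positions=anchors,
        scored_positions=tuple(header),
        weights=weights,
        assay=metadata["assay"],
        metadata=extra,
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "rank", "peptide", "binding", "activation", "killing", "combined",
    "ic50_nm", "hamming", "provenance", "max_tpm", "tissues_above_tpm",
)


def write_hits_report(scored, path: str | Path, *,
                      annotations: Mapping[str, object] | None = None,
                      metadata: Mapping[str, str] | None = None) -> None:
    """Write the ranked-hit TSV report.

    *scored* is an ordered list of ``ScoredPeptide``; *annotations* maps
    peptide → expression annotation (optional).  Metadata lines (resolved
    config, version) are '#'-prefixed so the table remains machine-readable.
    """
    path = Path(path)

    def fmt(value, spec="{:.10g}") -> str:
        return "NA" if value is None else spec.format(value)

    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for rank, sp in enumerate(scored, start=1):
            prov = ";".join(
                f"{p.protein_id}:{p.gene_symbol or 'NA'}:{p.start}" for p in sp.provenance
            ) or "NA"
            ann = (annotations or {}).get(sp.sequence)
            if ann is None or getattr(ann, "no_expression_data", True):
                max_tpm, n_above = "NA", "NA"
            else:
                max_tpm = f"{ann.max_tpm:.10g}"
                n_above = str(ann.tissues_above)
            fh.write("\t".join([
                str(rank), sp.sequence,
                fmt(sp.scores.binding), fmt(sp.scores.activation),
                fmt(sp.scores.killing), fmt(sp.scores.combined),
                fmt(sp.ic50_nm),
                "NA" if sp.hamming_to_reference is None else str(sp.hamming_to_reference),
                prov, max_tpm, n_above,
            ]) + "\n")


def write_motif_matrix(motif, path: str | Path) -> None:
    """Write one per-bin position frequency matrix as TSV."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# bin: {motif.bin_label}\n")
        fh.write(f"# n_peptides: {motif.n_peptides}\n")
        fh.write("aa\t" + "\t".join(str(i) for i in range(1, motif.k + 1)) + "\n")
        freqs = motif.frequencies
        for j, aa in enumerate(AMINO_ACIDS):
            if freqs is None:
                row = ["NA"] * motif.k
            else:
                row = [f"{freqs[i, j]:.10g}" for i in range(motif.k)]
            fh.write(aa + "\t" + "\t".join(row) + "\n")
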