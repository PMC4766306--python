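"""Sequence and expression-table input/output.

Two on-disk formats are supported: plain FASTA for transcript and peptide
sets, and a tab-separated expression matrix with one header line of tissue
labels and one row per transcript.  Expression values carry a unit tag:
``TPM`` (transcripts per million; columns must each sum to 10^6), ``RPM``
(reads per million) or ``relative`` (arbitrary linear units, e.g. RT-PCR
estimates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SequenceRecord",
    "ExpressionMatrix",
    "FastaParseError",
    "ExpressionFormatError",
    "read_fasta",
    "write_fasta",
    "read_expression",
    "write_expression",
    "infer_alphabet",
]

DNA_CHARS = set("ACGTNacgtn")
# IUPAC amino acids plus ambiguity/stop codes seen in predicted peptides.
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*acdefghiklmnpqrstvwyxbzjuo")

DEFAULT_TISSUES = ("leaf", "inflorescence", "bulb")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


class ExpressionFormatError(ValueError):
    """Raised for ragged, non-numeric or negative expression tables."""


def infer_alphabet(seq: str) -> str:
    """Guess ``dna`` or ``protein`` from residue characters."""
    if not seq:
        raise ValueError("cannot infer alphabet of an empty sequence")
    return "dna" if set(seq) <= DNA_CHARS else "protein"


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence (nucleotide or amino acid)."""

    id: str
    seq: str
    description: str = ""
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if self.alphabet == "dna" and not set(self.seq) <= DNA_CHARS:
            raise ValueError(f"sequence {self.id!r} contains non-nucleotide characters")
        if self.alphabet == "protein" and not set(self.seq) <= PROTEIN_CHARS:
            raise ValueError(f"sequence {self.id!r} contains non-amino-acid characters")

    def __len__(self) -> int:
        return len(self.seq)


def _validate_fasta_lines(path: Path) -> None:
    """Cheap structural pass so errors can name a line number."""
    last_header_line = None
    have_residues = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if line == ">":
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                if last_header_line is not None and not have_residues:
                    raise FastaParseError(
                        f"{path}: record starting at line {last_header_line} has no sequence"
                    )
                last_header_line = lineno
                have_residues = False
            else:
                if last_header_line is None:
                    raise FastaParseError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                have_residues = True
    if last_header_line is not None and not have_residues:
        raise FastaParseError(
            f"{path}: record starting at line {last_header_line} has no sequence"
        )


def read_fasta(
    path: str | Path,
    alphabet: str | None = None,
    min_length: int = 0,
) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Parameters
    ----------
    alphabet
        Force ``dna`` or ``protein``; by default inferred per record.
    min_length
        Optional minimum sequence length; shorter records are dropped
        (assembler-style length cutoff, default off).
    """
    path = Path(path)
    _validate_fasta_lines(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            parts = title.split(None, 1)
            rec_id = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if rec_id in seen:
                raise FastaParseError(f"{path}: duplicate sequence id {rec_id!r}")
            seen.add(rec_id)
            if len(seq) < min_length:
                continue
            records.append(
                SequenceRecord(
                    id=rec_id,
                    seq=seq,
                    description=desc,
                    alphabet=alphabet or infer_alphabet(seq),
                )
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            if wrap and wrap > 0:
                for i in range(0, len(rec.seq), wrap):
                    fh.write(rec.seq[i : i + wrap] + "\n")
            else:
                fh.write(rec.seq + "\n")


@dataclass
class ExpressionMatrix:
    """Transcript x tissue abundance values for one assembly.

    ``data`` is a DataFrame indexed by transcript id with one column per
    tissue, in biological order (default leaf, inflorescence, bulb).
    """

    assembly_id: str
    data: pd.DataFrame
    unit: str = "relative"

    def __post_init__(self) -> None:
        if self.unit not in ("TPM", "RPM", "relative"):
            raise ValueError(f"unknown expression unit {self.unit!r}")
        if self.data.isna().any().any():
            raise ExpressionFormatError(
                f"{self.assembly_id}: expression table contains missing values"
            )
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any():
            raise ExpressionFormatError(f"{self.assembly_id}: negative expression values")
        if self.unit == "TPM" and len(self.data):
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1e6, rtol=1e-3):
                raise ExpressionFormatError(
                    f"{self.assembly_id}: TPM columns must sum to 1e6 (got {sums})"
                )

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def transcripts(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    def vector(self, transcript_id: str, tissues: Sequence[str] | None = None) -> np.ndarray:
        """Expression vector for one transcript, optionally reordered."""
        row = self.data.loc[transcript_id]
        if tissues is not None:
            row = row[list(tissues)]
        return row.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def read_expression(
    path: str | Path,
    assembly_id: str | None = None,
    unit: str = "relative",
) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = tissues, first column = id)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ExpressionFormatError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        raise ExpressionFormatError(f"{path}: duplicate transcript ids")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        raise ExpressionFormatError(
            f"{path}: non-numeric values in columns {list(non_numeric)}"
        )
    return ExpressionMatrix(
        assembly_id=assembly_id or path.stem,
        data=df.astype(float),
        unit=unit,
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV at 6 significant digits (lossless round trip)."""
    matrix.data.to_csv(path, sep="\t", float_format="%.6g", index_label="transcript_id")
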