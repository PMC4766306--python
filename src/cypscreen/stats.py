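"""Assembly-level summary statistics and expression normalisation.

The N50 convention used throughout: sort sequence lengths descending and
accumulate; the first length whose running total reaches at least half the
total assembly length is the N50.  Median of an even-count set is the mean
of the central pair, matching common assembler reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SequenceRecord

__all__ = ["AssemblyStats", "assembly_stats", "tpm_from_counts"]


@dataclass(frozen=True)
class AssemblyStats:
    """Transcriptome summary: sequence count, longest, N50, mean, median."""

    n_sequences: int
    longest: int
    n50: int
    mean: float
    median: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def _lengths(records: Iterable[SequenceRecord] | Sequence[int]) -> np.ndarray:
    items = list(records)
    if items and isinstance(items[0], SequenceRecord):
        return np.array([len(r) for r in items], dtype=int)
    return np.asarray(items, dtype=int)


def assembly_stats(records: Iterable[SequenceRecord] | Sequence[int]) -> AssemblyStats:
    """Compute summary statistics from records (or raw lengths).

    All residues count toward length, including Ns.
    """
    lengths = _lengths(records)
    if lengths.size == 0:
        raise ValueError("assembly_stats requires at least one sequence")
    if (lengths <= 0).any():
        raise ValueError("sequence lengths must be positive")
    desc = np.sort(lengths)[::-1]
    half = desc.sum() / 2.0
    n50 = int(desc[np.searchsorted(np.cumsum(desc), half)])
    return AssemblyStats(
        n_sequences=int(lengths.size),
        longest=int(desc[0]),
        n50=n50,
        mean=float(lengths.mean()),
        median=float(np.median(lengths)),
    )


def tpm_from_counts(
    counts: Mapping[str, float] | pd.Series,
    lengths: Mapping[str, float] | pd.Series,
) -> pd.Series:
    """Length-normalised counts scaled to transcripts per million.

    Each count is divided by its transcript length to give a coverage rate;
    rates are rescaled to sum to 10^6.  An all-zero count vector returns an
    all-zero column with a warning.
    """
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths, dtype=float)
    if not counts.index.equals(lengths.index):
        lengths = lengths.reindex(counts.index)
        if lengths.isna().any():
            raise ValueError("every transcript needs a length")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        warnings.warn("all counts are zero; returning an all-zero TPM column")
        return rates
    return rates / total * 1e6
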