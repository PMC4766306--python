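"""Local-alignment homology search, E-value scoring and P450 annotation.

Pairwise search uses optimal Smith-Waterman alignment with affine gap
penalties (no seeding heuristics), scored with BLOSUM62 for peptides or
+1/-2 match/mismatch for nucleotides.  Significance follows the
Karlin-Altschul expectation E = K*m*n*exp(-lambda*S); the default (K,
lambda) pairs are the classic gapped-search estimates for these scoring
schemes and are configurable.  An optional shared-k-mer prefilter skips
pairs that cannot plausibly align, for speed on larger sets.

Also here: cytochrome P450 consensus-motif scanning (EXXR, PXRX, the
FXXGXRXCXG heme-binding motif and the (A/G)GX(D/E)TT oxygen binding and
activation motif), homology-based P450 classification against a packaged
reference set, and a six-frame longest-ORF peptide predictor used in place
of a trained ORF model.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io import SequenceRecord

__all__ = [
    "KarlinAltschulParams",
    "AlignmentScoring",
    "AlignmentHit",
    "MotifHit",
    "P450Classification",
    "protein_scoring",
    "dna_scoring",
    "local_align",
    "evalue_of",
    "find_homologs",
    "scan_p450_motifs",
    "classify_p450",
    "longest_orf_peptide",
    "P450_MOTIFS",
]

# Smallest positive double; strong hits underflow exp() and are clamped
# here so E-values stay positive and orderable.
_MIN_EVALUE = 5e-324


@dataclass(frozen=True)
class KarlinAltschulParams:
    """K and lambda of the extreme-value score distribution."""

    k: float
    lam: float

    def __post_init__(self) -> None:
        if self.k <= 0 or self.lam <= 0:
            raise ValueError("Karlin-Altschul K and lambda must be positive")


#: Gapped BLOSUM62 with 11/1 affine penalties.
PROTEIN_KA = KarlinAltschulParams(k=0.041, lam=0.267)
#: +1/-2 nucleotide scoring with 5/2 affine penalties.
DNA_KA = KarlinAltschulParams(k=0.46, lam=1.28)


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution scoring plus affine gap costs (open + per-residue extend)."""

    alphabet: str  # "protein" or "dna"
    matrix: str | None = None  # substitution matrix name, e.g. "BLOSUM62"
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 11.0
    gap_extend: float = 1.0
    ka: KarlinAltschulParams = PROTEIN_KA

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("affine gap penalties must be positive")


def protein_scoring() -> AlignmentScoring:
    """BLOSUM62, gap open 11 / extend 1 (classic protein-search defaults)."""
    return AlignmentScoring(alphabet="protein", matrix="BLOSUM62", gap_open=11, gap_extend=1, ka=PROTEIN_KA)


def dna_scoring() -> AlignmentScoring:
    """Match +1 / mismatch -2, gap open 5 / extend 2."""
    return AlignmentScoring(alphabet="dna", match=1, mismatch=-2, gap_open=5, gap_extend=2, ka=DNA_KA)


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if scoring.matrix is not None:
        aligner.substitution_matrix = _load_matrix(scoring.matrix)
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    # A gap of length k costs gap_open + k*gap_extend.
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _default_scoring(alphabet: str) -> AlignmentScoring:
    return protein_scoring() if alphabet == "protein" else dna_scoring()


def _sanitize(seq: str, alphabet: str) -> str:
    seq = seq.upper()
    if alphabet == "protein":
        # BLOSUM62 lacks J/U/O; map rare codes to X, which it scores.
        seq = seq.replace("J", "X").replace("U", "X").replace("O", "X").replace("*", "X")
    return seq


def evalue_of(raw_score: float, m: int, n: int, ka: KarlinAltschulParams = PROTEIN_KA) -> float:
    """Karlin-Altschul expectation E = K*m*n*exp(-lambda*S)."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths m, n must be >= 1")
    log_e = math.log(ka.k * m * n) - ka.lam * raw_score
    if log_e < -700:
        return _MIN_EVALUE
    return max(math.exp(log_e), _MIN_EVALUE)


def _bit_score(raw_score: float, ka: KarlinAltschulParams) -> float:
    return (ka.lam * raw_score - math.log(ka.k)) / math.log(2.0)


def local_align(
    a: SequenceRecord,
    b: SequenceRecord,
    scoring: AlignmentScoring | None = None,
) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment of ``a`` against ``b``.

    Returns a zero-score hit with empty spans when no residue pair scores
    positively.  Traceback is deterministic (the aligner's first-reported
    optimal path).
    """
    if a.alphabet != b.alphabet:
        raise ValueError(f"alphabet mismatch: {a.alphabet} vs {b.alphabet}")
    scoring = scoring or _default_scoring(a.alphabet)
    if scoring.alphabet != a.alphabet:
        raise ValueError("scoring scheme alphabet does not match the sequences")
    aligner = _make_aligner(scoring)
    sa, sb = _sanitize(a.seq, a.alphabet), _sanitize(b.seq, b.alphabet)
    score = aligner.score(sa, sb)
    m, n = len(sa), len(sb)
    if score <= 0:
        return AlignmentHit(
            query_id=a.id,
            subject_id=b.id,
            raw_score=0,
            bit_score=_bit_score(0.0, scoring.ka),
            evalue=evalue_of(0.0, m, n, scoring.ka),
            query_span=(0, 0),
            subject_span=(0, 0),
        )
    alignment = next(iter(aligner.align(sa, sb)))
    qblocks, sblocks = alignment.aligned
    raw = int(round(score))
    return AlignmentHit(
        query_id=a.id,
        subject_id=b.id,
        raw_score=raw,
        bit_score=_bit_score(raw, scoring.ka),
        evalue=evalue_of(raw, m, n, scoring.ka),
        query_span=(int(qblocks[0][0]), int(qblocks[-1][1])),
        subject_span=(int(sblocks[0][0]), int(sblocks[-1][1])),
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def find_homologs(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    e_cutoff: float,
    scoring: AlignmentScoring | None = None,
    prefilter_k: int | None = None,
) -> dict[str, AlignmentHit]:
    """Best subject hit per query with E <= cutoff.

    Ties on E-value (equivalently raw score) are broken by lexicographic
    subject id, so results do not depend on subject order.  ``prefilter_k``
    optionally requires a shared k-mer before aligning a pair (speed flag).
    Returns a mapping holding only queries with a passing hit.
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    results: dict[str, AlignmentHit] = {}
    if not subjects:
        return results
    ordered_subjects = sorted(subjects, key=lambda r: r.id)
    kmer_cache: dict[str, set[str]] = {}
    if prefilter_k:
        for s in ordered_subjects:
            kmer_cache[s.id] = _kmer_set(_sanitize(s.seq, s.alphabet), prefilter_k)
    for q in queries:
        best: AlignmentHit | None = None
        q_kmers = (
            _kmer_set(_sanitize(q.seq, q.alphabet), prefilter_k) if prefilter_k else None
        )
        for s in ordered_subjects:
            if q_kmers is not None and not (q_kmers & kmer_cache[s.id]):
                continue
            hit = local_align(q, s, scoring)
            if hit.raw_score <= 0:
                continue
            if best is None or hit.raw_score > best.raw_score:
                best = hit
        if best is not None and best.evalue <= e_cutoff:
            results[q.id] = best
    return results


#: Consensus cytochrome P450 motifs (X = any residue).
P450_MOTIFS: dict[str, str] = {
    "EXXR": r"E..R",
    "PXRX": r"P.R.",
    "heme_FXXGXRXCXG": r"F..G.R.C.G",
    "oxygen_binding": r"[AG]G.[DE]TT",
}


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of a P450 consensus motif (0-based position)."""

    motif_name: str
    position: int
    matched_text: str

    @property
    def position_1based(self) -> int:
        """1-based residue number, the convention of the P450 literature."""
        return self.position + 1


def scan_p450_motifs(peptide: SequenceRecord) -> list[MotifHit]:
    """All non-overlapping matches of each consensus motif in a peptide."""
    if peptide.alphabet != "protein":
        raise ValueError("motif scanning requires a protein sequence")
    seq = peptide.seq.upper()
    hits: list[MotifHit] = []
    for name, pattern in P450_MOTIFS.items():
        for m in re.finditer(pattern, seq):
            hits.append(MotifHit(motif_name=name, position=m.start(), matched_text=m.group()))
    return hits


@dataclass(frozen=True)
class P450Classification:
    """Outcome of homology-based P450 classification for one peptide."""

    is_p450: bool
    best_reference: str | None
    evalue: float | None
    motifs: tuple[MotifHit, ...]


def classify_p450(
    peptide: SequenceRecord,
    reference_p450s: Sequence[SequenceRecord],
    e_cutoff: float = 1e-4,
    scoring: AlignmentScoring | None = None,
) -> P450Classification:
    """Call a peptide a P450 iff its best reference-set hit has E <= cutoff.

    Motif hits are reported alongside as advisory annotation; they do not
    gate the call.
    """
    if not reference_p450s:
        raise ValueError("reference P450 set must be non-empty")
    hits = find_homologs([peptide], reference_p450s, e_cutoff=e_cutoff, scoring=scoring)
    motifs = tuple(scan_p450_motifs(peptide))
    hit = hits.get(peptide.id)
    if hit is None:
        return P450Classification(False, None, None, motifs)
    return P450Classification(True, hit.subject_id, hit.evalue, motifs)


_STOPS = {"TAA", "TAG", "TGA"}


def _orfs_in_frame(frame_seq: str) -> list[tuple[int, int]]:
    """ATG-initiated ORFs (codon-index start, end) within one frame string."""
    codons = [frame_seq[i : i + 3] for i in range(0, len(frame_seq) - 2, 3)]
    orfs: list[tuple[int, int]] = []
    start: int | None = None
    for i, codon in enumerate(codons):
        if start is None:
            if codon == "ATG":
                start = i
        elif codon in _STOPS:
            orfs.append((start, i))
            start = None
    if start is not None:
        # ORF runs off the end of the frame (incomplete 3' end).
        orfs.append((start, len(codons)))
    return orfs


def longest_orf_peptide(transcript: SequenceRecord, min_aa: int = 50) -> SequenceRecord | None:
    """Translate the longest ATG-initiated ORF over all six reading frames.

    The stop codon is excluded from the peptide; an ORF may run to the end
    of its frame without a stop (incomplete transcript ends are common in
    de novo assemblies).  Ties are broken deterministically: forward strand
    before reverse, lower frame first, then leftmost start.  Returns None
    when the best ORF is shorter than ``min_aa`` residues.
    """
    if transcript.alphabet != "dna":
        raise ValueError("ORF prediction requires a nucleotide sequence")
    seq = transcript.seq.upper()
    if not set(seq) <= set("ACGTN"):
        raise ValueError(f"{transcript.id}: non-ACGTN characters in transcript")
    strands = (seq, str(Seq(seq).reverse_complement()))
    best: tuple[int, str] | None = None  # (aa length, frame sequence slice)
    for strand in strands:
        for offset in range(3):
            frame = strand[offset:]
            for start, end in _orfs_in_frame(frame):
                aa_len = end - start
                if best is None or aa_len > best[0]:
                    best = (aa_len, frame[start * 3 : end * 3])
    if best is None or best[0] < min_aa:
        return None
    peptide = str(Seq(best[1]).translate())
    return SequenceRecord(
        id=transcript.id,
        seq=peptide,
        description="longest six-frame ORF",
        alphabet="protein",
    )
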