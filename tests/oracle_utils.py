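"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with naive algorithms (exhaustive
enumeration, plain-Python dynamic programming) so the implementations they
check are exercised through an unrelated code path.
"""

from __future__ import annotations

import math

NEG = -math.inf

BLOSUM62_SUBSET = None  # loaded lazily by tests that need it


def global_affine_score(a: str, b: str, score_fn, gap_open: float, gap_extend: float) -> float:
    """Needleman-Wunsch with affine gaps; a gap of length k costs
    gap_open + k*gap_extend.  Plain three-state DP."""
    la, lb = len(a), len(b)
    open_cost = gap_open + gap_extend
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Ix = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (consume a)
    Iy = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        Ix[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, lb + 1):
        Iy[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = score_fn(a[i - 1], b[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] - open_cost, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - open_cost, Iy[i][j - 1] - gap_extend)
    return max(M[la][lb], Ix[la][lb], Iy[la][lb])


def brute_force_local_score(a: str, b: str, score_fn, gap_open: float, gap_extend: float) -> float:
    """Best local alignment score by enumerating every substring pair and
    aligning each pair globally; the empty alignment scores 0."""
    best = 0.0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            for k in range(len(b)):
                for l in range(k + 1, len(b) + 1):
                    s = global_affine_score(a[i:j], b[k:l], score_fn, gap_open, gap_extend)
                    if s > best:
                        best = s
    return best


_CODON_AA = {}


def _codon_table() -> dict[str, str]:
    # Built from the standard-code amino-acid/codon listing, spelled out
    # here independently of the package's table.
    global _CODON_AA
    if _CODON_AA:
        return _CODON_AA
    spec = {
        "F": "TTT TTC", "L": "TTA TTG CTT CTC CTA CTG", "I": "ATT ATC ATA",
        "M": "ATG", "V": "GTT GTC GTA GTG", "S": "TCT TCC TCA TCG AGT AGC",
        "P": "CCT CCC CCA CCG", "T": "ACT ACC ACA ACG", "A": "GCT GCC GCA GCG",
        "Y": "TAT TAC", "H": "CAT CAC", "Q": "CAA CAG", "N": "AAT AAC",
        "K": "AAA AAG", "D": "GAT GAC", "E": "GAA GAG", "C": "TGT TGC",
        "W": "TGG", "R": "CGT CGC CGA CGG AGA AGG", "G": "GGT GGC GGA GGG",
        "*": "TAA TAG TGA",
    }
    for aa, codons in spec.items():
        for c in codons.split():
            _CODON_AA[c] = aa
    return _CODON_AA


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def brute_force_longest_orf(seq: str) -> str | None:
    """Longest ATG-initiated ORF over six frames, translated, stop excluded.

    Scans every position rather than codon-chunking, as an independent
    route; an ORF may run off the end of its frame.
    """
    table = _codon_table()
    best = ""
    for strand in (seq, revcomp(seq)):
        for start in range(len(strand) - 2):
            if strand[start : start + 3] != "ATG":
                continue
            aa = []
            pos = start
            while pos + 3 <= len(strand):
                codon = strand[pos : pos + 3]
                res = table.get(codon, "X")
                if res == "*":
                    break
                aa.append(res)
                pos += 3
            # only the leftmost ATG of a stop-free run can be the longest,
            # but scanning every ATG is fine for an oracle
            pep = "".join(aa)
            if len(pep) > len(best):
                best = pep
    return best or None


def pearson_direct(x, y) -> float:
    """Textbook Pearson formula, no numpy."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den
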