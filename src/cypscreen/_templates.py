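"""Synthetic template sequences for the screen's sequence universe.

Real reference sets (a curated plant P450 protein list; the bait gene's
protein) are external resources, so the package carries deterministic
synthetic stand-ins instead:

* a 500-residue P450-like template peptide carrying the four consensus
  motifs at literature-typical positions -- the oxygen binding and
  activation motif (A/G)GX(D/E)TT near residue 320, EXXR near 387, PXRX
  near 430 and the heme-binding FXXGXRXCXG motif at 464-473 (1-based);
* a 360-residue methyltransferase-like bait template scrubbed of P450
  motifs;
* a small synthetic reference P450 set (the template plus diverged
  variants, motifs preserved) packaged as
  ``data/p450_reference_synthetic.fasta``.

Everything is generated from fixed seeds, so templates are identical
across installs.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

import numpy as np

from .io import SequenceRecord, read_fasta
from .homology import P450_MOTIFS

__all__ = [
    "p450_template",
    "bait_template",
    "reference_p450_set",
    "bait_reference",
    "random_peptide",
    "scrub_p450_motifs",
    "mutate_peptide",
    "AA_ALPHABET",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_TEMPLATE_SEED = 961_001
_P450_LENGTH = 500
# 0-based motif start positions (1-based 320 / 387 / 430 / 464).
_MOTIF_INSERTS = {
    319: "AGNETT",       # (A/G)GX(D/E)TT
    386: "ETLR",         # EXXR
    429: "PERF",         # canonical instance of PXRX
    463: "FSAGSRNCIG",   # FXXGXRXCXG heme-binding decapeptide
}


def random_peptide(length: int, rng: np.random.Generator, start_met: bool = True) -> str:
    """Uniform-random peptide; optionally methionine-initiated."""
    aas = rng.choice(list(AA_ALPHABET), size=length)
    seq = "".join(aas)
    if start_met:
        seq = "M" + seq[1:]
    return seq


def scrub_p450_motifs(seq: str, rng: np.random.Generator) -> str:
    """Destroy any accidental P450 consensus motif occurrences.

    Used for non-P450 sequences so that motif annotation stays a true
    negative on them.  The first residue of each match is substituted until
    no motif pattern matches.
    """
    chars = list(seq)
    for _ in range(100):
        dirty = False
        for pattern in P450_MOTIFS.values():
            m = re.search(pattern, "".join(chars))
            if m:
                dirty = True
                old = chars[m.start()]
                choices = [a for a in AA_ALPHABET if a not in (old, "E", "P", "F", "A", "G")]
                chars[m.start()] = choices[int(rng.integers(len(choices)))]
        if not dirty:
            return "".join(chars)
    raise RuntimeError("could not scrub motifs")  # pragma: no cover


def mutate_peptide(
    seq: str,
    target_identity: float,
    rng: np.random.Generator,
    preserve: dict[int, str] | None = None,
) -> str:
    """Substitute residues to reach the target identity exactly.

    ``preserve`` maps positions to substrings that are re-imposed after
    mutation (used to keep consensus motifs intact in diverged P450s).
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target identity must lie in (0, 1]")
    n_sub = round((1.0 - target_identity) * len(seq))
    chars = list(seq)
    protected = {0}
    if preserve:
        for pos, text in preserve.items():
            protected.update(range(pos, pos + len(text)))
    candidates = [i for i in range(len(seq)) if i not in protected]
    for i in rng.choice(candidates, size=min(n_sub, len(candidates)), replace=False):
        alternatives = [a for a in AA_ALPHABET if a != chars[i]]
        chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    if preserve:
        for pos, text in preserve.items():
            chars[pos : pos + len(text)] = list(text)
    return "".join(chars)


@lru_cache(maxsize=1)
def p450_template() -> SequenceRecord:
    """The synthetic P450-like template peptide (all four motifs present)."""
    rng = np.random.default_rng(_TEMPLATE_SEED)
    chars = list(random_peptide(_P450_LENGTH, rng))
    for pos, text in _MOTIF_INSERTS.items():
        chars[pos : pos + len(text)] = list(text)
    return SequenceRecord(
        id="P450_template_synthetic",
        seq="".join(chars),
        description="synthetic cytochrome P450-like template peptide",
        alphabet="protein",
    )


@lru_cache(maxsize=1)
def bait_template() -> SequenceRecord:
    """The synthetic bait (methyltransferase-like) reference peptide."""
    rng = np.random.default_rng(_TEMPLATE_SEED + 1)
    seq = scrub_p450_motifs(random_peptide(360, rng), rng)
    return SequenceRecord(
        id="N4OMT_reference_synthetic",
        seq=seq,
        description="synthetic bait-gene (O-methyltransferase-like) reference peptide",
        alphabet="protein",
    )


def build_reference_p450_set(n: int = 8) -> list[SequenceRecord]:
    """Construct the synthetic reference P450 set deterministically.

    The template plus ``n - 1`` variants diverged to 60-90% identity with
    motifs preserved; this is what ships as
    ``data/p450_reference_synthetic.fasta``.
    """
    rng = np.random.default_rng(_TEMPLATE_SEED + 2)
    template = p450_template()
    records = [template]
    identities = np.linspace(0.9, 0.6, n - 1)
    for i, ident in enumerate(identities, start=1):
        seq = mutate_peptide(template.seq, float(ident), rng, preserve=_MOTIF_INSERTS)
        records.append(
            SequenceRecord(
                id=f"P450_ref_synthetic_{i:02d}",
                seq=seq,
                description=f"synthetic reference P450, {ident:.2f} identity to template",
                alphabet="protein",
            )
        )
    return records


@lru_cache(maxsize=1)
def reference_p450_set() -> tuple[SequenceRecord, ...]:
    """Load the packaged synthetic reference P450 protein set."""
    path = resources.files("cypscreen").joinpath("data/p450_reference_synthetic.fasta")
    with resources.as_file(path) as p:
        return tuple(read_fasta(p, alphabet="protein"))


@lru_cache(maxsize=1)
def bait_reference() -> SequenceRecord:
    """Load the packaged synthetic bait reference peptide."""
    path = resources.files("cypscreen").joinpath("data/bait_reference_synthetic.fasta")
    with resources.as_file(path) as p:
        return read_fasta(p, alphabet="protein")[0]
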