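"""End-to-end candidate screen across assemblies.

The workflow, per assembly: find the bait gene's closest homolog, list the
transcripts whose expression matches the bait model, and (in the reference
assembly) keep the co-expressing transcripts that classify as cytochrome
P450s.  Each reference candidate is then queried, at a stringent
nucleotide E-value cutoff, against the *co-expressing transcript lists* of
the other assemblies — presence means a best hit passing the cutoff among
those list members, not anywhere in the assembly.  Candidates present in
every assembly's list (the reference list counts itself) are flagged top
priority.

The screen itself is deterministic: no randomness outside the inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import _templates
from .coexpression import BaitModel, MatchCriteria, MatchResult, screen_matrix
from .homology import (
    AlignmentHit,
    MotifHit,
    classify_p450,
    dna_scoring,
    find_homologs,
    protein_scoring,
)
from .io import SequenceRecord
from .synthetic import AssemblyData

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "CandidateReport",
    "BaitNotFoundError",
    "select_bait",
    "p450_coexpress_list",
    "cross_assembly_presence",
    "run_screen",
]


class BaitNotFoundError(RuntimeError):
    """No bait homolog passes the protein cutoff in an assembly."""


@dataclass(frozen=True)
class ScreenConfig:
    """Cutoffs and references for a screen run."""

    reference_assembly: str
    criteria: MatchCriteria = MatchCriteria()
    protein_cutoff: float = 1e-4
    dna_cutoff: float = 1e-50
    required_presence: int | None = None  # None = all assemblies
    bait_reference: SequenceRecord | None = None
    reference_p450s: tuple[SequenceRecord, ...] | None = None

    def resolved_reference_p450s(self) -> tuple[SequenceRecord, ...]:
        if self.reference_p450s is not None:
            return self.reference_p450s
        return _templates.reference_p450_set()


@dataclass
class CandidateReport:
    """One reference-assembly candidate and its cross-assembly support."""

    candidate_id: str
    match_stats: MatchResult
    motif_hits: tuple[MotifHit, ...]
    per_assembly_link: dict[str, AlignmentHit]
    n_assemblies_present: int
    top_priority: bool


def select_bait(
    peptides: Sequence[SequenceRecord],
    bait_reference_protein: SequenceRecord,
    e_cutoff: float = 1e-4,
) -> str:
    """Id of the assembly transcript best matching the bait protein."""
    if not peptides:
        raise BaitNotFoundError("assembly has no predicted peptides")
    hits = find_homologs(
        [bait_reference_protein], peptides, e_cutoff=e_cutoff, scoring=protein_scoring()
    )
    hit = hits.get(bait_reference_protein.id)
    if hit is None:
        raise BaitNotFoundError(
            f"no bait homolog at E <= {e_cutoff:g} among {len(peptides)} peptides"
        )
    return hit.subject_id


def p450_coexpress_list(
    assembly: AssemblyData,
    criteria: MatchCriteria,
    reference_p450s: Sequence[SequenceRecord],
    protein_cutoff: float = 1e-4,
) -> list[str]:
    """Transcripts that both co-express with the bait and classify as P450.

    The intersection is computed lazily: classification runs only on the
    co-expressing transcripts, which yields the identical set.  Returned in
    id-sorted (deterministic) order.
    """
    passing = screen_matrix(assembly.expression, assembly.bait_model, criteria)
    peptide_by_id = {p.id: p for p in assembly.peptides}
    out: list[str] = []
    for res in passing:
        pep = peptide_by_id.get(res.transcript_id)
        if pep is None:
            continue
        call = classify_p450(pep, reference_p450s, e_cutoff=protein_cutoff)
        if call.is_p450:
            out.append(res.transcript_id)
    return out


def cross_assembly_presence(
    candidate: SequenceRecord,
    other_assembly_coexpress: Mapping[str, Sequence[SequenceRecord]],
    dna_cutoff: float = 1e-50,
) -> dict[str, AlignmentHit]:
    """Best nucleotide hit of the candidate within each other assembly's
    co-expressing transcript list, where one passes the cutoff."""
    links: dict[str, AlignmentHit] = {}
    for aid, members in other_assembly_coexpress.items():
        hits = find_homologs(
            [candidate], list(members), e_cutoff=dna_cutoff, scoring=dna_scoring()
        )
        hit = hits.get(candidate.id)
        if hit is not None:
            links[aid] = hit
    return links


def run_screen(
    assemblies: Mapping[str, AssemblyData],
    config: ScreenConfig,
) -> list[CandidateReport]:
    """Run the full cross-assembly candidate screen.

    Returns reports for every reference-assembly co-expressing P450,
    sorted by (assemblies present desc, correlation desc, id).
    """
    if len(assemblies) < 2:
        raise ValueError("the screen needs at least two assemblies")
    if config.reference_assembly not in assemblies:
        raise ValueError(f"unknown reference assembly {config.reference_assembly!r}")
    reference_p450s = config.resolved_reference_p450s()

    # Stage 1: bait per assembly (re-selected by homology when a reference
    # bait protein is configured; otherwise taken from the bait model).
    bait_ids: dict[str, str] = {}
    for aid, asm in assemblies.items():
        if config.bait_reference is not None:
            try:
                bait_ids[aid] = select_bait(
                    asm.peptides, config.bait_reference, e_cutoff=config.protein_cutoff
                )
            except BaitNotFoundError as exc:
                raise BaitNotFoundError(f"assembly {aid!r}: {exc}") from exc
        elif asm.bait_model.bait_transcript_id is not None:
            bait_ids[aid] = asm.bait_model.bait_transcript_id
        else:
            raise BaitNotFoundError(
                f"assembly {aid!r}: no bait reference protein and no bait transcript id"
            )

    # Stage 2: co-expressing transcripts per assembly.
    coexpress: dict[str, list[MatchResult]] = {}
    for aid, asm in sorted(assemblies.items()):
        bait = asm.bait_model
        if bait.bait_transcript_id != bait_ids[aid]:
            from dataclasses import replace

            bait = replace(bait, bait_transcript_id=bait_ids[aid])
        coexpress[aid] = screen_matrix(asm.expression, bait, config.criteria)
        logger.info("%s: %d transcripts co-express with the bait", aid, len(coexpress[aid]))

    # Stage 3: reference-assembly co-expressing P450 candidates.
    ref = assemblies[config.reference_assembly]
    peptide_by_id = {p.id: p for p in ref.peptides}
    ref_results = {res.transcript_id: res for res in coexpress[config.reference_assembly]}
    candidates: dict[str, tuple[MatchResult, tuple[MotifHit, ...]]] = {}
    for tid in sorted(ref_results):
        pep = peptide_by_id.get(tid)
        if pep is None:
            continue
        call = classify_p450(pep, reference_p450s, e_cutoff=config.protein_cutoff)
        if call.is_p450:
            candidates[tid] = (ref_results[tid], call.motifs)
    logger.info(
        "%s: %d co-expressing P450 candidates",
        config.reference_assembly,
        len(candidates),
    )

    # Stage 4: nucleotide linking against the other assemblies' lists.
    other_lists: dict[str, list[SequenceRecord]] = {}
    for aid, asm in assemblies.items():
        if aid == config.reference_assembly:
            continue
        members = {res.transcript_id for res in coexpress[aid]}
        seq_by_id = {t.id: t for t in asm.transcripts}
        other_lists[aid] = [seq_by_id[tid] for tid in sorted(members) if tid in seq_by_id]

    transcript_by_id = {t.id: t for t in ref.transcripts}
    n_total = len(assemblies)
    required = config.required_presence if config.required_presence is not None else n_total
    reports: list[CandidateReport] = []
    for tid, (match, motifs) in candidates.items():
        links = cross_assembly_presence(
            transcript_by_id[tid], other_lists, dna_cutoff=config.dna_cutoff
        )
        n_present = 1 + len(links)  # the reference list counts itself
        reports.append(
            CandidateReport(
                candidate_id=tid,
                match_stats=match,
                motif_hits=motifs,
                per_assembly_link=links,
                n_assemblies_present=n_present,
                top_priority=n_present >= required,
            )
        )
    reports.sort(key=lambda r: (-r.n_assemblies_present, -r.match_stats.r, r.candidate_id))
    logger.info("%d top-priority candidates", sum(r.top_priority for r in reports))
    return reports
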