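"""Synthetic multi-assembly screen datasets and noisy kinetics curves.

The screen generator emulates the statistical structure the comparative
co-expression screen assumes, at desk scale:

* five assemblies (species x assembler) by default, each with a bait
  transcript whose three-tissue expression equals that assembly's bait
  model (defaults are the published N4OMT models);
* exactly one planted P450 orthogroup (optional) whose noiseless
  expression is proportional to the bait model in every assembly, with
  multiplicative log-normal noise of log-scale sd ``expression_noise_sigma``;
* decoy P450s (diverged copies of the packaged P450 template, motifs
  intact) and non-P450 background transcripts, all with tissue expression
  drawn independently of the bait: per-tissue means uniform on [0.1, 200]
  (spanning the observed RPM/TPM range of real bait models) times
  log-normal noise;
* optionally one *non-P450* bait-correlated transcript, a negative
  control for the P450-classification gate.

Sequences are coding: peptides are reverse-translated with random codon
choice, framed by short UTRs.  Cross-assembly orthogroup members are
substitution-mutated at the DNA level from the reference-assembly member
at exactly ``homolog_identity`` (start codon protected, no in-frame stops
introduced), so the stringent nucleotide E-value linking step succeeds or
fails according to that single knob.  Decoys are generated independently
per assembly and therefore never link across assemblies at a stringent
cutoff.

All randomness flows from a single seeded generator per scenario;
identical scenario + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _templates
from .coexpression import DEFAULT_BAIT_MODELS, BaitModel
from .homology import longest_orf_peptide
from .io import DEFAULT_TISSUES, ExpressionMatrix, SequenceRecord
from .kinetics import KineticParams, rate

__all__ = [
    "ScreenScenario",
    "KineticScenario",
    "AssemblyData",
    "ScreenDataset",
    "generate_screen_dataset",
    "mutate_homolog",
    "simulate_rates",
    "reverse_translate",
]

_CODON_TABLE: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}
_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """Random-codon reverse translation of a peptide (no stop appended)."""
    return "".join(
        _CODON_TABLE[aa][int(rng.integers(len(_CODON_TABLE[aa])))] for aa in peptide
    )


def _make_transcript(
    peptide: str, rng: np.random.Generator
) -> tuple[str, tuple[int, int]]:
    """Coding DNA with short random UTRs and a stop codon.

    Returns the transcript and the (start, end) span of the coding region
    including the stop codon.
    """
    utr5 = "".join(rng.choice(list(_BASES), size=int(rng.integers(20, 50))))
    utr3 = "".join(rng.choice(list(_BASES), size=int(rng.integers(30, 70))))
    cds = reverse_translate(peptide, rng) + "TAA"
    return utr5 + cds + utr3, (len(utr5), len(utr5) + len(cds))


def _mutate_dna(
    seq: str,
    target_identity: float,
    rng: np.random.Generator,
    coding_span: tuple[int, int] | None = None,
) -> str:
    """Substitute bases to reach the target identity exactly.

    When ``coding_span`` (start, end of the ORF incl. stop) is given, the
    start codon is protected and substitutions that would create an
    in-frame stop are re-drawn, so the encoded peptide keeps its length.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target identity must lie in (0, 1]")
    n_sub = round((1.0 - target_identity) * len(seq))
    chars = list(seq)
    protected: set[int] = set()
    if coding_span is not None:
        protected.update(range(coding_span[0], coding_span[0] + 3))  # ATG
        protected.update(range(coding_span[1] - 3, coding_span[1]))  # stop
    candidates = [i for i in range(len(seq)) if i not in protected]
    positions = rng.choice(candidates, size=min(n_sub, len(candidates)), replace=False)
    for i in positions:
        alternatives = [b for b in _BASES if b != chars[i]]
        rng.shuffle(alternatives)
        original = chars[i]
        for b in alternatives:
            chars[i] = b
            if coding_span is None or not _creates_stop(chars, i, coding_span):
                break
        else:  # pragma: no cover - some alternative is always stop-free
            chars[i] = original
    return "".join(chars)


def _creates_stop(chars: list[str], i: int, coding_span: tuple[int, int]) -> bool:
    start, end = coding_span
    if not start <= i < end - 3:
        return False
    codon_start = start + ((i - start) // 3) * 3
    return "".join(chars[codon_start : codon_start + 3]) in _STOPS


def mutate_homolog(
    seq: SequenceRecord, target_identity: float, seed: int | np.random.Generator
) -> SequenceRecord:
    """Derive a homolog by substitutions only (no indels).

    The realized identity equals ``round((1-t)*L)/L`` substitutions, i.e.
    within one residue of the target.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if seq.alphabet == "dna":
        mutated = _mutate_dna(seq.seq, target_identity, rng)
    else:
        mutated = _templates.mutate_peptide(seq.seq, target_identity, rng)
    return SequenceRecord(
        id=seq.id,
        seq=mutated,
        description=f"homolog at ~{target_identity:.0%} identity",
        alphabet=seq.alphabet,
    )


@dataclass(frozen=True)
class ScreenScenario:
    """Parameters of a synthetic multi-assembly screen dataset."""

    n_assemblies: int = 5
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_p450_decoys: int = 60
    n_background: int = 60
    n_correlated_non_p450: int = 1
    planted_orthogroup: bool = True
    bait_models: tuple[BaitModel, ...] | None = None
    expression_noise_sigma: float = 0.02
    homolog_identity: float = 0.95
    decoy_identity_range: tuple[float, float] = (0.50, 0.65)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_assemblies < 2:
            raise ValueError("need at least two assemblies")
        if not 0 < self.homolog_identity <= 1:
            raise ValueError("homolog_identity must lie in (0, 1]")
        if self.expression_noise_sigma < 0:
            raise ValueError("expression noise sigma must be >= 0")
        if self.bait_models is not None and len(self.bait_models) != self.n_assemblies:
            raise ValueError("one bait model per assembly required")
        if self.bait_models is None and self.n_assemblies > len(DEFAULT_BAIT_MODELS):
            raise ValueError(
                f"default bait models cover at most {len(DEFAULT_BAIT_MODELS)} assemblies"
            )

    @property
    def n_transcripts(self) -> int:
        """Transcripts per assembly (bait + planted + decoys + background)."""
        return (
            1
            + int(self.planted_orthogroup)
            + self.n_p450_decoys
            + self.n_background
            + self.n_correlated_non_p450
        )

    def resolved_bait_models(self) -> tuple[BaitModel, ...]:
        if self.bait_models is not None:
            return self.bait_models
        return DEFAULT_BAIT_MODELS[: self.n_assemblies]


@dataclass
class AssemblyData:
    """One assembly's transcripts, predicted peptides, expression and bait."""

    assembly_id: str
    transcripts: list[SequenceRecord]
    peptides: list[SequenceRecord]
    expression: ExpressionMatrix
    bait_model: BaitModel


@dataclass
class ScreenDataset:
    """Generated screen inputs plus ground-truth bookkeeping for tests."""

    scenario: ScreenScenario
    assemblies: dict[str, AssemblyData]
    planted_ids: dict[str, str | None]
    correlated_non_p450_ids: dict[str, tuple[str, ...]]

    @property
    def reference_assembly(self) -> str:
        return next(iter(self.assemblies))


def _noisy_proportional(
    model: np.ndarray, rng: np.random.Generator, sigma: float
) -> np.ndarray:
    scale = rng.uniform(0.5, 3.0)
    noise = np.exp(rng.normal(0.0, sigma, size=model.size)) if sigma > 0 else 1.0
    return scale * model * noise


def _independent_profile(
    n_tissues: int, rng: np.random.Generator, sigma: float
) -> np.ndarray:
    means = rng.uniform(0.1, 200.0, size=n_tissues)
    noise = np.exp(rng.normal(0.0, sigma, size=n_tissues)) if sigma > 0 else 1.0
    return means * noise


def generate_screen_dataset(scenario: ScreenScenario) -> ScreenDataset:
    """Generate per-assembly sequence sets, expression matrices and baits."""
    rng = np.random.default_rng(scenario.seed)
    models = scenario.resolved_bait_models()
    sigma = scenario.expression_noise_sigma

    # Shared ancestors: the reference-assembly member of each orthologous
    # family is the ancestor; other assemblies carry diverged copies.
    planted_peptide = _templates.mutate_peptide(
        _templates.p450_template().seq, 0.85, rng, preserve=_templates._MOTIF_INSERTS
    )
    planted_ancestor, planted_span = _make_transcript(planted_peptide, rng)
    bait_ancestor, bait_span = _make_transcript(_templates.bait_template().seq, rng)

    assemblies: dict[str, AssemblyData] = {}
    planted_ids: dict[str, str | None] = {}
    correlated_ids: dict[str, tuple[str, ...]] = {}

    for a_idx, bait_model in enumerate(models):
        aid = bait_model.assembly_id
        entries: list[tuple[str, str, np.ndarray]] = []  # (kind, dna, expression)

        # Bait transcript: expression equals the assembly's model.
        if a_idx == 0:
            bait_dna = bait_ancestor
        else:
            bait_dna = _mutate_dna(bait_ancestor, scenario.homolog_identity, rng, bait_span)
        entries.append(("bait", bait_dna, bait_model.values.copy()))

        if scenario.planted_orthogroup:
            if a_idx == 0:
                dna = planted_ancestor
            else:
                dna = _mutate_dna(planted_ancestor, scenario.homolog_identity, rng, planted_span)
            entries.append(("planted", dna, _noisy_proportional(bait_model.values, rng, sigma)))

        lo, hi = scenario.decoy_identity_range
        for _ in range(scenario.n_p450_decoys):
            ident = rng.uniform(lo, hi)
            pep = _templates.mutate_peptide(
                _templates.p450_template().seq, ident, rng,
                preserve=_templates._MOTIF_INSERTS,
            )
            entries.append(
                ("p450_decoy", _make_transcript(pep, rng)[0],
                 _independent_profile(len(scenario.tissues), rng, sigma))
            )

        for _ in range(scenario.n_background):
            length = int(rng.integers(150, 420))
            pep = _templates.scrub_p450_motifs(
                _templates.random_peptide(length, rng), rng
            )
            entries.append(
                ("background", _make_transcript(pep, rng)[0],
                 _independent_profile(len(scenario.tissues), rng, sigma))
            )

        for _ in range(scenario.n_correlated_non_p450):
            length = int(rng.integers(150, 420))
            pep = _templates.scrub_p450_motifs(
                _templates.random_peptide(length, rng), rng
            )
            entries.append(
                ("correlated_non_p450", _make_transcript(pep, rng)[0],
                 _noisy_proportional(bait_model.values, rng, sigma))
            )

        # Shuffle record order and assign opaque sequential ids so transcript
        # ids carry no category information.
        order = rng.permutation(len(entries))
        transcripts: list[SequenceRecord] = []
        expression_rows: dict[str, np.ndarray] = {}
        bait_id = None
        planted_id = None
        corr_ids: list[str] = []
        for new_idx, old_idx in enumerate(order):
            kind, dna, expr = entries[int(old_idx)]
            tid = f"{aid}|t{new_idx:04d}"
            transcripts.append(SequenceRecord(id=tid, seq=dna, alphabet="dna"))
            expression_rows[tid] = expr
            if kind == "bait":
                bait_id = tid
            elif kind == "planted":
                planted_id = tid
            elif kind == "correlated_non_p450":
                corr_ids.append(tid)

        peptides = []
        for t in transcripts:
            pep = longest_orf_peptide(t, min_aa=50)
            if pep is not None:
                peptides.append(pep)

        matrix = ExpressionMatrix(
            assembly_id=aid,
            data=pd.DataFrame.from_dict(
                expression_rows, orient="index", columns=list(scenario.tissues)
            ),
            unit="relative",
        )
        assemblies[aid] = AssemblyData(
            assembly_id=aid,
            transcripts=transcripts,
            peptides=peptides,
            expression=matrix,
            bait_model=replace(bait_model, tissues=scenario.tissues,
                               bait_transcript_id=bait_id),
        )
        planted_ids[aid] = planted_id
        correlated_ids[aid] = tuple(corr_ids)

    return ScreenDataset(
        scenario=scenario,
        assemblies=assemblies,
        planted_ids=planted_ids,
        correlated_non_p450_ids=correlated_ids,
    )


@dataclass(frozen=True)
class KineticScenario:
    """Parameters for simulating noisy substrate-inhibition rate curves.

    Defaults are the published constants for the preferred substrate
    (Km 1.13 uM, kcat 15.0 1/min, Ki 64.3 uM) at 2.5 nM enzyme, observed on
    a 12-point 0.25-200 uM geometric substrate grid in triplicate with 5%
    multiplicative Gaussian noise.
    """

    km: float = 1.13
    kcat: float = 15.0
    ki: float = 64.3
    enzyme_conc: float = 2.5
    substrate_grid: tuple[float, ...] = tuple(np.geomspace(0.25, 200.0, 12))
    replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.km, self.kcat, self.ki, self.enzyme_conc) <= 0:
            raise ValueError("concentrations and rate constants must be positive")
        if not self.substrate_grid:
            raise ValueError("substrate grid must be non-empty")
        if self.noise_cv < 0 or self.replicates < 1:
            raise ValueError("noise_cv must be >= 0 and replicates >= 1")

    @property
    def params(self) -> KineticParams:
        return KineticParams(
            km=self.km, kcat=self.kcat, ki=self.ki, enzyme_conc=self.enzyme_conc
        )


def simulate_rates(scenario: KineticScenario) -> pd.DataFrame:
    """Simulate (S_uM, replicate, v) observations from the rate law.

    v = model(S) * (1 + eps), eps ~ Normal(0, noise_cv), clipped at zero.
    """
    rng = np.random.default_rng(scenario.seed)
    S = np.asarray(scenario.substrate_grid, dtype=float)
    truth = rate(S, scenario.params)
    rows = []
    for rep in range(1, scenario.replicates + 1):
        eps = rng.normal(0.0, scenario.noise_cv, size=S.size) if scenario.noise_cv > 0 else 0.0
        v = np.clip(truth * (1.0 + eps), 0.0, None)
        for s_val, v_val in zip(S, v):
            rows.append({"S_uM": s_val, "replicate": rep, "v": v_val})
    return pd.DataFrame(rows)
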