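"""Bait-model expression matching (HAYSTACK-style pattern screen).

A transcript is declared co-expressed with the bait gene when its tissue
expression vector matches the bait's model vector under four criteria:

* Pearson correlation r >= ``corr_cutoff`` (default 0.8),
* maximum abundance (``background``) >= ``background_cutoff`` (default 1),
* max/min fold change >= ``fold_cutoff`` (default 4), and
* correlation p-value <= ``p_cutoff`` (default 0.05, optional).

The p-value is the parametric two-sided test on r, t = r*sqrt((n-2)/(1-r^2))
with n-2 degrees of freedom.  With only three tissues this criterion is by
far the strictest: p <= 0.05 at n = 3 requires r >= 0.99692, so the p test
dominates the 0.8 correlation cutoff whenever it is enabled.  (A label
permutation test cannot reach 0.05 with 3 tissues, so the parametric form
is the only criterion under which near-perfect profiles can pass.)

Fold change is protected against zero denominators by flooring the minimum
abundance at the background cutoff; bait models legitimately contain
near-zero entries (e.g. 0.01 RPM in leaf) that would otherwise explode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .io import ExpressionMatrix

__all__ = [
    "BaitModel",
    "MatchCriteria",
    "MatchResult",
    "ConstantVectorError",
    "pearson_r",
    "fold_and_background",
    "correlation_pvalue",
    "model_match",
    "screen_matrix",
    "DEFAULT_BAIT_MODELS",
]


class ConstantVectorError(ValueError):
    """Correlation is undefined for a constant vector."""


@dataclass(frozen=True)
class BaitModel:
    """Per-assembly bait expression model over the screened tissues."""

    assembly_id: str
    tissues: tuple[str, ...]
    model_values: tuple[float, ...]
    bait_transcript_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.tissues) != len(self.model_values):
            raise ValueError("model length must equal tissue count")
        if any(v < 0 for v in self.model_values):
            raise ValueError("model values must be non-negative")
        if len(set(self.model_values)) == 1:
            raise ValueError("model values must not all be equal")

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.model_values, dtype=float)


#: Bait (N4OMT) expression models for the five usable assemblies:
#: relative RT-PCR units for the reference Narcissus assembly, RPM for the
#: Galanthus short-read assemblies, TPM for the Trinity re-assemblies.
#: Tissue order: leaf, inflorescence, bulb.
DEFAULT_BAIT_MODELS: tuple[BaitModel, ...] = (
    BaitModel("narcissus_abyss_mira", ("leaf", "inflorescence", "bulb"), (1.0, 30.0, 45.0)),
    BaitModel("galanthus_sp_abyss_mira", ("leaf", "inflorescence", "bulb"), (0.01, 33.3, 140.0)),
    BaitModel("galanthus_elwesii_abyss_mira", ("leaf", "inflorescence", "bulb"), (2.24, 22.6, 71.7)),
    BaitModel("galanthus_sp_trinity", ("leaf", "inflorescence", "bulb"), (2.42, 29.0, 94.7)),
    BaitModel("galanthus_elwesii_trinity", ("leaf", "inflorescence", "bulb"), (16.0, 49.3, 202.0)),
)


@dataclass(frozen=True)
class MatchCriteria:
    """Cutoffs of the four-way co-expression decision."""

    corr_cutoff: float = 0.8
    background_cutoff: float = 1.0
    fold_cutoff: float = 4.0
    p_cutoff: float = 0.05
    use_p: bool = True
    log_transform: bool = False

    def __post_init__(self) -> None:
        if not -1.0 <= self.corr_cutoff <= 1.0:
            raise ValueError("corr_cutoff must lie in [-1, 1]")
        if self.background_cutoff <= 0 or self.fold_cutoff <= 0 or self.p_cutoff <= 0:
            raise ValueError("background, fold and p cutoffs must be positive")


@dataclass(frozen=True)
class MatchResult:
    """Per-transcript co-expression statistics and the pass/fail verdict."""

    transcript_id: str
    r: float
    fold: float
    background: float
    p: float
    passed: bool
    failed_criteria: tuple[str, ...]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be one-dimensional and equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least three points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.clip((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)), -1.0, 1.0))


def fold_and_background(v: Sequence[float], floor: float = 1.0) -> tuple[float, float]:
    """(fold, background) of an expression vector.

    background = max(v); fold = max(v) / max(min(v), floor).  An all-zero
    vector has no meaningful fold and raises (callers report a non-match).
    """
    v = np.asarray(v, dtype=float)
    if (v < 0).any():
        raise ValueError("abundances must be non-negative")
    background = float(v.max())
    if background == 0:
        raise ValueError("fold change undefined for an all-zero vector")
    fold = background / max(float(v.min()), floor)
    return fold, background


def correlation_pvalue(r: float, n_tissues: int) -> float:
    """Two-sided p for a Pearson r on n points (t-test, n-2 df)."""
    if n_tissues < 3:
        raise ValueError("p-value needs at least three tissues")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n_tissues - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n_tissues - 2))


def model_match(
    v: Sequence[float],
    bait: BaitModel,
    criteria: MatchCriteria = MatchCriteria(),
    transcript_id: str = "",
) -> MatchResult:
    """Apply the four-criterion decision to one expression vector.

    ``v`` must already be in the bait's tissue order.  Degenerate vectors
    (constant, or all zero) are reported as non-matches rather than errors.
    All four statistics are reported whether or not the transcript passes.
    """
    v = np.asarray(v, dtype=float)
    model = bait.values
    if v.shape != model.shape:
        raise ValueError("expression vector and bait model differ in length")
    failed: list[str] = []

    try:
        fold, background = fold_and_background(v, floor=criteria.background_cutoff)
    except ValueError:
        return MatchResult(transcript_id, math.nan, math.nan, float(np.max(v)), math.nan,
                           False, ("degenerate_vector",))

    if criteria.log_transform:
        x, y = np.log1p(v), np.log1p(model)
    else:
        x, y = v, model
    try:
        r = pearson_r(x, y)
    except ConstantVectorError:
        return MatchResult(transcript_id, math.nan, fold, background, math.nan,
                           False, ("undefined_correlation",))

    p = correlation_pvalue(r, len(v))
    if r < criteria.corr_cutoff:
        failed.append("correlation")
    if background < criteria.background_cutoff:
        failed.append("background")
    if fold < criteria.fold_cutoff:
        failed.append("fold")
    if criteria.use_p and p > criteria.p_cutoff:
        failed.append("p_value")
    return MatchResult(transcript_id, r, fold, background, p, not failed, tuple(failed))


def screen_matrix(
    matrix: ExpressionMatrix,
    bait: BaitModel,
    criteria: MatchCriteria = MatchCriteria(),
    return_all: bool = False,
) -> list[MatchResult]:
    """Match every transcript of an assembly against the bait model.

    The bait's own transcript (``bait.bait_transcript_id``) is excluded
    from the passing set; its self-match is trivially perfect.  Returns the
    passing subset sorted by transcript id, or every result (same order)
    when ``return_all`` is set.
    """
    missing = set(bait.tissues) - set(matrix.tissues)
    if missing:
        raise ValueError(f"matrix lacks bait tissues {sorted(missing)}")
    results: list[MatchResult] = []
    for tid in sorted(matrix.transcripts):
        if tid == bait.bait_transcript_id:
            continue
        v = matrix.vector(tid, tissues=bait.tissues)
        results.append(model_match(v, bait, criteria, transcript_id=tid))
    if return_all:
        return results
    return [res for res in results if res.passed]
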