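"""Allele-specific selection of candidate neoepitopes from predicted affinities.

Human rule set (per mutant/wild-type affinity pair on one allele):

* The mutation sits at an *anchor* position (1, 2 or the C-terminus) or at a
  *TCR-facing* interior position.
* Differential rule: mutant predicted affinity strictly below the allele
  threshold (1000 nM for HLA-A*02:01, 1500 nM for HLA-A*03:01, 2500 nM for
  HLA-A*24:02) while the wild-type counterpart is strictly above its floor —
  the mutation itself creates the binder, so even an anchor substitution is
  tumor-discriminating.
* Similar rule: when mutant and wild-type both bind below the threshold with
  similar affinities (ratio <= ``similar_affinity_fold``), the candidate is
  kept only if the mutation is TCR-facing, where the substituted side chain
  is what the T-cell receptor sees.

Mouse rule set: a candidate is selected when its best percentile rank over
the H2-Db / H2-Kb alleles is within the 1% cut-off (inclusive).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .config import PipelineConfig
from .epitopes import EpitopeCandidate
from .errors import ConfigurationError, ConsistencyError, FormatError

__all__ = [
    "AffinityPrediction",
    "MutationPosition",
    "RulePath",
    "SelectionDecision",
    "classify_mutation_position",
    "select_human_candidates",
    "select_mouse_candidates",
    "mock_affinity_predictor",
    "MOUSE_ALLELES",
]

MOUSE_ALLELES = ("H2-Db", "H2-Kb")

_MOCK_AFF_MIN = 1.0
_MOCK_AFF_MAX = 50000.0


@dataclass(frozen=True)
class AffinityPrediction:
    """Predicted binding of one peptide-allele pair (nM and percentile rank)."""

    peptide: str
    allele: str
    affinity_nm: float
    rank_pct: float

    def __post_init__(self) -> None:
        if not self.affinity_nm > 0:
            raise FormatError(
                f"{self.peptide}/{self.allele}: affinity_nm must be > 0, "
                f"got {self.affinity_nm}"
            )
        if not 0.0 <= self.rank_pct <= 100.0:
            raise FormatError(
                f"{self.peptide}/{self.allele}: rank_pct must be in [0,100], "
                f"got {self.rank_pct}"
            )


class MutationPosition(str, Enum):
    ANCHOR = "anchor"
    TCR_FACING = "tcr_facing"


class RulePath(str, Enum):
    """Which selection branch fired (or why the candidate was rejected)."""

    ANCHOR_DIFFERENTIAL = "anchor_differential"  # mutant binds, WT does not
    NONANCHOR_SIMILAR = "nonanchor_similar"  # both bind similarly, TCR-facing mutation
    MOUSE_RANK = "mouse_rank"
    REJECTED_AFFINITY = "rejected_affinity"  # mutant above threshold
    REJECTED_WT = "rejected_wt"  # WT requirement failed
    REJECTED_POSITION = "rejected_position"  # similar pair but anchor mutation


_SELECTED_PATHS = frozenset(
    {RulePath.ANCHOR_DIFFERENTIAL, RulePath.NONANCHOR_SIMILAR, RulePath.MOUSE_RANK}
)


@dataclass(frozen=True)
class SelectionDecision:
    candidate: EpitopeCandidate
    selected: bool
    rule_path: RulePath
    mutant_nm: float | None = None
    wt_nm: float | None = None
    qualifying_allele: str | None = None

    def __post_init__(self) -> None:
        if self.selected != (self.rule_path in _SELECTED_PATHS):
            raise ConsistencyError(
                f"selected={self.selected} inconsistent with rule_path={self.rule_path}"
            )


def classify_mutation_position(candidate: EpitopeCandidate) -> MutationPosition:
    """Anchor positions are 1, 2 and the C-terminus; the rest face the TCR."""
    if candidate.mut_offset in (1, 2, candidate.length):
        return MutationPosition.ANCHOR
    return MutationPosition.TCR_FACING


def _lookup(
    affinities: Mapping[tuple[str, str], AffinityPrediction], peptide: str, allele: str
) -> AffinityPrediction:
    try:
        return affinities[(peptide, allele)]
    except KeyError:
        raise ConsistencyError(
            f"no affinity prediction for peptide {peptide!r} on allele {allele!r}"
        ) from None


def select_human_candidates(
    candidates: Sequence[EpitopeCandidate],
    affinities: Mapping[tuple[str, str], AffinityPrediction],
    cfg: PipelineConfig,
) -> list[SelectionDecision]:
    """Apply the anchor/TCR-facing differential-vs-similar rules per candidate.

    Every candidate must carry an allele and have predictions for both the
    mutant and the wild-type peptide on that allele.
    """
    decisions: list[SelectionDecision] = []
    for cand in candidates:
        if cand.allele is None:
            raise ConfigurationError(
                f"candidate {cand.mutant_peptide} has no allele assigned"
            )
        thr = cfg.mutant_threshold(cand.allele)
        wt_floor = cfg.wt_floor(cand.allele)
        mut_nm = _lookup(affinities, cand.mutant_peptide, cand.allele).affinity_nm
        wt_nm = _lookup(affinities, cand.wt_peptide, cand.allele).affinity_nm
        position = classify_mutation_position(cand)

        if not mut_nm < thr:
            path = RulePath.REJECTED_AFFINITY
        elif wt_nm > wt_floor:
            path = RulePath.ANCHOR_DIFFERENTIAL
        else:
            similar = (
                wt_nm < thr
                and max(mut_nm, wt_nm) / min(mut_nm, wt_nm) <= cfg.similar_affinity_fold
            )
            if position is MutationPosition.TCR_FACING and similar:
                path = RulePath.NONANCHOR_SIMILAR
            elif similar:
                path = RulePath.REJECTED_POSITION
            else:
                path = RulePath.REJECTED_WT
        decisions.append(
            SelectionDecision(
                candidate=cand,
                selected=path in _SELECTED_PATHS,
                rule_path=path,
                mutant_nm=mut_nm,
                wt_nm=wt_nm,
                qualifying_allele=cand.allele if path in _SELECTED_PATHS else None,
            )
        )
    return decisions


def select_mouse_candidates(
    candidates: Sequence[EpitopeCandidate],
    affinities: Mapping[tuple[str, str], AffinityPrediction],
    cfg: PipelineConfig,
    alleles: Iterable[str] = MOUSE_ALLELES,
) -> list[SelectionDecision]:
    """Keep candidates whose best rank over the alleles is <= the 1% cut-off.

    The boundary is inclusive ("within the 1% percentile rank"); the decision
    records the qualifying allele (the one with the best rank).
    """
    alleles = tuple(alleles)
    if not alleles:
        raise ConfigurationError("at least one mouse allele is required")
    decisions: list[SelectionDecision] = []
    for cand in candidates:
        preds = [
            affinities[(cand.mutant_peptide, a)]
            for a in alleles
            if (cand.mutant_peptide, a) in affinities
        ]
        if not preds:
            raise ConsistencyError(
                f"no prediction on any of {alleles} for peptide {cand.mutant_peptide!r}"
            )
        best = min(preds, key=lambda p: p.rank_pct)
        selected = best.rank_pct <= cfg.mouse_rank_max
        decisions.append(
            SelectionDecision(
                candidate=cand.with_allele(best.allele),
                selected=selected,
                rule_path=RulePath.MOUSE_RANK if selected else RulePath.REJECTED_AFFINITY,
                mutant_nm=best.affinity_nm,
                qualifying_allele=best.allele if selected else None,
            )
        )
    return decisions


def mock_affinity_predictor(peptide: str, allele: str, seed: int = 0) -> AffinityPrediction:
    """Deterministic stand-in for an external peptide-MHC affinity predictor.

    Hashes (peptide, allele, seed) to a log-uniform affinity in
    [1, 50000] nM; the percentile rank is a fixed strictly monotone transform
    of the affinity, so rank ordering always matches affinity ordering.
    Intended for offline pipeline runs and tests, not for biology.
    """
    if not 8 <= len(peptide) <= 11:
        raise FormatError(f"peptide length must be 8-11, got {len(peptide)} ({peptide!r})")
    digest = hashlib.sha256(f"{peptide}|{allele}|{seed}".encode()).digest()
    u = int.from_bytes(digest[:8], "big") / 2**64  # uniform in [0, 1)
    log_span = math.log(_MOCK_AFF_MAX / _MOCK_AFF_MIN)
    affinity_nm = _MOCK_AFF_MIN * math.exp(u * log_span)
    rank_pct = 100.0 * math.log(affinity_nm / _MOCK_AFF_MIN) / log_span
    return AffinityPrediction(peptide, allele, affinity_nm, rank_pct)
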