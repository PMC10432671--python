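"""Matching MS-eluted MHC ligand lists against candidate neoantigens.

Mass-spectrometry ligandomes are exact peptide-string sets; a candidate is
"displayed" when its mutant peptide occurs verbatim in the eluted list.
Because MS cannot distinguish leucine from isoleucine, an optional I/L-
equivalent mode collapses the two before comparison; it is off by default
so the strict (database-identity) semantics govern.  Wild-type-only hits —
the WT counterpart eluted but the mutant not — are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .epitopes import EpitopeCandidate
from .errors import FormatError

__all__ = ["LigandomeList", "MatchReport", "match_candidates"]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class LigandomeList:
    """Set of MS-eluted peptides with their sample and allele context."""

    peptides: frozenset[str]
    sample_id: str = ""
    alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptides", frozenset(self.peptides))
        for p in self.peptides:
            if not p or not set(p) <= _AA:
                raise FormatError(f"invalid ligandome peptide {p!r}")


@dataclass(frozen=True)
class MatchReport:
    """Candidates whose mutant (or only wild-type) peptide was eluted."""

    mutant_hits: tuple[EpitopeCandidate, ...]
    wt_only_hits: tuple[EpitopeCandidate, ...]
    il_equivalent: bool

    @property
    def mutant_peptides(self) -> set[str]:
        return {c.mutant_peptide for c in self.mutant_hits}


def _canon(peptide: str, il_equivalent: bool) -> str:
    return peptide.replace("I", "L") if il_equivalent else peptide


def match_candidates(
    ligandome: LigandomeList | Iterable[str],
    candidates: Sequence[EpitopeCandidate],
    il_equivalent: bool = False,
) -> MatchReport:
    """Exact-string overlap between the ligandome and the candidate list.

    Under ``il_equivalent`` the comparison treats I and L as identical, so
    the resulting overlap is a superset of the exact overlap.
    """
    peptides = ligandome.peptides if isinstance(ligandome, LigandomeList) else set(ligandome)
    eluted = {_canon(p, il_equivalent) for p in peptides}
    mutant_hits = tuple(
        c for c in candidates if _canon(c.mutant_peptide, il_equivalent) in eluted
    )
    mutant_set = {id(c) for c in mutant_hits}
    wt_only = tuple(
        c
        for c in candidates
        if id(c) not in mutant_set and _canon(c.wt_peptide, il_equivalent) in eluted
    )
    return MatchReport(mutant_hits, wt_only, il_equivalent)
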