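"""31-mer long-peptide (LP) design for vaccine formulation.

Each LP carries one H2-Db and one H2-Kb minimal epitope derived from the
same somatic mutation.  The LP is the native 31-residue window of the
mutated protein that covers both epitopes and the mutated residue, centred
on the mutation as nearly as the protein termini and epitope span allow
(ties broken toward the N-terminus).  LPs are always exact substrings of
the mutated protein — no linkers or synthetic junctions — so antigen
processing sees natural flanking sequence.  Epitope pairs whose union
cannot fit in 31 native residues are reported as non-coverable rather than
concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import PipelineConfig
from .epitopes import EpitopeCandidate, ProteinContext
from .errors import ConsistencyError, NotCoverableError

__all__ = ["LongPeptide", "design_31mer"]


@dataclass(frozen=True)
class LongPeptide:
    """A designed LP with 1-based offsets of its two epitopes within it."""

    sequence: str
    db_epitope: EpitopeCandidate
    kb_epitope: EpitopeCandidate
    db_offset: int
    kb_offset: int
    mut_offset: int
    source_variant: str

    def __post_init__(self) -> None:
        for name, epi, off in (
            ("db", self.db_epitope, self.db_offset),
            ("kb", self.kb_epitope, self.kb_offset),
        ):
            found = self.sequence[off - 1 : off - 1 + epi.length]
            if found != epi.mutant_peptide:
                raise ConsistencyError(
                    f"{name} epitope {epi.mutant_peptide} not at offset {off} "
                    f"of LP {self.sequence}"
                )


def _epitope_span(epi: EpitopeCandidate, ctx: ProteinContext) -> tuple[int, int]:
    """1-based [start, end] of the epitope in the mutated protein.

    Located via the candidate's own mutation offset (start = aa_pos -
    mut_offset + 1) and verified against the sequence.
    """
    start = ctx.aa_pos - epi.mut_offset + 1
    end = start + epi.length - 1
    if start < 1 or end > len(ctx.mut_sequence):
        raise ConsistencyError(
            f"epitope {epi.mutant_peptide} falls outside protein {ctx.protein_id}"
        )
    if ctx.mut_sequence[start - 1 : end] != epi.mutant_peptide:
        raise ConsistencyError(
            f"epitope {epi.mutant_peptide} is not a substring of the mutated "
            f"protein {ctx.protein_id} at its stated position"
        )
    return start, end


def design_31mer(
    db: EpitopeCandidate,
    kb: EpitopeCandidate,
    ctx: ProteinContext,
    cfg: PipelineConfig | None = None,
) -> LongPeptide:
    """Select the LP window of the mutated protein covering both epitopes.

    Raises :class:`NotCoverableError` when the union of the two epitope
    spans exceeds the LP length or the protein is too short, and
    :class:`ConsistencyError` when the epitopes do not derive from the same
    variant or are not substrings of the mutated protein.
    """
    cfg = cfg or PipelineConfig()
    lp_len = cfg.lp_len
    if db.source_variant != kb.source_variant:
        raise ConsistencyError(
            f"epitopes derive from different variants "
            f"({db.source_variant!r} vs {kb.source_variant!r})"
        )
    db_start, db_end = _epitope_span(db, ctx)
    kb_start, kb_end = _epitope_span(kb, ctx)
    union_start = min(db_start, kb_start)
    union_end = max(db_end, kb_end)
    if union_end - union_start + 1 > lp_len:
        raise NotCoverableError(
            f"epitope union spans {union_end - union_start + 1} residues; "
            f"no {lp_len}-residue native window can cover both"
        )
    if len(ctx.mut_sequence) < lp_len:
        raise NotCoverableError(
            f"protein {ctx.protein_id} is shorter ({len(ctx.mut_sequence)}) "
            f"than the LP length {lp_len}"
        )
    # feasible window starts: cover the union and stay inside the protein
    lo = max(1, union_end - lp_len + 1)
    hi = min(union_start, len(ctx.mut_sequence) - lp_len + 1)
    if lo > hi:  # defensive; cannot occur given the checks above
        raise NotCoverableError("no feasible LP window")
    # centre the mutation: ideal start places it at offset (lp_len + 1) // 2
    ideal = ctx.aa_pos - (lp_len + 1) // 2 + 1
    start = min(max(ideal, lo), hi)
    seq = ctx.mut_sequence[start - 1 : start - 1 + lp_len]
    return LongPeptide(
        sequence=seq,
        db_epitope=db,
        kb_epitope=kb,
        db_offset=db_start - start + 1,
        kb_offset=kb_start - start + 1,
        mut_offset=ctx.aa_pos - start + 1,
        source_variant=db.source_variant,
    )
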