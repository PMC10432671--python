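"""Mutant epitope enumeration from filtered missense variants.

Each missense variant is applied to its protein, a sequence context of the
mutation (by default 10 residues of native flank on each side, a 21-mer for
interior mutations) is extracted, and every 8/9/10-mer window of the mutated
sequence that contains the substituted residue is emitted, paired with its
wild-type counterpart window.  Windows are truncated, never padded, at
protein termini, so a mutation ``p`` residues from a terminus yields fewer
windows; an interior mutation yields exactly L windows per length L.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from .errors import FormatError

__all__ = [
    "ProteinContext",
    "EpitopeCandidate",
    "apply_mutation",
    "build_context_21mer",
    "enumerate_mutant_windows",
    "window_count",
]

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinContext:
    """A protein with one applied missense substitution (1-based ``aa_pos``)."""

    protein_id: str
    wt_sequence: str
    mut_sequence: str
    aa_pos: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if not 1 <= self.aa_pos <= len(self.wt_sequence):
            raise FormatError(
                f"{self.protein_id}: aa_pos {self.aa_pos} outside 1..{len(self.wt_sequence)}"
            )
        if self.wt_sequence[self.aa_pos - 1] != self.ref_aa:
            raise FormatError(
                f"{self.protein_id}: expected {self.ref_aa} at position {self.aa_pos}, "
                f"found {self.wt_sequence[self.aa_pos - 1]}"
            )
        if self.mut_sequence[self.aa_pos - 1] != self.alt_aa:
            raise FormatError(f"{self.protein_id}: mut_sequence lacks alt_aa at aa_pos")


@dataclass(frozen=True)
class EpitopeCandidate:
    """A mutant minimal epitope paired with its wild-type counterpart.

    ``mut_offset`` is the 1-based position of the substituted residue within
    the peptide; mutant and WT differ at exactly that position.
    """

    mutant_peptide: str
    wt_peptide: str
    mut_offset: int
    source_variant: str
    allele: str | None = None

    def __post_init__(self) -> None:
        if len(self.mutant_peptide) != len(self.wt_peptide):
            raise FormatError("mutant and wild-type peptides differ in length")
        if not 1 <= self.mut_offset <= len(self.mutant_peptide):
            raise FormatError(
                f"mut_offset {self.mut_offset} outside 1..{len(self.mutant_peptide)}"
            )
        diffs = [
            i + 1
            for i, (a, b) in enumerate(zip(self.mutant_peptide, self.wt_peptide))
            if a != b
        ]
        if diffs != [self.mut_offset]:
            raise FormatError(
                f"peptide pair {self.mutant_peptide}/{self.wt_peptide} must differ "
                f"exactly at mut_offset {self.mut_offset}, differs at {diffs}"
            )

    @property
    def length(self) -> int:
        return len(self.mutant_peptide)

    def with_allele(self, allele: str) -> "EpitopeCandidate":
        return replace(self, allele=allele)


def apply_mutation(
    sequence: str, aa_pos: int, ref_aa: str, alt_aa: str, protein_id: str = ""
) -> ProteinContext:
    """Substitute ``alt_aa`` for ``ref_aa`` at 1-based ``aa_pos``.

    Raises :class:`FormatError` naming the position and the residue actually
    observed when the reference does not match.
    """
    sequence = sequence.upper()
    if not 1 <= aa_pos <= len(sequence):
        raise FormatError(f"{protein_id}: aa_pos {aa_pos} outside 1..{len(sequence)}")
    observed = sequence[aa_pos - 1]
    if observed != ref_aa:
        raise FormatError(
            f"{protein_id}: reference mismatch at position {aa_pos}: "
            f"expected {ref_aa}, observed {observed}"
        )
    mut = sequence[: aa_pos - 1] + alt_aa + sequence[aa_pos:]
    return ProteinContext(protein_id, sequence, mut, aa_pos, ref_aa, alt_aa)


def build_context_21mer(ctx: ProteinContext, flank_len: int = 10) -> tuple[str, int]:
    """Mutation-centred context: up to ``flank_len`` native residues per side.

    Returns the (mutated) context peptide and the 1-based offset of the
    mutant residue within it.  Contexts are truncated at protein termini,
    never padded: an interior mutation gives a ``2*flank_len + 1``-mer with
    the mutation at offset ``flank_len + 1``.
    """
    start = max(1, ctx.aa_pos - flank_len)
    end = min(len(ctx.mut_sequence), ctx.aa_pos + flank_len)
    return ctx.mut_sequence[start - 1 : end], ctx.aa_pos - start + 1


def window_count(aa_pos: int, protein_len: int, length: int) -> int:
    """Closed-form number of length-L windows containing ``aa_pos``."""
    lo = max(1, aa_pos - length + 1)
    hi = min(aa_pos, protein_len - length + 1)
    return max(0, hi - lo + 1)


def enumerate_mutant_windows(
    ctx: ProteinContext,
    lengths: Iterable[int] = (8, 9, 10),
    source_variant: str | None = None,
) -> list[EpitopeCandidate]:
    """All mutant windows of the requested lengths containing the mutation.

    Each mutant window is paired with the same-coordinate window of the
    wild-type sequence.  Duplicate (mutant peptide, length) pairs are
    collapsed to the first occurrence; windows containing ``X`` or other
    non-standard residues are excluded.
    """
    src = source_variant if source_variant is not None else ctx.protein_id
    out: list[EpitopeCandidate] = []
    seen: set[str] = set()
    for length in sorted(set(lengths)):
        lo = max(1, ctx.aa_pos - length + 1)
        hi = min(ctx.aa_pos, len(ctx.mut_sequence) - length + 1)
        for start in range(lo, hi + 1):
            mut_pep = ctx.mut_sequence[start - 1 : start - 1 + length]
            wt_pep = ctx.wt_sequence[start - 1 : start - 1 + length]
            if not set(mut_pep) <= _STANDARD_AA or not set(wt_pep) <= _STANDARD_AA:
                continue
            if mut_pep in seen:
                continue
            seen.add(mut_pep)
            out.append(
                EpitopeCandidate(
                    mutant_peptide=mut_pep,
                    wt_peptide=wt_pep,
                    mut_offset=ctx.aa_pos - start + 1,
                    source_variant=src,
                )
            )
    return out
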