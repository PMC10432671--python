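"""Somatic missense variants and the post-call filter that selects them.

The filter is a conjunction of six per-variant rules applied to annotated,
protein-level calls: read coverage in tumor and in normal (strict >10x by
default), variant allele fraction below 1% in normal and above 15% in tumor,
variant support on both DNA strands, and population minor-allele frequency
at most 1% (variants common in 1000 Genomes / ESP6500 are germline, not
somatic).  VAF is recomputed from read counts so the filter is
self-contained rather than trusting an upstream caller's field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .config import PipelineConfig
from .errors import FormatError, UndefinedVafError

__all__ = [
    "SomaticVariant",
    "FILTER_RULES",
    "FilterAudit",
    "tumor_vaf",
    "normal_vaf",
    "passes_rule",
    "apply_somatic_filters",
]

#: Rule names in evaluation order; the audit reports the first that fails.
FILTER_RULES: tuple[str, ...] = (
    "tumor_coverage",
    "normal_coverage",
    "normal_vaf",
    "tumor_vaf",
    "strand_support",
    "population_maf",
)

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SomaticVariant:
    """One tumor/normal missense call with read-level support.

    ``aa_pos`` is the 1-based residue index of the substitution in the protein
    named by ``protein_id``.  Only single-residue missense changes are valid
    (``ref_aa != alt_aa``, both single amino acids).
    """

    id: str
    gene: str
    protein_id: str
    aa_pos: int
    ref_aa: str
    alt_aa: str
    tumor_depth: int
    normal_depth: int
    tumor_alt_reads: int
    normal_alt_reads: int
    alt_fwd: int
    alt_rev: int
    pop_maf: float

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise FormatError(f"{self.id}: ref_aa equals alt_aa ({self.ref_aa}); not missense")
        for label, aa in (("ref_aa", self.ref_aa), ("alt_aa", self.alt_aa)):
            if len(aa) != 1 or aa not in _AA:
                raise FormatError(f"{self.id}: {label}={aa!r} is not a single amino acid")
        if self.aa_pos < 1:
            raise FormatError(f"{self.id}: aa_pos must be 1-based positive, got {self.aa_pos}")
        if self.tumor_alt_reads > self.tumor_depth:
            raise FormatError(f"{self.id}: tumor_alt_reads exceeds tumor_depth")
        if self.normal_alt_reads > self.normal_depth:
            raise FormatError(f"{self.id}: normal_alt_reads exceeds normal_depth")
        if self.alt_fwd + self.alt_rev != self.tumor_alt_reads:
            raise FormatError(
                f"{self.id}: alt_fwd + alt_rev ({self.alt_fwd}+{self.alt_rev}) "
                f"!= tumor_alt_reads ({self.tumor_alt_reads})"
            )
        if not 0.0 <= self.pop_maf <= 1.0:
            raise FormatError(f"{self.id}: pop_maf must be in [0,1], got {self.pop_maf}")
        for label, n in (
            ("tumor_depth", self.tumor_depth),
            ("normal_depth", self.normal_depth),
            ("tumor_alt_reads", self.tumor_alt_reads),
            ("normal_alt_reads", self.normal_alt_reads),
            ("alt_fwd", self.alt_fwd),
            ("alt_rev", self.alt_rev),
        ):
            if n < 0:
                raise FormatError(f"{self.id}: {label} must be non-negative, got {n}")


@dataclass(frozen=True)
class FilterAudit:
    """Per-variant filter outcome; ``failed_rule`` is None when retained."""

    variant_id: str
    retained: bool
    failed_rule: str | None


def tumor_vaf(v: SomaticVariant) -> float:
    """Tumor variant allele fraction: variant-supporting reads / total depth."""
    if v.tumor_depth == 0:
        raise UndefinedVafError(f"{v.id}: tumor depth is zero; VAF undefined")
    return v.tumor_alt_reads / v.tumor_depth


def normal_vaf(v: SomaticVariant) -> float:
    """Normal-tissue variant allele fraction."""
    if v.normal_depth == 0:
        raise UndefinedVafError(f"{v.id}: normal depth is zero; VAF undefined")
    return v.normal_alt_reads / v.normal_depth


def passes_rule(v: SomaticVariant, rule: str, cfg: PipelineConfig) -> bool:
    """Evaluate one named filter rule in isolation."""
    if rule == "tumor_coverage":
        return v.tumor_depth > cfg.coverage_min
    if rule == "normal_coverage":
        return v.normal_depth > cfg.coverage_min
    if rule == "normal_vaf":
        return normal_vaf(v) < cfg.normal_vaf_max
    if rule == "tumor_vaf":
        return tumor_vaf(v) > cfg.tumor_vaf_min
    if rule == "strand_support":
        return v.alt_fwd >= 1 and v.alt_rev >= 1
    if rule == "population_maf":
        return v.pop_maf <= cfg.pop_maf_max
    raise ValueError(f"unknown filter rule {rule!r}")


def apply_somatic_filters(
    variants: Sequence[SomaticVariant] | Iterable[SomaticVariant],
    cfg: PipelineConfig,
) -> tuple[list[SomaticVariant], list[FilterAudit]]:
    """Apply the six-rule somatic filter; preserve input order.

    Returns the retained variants and one audit record per input variant
    naming the first rule (in :data:`FILTER_RULES` order) that failed.
    """
    retained: list[SomaticVariant] = []
    audit: list[FilterAudit] = []
    for v in variants:
        failed = next((r for r in FILTER_RULES if not passes_rule(v, r, cfg)), None)
        if failed is None:
            retained.append(v)
        audit.append(FilterAudit(v.id, failed is None, failed))
    return retained, audit
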