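"""Pipeline configuration: every numeric threshold used by any stage.

All thresholds live here so that no selection rule, filter or assay cut-off is
hard-coded.  Defaults reflect the study conditions the pipeline was designed
for: strict >10x coverage in tumor and normal, normal VAF < 1%, tumor VAF >
15%, variant support on both strands, population MAF <= 1%; allele-specific
mutant affinity ceilings (HLA-A*02:01 1000 nM, HLA-A*03:01 1500 nM,
HLA-A*24:02 2500 nM); mouse percentile-rank cut-off of 1%; T-cell responder
fold of 2; stabilization assays titrated from 100 uM in eight serial
dilutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig", "DEFAULT_ALLELE_THRESHOLDS"]

#: Mutant-peptide predicted-affinity ceilings (nM) per HLA allele.
DEFAULT_ALLELE_THRESHOLDS: dict[str, float] = {
    "HLA-A*02:01": 1000.0,
    "HLA-A*03:01": 1500.0,
    "HLA-A*24:02": 2500.0,
}


@dataclass
class PipelineConfig:
    """Flat bundle of all tunable thresholds.

    Units are stated per field; see docs/methods.md for rationale.
    """

    #: minimum read depth, strict greater-than, in both tumor and normal (reads)
    coverage_min: int = 10
    #: maximum variant allele fraction tolerated in normal tissue (fraction)
    normal_vaf_max: float = 0.01
    #: minimum variant allele fraction required in tumor (fraction, strict >)
    tumor_vaf_min: float = 0.15
    #: maximum population minor-allele frequency (fraction; > is removed)
    pop_maf_max: float = 0.01
    #: mutant predicted-affinity ceiling per allele (nM, strict <)
    allele_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ALLELE_THRESHOLDS)
    )
    #: wild-type affinity floor for the anchor differential rule on HLA-A*02:01 (nM, strict >)
    wt_affinity_min_a0201: float = 1000.0
    #: mouse percentile-rank cut-off (percent, inclusive <=)
    mouse_rank_max: float = 1.0
    #: stimulated/unstimulated IFN-gamma fold for a responder call (inclusive >=)
    responder_fold: float = 2.0
    #: unstimulated background floor used in the responder ratio (% IFN-g+ of CD8+)
    zero_floor_pct: float = 0.1
    #: top peptide concentration of the dilution series (uM)
    top_concentration: float = 100.0
    #: number of serial dilution steps
    n_dilutions: int = 8
    #: fold between successive dilutions
    dilution_factor: float = 3.0
    #: plateau-over-control fold required to call a stabilization binder
    binder_plateau_fold: float = 1.5
    #: residues flanking the mutation on each side of the sequence context
    flank_len: int = 10
    #: long-peptide length (residues)
    lp_len: int = 31
    #: max mutant/WT affinity ratio still counted as "similar" (fold)
    similar_affinity_fold: float = 3.0
    #: master seed for stochastic components
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            ("coverage_min", self.coverage_min),
            ("normal_vaf_max", self.normal_vaf_max),
            ("tumor_vaf_min", self.tumor_vaf_min),
            ("pop_maf_max", self.pop_maf_max),
            ("wt_affinity_min_a0201", self.wt_affinity_min_a0201),
            ("mouse_rank_max", self.mouse_rank_max),
            ("responder_fold", self.responder_fold),
            ("zero_floor_pct", self.zero_floor_pct),
            ("top_concentration", self.top_concentration),
            ("dilution_factor", self.dilution_factor),
            ("binder_plateau_fold", self.binder_plateau_fold),
            ("flank_len", self.flank_len),
            ("lp_len", self.lp_len),
            ("similar_affinity_fold", self.similar_affinity_fold),
        ]
        for name, value in positive:
            if not value > 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {value!r}")
        if self.n_dilutions < 2:
            raise ConfigurationError(f"n_dilutions must be >= 2, got {self.n_dilutions}")
        for allele, nm in self.allele_thresholds.items():
            if not isinstance(allele, str) or not allele.strip():
                raise ConfigurationError(f"invalid allele name {allele!r}")
            if not nm > 0:
                raise ConfigurationError(f"threshold for {allele} must be positive, got {nm!r}")

    # -- allele helpers ----------------------------------------------------

    def mutant_threshold(self, allele: str) -> float:
        try:
            return self.allele_thresholds[allele]
        except KeyError:
            raise ConfigurationError(
                f"no affinity threshold configured for allele {allele!r}"
            ) from None

    def wt_floor(self, allele: str) -> float:
        """WT affinity the anchor rule must exceed; A*02:01 has its own knob."""
        if allele == "HLA-A*02:01":
            return self.wt_affinity_min_a0201
        return self.mutant_threshold(allele)

    def concentrations_um(self) -> list[float]:
        """Descending dilution series from top_concentration."""
        return [
            self.top_concentration / self.dilution_factor**k for k in range(self.n_dilutions)
        ]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(data))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a key: value mapping")
        return cls.from_dict(data)
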