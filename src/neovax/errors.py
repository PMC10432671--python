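"""Exception hierarchy shared across the pipeline stages."""


class NeovaxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NeovaxError):
    """A threshold, allele or column required by the configuration is missing/invalid."""


class FormatError(NeovaxError):
    """An input file violates its declared format (bad row, bad value, duplicate id)."""


class ConsistencyError(NeovaxError):
    """Cross-table consistency violated, e.g. a peptide appears downstream but not upstream."""


class UndefinedVafError(NeovaxError):
    """VAF requested at a site with zero read depth."""


class InsufficientDataError(NeovaxError):
    """Too few data points to attempt a curve fit."""


class NotCoverableError(NeovaxError):
    """No native 31-residue window covers both epitopes of a long-peptide pair."""


class PipelineError(NeovaxError):
    """A pipeline stage failed or a required input is missing."""
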