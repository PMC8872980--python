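"""Exception hierarchy.

The CLI maps these onto exit codes: usage errors are handled by click,
data-validation problems exit 3, statistical degeneracy exits 4.
"""


class KpuumapError(Exception):
    """Base class for all package errors."""


class StructuralError(KpuumapError):
    """Dataset on disk is inconsistent with its manifest (shapes, missing arrays)."""


class DataValidationError(KpuumapError):
    """Values violate an invariant (negative intensities, bad units, bad masks)."""


class ConfigurationError(KpuumapError):
    """Inconsistent request: unknown region/channel, missing internal standard."""


class DegenerateInputError(KpuumapError):
    """Input is formally valid but leaves nothing to compute on (empty mask)."""


class InsufficientDataError(KpuumapError):
    """Too few observations for the requested statistic."""


class AlignmentError(KpuumapError):
    """Region labels do not match across conditions or datasets."""


class DegenerateStatisticsError(KpuumapError):
    """A statistical procedure cannot run (zero pooled variance etc.)."""
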