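"""Exception hierarchy.

Every error the library raises derives from :class:`CbescanError` so callers
(and the CLI) can distinguish domain failures from programming errors.
"""


class CbescanError(Exception):
    """Base class for all cbescan errors."""


class InvalidSubstitutionError(CbescanError):
    """Ref/alt pair is not a valid single-nucleotide substitution."""


class UndefinedVafError(CbescanError):
    """VAF requested at a site with zero total depth."""


class MissingAnnotationError(CbescanError):
    """A required record annotation (e.g. VAF) is unset."""


class UnknownContigError(CbescanError):
    """Contig name absent from the reference genome."""


class InconsistentWindowError(CbescanError):
    """Context windows of mixed lengths where uniform length is required."""


class OrientationError(CbescanError):
    """Window central base is not C where a C-centered window is required."""


class InsufficientReplicatesError(CbescanError):
    """Fewer than two samples in a group passed to a two-sample test."""


class EmptyClassError(CbescanError):
    """A class (positive or negative) is empty where both are required."""


class ConfigurationError(CbescanError):
    """Invalid or incomplete run configuration."""


class CoordinateError(CbescanError):
    """Genomic/transcript coordinate out of range."""


class FrameError(CbescanError):
    """CDS length is not a multiple of three."""


class ContractViolationError(CbescanError):
    """External scorer returned a value outside its contract."""


class StratumTooSmallError(CbescanError):
    """A benchmark stratum has too few members of a class."""


class DegenerateDistributionError(CbescanError):
    """Statistic undefined on a degenerate (zero-variance) input."""


class PlacementError(CbescanError):
    """Simulator could not place the requested features on the genome."""


class FormatError(CbescanError):
    """Malformed input file."""
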