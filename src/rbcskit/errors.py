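"""Exception hierarchy shared across rbcskit modules."""


class RbcskitError(Exception):
    """Base class for all rbcskit errors."""


class FormatError(RbcskitError):
    """A file does not conform to its declared format."""


class AlphabetError(RbcskitError):
    """A sequence contains characters outside its declared alphabet."""


class AnnotationError(RbcskitError):
    """A GFF3 record lacks required attributes."""


class CoordinateError(RbcskitError):
    """Genomic coordinates violate an invariant (e.g. start > end)."""


class ParseError(RbcskitError):
    """A structured text input (e.g. Newick) could not be parsed."""


class LayoutError(RbcskitError):
    """A simulated genome layout does not fit its chromosome."""


class PlanError(RbcskitError):
    """A motif-planting plan is internally inconsistent (e.g. overlaps)."""


class InputError(RbcskitError):
    """An argument violates a documented precondition."""


class UndefinedStatisticError(RbcskitError):
    """A statistic is undefined for the given data (zero variance, zero sum)."""


class SaturationError(RbcskitError):
    """Substitution proportions too large for the distance correction."""
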