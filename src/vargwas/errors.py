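"""Exception types shared across the package."""


class VargwasError(Exception):
    """Base class for all package errors."""


class PedigreeError(VargwasError):
    """Structural problem in a pedigree (cycles, unknown parents, duplicates)."""


class ValidationError(VargwasError):
    """Invalid input data (negative counts, malformed ids, misaligned tables)."""


class RankDeficiencyError(VargwasError):
    """Singular fixed-effect structure in a mixed model."""


class ConvergenceError(VargwasError):
    """An iterative estimation procedure failed to converge."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class DomainError(VargwasError):
    """Argument outside the mathematical domain of an operation."""


class ConfigurationError(VargwasError):
    """Inconsistent or incomplete configuration."""
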