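"""Exception hierarchy for the force-curve and map pipelines."""


class CellmechError(Exception):
    """Base class for all package errors."""


class DomainError(CellmechError, ValueError):
    """An argument is outside the physical domain of the operation."""


class ConfigurationError(CellmechError, ValueError):
    """Missing or inconsistent calibration / configuration values."""


class NoContact(CellmechError):
    """No tip-sample contact could be established on a curve."""


class MissingRetract(CellmechError):
    """Viscoelastic fitting requires a retract phase that is absent."""


class SolverError(CellmechError):
    """Numerical solver failed; carries diagnostics in args."""


class EmptyCell(CellmechError):
    """A cell mask selected no usable pixels."""


class EmptyMap(CellmechError):
    """A force-volume map yielded no usable pixels."""


class GenerationError(CellmechError):
    """A synthetic-data spec could not be realised (e.g. no contact)."""
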