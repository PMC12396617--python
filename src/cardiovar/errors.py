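"""Exception hierarchy for the cardiovar pipeline."""


class CardiovarError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CardiovarError):
    """A file could not be parsed (missing/garbled header, wrong columns)."""


class DataError(CardiovarError):
    """File parsed but contains invalid data (non-finite sample, bad ordering)."""


class ConfigurationError(CardiovarError):
    """Invalid analysis configuration (bands, rates, segment lengths)."""


class DetectionError(CardiovarError):
    """Beat detection failed (no pulsatility, no peaks above threshold)."""


class LengthError(CardiovarError):
    """A series is too short for the requested operation."""


class SimulationError(CardiovarError):
    """A simulation spec would produce a physically impossible series."""


class InsufficientDataError(CardiovarError):
    """Too few observations per group for a statistical comparison."""
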