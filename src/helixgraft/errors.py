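"""Exception hierarchy.

All package errors derive from :class:`HelixgraftError` so callers (and the
CLI) can distinguish data problems from programming errors.
"""


class HelixgraftError(Exception):
    """Base class for all helixgraft errors."""


class AlphabetError(HelixgraftError, ValueError):
    """A sequence contains a residue outside the 20 canonical amino acids."""


class CoordinateError(HelixgraftError, IndexError):
    """A residue index falls outside its coordinate system."""


class ParameterError(HelixgraftError, ValueError):
    """An operation parameter violates its precondition."""


class PredictionError(HelixgraftError, RuntimeError):
    """A secondary-structure predictor failed or returned malformed output."""


class FormatError(HelixgraftError, ValueError):
    """A file does not conform to its declared format."""


class AtomLookupError(HelixgraftError, KeyError):
    """A referenced atom is missing from a coordinate frame."""
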