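"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`BarcodeIDError`, so callers (and the CLI) can distinguish domain
errors from genuine bugs.
"""

from __future__ import annotations


class BarcodeIDError(Exception):
    """Base class for all errors raised by barcodeid."""


class ParseError(BarcodeIDError):
    """Malformed input file (FASTA/TSV); message names the offending entry."""


class ValidationError(BarcodeIDError):
    """A record or argument violates an invariant (alphabet, duplicate id...)."""


class FixtureIntegrityError(BarcodeIDError):
    """A bundled fixture does not have the expected shape or content."""


class ShapeError(BarcodeIDError):
    """Sequences are not positionally comparable (unequal aligned lengths)."""


class InsufficientOverlapError(BarcodeIDError):
    """The comparable overlap between two sequences is below the minimum.

    Carries the realized overlap length in :attr:`overlap_len`.
    """

    def __init__(self, overlap_len: int, min_overlap: int, detail: str = ""):
        self.overlap_len = overlap_len
        self.min_overlap = min_overlap
        msg = f"comparable overlap {overlap_len} < required {min_overlap}"
        if detail:
            msg = f"{msg} ({detail})"
        super().__init__(msg)


class SaturationError(BarcodeIDError):
    """Distance correction undefined: substitution saturation (log domain)."""


class LabellingError(BarcodeIDError):
    """A species label required by the operation is missing."""


class ConfigurationError(BarcodeIDError):
    """A search/evaluation configuration is unusable (e.g. empty library)."""


class GenerationError(BarcodeIDError):
    """The synthetic-data generator could not satisfy the requested geometry."""
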