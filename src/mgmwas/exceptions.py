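"""Exception hierarchy for the mgmwas pipeline."""


class MGMWASError(Exception):
    """Base class for all package errors."""


class FormatError(MGMWASError, ValueError):
    """A profile file violates its dialect (bad lineage, duplicate row, negative value)."""


class DataError(MGMWASError, ValueError):
    """Structurally valid input that cannot be analysed (zero-sum sample, empty group)."""


class ConfigurationError(MGMWASError, ValueError):
    """An inconsistent simulation or pipeline configuration."""


class CalibrationError(MGMWASError, ValueError):
    """A standard curve that cannot be fitted or inverted."""
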