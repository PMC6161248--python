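"""Exception hierarchy shared across the toolkit."""


class MetaboquantError(Exception):
    """Base class for all package errors."""


class PanelError(MetaboquantError):
    """Invalid panel or reference-database content."""


class FlatFileError(MetaboquantError):
    """Structural problem in an instrument flat-text export."""


class CalibrationError(MetaboquantError):
    """Calibration series or regression configuration is unusable."""


class QuantificationError(MetaboquantError):
    """Concentration-correction input outside its valid domain."""


class ValidationDesignError(MetaboquantError):
    """Spike/stability design arms missing or degenerate."""
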