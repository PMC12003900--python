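"""Exception hierarchy shared across the package."""


class RamanTDMError(Exception):
    """Base class for all package-specific errors."""


class SpectraFormatError(RamanTDMError):
    """A file does not conform to the expected column layout."""


class SpectraParseError(RamanTDMError):
    """A cell could not be parsed as the expected type."""


class SpectraIntegrityError(RamanTDMError):
    """Metadata constraints (e.g. unique sample/replicate pairs) violated."""


class AxisMismatchError(RamanTDMError):
    """Operation requires identical wavenumber axes but they differ."""


class CalibrationError(RamanTDMError):
    """Wavenumber calibration map is unusable (e.g. non-monotonic)."""


class RangeError(RamanTDMError):
    """Requested wavenumber range lies outside the available data."""


class NormalizationError(RamanTDMError):
    """Normalization is undefined for this spectrum (zero norm etc.)."""


class DegenerateFitError(RamanTDMError):
    """A least-squares decomposition collapsed (scale factor ~ 0)."""


class FactorSignError(RamanTDMError):
    """Predicted concentrations anti-correlated with set values."""


class SlopeSignError(RamanTDMError):
    """Calibration slope is non-positive; quantification impossible."""


class StageError(RamanTDMError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
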