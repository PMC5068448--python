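"""Exception hierarchy for gel scoring."""


class GelQuantError(Exception):
    """Base class for all gelquant errors."""


class CatalogError(GelQuantError):
    """Unknown ladder name or malformed ladder catalog entry."""


class CalibrationError(GelQuantError):
    """Migration-model calibration failed (non-monotone or insufficient pairs)."""


class GeometryError(GelQuantError):
    """Lane box or reference-point geometry is invalid."""


class ImageStateError(GelQuantError):
    """Operation applied to a gel image in the wrong processing state."""


class ParameterError(GelQuantError):
    """Invalid numeric parameter (radius, rows, hours, ...)."""


class DetectionError(GelQuantError):
    """Automatic lane detection found nothing usable."""


class LadderCallError(GelQuantError):
    """Too few ladder bands could be detected/assigned in a ladder lane."""


class ThresholdError(GelQuantError):
    """The requested threshold band is not assigned in a ladder lane."""


class BracketingError(GelQuantError):
    """Sample lanes are not bracketed by ladder lanes on both sides."""


class DesignError(GelQuantError):
    """Measurement table does not form a balanced crossed design."""


class SpecError(GelQuantError):
    """Synthetic gel specification is internally inconsistent."""
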