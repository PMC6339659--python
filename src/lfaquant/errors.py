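"""Exception hierarchy for the LFA readout pipeline.

Every failure mode a caller may want to branch on has its own class; all
inherit from :class:`LfaError` so batch drivers can catch one base type,
record the strip-level failure and continue.
"""


class LfaError(Exception):
    """Base class for all errors raised by lfaquant."""


class DecodeError(LfaError):
    """Image file could not be read or decoded."""


class InvalidInputError(LfaError):
    """Structurally invalid input (zero-area image, empty value list, ...)."""


class ConfigurationError(LfaError):
    """Unknown option value (channel policy, baseline method, ...)."""


class OrientationAmbiguousError(LfaError):
    """Automatic orientation cannot decide the flow direction."""


class InvalidGeometryError(LfaError):
    """Image geometry too degenerate to profile (e.g. ROI narrower than 3 px)."""


class ParameterError(LfaError):
    """Numeric parameter outside its valid range."""


class BandNotFoundError(LfaError):
    """Fewer than two qualifying bands found on the strip.

    ``missing`` names the line(s) that could not be located ('tl', 'cl'
    or 'tl+cl').
    """

    def __init__(self, message: str, missing: str = "tl+cl"):
        super().__init__(message)
        self.missing = missing


class AmbiguousBandsError(LfaError):
    """More than one candidate band pair ties in prominence."""


class DesignError(LfaError):
    """Calibration design insufficient (fewer than two distinct concentrations)."""


class InsufficientBlanksError(LfaError):
    """Fewer than two blank (0 nM) replicates available."""


class Method2UnavailableError(LfaError):
    """Second limits method needs a 1 nM replicate group that is absent."""


class NonInvertibleModelError(LfaError):
    """Calibration slope is zero; intensities cannot be mapped to concentration."""


class UndefinedCorrelationError(LfaError):
    """Pearson correlation undefined because one vector has zero variance."""


class GenerationError(LfaError):
    """Synthetic strip parameters would clip (amplitudes + background > 1)."""


class ScenarioError(LfaError):
    """Synthetic scenario parameters imply impossible strips (e.g. ratio <= 0)."""
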