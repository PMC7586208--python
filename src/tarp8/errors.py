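"""Exception hierarchy shared across the package."""


class Tarp8Error(Exception):
    """Base class for all package-specific errors."""


class ParseError(Tarp8Error):
    """A file record could not be parsed (message names the line)."""


class FormatError(Tarp8Error):
    """A file is structurally inconsistent (e.g. ragged frames, uneven sampling)."""


class ConfigError(Tarp8Error):
    """Required metadata / configuration is missing or invalid."""


class SelectionError(Tarp8Error):
    """An atom selection resolved to the wrong number of atoms."""


class ParameterError(Tarp8Error):
    """Generator or analysis parameters violate their invariants."""


class AnalysisError(Tarp8Error):
    """An analysis precondition on the data is not met."""


class DegeneratePeakError(AnalysisError):
    """No peak above the noise floor in the search window."""
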