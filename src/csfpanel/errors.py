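"""Exception hierarchy shared across the pipeline stages."""


class CsfPanelError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CsfPanelError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(CsfPanelError, ValueError):
    """A malformed input table or annotation file."""


class AnalysisError(CsfPanelError, ValueError):
    """Input data that a stage cannot analyse (degenerate geometry, missing groups, ...)."""
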