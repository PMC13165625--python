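"""Exception hierarchy shared across the pipeline.

Each error class maps to a distinct CLI exit code (see :mod:`stsradar.cli`):
configuration/parameter problems, malformed scene or trajectory
specifications, on-disk format problems, and recordings in which no
sit-to-stand cycles can be found.
"""


class StsRadarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StsRadarError, ValueError):
    """Radar configuration violates a physical or structural invariant."""


class ParameterError(StsRadarError, ValueError):
    """A processing parameter is out of its valid domain."""


class SpecError(StsRadarError, ValueError):
    """A trajectory or scene specification is internally inconsistent."""


class FormatError(StsRadarError, ValueError):
    """An on-disk container and its sidecar disagree, or a file is malformed."""


class NoCyclesError(StsRadarError, ValueError):
    """The range trajectory contains no detectable sit-to-stand cycles."""
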