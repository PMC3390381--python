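"""Exception hierarchy.

All package errors derive from :class:`NetdmsError` so callers (and the CLI)
can separate configuration problems from data problems.
"""


class NetdmsError(Exception):
    """Base class for all errors raised by netdms."""


class FormatError(NetdmsError, ValueError):
    """An input file does not conform to the expected tabular format."""


class DomainError(NetdmsError, ValueError):
    """A value is outside its mathematical domain (e.g. P value of 0)."""


class MembershipError(NetdmsError, KeyError):
    """A gene was referenced that is not present in the relevant container."""


class DegenerateDistributionError(NetdmsError, ValueError):
    """A distribution fit was requested on degenerate (constant) data."""


class ConfigError(NetdmsError, ValueError):
    """A run configuration failed validation."""
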