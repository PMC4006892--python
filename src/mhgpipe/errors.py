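"""Exception hierarchy for the pipeline.

All errors derive from :class:`ValueError` so callers that do not care about
the distinction can catch a single base class.
"""


class MhgpipeError(ValueError):
    """Base class for all pipeline errors."""


class ConfigError(MhgpipeError):
    """A configuration value is invalid; the message names the field."""


class InputError(MhgpipeError):
    """An input table or file violates the format contract."""


class DesignError(MhgpipeError):
    """The experimental design cannot support the requested statistic
    (e.g. a group with fewer than two replicates)."""
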