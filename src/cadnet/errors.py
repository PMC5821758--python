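"""Exception types shared across the pipeline."""


class CadnetError(Exception):
    """Base class for all cadnet errors."""


class ConfigurationError(CadnetError):
    """An input table, parameter or simulation setting is invalid.

    The message always names the offending field or file.
    """


class LookupError_(CadnetError):
    """A gene/node referenced by an operation is absent from its container."""
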