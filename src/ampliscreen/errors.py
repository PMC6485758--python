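"""Exception hierarchy shared across the package."""


class AmpliscreenError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AmpliscreenError, ValueError):
    """A line of an external file could not be parsed."""


class ValidationError(AmpliscreenError, ValueError):
    """Parsed content violates a documented invariant."""


class IntegrityError(AmpliscreenError, ValueError):
    """Internally inconsistent data, e.g. a pileup depth field that does
    not reconcile with the parsed per-read symbols."""


class ConfigError(AmpliscreenError, ValueError):
    """A configuration value outside its documented range."""
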