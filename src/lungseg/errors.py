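"""Exception hierarchy shared by all lungseg modules."""


class LungSegError(Exception):
    """Base class for all errors raised by lungseg."""


class ValidationError(LungSegError, ValueError):
    """An input object violates a documented contract (shape, range, type)."""


class ConfigurationError(LungSegError):
    """A required configuration value (e.g. an intensity-to-HU mapping) is missing."""


class SeedSelectionError(LungSegError):
    """No plausible lung seed could be found; the slice is likely lungless."""


class NumericalError(LungSegError):
    """A linear system was singular or a solve failed to converge."""
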