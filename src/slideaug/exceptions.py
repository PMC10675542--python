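"""Exception hierarchy shared across the package."""


class SlideAugError(Exception):
    """Base class for all slideaug errors."""


class FormatError(SlideAugError, ValueError):
    """A file or data structure does not match the expected layout."""


class ParameterError(SlideAugError, ValueError):
    """A transform or placement parameter is outside its legal domain."""


class ConfigurationError(SlideAugError, ValueError):
    """An augmentation configuration is inconsistent with the available data."""
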