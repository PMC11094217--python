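"""Exception hierarchy shared across the pipeline stages."""


class HossnfError(Exception):
    """Base class for every error raised by this package."""


class InputError(HossnfError):
    """A required input (file, directory, argument) is missing or unusable."""


class FormatError(HossnfError):
    """An input file exists but is not in a supported format."""


class ValidationError(HossnfError):
    """Structured data (manifest, config values) failed validation."""


class ConfigError(HossnfError):
    """A configuration value is out of its legal range."""


class ObjectiveError(HossnfError):
    """An objective function returned a non-finite value where one is required."""


class SegmentationFailure(HossnfError):
    """Segmentation produced no usable cell region."""


class SchemaError(HossnfError):
    """A serialized model file has an unsupported schema version."""
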