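"""Exception hierarchy shared across the package."""


class ThorsegError(Exception):
    """Base class for all package-specific errors."""


class VolumeFormatError(ThorsegError):
    """A file on disk is not a volume this package can read."""


class ValidationError(ThorsegError):
    """Inputs violate a documented contract (shape, spacing, labels...)."""


class ContractError(ValidationError):
    """An intensity-space or configuration precondition was violated."""


class EmptyMaskError(ThorsegError):
    """A surface/distance operation received an empty mask."""


class LocalizerError(ThorsegError):
    """The crop localizer has no centroid and no fallback to chain from."""


class ConfigError(ThorsegError):
    """A network or pipeline configuration is internally inconsistent."""


class GenerationError(ThorsegError):
    """Phantom geometry cannot be placed inside the body outline."""
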