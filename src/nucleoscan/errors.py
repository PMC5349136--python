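"""Exception hierarchy for nucleoscan."""


class NucleoscanError(Exception):
    """Base class for all nucleoscan errors."""


class ChannelError(NucleoscanError):
    """Requested color channel not available in the image."""


class ShapeMismatchError(NucleoscanError):
    """Planes of a z-stack (or a channel pair) do not share one shape."""


class ParameterError(NucleoscanError):
    """A detection / linking parameter is out of its documented range."""


class SceneSpecError(NucleoscanError):
    """A synthetic-scene specification is infeasible or invalid."""


class EmptySampleError(NucleoscanError):
    """No nuclei were detected where at least one is required."""


class ConfigError(NucleoscanError):
    """A batch run configuration is invalid."""
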