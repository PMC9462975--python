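"""Exception hierarchy.

Every contract violation raises a distinct, named error so callers can
react programmatically instead of parsing messages.
"""


class ScsesegError(Exception):
    """Base class for all package errors."""


class NotAVolumeError(ScsesegError):
    """A file or array that is not a single-channel 3D volume (2D, 4D, ...)."""


class NonFiniteVoxelError(ScsesegError):
    """A volume contains NaN or infinite intensities."""


class InvalidLabelError(ScsesegError):
    """A label grid contains values outside {0, ..., num_classes - 1} or is non-integer."""


class ShapeMismatchError(ScsesegError):
    """Two grids that must be aligned have different shapes (or class counts)."""


class InvalidInputShapeError(ScsesegError):
    """A volume whose spatial dimensions the network cannot process."""


class SelfPairError(ScsesegError):
    """A pairwise kernel was asked for a voxel paired with itself."""


class InstanceTooLargeError(ScsesegError):
    """An exact dense computation was requested on too many voxels."""


class EmptySegmentationError(ScsesegError):
    """A surface or distance was requested for an empty mask."""


class IdCollisionError(ScsesegError):
    """A pseudo-labeled pair would shadow a true-labeled pair with the same id."""


class ConfigError(ScsesegError):
    """Base class for configuration problems."""


class ConfigParseError(ConfigError):
    """The config file could not be parsed at all."""


class UnknownConfigKeyError(ConfigError):
    """The config file contains a key no module defines."""


class ConfigValueError(ConfigError):
    """A config value violates a module invariant; the message names the field."""
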