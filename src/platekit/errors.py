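"""Exception hierarchy.

All package errors derive from :class:`PlateKitError` so callers (and the
CLI) can distinguish data/validation problems from programming errors.
"""


class PlateKitError(Exception):
    """Base class for all errors raised by platekit."""


class GeometryError(PlateKitError):
    """A well, row, column or selection is invalid for a plate geometry."""


class WellNameError(PlateKitError, ValueError):
    """A well name could not be parsed or lies outside the plate."""

    def __init__(self, name: str, reason: str):
        self.name = name
        super().__init__(f"cannot parse well name {name!r}: {reason}")


class LayoutError(PlateKitError):
    """Invalid layout construction (duplicate area, unknown layer, ...)."""


class OverlapError(LayoutError):
    """Strict-mode violation: control and sample/range tags on one well."""

    def __init__(self, wells, message: str):
        self.wells = list(wells)
        super().__init__(message)


class ValidationError(PlateKitError):
    """A serialized document violates the layout schema.

    ``path`` is a JSON-path-like string locating the offending node.
    """

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


class MappingError(PlateKitError):
    """Column mapping is missing or inconsistent for the requested task."""


class PairingError(PlateKitError):
    """A manual pairing references an unknown plate key."""


class ConfigError(PlateKitError):
    """Invalid configuration value (normalization domain, fixture spec...)."""
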