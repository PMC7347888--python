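"""Exception hierarchy for the zone-detection pipeline.

Each error maps to a CLI exit code (see :mod:`padscan.cli`): configuration
and usage problems exit 2, an image in which no zones survive filtering or
matching exits 3, and I/O failures exit 4.
"""


class PadscanError(Exception):
    """Base class for all package errors."""


class ConfigError(PadscanError):
    """Invalid parameter value, unknown option, or malformed preset."""


class PresetParseError(ConfigError):
    """Preset document could not be parsed; message names the offending field."""


class PresetVersionError(ConfigError):
    """Preset schema version is not supported."""


class UsageError(PadscanError):
    """API called with inconsistent arguments (e.g. reference not in list)."""


class NoZonesError(PadscanError):
    """No contours survived masking/area filtering, or no similar contours.

    Carries the binarized mask (``mask`` attribute, may be None) so callers
    can save it for inspection.
    """

    def __init__(self, message, mask=None):
        super().__init__(message)
        self.mask = mask


class ZoneNotFoundError(PadscanError):
    """A seed point matched no contour (not inside any, none within 10 px)."""


class DegenerateRegionError(PadscanError):
    """An analysis region rasterized to zero pixels inside the image bounds."""


class SpecError(PadscanError):
    """Invalid synthetic device specification (e.g. overlapping zones)."""
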