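"""Named analysis presets: save, load, validate.

A preset bundles every tunable of the pipeline — masking thresholds, blur
and morphology, similarity tolerances, refinement geometry, and the color
spaces to report — so that replicate images are analyzed with identical
settings. Presets are stored as YAML with a ``schema_version`` field;
loading is strict: a missing block or out-of-range value raises an error
naming the offending field, never a silent default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .color import SPACES
from .contours import MatchParams
from .errors import PresetParseError, PresetVersionError, ConfigError
from .masking import MaskParams
from .zones import RegionGeometry

__all__ = ["Preset", "save_preset", "load_preset", "default_preset", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Preset:
    name: str
    mask: MaskParams = field(default_factory=MaskParams)
    match: MatchParams = field(default_factory=MatchParams)
    geometry: RegionGeometry = field(default_factory=RegionGeometry)
    spaces: tuple = SPACES

    def validate(self) -> None:
        if not isinstance(self.name, str) or not self.name:
            raise ConfigError("preset.name must be a non-empty string")
        self.mask.validate()
        self.match.validate()
        self.geometry.validate()
        if not self.spaces:
            raise ConfigError("preset.spaces must name at least one color space")
        for s in self.spaces:
            if s.upper() not in SPACES:
                raise ConfigError(f"preset.spaces contains unknown space {s!r}")


def default_preset(name: str = "default") -> Preset:
    """Settings suited to scans of dark-barrier devices with ~30 px zones.

    Thresholds 0.15/0.15 separate colored zones from near-black wax and
    gray paper; a 3 px blur smooths mask edges; the measurement circle
    (radius 24 px) sits inside a 30 px zone, clear of barrier edges and
    contrast rings.
    """
    return Preset(
        name=name,
        mask=MaskParams(v_min=0.15, s_min=0.15, blur_kernel=3),
        match=MatchParams(size_tolerance=0.15, shape_tolerance=0.5),
        geometry=RegionGeometry(shape="circle", radius=24.0),
        spaces=SPACES,
    )


def save_preset(preset: Preset, path) -> None:
    """Write a preset as YAML; round-trips losslessly through load."""
    preset.validate()
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": preset.name,
        "mask": asdict(preset.mask),
        "match": asdict(preset.match),
        "geometry": asdict(preset.geometry),
        "spaces": list(preset.spaces),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _take(doc: dict, block: str, cls, fields: dict):
    if block not in doc or doc[block] is None:
        raise PresetParseError(f"preset is missing the required '{block}' block")
    sub = doc[block]
    if not isinstance(sub, dict):
        raise PresetParseError(f"preset block '{block}' must be a mapping")
    unknown = set(sub) - set(fields)
    if unknown:
        raise PresetParseError(f"preset block '{block}' has unknown field(s): {sorted(unknown)}")
    kwargs = {}
    for name, caster in fields.items():
        if name in sub:
            try:
                kwargs[name] = caster(sub[name])
            except (TypeError, ValueError) as exc:
                raise PresetParseError(f"preset field '{block}.{name}' is malformed: {exc}")
    return cls(**kwargs)


def load_preset(path) -> Preset:
    """Parse and validate a preset file.

    Raises :class:`PresetParseError` naming the offending field on any
    structural problem, :class:`PresetVersionError` on an unsupported
    schema version, and :class:`ConfigError` on out-of-range values.
    """
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise PresetParseError(f"preset file is not valid YAML: {exc}")
    if not isinstance(doc, dict):
        raise PresetParseError("preset file does not contain a mapping")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise PresetVersionError(
            f"unsupported preset schema_version {version!r}; this build reads version {SCHEMA_VERSION}"
        )
    if "name" not in doc or not doc["name"]:
        raise PresetParseError("preset is missing the required 'name' field")

    mask = _take(doc, "mask", MaskParams, {
        "v_min": float, "s_min": float, "blur_kernel": int,
        "dilate_iters": int, "erode_iters": int,
    })
    match = _take(doc, "match", MatchParams, {
        "size_tolerance": float, "shape_tolerance": float,
    })
    geometry = _take(doc, "geometry", RegionGeometry, {
        "shape": str, "radius": float, "n_sides": int,
        "dx": float, "dy": float, "angle": float,
    })
    spaces = doc.get("spaces")
    if not isinstance(spaces, list) or not spaces:
        raise PresetParseError("preset field 'spaces' must be a non-empty list")
    preset = Preset(
        name=str(doc["name"]), mask=mask, match=match,
        geometry=geometry, spaces=tuple(str(s).upper() for s in spaces),
    )
    preset.validate()
    return preset
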