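"""Run configuration shared by the CLI commands."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields

from .colour import EQUAL_ENERGY_WHITE, WhitePoint
from .errors import ConfigurationError


@dataclass
class RunConfig:
    """Knobs of the pipeline, serializable to/from a JSON config file.

    white_point: reference-white tristimulus triple, or None for the
        equal-energy white of the conversion matrix.
    lab_low_branch: L* formula below the breakpoint ('linear' or 'cube_root').
    l_levels / ab_levels: histogram quantization of L* and a*/b*.
    variance_form: within-class spread form ('as_printed' or 'squared').
    target_classes: class count the merger is forced down to (None = dynamic).
    hd_usable_fraction: usable share of the half-dried class in [0, 1].
    weighting: error-matrix sample-unit weighting ('pixel' or 'unit').
    """

    white_point: tuple[float, float, float] | None = None
    lab_low_branch: str = "linear"
    l_levels: int = 101
    ab_levels: int = 221
    variance_form: str = "as_printed"
    target_classes: int | None = 4
    hd_usable_fraction: float = 0.5
    area_per_pixel: float = 1.0
    weighting: str = "pixel"
    seed: int = 0

    def resolve_white(self) -> WhitePoint:
        if self.white_point is None:
            return EQUAL_ENERGY_WHITE
        return WhitePoint(*self.white_point)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if data.get("white_point") is not None:
            data["white_point"] = tuple(data["white_point"])
        return cls(**data)
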