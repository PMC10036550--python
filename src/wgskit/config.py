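"""Numeric thresholds used when mapping measurements to suggested ratings.

The rubric anchors fix some boundaries outright (one / two shoe widths for
stance width and circumduction, 45 degrees for external rotation); those
defaults should not normally be changed. Where the scale is qualitative
("equal", "slight pauses") the defaults below are documented engineering
choices, exposed so a clinic can calibrate them: an angle is called "equal"
within 5 degrees, a stance-time ratio within 10 %, a pause is "slight"
above 0.1 s and "marked" above 0.3 s, and so on.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

from .errors import SchemaError

__all__ = ["ThresholdConfig", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class ThresholdConfig:
    # "equal" tolerances for side-to-side comparisons
    angle_equal_tol_deg: float = 5.0      # items 7, 8, 11
    time_ratio_equal: float = 0.9         # item 2: ratio >= this -> Equal
    time_ratio_brief: float = 0.5         # item 2: ratio < this -> Very Brief

    # item 6 guardedness (pause before toe off)
    pause_slight_s: float = 0.1
    pause_marked_s: float = 0.3
    pause_speed_fraction: float = 0.1     # hip speed below this x mean counts as paused

    # items 5 / 9 shoe-width anchors ("up to" is inclusive)
    shoe_width_normal: float = 1.0
    shoe_width_moderate: float = 2.0
    circumduction_none_sw: float = 0.1

    # item 7 hip extension
    hip_marked_flexion_deg: float = 10.0  # affected hip flexed beyond this at toe off -> Marked

    # item 8 external rotation
    external_rotation_marked_deg: float = 45.0

    # item 10 hip hiking (pelvic crest elevation at mid swing)
    hip_hiking_none_sw: float = 0.1
    hip_hiking_vault_sw: float = 0.5

    # item 11 knee flexion floors/ceilings
    knee_minimal_floor_deg: float = 5.0
    knee_maximal_ceiling_deg: float = 75.0
    knee_extension_floor_deg: float = 1.0

    # item 12 toe clearance
    toe_drag_floor_px: float = 1.0        # clearance at/below this counts as dragging
    toe_drag_majority: float = 0.5        # drag fraction above this -> Marked

    # item 4 trunk shift (fraction of the midline-to-affected-foot distance)
    trunk_full_shift_fraction: float = 0.9

    # item 13 pelvic rotation and item 14 initial contact
    pelvic_rotation_tol_deg: float = 5.0
    foot_contact_tol_deg: float = 5.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise SchemaError(f"threshold {f.name} must be finite, got {v!r}")
        if not self.time_ratio_brief < self.time_ratio_equal:
            raise SchemaError("time_ratio_brief must be below time_ratio_equal")
        if not self.shoe_width_normal < self.shoe_width_moderate:
            raise SchemaError("shoe_width_normal must be below shoe_width_moderate")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdConfig":
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as e:
            raise SchemaError(f"invalid threshold config JSON: {e}") from e
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown threshold names: {sorted(unknown)}")
        return cls(**data)


DEFAULT_CONFIG = ThresholdConfig()
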