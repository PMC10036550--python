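"""Frame geometry for the computerised gait scale.

The computerised scale works on freeze-frames of a walking child annotated
with named 2-D anatomical landmarks (trochanter, lateral femoral condyle,
fibula head, lateral malleolus, heel, toe, pelvic crest, trunk midline),
one set per body side. From these it reconstructs the quantities a rater
inspects: auxiliary-line joint angles (knee flexion as the angle between a
thigh line trochanter-condyle and a shank line fibula head-malleolus, hip
extension as the thigh inclination from vertical), durations of gait phases
from annotated event frames, and distances expressed in the scale's own
unit, the shoe width.

Coordinate conventions (design choices, since video pixel geometry carries
no intrinsic frame): image origin top-left, y increases downward, units are
pixels. The progression direction is part of the calibration; in sagittal
views it is the (approximately horizontal) walking direction, in frontal
views it points towards the camera and is assigned the image direction
(0, -1), so a foot long-axis angle against it measures foot rotation out of
the plane of progression. Vertical measurements (clearance, pelvic
elevation) use the global image vertical. All angle computations are built
from vector differences, so translation of the coordinate frame cancels,
and angles are invariant under rotation and uniform scaling.

Suggested ratings are advisory: they carry the numeric evidence they were
derived from, and the stored rating is always the human rater's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, ThresholdConfig
from .errors import (
    GeometryError,
    MissingLandmarkError,
    SchemaError,
    TimelineError,
)

__all__ = [
    "SIDES",
    "EVENTS",
    "KNOWN_LANDMARKS",
    "LandmarkFrame",
    "LandmarkSeries",
    "CalibrationInfo",
    "GaitEventTimeline",
    "Annotation",
    "MeasurementSet",
    "KneeFlexionComparison",
    "Suggestion",
    "angle_between_lines",
    "angle_between_vectors",
    "knee_flexion",
    "hip_extension_angle",
    "compare_knee_flexion",
    "stance_time",
    "stance_width",
    "circumduction",
    "external_rotation",
    "measure_trial",
    "suggest_ratings",
]

SIDES = ("affected", "unaffected")
#: ``mid`` holds midline landmarks (trunk midline) that belong to no side.
ALL_SIDES = SIDES + ("mid",)
EVENTS = ("heel_strike", "toe_off", "mid_swing", "terminal_swing")
KNOWN_LANDMARKS = frozenset(
    {
        "trochanter",
        "lateral_femoral_condyle",
        "fibula_head",
        "lateral_malleolus",
        "heel",
        "toe",
        "pelvis_crest",
        "trunk_midline",
    }
)

_UP = np.array([0.0, -1.0])  # image y grows downward


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class LandmarkFrame:
    """Named 2-D landmarks of one video frame, keyed by (name, side)."""

    frame_index: int
    points: dict[tuple[str, str], np.ndarray]

    def __post_init__(self):
        if self.frame_index < 0:
            raise SchemaError(f"frame_index must be >= 0, got {self.frame_index}")
        pts = {}
        for (name, side), xy in self.points.items():
            if side not in ALL_SIDES:
                raise SchemaError(f"unknown side {side!r} for landmark {name!r}")
            arr = np.asarray(xy, dtype=float)
            if arr.shape != (2,) or not np.all(np.isfinite(arr)):
                raise SchemaError(
                    f"landmark {name!r}/{side!r} in frame {self.frame_index} "
                    f"must be a finite 2-vector"
                )
            pts[(name, side)] = arr
        self.points = pts

    def has(self, name: str, side: str) -> bool:
        return (name, side) in self.points

    def get(self, name: str, side: str) -> np.ndarray:
        try:
            return self.points[(name, side)]
        except KeyError:
            raise MissingLandmarkError(name, side, self.frame_index) from None


@dataclass
class LandmarkSeries:
    """Time-ordered landmark frames with index-based lookup."""

    frames: list[LandmarkFrame]
    _by_index: dict[int, LandmarkFrame] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        self.frames = sorted(self.frames, key=lambda f: f.frame_index)
        by = {f.frame_index: f for f in self.frames}
        if len(by) != len(self.frames):
            raise SchemaError("duplicate frame_index in landmark series")
        self._by_index = by

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def frame(self, index: int) -> LandmarkFrame:
        try:
            return self._by_index[index]
        except KeyError:
            raise TimelineError(f"no landmark frame with index {index}") from None

    def has_frame(self, index: int) -> bool:
        return index in self._by_index

    def trajectory(
        self, name: str, side: str, frame_indices: Optional[Iterable[int]] = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(frame indices, Nx2 coordinates) where the landmark is present."""
        if frame_indices is None:
            frames = self.frames
        else:
            frames = [self._by_index[i] for i in frame_indices if i in self._by_index]
        idx, xy = [], []
        for f in frames:
            if f.has(name, side):
                idx.append(f.frame_index)
                xy.append(f.get(name, side))
        return np.asarray(idx, dtype=int), np.asarray(xy, dtype=float).reshape(-1, 2)


@dataclass
class CalibrationInfo:
    """Frame rate, shoe-width pixel scale, progression axis and camera view."""

    fps: float
    shoe_width_px: float
    progression_direction: np.ndarray
    view: str  # "sagittal" | "frontal"

    def __post_init__(self):
        if not self.fps > 0:
            raise SchemaError(f"fps must be > 0, got {self.fps}")
        if not self.shoe_width_px > 0:
            raise SchemaError(f"shoe_width_px must be > 0, got {self.shoe_width_px}")
        if self.view not in ("sagittal", "frontal"):
            raise SchemaError(f"view must be 'sagittal' or 'frontal', got {self.view!r}")
        d = np.asarray(self.progression_direction, dtype=float)
        n = np.linalg.norm(d)
        if d.shape != (2,) or not np.isfinite(n) or n == 0:
            raise SchemaError("progression_direction must be a non-zero 2-vector")
        self.progression_direction = d / n

    @property
    def lateral_axis(self) -> np.ndarray:
        f = self.progression_direction
        return np.array([-f[1], f[0]])


@dataclass
class GaitEventTimeline:
    """Annotated gait-event frame indices per side.

    Events are inputs, not detected: the rater marks heel strike, toe off,
    mid swing and terminal swing per cycle. Within a cycle the frame order
    heel_strike < toe_off < mid_swing < terminal_swing must hold.
    """

    events: dict[str, dict[str, tuple[int, ...]]]

    def __post_init__(self):
        clean: dict[str, dict[str, tuple[int, ...]]] = {}
        for side, ev in self.events.items():
            if side not in SIDES:
                raise TimelineError(f"unknown side {side!r} in timeline")
            clean[side] = {}
            for name, idxs in ev.items():
                if name not in EVENTS:
                    raise TimelineError(f"unknown gait event {name!r}")
                t = tuple(int(i) for i in idxs)
                if any(i < 0 for i in t):
                    raise TimelineError(f"negative frame index in {side}/{name}")
                if list(t) != sorted(t) or len(set(t)) != len(t):
                    raise TimelineError(f"{side}/{name} frames must be strictly increasing")
                clean[side][name] = t
            n = min((len(clean[side].get(e, ())) for e in EVENTS), default=0)
            for i in range(n):
                hs = clean[side]["heel_strike"][i]
                to = clean[side]["toe_off"][i]
                ms = clean[side]["mid_swing"][i]
                ts = clean[side]["terminal_swing"][i]
                if not hs < to < ms < ts:
                    raise TimelineError(
                        f"{side} cycle {i}: require heel_strike < toe_off < "
                        f"mid_swing < terminal_swing, got {hs}, {to}, {ms}, {ts}"
                    )
        self.events = clean

    def frames_of(self, side: str, event: str) -> tuple[int, ...]:
        return self.events.get(side, {}).get(event, ())

    def cycles(self, side: str) -> list[dict[str, int]]:
        """Complete event quadruples for a side, paired by cycle order."""
        ev = self.events.get(side, {})
        n = min((len(ev.get(e, ())) for e in EVENTS), default=0)
        return [{e: ev[e][i] for e in EVENTS} for i in range(n)]

    def stance_intervals(self, side: str) -> list[tuple[int, int]]:
        """(heel_strike, toe_off) pairs: each heel strike with the next toe off."""
        hs = self.frames_of(side, "heel_strike")
        to = list(self.frames_of(side, "toe_off"))
        out = []
        for h in hs:
            nxt = [t for t in to if t > h]
            if nxt:
                out.append((h, nxt[0]))
        return out


@dataclass
class Annotation:
    """One annotated recording: landmarks, events and calibration."""

    series: LandmarkSeries
    timeline: GaitEventTimeline
    calibration: CalibrationInfo


# ---------------------------------------------------------------------------
# angle primitives
# ---------------------------------------------------------------------------


def angle_between_vectors(u: Sequence[float], v: Sequence[float]) -> float:
    """Angle between two directed vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not np.any(u) or not np.any(v):
        raise GeometryError("cannot measure an angle with a zero-length vector")
    # atan2 of (|cross|, dot) is well conditioned near 0 and 180 degrees
    cross = u[0] * v[1] - u[1] * v[0]
    return math.degrees(math.atan2(abs(cross), float(np.dot(u, v))))


def angle_between_lines(
    a1: Sequence[float],
    a2: Sequence[float],
    b1: Sequence[float],
    b2: Sequence[float],
    directed: bool = False,
) -> float:
    """Angle between line a1-a2 and line b1-b2 in degrees.

    Undirected lines (the default, as drawn on a freeze frame) give an
    angle in [0, 90]; with ``directed=True`` the vectors a1->a2 and b1->b2
    are compared and the angle lies in [0, 180].
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    if np.array_equal(a1, a2) or np.array_equal(b1, b2):
        raise GeometryError("coincident endpoints define no line")
    ang = angle_between_vectors(a2 - a1, b2 - b1)
    if not directed and ang > 90.0:
        ang = 180.0 - ang
    return ang


def knee_flexion(frame: LandmarkFrame, side: str) -> float:
    """Knee flexion in degrees from thigh and shank auxiliary lines.

    The thigh line runs trochanter -> lateral femoral condyle, the shank
    line fibula head -> lateral malleolus. Flexion is the directed angle
    between the two (equivalently 180 degrees minus the interior knee
    angle): 0 for a fully extended leg, 90 for a right-angle bend.
    """
    thigh = frame.get("lateral_femoral_condyle", side) - frame.get("trochanter", side)
    shank = frame.get("lateral_malleolus", side) - frame.get("fibula_head", side)
    return angle_between_vectors(thigh, shank)


def hip_extension_angle(frame: LandmarkFrame, side: str, cal: CalibrationInfo) -> float:
    """Signed hip angle at the thigh in degrees: extension positive.

    Measured as the thigh-line inclination from the image vertical,
    positive when the knee trails behind the hip relative to the
    progression direction (hip extension), negative for hip flexion.
    Assumes an approximately horizontal progression axis (sagittal view).
    """
    v = frame.get("lateral_femoral_condyle", side) - frame.get("trochanter", side)
    fwd = float(np.dot(v, cal.progression_direction))
    down = float(-np.dot(v, _UP))
    if fwd == 0 and down == 0:
        raise GeometryError("coincident trochanter and condyle")
    return -math.degrees(math.atan2(fwd, down))


# ---------------------------------------------------------------------------
# per-item measurements
# ---------------------------------------------------------------------------

_KNEE_CODE = {
    "equal": "1",
    "less": "2a",
    "more": "2b",
    "minimal": "3a",
    "maximal": "3b",
    "none": "4",
}


@dataclass(frozen=True)
class KneeFlexionComparison:
    """Outcome of the affected-vs-unaffected knee flexion comparison."""

    affected_peak_deg: float
    unaffected_peak_deg: float
    swing_peak_affected_deg: float
    category: str  # equal | less | more | minimal | maximal | none

    @property
    def code(self) -> str:
        return _KNEE_CODE[self.category]


def _peak_flexion(series: LandmarkSeries, side: str, lo: int, hi: int) -> Optional[float]:
    vals = []
    for f in series.frames:
        if lo <= f.frame_index <= hi:
            try:
                vals.append(knee_flexion(f, side))
            except (MissingLandmarkError, GeometryError):
                continue
    return max(vals) if vals else None


def compare_knee_flexion(
    series: LandmarkSeries,
    timeline: GaitEventTimeline,
    tolerance_deg: float = DEFAULT_CONFIG.angle_equal_tol_deg,
    *,
    minimal_floor_deg: float = DEFAULT_CONFIG.knee_minimal_floor_deg,
    maximal_ceiling_deg: float = DEFAULT_CONFIG.knee_maximal_ceiling_deg,
    extension_floor_deg: float = DEFAULT_CONFIG.knee_extension_floor_deg,
) -> KneeFlexionComparison:
    """Classify affected-side knee flexion from toe off to mid swing.

    Peak flexion of each side is taken over its toe_off..mid_swing window
    (all annotated cycles pooled). Classification order: the affected knee
    staying at/below the extension floor throughout swing means "none"
    (code 4); a window peak below the minimal-flexion floor is "minimal"
    (3a); above the maximal ceiling "maximal" (3b); otherwise the peak is
    compared with the unaffected side within ``tolerance_deg`` to give
    "equal" (1), "less" (2a) or "more" (2b).
    """
    peaks: dict[str, float] = {}
    for side in SIDES:
        cycles = timeline.cycles(side)
        windows = [(c["toe_off"], c["mid_swing"]) for c in cycles]
        vals = [
            p for lo, hi in windows if (p := _peak_flexion(series, side, lo, hi)) is not None
        ]
        if not vals:
            raise TimelineError(
                f"no measurable toe_off..mid_swing knee-flexion window for side {side!r}"
            )
        peaks[side] = max(vals)
    swing_vals = [
        p
        for c in timeline.cycles("affected")
        if (p := _peak_flexion(series, "affected", c["toe_off"], c["terminal_swing"]))
        is not None
    ]
    swing_peak = max(swing_vals) if swing_vals else peaks["affected"]

    aff, unaff = peaks["affected"], peaks["unaffected"]
    if swing_peak <= extension_floor_deg:
        cat = "none"
    elif aff < minimal_floor_deg:
        cat = "minimal"
    elif aff > maximal_ceiling_deg:
        cat = "maximal"
    elif abs(aff - unaff) <= tolerance_deg:
        cat = "equal"
    elif aff < unaff:
        cat = "less"
    else:
        cat = "more"
    return KneeFlexionComparison(aff, unaff, swing_peak, cat)


def stance_time(timeline: GaitEventTimeline, cal: CalibrationInfo, side: str) -> float:
    """Mean stance duration (heel strike to toe off) in seconds for a side."""
    intervals = timeline.stance_intervals(side)
    if not intervals:
        raise TimelineError(f"no complete heel_strike..toe_off interval for side {side!r}")
    return float(np.mean([(t - h) / cal.fps for h, t in intervals]))


def stance_width(frame: LandmarkFrame, cal: CalibrationInfo) -> float:
    """Lateral heel separation in shoe widths (frontal view only)."""
    if cal.view != "frontal":
        raise GeometryError(f"stance width requires a frontal view, got {cal.view!r}")
    sep = frame.get("heel", "affected") - frame.get("heel", "unaffected")
    return abs(float(np.dot(sep, cal.lateral_axis))) / cal.shoe_width_px


def circumduction(
    series: LandmarkSeries, timeline: GaitEventTimeline, cal: CalibrationInfo
) -> float:
    """Peak lateral swing deviation of the affected foot, in shoe widths.

    For each cycle, the affected heel's stance-phase lateral position
    defines the stance line; the maximum absolute lateral deviation from it
    during toe_off..terminal_swing is taken, and the worst cycle reported.
    """
    if cal.view != "frontal":
        raise GeometryError(f"circumduction requires a frontal view, got {cal.view!r}")
    lat = cal.lateral_axis
    best: Optional[float] = None
    for c in timeline.cycles("affected"):
        _, stance_xy = series.trajectory(
            "heel", "affected", range(c["heel_strike"], c["toe_off"] + 1)
        )
        _, swing_xy = series.trajectory(
            "heel", "affected", range(c["toe_off"], c["terminal_swing"] + 1)
        )
        if stance_xy.size == 0 or swing_xy.size == 0:
            continue
        ref = float(np.median(stance_xy @ lat))
        dev = float(np.max(np.abs(swing_xy @ lat - ref)))
        best = dev if best is None else max(best, dev)
    if best is None:
        raise TimelineError("no swing frames with an affected heel landmark")
    return best / cal.shoe_width_px


def external_rotation(
    frame: LandmarkFrame, cal: CalibrationInfo, side: str = "affected"
) -> float:
    """Unsigned angle between the foot long-axis (heel->toe) and progression."""
    v = frame.get("toe", side) - frame.get("heel", side)
    if not np.any(v):
        raise GeometryError("heel and toe coincide; foot axis undefined")
    return angle_between_vectors(v, cal.progression_direction)


# ---------------------------------------------------------------------------
# measurement assembly
# ---------------------------------------------------------------------------


@dataclass
class MeasurementSet:
    """Per-item quantitative evidence derived from annotated recordings.

    Every field is optional: a missing landmark or view leaves the
    dependent fields ``None`` and the corresponding items fall back to
    manual rating. Durations and shoe-width quantities are non-negative.
    """

    knee_flexion_affected_deg: Optional[float] = None
    knee_flexion_unaffected_deg: Optional[float] = None
    knee_flexion_class: Optional[str] = None
    hip_extension_affected_deg: Optional[float] = None
    hip_extension_unaffected_deg: Optional[float] = None
    stance_time_affected_s: Optional[float] = None
    stance_time_unaffected_s: Optional[float] = None
    pause_before_toe_off_s: Optional[float] = None
    stance_width_sw: Optional[float] = None
    circumduction_sw: Optional[float] = None
    external_rotation_affected_deg: Optional[float] = None
    external_rotation_unaffected_deg: Optional[float] = None
    hip_hiking_sw: Optional[float] = None
    toe_clearance_px: Optional[float] = None
    toe_drag_fraction: Optional[float] = None
    step_beyond_toe_sw: Optional[float] = None
    step_beyond_heel_sw: Optional[float] = None
    trunk_shift_fraction: Optional[float] = None
    pelvic_rotation_deg: Optional[float] = None
    foot_contact_angle_deg: Optional[float] = None

    def __post_init__(self):
        for name in (
            "stance_time_affected_s",
            "stance_time_unaffected_s",
            "pause_before_toe_off_s",
            "stance_width_sw",
            "circumduction_sw",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise SchemaError(f"{name} must be non-negative, got {v}")

    def to_dict(self) -> dict[str, object]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _mean_or_none(vals: list[float]) -> Optional[float]:
    return float(np.mean(vals)) if vals else None


def _try(fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (MissingLandmarkError, GeometryError, TimelineError):
        return None


def _forward_speeds(
    series: LandmarkSeries, name: str, side: str, cal: CalibrationInfo
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame forward speed (px/s) of a landmark; (frame idx, speed)."""
    idx, xy = series.trajectory(name, side)
    if len(idx) < 2:
        return np.array([], dtype=int), np.array([])
    pos = xy @ cal.progression_direction
    dt = np.diff(idx) / cal.fps
    speeds = np.diff(pos) / dt
    return idx[1:], speeds


def _measure_sagittal(ann: Annotation, ms: MeasurementSet, cfg: ThresholdConfig) -> None:
    series, tl, cal = ann.series, ann.timeline, ann.calibration

    cmp_res = _try(
        compare_knee_flexion,
        series,
        tl,
        cfg.angle_equal_tol_deg,
        minimal_floor_deg=cfg.knee_minimal_floor_deg,
        maximal_ceiling_deg=cfg.knee_maximal_ceiling_deg,
        extension_floor_deg=cfg.knee_extension_floor_deg,
    )
    if cmp_res is not None:
        ms.knee_flexion_affected_deg = cmp_res.affected_peak_deg
        ms.knee_flexion_unaffected_deg = cmp_res.unaffected_peak_deg
        ms.knee_flexion_class = cmp_res.category

    for side in SIDES:
        setattr(ms, f"stance_time_{side}_s", _try(stance_time, tl, cal, side))
        ext = [
            v
            for to in tl.frames_of(side, "toe_off")
            if series.has_frame(to)
            and (v := _try(hip_extension_angle, series.frame(to), side, cal)) is not None
        ]
        setattr(ms, f"hip_extension_{side}_deg", _mean_or_none(ext))

    # guardedness: hip forward-speed drop in late stance of the affected leg
    idx, speeds = _forward_speeds(series, "trochanter", "affected", cal)
    if speeds.size:
        mean_speed = float(np.mean(np.abs(speeds)))
        if mean_speed > 0:
            pauses = []
            for h, t in tl.stance_intervals("affected"):
                mid = (h + t) // 2
                sel = (idx >= mid) & (idx <= t)
                if np.any(sel):
                    n_paused = int(
                        np.sum(np.abs(speeds[sel]) < cfg.pause_speed_fraction * mean_speed)
                    )
                    pauses.append(n_paused / cal.fps)
            if pauses:
                ms.pause_before_toe_off_s = max(pauses)

    # toe clearance / drag over affected swing
    clear, drags = [], []
    aff_hs = tl.frames_of("affected", "heel_strike")
    for c in tl.cycles("affected"):
        _, stance_xy = series.trajectory(
            "toe", "affected", range(c["heel_strike"], c["toe_off"] + 1)
        )
        nxt = [h for h in aff_hs if h > c["toe_off"]]
        end = nxt[0] if nxt else c["terminal_swing"] + 1
        sw_idx, sw_xy = series.trajectory(
            "toe", "affected", range(c["toe_off"] + 1, end)
        )
        if stance_xy.size == 0 or sw_xy.size == 0:
            continue
        floor_y = float(np.max(stance_xy[:, 1]))
        clearance = floor_y - sw_xy[:, 1]
        clear.append(float(np.min(clearance)))
        drags.append(float(np.mean(clearance <= cfg.toe_drag_floor_px)))
    if clear:
        ms.toe_clearance_px = min(clear)
        ms.toe_drag_fraction = max(drags)

    # step length of the unaffected side, relative to the planted affected foot
    bt, bh = [], []
    for h in tl.frames_of("unaffected", "heel_strike"):
        if not series.has_frame(h):
            continue
        f = series.frame(h)
        if f.has("toe", "unaffected") and f.has("toe", "affected") and f.has("heel", "affected"):
            fwd = cal.progression_direction
            toe_u = float(np.dot(f.get("toe", "unaffected"), fwd))
            bt.append((toe_u - float(np.dot(f.get("toe", "affected"), fwd))) / cal.shoe_width_px)
            bh.append((toe_u - float(np.dot(f.get("heel", "affected"), fwd))) / cal.shoe_width_px)
    ms.step_beyond_toe_sw = _mean_or_none(bt)
    ms.step_beyond_heel_sw = _mean_or_none(bh)

    # initial contact pitch of the affected foot
    pitches = []
    for h in tl.frames_of("affected", "heel_strike"):
        if not series.has_frame(h):
            continue
        f = series.frame(h)
        if f.has("toe", "affected") and f.has("heel", "affected"):
            v = f.get("toe", "affected") - f.get("heel", "affected")
            fwd = float(np.dot(v, cal.progression_direction))
            up = float(np.dot(v, _UP))
            if fwd != 0 or up != 0:
                pitches.append(math.degrees(math.atan2(up, abs(fwd))))
    ms.foot_contact_angle_deg = _mean_or_none(pitches)

    if ms.hip_hiking_sw is None:
        ms.hip_hiking_sw = _hip_hiking(ann, cfg)


def _hip_hiking(ann: Annotation, cfg: ThresholdConfig) -> Optional[float]:
    """Affected pelvic-crest elevation at mid swing, in shoe widths.

    Uses pelvic obliquity (height of the affected crest above the
    unaffected one) referenced to its affected-stance baseline, so shared
    vertical pelvis oscillation cancels.
    """
    series, tl, cal = ann.series, ann.timeline, ann.calibration

    def obliquity(frame: LandmarkFrame) -> Optional[float]:
        if frame.has("pelvis_crest", "affected") and frame.has("pelvis_crest", "unaffected"):
            # image y grows downward: positive = affected crest higher
            return float(
                frame.get("pelvis_crest", "unaffected")[1]
                - frame.get("pelvis_crest", "affected")[1]
            )
        return None

    vals = []
    for c in tl.cycles("affected"):
        stance = [
            o
            for i in range(c["heel_strike"], c["toe_off"] + 1)
            if series.has_frame(i) and (o := obliquity(series.frame(i))) is not None
        ]
        msf = c["mid_swing"]
        if not stance or not series.has_frame(msf):
            continue
        o_ms = obliquity(series.frame(msf))
        if o_ms is None:
            continue
        vals.append((o_ms - float(np.mean(stance))) / cal.shoe_width_px)
    return _mean_or_none(vals)


def _measure_frontal(ann: Annotation, ms: MeasurementSet, cfg: ThresholdConfig) -> None:
    series, tl, cal = ann.series, ann.timeline, ann.calibration

    widths = [
        w
        for h in tl.frames_of("affected", "heel_strike")
        if series.has_frame(h)
        and (w := _try(stance_width, series.frame(h), cal)) is not None
    ]
    ms.stance_width_sw = _mean_or_none(widths)

    ms.circumduction_sw = _try(circumduction, series, tl, cal)

    for side in SIDES:
        rots = []
        for c in tl.cycles(side):
            fi = c["toe_off"] + max(1, (c["mid_swing"] - c["toe_off"]) // 3)
            if series.has_frame(fi):
                r = _try(external_rotation, series.frame(fi), cal, side)
                if r is not None:
                    rots.append(r)
        setattr(ms, f"external_rotation_{side}_deg", _mean_or_none(rots))

    fracs = []
    for h, t in tl.stance_intervals("affected"):
        mid = (h + t) // 2
        if not series.has_frame(mid):
            continue
        f = series.frame(mid)
        if not (
            f.has("trunk_midline", "mid") and f.has("heel", "affected") and f.has("heel", "unaffected")
        ):
            continue
        lat = cal.lateral_axis
        a = float(np.dot(f.get("heel", "affected"), lat))
        u = float(np.dot(f.get("heel", "unaffected"), lat))
        trunk = float(np.dot(f.get("trunk_midline", "mid"), lat))
        centre = (a + u) / 2.0
        denom = a - centre
        if abs(denom) > 1e-9:
            fracs.append((trunk - centre) / denom)
    ms.trunk_shift_fraction = _mean_or_none(fracs)

    hik = _hip_hiking(ann, cfg)
    if hik is not None:
        ms.hip_hiking_sw = hik


def measure_trial(
    sagittal: Optional[Annotation] = None,
    frontal: Optional[Annotation] = None,
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> MeasurementSet:
    """Derive the full measurement set from sagittal and/or frontal trials.

    Either view may be omitted; only the measurements that view supports
    are filled in. Pelvic rotation (item 13) is a transverse-plane quantity
    that single-plane landmarks cannot resolve; it stays ``None`` unless
    supplied directly by the caller.
    """
    if sagittal is None and frontal is None:
        raise SchemaError("measure_trial needs at least one annotated view")
    for ann, expected in ((sagittal, "sagittal"), (frontal, "frontal")):
        if ann is not None and ann.calibration.view != expected:
            raise SchemaError(
                f"annotation passed as {expected} has view {ann.calibration.view!r}"
            )
    ms = MeasurementSet()
    if frontal is not None:
        _measure_frontal(frontal, ms, config)
    if sagittal is not None:
        _measure_sagittal(sagittal, ms, config)
    return ms


# ---------------------------------------------------------------------------
# rating suggestions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Suggestion:
    """An advisory option-code suggestion with its numeric evidence."""

    item_id: int
    code: Optional[str]  # None when status == "manual"
    status: str  # "suggested" | "manual"
    evidence: dict[str, float]
    unit: str
    rationale: str

    @classmethod
    def manual(cls, item_id: int, why: str) -> "Suggestion":
        return cls(item_id, None, "manual", {}, "", why)


def _sugg_2(m: MeasurementSet, c: ThresholdConfig) -> Optional[Suggestion]:
    if m.stance_time_affected_s is None or m.stance_time_unaffected_s is None:
        return None
    if m.stance_time_unaffected_s == 0:
        return None
    r = m.stance_time_affected_s / m.stance_time_unaffected_s
    code = "1" if r >= c.time_ratio_equal else ("2" if r >= c.time_ratio_brief else "3")
    return Suggestion(
        2,
        code,
        "suggested",
        {
            "stance_time_affected_s": m.stance_time_affected_s,
            "stance_time_unaffected_s": m.stance_time_unaffected_s,
            "ratio": r,
        },
        "s",
        f"affected/unaffected stance-time ratio {r:.2f} "
        f"(equal >= {c.time_ratio_equal:g}, very brief < {c.time_ratio_brief:g})",
    )


def _sugg_3(m: MeasurementSet, c: ThresholdConfig) -> Optional[Suggestion]:
    if m.step_beyond_toe_sw is None or m.step_beyond_heel_sw is None:
        return None
    if m.step_beyond_toe_sw > 0:
        code = "1"
    elif m.step_beyond_heel_sw > 0:
        code = "2"
    else:
        code = "3"
    return Suggestion(
        3,
        code,
        "suggested",
        {
            "step_beyond_toe_sw": m.step_beyond_toe_sw,
            "step_beyond_heel_sw": m.step_beyond_heel_sw,
        },
        "shoe widths",
        f"unaffected toe lands {m.step_beyond_toe_sw:+.2f} sw past the affected toe "
        f"and {m.step_beyond_heel_sw:+.2f} sw past the affected heel",
    )


def _sugg_4(m: MeasurementSet, c: ThresholdConfig) -> Optional[Suggestion]:
    if m.trunk_shift_fraction is None:
        return None
    f = m.trunk_shift_fraction
    if f >= c.trunk_full_shift_fraction:
        code = "1"
    elif f > 0:
        code = "2a"
    else:
        code = "3a"
    return Suggestion(
        4,
        code,
        "suggested",
        {"trunk_shift_fraction": f},
        "fraction of midline-to-foot distance",
        f"trunk midline shifts {f:+.2f} of the way from midline to the affected "
        f"foot at mid-stance (full shift >= {c.trunk_full_shift_fraction:g}); "
        "a/b variant left to the rater",
    )


def _sugg_5(m: MeasurementSet, c: ThresholdConfig) -> Optional[Suggestion]:
    if m.stance_width_sw is None:
        return None
    w = m.stance_width_sw
    code = "1" if w <= c.shoe_width_normal else ("2" if w <= c.shoe_width_moderate else "3")
    return Suggestion(
        5,
        code,
        "suggested",
        {"stance_width_sw": w},
        "shoe widths",
        f"heel separation {w:.2f} shoe widths (normal <= {c.shoe_width_normal:g}, "
        f"moderate <= {c.shoe_width_moderate:g})",
    )


def _sugg_6(m: MeasurementSet, c: ThresholdConfig) -> Optional[Suggestion]:
    if m.pause_before_toe_off_s is None:
        return None
    p = m.pause_before_toe_off_s
    code = "1" if p <= c.pause_slight_s else ("2" if p <= c.pause_marked_s else "3")
    return Suggestion(
        6,
        code,
        "suggested",
        {"pause_before_toe_off_s": p},
        "s",
        f"forward momentum pause of {p:.2f} s before toe off "
        f"(slight > {c.pause_slight_s:g} s, marked > {c.pause_marked_s:g} s)",
    )


def _sugg_7(m: MeasurementSet, c: ThresholdConfig) -> Optional[Suggestion]:
    if m.hip_extension_affected_deg is None or m.hip_extension_unaffected_deg is None:
        return None
    aff, unaff = m.hip_extension_affected_deg, m.hip_extension_unaffected_deg
    if unaff - aff <= c.angle_equal_tol_deg:
        code = "1"
    elif aff >= -c.hip_marked_flexion_deg:
        code = "2"
    else:
        code = "3"
    return Suggestion(
        7,
        code,
        "suggested",
        {"hip_extension_affected_deg": aff, "hip_extension_unaffected_deg": unaff},
        "deg",
        f"hip extension at toe off: affected {aff:.1f} vs unaffected {unaff:.1f} deg "
        f"(equal within {c.angle_equal_tol_deg:g} deg, marked flexion beyond "
        f"{c.hip_marked_flexion_deg:g} deg of hip flexion)",
    )


def _sugg_8(m: MeasurementSet, c: ThresholdConfig) -> Optional[Suggestion]:
    if m.external_rotation_affected_deg is None or m.external_rotation_unaffected_deg is None:
        return None
    aff, unaff = m.external_rotation_affected_deg, m.external_rotation_unaffected_deg
    if abs(aff - unaff) <= c.angle_equal_tol_deg:
        code = "1"
    elif aff <= c.external_rotation_marked_deg:
        code = "2"
    else:
        code = "3"
    return Suggestion(
        8,
        code,
        "suggested",
        {"external_rotation_affected_deg": aff, "external_rotation_unaffected_deg": unaff},
        "deg",
        f"foot external rotation at initial swing: affected {aff:.1f} vs "
        f"unaffected {unaff:.1f} deg (marked > {c.external_rotation_marked_deg:g} deg)",
    )


def _sugg_9(m: MeasurementSet, c: ThresholdConfig) -> Optional[Suggestion]:
    if m.circumduction_sw is None:
        return None
    v = m.circumduction_sw
    if v <= c.circumduction_none_sw:
        code = "1"
    elif v <= c.shoe_width_normal:
        code = "2"
    else:
        code = "3"
    return Suggestion(
        9,
        code,
        "suggested",
        {"circumduction_sw": v},
        "shoe widths",
        f"peak lateral swing deviation {v:.2f} shoe widths "
        f"(none <= {c.circumduction_none_sw:g}, moderate <= {c.shoe_width_normal:g})",
    )


def _sugg_10(m: MeasurementSet, c: ThresholdConfig) -> Optional[Suggestion]:
    if m.hip_hiking_sw is None:
        return None
    v = m.hip_hiking_sw
    code = "1" if v <= c.hip_hiking_none_sw else ("2" if v <= c.hip_hiking_vault_sw else "3")
    return Suggestion(
        10,
        code,
        "suggested",
        {"hip_hiking_sw": v},
        "shoe widths",
        f"pelvic crest rises {v:.2f} shoe widths at mid swing "
        f"(none <= {c.hip_hiking_none_sw:g}, vault > {c.hip_hiking_vault_sw:g})",
    )


def _sugg_11(m: MeasurementSet, c: ThresholdConfig) -> Optional[Suggestion]:
    if m.knee_flexion_class is None:
        return None
    ev = {}
    if m.knee_flexion_affected_deg is not None:
        ev["knee_flexion_affected_deg"] = m.knee_flexion_affected_deg
    if m.knee_flexion_unaffected_deg is not None:
        ev["knee_flexion_unaffected_deg"] = m.knee_flexion_unaffected_deg
    return Suggestion(
        11,
        _KNEE_CODE[m.knee_flexion_class],
        "suggested",
        ev,
        "deg",
        f"affected knee flexion classified '{m.knee_flexion_class}' "
        f"(peak affected {ev.get('knee_flexion_affected_deg', float('nan')):.1f} vs "
        f"unaffected {ev.get('knee_flexion_unaffected_deg', float('nan')):.1f} deg)",
    )


def _sugg_12(m: MeasurementSet, c: ThresholdConfig) -> Optional[Suggestion]:
    if m.toe_drag_fraction is None:
        return None
    d = m.toe_drag_fraction
    code = "1" if d == 0 else ("2" if d < c.toe_drag_majority else "3")
    ev = {"toe_drag_fraction": d}
    if m.toe_clearance_px is not None:
        ev["toe_clearance_px"] = m.toe_clearance_px
    return Suggestion(
        12,
        code,
        "suggested",
        ev,
        "fraction of swing",
        f"toe drags for {d:.0%} of swing "
        f"(marked >= {c.toe_drag_majority:.0%}); min clearance "
        f"{m.toe_clearance_px if m.toe_clearance_px is not None else float('nan'):.1f} px",
    )


def _sugg_13(m: MeasurementSet, c: ThresholdConfig) -> Optional[Suggestion]:
    if m.pelvic_rotation_deg is None:
        return None
    r = m.pelvic_rotation_deg
    if r >= c.pelvic_rotation_tol_deg:
        code = "1"
    elif r > -c.pelvic_rotation_tol_deg:
        code = "2"
    else:
        code = "3"
    return Suggestion(
        13,
        code,
        "suggested",
        {"pelvic_rotation_deg": r},
        "deg",
        f"pelvic rotation at terminal swing {r:+.1f} deg "
        f"(forward >= {c.pelvic_rotation_tol_deg:g}, retracted <= "
        f"-{c.pelvic_rotation_tol_deg:g})",
    )


def _sugg_14(m: MeasurementSet, c: ThresholdConfig) -> Optional[Suggestion]:
    if m.foot_contact_angle_deg is None:
        return None
    a = m.foot_contact_angle_deg
    if a >= c.foot_contact_tol_deg:
        code = "1"
    elif a > -c.foot_contact_tol_deg:
        code = "2"
    else:
        code = "3"
    return Suggestion(
        14,
        code,
        "suggested",
        {"foot_contact_angle_deg": a},
        "deg",
        f"foot pitch at initial contact {a:+.1f} deg "
        f"(heel first >= {c.foot_contact_tol_deg:g}, toe first <= "
        f"-{c.foot_contact_tol_deg:g})",
    )


_SUGGESTERS = {
    2: _sugg_2,
    3: _sugg_3,
    4: _sugg_4,
    5: _sugg_5,
    6: _sugg_6,
    7: _sugg_7,
    8: _sugg_8,
    9: _sugg_9,
    10: _sugg_10,
    11: _sugg_11,
    12: _sugg_12,
    13: _sugg_13,
    14: _sugg_14,
}


def suggest_ratings(
    meas: MeasurementSet, thresholds: ThresholdConfig = DEFAULT_CONFIG
) -> list[Suggestion]:
    """Advisory option-code suggestions for all 14 items.

    Item 1 (gait-aid use) is never measured and is always ``manual``; any
    item whose measurements are missing degrades to ``manual`` rather than
    failing. Each suggestion carries the numeric evidence used.
    """
    out = [Suggestion.manual(1, "gait-aid use is observed, not measured")]
    for item_id in range(2, 15):
        s = _SUGGESTERS[item_id](meas, thresholds)
        if s is None:
            s = Suggestion.manual(item_id, "required measurement unavailable")
        out.append(s)
    return out
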