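"""Synthetic ratings panels and landmark gait series with known ground truth.

No patient recordings or ratings ship with the package, so every analysis
module is exercised on simulated data whose generating parameters are
known exactly.

Panels
------
:func:`simulate_panel` mirrors the reliability study design: a latent true
option per participant and item is drawn from a per-item distribution, and
each rater/session rating is a possibly perturbed copy. Rater error is a
symmetric +/-1-category step (clamped at the scale ends) applied with
probability ``rater_noise``; session-2 ratings drift from the rater's
session-1 rating with probability ``session_drift``. Defaults reproduce
the study conditions: 31 participants, 3 raters, 2 sessions, and a
high-agreement noise regime.

Gait trials
-----------
:func:`simulate_gait` drives a 2-D sagittal segment chain
(pelvis-thigh-shank-foot, lengths as standard fractions of stature) with
sinusoidal joint waveforms sampled at the video frame rate, plus a frontal
ground-plane projection for lateral quantities. Deficits are injected on
the affected side only - knee-flexion deficit fraction, circumduction
amplitude, external foot rotation, stance-time ratio, stance width, hip
hiking, toe drag, guardedness pause, trunk-shift deficit, altered initial
contact - and gait events are placed at known frames, so the geometric
round trip through :mod:`wgskit.kinematics` can be checked against the
planted values. Landmark groups are generated from their own waveforms;
full kinematic-chain consistency between knee and foot landmarks is not
enforced (and not needed by any measurement).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import SchemaError
from .kinematics import (
    Annotation,
    CalibrationInfo,
    GaitEventTimeline,
    LandmarkFrame,
    LandmarkSeries,
)
from .panel import RatingsPanel
from .rubric import RubricTable, load_rubric

__all__ = ["PanelSpec", "GaitProfile", "simulate_panel", "simulate_gait", "simulate_trial"]


# ---------------------------------------------------------------------------
# ratings panels
# ---------------------------------------------------------------------------

#: Default latent score distributions: most children score in the milder
#: half of each item, a/b variants split the probability of their level.
_DEFAULT_DIST: dict[int, dict[str, float]] = {
    1: {"1": 0.40, "2": 0.25, "3": 0.15, "4": 0.12, "5": 0.08},
    4: {"1": 0.35, "2a": 0.20, "2b": 0.15, "3a": 0.18, "3b": 0.12},
    11: {"1": 0.30, "2a": 0.20, "2b": 0.13, "3a": 0.15, "3b": 0.12, "4": 0.10},
}
for _i in (2, 3, 5, 6, 7, 8, 9, 10, 12, 13, 14):
    _DEFAULT_DIST[_i] = {"1": 0.40, "2": 0.35, "3": 0.25}


@dataclass(frozen=True)
class PanelSpec:
    """Generating parameters of a synthetic ratings panel."""

    n_subjects: int = 31
    n_raters: int = 3
    n_sessions: int = 2
    item_true_score_distribution: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_DIST.items()}
    )
    rater_noise: float = 0.05
    session_drift: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_raters < 1 or self.n_sessions < 1:
            raise SchemaError("panel dimensions must be positive")
        for p in (self.rater_noise, self.session_drift):
            if not 0.0 <= p <= 1.0:
                raise SchemaError(f"noise probabilities must lie in [0, 1], got {p}")
        for item_id, dist in self.item_true_score_distribution.items():
            probs = np.array(list(dist.values()), dtype=float)
            if np.any(probs < 0) or np.any(probs > 1) or not math.isclose(
                probs.sum(), 1.0, abs_tol=1e-9
            ):
                raise SchemaError(
                    f"item {item_id}: option probabilities must be in [0, 1] and sum to 1"
                )


def _perturb_code(code: str, item, p: float, rng: np.random.Generator) -> str:
    """Symmetric +/-1-category random step, clamped to the item's range."""
    if p == 0.0 or rng.random() >= p:
        return code
    score = int(re.match(r"\d+", code).group())
    step = 1 if rng.random() < 0.5 else -1
    new = min(max(score + step, min(item.scores)), max(item.scores))
    if new == score:
        return code
    variants = [o.code for o in item.options if o.score == new]
    return variants[rng.integers(len(variants))] if len(variants) > 1 else variants[0]


def simulate_panel(
    spec: PanelSpec = PanelSpec(), rubric: Optional[RubricTable] = None
) -> RatingsPanel:
    """Draw a reproducible synthetic ratings panel under ``spec``.

    With ``rater_noise = 0`` and ``session_drift = 0`` every rater and
    session reproduces the latent truth exactly, so downstream ICCs are 1
    wherever the item varies between subjects.
    """
    rubric = rubric if rubric is not None else load_rubric()
    spec_items = spec.item_true_score_distribution
    unknown = set(spec_items) - set(rubric.item_ids)
    if unknown:
        raise SchemaError(f"distribution given for unknown items: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    rows = []
    subjects = [f"P{i + 1:03d}" for i in range(spec.n_subjects)]
    raters = [f"R{j + 1}" for j in range(spec.n_raters)]
    for pid in subjects:
        latent: dict[int, str] = {}
        for item in rubric:
            dist = spec_items.get(item.item_id)
            if dist is None:
                raise SchemaError(f"no score distribution for item {item.item_id}")
            bad = set(dist) - set(item.codes)
            if bad:
                raise SchemaError(
                    f"item {item.item_id}: distribution uses unknown codes {sorted(bad)}"
                )
            codes = list(dist.keys())
            probs = np.array(list(dist.values()), dtype=float)
            latent[item.item_id] = codes[rng.choice(len(codes), p=probs / probs.sum())]
        for rid in raters:
            base = {
                i: _perturb_code(c, rubric.item(i), spec.rater_noise, rng)
                for i, c in latent.items()
            }
            prev = base
            for ses in range(1, spec.n_sessions + 1):
                rated = (
                    prev
                    if ses == 1
                    else {
                        i: _perturb_code(c, rubric.item(i), spec.session_drift, rng)
                        for i, c in prev.items()
                    }
                )
                prev = rated
                for i, c in rated.items():
                    rows.append(
                        {
                            "participant_id": pid,
                            "rater_id": rid,
                            "session": ses,
                            "item_id": i,
                            "option_code": c,
                        }
                    )
    return RatingsPanel.from_codes(pd.DataFrame(rows), rubric)


# ---------------------------------------------------------------------------
# gait trials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaitProfile:
    """Generating parameters of one synthetic recorded walk.

    Amplitude units are degrees, shoe widths (sw), seconds or pixels as
    suffixed. A profile with all deficit fields at their defaults produces
    a symmetric, unimpaired gait; each deficit alters the affected side
    only.
    """

    fps: float = 30.0
    n_cycles: int = 3
    view: str = "sagittal"  # view to emit: "sagittal" | "frontal"
    seed: int = 0

    # body scale (pixels) and segment fractions of stature
    stature_px: float = 600.0
    thigh_fraction: float = 0.245
    shank_fraction: float = 0.246
    foot_fraction: float = 0.152
    hip_height_fraction: float = 0.53
    shoe_width_fraction: float = 0.055

    # base gait waveform
    cycle_time_s: float = 1.0
    stance_fraction: float = 0.62
    stride_fraction: float = 0.65  # hip advance per cycle, fraction of stature
    knee_peak_unaffected_deg: float = 60.0
    knee_peak_affected_deg: float = 60.0
    knee_stance_deg: float = 12.0
    hip_flexion_max_deg: float = 25.0
    hip_extension_min_deg: float = -10.0
    external_rotation_unaffected_deg: float = 7.0
    stance_width_sw: float = 0.8
    toe_clearance_px: float = 25.0
    trunk_shift_fraction: float = 1.0

    # injected deficits (affected side only)
    flexion_deficit_fraction: float = 0.0
    hip_extension_deficit_deg: float = 0.0
    circumduction_sw: float = 0.0
    external_rotation_deg: float = 7.0
    stance_time_ratio: float = 1.0
    hip_hiking_sw: float = 0.0
    pause_s: float = 0.0
    toe_drag_fraction: float = 0.0
    step_mode: str = "through"  # "through" | "to_toe" | "behind"
    foot_contact: str = "heel"  # "heel" | "flat" | "toe"

    # measurement noise
    landmark_noise_sd_px: float = 0.0

    def __post_init__(self):
        if self.fps <= 0 or self.cycle_time_s <= 0 or self.n_cycles < 1:
            raise SchemaError("fps, cycle_time_s and n_cycles must be positive")
        if self.view not in ("sagittal", "frontal"):
            raise SchemaError(f"view must be 'sagittal' or 'frontal', got {self.view!r}")
        for name in ("thigh_fraction", "shank_fraction", "foot_fraction",
                     "hip_height_fraction", "shoe_width_fraction", "stature_px"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"{name} must be positive (degenerate segment)")
        for name in ("knee_peak_unaffected_deg", "knee_peak_affected_deg",
                     "circumduction_sw", "stance_width_sw", "hip_hiking_sw",
                     "pause_s", "landmark_noise_sd_px", "toe_clearance_px"):
            if getattr(self, name) < 0:
                raise SchemaError(f"{name} must be non-negative")
        if not 0.0 <= self.toe_drag_fraction <= 1.0:
            raise SchemaError("toe_drag_fraction must lie in [0, 1]")
        if not 0.05 <= self.stance_fraction <= 0.9:
            raise SchemaError("stance_fraction must lie in [0.05, 0.9]")
        if self.step_mode not in ("through", "to_toe", "behind"):
            raise SchemaError(f"unknown step_mode {self.step_mode!r}")
        if self.foot_contact not in ("heel", "flat", "toe"):
            raise SchemaError(f"unknown foot_contact {self.foot_contact!r}")

    @property
    def shoe_width_px(self) -> float:
        return self.shoe_width_fraction * self.stature_px

    def knee_peak(self, side: str) -> float:
        if side == "affected":
            return self.knee_peak_affected_deg * (1.0 - self.flexion_deficit_fraction)
        return self.knee_peak_unaffected_deg

    def stance_frac(self, side: str) -> float:
        if side == "affected":
            return float(np.clip(self.stance_fraction * self.stance_time_ratio, 0.1, 0.85))
        return self.stance_fraction


_OFFSETS = {"affected": 0.0, "unaffected": 0.5}


def _events(profile: GaitProfile, n_frames: int) -> GaitEventTimeline:
    T, F = profile.cycle_time_s, profile.fps
    ev: dict[str, dict[str, list[int]]] = {}
    for side, off in _OFFSETS.items():
        sf = profile.stance_frac(side)
        d = {k: [] for k in ("heel_strike", "toe_off", "mid_swing", "terminal_swing")}
        for c in range(profile.n_cycles + 1):
            hs = round((c + off) * T * F)
            to = round((c + off + sf) * T * F)
            ms = round((c + off + sf + 0.5 * (1 - sf)) * T * F)
            ts = round((c + off + 1 - 0.03) * T * F)
            if ts <= n_frames - 1 and hs >= 0:
                d["heel_strike"].append(hs)
                d["toe_off"].append(to)
                d["mid_swing"].append(ms)
                d["terminal_swing"].append(ts)
        ev[side] = {k: tuple(v) for k, v in d.items()}
    return GaitEventTimeline(ev)


def _phase(t: float, off: float, T: float) -> tuple[int, float]:
    u = t / T - off
    c = math.floor(u)
    return c, u - c


def _knee_angle(profile: GaitProfile, side: str, tau: float) -> float:
    sf = profile.stance_frac(side)
    if tau < sf:
        return profile.knee_stance_deg * math.sin(math.pi * tau / sf) ** 2
    s = (tau - sf) / (1 - sf)
    return profile.knee_peak(side) * math.sin(math.pi * s) ** 2


def _hip_angle(profile: GaitProfile, side: str, tau: float) -> float:
    lo = profile.hip_extension_min_deg
    if side == "affected":
        lo = lo + profile.hip_extension_deficit_deg
    hi = profile.hip_flexion_max_deg
    mid, amp = (hi + lo) / 2.0, (hi - lo) / 2.0
    return mid + amp * math.cos(2 * math.pi * tau)


def _contact_pitch(profile: GaitProfile, tau: float) -> float:
    theta0 = {"heel": 15.0, "flat": 0.0, "toe": -10.0}[profile.foot_contact]
    return theta0 * max(0.0, 1.0 - tau / 0.10)


def _stance_positions(profile: GaitProfile, side: str) -> dict[int, float]:
    """Heel x (progression axis) of each stance cycle, sagittal."""
    stride = profile.stride_fraction * profile.stature_px
    Lf = profile.foot_fraction * profile.stature_px
    x0 = 100.0
    out = {}
    for c in range(-1, profile.n_cycles + 2):
        if side == "affected":
            out[c] = x0 + c * stride
        else:
            base = x0 + c * stride
            if profile.step_mode == "through":
                out[c] = base + 0.5 * stride
            elif profile.step_mode == "to_toe":
                out[c] = base - 0.4 * Lf  # unaffected toe lands within the affected foot
            else:  # behind
                out[c] = base - 1.5 * Lf  # unaffected toe lands behind the affected heel
    return out


def _body_x(profile: GaitProfile, times: np.ndarray) -> np.ndarray:
    """Forward hip position with optional pre-toe-off freezes (guardedness)."""
    speed = profile.stride_fraction * profile.stature_px / profile.cycle_time_s
    moving = np.ones_like(times)
    if profile.pause_s > 0:
        # freeze forward progress just before every affected toe off,
        # including toe offs of incomplete trailing cycles
        T = profile.cycle_time_s
        sf = profile.stance_frac("affected")
        for c in range(profile.n_cycles + 2):
            t_to = (c + sf) * T
            moving[(times > t_to - profile.pause_s) & (times <= t_to)] = 0.0
    dt = np.diff(times, prepend=times[0])
    return 100.0 + np.cumsum(moving * dt) * speed


def simulate_gait(profile: GaitProfile) -> Annotation:
    """Generate one annotated synthetic walking trial for ``profile.view``.

    Returns an :class:`~wgskit.kinematics.Annotation` whose landmark
    series, gait-event timeline and calibration use the same formats the
    analysis modules consume.
    """
    T, F = profile.cycle_time_s, profile.fps
    n_frames = int(round(profile.n_cycles * T * F)) + 1
    timeline = _events(profile, n_frames)
    rng = np.random.default_rng(profile.seed)
    S = profile.stature_px
    Lt, Ls, Lf = (
        profile.thigh_fraction * S,
        profile.shank_fraction * S,
        profile.foot_fraction * S,
    )
    sw = profile.shoe_width_px
    floor_y = 700.0
    hip_y0 = floor_y - profile.hip_height_fraction * S
    times = np.arange(n_frames) / F
    body_x = _body_x(profile, times)
    stance_x = {s: _stance_positions(profile, s) for s in _OFFSETS}
    lat_centre = 300.0
    lat = {"affected": lat_centre + profile.stance_width_sw * sw / 2.0,
           "unaffected": lat_centre - profile.stance_width_sw * sw / 2.0}
    rot = {"affected": profile.external_rotation_deg,
           "unaffected": profile.external_rotation_unaffected_deg}
    out_sign = {"affected": 1.0, "unaffected": -1.0}

    frames = []
    for i in range(n_frames):
        t = times[i]
        hip_y = hip_y0 + 2.0 * (1 - math.cos(4 * math.pi * t / T))
        pts: dict[tuple[str, str], np.ndarray] = {}
        for side, off in _OFFSETS.items():
            c, tau = _phase(t, off, T)
            sf = profile.stance_frac(side)
            swing_s = 0.0 if tau < sf else (tau - sf) / (1 - sf)

            # ---- foot (heel, toe) ----
            if tau < sf:  # stance: planted, possibly pitched just after contact
                theta = math.radians(_contact_pitch(profile, tau))
                heel_x = stance_x[side][c]
                if theta >= 0:
                    heel_y = floor_y
                else:
                    heel_y = floor_y + Lf * math.sin(theta)
                toe_x = heel_x + Lf * math.cos(theta)
                toe_y = heel_y - Lf * math.sin(theta)
                lat_x = lat[side]
            else:  # swing: travel to the next stance position under a clearance arc
                drag = profile.toe_drag_fraction if side == "affected" else 0.0
                h = 0.0 if swing_s < drag else profile.toe_clearance_px * math.sin(
                    math.pi * swing_s
                )
                x_from, x_to_ = stance_x[side][c], stance_x[side][c + 1]
                prog = (1 - math.cos(math.pi * swing_s)) / 2.0
                heel_x = x_from + (x_to_ - x_from) * prog
                heel_y = floor_y - h
                toe_x = heel_x + Lf
                toe_y = heel_y
                circ = profile.circumduction_sw if side == "affected" else 0.0
                lat_x = lat[side] + out_sign[side] * circ * sw * math.sin(math.pi * swing_s)

            # ---- sagittal leg chain from joint waveforms ----
            phi = math.radians(_hip_angle(profile, side, tau))
            k = math.radians(_knee_angle(profile, side, tau))
            psi = phi - k
            troch = np.array([body_x[i], hip_y])
            condyle = troch + Lt * np.array([math.sin(phi), math.cos(phi)])
            shank_dir = np.array([math.sin(psi), math.cos(psi)])
            fib = condyle + 0.08 * Ls * shank_dir
            mall = condyle + Ls * shank_dir

            # ---- pelvis / trunk ----
            hik = (
                profile.hip_hiking_sw * sw * math.sin(math.pi * swing_s)
                if side == "affected"
                else 0.0
            )
            crest_y = hip_y - 0.08 * S - hik

            if profile.view == "sagittal":
                pts[("trochanter", side)] = troch
                pts[("lateral_femoral_condyle", side)] = condyle
                pts[("fibula_head", side)] = fib
                pts[("lateral_malleolus", side)] = mall
                pts[("heel", side)] = np.array([heel_x, heel_y])
                pts[("toe", side)] = np.array([toe_x, toe_y])
                pts[("pelvis_crest", side)] = np.array([body_x[i] + 10.0, crest_y])
            else:  # frontal ground-plane projection
                rho = math.radians(rot[side])
                heel = np.array([lat_x, heel_y])
                toe = heel + Lf * np.array([math.sin(rho) * out_sign[side], -math.cos(rho)])
                pts[("heel", side)] = heel
                pts[("toe", side)] = toe
                pts[("pelvis_crest", side)] = np.array(
                    [lat_centre + out_sign[side] * 0.06 * S, crest_y]
                )
        if profile.view == "frontal":
            # trunk midline sways towards the stance-side foot
            _, tau_a = _phase(t, 0.0, T)
            sf_a = profile.stance_frac("affected")
            f_shift = profile.trunk_shift_fraction
            w_half = profile.stance_width_sw * sw / 2.0
            trunk_x = lat_centre + f_shift * w_half * math.cos(
                2 * math.pi * (tau_a - sf_a / 2.0)
            )
            pts[("trunk_midline", "mid")] = np.array([trunk_x, hip_y - 0.25 * S])

        if profile.landmark_noise_sd_px > 0:
            pts = {
                key: xy + rng.normal(0.0, profile.landmark_noise_sd_px, size=2)
                for key, xy in pts.items()
            }
        frames.append(LandmarkFrame(i, pts))

    cal = CalibrationInfo(
        fps=F,
        shoe_width_px=sw,
        progression_direction=np.array([1.0, 0.0])
        if profile.view == "sagittal"
        else np.array([0.0, -1.0]),
        view=profile.view,
    )
    return Annotation(LandmarkSeries(frames), timeline, cal)


def simulate_trial(profile: GaitProfile) -> dict[str, Annotation]:
    """Both camera views of the same trial: {'sagittal': ..., 'frontal': ...}."""
    return {
        view: simulate_gait(replace(profile, view=view))
        for view in ("sagittal", "frontal")
    }
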