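"""File formats: annotation JSON, ratings CSV, report export.

Annotation JSON schema::

    {
      "video": {"fps": 30.0, "view": "sagittal", "shoe_width_px": 33.0,
                "progression_direction": [1.0, 0.0]},
      "frames": [{"frame_index": 0,
                  "points": {"heel_affected": [x, y], ...}}, ...],
      "events": {"affected": {"heel_strike": [...], "toe_off": [...],
                              "mid_swing": [...], "terminal_swing": [...]},
                 "unaffected": {...}}
    }

Point keys are ``<landmark>_<side>`` with side ``affected``, ``unaffected``
or ``mid`` (midline landmarks). Unknown landmark names are preserved with
a warning; malformed structure raises :class:`~wgskit.errors.SchemaError`
carrying the JSON path of the offending field.

Ratings CSV (long format) has the header
``participant_id,rater_id,session,item_id,option_code``; files are UTF-8,
comma-delimited, decimal point ``.``. Writers emit a canonical row order
so a written file round-trips byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
import pydantic

from .errors import SchemaError
from .kinematics import (
    ALL_SIDES,
    Annotation,
    CalibrationInfo,
    GaitEventTimeline,
    KNOWN_LANDMARKS,
    LandmarkFrame,
    LandmarkSeries,
    MeasurementSet,
    Suggestion,
)
from .panel import RatingsPanel, TOTAL_KEY
from .reliability import ReliabilityReport
from .rubric import Assessment, RubricTable, load_rubric, round_total, total_score

__all__ = [
    "read_annotation",
    "write_annotation",
    "read_ratings",
    "write_ratings",
    "write_assessments",
    "write_measurement_report",
    "report_to_dict",
    "write_report_json",
    "report_tables",
    "write_report_tables",
]

RATINGS_COLUMNS = ["participant_id", "rater_id", "session", "item_id", "option_code"]


# ---------------------------------------------------------------------------
# annotation JSON
# ---------------------------------------------------------------------------


class _VideoModel(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    fps: float = pydantic.Field(gt=0)
    view: Literal["sagittal", "frontal"]
    shoe_width_px: float = pydantic.Field(gt=0)
    progression_direction: tuple[float, float]


class _FrameModel(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    frame_index: int = pydantic.Field(ge=0)
    points: dict[str, tuple[float, float]]


class _AnnotationModel(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    video: _VideoModel
    frames: list[_FrameModel]
    events: dict[str, dict[str, list[int]]]


def _split_point_key(key: str) -> tuple[str, str]:
    name, _, side = key.rpartition("_")
    if not name or side not in ALL_SIDES:
        raise SchemaError(
            f"point key {key!r} must be '<landmark>_<side>' with side in {ALL_SIDES}"
        )
    return name, side


def read_annotation(path: Union[str, Path]) -> Annotation:
    """Read and validate an annotation JSON file."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: not valid JSON: {e}") from e
    try:
        model = _AnnotationModel.model_validate(raw)
    except pydantic.ValidationError as e:
        first = e.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise SchemaError(f"{path}: invalid annotation at {loc}: {first['msg']}") from e

    frames = []
    for fm in model.frames:
        pts = {}
        for key, xy in fm.points.items():
            name, side = _split_point_key(key)
            if name not in KNOWN_LANDMARKS:
                warnings.warn(
                    f"{path}: unknown landmark name {name!r} preserved", stacklevel=2
                )
            pts[(name, side)] = np.asarray(xy, dtype=float)
        frames.append(LandmarkFrame(fm.frame_index, pts))

    cal = CalibrationInfo(
        fps=model.video.fps,
        shoe_width_px=model.video.shoe_width_px,
        progression_direction=np.asarray(model.video.progression_direction, dtype=float),
        view=model.video.view,
    )
    timeline = GaitEventTimeline(
        {s: {e: tuple(v) for e, v in ev.items()} for s, ev in model.events.items()}
    )
    return Annotation(LandmarkSeries(frames), timeline, cal)


def write_annotation(annotation: Annotation, path: Union[str, Path]) -> None:
    """Write an annotation to JSON in canonical (sorted, reproducible) form."""
    cal = annotation.calibration
    doc = {
        "video": {
            "fps": cal.fps,
            "view": cal.view,
            "shoe_width_px": cal.shoe_width_px,
            "progression_direction": [float(v) for v in cal.progression_direction],
        },
        "frames": [
            {
                "frame_index": f.frame_index,
                "points": {
                    f"{name}_{side}": [float(xy[0]), float(xy[1])]
                    for (name, side), xy in sorted(f.points.items())
                },
            }
            for f in annotation.series.frames
        ],
        "events": {
            side: {e: list(v) for e, v in sorted(ev.items())}
            for side, ev in sorted(annotation.timeline.events.items())
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# ratings CSV
# ---------------------------------------------------------------------------


def read_ratings(path: Union[str, Path], rubric: Optional[RubricTable] = None) -> RatingsPanel:
    """Read a long-format ratings CSV into a validated panel.

    Scores are derived from option codes against the rubric; an invalid
    code or a duplicated (participant, rater, session, item) row raises
    :class:`~wgskit.errors.SchemaError` citing the file row number (header
    is row 1).
    """
    rubric = rubric if rubric is not None else load_rubric()
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(RATINGS_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    try:
        df["session"] = df["session"].astype(int)
    except ValueError as e:
        raise SchemaError(f"{path}: non-integer session value: {e}") from e
    try:
        df["item_id"] = df["item_id"].astype(int)
    except ValueError as e:
        raise SchemaError(f"{path}: non-integer item_id value: {e}") from e
    for pos, (i, c) in enumerate(zip(df["item_id"], df["option_code"])):
        try:
            rubric.item(int(i)).option(str(c))
        except Exception as e:
            raise SchemaError(f"{path}, row {pos + 2}: {e}") from e
    dup = df.duplicated(RATINGS_COLUMNS[:4], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup]]
        raise SchemaError(f"{path}: duplicate rating rows at CSV rows {rows[:10]}")
    return RatingsPanel.from_codes(df, rubric)


def write_ratings(panel: RatingsPanel, path: Union[str, Path]) -> None:
    """Write the option-code rows of a panel as canonical ratings CSV.

    Derived ``total`` rows are not written (they are recomputed on read).
    Rows are sorted by participant, rater, session, item so the file is
    byte-reproducible.
    """
    df = panel.data[panel.data["item_id"] != TOTAL_KEY].copy()
    df["item_id"] = df["item_id"].astype(int)
    df = df.sort_values(RATINGS_COLUMNS[:4], kind="mergesort")
    df[RATINGS_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def write_assessments(
    assessments: list[Assessment],
    path: Union[str, Path],
    rubric: Optional[RubricTable] = None,
) -> None:
    """One row per assessment: codes and scores of all 14 items plus total."""
    rubric = rubric if rubric is not None else load_rubric()
    rows = []
    for a in assessments:
        codes = a.codes()
        row: dict[str, object] = {
            "participant_id": a.participant_id,
            "rater_id": a.rater_id,
            "session": a.session,
            "affected_side": a.affected_side if a.affected_side else "unspecified",
        }
        for item in rubric:
            code = codes.get(item.item_id, "")
            row[f"item{item.item_id}_code"] = code
            row[f"item{item.item_id}_score"] = (
                item.option(code).score if code else ""
            )
        row["total"] = str(round_total(total_score(a, rubric)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# measurement / reliability report export
# ---------------------------------------------------------------------------


def write_measurement_report(
    meas: MeasurementSet,
    suggestions: list[Suggestion],
    path: Union[str, Path],
) -> None:
    """Per-item CSV: measurement evidence, unit, suggested code, rationale."""
    rows = []
    for s in suggestions:
        rows.append(
            {
                "item_id": s.item_id,
                "status": s.status,
                "suggested_code": s.code if s.code is not None else "",
                "measurement": ";".join(f"{k}={v:.4g}" for k, v in s.evidence.items()),
                "unit": s.unit,
                "rationale": s.rationale,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (obj != obj):  # NaN -> null for strict JSON
        return None
    return obj


def report_to_dict(report: ReliabilityReport) -> dict:
    return _jsonify(report)


def write_report_json(report: ReliabilityReport, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(report_to_dict(report), indent=1, allow_nan=False) + "\n",
        encoding="utf-8",
    )


def report_tables(report: ReliabilityReport) -> dict[str, pd.DataFrame]:
    """Flat tables mirroring the classic report layouts.

    ``descriptives``: one row per item x rater x session with mean, median,
    min, max, quartiles and SD. ``kruskal``: items x sessions p-values
    (between-rater comparison). ``wilcoxon``: items x raters p-values
    (test-retest). ``icc``: all ICC estimates with category.
    ``bland_altman``: mean difference, SD and limits per comparison.
    """
    desc_rows, kw_rows, wx_rows, icc_rows, ba_rows = [], [], [], [], []
    for item, rep in report.items.items():
        for key, d in rep.descriptives.items():
            rater, session = key.split("|")
            desc_rows.append(
                {
                    "item": item, "rater": rater, "session": int(session),
                    "n": d.n, "mean": d.mean, "median": d.median, "min": d.min,
                    "max": d.max, "q1": d.q1, "q3": d.q3, "sd": d.sd,
                }
            )
        kw = {"item": item}
        for s, t in rep.kruskal_by_session.items():
            kw[f"p_session_{s}"] = t.p_value if hasattr(t, "p_value") else str(t)
        kw_rows.append(kw)
        wx = {"item": item}
        for r, t in rep.wilcoxon_by_rater.items():
            wx[f"p_{r}"] = t.p_value if hasattr(t, "p_value") else str(t)
        wx_rows.append(wx)
        for s, e in rep.inter_rater_icc.items():
            icc_rows.append(
                {
                    "item": item, "kind": "inter-rater", "which": f"session {s}",
                    "icc": e.value if hasattr(e, "value") else "",
                    "category": e.category if hasattr(e, "category") else str(e),
                }
            )
        for r, e in rep.intra_rater_icc.items():
            icc_rows.append(
                {
                    "item": item, "kind": "intra-rater", "which": r,
                    "icc": e.value if hasattr(e, "value") else "",
                    "category": e.category if hasattr(e, "category") else str(e),
                }
            )
        for label, group in (
            ("raters", rep.bland_altman_rater_pairs),
            ("sessions", rep.bland_altman_sessions),
        ):
            for key, b in group.items():
                row = {"item": item, "comparison": f"{label}:{key}"}
                if hasattr(b, "mean_diff"):
                    row.update(
                        {
                            "n": b.n, "mean_diff": b.mean_diff, "sd_diff": b.sd_diff,
                            "loa_low": b.loa_low, "loa_high": b.loa_high,
                            "within_fraction": b.within_fraction,
                        }
                    )
                else:
                    row["note"] = str(b)
                ba_rows.append(row)
    return {
        "descriptives": pd.DataFrame(desc_rows),
        "kruskal": pd.DataFrame(kw_rows),
        "wilcoxon": pd.DataFrame(wx_rows),
        "icc": pd.DataFrame(icc_rows),
        "bland_altman": pd.DataFrame(ba_rows),
    }


def write_report_tables(report: ReliabilityReport, out_dir: Union[str, Path]) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in report_tables(report).items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, lineterminator="\n")
        paths.append(p)
    return paths
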