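"""Long-format ratings panel: participant x rater x session x item scores.

This is the in-memory container behind the reliability analyses. It mirrors
the study design: every participant is rated on each of the 14 items by
several raters in (typically two) sessions. Rows carry the chosen option
code and its numeric score; a derived ``total`` row per
(participant, rater, session) holds the weighted total whenever all 14
items are rated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import SchemaError, StatsError
from .rubric import Assessment, RubricTable, load_rubric, total_score

__all__ = ["RatingsPanel", "TOTAL_KEY"]

TOTAL_KEY = "total"

_KEY = ["participant_id", "rater_id", "session", "item_id"]


@dataclass
class RatingsPanel:
    """Validated long-format score table.

    ``data`` columns: participant_id (str), rater_id (str), session (int),
    item_id (str, "1".."14" or "total"), option_code (str, empty for the
    total rows) and score (float).
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        required = set(_KEY + ["score"])
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"panel is missing columns: {sorted(missing)}")
        if "option_code" not in df.columns:
            df["option_code"] = ""
        df["participant_id"] = df["participant_id"].astype(str)
        df["rater_id"] = df["rater_id"].astype(str)
        df["session"] = df["session"].astype(int)
        df["item_id"] = df["item_id"].astype(str)
        df["option_code"] = df["option_code"].fillna("").astype(str)
        df["score"] = df["score"].astype(float)
        dup = df.duplicated(_KEY, keep=False)
        if dup.any():
            keys = df.loc[dup, _KEY].drop_duplicates().itertuples(index=False, name=None)
            raise SchemaError(f"duplicate panel records for keys: {list(keys)[:10]}")
        self.data = df.sort_values(_KEY, kind="mergesort").reset_index(drop=True)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_codes(
        cls, codes: pd.DataFrame, rubric: Optional[RubricTable] = None
    ) -> "RatingsPanel":
        """Build a panel from option codes, deriving scores and totals.

        ``codes`` needs columns participant_id, rater_id, session, item_id
        (integers 1..14) and option_code. A ``total`` row is added for every
        (participant, rater, session) rating all rubric items.
        """
        rubric = rubric if rubric is not None else load_rubric()
        df = codes.copy()
        need = {"participant_id", "rater_id", "session", "item_id", "option_code"}
        missing = need - set(df.columns)
        if missing:
            raise SchemaError(f"codes table is missing columns: {sorted(missing)}")
        df["item_id"] = df["item_id"].astype(int)
        df["option_code"] = df["option_code"].astype(str)
        df["score"] = [
            float(rubric.item(i).option(c).score)
            for i, c in zip(df["item_id"], df["option_code"])
        ]
        rows = df.assign(item_id=df["item_id"].astype(str))

        totals = []
        all_items = set(rubric.item_ids)
        for (pid, rid, ses), grp in df.groupby(
            ["participant_id", "rater_id", "session"], sort=False
        ):
            if set(grp["item_id"]) == all_items:
                a = Assessment.from_codes(
                    dict(zip(grp["item_id"], grp["option_code"])),
                    participant_id=str(pid),
                    rater_id=str(rid),
                    session=int(ses),
                )
                totals.append(
                    {
                        "participant_id": str(pid),
                        "rater_id": str(rid),
                        "session": int(ses),
                        "item_id": TOTAL_KEY,
                        "option_code": "",
                        "score": float(total_score(a, rubric)),
                    }
                )
        out = pd.concat([rows, pd.DataFrame(totals)], ignore_index=True)
        return cls(out)

    # -- accessors -----------------------------------------------------------

    @property
    def participants(self) -> list[str]:
        return sorted(self.data["participant_id"].unique())

    @property
    def raters(self) -> list[str]:
        return sorted(self.data["rater_id"].unique())

    @property
    def sessions(self) -> list[int]:
        return sorted(self.data["session"].unique())

    @property
    def items(self) -> list[str]:
        keys = set(self.data["item_id"].unique())
        numeric = sorted((k for k in keys if k != TOTAL_KEY), key=int)
        return numeric + ([TOTAL_KEY] if TOTAL_KEY in keys else [])

    def matrix(self, item: str | int, session: int) -> pd.DataFrame:
        """Participant x rater score matrix for one item and session."""
        sub = self.data[
            (self.data["item_id"] == str(item)) & (self.data["session"] == int(session))
        ]
        if sub.empty:
            raise StatsError(f"no records for item {item!r} in session {session}")
        return sub.pivot(index="participant_id", columns="rater_id", values="score")

    def matrix_across_sessions(self, item: str | int, rater: str) -> pd.DataFrame:
        """Participant x session score matrix for one item and rater."""
        sub = self.data[
            (self.data["item_id"] == str(item)) & (self.data["rater_id"] == str(rater))
        ]
        if sub.empty:
            raise StatsError(f"no records for item {item!r} and rater {rater!r}")
        return sub.pivot(index="participant_id", columns="session", values="score")

    def scores(self, item: str | int, rater: str, session: int) -> pd.Series:
        sub = self.data[
            (self.data["item_id"] == str(item))
            & (self.data["rater_id"] == str(rater))
            & (self.data["session"] == int(session))
        ]
        return sub.set_index("participant_id")["score"].sort_index()
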