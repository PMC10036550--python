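"""The paediatric Wisconsin Gait Scale rubric and its scoring rules.

The paediatric WGS rates 14 gait features ("items") grouped by gait phase
(stance, toe-off, swing, heel strike of the affected leg). Most items use a
three-point ordinal scale (1 = best, 3 = worst); item 1 (gait-aid use) uses
five points and item 11 (knee flexion from toe off to mid swing) four. Items
4 and 11 additionally split scores 2 and 3 into ``a``/``b`` variants that
describe *how* the deviation occurs without changing its numeric severity.

The total score is the sum of the numeric scores of items 2-10 and 12-14
plus item 1 weighted by 3/5 and item 11 weighted by 3/4, so that every item
contributes at most 3 points::

    total = (3/5) * s1 + (3/4) * s11 + sum(s_i for i not in {1, 11})

which spans 13.35 (best possible gait) to 42 (worst). Totals are kept as
exact :class:`fractions.Fraction` internally and rounded half-up to two
decimals only on export.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Iterable, Iterator, Mapping, Optional

from .errors import MissingItemsError, RubricValidationError

__all__ = [
    "RubricOption",
    "RubricItem",
    "RubricTable",
    "ItemRating",
    "Assessment",
    "load_rubric",
    "item_score",
    "total_score",
    "score_range",
    "round_total",
    "PHASES",
]

PHASES = ("stance", "toe_off", "swing", "heel_strike")

_CODE_RE = re.compile(r"^(\d+)([ab]?)$")


@dataclass(frozen=True)
class RubricOption:
    """One selectable option of a rubric item."""

    code: str  # e.g. "1", "2a"
    score: int  # leading digit of the code
    anchor: str  # behavioural anchor text

    def __post_init__(self):
        m = _CODE_RE.match(self.code)
        if not m:
            raise RubricValidationError(f"malformed option code {self.code!r}")
        if int(m.group(1)) != self.score:
            raise RubricValidationError(
                f"option code {self.code!r} does not match score {self.score}"
            )


@dataclass(frozen=True)
class RubricItem:
    """A single scale item with its ordered options and weight."""

    item_id: int
    name: str
    phase: str
    options: tuple[RubricOption, ...]
    weight: Fraction = Fraction(1)

    def __post_init__(self):
        if self.phase not in PHASES:
            raise RubricValidationError(f"item {self.item_id}: unknown phase {self.phase!r}")
        codes = [o.code for o in self.options]
        if len(codes) != len(set(codes)):
            raise RubricValidationError(f"item {self.item_id}: duplicate option codes")
        if self.weight <= 0:
            raise RubricValidationError(f"item {self.item_id}: weight must be positive")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(o.code for o in self.options)

    @property
    def scores(self) -> tuple[int, ...]:
        return tuple(o.score for o in self.options)

    def option(self, code: str) -> RubricOption:
        for o in self.options:
            if o.code == code:
                return o
        raise RubricValidationError(
            f"item {self.item_id} ({self.name}): unknown option_code {code!r}; "
            f"valid codes are {list(self.codes)}"
        )

    def min_score(self) -> int:
        return min(self.scores)

    def max_score(self) -> int:
        return max(self.scores)


@dataclass(frozen=True)
class RubricTable:
    """An ordered collection of rubric items, addressable by item id."""

    items: tuple[RubricItem, ...]
    _by_id: Mapping[int, RubricItem] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        by_id = {it.item_id: it for it in self.items}
        if len(by_id) != len(self.items):
            raise RubricValidationError("duplicate item_id in rubric")
        object.__setattr__(self, "_by_id", by_id)

    def __iter__(self) -> Iterator[RubricItem]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> tuple[int, ...]:
        return tuple(it.item_id for it in self.items)

    def item(self, item_id: int) -> RubricItem:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise RubricValidationError(
                f"unknown item_id {item_id!r}; rubric has items {list(self.item_ids)}"
            ) from None

    def restrict(self, item_ids: Iterable[int]) -> "RubricTable":
        """A sub-rubric containing only the given items (order preserved)."""
        keep = set(item_ids)
        return RubricTable(tuple(it for it in self.items if it.item_id in keep))

    def with_unit_weights(self) -> "RubricTable":
        """The same rubric with every item weight forced to 1."""
        return RubricTable(tuple(replace(it, weight=Fraction(1)) for it in self.items))


@dataclass(frozen=True)
class ItemRating:
    """One rater's choice of option for one item."""

    item_id: int
    option_code: str


@dataclass(frozen=True)
class Assessment:
    """One rater's complete 14-item rating of one participant/session.

    ``affected_side`` may be left ``None``; scoring still works but reports
    flag the assessment because the rubric is phrased relative to the
    affected leg.
    """

    participant_id: str
    rater_id: str
    session: int
    ratings: tuple[ItemRating, ...]
    affected_side: Optional[str] = None  # "left" | "right" | None

    def __post_init__(self):
        if self.affected_side not in (None, "left", "right"):
            raise RubricValidationError(
                f"affected_side must be 'left', 'right' or None, got {self.affected_side!r}"
            )

    @classmethod
    def from_codes(
        cls,
        codes: Mapping[int, str],
        participant_id: str = "P01",
        rater_id: str = "R1",
        session: int = 1,
        affected_side: Optional[str] = None,
    ) -> "Assessment":
        ratings = tuple(ItemRating(i, c) for i, c in sorted(codes.items()))
        return cls(participant_id, rater_id, session, ratings, affected_side)

    def codes(self) -> dict[int, str]:
        return {r.item_id: r.option_code for r in self.ratings}

    def total(self, rubric: Optional["RubricTable"] = None) -> Fraction:
        return total_score(self, rubric if rubric is not None else load_rubric())


def _opts(*pairs: tuple[str, str]) -> tuple[RubricOption, ...]:
    out = []
    for code, anchor in pairs:
        out.append(RubricOption(code, int(_CODE_RE.match(code).group(1)), anchor))
    return tuple(out)


# The encoded 14-item paediatric WGS. Anchor texts follow the published
# scale wording; item 1 is weighted 3/5 and item 11 is weighted 3/4 so the
# total spans 13.35-42 points (higher = poorer gait).
_RUBRIC = RubricTable(
    (
        RubricItem(
            1,
            "Use of hand-held gait aid",
            "stance",
            _opts(
                ("1", "No gait aid"),
                ("2", "Minimal gait aid use"),
                ("3", "Minimal gait aid, wide base"),
                ("4", "Marked use"),
                ("5", "Marked use, wide base"),
            ),
            Fraction(3, 5),
        ),
        RubricItem(
            2,
            "Stance time on affected side",
            "stance",
            _opts(
                ("1", "Equal"),
                (
                    "2",
                    "Unequal: compared to unaffected limb remains on the affected "
                    "leg for a shorter period of time",
                ),
                ("3", "Very Brief: least amount of time"),
            ),
        ),
        RubricItem(
            3,
            "Step length on unaffected side",
            "stance",
            _opts(
                ("1", "Step through"),
                ("2", "Foot does not advance beyond the toe of the affected foot"),
                ("3", "Step to behind or up to, but not beyond the affected foot"),
            ),
        ),
        RubricItem(
            4,
            "Weight shift to affected side",
            "stance",
            _opts(
                ("1", "Full shift"),
                (
                    "2a",
                    "Decreased shift: head and trunk crosses midline, but not over "
                    "the affected foot",
                ),
                (
                    "2b",
                    "Decreased shift: head and trunk crosses midline, but not over "
                    "the unaffected foot, head and trunk for part of stance phase "
                    "leaning towards the affected side",
                ),
                (
                    "3a",
                    "Very limited shift: head and trunk does not cross midline, "
                    "minimal weight shift in the direction of the affected side",
                ),
                (
                    "3b",
                    "Very limited shift: head and trunk does not cross midline, "
                    "minimal weight shift in the direction of the unaffected side, "
                    "head and trunk during entire stance phase leaning towards the "
                    "affected side",
                ),
            ),
        ),
        RubricItem(
            5,
            "Stance width",
            "stance",
            _opts(
                ("1", "Normal: Up to one shoe width between feet"),
                ("2", "Moderate: Up to two shoe widths between feet"),
                ("3", "Wide: Greater than two shoe widths between feet"),
            ),
        ),
        RubricItem(
            6,
            "Guardedness (pause prior to advancing affected leg)",
            "toe_off",
            _opts(
                ("1", "None: Good forward momentum with no hesitancy noted"),
                ("2", "Slight: Slight pauses prior to toe off"),
                ("3", "Marked hesitation: Subject pauses prior to toe off"),
            ),
        ),
        RubricItem(
            7,
            "Hip extension on affected side",
            "toe_off",
            _opts(
                ("1", "Equal extension"),
                ("2", "Slight flexion"),
                ("3", "Marked flexion"),
            ),
        ),
        RubricItem(
            8,
            "External rotation during initial swing",
            "swing",
            _opts(
                ("1", "Same as unimpaired leg"),
                ("2", "Increased rotation: Externally rotates the leg < 45 degrees"),
                ("3", "Marked Rotation: Externally rotates the leg > 45 degrees"),
            ),
        ),
        RubricItem(
            9,
            "Circumduction at mid swing",
            "swing",
            _opts(
                ("1", "None"),
                ("2", "Moderate: Affected foot abducts up to one shoe width during swing"),
                ("3", "Marked: Affected foot circumducts more than one shoe width during swing"),
            ),
        ),
        RubricItem(
            10,
            "Hip hiking at mid swing",
            "swing",
            _opts(("1", "None"), ("2", "Elevation"), ("3", "Vaults")),
        ),
        RubricItem(
            11,
            "Knee flexion from toe off to mid swing",
            "swing",
            _opts(
                ("1", "Normal (affected knee flexes equally to unaffected side)"),
                ("2a", "Some (affected knee flexes, but less than unaffected knee)"),
                ("2b", "Some (affected knee flexes, but more than unaffected knee)"),
                ("3a", "Minimal (minimal flexion noted in affected knee (hardly visible)"),
                ("3b", "Maximal (maximal flexion noted in affected knee (well visible)"),
                ("4", "None (knee remains in extension throughout swing)"),
            ),
            Fraction(3, 4),
        ),
        RubricItem(
            12,
            "Toe clearance",
            "swing",
            _opts(
                ("1", "Normal: Toe clears the floor throughout swing"),
                ("2", "Slight drag: Toe drags slightly at the beginning of swing phase"),
                ("3", "Marked: Toe drags during the majority of swing"),
            ),
        ),
        RubricItem(
            13,
            "Pelvic rotation at terminal swing",
            "swing",
            _opts(
                ("1", "Forward: The pelvis is rotated forward to prepare for heel strike"),
                ("2", "Neutral: Posture is erect with pelvis in neutral rotation"),
                ("3", "Retracted: Pelvis has marked lag behind the unaffected leg"),
            ),
        ),
        RubricItem(
            14,
            "Initial foot contact",
            "heel_strike",
            _opts(
                ("1", "Heel strike"),
                ("2", "Foot flat: Foot lands with weight distributed over entire foot"),
                ("3", "No contact of heel: Foot lands on the lateral border of the foot or toes"),
            ),
        ),
    )
)


def load_rubric() -> RubricTable:
    """Return the packaged 14-item paediatric WGS rubric."""
    return _RUBRIC


def item_score(rating: ItemRating, rubric: Optional[RubricTable] = None) -> int:
    """Numeric score of a rating: the leading digit of its option code.

    Variant codes share the numeric score of their leading digit
    ("2a" and "2b" both score 2). Unknown item ids or option codes raise
    :class:`RubricValidationError` naming the offending field.
    """
    rubric = rubric if rubric is not None else _RUBRIC
    return rubric.item(rating.item_id).option(rating.option_code).score


def total_score(assessment: Assessment, rubric: Optional[RubricTable] = None) -> Fraction:
    """Weighted total of an assessment as an exact rational.

    Every rubric item must be rated exactly once; missing items raise
    :class:`MissingItemsError` listing the offending ids.
    """
    rubric = rubric if rubric is not None else _RUBRIC
    rated = [r.item_id for r in assessment.ratings]
    if len(rated) != len(set(rated)):
        dupes = sorted({i for i in rated if rated.count(i) > 1})
        raise RubricValidationError(f"duplicate ratings for items: {dupes}")
    missing = set(rubric.item_ids) - set(rated)
    if missing:
        raise MissingItemsError(missing)
    total = Fraction(0)
    for r in assessment.ratings:
        if r.item_id not in rubric._by_id:
            raise RubricValidationError(f"rating for item {r.item_id} not in rubric")
        total += rubric.item(r.item_id).weight * item_score(r, rubric)
    return total


def score_range(rubric: Optional[RubricTable] = None) -> tuple[Fraction, Fraction]:
    """(min, max) achievable weighted totals, by per-item exhaustive search."""
    rubric = rubric if rubric is not None else _RUBRIC
    lo = sum((it.weight * min(it.scores) for it in rubric), Fraction(0))
    hi = sum((it.weight * max(it.scores) for it in rubric), Fraction(0))
    return lo, hi


def round_total(total: Fraction, ndigits: int = 2) -> Decimal:
    """Round a rational total half-up to ``ndigits`` decimals for export."""
    d = Decimal(total.numerator) / Decimal(total.denominator)
    return d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)
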