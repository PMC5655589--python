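"""Instrument definitions and scoring rules for the DLQI and the EQ-5D-3L.

The Dermatology Life Quality Index (DLQI) is a ten-item dermatology-specific
quality-of-life questionnaire.  Every item is answered on a four-level ordinal
scale scored 3 ("Very much"), 2 ("A lot"), 1 ("A little") and 0 ("Not at
all"); the total score is the sum over the ten items and ranges 0-30, higher
meaning worse quality of life.  Item 7 has two parts (work/study prevented
yes/no, and if not prevented, how much of a problem) which are combined into a
single 0-3 score, so the instrument presents a uniform four-level response
system.  An item left unanswered is scored zero, following the instrument
developers' scoring instructions.

The EQ-5D-3L descriptive system records five domains -- mobility, self-care,
usual activities, pain/discomfort and anxiety/depression -- each at one of
three levels: 1 (no problems), 2 (some problems), 3 (extreme problems).  A
response pattern is one of 3**5 = 243 distinct health states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

N_ITEMS = 10
ITEM_LEVELS = (0, 1, 2, 3)

#: Canonical EQ-5D-3L domain order used everywhere in this package.
EQ5D_DOMAINS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

N_STATES = 3 ** len(EQ5D_DOMAINS)  # 243


@dataclass(frozen=True)
class DlqiResponse:
    """A scored DLQI questionnaire.

    Parameters
    ----------
    items
        Ten integer scores in {0, 1, 2, 3}, in questionnaire order (item 7
        already combined into a single score).
    missing_mask
        Ten booleans marking items that were originally unanswered.  A
        missing item always carries score 0 (the developers' rule).
    """

    items: tuple[int, ...]
    missing_mask: tuple[bool, ...] = field(default=(False,) * N_ITEMS)

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} DLQI items, got {len(self.items)}")
        if len(self.missing_mask) != N_ITEMS:
            raise ValueError("missing_mask must have ten entries")
        for i, score in enumerate(self.items):
            if score not in ITEM_LEVELS:
                raise ValueError(
                    f"DLQI item {i + 1} score {score!r} outside {{0,1,2,3}}"
                )
            if self.missing_mask[i] and score != 0:
                raise ValueError(
                    f"DLQI item {i + 1} flagged missing but scored {score} (must be 0)"
                )

    @property
    def total(self) -> int:
        """Total DLQI score, 0-30."""
        return sum(self.items)


def score_missing_items(raw_items: Sequence[Optional[int]]) -> DlqiResponse:
    """Score a partially answered DLQI questionnaire.

    Unanswered items (``None``) are scored zero and flagged in the missing
    mask; answered items pass through unchanged.  Idempotent: scoring an
    already-complete item vector returns the same scores with no flags.

    Raises
    ------
    ValueError
        If a present value lies outside {0, 1, 2, 3}; the message names the
        offending item (1-based).
    """
    if len(raw_items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} raw DLQI items, got {len(raw_items)}")
    items = []
    mask = []
    for i, value in enumerate(raw_items):
        if value is None:
            items.append(0)
            mask.append(True)
        else:
            value = int(value)
            if value not in ITEM_LEVELS:
                raise ValueError(
                    f"DLQI item {i + 1} score {value!r} outside {{0,1,2,3}}"
                )
            items.append(value)
            mask.append(False)
    return DlqiResponse(items=tuple(items), missing_mask=tuple(mask))


#: Allowed answers to the first part of DLQI item 7 ("has your skin prevented
#: you from working or studying?").
ITEM7_PART_A = ("prevented_yes", "no", "not_relevant")


def combine_item7(part_a: str, part_b: Optional[int] = None) -> int:
    """Combine the two parts of DLQI item 7 into a single 0-3 score.

    "Yes, prevented from work/study" scores 3.  Otherwise the second part
    ("how much of a problem at work/study": 2 = a lot, 1 = a little,
    0 = not at all) provides the score; an absent second part is scored zero
    under the missing-item rule.

    Raises
    ------
    ValueError
        For an unknown ``part_a`` label, a ``part_b`` outside {0, 1, 2}, or
        the inconsistent combination of "prevented" with a nonzero part-b.
    """
    if part_a not in ITEM7_PART_A:
        raise ValueError(f"unknown item-7 part-a response {part_a!r}")
    if part_a == "prevented_yes":
        if part_b not in (None, 0):
            raise ValueError(
                "inconsistent item 7: work/study prevented but part b answered nonzero"
            )
        return 3
    if part_b is None:
        return 0  # missing rule: unanswered part scored zero
    part_b = int(part_b)
    if part_b not in (0, 1, 2):
        raise ValueError(f"item-7 part-b score {part_b!r} outside {{0,1,2}}")
    return part_b


def dlqi_total(dlqi: DlqiResponse) -> int:
    """Total DLQI score (sum of the ten item scores), range 0-30."""
    return dlqi.total


@dataclass(frozen=True)
class Eq5dState:
    """An EQ-5D-3L health state: five domain levels, each in {1, 2, 3}."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for name in EQ5D_DOMAINS:
            level = getattr(self, name)
            if level not in (1, 2, 3):
                raise ValueError(f"EQ-5D domain {name} level {level!r} outside {{1,2,3}}")

    @property
    def levels(self) -> tuple[int, ...]:
        """Domain levels in canonical order."""
        return tuple(getattr(self, name) for name in EQ5D_DOMAINS)


def state_index(state: Eq5dState) -> int:
    """Map a state to its index in 0..242.

    Base-3 ordering with mobility the most significant digit and
    ``level - 1`` as the digit, so (1,1,1,1,1) -> 0 and (3,3,3,3,3) -> 242.
    """
    idx = 0
    for level in state.levels:
        idx = idx * 3 + (level - 1)
    return idx


def state_from_index(index: int) -> Eq5dState:
    """Inverse of :func:`state_index`."""
    if not 0 <= index < N_STATES:
        raise ValueError(f"state index {index} outside 0..{N_STATES - 1}")
    digits = []
    for _ in range(5):
        digits.append(index % 3 + 1)
        index //= 3
    return Eq5dState(*reversed(digits))


@lru_cache(maxsize=1)
def all_states() -> tuple[Eq5dState, ...]:
    """All 243 EQ-5D-3L states in index order."""
    return tuple(state_from_index(i) for i in range(N_STATES))


@dataclass
class SubjectRecord:
    """One subject: demographics, DLQI response and (optionally) EQ-5D state.

    ``sex`` is coded 0 = male, 1 = female; ``age`` is in years and enters
    models as a linear term (any non-negative value accepted, no upper
    clamp).  ``diagnosis`` and ``country`` are free-text labels used only for
    subgroup selection.
    """

    id: str
    age: float
    sex: int
    dlqi: DlqiResponse
    eq5d: Optional[Eq5dState] = None
    diagnosis: Optional[str] = None
    country: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 (male) or 1 (female), got {self.sex!r}")
        if not self.age >= 0:
            raise ValueError(f"age must be non-negative, got {self.age!r}")


def records_from_iterable(records: Iterable[SubjectRecord]) -> list[SubjectRecord]:
    """Materialize and sanity-check an iterable of subject records."""
    out = list(records)
    seen = set()
    for r in out:
        if r.id in seen:
            raise ValueError(f"duplicate subject id {r.id!r}")
        seen.add(r.id)
    return out
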