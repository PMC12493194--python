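"""Edinburgh Handedness Inventory (EHI) scoring and handedness classification.

The EHI asks for the preferred hand on a set of everyday manual tasks, each
answered on a five-level scale from "always left" to "always right".  This
module works with the nine-item manual variant (the ten-item inventory minus
"drawing") and summarises an answer pattern as the laterality quotient

    LQ = 100 * (R - L) / (R + L),

where ``R`` and ``L`` are right- and left-hand points accumulated over the
items and the "writing" item is counted twice.  LQ runs from -100 (fully
left-preferent) to +100 (fully right-preferent).

On top of the quotient, three group codings that are common in the corpus
callosum literature are provided:

* a qualitative consistency classification (after Witelson): consistent
  right-handers (cRH) report no left preference on any item and answer
  "no preference" on fewer than five of the nine items; the remainder are
  non-consistent (NcRH) and split into consistent left-handers (cLH, no
  right-preferent item at all) and mixed-handers (MH);
* a quantitative consistency classification (after Habib): cRH iff
  LQ >= +80, cLH iff LQ <= -80, MH otherwise (boundaries inclusive);
* a direction classification by the sign of the LQ (dRH / dLH / none).

Boundary comparisons (e.g. LQ >= 80) are done on the exact integer point
sums, never on floating-point quotients.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANSWER_LEVELS",
    "EHI_ITEMS",
    "POINT_MAPPINGS",
    "SHORT_CODES",
    "EHIResponse",
    "EHIValidationError",
    "LQRecord",
    "classify_at_threshold",
    "classify_direction",
    "classify_habib",
    "classify_witelson",
    "compute_lq",
    "crosstab_classifications",
    "mirror_response",
    "score_table",
]

#: The nine manual items (ten-item inventory without "drawing").
EHI_ITEMS: tuple[str, ...] = (
    "writing",
    "throwing",
    "scissors",
    "toothbrush",
    "knife",
    "spoon",
    "broom",
    "striking_match",
    "opening_box",
)

ANSWER_LEVELS: tuple[str, ...] = (
    "always_left",
    "usually_left",
    "no_preference",
    "usually_right",
    "always_right",
)

#: Two-letter CSV codes for the answer levels.
SHORT_CODES: dict[str, str] = {
    "AL": "always_left",
    "UL": "usually_left",
    "NP": "no_preference",
    "UR": "usually_right",
    "AR": "always_right",
}

#: Answer level -> (left points, right points).  "standard" is the
#: conventional five-level quantification in which "no preference" credits
#: one point to each hand (guaranteeing R + L > 0); "strict" discards
#: "no preference" answers entirely.
POINT_MAPPINGS: dict[str, dict[str, tuple[int, int]]] = {
    "standard": {
        "always_left": (2, 0),
        "usually_left": (1, 0),
        "no_preference": (1, 1),
        "usually_right": (0, 1),
        "always_right": (0, 2),
    },
    "strict": {
        "always_left": (2, 0),
        "usually_left": (1, 0),
        "no_preference": (0, 0),
        "usually_right": (0, 1),
        "always_right": (0, 2),
    },
}

_LEFT_ANSWERS = frozenset({"always_left", "usually_left"})
_RIGHT_ANSWERS = frozenset({"always_right", "usually_right"})

_MIRROR = {
    "always_left": "always_right",
    "usually_left": "usually_right",
    "no_preference": "no_preference",
    "usually_right": "usually_left",
    "always_right": "always_left",
}


class EHIValidationError(ValueError):
    """Raised for structurally invalid EHI input (missing/unknown answers)."""


@dataclass(frozen=True)
class EHIResponse:
    """One participant's answers to the nine manual EHI items.

    Parameters
    ----------
    participant_id:
        Opaque identifier.
    items:
        Mapping from item name to answer level.  Exactly the nine manual
        items must be present and answered; "writing" is mandatory because
        its answer is double-weighted in the quotient.
    sex:
        ``"female"`` or ``"male"``.
    """

    participant_id: str
    items: Mapping[str, str]
    sex: str

    def __post_init__(self) -> None:
        items = dict(self.items)
        if set(items) != set(EHI_ITEMS):
            missing = sorted(set(EHI_ITEMS) - set(items))
            extra = sorted(set(items) - set(EHI_ITEMS))
            raise EHIValidationError(
                f"participant {self.participant_id!r}: expected exactly the nine "
                f"manual EHI items; missing={missing}, unexpected={extra}"
            )
        for name, answer in items.items():
            if answer not in ANSWER_LEVELS:
                raise EHIValidationError(
                    f"participant {self.participant_id!r}: item {name!r} has "
                    f"unknown answer {answer!r}"
                )
        if self.sex not in ("female", "male"):
            raise EHIValidationError(
                f"participant {self.participant_id!r}: sex must be 'female' or "
                f"'male', got {self.sex!r}"
            )
        object.__setattr__(self, "items", items)


@dataclass(frozen=True)
class LQRecord:
    """Laterality quotient as exact point sums.

    ``left_points``/``right_points`` are the accumulated (writing-doubled)
    hand points; the quotient itself is derived from them so that boundary
    classifications can compare exactly.
    """

    left_points: int
    right_points: int

    def __post_init__(self) -> None:
        if self.left_points < 0 or self.right_points < 0:
            raise EHIValidationError("point sums must be non-negative")
        if self.left_points + self.right_points == 0:
            raise EHIValidationError(
                "R + L = 0: laterality quotient undefined under this mapping"
            )

    @property
    def lq_exact(self) -> Fraction:
        return Fraction(
            100 * (self.right_points - self.left_points),
            self.right_points + self.left_points,
        )

    @property
    def lq(self) -> float:
        return float(self.lq_exact)

    @property
    def abs_lq(self) -> float:
        return abs(self.lq)

    @classmethod
    def from_lq(cls, lq: float, denominator: int = 1000) -> "LQRecord":
        """Build a record from a plain quotient value (used when only the
        LQ itself, not an answer pattern, is available)."""
        if not -100.0 <= lq <= 100.0:
            raise EHIValidationError(f"LQ must lie in [-100, 100], got {lq}")
        frac = Fraction(lq).limit_denominator(10**6) / 100
        right = frac * denominator + denominator
        left = 2 * denominator - right
        # scale to integers
        denom = right.denominator * left.denominator
        return cls(int(left * denom), int(right * denom))


def compute_lq(response: EHIResponse, mapping: str = "standard") -> LQRecord:
    """Score an answer pattern as the writing-double-weighted laterality
    quotient.

    Each item contributes left/right points per the answer mapping; the
    "writing" item's points are counted twice.  Raises
    :class:`EHIValidationError` if the mapping leaves R + L = 0 (possible
    only under the "strict" mapping when every answer is discarded).
    """
    try:
        points = POINT_MAPPINGS[mapping]
    except KeyError:
        raise ValueError(
            f"unknown mapping {mapping!r}; available: {sorted(POINT_MAPPINGS)}"
        ) from None
    left = right = 0
    for name, answer in response.items.items():
        l_pts, r_pts = points[answer]
        weight = 2 if name == "writing" else 1
        left += weight * l_pts
        right += weight * r_pts
    return LQRecord(left_points=left, right_points=right)


def classify_witelson(response: EHIResponse) -> str:
    """Qualitative consistency classification of an answer pattern.

    cRH: no item answered with left preference and fewer than five of the
    nine items answered "no preference".  Everyone else is non-consistent;
    within the non-consistent, cLH additionally has no right-preferent item,
    the remainder are MH.
    """
    answers = list(response.items.values())
    any_left = any(a in _LEFT_ANSWERS for a in answers)
    any_right = any(a in _RIGHT_ANSWERS for a in answers)
    n_neutral = sum(a == "no_preference" for a in answers)
    if not any_left and n_neutral < 5:
        return "cRH"
    if not any_right:
        return "cLH"
    return "MH"


def classify_habib(lq: LQRecord) -> str:
    """Quantitative consistency classification: cRH iff LQ >= +80, cLH iff
    LQ <= -80, MH otherwise.  Comparisons are exact on the point sums
    (LQ >= 80 is equivalent to R >= 9 L)."""
    left, right = lq.left_points, lq.right_points
    if right >= 9 * left:
        return "cRH"
    if left >= 9 * right:
        return "cLH"
    return "MH"


def classify_direction(lq: LQRecord) -> str:
    """Direction of preference by LQ sign: dRH (positive), dLH (negative),
    "none" for LQ exactly zero."""
    if lq.right_points > lq.left_points:
        return "dRH"
    if lq.right_points < lq.left_points:
        return "dLH"
    return "none"


def classify_at_threshold(lq: LQRecord, threshold: float) -> str:
    """Binary consistency split at a |LQ| threshold in [10, 100]:
    "consistent" iff |LQ| >= threshold (inclusive, matching the +/-80
    convention of the quantitative classifier)."""
    if not 10.0 <= threshold <= 100.0:
        raise ValueError(f"threshold must lie in [10, 100], got {threshold}")
    thr = Fraction(threshold)
    total = lq.left_points + lq.right_points
    if 100 * abs(lq.right_points - lq.left_points) >= thr * total:
        return "consistent"
    return "nonconsistent"


def mirror_response(response: EHIResponse) -> EHIResponse:
    """Swap left and right in every answer (used for symmetry checks)."""
    return EHIResponse(
        participant_id=response.participant_id,
        items={k: _MIRROR[v] for k, v in response.items.items()},
        sex=response.sex,
    )


def crosstab_classifications(
    labels_a: Sequence[str], labels_b: Sequence[str]
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate two label vectors over the same participants.

    Returns the contingency table (rows = first labelling) and the fraction
    of participants whose two labels differ.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label sequences differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if len(labels_a) == 0:
        raise ValueError("cannot cross-tabulate empty label sequences")
    a = pd.Series(list(labels_a), name="a")
    b = pd.Series(list(labels_b), name="b")
    table = pd.crosstab(a, b)
    discordance = float(np.mean(a.to_numpy() != b.to_numpy()))
    return table, discordance


def _row_to_response(
    row: pd.Series, item_columns: Mapping[str, str], id_col: str, sex_col: str
) -> EHIResponse:
    items = {}
    for item, col in item_columns.items():
        raw = row[col]
        answer = SHORT_CODES.get(str(raw).strip(), str(raw).strip())
        items[item] = answer
    return EHIResponse(
        participant_id=str(row[id_col]), items=items, sex=str(row[sex_col]).strip()
    )


def score_table(
    df: pd.DataFrame,
    mapping: str = "standard",
    item_columns: Mapping[str, str] | None = None,
    id_col: str = "participant_id",
    sex_col: str = "sex",
) -> pd.DataFrame:
    """Score a questionnaire table (one row per participant).

    Item answers may use the two-letter codes (AL/UL/NP/UR/AR) or the full
    level names.  ``item_columns`` maps item name -> column name for inputs
    with non-default headers.

    Returns a data frame with ``participant_id``, ``sex``, ``lq``,
    ``abs_lq``, ``witelson``, ``habib`` and ``direction`` columns.
    """
    if item_columns is None:
        item_columns = {item: item for item in EHI_ITEMS}
    records = []
    for _, row in df.iterrows():
        resp = _row_to_response(row, item_columns, id_col, sex_col)
        lq = compute_lq(resp, mapping=mapping)
        records.append(
            {
                "participant_id": resp.participant_id,
                "sex": resp.sex,
                "lq": lq.lq,
                "abs_lq": lq.abs_lq,
                "left_points": lq.left_points,
                "right_points": lq.right_points,
                "witelson": classify_witelson(resp),
                "habib": classify_habib(lq),
                "direction": classify_direction(lq),
            }
        )
    return pd.DataFrame.from_records(records)
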