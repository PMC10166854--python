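"""Tremor outcome scores and treatment-parameter summaries.

The Clinical Rating Scale for Tremor (CRST) has parts A (tremor by body
region), B (task performance) and C (tremor-related disability); the
combined score CRST_T = A + B + C has maximum 160. The Hand Tremor Score
(HTS) is a CRST-derived upper-limb subscore: eight items for the dominant
hand (rest, postural and action tremor, pouring, handwriting, large and
small constrained spirals, constrained straight lines) and seven for the
non-dominant hand (handwriting is tested only in the dominant hand), each
scored 0-4, giving maxima of 32 and 28 points.

Outcome is the signed percent change of a score between the pre-treatment
visit and the latest available follow-up; a positive value means the
tremor score decreased (improvement).

Transducer skull parameters (skull density ratio, skull thickness, inner
and outer skull angle) are recorded per element of the 1,024-element
phased array; the analysis uses their mean and sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedChangeError, ValidationError

__all__ = [
    "HTS_ITEMS_DOMINANT",
    "HTS_ITEMS_NONDOMINANT",
    "N_TRANSDUCER_ELEMENTS",
    "SKULL_PARAMETERS",
    "ClinicalRecord",
    "TreatmentParams",
    "hts_score",
    "crst_total",
    "percent_change",
    "treatment_summary",
    "latest_followup",
]

HTS_ITEMS_DOMINANT = (
    "rest", "postural", "action", "pouring", "handwriting",
    "spiral_large", "spiral_small", "straight_lines",
)
HTS_ITEMS_NONDOMINANT = tuple(i for i in HTS_ITEMS_DOMINANT if i != "handwriting")

MAX_ITEM_SCORE = 4
MAX_CRST_TOTAL = 160

N_TRANSDUCER_ELEMENTS = 1024
SKULL_PARAMETERS = ("sdr", "skull_thickness", "inner_angle", "outer_angle")


@dataclass
class ClinicalRecord:
    """One subject's tremor scores at one timepoint."""

    subject_id: str
    timepoint: str  # "pre" | "post"
    crst_a: float
    crst_b: float
    crst_c: float
    hts_items_dominant: dict = field(default_factory=dict)
    hts_items_nondominant: dict = field(default_factory=dict)
    date: str | None = None

    def __post_init__(self):
        for part, v in (("crst_a", self.crst_a), ("crst_b", self.crst_b),
                        ("crst_c", self.crst_c)):
            if v < 0:
                raise ValidationError(f"{part} must be non-negative, got {v}")
        if self.crst_a + self.crst_b + self.crst_c > MAX_CRST_TOTAL:
            raise ValidationError(
                f"combined CRST exceeds the scale maximum of {MAX_CRST_TOTAL}"
            )
        if self.timepoint not in ("pre", "post"):
            raise ValidationError(f"timepoint must be 'pre' or 'post', got "
                                  f"'{self.timepoint}'")


def _check_items(items: dict, expected: tuple, hand: str) -> float:
    total = 0.0
    for name in expected:
        if name not in items:
            raise ValidationError(f"missing {hand}-hand HTS item '{name}'")
        v = items[name]
        if not (0 <= v <= MAX_ITEM_SCORE):
            raise ValidationError(
                f"{hand}-hand HTS item '{name}' = {v} outside 0-{MAX_ITEM_SCORE}"
            )
        total += v
    return total


def hts_score(record: ClinicalRecord, hand: str) -> float:
    """Hand Tremor Score: sum of the 0-4 upper-limb items for one hand.

    Maximum 32 for the dominant hand, 28 for the non-dominant hand.
    """
    if hand == "dominant":
        return _check_items(record.hts_items_dominant, HTS_ITEMS_DOMINANT, hand)
    if hand == "non-dominant":
        return _check_items(record.hts_items_nondominant, HTS_ITEMS_NONDOMINANT,
                            hand)
    raise ValidationError(f"hand must be 'dominant' or 'non-dominant', got "
                          f"'{hand}'")


def crst_total(record: ClinicalRecord) -> float:
    """Combined CRST score (parts A + B + C, maximum 160)."""
    return record.crst_a + record.crst_b + record.crst_c


def percent_change(pre: float, post: float) -> float:
    """Signed percent change; positive when the score decreased.

    ``100 * (pre - post) / pre``. Raises when the pre-treatment score is
    zero (the change is undefined and the record is excluded downstream).
    """
    if pre < 0 or post < 0:
        raise ValidationError("scores must be non-negative")
    if pre == 0:
        raise UndefinedChangeError("percent change undefined for pre-score 0")
    return 100.0 * (pre - post) / pre


@dataclass
class TreatmentParams:
    """Per-element skull parameter arrays plus per-treatment scalars."""

    subject_id: str
    arrays: dict  # parameter name -> length-1024 array
    max_temperature: float | None = None
    active_elements: int | None = None
    total_sonications: int | None = None
    summed_temperature: float | None = None

    def __post_init__(self):
        for name, arr in self.arrays.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != (N_TRANSDUCER_ELEMENTS,):
                raise ValidationError(
                    f"parameter '{name}' has {arr.size} elements; expected "
                    f"{N_TRANSDUCER_ELEMENTS} (one per transducer element)"
                )
            self.arrays[name] = arr


def treatment_summary(params: TreatmentParams) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) per skull parameter.

    Returns a frame indexed by parameter with columns ``mean`` and ``sd``.
    """
    rows = {name: {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1))}
            for name, arr in params.arrays.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[["mean", "sd"]]


def latest_followup(records: list) -> ClinicalRecord:
    """Pick the latest-dated post-treatment record of one subject.

    Not every subject returns for every follow-up, so outcome is assessed
    at the latest visit available. Ties on date (or absent dates) resolve
    to the last record in input order.
    """
    post = [r for r in records if r.timepoint == "post"]
    if not post:
        raise ValidationError("no post-treatment records")
    keyed = [(r.date if r.date is not None else "", i) for i, r in enumerate(post)]
    _, best = max(keyed)
    return post[best]
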