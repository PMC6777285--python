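"""MVPA heart-rate zone classification and 2×2 device-agreement tables.

An epoch is MVPA when HR ≥ 64% of the age-predicted maximum (220 − age);
the boundary is inclusive. Epochs classified by the criterion and by a
tracker are cross-tabulated, pooled over participants (each participant's own
age sets their threshold), into sensitivity, specificity and overall
accuracy. Percentages follow half-up rounding to 2 decimals, the convention
used in published device-validation tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

DEFAULT_CUTOFF_FRACTION = 0.64
HRMAX_FORMULA = "220-age"

# boundary comparisons tolerate float rounding in cutoff·(220−age):
# 0.64 × 190 evaluates to 121.60000000000001, yet 121.6 bpm is in-zone
_BOUNDARY_EPS = 1e-9


def hr_max(age: float) -> float:
    """Age-predicted maximum heart rate, 220 − age (years)."""
    if age <= 0:
        raise ValueError("age must be positive")
    return 220.0 - age


def mvpa_threshold(age: float, cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION) -> float:
    """The MVPA zone boundary in bpm for one participant."""
    return cutoff_fraction * hr_max(age)


def classify_epoch(
    hr_bpm: float, age: float, cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION
) -> str:
    """Zone label for a single epoch: 'MVPA' iff hr ≥ cutoff·HRmax."""
    if hr_bpm < 0:
        raise ValueError("hr_bpm must be ≥ 0")
    thr = mvpa_threshold(age, cutoff_fraction)
    return "MVPA" if hr_bpm >= thr - _BOUNDARY_EPS else "below"


def percent_half_up(numerator: int, denominator: int, decimals: int = 2) -> float:
    """numerator/denominator as a percentage, half-up at ``decimals``."""
    if denominator == 0:
        return float("nan")
    q = Decimal(100 * numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """Pooled 2×2 epoch counts at the MVPA threshold.

    tp counts epochs MVPA under both devices; fn criterion-MVPA missed by the
    tracker; fp tracker-MVPA not confirmed by the criterion; tn both below.
    """

    tp: int
    fn: int
    fp: int
    tn: int
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION
    hrmax_formula: str = HRMAX_FORMULA

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be ≥ 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        """% of criterion-MVPA epochs the tracker also flags."""
        return percent_half_up(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        """% of criterion below-zone epochs the tracker also keeps below."""
        return percent_half_up(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return percent_half_up(self.tp + self.tn, self.total)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
            "cutoff_fraction": self.cutoff_fraction,
            "hrmax_formula": self.hrmax_formula,
        }


def confusion(
    matched: "MatchedPairs | list",
    roster: pd.DataFrame,
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION,
) -> ConfusionTable:
    """Cross-tabulate criterion vs tracker zone labels, pooled over participants.

    ``matched`` is one MatchedPairs or a list of them (same phase/tracker);
    ``roster`` must supply an ``age`` for every participant involved. Each
    epoch is classified under both devices at that participant's threshold,
    then counts are summed.
    """
    from .streams import MatchedPairs  # local import to avoid cycle

    if isinstance(matched, MatchedPairs):
        matched = [matched]
    ages = roster.set_index("participant_id")["age"]
    tp = fn = fp = tn = 0
    for m in matched:
        if m.participant_id not in ages.index:
            raise KeyError(f"participant {m.participant_id!r} missing from roster")
        thr = mvpa_threshold(float(ages[m.participant_id]), cutoff_fraction)
        crit = m.criterion >= thr - _BOUNDARY_EPS
        trck = m.tracker >= thr - _BOUNDARY_EPS
        tp += int(np.sum(crit & trck))
        fn += int(np.sum(crit & ~trck))
        fp += int(np.sum(~crit & trck))
        tn += int(np.sum(~crit & ~trck))
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn, cutoff_fraction=cutoff_fraction)
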