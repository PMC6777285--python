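"""Criterion-ranked decile comparison of tracker vs criterion heart rate.

Matched epochs are ranked by the criterion value and split into ten
equal-count bins (decile 1 = lowest 10% of criterion HR, decile 10 =
highest); tracker values travel with their epochs. Per-decile five-number
summaries and the mean tracker−criterion difference expose HR-dependent
(proportional) bias that a single pooled statistic hides: a tracker whose
underestimation grows with HR shows a widening difference toward decile 10.

Deciles are computed per phase, pooled across participants, on each
tracker's own matched set (pair counts differ between trackers).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .streams import MatchedPairs

N_DECILES = 10


def pool_pairs(pairs: MatchedPairs | list[MatchedPairs]) -> pd.DataFrame:
    """Concatenate matched pairs into one long frame for pooled analysis."""
    if isinstance(pairs, MatchedPairs):
        pairs = [pairs]
    frames = []
    for m in pairs:
        f = m.pairs.copy()
        f.insert(0, "participant_id", m.participant_id)
        frames.append(f)
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "epoch_start", "criterion_bpm", "tracker_bpm"]
        )
    return pd.concat(frames, ignore_index=True)


def assign_deciles(
    pairs: MatchedPairs | list[MatchedPairs] | pd.DataFrame,
    n_bins: int = N_DECILES,
) -> pd.Series:
    """Rank pooled epochs by criterion HR and split into equal-count bins.

    Returns a Series of bin indices 1..n_bins aligned to the pooled frame's
    rows. Ties in criterion value are broken by epoch timestamp (stable), so
    all-equal inputs fill bins in time order. Bin sizes are ⌊n/10⌋ or ⌈n/10⌉.
    """
    pooled = pairs if isinstance(pairs, pd.DataFrame) else pool_pairs(pairs)
    n = len(pooled)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} matched epochs, got {n}")
    order = np.lexsort(
        (
            pooled["participant_id"].to_numpy(),
            pooled["epoch_start"].to_numpy(),
            pooled["criterion_bpm"].to_numpy(),
        )
    )
    assignment = np.empty(n, dtype=int)
    for i, chunk in enumerate(np.array_split(order, n_bins), start=1):
        assignment[chunk] = i
    return pd.Series(assignment, index=pooled.index, name="decile")


def summarize_deciles(
    assignment: pd.Series,
    pairs: MatchedPairs | list[MatchedPairs] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-decile distribution summaries for both devices.

    One row per decile: epoch count, five-number summary (min, Q1, median,
    Q3, max) plus mean for criterion and tracker, and the mean
    tracker−criterion difference.
    """
    pooled = pairs if isinstance(pairs, pd.DataFrame) else pool_pairs(pairs)
    if len(assignment) != len(pooled) or not assignment.index.equals(pooled.index):
        raise ValueError("assignment must cover all pairs")
    rows = []
    for d in range(1, int(assignment.max()) + 1):
        sub = pooled[assignment.values == d]
        crit = sub["criterion_bpm"].to_numpy(dtype=float)
        trck = sub["tracker_bpm"].to_numpy(dtype=float)
        row: dict = {"decile": d, "n_epochs": len(sub)}
        for name, x in (("criterion", crit), ("tracker", trck)):
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            row.update(
                {
                    f"{name}_mean": x.mean(),
                    f"{name}_min": x.min(),
                    f"{name}_q1": q1,
                    f"{name}_median": med,
                    f"{name}_q3": q3,
                    f"{name}_max": x.max(),
                }
            )
        row["mean_diff_bpm"] = float((trck - crit).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def decile_table(pairs: MatchedPairs | list[MatchedPairs]) -> pd.DataFrame:
    """Convenience: assign deciles and summarize in one call."""
    pooled = pool_pairs(pairs)
    return summarize_deciles(assign_deciles(pooled), pooled)
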