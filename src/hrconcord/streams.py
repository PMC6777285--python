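"""Stream ingestion, 10-second epoching, time-matching and inclusion rules.

All downstream statistics operate on a canonical 10-second epoch grid
anchored at Unix-epoch-aligned boundaries (timestamp seconds ≡ 0 mod 10).
Devices are assumed clock-synchronized (NTP), so no lag search is performed:
matching is an inner join on epoch start times after zero-filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

EPOCH_SECONDS = 10

Phase = Literal["lab", "free"]

#: Inclusion thresholds: minimum minutes of time-matched data per phase.
MIN_MATCHED_MINUTES = {"lab": 10, "free": 180}


class StreamValidationError(ValueError):
    """Raised when a stream file or in-memory stream violates the schema."""


@dataclass
class HRStream:
    """Raw time-stamped heart-rate readings for one participant+device+phase.

    ``data`` is a float Series of bpm values indexed by a strictly increasing
    DatetimeIndex (second resolution). Zero values represent dropout/no-read
    samples that downstream matching must filter out.
    """

    participant_id: str
    device_id: str
    phase: str
    data: pd.Series

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise StreamValidationError("stream index must be a DatetimeIndex")
        if len(idx) > 1 and not idx.is_monotonic_increasing:
            raise StreamValidationError("timestamps must be increasing")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise StreamValidationError(f"duplicate timestamp {dup}")
        if (self.data.values < 0).any():
            row = int(np.argmax(self.data.values < 0))
            raise StreamValidationError(f"negative hr_bpm at row {row}")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class EpochSeries:
    """HR values on the canonical 10-second grid (one value per epoch)."""

    participant_id: str
    device_id: str
    phase: str
    data: pd.Series  # index: epoch start timestamps on the 10-s grid
    epoch_length: int = EPOCH_SECONDS

    def __post_init__(self) -> None:
        secs = self.data.index.asi8 // 10**9
        if (secs % EPOCH_SECONDS).any():
            raise StreamValidationError("epoch starts must lie on the 10-s grid")
        if self.data.index.has_duplicates:
            raise StreamValidationError("at most one value per epoch")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class MatchedPairs:
    """Criterion/tracker bpm pairs on common epochs, zeros removed.

    ``pairs`` has columns ``epoch_start``, ``criterion_bpm``, ``tracker_bpm``,
    sorted by epoch; both bpm columns are strictly positive.
    """

    participant_id: str
    phase: str
    tracker_device_id: str
    pairs: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def criterion(self) -> np.ndarray:
        return self.pairs["criterion_bpm"].to_numpy(dtype=float)

    @property
    def tracker(self) -> np.ndarray:
        return self.pairs["tracker_bpm"].to_numpy(dtype=float)


STREAM_COLUMNS = ["participant_id", "device_id", "phase", "timestamp", "hr_bpm"]


def read_stream(path: str | Path) -> HRStream:
    """Read a long-format stream CSV holding one participant+device+phase.

    Raises :class:`StreamValidationError` naming the offending row for
    malformed timestamps, negative bpm or duplicate timestamps.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "device_id": str})
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise StreamValidationError(f"{path}: missing columns {missing}")
    for col in ("participant_id", "device_id", "phase"):
        if df[col].nunique() > 1:
            raise StreamValidationError(f"{path}: multiple values in {col}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        row = int(ts.isna().idxmax())
        raise StreamValidationError(f"{path}: malformed timestamp at row {row}")
    bpm = pd.to_numeric(df["hr_bpm"], errors="coerce")
    if bpm.isna().any():
        row = int(bpm.isna().idxmax())
        raise StreamValidationError(f"{path}: non-numeric hr_bpm at row {row}")
    if (bpm < 0).any():
        row = int((bpm < 0).idxmax())
        raise StreamValidationError(f"{path}: negative hr_bpm at row {row}")
    if ts.duplicated().any():
        row = int(ts.duplicated().idxmax())
        raise StreamValidationError(f"{path}: duplicate timestamp at row {row}")
    order = np.argsort(ts.values, kind="stable")
    data = pd.Series(bpm.values[order], index=pd.DatetimeIndex(ts.values[order]))
    return HRStream(
        participant_id=str(df["participant_id"].iloc[0]),
        device_id=str(df["device_id"].iloc[0]),
        phase=str(df["phase"].iloc[0]),
        data=data,
    )


def write_stream(stream: HRStream, path: str | Path) -> None:
    """Write a stream as CSV; bpm is rounded to non-negative integers."""
    df = pd.DataFrame(
        {
            "participant_id": stream.participant_id,
            "device_id": stream.device_id,
            "phase": stream.phase,
            "timestamp": stream.data.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "hr_bpm": np.rint(stream.data.values).astype(int),
        }
    )
    df.to_csv(path, index=False)


def to_epochs(stream: HRStream, rule: str = "instant") -> EpochSeries:
    """Reduce a raw stream to the canonical 10-second grid.

    ``rule='instant'`` (default) takes the reading whose timestamp equals the
    epoch start; this is the only rule a 0.1 Hz device can satisfy, so it is
    uniform across devices. ``rule='mean'`` averages all readings falling in
    [start, start+10s) instead. Epochs with no reading are absent.
    """
    if rule not in ("instant", "mean"):
        raise ValueError(f"unknown epoching rule {rule!r}")
    secs = stream.data.index.asi8 // 10**9
    if rule == "instant":
        on_grid = (secs % EPOCH_SECONDS) == 0
        data = stream.data[on_grid]
    else:
        starts = pd.DatetimeIndex((secs - secs % EPOCH_SECONDS) * 10**9)
        data = stream.data.groupby(starts).mean()
    return EpochSeries(
        participant_id=stream.participant_id,
        device_id=stream.device_id,
        phase=stream.phase,
        data=data,
    )


def match_pairs(criterion: EpochSeries, tracker: EpochSeries) -> MatchedPairs:
    """Inner-join tracker epochs onto criterion epochs, dropping zeros.

    Pairs where either device reads 0 bpm are removed: tracker zeros are
    dropout artefacts, and a 0 bpm criterion is nonphysiological (and would
    break MAPE's division). Disjoint grids yield an empty (valid) result.
    """
    if criterion.participant_id != tracker.participant_id:
        raise ValueError(
            f"participant mismatch: {criterion.participant_id} vs "
            f"{tracker.participant_id}"
        )
    if criterion.phase != tracker.phase:
        raise ValueError(f"phase mismatch: {criterion.phase} vs {tracker.phase}")
    joined = pd.DataFrame({"criterion_bpm": criterion.data}).join(
        pd.DataFrame({"tracker_bpm": tracker.data}), how="inner"
    )
    joined = joined[(joined["criterion_bpm"] > 0) & (joined["tracker_bpm"] > 0)]
    joined = joined.sort_index()
    pairs = joined.reset_index(names="epoch_start")
    return MatchedPairs(
        participant_id=criterion.participant_id,
        phase=criterion.phase,
        tracker_device_id=tracker.device_id,
        pairs=pairs,
    )


def restrict_complete_triplets(matched: list[MatchedPairs]) -> list[MatchedPairs]:
    """Keep only epochs present in every tracker's matched set.

    Secondary-analysis mode: restricts each tracker-vs-criterion pair set for
    one participant+phase to epochs available from all devices simultaneously.
    """
    if not matched:
        return []
    common = matched[0].pairs["epoch_start"]
    for m in matched[1:]:
        common = common[common.isin(m.pairs["epoch_start"])]
    out = []
    for m in matched:
        keep = m.pairs[m.pairs["epoch_start"].isin(common)].reset_index(drop=True)
        out.append(
            MatchedPairs(m.participant_id, m.phase, m.tracker_device_id, keep)
        )
    return out


@dataclass
class InclusionResult:
    included: bool
    reason: str | None  # machine-readable reason when excluded
    n_pairs: int
    required: int


def apply_inclusion(matched: MatchedPairs, phase: str,
                    min_minutes: float | None = None) -> InclusionResult:
    """Check the per-phase minimum of time-matched data.

    Defaults: 10 min (60 epochs) for the laboratory phase, 180 min (1,080
    epochs) for the free-living phase; the boundary is inclusive.
    """
    if phase not in MIN_MATCHED_MINUTES:
        raise ValueError(f"unknown phase {phase!r}")
    minutes = MIN_MATCHED_MINUTES[phase] if min_minutes is None else min_minutes
    required = int(np.ceil(minutes * 60 / EPOCH_SECONDS))
    n = len(matched)
    if n >= required:
        return InclusionResult(True, None, n, required)
    return InclusionResult(
        False, f"insufficient_matched_epochs:{n}<{required}", n, required
    )


def wear_time(series: EpochSeries) -> float:
    """Wear time in hours: nonzero epochs × 10 s."""
    return float((series.data.values > 0).sum()) * EPOCH_SECONDS / 3600.0
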