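"""Synthetic paired heart-rate streams for validation-pipeline testing.

No raw device exports from the original study are public, so this module
emulates them: a ground-truth 1 Hz heart-rate trajectory per participant for
a laboratory cycling session (seated rest, four 5-min stages at 45/55/65/75%
of age-predicted HRmax ± 10 bpm, recovery) and a free-living wear day with at
least one ≥10-min MVPA bout; plus a phenomenological wrist-sensor error model
(additive bias, HR-proportional bias, heteroscedastic Gaussian noise, and
dropout-to-zero readings) applied at each device's sampling rate.

The trajectory is a deterministic protocol backbone with first-order
exponential transitions plus a mean-reverting Ornstein–Uhlenbeck wander, so
rank/decile structure downstream is nontrivial. Everything is reproducible
from integer seeds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .streams import HRStream, write_stream
from .zones import hr_max, mvpa_threshold

DEFAULT_START = "2018-04-02T09:00:00"

CRITERION_DEVICE = "chest_strap"
TRACKER_1HZ = "wrist_1hz"
TRACKER_01HZ = "wrist_01hz"


@dataclass(frozen=True)
class Participant:
    """One study participant; HRmax is always derived as 220 − age."""

    id: str
    age: int
    resting_hr: float = 65.0

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if not 40 <= self.resting_hr < self.hr_max:
            raise ValueError("resting_hr must lie in [40, HRmax)")

    @property
    def hr_max(self) -> float:
        return hr_max(self.age)


@dataclass(frozen=True)
class LabProtocol:
    """Incremental cycling session: rest, graded stages, recovery.

    Stage targets are fractions of HRmax; adherence tolerance is ±10 bpm
    around each stage target, which the generated trajectory respects in
    stage means.
    """

    rest_minutes: float = 5.0
    stage_minutes: float = 5.0
    stage_targets: tuple[float, ...] = (0.45, 0.55, 0.65, 0.75)
    stage_tolerance_bpm: float = 10.0
    recovery_minutes: float = 5.0

    def __post_init__(self) -> None:
        t = self.stage_targets
        if not all(0 < x < 1 for x in t) or list(t) != sorted(set(t)):
            raise ValueError("stage_targets must be strictly increasing, in (0,1)")
        if min(self.rest_minutes, self.stage_minutes, self.recovery_minutes) <= 0:
            raise ValueError("durations must be positive")

    @property
    def total_seconds(self) -> int:
        mins = (
            self.rest_minutes
            + self.stage_minutes * len(self.stage_targets)
            + self.recovery_minutes
        )
        return int(round(mins * 60))


@dataclass(frozen=True)
class FreeLivingProtocol:
    """A wear day: low-intensity baseline plus ≥1 bout of ≥10 min MVPA."""

    wear_hours: float = 12.0
    mvpa_bouts: int = 1
    bout_minutes: float = 10.0
    baseline_hr_fraction: float = 0.45
    bout_hr_fraction: float = 0.72

    def __post_init__(self) -> None:
        if self.mvpa_bouts < 1:
            raise ValueError("mvpa_bouts must be ≥ 1")
        if self.bout_minutes < 10:
            raise ValueError("bout_minutes must be ≥ 10")
        if self.mvpa_bouts * self.bout_minutes * 60 >= self.wear_hours * 3600:
            raise ValueError("total bout time must be less than wear time")

    @property
    def total_seconds(self) -> int:
        return int(round(self.wear_hours * 3600))


Protocol = Union[LabProtocol, FreeLivingProtocol]


@dataclass(frozen=True)
class DeviceErrorModel:
    """Phenomenological wrist-sensor error applied to the true trajectory.

    reading = truth + additive_bias + proportional_bias·(truth − rest)
              + N(0, noise_sd_base + noise_sd_slope·(truth − rest)), floor 0;
    with probability ``dropout_prob`` the reading is emitted as a literal
    0 bpm (zeros must exist for the nonzero-filter rule to be exercised).
    """

    additive_bias: float = 0.0
    proportional_bias: float = 0.0
    noise_sd_base: float = 0.0
    noise_sd_slope: float = 0.0
    dropout_prob: float = 0.0
    sampling_period: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0,1]")
        if self.sampling_period not in (1, 2, 5, 10):
            raise ValueError("sampling_period must divide 10 (or equal 10)")
        if self.noise_sd_base < 0 or self.noise_sd_slope < 0:
            raise ValueError("noise SDs must be ≥ 0")


ZERO_ERROR = DeviceErrorModel()


def _ou_wander(n: int, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-reverting wander: AR(1) discretization of an OU process at 1 Hz."""
    if sd == 0:
        return np.zeros(n)
    phi = np.exp(-1.0 / tau)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _segment_backbone(levels: list[tuple[float, int]], start_hr: float,
                      tau: float) -> np.ndarray:
    """Piecewise exponential approach: each segment relaxes toward its level."""
    out = np.empty(sum(n for _, n in levels))
    pos, current = 0, start_hr
    for level, n in levels:
        t = np.arange(n, dtype=float)
        seg = level + (current - level) * np.exp(-t / tau)
        out[pos : pos + n] = seg
        current = seg[-1]
        pos += n
    return out


def true_hr_trajectory(
    participant: Participant,
    protocol: Protocol,
    seed: int,
    *,
    response_tau_s: float = 30.0,
    wander_sd_bpm: float = 2.0,
    wander_tau_s: float = 60.0,
    start: str = DEFAULT_START,
) -> HRStream:
    """Generate the 1 Hz criterion-truth stream for one participant.

    Laboratory sessions follow the rest/stage/recovery backbone with a
    first-order exponential approach (time constant ``response_tau_s``); the
    empirical mean of each stage stays within the protocol tolerance of its
    target. Free-living days sit at the baseline fraction of HRmax and rise
    into each MVPA bout; outside bouts the trajectory is kept strictly below
    the MVPA threshold and within bouts strictly above it (clipped at ±1 bpm
    around the threshold so zone truth is unambiguous).
    """
    hrmax = participant.hr_max
    rng = np.random.default_rng(seed)
    if isinstance(protocol, LabProtocol):
        targets_bpm = [f * hrmax for f in protocol.stage_targets]
        if max(targets_bpm) > hrmax:
            raise ValueError("stage target exceeds HRmax")
        stage_n = int(round(protocol.stage_minutes * 60))
        levels = [(participant.resting_hr, int(round(protocol.rest_minutes * 60)))]
        levels += [(t, stage_n) for t in targets_bpm]
        levels += [(participant.resting_hr * 1.1,
                    int(round(protocol.recovery_minutes * 60)))]
        backbone = _segment_backbone(levels, participant.resting_hr, response_tau_s)
        hr = backbone + _ou_wander(len(backbone), wander_sd_bpm, wander_tau_s, rng)
    else:
        n = protocol.total_seconds
        baseline = protocol.baseline_hr_fraction * hrmax
        bout_level = protocol.bout_hr_fraction * hrmax
        if bout_level > hrmax:
            raise ValueError("bout target exceeds HRmax")
        thr = mvpa_threshold(participant.age)
        bout_n = int(round(protocol.bout_minutes * 60))
        # one bout placed uniformly at random inside each equal slice of the day
        slice_n = n // protocol.mvpa_bouts
        in_bout = np.zeros(n, dtype=bool)
        for b in range(protocol.mvpa_bouts):
            lo = b * slice_n
            start_idx = lo + int(rng.integers(0, slice_n - bout_n))
            in_bout[start_idx : start_idx + bout_n] = True
        levels_arr = np.where(in_bout, bout_level, baseline)
        # exponential relaxation toward the current level, then hard zone clip
        hr = np.empty(n)
        current = baseline
        phi = np.exp(-1.0 / response_tau_s)
        for i in range(n):
            current = levels_arr[i] + (current - levels_arr[i]) * phi
            hr[i] = current
        hr = hr + _ou_wander(n, wander_sd_bpm, wander_tau_s, rng)
        hr = np.where(in_bout, np.maximum(hr, thr + 1.0), np.minimum(hr, thr - 1.0))
    hr = np.clip(np.rint(hr), 30.0, hrmax)
    index = pd.date_range(start=start, periods=len(hr), freq="1s")
    return HRStream(
        participant_id=participant.id,
        device_id=CRITERION_DEVICE,
        phase="lab" if isinstance(protocol, LabProtocol) else "free",
        data=pd.Series(hr, index=index),
    )


def apply_device_error(
    truth: HRStream,
    model: DeviceErrorModel,
    resting_hr: float = 60.0,
    device_id: str | None = None,
) -> HRStream:
    """Corrupt a 1 Hz truth stream into a device stream at the model's rate.

    Proportional bias and the noise SD both scale with HR elevation above
    ``resting_hr``. Readings are floored at 0 bpm; dropout emits literal 0 bpm
    readings rather than missing rows. Deterministic given ``model.seed``.
    """
    secs = truth.data.index.asi8 // 10**9
    if len(secs) > 1 and not np.all(np.diff(secs) == 1):
        raise ValueError("truth stream must be sampled at 1 Hz")
    keep = (secs % model.sampling_period) == 0
    t = truth.data.values[keep].astype(float)
    idx = truth.data.index[keep]
    rng = np.random.default_rng(model.seed)
    elev = t - resting_hr
    reading = t + model.additive_bias + model.proportional_bias * elev
    sd = np.maximum(model.noise_sd_base + model.noise_sd_slope * elev, 0.0)
    if model.noise_sd_base > 0 or model.noise_sd_slope > 0:
        reading = reading + rng.normal(0.0, 1.0, size=len(t)) * sd
    reading = np.maximum(reading, 0.0)
    if model.dropout_prob > 0:
        reading = np.where(
            rng.random(len(t)) < model.dropout_prob, 0.0, reading
        )
    return HRStream(
        participant_id=truth.participant_id,
        device_id=device_id or f"device_p{model.sampling_period}",
        phase=truth.phase,
        data=pd.Series(reading, index=idx),
    )


@dataclass(frozen=True)
class Scenario:
    """Study conditions for a simulated cohort.

    Device error defaults emulate the study's observed phenomenology: the
    1 Hz wrist tracker has a modest negative bias and well-behaved noise; the
    0.1 Hz tracker underestimates increasingly at higher HR (negative
    HR-proportional bias) with heteroscedastic noise. The criterion chest
    strap is treated as truth apart from occasional dropout.
    """

    lab: LabProtocol = field(default_factory=LabProtocol)
    free: FreeLivingProtocol = field(default_factory=FreeLivingProtocol)
    criterion_error: DeviceErrorModel = field(
        default_factory=lambda: DeviceErrorModel(dropout_prob=0.02)
    )
    tracker_1hz_error: DeviceErrorModel = field(
        default_factory=lambda: DeviceErrorModel(
            additive_bias=-5.7,
            noise_sd_base=3.0,
            noise_sd_slope=0.02,
            dropout_prob=0.03,
            sampling_period=1,
        )
    )
    tracker_01hz_error: DeviceErrorModel = field(
        default_factory=lambda: DeviceErrorModel(
            additive_bias=-2.0,
            proportional_bias=-0.08,
            noise_sd_base=3.0,
            noise_sd_slope=0.05,
            dropout_prob=0.05,
            sampling_period=10,
        )
    )
    age_range: tuple[int, int] = (21, 50)
    resting_hr_range: tuple[int, int] = (55, 75)

    @staticmethod
    def zero_error() -> "Scenario":
        """All devices read the truth exactly; no dropout."""
        return Scenario(
            criterion_error=ZERO_ERROR,
            tracker_1hz_error=DeviceErrorModel(sampling_period=1),
            tracker_01hz_error=DeviceErrorModel(sampling_period=10),
        )


def _derive_seed(seed: int, *parts: str) -> int:
    """Stable per-stream sub-seed below 2**31."""
    h = hashlib.sha256(("|".join(map(str, parts)) + f"|{seed}").encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def simulate_participant(
    participant: Participant, scenario: Scenario, seed: int
) -> dict[tuple[str, str], HRStream]:
    """Simulate all six streams (2 phases × 3 devices) for one participant.

    Returns a mapping from (device_id, phase) to the stream. The criterion
    stream is the error-modelled chest strap; truth itself is recoverable via
    :func:`true_hr_trajectory` with the same seed.
    """
    out: dict[tuple[str, str], HRStream] = {}
    for phase, protocol in (("lab", scenario.lab), ("free", scenario.free)):
        truth = true_hr_trajectory(
            participant, protocol, _derive_seed(seed, participant.id, phase)
        )
        for device_id, model in (
            (CRITERION_DEVICE, scenario.criterion_error),
            (TRACKER_1HZ, scenario.tracker_1hz_error),
            (TRACKER_01HZ, scenario.tracker_01hz_error),
        ):
            m = replace(
                model, seed=_derive_seed(seed, participant.id, phase, device_id)
            )
            out[(device_id, phase)] = apply_device_error(
                truth, m, resting_hr=participant.resting_hr, device_id=device_id
            )
    return out


def simulate_cohort(
    n: int, seed: int, scenario: Scenario | None = None
) -> tuple[pd.DataFrame, dict[tuple[str, str, str], HRStream]]:
    """Simulate a cohort in memory.

    Returns the roster (participant_id, age, resting_hr) and a mapping from
    (participant_id, device_id, phase) to streams.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    scenario = scenario or Scenario()
    rng = np.random.default_rng(_derive_seed(seed, "roster"))
    lo, hi = scenario.age_range
    ages = rng.integers(lo, hi + 1, size=n)
    rlo, rhi = scenario.resting_hr_range
    rests = rng.integers(rlo, rhi + 1, size=n)
    roster = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n)],
            "age": ages,
            "resting_hr": rests,
        }
    )
    streams: dict[tuple[str, str, str], HRStream] = {}
    for _, row in roster.iterrows():
        p = Participant(
            id=row["participant_id"],
            age=int(row["age"]),
            resting_hr=float(row["resting_hr"]),
        )
        for (device_id, phase), s in simulate_participant(p, scenario, seed).items():
            streams[(p.id, device_id, phase)] = s
    return roster, streams


def generate_cohort(
    n: int,
    seed: int,
    out_dir: str | Path,
    scenario: Scenario | None = None,
) -> list[Path]:
    """Write a simulated cohort to disk: roster.csv plus one stream CSV per
    participant × device × phase (6 files per participant). Byte-identical
    across runs with the same seed and scenario."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        roster, streams = simulate_cohort(n, seed, scenario)
        paths = [out / "roster.csv"]
        roster.to_csv(paths[0], index=False)
        for (pid, device, phase), stream in streams.items():
            path = out / f"{pid}_{device}_{phase}.csv"
            write_stream(stream, path)
            paths.append(path)
    except OSError as exc:
        raise OSError(f"failed writing cohort to {out}: {exc}") from exc
    return paths
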