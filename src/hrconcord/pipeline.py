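"""End-to-end orchestration: simulate/load → epoch → match → analyse → report.

The pipeline reduces every device stream to the 10-second grid, time-matches
each tracker to the criterion per participant and phase, applies the
inclusion rules, then emits pooled agreement statistics, decile summaries
and MVPA confusion tables, plus an exclusion log and a run manifest. All
outputs are plain CSV/JSON and deterministic given the seed, so the manifest
suffices to reproduce any report. Epoch counts in and out of every filter
are recorded: the filter accounting is the analysis's audit trail.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import agreement as agr
from . import deciles as dec
from . import zones as zon
from .streams import (
    HRStream,
    MatchedPairs,
    apply_inclusion,
    match_pairs,
    read_stream,
    restrict_complete_triplets,
    to_epochs,
    wear_time,
)
from .synthetic import (
    CRITERION_DEVICE,
    TRACKER_01HZ,
    TRACKER_1HZ,
    Scenario,
    simulate_cohort,
)

TRACKERS = (TRACKER_1HZ, TRACKER_01HZ)
PHASES = ("lab", "free")

PAIRS_COLUMNS = [
    "participant_id",
    "phase",
    "tracker",
    "epoch_start",
    "criterion_bpm",
    "tracker_bpm",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``streams_dir`` (with ``roster_path``) or ``simulate_n``
    must be set: real exports or a simulated cohort, never both.
    """

    out_dir: str
    seed: int = 0
    simulate_n: int | None = None
    scenario: Scenario | None = None
    streams_dir: str | None = None
    roster_path: str | None = None
    phases: tuple[str, ...] = PHASES
    min_lab_minutes: float = 10.0
    min_free_minutes: float = 180.0
    epoch_rule: str = "instant"
    cutoff_fraction: float = zon.DEFAULT_CUTOFF_FRACTION
    exclude_outliers: bool = False
    complete_triplets: bool = False

    def __post_init__(self) -> None:
        has_sim = self.simulate_n is not None
        has_paths = self.streams_dir is not None
        if has_sim == has_paths:
            raise ValueError(
                "exactly one of simulate_n or streams_dir must be set"
            )
        if has_paths and self.roster_path is None:
            raise ValueError("streams_dir requires roster_path")
        if self.min_lab_minutes <= 0 or self.min_free_minutes <= 0:
            raise ValueError("inclusion thresholds must be positive")
        if not 0 < self.cutoff_fraction < 1:
            raise ValueError("cutoff_fraction must be in (0,1)")

    def digest(self) -> str:
        """Hash of the analysis inputs (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()


@dataclass
class ReportBundle:
    """In-memory results of one run plus the paths written."""

    agreement: pd.DataFrame
    deciles: pd.DataFrame
    confusion: pd.DataFrame
    exclusions: pd.DataFrame
    wear: pd.DataFrame
    pairs: dict[tuple[str, str], list[MatchedPairs]]  # (phase, tracker) → sets
    outlier_status: dict[str, dict[str, str]]  # tracker → participant → status
    paths: dict[str, Path] = field(default_factory=dict)


def write_pairs(matched: list[MatchedPairs], path: str | Path) -> None:
    """Write matched pairs in the long CSV exchange format."""
    frames = []
    for m in matched:
        f = m.pairs.copy()
        f.insert(0, "tracker", m.tracker_device_id)
        f.insert(0, "phase", m.phase)
        f.insert(0, "participant_id", m.participant_id)
        frames.append(f)
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=PAIRS_COLUMNS)
    )
    df["epoch_start"] = pd.to_datetime(df["epoch_start"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    df.to_csv(path, index=False)


def read_pairs(path: str | Path) -> list[MatchedPairs]:
    """Read the matched-pairs exchange CSV back into MatchedPairs objects."""
    df = pd.read_csv(path, dtype={"participant_id": str, "tracker": str})
    df["epoch_start"] = pd.to_datetime(df["epoch_start"])
    out = []
    for (pid, phase, tracker), grp in df.groupby(
        ["participant_id", "phase", "tracker"], sort=True
    ):
        pairs = grp[["epoch_start", "criterion_bpm", "tracker_bpm"]].reset_index(
            drop=True
        )
        out.append(MatchedPairs(pid, phase, tracker, pairs))
    return out


def _load_streams(
    config: RunConfig,
) -> tuple[pd.DataFrame, dict[tuple[str, str, str], HRStream]]:
    if config.simulate_n is not None:
        return simulate_cohort(
            config.simulate_n, config.seed, config.scenario
        )
    roster = pd.read_csv(config.roster_path, dtype={"participant_id": str})
    streams: dict[tuple[str, str, str], HRStream] = {}
    for path in sorted(Path(config.streams_dir).glob("*.csv")):
        if path.name == "roster.csv":
            continue
        s = read_stream(path)
        streams[(s.participant_id, s.device_id, s.phase)] = s
    if not streams:
        raise PipelineError(f"ingest: no stream CSVs found in {config.streams_dir}")
    return roster, streams


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        roster, streams = _load_streams(config)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-named rewrap
        raise PipelineError(f"ingest: {exc}") from exc

    # epoch every stream once; record wear time
    epochs: dict[tuple[str, str, str], object] = {}
    wear_rows = []
    for key, stream in streams.items():
        es = to_epochs(stream, rule=config.epoch_rule)
        epochs[key] = es
        pid, device, phase = key
        wear_rows.append(
            {
                "participant_id": pid,
                "device_id": device,
                "phase": phase,
                "n_epochs": len(es),
                "wear_hours": wear_time(es),
            }
        )
    wear_df = pd.DataFrame(wear_rows).sort_values(
        ["participant_id", "phase", "device_id"], ignore_index=True
    )

    # match each tracker to the criterion per participant × phase
    min_minutes = {"lab": config.min_lab_minutes, "free": config.min_free_minutes}
    participants = sorted({pid for pid, _, _ in streams})
    matched: dict[tuple[str, str], list[MatchedPairs]] = {
        (ph, tr): [] for ph in config.phases for tr in TRACKERS
    }
    excl_rows = []
    for pid in participants:
        for phase in config.phases:
            crit = epochs.get((pid, CRITERION_DEVICE, phase))
            if crit is None:
                excl_rows.append(
                    {
                        "participant_id": pid,
                        "phase": phase,
                        "tracker": "*",
                        "reason": "missing_criterion_stream",
                        "n_pairs": 0,
                    }
                )
                continue
            per_tracker = []
            for tracker in TRACKERS:
                tes = epochs.get((pid, tracker, phase))
                if tes is None:
                    excl_rows.append(
                        {
                            "participant_id": pid,
                            "phase": phase,
                            "tracker": tracker,
                            "reason": "missing_tracker_stream",
                            "n_pairs": 0,
                        }
                    )
                    continue
                per_tracker.append(match_pairs(crit, tes))
            if config.complete_triplets and len(per_tracker) == len(TRACKERS):
                per_tracker = restrict_complete_triplets(per_tracker)
            for m in per_tracker:
                incl = apply_inclusion(m, phase, min_minutes[phase])
                if incl.included:
                    matched[(phase, m.tracker_device_id)].append(m)
                else:
                    excl_rows.append(
                        {
                            "participant_id": pid,
                            "phase": phase,
                            "tracker": m.tracker_device_id,
                            "reason": incl.reason,
                            "n_pairs": incl.n_pairs,
                        }
                    )

    # laboratory Pearson-r outlier screen, per tracker
    outlier_status: dict[str, dict[str, str]] = {}
    for tracker in TRACKERS:
        lab_by_pid = {m.participant_id: m for m in matched.get(("lab", tracker), [])}
        outlier_status[tracker] = agr.flag_outliers(lab_by_pid)
    if config.exclude_outliers:
        for (phase, tracker), sets in matched.items():
            flagged = {
                pid
                for pid, st in outlier_status[tracker].items()
                if st == "flagged"
            }
            kept = []
            for m in sets:
                if m.participant_id in flagged:
                    excl_rows.append(
                        {
                            "participant_id": m.participant_id,
                            "phase": phase,
                            "tracker": tracker,
                            "reason": "lab_pearson_r_below_0.3",
                            "n_pairs": len(m),
                        }
                    )
                else:
                    kept.append(m)
            matched[(phase, tracker)] = kept

    agr_rows, dec_frames, conf_rows = [], [], []
    for phase in config.phases:
        for tracker in TRACKERS:
            sets = matched.get((phase, tracker), [])
            n_total = sum(len(m) for m in sets)
            if n_total < 10:
                continue
            try:
                res = agr.compute_agreement(sets)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"agree[{phase},{tracker}]: {exc}") from exc
            agr_rows.append(
                {"phase": phase, "tracker": tracker, "scope": "pooled", **res.summary()}
            )
            for m in sets:  # per-participant summaries alongside pooled rows
                if len(m) >= 3:
                    em = agr.error_metrics(m)
                    agr_rows.append(
                        {
                            "phase": phase,
                            "tracker": tracker,
                            "scope": m.participant_id,
                            "mae_bpm": round(em.mae_bpm, 1),
                            "mape_percent": round(em.mape_percent, 1),
                            "mean_diff_bpm": round(em.mean_diff_bpm, 1),
                            "n_pairs": em.n_pairs,
                        }
                    )
            try:
                dtab = dec.decile_table(sets)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"deciles[{phase},{tracker}]: {exc}") from exc
            dtab.insert(0, "tracker", tracker)
            dtab.insert(0, "phase", phase)
            dec_frames.append(dtab)
            try:
                ct = zon.confusion(sets, roster, config.cutoff_fraction)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"zones[{phase},{tracker}]: {exc}") from exc
            conf_rows.append({"phase": phase, "tracker": tracker, **ct.to_dict()})

    agreement_df = pd.DataFrame(agr_rows)
    deciles_df = (
        pd.concat(dec_frames, ignore_index=True) if dec_frames else pd.DataFrame()
    )
    confusion_df = pd.DataFrame(conf_rows)
    exclusions_df = pd.DataFrame(
        excl_rows, columns=["participant_id", "phase", "tracker", "reason", "n_pairs"]
    )

    paths = {
        "agreement_csv": out / "agreement.csv",
        "agreement_json": out / "agreement.json",
        "deciles_csv": out / "deciles.csv",
        "confusion_csv": out / "confusion.csv",
        "exclusions_csv": out / "exclusions.csv",
        "wear_csv": out / "wear_time.csv",
        "pairs_csv": out / "matched_pairs.csv",
        "manifest_json": out / "manifest.json",
    }
    agreement_df.to_csv(paths["agreement_csv"], index=False)
    paths["agreement_json"].write_text(
        json.dumps(agr_rows, indent=2, default=str) + "\n"
    )
    deciles_df.to_csv(paths["deciles_csv"], index=False)
    confusion_df.to_csv(paths["confusion_csv"], index=False)
    exclusions_df.to_csv(paths["exclusions_csv"], index=False)
    wear_df.to_csv(paths["wear_csv"], index=False)
    write_pairs([m for sets in matched.values() for m in sets], paths["pairs_csv"])
    config_dict = asdict(config)
    config_dict.pop("out_dir")  # manifest describes the analysis, not the location
    manifest = {
        "config": json.loads(json.dumps(config_dict, default=str)),
        "config_sha256": config.digest(),
        "n_participants": len(participants),
        "outlier_status": outlier_status,
    }
    paths["manifest_json"].write_text(json.dumps(manifest, indent=2) + "\n")

    return ReportBundle(
        agreement=agreement_df,
        deciles=deciles_df,
        confusion=confusion_df,
        exclusions=exclusions_df,
        wear=wear_df,
        pairs=matched,
        outlier_status=outlier_status,
        paths=paths,
    )
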