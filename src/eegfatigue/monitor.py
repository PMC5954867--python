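"""End-to-end fatigue monitor: clean -> epoch -> features -> score -> alarm.

The monitor streams a recording through the full pipeline and logs one
JSON object per epoch.  Epochs still violating the 50 microvolt rule
after cleaning are skipped (their spectra would corrupt the deviation
statistic) and logged as such rather than scored.  An alarm event is
recorded for exactly the epochs whose combined deviation D_C strictly
exceeds the threshold in force; "alarm" is a structured log event, not
a sound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import DEFAULT_FATIGUE_THRESHOLD, debounced_alarms
from .features import band_feature_vector, decompose
from .io import EEGRecord, epoch_stream
from .preprocessing import ARTIFACT_CUTOFF_UV, BSSArtifactRemover, flag_artifacts
from .scoring import FatigueScorer, score_epoch

__all__ = ["MonitorConfig", "AlarmEvent", "MonitorResult", "run_monitor", "audit_log"]


@dataclass
class MonitorConfig:
    """Monitor pipeline settings."""

    epoch_length: float = 2.0
    sigma: float = 0.5
    threshold: float = DEFAULT_FATIGUE_THRESHOLD
    cutoff: float = ARTIFACT_CUTOFF_UV
    channel: int = 0
    debounce: int = 1
    apply_bss: bool = True
    embed_dim: int = 16


@dataclass
class AlarmEvent:
    """One fatigue alarm."""

    epoch_index: int
    time_offset: float
    d_c: float
    threshold: float


@dataclass
class MonitorResult:
    """Outcome of a monitoring run.

    ``scores`` has one row per scored epoch; skipped (artifact) epochs
    appear only in the counters and the log.  Invariant:
    ``n_scored + n_skipped == n_epochs``.
    """

    scores: pd.DataFrame
    events: list[AlarmEvent] = field(default_factory=list)
    n_epochs: int = 0
    n_skipped: int = 0
    threshold: float = DEFAULT_FATIGUE_THRESHOLD

    @property
    def n_scored(self) -> int:
        return len(self.scores)

    @property
    def n_alarms(self) -> int:
        return len(self.events)

    def summary(self) -> dict:
        return {
            "epochs": self.n_epochs,
            "scored": self.n_scored,
            "skipped": self.n_skipped,
            "alarms": self.n_alarms,
            "threshold": self.threshold,
        }


def run_monitor(
    record: EEGRecord,
    baseline: FatigueScorer,
    config: MonitorConfig | None = None,
    log_path=None,
) -> MonitorResult:
    """Run the full monitoring pipeline over a recording.

    Parameters
    ----------
    record : EEGRecord
        The session to monitor (file input; processing is epoch by
        epoch in input order and deterministic).
    baseline : FatigueScorer
        Fitted alert-state baseline; fit one with
        :func:`eegfatigue.scoring.fit_baseline` or the ``calibrate``
        CLI command first.
    config : MonitorConfig
    log_path : path, optional
        JSON-lines log, one object per epoch plus a final summary.
    """
    if config is None:
        config = MonitorConfig()
    if not hasattr(baseline, "mu_theta_"):
        raise ValueError(
            "baseline is not fitted; run calibration (fit_baseline / the "
            "'calibrate' command) before monitoring"
        )
    work = record
    if config.apply_bss:
        remover = BSSArtifactRemover(cutoff=config.cutoff, embed_dim=config.embed_dim)
        work, _ = remover.clean(record)

    epochs = epoch_stream(work, epoch_length=config.epoch_length)
    rows: list[dict] = []
    log_rows: list[dict] = []
    n_skipped = 0
    for ep in epochs:
        entry: dict = {"epoch": ep.index, "t": round(ep.start_offset, 6)}
        mask = flag_artifacts(ep.data[config.channel], cutoff=config.cutoff)
        if mask.any_flagged:
            n_skipped += 1
            entry.update(skipped=True, reason="amplitude>cutoff")
            log_rows.append(entry)
            continue
        dec = decompose(ep, work.sfreq, channel=config.channel)
        feats = band_feature_vector(dec, epoch_index=ep.index)
        score = score_epoch(feats, baseline, sigma=config.sigma)
        entry.update(
            skipped=False,
            d_theta=score.d_theta,
            d_alpha=score.d_alpha,
            d_c=score.d_c,
        )
        rows.append(
            {
                "epoch": ep.index,
                "t": ep.start_offset,
                "d_theta": score.d_theta,
                "d_alpha": score.d_alpha,
                "d_c": score.d_c,
            }
        )
        log_rows.append(entry)

    scores = pd.DataFrame(rows, columns=["epoch", "t", "d_theta", "d_alpha", "d_c"])
    raw_alarms = scores["d_c"].to_numpy() > config.threshold
    alarms = debounced_alarms(raw_alarms, config.debounce)
    events = [
        AlarmEvent(
            epoch_index=int(scores["epoch"][i]),
            time_offset=float(scores["t"][i]),
            d_c=float(scores["d_c"][i]),
            threshold=config.threshold,
        )
        for i in np.flatnonzero(alarms)
    ]
    scores["alarm"] = alarms
    alarm_by_epoch = dict(zip(scores["epoch"], alarms))
    for entry in log_rows:
        if not entry.get("skipped", False):
            entry["alarm"] = bool(alarm_by_epoch[entry["epoch"]])
            entry["threshold"] = config.threshold

    result = MonitorResult(
        scores=scores,
        events=events,
        n_epochs=len(epochs),
        n_skipped=n_skipped,
        threshold=config.threshold,
    )
    if log_path is not None:
        with open(log_path, "w") as fh:
            for entry in log_rows:
                fh.write(json.dumps(entry) + "\n")
            fh.write(json.dumps({"summary": result.summary()}) + "\n")
    return result


def audit_log(log_path) -> bool:
    """Post-hoc consistency audit of a monitor log: every alarm row
    must satisfy d_c > threshold and every non-alarm scored row must
    not.  Returns True if consistent, raises otherwise."""
    n_rows = n_skipped = 0
    summary = None
    for line in Path(log_path).read_text().splitlines():
        obj = json.loads(line)
        if "summary" in obj:
            summary = obj["summary"]
            continue
        n_rows += 1
        if obj.get("skipped"):
            n_skipped += 1
            continue
        if obj["alarm"] and not obj["d_c"] > obj["threshold"]:
            raise AssertionError(f"alarm without exceedance at epoch {obj['epoch']}")
    if summary is not None and summary["scored"] + summary["skipped"] != summary["epochs"]:
        raise AssertionError("log summary counters inconsistent")
    if summary is not None and n_rows != summary["epochs"]:
        raise AssertionError("log row count does not match summary")
    return True
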