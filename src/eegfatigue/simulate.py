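"""Synthetic EEG sessions, artifacts, and peg-transfer trial series.

The EEG generator builds band-structured signals as sums of
narrowband-filtered Gaussian noise (delta/theta/alpha/beta) plus a
broadband noise floor, with a per-epoch fatigue "drift" that scales the
theta- and alpha-band amplitudes.  The default direction of change is a
*decrease* of theta/alpha power with growing fatigue.  The trial
generator produces learning-curve series (errors, completion time,
subjective fatigue) from piecewise-linear phase models with optional
Gaussian noise, clipped at zero below and at the simulator cap (300 s
for completion time) above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EEGRecord

__all__ = [
    "SimConfig",
    "Phase",
    "BANDS",
    "DEFAULT_BAND_AMPLITUDES",
    "TRIAL_TIME_CAP",
    "DEFAULT_ERROR_PHASES",
    "DEFAULT_FATIGUE_PHASES",
    "DEFAULT_COMPLETION_TIME_PHASES",
    "simulate_eeg",
    "inject_artifacts",
    "simulate_trials",
    "step_trajectory",
    "ramp_trajectory",
]

#: Nominal EEG rhythm bands in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 11.0),
    "beta": (12.0, 30.0),
}

#: Default per-band RMS amplitudes (microvolts) for an awake forehead
#: recording: alpha-dominant with moderate theta and weak beta.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 4.0,
    "theta": 6.0,
    "alpha": 8.0,
    "beta": 3.0,
}

#: Simulator cap on peg-transfer completion time, seconds.
TRIAL_TIME_CAP = 300.0


class Phase(NamedTuple):
    """One linear segment ``value = intercept + slope * trial`` over
    inclusive 1-based trials ``start..end``."""

    start: int
    end: int
    intercept: float
    slope: float


#: Three-phase error learning curve: steep skill acquisition, a plateau
#: near two errors, then a fatigue-driven rise from trial 13.
DEFAULT_ERROR_PHASES = [
    Phase(1, 7, 12.13, -1.4),
    Phase(8, 12, 3.34, -0.13),
    Phase(13, 20, -5.96, 0.62),
]

#: Subjective fatigue trajectory: gradual build-up, a fluctuation
#: plateau near 3.6, then a sharp late rise from trial 14.
DEFAULT_FATIGUE_PHASES = [
    Phase(1, 9, 2.35, 0.15),
    Phase(10, 13, 3.6, 0.0),
    Phase(14, 20, 3.15, 0.212),
]

#: Completion-time curve reconstructed from its printed anchors
#: (about 130 s on the first trial, a minimum near 92 s around trial
#: 14, rising to about 110 s by trial 20).
DEFAULT_COMPLETION_TIME_PHASES = [
    Phase(1, 13, 135.0, -3.3),
    Phase(14, 20, 50.0, 3.0),
]


@dataclass
class SimConfig:
    """Configuration of the synthetic EEG generator.

    Parameters
    ----------
    sampling_rate : float
        Hz; 512 by default (typical of consumer forehead headsets, and
        dyadic-friendly for wavelet analysis).
    duration : float
        Session length in seconds; must be a multiple of
        ``epoch_length``.
    band_amplitudes : dict
        Band name -> RMS amplitude in microvolts.
    noise_rms : float
        Broadband (white) noise floor, microvolts RMS.
    epoch_length : float
        Seconds per analysis epoch; the fatigue trajectory has one
        value per epoch.
    fatigue_gain : float
        Fractional amplitude change of the theta/alpha bands at full
        drift (drift = 1).
    direction : int
        -1 (default): theta/alpha power decreases with fatigue;
        +1 flips the sign for sensitivity analyses.
    mains_freq : float
        Power-line frequency in Hz used by the line-noise artifact.
    seed : int
        Seed for all randomness in the generator.
    """

    sampling_rate: float = 512.0
    duration: float = 60.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    noise_rms: float = 2.0
    epoch_length: float = 2.0
    fatigue_gain: float = 0.6
    direction: int = -1
    mains_freq: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if any(a < 0 for a in self.band_amplitudes.values()) or self.noise_rms < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be -1 or +1")
        n = self.duration / self.epoch_length
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be an integer number of epochs")

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration / self.epoch_length))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def step_trajectory(n_epochs: int, step_at: int, level: float = 1.0) -> np.ndarray:
    """Drift 0 for epochs before ``step_at``, ``level`` afterwards."""
    traj = np.zeros(n_epochs)
    traj[step_at:] = level
    return traj


def ramp_trajectory(n_epochs: int, level: float = 1.0) -> np.ndarray:
    """Drift rising linearly from 0 to ``level`` over the session."""
    return np.linspace(0.0, level, n_epochs)


def _band_noise(rng: np.random.Generator, n: int, sfreq: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to (lo, hi) Hz."""
    white = rng.standard_normal(n)
    nyq = sfreq / 2
    hi = min(hi, 0.99 * nyq)
    sos = sps.butter(6, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
    shaped = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def simulate_eeg(
    config: SimConfig, trajectory: np.ndarray | None = None
) -> tuple[EEGRecord, np.ndarray]:
    """Generate a single-channel EEG session with a fatigue trajectory.

    Parameters
    ----------
    config : SimConfig
    trajectory : array of shape (n_epochs,), optional
        Per-epoch drift level in [0, 1]; all-zero (fully alert) by
        default.  Epochs with drift 0 are labeled ``"alert"``, others
        ``"fatigued"``; the theta/alpha band amplitudes of an epoch are
        scaled by ``1 + direction * fatigue_gain * drift``.

    Returns
    -------
    record : EEGRecord
        One channel, ``config.duration`` seconds at
        ``config.sampling_rate``.
    labels : ndarray of str
        Per-epoch state labels, ``"alert"`` or ``"fatigued"``.
    """
    n_epochs = config.n_epochs
    if trajectory is None:
        trajectory = np.zeros(n_epochs)
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.shape != (n_epochs,):
        raise ValueError(
            f"trajectory length {trajectory.shape} does not match {n_epochs} epochs"
        )
    if np.any((trajectory < 0) | (trajectory > 1)):
        raise ValueError("drift levels must lie in [0, 1]")

    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sfreq = config.sampling_rate
    epoch_samples = int(round(config.epoch_length * sfreq))

    # per-sample scaling envelope for the fatigue-sensitive bands
    scale = 1.0 + config.direction * config.fatigue_gain * trajectory
    scale = np.clip(scale, 0.05, None)
    envelope = np.repeat(scale, epoch_samples)

    total = np.zeros(n)
    for band, amp in config.band_amplitudes.items():
        if amp <= 0:
            continue
        lo, hi = BANDS[band]
        component = amp * _band_noise(rng, n, sfreq, lo, hi)
        if band in ("theta", "alpha"):
            component = component * envelope
        total += component
    if config.noise_rms > 0:
        total += config.noise_rms * rng.standard_normal(n)

    record = EEGRecord(total[np.newaxis, :], sfreq=sfreq, ch_names=["FP1"])
    labels = np.where(trajectory > 0, "fatigued", "alert")
    return record, labels


# ---------------------------------------------------------------------------
# Artifacts


@dataclass
class ArtifactEvent:
    """Location of one injected artifact, as a sample slice."""

    kind: str
    start: int
    stop: int


def _place_disjoint(
    rng: np.random.Generator, n: int, width: int, count: int
) -> list[int]:
    """Random disjoint start indices for `count` events of `width` samples."""
    if count * width * 2 > n:
        raise ValueError(f"cannot place {count} disjoint events of {width} samples")
    starts: list[int] = []
    for _ in range(10_000):
        if len(starts) == count:
            break
        cand = int(rng.integers(0, n - width))
        if all(abs(cand - s) >= 2 * width for s in starts):
            starts.append(cand)
    else:
        raise RuntimeError("failed to place disjoint artifact events")
    return sorted(starts)


def inject_artifacts(
    record: EEGRecord,
    kind: str,
    count: int,
    seed: int = 0,
    mains_freq: float = 50.0,
    line_rms: float = 25.0,
) -> tuple[EEGRecord, list[ArtifactEvent]]:
    """Return a copy of ``record`` with artifact events added.

    Kinds
    -----
    ``"blink"``
        300 ms raised-cosine pulses, peak 100-150 microvolts (well
        above the 50 microvolt artifact criterion).
    ``"spike"``
        20 ms triangular muscle-like transients, peak 80-150
        microvolts, random sign.
    ``"line"``
        A continuous mains-frequency sinusoid over the whole record
        (``count > 0`` switches it on; its RMS is ``line_rms``).
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    out = record.copy()
    events: list[ArtifactEvent] = []
    if count == 0:
        return out, events
    rng = np.random.default_rng(seed)
    n = out.n_samples
    sfreq = out.sfreq

    if kind == "blink":
        width = int(round(0.3 * sfreq))
        pulse = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / (width - 1)))
        for start in _place_disjoint(rng, n, width, count):
            peak = rng.uniform(100.0, 150.0)
            out.data[:, start : start + width] += peak * pulse
            events.append(ArtifactEvent("blink", start, start + width))
    elif kind == "spike":
        width = max(3, int(round(0.02 * sfreq)))
        half = width // 2
        pulse = 1 - np.abs(np.arange(width) - half) / half
        for start in _place_disjoint(rng, n, width, count):
            peak = rng.uniform(80.0, 150.0) * rng.choice([-1.0, 1.0])
            out.data[:, start : start + width] += peak * pulse
            events.append(ArtifactEvent("spike", start, start + width))
    elif kind == "line":
        t = out.times()
        phase = rng.uniform(0, 2 * np.pi)
        out.data += line_rms * np.sqrt(2) * np.sin(2 * np.pi * mains_freq * t + phase)
        events.append(ArtifactEvent("line", 0, n))
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")
    return out, events


# ---------------------------------------------------------------------------
# Trial series


def _validate_phases(phases: Sequence[Phase]) -> list[Phase]:
    phases = [Phase(*p) for p in phases]
    for p in phases:
        if p.end < p.start:
            raise ValueError(f"phase {p} has end < start")
    for a, b in zip(phases, phases[1:]):
        if b.start <= a.end:
            raise ValueError(f"phases {a} and {b} overlap")
        if b.start != a.end + 1:
            raise ValueError(f"phases {a} and {b} are not contiguous")
    return phases


def simulate_trials(
    phases: Sequence[Phase | tuple],
    noise_sd: float = 0.0,
    cap: float | None = TRIAL_TIME_CAP,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a trial-metric series from piecewise-linear phase models.

    Each trial's value is ``intercept + slope * trial`` for its phase,
    plus Gaussian noise of standard deviation ``noise_sd``, clipped at
    0 below and at ``cap`` above (``cap=None`` disables the upper
    clip).  With ``noise_sd=0`` and values inside the clip range, the
    line is reproduced exactly.

    Returns
    -------
    DataFrame with columns ``trial`` (1-based, strictly increasing) and
    ``value``.
    """
    phases = _validate_phases(phases)
    rng = np.random.default_rng(seed)
    rows = []
    for p in phases:
        trials = np.arange(p.start, p.end + 1)
        values = p.intercept + p.slope * trials
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=trials.size)
        values = np.clip(values, 0.0, cap if cap is not None else np.inf)
        rows.append(pd.DataFrame({"trial": trials, "value": values}))
    return pd.concat(rows, ignore_index=True)


def simulate_session_trials(
    noise_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """All three peg-transfer metrics for a 20-trial session, using the
    default phase models (errors, completion time capped at 300 s,
    subjective fatigue)."""
    errors = simulate_trials(DEFAULT_ERROR_PHASES, noise_sd, cap=None, seed=seed)
    time = simulate_trials(
        DEFAULT_COMPLETION_TIME_PHASES, noise_sd * 10, cap=TRIAL_TIME_CAP, seed=seed + 1
    )
    fatigue = simulate_trials(DEFAULT_FATIGUE_PHASES, noise_sd, cap=None, seed=seed + 2)
    return pd.DataFrame(
        {
            "trial": errors["trial"],
            "errors": errors["value"],
            "completion_time": time["value"],
            "fatigue_value": fatigue["value"],
        }
    )
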