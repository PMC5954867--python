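"""EEG data containers, file readers/writers, and epoching.

Recordings are held as a channels-by-time matrix of amplitudes in
microvolts together with the sampling rate.  Two on-disk formats are
supported: a plain CSV dialect (header row; first column time in
seconds, one column per channel in microvolts) which round-trips
losslessly, and EDF (European Data Format), which is lossy only by its
16-bit integer quantization.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecord",
    "Epoch",
    "ParseError",
    "EmptyStreamError",
    "read_recording",
    "write_recording",
    "epoch_stream",
]


class ParseError(ValueError):
    """A file did not conform to the expected on-disk format."""


class EmptyStreamError(ValueError):
    """The recording is too short to yield a single analysis epoch."""


@dataclass
class EEGRecord:
    """A multichannel EEG recording.

    Parameters
    ----------
    data : ndarray of shape (n_channels, n_samples)
        Amplitudes in microvolts.  A 1-D array is promoted to a single
        channel.
    sfreq : float
        Sampling rate in Hz, strictly positive.
    ch_names : list of str, optional
        Channel labels; defaults to ``EEG1..EEGn``.
    start_time : datetime, optional
        Wall-clock start of the recording.  All analysis uses 0-based
        seconds from record start.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str] = field(default_factory=list)
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a (n_channels, n_samples) matrix")
        if not self.sfreq > 0:
            raise ValueError(f"sampling rate must be positive, got {self.sfreq}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("amplitudes must be finite")
        if not self.ch_names:
            self.ch_names = [f"EEG{i + 1}" for i in range(self.n_channels)]
        if len(self.ch_names) != self.n_channels:
            raise ValueError(
                f"{len(self.ch_names)} channel labels for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.sfreq

    def times(self) -> np.ndarray:
        """Sample times in seconds from record start."""
        return np.arange(self.n_samples) / self.sfreq

    def copy(self) -> "EEGRecord":
        return EEGRecord(
            self.data.copy(), self.sfreq, list(self.ch_names), self.start_time
        )


@dataclass
class Epoch:
    """One fixed-length analysis window cut from a recording."""

    index: int
    data: np.ndarray  # (n_channels, window_samples)
    start_offset: float  # seconds from record start

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# Epoching


def epoch_stream(
    record: EEGRecord, epoch_length: float = 2.0, overlap: float = 0.0
) -> list[Epoch]:
    """Cut a recording into ordered fixed-length epochs.

    The window holds ``W = epoch_length * sfreq`` samples (must be a
    positive integer) and advances by ``S = W * (1 - overlap)`` samples.
    The number of epochs is ``floor((N - W) / S) + 1``; a trailing
    partial window is discarded.

    Raises
    ------
    EmptyStreamError
        If the recording is shorter than one epoch.
    """
    w_float = epoch_length * record.sfreq
    window = int(round(w_float))
    if window <= 0 or abs(w_float - window) > 1e-9:
        raise ValueError(
            f"epoch_length * sfreq must be a positive integer, got {w_float}"
        )
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must lie in [0, 1), got {overlap}")
    step = max(1, int(round(window * (1 - overlap))))
    n = record.n_samples
    if n < window:
        raise EmptyStreamError(
            f"record of {n} samples is shorter than one {window}-sample epoch"
        )
    n_epochs = (n - window) // step + 1
    return [
        Epoch(
            index=i,
            data=record.data[:, i * step : i * step + window].copy(),
            start_offset=i * step / record.sfreq,
        )
        for i in range(n_epochs)
    ]


# ---------------------------------------------------------------------------
# CSV


def _write_csv(path: Path, record: EEGRecord, fmt: str = "%.17g") -> None:
    t = record.times()
    header = ",".join(["time"] + list(record.ch_names))
    body = np.column_stack([t, record.data.T])
    np.savetxt(path, body, delimiter=",", header=header, comments="", fmt=fmt)


def _read_csv(path: Path) -> EEGRecord:
    try:
        frame = pd.read_csv(path, header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise ParseError(f"{path}: not parseable as CSV: {exc}") from exc
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: need a time column plus >=1 channel column")
    numeric = pd.DataFrame(index=frame.index)
    for col in frame.columns:
        values = frame[col]
        try:
            # float() round-trips %.17g text exactly (pandas' fast
            # parser does not)
            numeric[col] = values.map(float)
        except (TypeError, ValueError):
            for i, cell in enumerate(values):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric value {cell!r} in column "
                        f"{col!r} at line {i + 2}"  # header + 1-based
                    ) from None
            raise
        if numeric[col].isna().any():
            row = int(numeric[col].isna().idxmax()) + 2
            raise ParseError(f"{path}: missing value in column {col!r} at line {row}")
    t = numeric.iloc[:, 0].to_numpy()
    if len(t) < 2:
        raise ParseError(f"{path}: at least two samples required")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ParseError(f"{path}: time column is not uniformly increasing")
    sfreq = 1.0 / float(np.median(dt))
    data = numeric.iloc[:, 1:].to_numpy().T
    return EEGRecord(data, sfreq=sfreq, ch_names=list(frame.columns[1:]))


# ---------------------------------------------------------------------------
# EDF (European Data Format): fixed-layout ASCII header + little-endian
# int16 samples.  Written here directly because the format is trivial;
# readers such as MNE interoperate (checked in the test suite).

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(path: Path, record: EEGRecord, phys_range: float | None = None) -> None:
    sfreq_i = int(round(record.sfreq))
    if abs(record.sfreq - sfreq_i) > 1e-9:
        raise ValueError("EDF output requires an integer sampling rate")
    nch = record.n_channels
    spr = sfreq_i  # one-second data records
    n_records = math.ceil(record.n_samples / spr)
    padded = np.zeros((nch, n_records * spr))
    padded[:, : record.n_samples] = record.data

    if phys_range is None:
        phys_range = float(np.max(np.abs(padded))) or 1.0
    # quantize against the range as it is stored (8-char header field),
    # so reader and writer use identical scaling
    pmax = float(f"{phys_range:.6g}"[:8])
    while pmax < phys_range:  # never clip data by header rounding
        phys_range *= 1.00001
        pmax = float(f"{phys_range:.6g}"[:8])
    pmin = -pmax
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)
    digital = np.clip(
        np.round((padded - pmin) * scale) + _EDF_DIG_MIN, _EDF_DIG_MIN, _EDF_DIG_MAX
    ).astype("<i2")

    start = record.start_time or datetime(2000, 1, 1)
    header = b"".join(
        [
            _ascii(0, 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii(start.strftime("%d.%m.%y"), 8),
            _ascii(start.strftime("%H.%M.%S"), 8),
            _ascii(256 + 256 * nch, 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),
            _ascii(nch, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_ascii(name, 16) for name in record.ch_names),
            b"".join(_ascii("", 80) for _ in range(nch)),
            b"".join(_ascii("uV", 8) for _ in range(nch)),
            b"".join(_ascii(f"{pmin:.6g}"[:8], 8) for _ in range(nch)),
            b"".join(_ascii(f"{pmax:.6g}"[:8], 8) for _ in range(nch)),
            b"".join(_ascii(_EDF_DIG_MIN, 8) for _ in range(nch)),
            b"".join(_ascii(_EDF_DIG_MAX, 8) for _ in range(nch)),
            b"".join(_ascii("", 80) for _ in range(nch)),
            b"".join(_ascii(spr, 8) for _ in range(nch)),
            b"".join(_ascii("", 32) for _ in range(nch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def _read_edf(path: Path) -> EEGRecord:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise ParseError(f"{path}: truncated EDF header")

    def f(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", "replace").strip()

    try:
        n_records = int(f(236, 8))
        record_dur = float(f(244, 8))
        nch = int(f(252, 4))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed EDF header field: {exc}") from exc
    base = 256
    labels = [f(base + 16 * i, 16) for i in range(nch)]
    off = base + nch * (16 + 80 + 8)
    pmin = [float(f(off + 8 * i, 8)) for i in range(nch)]
    off += nch * 8
    pmax = [float(f(off + 8 * i, 8)) for i in range(nch)]
    off += nch * 8
    dmin = [int(f(off + 8 * i, 8)) for i in range(nch)]
    off += nch * 8
    dmax = [int(f(off + 8 * i, 8)) for i in range(nch)]
    off += nch * 8 + nch * 80
    spr = [int(f(off + 8 * i, 8)) for i in range(nch)]
    if len(set(spr)) != 1:
        raise ParseError(f"{path}: per-channel sampling rates differ: {spr}")
    header_bytes = 256 + 256 * nch
    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expected = n_records * sum(spr)
    if body.size != expected:
        raise ParseError(
            f"{path}: expected {expected} samples in data records, found {body.size}"
        )
    chans = [np.empty(n_records * spr[c], dtype=float) for c in range(nch)]
    pos = 0
    for r in range(n_records):
        for c in range(nch):
            seg = body[pos : pos + spr[c]].astype(np.float64)
            gain = (pmax[c] - pmin[c]) / (dmax[c] - dmin[c])
            chans[c][r * spr[c] : (r + 1) * spr[c]] = (seg - dmin[c]) * gain + pmin[c]
            pos += spr[c]
    sfreq = spr[0] / record_dur
    return EEGRecord(np.vstack(chans), sfreq=sfreq, ch_names=labels)


def edf_quantization_step(phys_range: float) -> float:
    """Amplitude resolution of an EDF file written with the given
    symmetric physical range (microvolts per digital unit)."""
    return 2 * phys_range / (_EDF_DIG_MAX - _EDF_DIG_MIN)


# ---------------------------------------------------------------------------
# Dispatch


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


def read_recording(path, format: str | None = None) -> EEGRecord:
    """Read an EEG recording from CSV or EDF."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_recording(
    path, record: EEGRecord, format: str | None = None, phys_range: float | None = None
) -> None:
    """Write an EEG recording to CSV (lossless) or EDF (16-bit quantized).

    ``phys_range`` sets the symmetric EDF amplitude range in microvolts;
    by default the maximum absolute amplitude is used.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(path, record)
    elif fmt == "edf":
        _write_edf(path, record, phys_range=phys_range)
    else:
        raise ValueError(f"unknown format {fmt!r}")
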