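"""Time-domain DEER traces: containers, file I/O and pre-processing.

Trace files are plain two-column (or three-column, with an imaginary part)
delimited text. Time is stored in us internally; files in ns are detected by
magnitude and converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numpy.typing import NDArray
from scipy.signal import savgol_filter

__all__ = ["DipolarTrace", "TraceSet", "read_trace", "write_trace", "truncate_end"]

MIN_POINTS = 50


@dataclass
class DipolarTrace:
    """One dipolar evolution trace, time zero-aligned and scale-normalised."""

    time_us: NDArray[np.float64]
    signal: NDArray[np.float64]
    noise_sd: float | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_us = np.asarray(self.time_us, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_us.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if self.time_us.size < MIN_POINTS:
            raise ValueError(f"trace needs >= {MIN_POINTS} points, got {self.time_us.size}")
        if np.any(np.diff(self.time_us) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def t_max(self) -> float:
        return float(self.time_us[-1])

    def __len__(self) -> int:
        return self.time_us.size

    def estimate_noise(self) -> float:
        """Noise level from the high-frequency residual of a moving polynomial fit."""
        window = min(17, (len(self) // 2) * 2 - 1)
        smooth = savgol_filter(self.signal, window_length=window, polyorder=3)
        return float(np.std(self.signal - smooth, ddof=1))

    def with_noise_estimate(self) -> "DipolarTrace":
        if self.noise_sd is not None:
            return self
        return replace(self, noise_sd=self.estimate_noise())


@dataclass
class TraceSet:
    """1-6 traces of the same sample, to be fitted with one shared P(r)."""

    traces: list[DipolarTrace]
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("trace set must contain at least one trace")
        if len(self.traces) > 6:
            raise ValueError("trace set supports at most 6 traces")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)


def _phase_correct(real: NDArray, imag: NDArray) -> NDArray:
    """Rotate the complex signal so the imaginary channel has minimal RMS."""
    z = real + 1j * imag
    # analytic minimiser: phase of sum(z^2) halved, then sign fixed
    phi = 0.5 * np.angle(np.sum(z**2))
    rot = z * np.exp(-1j * phi)
    if np.sum(rot.real) < 0:
        rot = -rot
    return rot.real


def read_trace(path: str | Path, time_unit: str = "auto", label: str | None = None) -> DipolarTrace:
    """Read a two- or three-column delimited text trace.

    Time units are auto-detected by magnitude (max > 100 is taken as ns) and
    converted to us; the time axis is shifted to start at zero and the signal
    scaled so that the first point is 1. A third column is treated as the
    imaginary channel, phase-rotated to minimise its RMS and then discarded.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "%", "//")):
                continue
            parts = stripped.replace(",", " ").split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row: {stripped!r}") from exc
    if len(rows) < MIN_POINTS:
        raise ValueError(f"{path}: fewer than {MIN_POINTS} data rows")
    ncol = len(rows[0])
    if ncol not in (2, 3) or any(len(r) != ncol for r in rows):
        raise ValueError(f"{path}: expected 2 or 3 columns in every row")
    data = np.array(rows, dtype=float)
    t, sig = data[:, 0], data[:, 1]
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2
        raise ValueError(f"{path}: time axis not strictly increasing near row {bad}")
    if ncol == 3:
        sig = _phase_correct(sig, data[:, 2])
    if time_unit == "auto":
        time_unit = "ns" if t.max() > 100.0 else "us"
    if time_unit == "ns":
        t = t / 1000.0
    elif time_unit != "us":
        raise ValueError(f"unknown time unit {time_unit!r}")
    t = t - t[0]
    if sig[0] == 0:
        raise ValueError(f"{path}: first signal point is zero, cannot normalise")
    sig = sig / sig[0]
    return DipolarTrace(t, sig, label=label or path.stem)


def write_trace(trace: DipolarTrace, path: str | Path) -> None:
    """Write a trace as two-column text (time us, signal), full precision."""
    np.savetxt(
        path,
        np.column_stack([trace.time_us, trace.signal]),
        fmt="%.17g",
        header="time_us signal",
    )


def truncate_end(trace: DipolarTrace, n_points: int) -> DipolarTrace:
    """Drop the last ``n_points`` samples (removal of '2+1' end artefacts)."""
    if n_points < 0 or len(trace) - n_points < MIN_POINTS:
        raise ValueError(
            f"cannot truncate {n_points} of {len(trace)} points "
            f"(at least {MIN_POINTS} must remain)"
        )
    if n_points == 0:
        return trace
    meta = dict(trace.meta)
    meta["truncated_points"] = meta.get("truncated_points", 0) + n_points
    return DipolarTrace(
        trace.time_us[:-n_points].copy(),
        trace.signal[:-n_points].copy(),
        noise_sd=trace.noise_sd,
        label=trace.label,
        meta=meta,
    )
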