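"""Trace container, normalization, phase segmentation and detrending.

An FMSF-PORH recording is a single fluorescence time series on a uniform
grid with three protocol phases: a resting baseline, a 3-minute brachial
occlusion, and a reperfusion period after cuff release.  Analysis-ready
segments are produced by (1) dividing by the baseline mean so the signal is
dimensionless with baseline level 1, (2) cutting the trace at the phase
markers (skipping a guard interval after release so the hyperemic transient
is not mistaken for oscillation), and (3) subtracting a slow trend from each
segment before spectral estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FMSFTrace",
    "PhaseSegmentation",
    "normalize_trace",
    "segment_phases",
    "detrend_segment",
]

#: Minimum usable window for spectral analysis, seconds.
MIN_SPECTRAL_WINDOW = 60.0


@dataclass(frozen=True)
class FMSFTrace:
    """Uniformly sampled fluorescence trace with protocol phase markers.

    ``time`` is in seconds on a strictly increasing uniform grid;
    ``fluorescence`` is in arbitrary device units (dimensionless after
    :func:`normalize_trace`).  Markers satisfy
    ``0 < occlusion_start < occlusion_end < record_end``.
    """

    time: np.ndarray
    fluorescence: np.ndarray
    occlusion_start: float
    occlusion_end: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)
        if t.ndim != 1 or t.size < 2 or f.shape != t.shape:
            raise ValueError("time and fluorescence must be 1-D arrays of equal length >= 2")
        if not (np.isfinite(t).all() and np.isfinite(f).all()):
            raise ValueError("trace contains non-finite samples")
        dt = np.diff(t)
        if not (dt > 0).all():
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")
        if not (0.0 < self.occlusion_start < self.occlusion_end < self.record_end):
            raise ValueError(
                "phase markers must satisfy 0 < occlusion_start < occlusion_end < record_end"
            )

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def record_end(self) -> float:
        """Exclusive end of the record (last sample time + one step)."""
        t = self.time
        return float(t[-1] + (t[1] - t[0]))

    def window_values(self, start: float, end: float) -> np.ndarray:
        """Samples with ``start <= t < end`` (half-open convention)."""
        mask = (self.time >= start) & (self.time < end)
        return self.fluorescence[mask]


@dataclass(frozen=True)
class PhaseSegmentation:
    """Half-open ``[start, end)`` windows, ordered and non-overlapping."""

    baseline_window: tuple[float, float]
    occlusion_window: tuple[float, float]
    reperfusion_window: tuple[float, float]

    def __post_init__(self) -> None:
        b, o, r = self.baseline_window, self.occlusion_window, self.reperfusion_window
        for lo, hi in (b, o, r):
            if not hi > lo:
                raise ValueError("windows must have positive length")
        if not (b[1] <= o[0] and o[1] <= r[0]):
            raise ValueError("windows must be ordered and non-overlapping")

    @property
    def guard_seconds(self) -> float:
        return self.reperfusion_window[0] - self.occlusion_window[1]


def normalize_trace(trace: FMSFTrace) -> FMSFTrace:
    """Divide by the mean over the baseline phase.

    The result is dimensionless with baseline mean exactly 1, which makes
    every downstream quantity (band powers, VM, HS, IR_max, HR_max)
    invariant under rescaling of the raw signal.  Raises on a non-positive
    baseline mean (non-physical) or a baseline shorter than 60 s.
    """
    baseline = trace.window_values(0.0, trace.occlusion_start)
    if trace.occlusion_start < MIN_SPECTRAL_WINDOW:
        raise ValueError(
            f"baseline phase is {trace.occlusion_start:g} s; "
            f">= {MIN_SPECTRAL_WINDOW:g} s required for normalization"
        )
    mean = float(baseline.mean())
    if mean <= 0.0:
        raise ValueError(f"baseline mean {mean:g} is not positive; non-physical signal")
    return replace(trace, fluorescence=trace.fluorescence / mean)


def segment_phases(trace: FMSFTrace, guard_seconds: float = 30.0) -> PhaseSegmentation:
    """Cut the trace at its phase markers.

    ``guard_seconds`` (default 30) is skipped at the start of reperfusion so
    the hyperemic dip/transient after cuff release does not contaminate the
    reperfusion spectrum.  The reperfusion window must retain at least 60 s.
    """
    if guard_seconds < 0:
        raise ValueError("guard_seconds must be >= 0")
    rep_start = trace.occlusion_end + guard_seconds
    rep_len = trace.record_end - rep_start
    if rep_len < MIN_SPECTRAL_WINDOW:
        raise ValueError(
            f"reperfusion window is {rep_len:g} s after a {guard_seconds:g} s guard; "
            f">= {MIN_SPECTRAL_WINDOW:g} s required"
        )
    return PhaseSegmentation(
        baseline_window=(0.0, trace.occlusion_start),
        occlusion_window=(trace.occlusion_start, trace.occlusion_end),
        reperfusion_window=(rep_start, trace.record_end),
    )


def _triangular_trend(x: np.ndarray, half_width: int) -> np.ndarray:
    """Centered triangular-weighted moving average.

    Equivalent to two cascaded flat averages of ``half_width`` samples.
    The segment is extended by antisymmetric (odd) reflection before
    convolving, so linear trends are estimated exactly all the way to the
    endpoints and oscillations are not tapered at the segment edges.
    """
    h = half_width
    w = (h + 1 - np.abs(np.arange(-h, h + 1))).astype(float)
    w /= w.sum()
    padded = np.pad(x, h, mode="reflect", reflect_type="odd")
    return np.convolve(padded, w, mode="valid")


def detrend_segment(
    segment: np.ndarray, cutoff_frequency: float, sampling_rate: float
) -> np.ndarray:
    """Remove the slow baseline trend below ``cutoff_frequency``.

    Subtracts a centered moving-average trend estimate with triangular
    weights of half-width ``1/cutoff_frequency`` seconds.  The subtraction
    transfer function is ``1 - sinc^2(f/cutoff)``: components below the
    cutoff (drift, the slow hyperemic recovery) are removed, while any
    sinusoid at ``f >= 2*cutoff`` keeps its amplitude to within ~2% --
    in particular the whole myogenic band for the default 0.03 Hz cutoff.

    The segment must span at least ``2/cutoff_frequency`` seconds.
    """
    x = np.asarray(segment, dtype=float)
    if cutoff_frequency <= 0:
        raise ValueError("cutoff_frequency must be positive")
    duration = x.size / sampling_rate
    if duration < 2.0 / cutoff_frequency:
        raise ValueError(
            f"segment of {duration:g} s is too short for a {cutoff_frequency:g} Hz "
            f"cutoff; >= {2.0 / cutoff_frequency:g} s required"
        )
    h = int(round(sampling_rate / cutoff_frequency))
    return x - _triangular_trend(x, h)
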