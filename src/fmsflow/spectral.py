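"""Band-power spectral parameters: VM, HS, band shares, IR_max, HR_max.

The two diagnostic parameters of the FMSF-PORH method are band-integrated
power spectral densities of the normalized fluorescence signal in the
myogenic band (0.052-0.15 Hz), scaled by 1e6:

* ``VM`` -- computed on the resting baseline (normoxia); measures myogenic
  vasomotion at rest.
* ``HS`` -- the same statistic on the reperfusion segment after a 3-minute
  occlusion; measures myogenic activation by transient hypoxia
  ("hypoxia sensitivity").

"Mean squared amplitude" is realized as the one-sided periodogram
integrated over the band, which by Parseval equals the mean square of the
band-limited signal.  Both parameters are reported on a log10 scale for
statistics, since their linear values span orders of magnitude while the
logs are close to normally distributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

from .bands import DEFAULT_BAND_SCHEME, Band, BandScheme
from .trace import FMSFTrace, PhaseSegmentation, detrend_segment, normalize_trace, segment_phases

__all__ = [
    "Spectrum",
    "FlowmotionResult",
    "compute_psd",
    "band_power",
    "compute_vm",
    "compute_hs",
    "log_param",
    "compute_band_shares",
    "compute_ir_hr",
    "analyze_trace",
]

#: VM and HS are band mean-squares of the normalized signal scaled by 1e6.
PSD_SCALE = 1.0e6

#: Default detrend cutoff for myogenic-band analysis (Hz).  Removes drift
#: and the endothelial/neurogenic trend without touching 0.052-0.15 Hz.
MYOGENIC_DETREND_CUTOFF = 0.03

#: Detrend cutoff for full five-band share analysis (Hz); requires a long
#: segment, so it is clamped to 2/duration where necessary.
SHARE_DETREND_CUTOFF = 0.005


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectral density of a detrended segment.

    Normalized so that ``sum(power_density) * df`` equals the mean square
    of the segment (Parseval-exact, rectangular window).
    """

    frequencies: np.ndarray
    power_density: np.ndarray
    segment_duration: float

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    @property
    def total_power(self) -> float:
        return float(self.power_density.sum() * self.df)


def compute_psd(segment: np.ndarray, sampling_rate: float, window: str = "boxcar") -> Spectrum:
    """One-sided periodogram of a (detrended) segment.

    The default rectangular window keeps Parseval bookkeeping exact:
    integrated density equals the segment mean square to machine precision.
    A ``"hann"`` window is available to trade a little bandwidth for lower
    leakage; scipy's density scaling keeps the integral unbiased for
    broadband signals.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 64:
        raise ValueError(f"segment has {x.size} samples; >= 64 required for a spectrum")
    freqs, psd = periodogram(x, fs=sampling_rate, window=window, detrend=False)
    return Spectrum(frequencies=freqs, power_density=psd, segment_duration=x.size / sampling_rate)


def band_power(spectrum: Spectrum, band: Band) -> float:
    """Mean square of the signal in the half-open band ``(lower, upper]``."""
    f = spectrum.frequencies
    mask = (f > band.lower) & (f <= band.upper)
    if not mask.any():
        raise ValueError(
            f"no spectral bins in ({band.lower}, {band.upper}] Hz; segment of at least "
            f"{1.0 / band.width:.0f} s needed to resolve this band"
        )
    return float(spectrum.power_density[mask].sum() * spectrum.df)


def log_param(x: float) -> float:
    """log10 of a (positive) VM/HS value, the scale used for statistics."""
    if not np.isfinite(x) or x <= 0.0:
        raise ValueError(f"log parameter requires a positive finite value, got {x!r}")
    return float(np.log10(x))


def _band_mean_square(
    trace: FMSFTrace,
    window: tuple[float, float],
    band: Band,
    detrend_cutoff: float,
) -> float:
    values = trace.window_values(*window)
    detrended = detrend_segment(values, detrend_cutoff, trace.sampling_rate)
    return band_power(compute_psd(detrended, trace.sampling_rate), band)


def compute_vm(
    trace: FMSFTrace,
    segmentation: PhaseSegmentation | None = None,
    band_scheme: BandScheme = DEFAULT_BAND_SCHEME,
    detrend_cutoff: float = MYOGENIC_DETREND_CUTOFF,
) -> float:
    """Normoxic myogenic parameter: baseline myogenic mean square x 1e6."""
    trace = normalize_trace(trace)
    seg = segmentation or segment_phases(trace)
    return PSD_SCALE * _band_mean_square(
        trace, seg.baseline_window, band_scheme["myogenic"], detrend_cutoff
    )


def compute_hs(
    trace: FMSFTrace,
    segmentation: PhaseSegmentation | None = None,
    band_scheme: BandScheme = DEFAULT_BAND_SCHEME,
    detrend_cutoff: float = MYOGENIC_DETREND_CUTOFF,
) -> float:
    """Hypoxia sensitivity: reperfusion myogenic mean square x 1e6."""
    trace = normalize_trace(trace)
    seg = segmentation or segment_phases(trace)
    return PSD_SCALE * _band_mean_square(
        trace, seg.reperfusion_window, band_scheme["myogenic"], detrend_cutoff
    )


def compute_band_shares(
    spectrum: Spectrum,
    band_scheme: BandScheme = DEFAULT_BAND_SCHEME,
    bands_to_include: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """Fraction of oscillatory power in each band; fractions sum to 1."""
    names = bands_to_include or tuple(band_scheme)
    powers = {name: band_power(spectrum, band_scheme[name]) for name in names}
    total = sum(powers.values())
    if total <= 0.0:
        raise ValueError("total power over the included bands is zero")
    return {name: p / total for name, p in powers.items()}


def compute_ir_hr(
    trace: FMSFTrace, segmentation: PhaseSegmentation | None = None
) -> tuple[float, float]:
    """Maximal ischemic rise and hyperemic drop, percent of baseline.

    ``IR_max`` is the peak fractional rise of the normalized signal during
    occlusion; ``HR_max`` the peak fractional drop in the guard interval
    immediately after cuff release (where the hyperemic transient lives).
    """
    trace = normalize_trace(trace)
    seg = segmentation or segment_phases(trace)
    occ = trace.window_values(*seg.occlusion_window)
    guard_end = seg.reperfusion_window[0]
    release = trace.window_values(seg.occlusion_window[1], max(guard_end, seg.occlusion_window[1] + trace.dt))
    ir_max = 100.0 * (float(occ.max()) - 1.0)
    hr_max = 100.0 * (1.0 - float(release.min()))
    return ir_max, hr_max


@dataclass(frozen=True)
class FlowmotionResult:
    """Per-trace derived parameters."""

    vm: float
    hs: float
    log_vm: float
    log_hs: float
    ir_max: float
    hr_max: float
    band_shares: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, float]:
        out = {
            "vm": self.vm,
            "hs": self.hs,
            "log_vm": self.log_vm,
            "log_hs": self.log_hs,
            "ir_max": self.ir_max,
            "hr_max": self.hr_max,
        }
        for name, share in self.band_shares.items():
            out[f"share_{name}"] = share
        return out


def analyze_trace(
    trace: FMSFTrace,
    guard_seconds: float = 30.0,
    band_scheme: BandScheme = DEFAULT_BAND_SCHEME,
    detrend_cutoff: float = MYOGENIC_DETREND_CUTOFF,
    share_detrend_cutoff: float = SHARE_DETREND_CUTOFF,
) -> FlowmotionResult:
    """Full single-trace analysis: normalize, segment, VM, HS, shares, IR/HR.

    Band shares are computed on the baseline segment with a lower detrend
    cutoff so the endothelial and neurogenic bands are retained; the cutoff
    is clamped to ``2 / baseline_duration`` when the baseline is too short
    for the requested value.
    """
    trace = normalize_trace(trace)
    seg = segment_phases(trace, guard_seconds)
    vm = compute_vm(trace, seg, band_scheme, detrend_cutoff)
    hs = compute_hs(trace, seg, band_scheme, detrend_cutoff)
    ir_max, hr_max = compute_ir_hr(trace, seg)

    base_start, base_end = seg.baseline_window
    base_duration = base_end - base_start
    cutoff = max(share_detrend_cutoff, 2.0 / base_duration)
    baseline = trace.window_values(base_start, base_end)
    detrended = detrend_segment(baseline, cutoff, trace.sampling_rate)
    shares = compute_band_shares(compute_psd(detrended, trace.sampling_rate), band_scheme)

    return FlowmotionResult(
        vm=vm,
        hs=hs,
        log_vm=log_param(vm),
        log_hs=log_param(hs),
        ir_max=ir_max,
        hr_max=hr_max,
        band_shares=shares,
    )
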