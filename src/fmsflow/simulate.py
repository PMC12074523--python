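"""Synthetic FMSF-PORH traces and subject cohorts.

Two generators, both fully seeded:

* :func:`generate_trace` builds a single-subject trace as a deterministic
  PORH envelope (logistic ischemic rise during the 3-minute occlusion, a
  short release transient down to the hyperemic minimum, exponential
  recovery) plus one representative sinusoid per flowmotion band and white
  measurement noise.  Baseline oscillation amplitudes are of order 0.5% of
  the fluorescence level; on reperfusion the myogenic tone is multiplied by
  a constant gain, emulating hypoxia-driven activation.

* :func:`generate_cohort` draws subject-level (VM, HS) pairs from a
  log-linear generative law per group: log10(VM) is Normal with the group
  mean/SD, and log10(HS) is a linear function of log10(VM) plus a Gaussian
  residual.  :func:`calibrate_residual_sd` chooses the residual SD so that
  the marginal SD of log10(HS) matches a prescribed value, which ties the
  group SDs and the regression slope into a consistent bivariate model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import DEFAULT_BAND_SCHEME
from .trace import FMSFTrace

__all__ = [
    "ProtocolSpec",
    "BandTone",
    "OscillationSpec",
    "ResponseSpec",
    "GroupModel",
    "CohortModel",
    "generate_trace",
    "calibrate_residual_sd",
    "generate_cohort",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Measurement protocol timing: baseline / occlusion / reperfusion."""

    sampling_rate: float = 10.0
    baseline_duration: float = 180.0
    occlusion_duration: float = 180.0
    reperfusion_duration: float = 300.0

    def __post_init__(self) -> None:
        for name in ("baseline_duration", "occlusion_duration", "reperfusion_duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not np.isfinite(self.sampling_rate) or self.sampling_rate < 4.0:
            raise ValueError("sampling_rate must be >= 4 Hz to resolve the cardiac band")

    @property
    def total_duration(self) -> float:
        return self.baseline_duration + self.occlusion_duration + self.reperfusion_duration


@dataclass(frozen=True)
class BandTone:
    """One representative oscillation tone inside a named band."""

    band: str
    frequency: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.band not in DEFAULT_BAND_SCHEME:
            raise ValueError(f"unknown band {self.band!r}")
        if self.frequency not in DEFAULT_BAND_SCHEME[self.band]:
            b = DEFAULT_BAND_SCHEME[self.band]
            raise ValueError(
                f"{self.band} tone at {self.frequency} Hz lies outside ({b.lower}, {b.upper}] Hz"
            )
        if not (np.isfinite(self.amplitude) and self.amplitude >= 0):
            raise ValueError("tone amplitude must be finite and >= 0")


def _default_tones() -> tuple[BandTone, ...]:
    # Fractional amplitudes: low-frequency oscillations of order 0.5% of the
    # fluorescence level; the cardiac pulse orders of magnitude weaker.
    return (
        BandTone("endothelial", 0.010, 5.0e-3),
        BandTone("neurogenic", 0.035, 4.0e-3),
        BandTone("myogenic", 0.100, 4.8166e-3),
        BandTone("respiratory", 0.250, 1.0e-3),
        BandTone("cardiac", 1.000, 2.0e-4),
    )


@dataclass(frozen=True)
class OscillationSpec:
    """Per-band tones plus the reperfusion myogenic activation gain."""

    tones: tuple[BandTone, ...] = field(default_factory=_default_tones)
    reperfusion_myogenic_gain: float = 3.6

    def __post_init__(self) -> None:
        if not (np.isfinite(self.reperfusion_myogenic_gain) and self.reperfusion_myogenic_gain >= 1.0):
            raise ValueError("reperfusion_myogenic_gain must be >= 1")

    @property
    def max_frequency(self) -> float:
        return max((t.frequency for t in self.tones), default=0.0)


@dataclass(frozen=True)
class ResponseSpec:
    """PORH envelope parameters (percent changes of the baseline level)."""

    ir_max: float = 16.3
    hr_max: float = 19.8
    occlusion_rise_time_constant: float = 30.0
    recovery_time_constant: float = 60.0
    release_transient_duration: float = 5.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ir_max) and self.ir_max >= 0):
            raise ValueError("ir_max must be finite and >= 0")
        if not (np.isfinite(self.hr_max) and self.hr_max >= 0):
            raise ValueError("hr_max must be finite and >= 0")
        for name in (
            "occlusion_rise_time_constant",
            "recovery_time_constant",
            "release_transient_duration",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def _porh_envelope(t: np.ndarray, protocol: ProtocolSpec, resp: ResponseSpec) -> np.ndarray:
    """Deterministic trace morphology: 1 at baseline, logistic rise to
    1+IR/100 over the occlusion, cosine fall to 1-HR/100 within the release
    transient, exponential recovery back toward 1."""
    t0 = protocol.baseline_duration
    t1 = t0 + protocol.occlusion_duration
    tr = resp.release_transient_duration
    a = resp.ir_max / 100.0
    b = resp.hr_max / 100.0

    env = np.ones_like(t)

    occ = (t >= t0) & (t < t1)
    tau = resp.occlusion_rise_time_constant
    dur = protocol.occlusion_duration

    def logistic(u: np.ndarray | float) -> np.ndarray | float:
        return 1.0 / (1.0 + np.exp(-(u - dur / 2.0) / tau))

    g0, g1 = logistic(0.0), logistic(dur)
    env[occ] = 1.0 + a * (logistic(t[occ] - t0) - g0) / (g1 - g0)

    rel = (t >= t1) & (t < t1 + tr)
    u = (t[rel] - t1) / tr
    top, bot = 1.0 + a, 1.0 - b
    env[rel] = (top + bot) / 2.0 + (top - bot) / 2.0 * np.cos(np.pi * u)

    rec = t >= t1 + tr
    env[rec] = 1.0 - b * np.exp(-(t[rec] - t1 - tr) / resp.recovery_time_constant)
    return env


def generate_trace(
    protocol: ProtocolSpec,
    osc: OscillationSpec,
    resp: ResponseSpec,
    noise_sd: float = 5.0e-4,
    seed: int = 0,
) -> FMSFTrace:
    """Simulate one FMSF-PORH trace (normalized units, baseline level 1).

    Band tones oscillate during the baseline and reperfusion phases (no
    flow implies no flowmotion during occlusion); the myogenic tone is
    amplified by ``reperfusion_myogenic_gain`` after cuff release.  Tone
    phases and the white noise come from a seeded generator, so identical
    inputs and seed give a bit-identical trace.
    """
    if not (np.isfinite(noise_sd) and noise_sd >= 0):
        raise ValueError("noise_sd must be finite and >= 0")
    nyquist = protocol.sampling_rate / 2.0
    for tone in osc.tones:
        if tone.frequency >= nyquist:
            raise ValueError(
                f"sampling_rate {protocol.sampling_rate} Hz cannot resolve the "
                f"{tone.band} band tone at {tone.frequency} Hz (Nyquist {nyquist} Hz)"
            )

    n = int(round(protocol.total_duration * protocol.sampling_rate))
    t = np.arange(n) / protocol.sampling_rate
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(osc.tones))

    t0 = protocol.baseline_duration
    t1 = t0 + protocol.occlusion_duration
    baseline = t < t0
    reperfusion = t >= t1

    signal = _porh_envelope(t, protocol, resp)
    for tone, phase in zip(osc.tones, phases):
        if tone.amplitude == 0.0:
            continue
        wave = np.sin(2.0 * np.pi * tone.frequency * t + phase)
        gain = osc.reperfusion_myogenic_gain if tone.band == "myogenic" else 1.0
        signal[baseline] += tone.amplitude * wave[baseline]
        signal[reperfusion] += tone.amplitude * gain * wave[reperfusion]
    if noise_sd > 0.0:
        signal = signal + rng.normal(0.0, noise_sd, size=n)

    return FMSFTrace(
        time=t, fluorescence=signal, occlusion_start=t0, occlusion_end=t1
    )


def calibrate_residual_sd(sd_x: float, slope: float, sd_y: float) -> float:
    """Residual SD that makes the marginal SD of the response equal sd_y.

    In the linear model ``y = slope * x + intercept + eps`` with
    ``x ~ Normal(., sd_x)`` and ``eps ~ Normal(0, residual_sd)``, the
    marginal SD of y is ``sqrt((slope*sd_x)^2 + residual_sd^2)``.  Solving
    for the residual SD requires ``sd_y >= |slope|*sd_x``, i.e. an implied
    correlation ``|r| = |slope|*sd_x/sd_y <= 1``.
    """
    if sd_x <= 0 or sd_y <= 0:
        raise ValueError("sd_x and sd_y must be positive")
    explained = (slope * sd_x) ** 2
    if sd_y**2 < explained:
        raise ValueError(
            f"sd_y={sd_y} is smaller than |slope|*sd_x={abs(slope) * sd_x:.4f}: "
            f"implied |r| = {abs(slope) * sd_x / sd_y:.3f} > 1"
        )
    return math.sqrt(sd_y**2 - explained)


@dataclass(frozen=True)
class GroupModel:
    """Generative parameters of one subject group (all on the log10 scale).

    ``log10(VM) ~ Normal(mean_logvm, sd_logvm)`` and
    ``log10(HS) = slope * log10(VM) + intercept + Normal(0, residual_sd)``.
    Optional linear age effects shift both parameters away from
    ``reference_age``; they are off (None) by default.
    """

    group_name: str
    mean_logvm: float
    sd_logvm: float
    slope: float
    intercept: float
    residual_sd: float
    age_slope_logvm: float | None = None
    age_slope_loghs: float | None = None
    reference_age: float = 50.0
    female_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.sd_logvm > 0:
            raise ValueError("sd_logvm must be positive")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")

    @property
    def implied_r(self) -> float:
        """Population correlation of log10(HS) with log10(VM)."""
        num = self.slope * self.sd_logvm
        return num / math.sqrt(num**2 + self.residual_sd**2)

    @property
    def marginal_sd_loghs(self) -> float:
        return math.sqrt((self.slope * self.sd_logvm) ** 2 + self.residual_sd**2)


@dataclass(frozen=True)
class CohortModel:
    """Mixture of groups with per-group subject counts."""

    groups: tuple[tuple[GroupModel, int], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort model must contain at least one group")
        for model, n in self.groups:
            if n < 1:
                raise ValueError(f"group {model.group_name!r} has n={n}; n >= 1 required")


def generate_cohort(
    model: CohortModel,
    ages: tuple[float, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a cohort table: subject_id, group, sex, age, vm, hs.

    ``ages`` is an optional (low, high) range for uniform age sampling; if
    omitted every subject gets the group's reference age and age effects are
    inert.  VM and HS are stored on the linear scale (logs are derived,
    never stored).  Reproducible under ``seed`` (defaults to the model's).
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    frames = []
    for group, n in model.groups:
        if ages is not None:
            age = rng.uniform(ages[0], ages[1], size=n)
        else:
            age = np.full(n, group.reference_age)
        age_offset = age - group.reference_age

        mean_x = group.mean_logvm
        if group.age_slope_logvm is not None:
            mean_x = mean_x + group.age_slope_logvm * age_offset
        log_vm = rng.normal(mean_x, group.sd_logvm, size=n)

        log_hs = group.slope * log_vm + group.intercept
        if group.age_slope_loghs is not None:
            slope_vm_age = group.age_slope_logvm or 0.0
            # Direct age effect beyond what propagates through log(VM), so
            # the marginal log(HS)-vs-age slope equals age_slope_loghs.
            log_hs = log_hs + (group.age_slope_loghs - group.slope * slope_vm_age) * age_offset
        log_hs = log_hs + rng.normal(0.0, group.residual_sd, size=n)

        sex = np.where(rng.random(n) < group.female_fraction, "F", "M")
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{group.group_name}-{i:06d}" for i in range(n)],
                    "group": group.group_name,
                    "sex": sex,
                    "age": age,
                    "vm": np.power(10.0, log_vm),
                    "hs": np.power(10.0, log_hs),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
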