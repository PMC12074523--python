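"""CSV dialects, run configuration and logging helpers.

Trace CSV: columns ``time_s, fluorescence, phase`` with phase one of
baseline/occlusion/reperfusion; phase markers are reconstructed from the
phase transitions on read.  Cohort CSV: ``subject_id, group, sex, age, vm,
hs`` with VM/HS on the linear scale (logs derived, never stored).  Run
configuration is a YAML file mirroring the generator and analysis dataclass
fields; unknown keys are rejected so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .simulate import (
    BandTone,
    CohortModel,
    GroupModel,
    OscillationSpec,
    ProtocolSpec,
    ResponseSpec,
)
from .trace import FMSFTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "RunConfig",
    "load_config",
    "default_config",
]

logger = logging.getLogger("fmsflow")

PHASE_LABELS = ("baseline", "occlusion", "reperfusion")
TRACE_COLUMNS = ("time_s", "fluorescence", "phase")
COHORT_COLUMNS = ("subject_id", "group", "sex", "age", "vm", "hs")

#: Floats are written with 9 significant digits; round-trip is lossless to
#: that precision.
FLOAT_FORMAT = "%.9g"


def write_trace_csv(trace: FMSFTrace, path: str | Path) -> None:
    phase = np.where(
        trace.time < trace.occlusion_start,
        "baseline",
        np.where(trace.time < trace.occlusion_end, "occlusion", "reperfusion"),
    )
    frame = pd.DataFrame(
        {"time_s": trace.time, "fluorescence": trace.fluorescence, "phase": phase}
    )
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trace_csv(path: str | Path) -> FMSFTrace:
    frame = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    time = np.asarray(frame["time_s"], dtype=float)
    bad = np.flatnonzero(np.diff(time) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: time_s not strictly increasing at data row {int(bad[0]) + 2}"
        )
    unknown = ~frame["phase"].isin(PHASE_LABELS)
    if unknown.any():
        row = int(np.flatnonzero(unknown)[0])
        raise ValueError(
            f"{path}: unknown phase label {frame['phase'].iloc[row]!r} at data row {row + 2}"
        )
    occ_rows = np.flatnonzero(frame["phase"] == "occlusion")
    rep_rows = np.flatnonzero(frame["phase"] == "reperfusion")
    if occ_rows.size == 0 or rep_rows.size == 0:
        raise ValueError(f"{path}: trace must contain occlusion and reperfusion phases")
    return FMSFTrace(
        time=time,
        fluorescence=np.asarray(frame["fluorescence"], dtype=float),
        occlusion_start=float(time[occ_rows[0]]),
        occlusion_end=float(time[rep_rows[0]]),
    )


def write_cohort_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False, columns=list(COHORT_COLUMNS), float_format=FLOAT_FORMAT)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    valid = (frame["vm"] > 0) & (frame["hs"] > 0)
    n_rejected = int((~valid).sum())
    if n_rejected:
        logger.warning(
            "%s: rejected %d row(s) with non-positive vm/hs (cannot log-transform)",
            path,
            n_rejected,
        )
    frame = frame[valid].reset_index(drop=True)
    logger.info("%s: loaded %d subjects", path, len(frame))
    return frame


# --------------------------------------------------------------------------
# Run configuration


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs, with documented defaults."""

    protocol: ProtocolSpec
    oscillation: OscillationSpec
    response: ResponseSpec
    cohort: CohortModel
    scheme: str = "revised"
    seed: int = 0
    noise_sd: float = 5.0e-4


def _check_keys(section: str, data: dict, allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {section}: {sorted(unknown)}")


def _build(cls, section: str, data: dict):
    _check_keys(section, data, {f.name for f in dataclasses.fields(cls)})
    return cls(**data)


def _build_oscillation(data: dict) -> OscillationSpec:
    data = dict(data)
    tones_raw = data.pop("bands", None)
    _check_keys("oscillation", data, {"reperfusion_myogenic_gain"})
    kwargs: dict[str, Any] = dict(data)
    if tones_raw is not None:
        tones = []
        for band, spec in tones_raw.items():
            _check_keys(f"oscillation.bands.{band}", spec, {"frequency", "amplitude"})
            tones.append(BandTone(band=band, **spec))
        kwargs["tones"] = tuple(tones)
    return OscillationSpec(**kwargs)


def _build_cohort(data: dict) -> CohortModel:
    data = dict(data)
    groups_raw = data.pop("groups")
    _check_keys("cohort", data, {"seed"})
    group_fields = {f.name for f in dataclasses.fields(GroupModel)}
    groups = []
    for entry in groups_raw:
        entry = dict(entry)
        n = entry.pop("n")
        _check_keys(f"cohort group {entry.get('group_name')}", entry, group_fields)
        groups.append((GroupModel(**entry), int(n)))
    return CohortModel(groups=tuple(groups), **data)


def default_config(seed: int = 0) -> RunConfig:
    from .constants import reference_cohort_model

    return RunConfig(
        protocol=ProtocolSpec(),
        oscillation=OscillationSpec(),
        response=ResponseSpec(),
        cohort=reference_cohort_model(seed=seed),
        seed=seed,
    )


def load_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    """Load a YAML run configuration; every omitted section gets defaults.

    Unknown keys anywhere raise a ``ValueError`` naming the section.
    """
    if path is None:
        cfg = default_config(seed or 0)
        return dataclasses.replace(cfg, seed=seed if seed is not None else cfg.seed)
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    _check_keys(
        "config",
        raw,
        {"protocol", "oscillation", "response", "cohort", "scheme", "seed", "noise_sd"},
    )
    base = default_config(int(raw.get("seed", 0)))
    cfg = RunConfig(
        protocol=_build(ProtocolSpec, "protocol", raw.get("protocol", {}))
        if "protocol" in raw
        else base.protocol,
        oscillation=_build_oscillation(raw["oscillation"])
        if "oscillation" in raw
        else base.oscillation,
        response=_build(ResponseSpec, "response", raw.get("response", {}))
        if "response" in raw
        else base.response,
        cohort=_build_cohort(raw["cohort"]) if "cohort" in raw else base.cohort,
        scheme=str(raw.get("scheme", base.scheme)),
        seed=int(raw.get("seed", base.seed)),
        noise_sd=float(raw.get("noise_sd", base.noise_sd)),
    )
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    return cfg
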