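"""Registry of published FMSF reference values used across the pipeline.

Every printed calibration constant lives here: the cohort summary
statistics of the FMSF reference groups (a control group of 153 healthy
volunteers/athletes and 910 cardiovascular and type-2-diabetes patients),
the log-linear VM-HS regression coefficients reported for each group, the
age-trend slopes, and the named diagnostic threshold schemes.  Stage code
imports from here; no magic numbers elsewhere.
"""

from __future__ import annotations

from .diagnostics import ThresholdScheme
from .simulate import CohortModel, GroupModel, calibrate_residual_sd

__all__ = [
    "CONTROL_STATS",
    "CVD_DM2_STATS",
    "REFERENCE_GROUP_SIZES",
    "control_group_model",
    "cvd_dm2_group_model",
    "reference_cohort_model",
    "VM_SCHEME_ORIGINAL",
    "VM_SCHEME_REVISED",
    "VM_SCHEME_YOUDEN",
    "HS_SCHEME",
    "THRESHOLD_SCHEMES",
    "WORKED_EXAMPLE",
]

#: Reference cohort statistics, log10 scale (mean +/- SD of the cohorts the
#: FMSF calibration was published on), plus the per-group log-linear
#: regression log(HS) = slope * log(VM) + intercept and age-trend slopes.
CONTROL_STATS = {
    "mean_logvm": 1.23,
    "sd_logvm": 0.50,
    "mean_loghs": 1.80,
    "sd_loghs": 0.44,
    "slope": 0.56,
    "intercept": 1.11,
    "pearson_r": 0.639,
    "age_slope_logvm": -0.017,  # a.u./year
    "age_slope_loghs": -0.012,
    "mean_age": 32.6,
    "n": 153,
    "female_fraction": 34 / 153,
    "ir_max": 16.3,  # percent
    "hr_max": 19.8,
}

CVD_DM2_STATS = {
    "mean_logvm": 0.53,
    "sd_logvm": 0.58,
    "mean_loghs": 1.14,
    "sd_loghs": 0.56,
    "slope": 0.62,
    "intercept": 0.81,
    "pearson_r": 0.636,
    "age_slope_logvm": -0.012,
    "age_slope_loghs": -0.013,
    "mean_age": 67.6,
    "n": 910,
    "female_fraction": 519 / 910,
    "ir_max": 11.4,
    "hr_max": 16.5,
}

#: Pooled ROC analyses weight the groups as in the 1063-subject reference
#: cohort (153 control : 910 CVD+DM2).
REFERENCE_GROUP_SIZES = {"control": 153, "cvd_dm2": 910}


def _group_model(name: str, stats: dict, with_age_effects: bool) -> GroupModel:
    return GroupModel(
        group_name=name,
        mean_logvm=stats["mean_logvm"],
        sd_logvm=stats["sd_logvm"],
        slope=stats["slope"],
        intercept=stats["intercept"],
        # Residual SD derived, not hard-coded: chosen so the marginal SD of
        # log(HS) reproduces the published cohort SD.
        residual_sd=calibrate_residual_sd(stats["sd_logvm"], stats["slope"], stats["sd_loghs"]),
        age_slope_logvm=stats["age_slope_logvm"] if with_age_effects else None,
        age_slope_loghs=stats["age_slope_loghs"] if with_age_effects else None,
        reference_age=stats["mean_age"],
        female_fraction=stats["female_fraction"],
    )


def control_group_model(with_age_effects: bool = False) -> GroupModel:
    """Calibrated generative model of the healthy control group."""
    return _group_model("control", CONTROL_STATS, with_age_effects)


def cvd_dm2_group_model(with_age_effects: bool = False) -> GroupModel:
    """Calibrated generative model of the CVD+DM2 patient group."""
    return _group_model("cvd_dm2", CVD_DM2_STATS, with_age_effects)


def reference_cohort_model(
    n_total: int = 1063, seed: int = 0, with_age_effects: bool = False
) -> CohortModel:
    """Two-group mixture with the reference 153:910 group weighting."""
    n_ref = sum(REFERENCE_GROUP_SIZES.values())
    n_control = int(round(n_total * REFERENCE_GROUP_SIZES["control"] / n_ref))
    n_patient = n_total - n_control
    return CohortModel(
        groups=(
            (control_group_model(with_age_effects), n_control),
            (cvd_dm2_group_model(with_age_effects), n_patient),
        ),
        seed=seed,
    )


import math as _math

# Named diagnostic threshold schemes.  The original/revised VM schemes and
# the HS scheme are defined by their linear cut-offs (VM 2/12, VM 2.5/8,
# HS 10/30; their logs print as 0.30/1.08, 0.4/0.9 and 1/1.48), while the
# Youden scheme comes from ROC analysis directly on the log scale
# (0.53/0.83, i.e. VM 3.4/6.8).
VM_SCHEME_ORIGINAL = ThresholdScheme(
    "original", lower_log=_math.log10(2.0), upper_log=_math.log10(12.0), applies_to="vm"
)
VM_SCHEME_REVISED = ThresholdScheme(
    "revised", lower_log=_math.log10(2.5), upper_log=_math.log10(8.0), applies_to="vm"
)
VM_SCHEME_YOUDEN = ThresholdScheme("youden", lower_log=0.53, upper_log=0.83, applies_to="vm")
HS_SCHEME = ThresholdScheme(
    "hs", lower_log=1.00, upper_log=_math.log10(30.0), applies_to="hs"
)

THRESHOLD_SCHEMES = {
    "original": VM_SCHEME_ORIGINAL,
    "revised": VM_SCHEME_REVISED,
    "youden": VM_SCHEME_YOUDEN,
    "hs": HS_SCHEME,
}

#: Single-subject worked example (an active amateur athlete, before and
#: after one intermittent-hypoxia session): VM/HS on the linear scale.
WORKED_EXAMPLE = {
    "vm_before": 11.6,
    "hs_before": 150.6,
    "vm_after": 38.3,
    "hs_after": 246.0,
}
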