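"""Generate the synthetic study inputs: one worked-example trace pair and
the calibrated two-group cohort.

Writes under results/:
  trace_before_iht.csv / trace_after_iht.csv -- single-subject traces whose
    myogenic tone amplitudes are set to reproduce the reference worked
    example (VM 11.6 -> 38.3 across an intermittent-hypoxia session, HS
    150.6 -> 246).
  cohort.csv -- 10,000 subjects, 153:910 control:patient weighting, drawn
    from the published group moments and log-linear laws.
"""

import math
import pathlib

from fmsflow import BandTone, OscillationSpec, ProtocolSpec, ResponseSpec, generate_trace
from fmsflow.constants import WORKED_EXAMPLE, reference_cohort_model
from fmsflow.io import write_cohort_csv, write_trace_csv
from fmsflow.simulate import generate_cohort

SEED = 2025
RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def tone_amplitude(param_value: float) -> float:
    """Fractional tone amplitude whose band mean square x 1e6 = param."""
    return math.sqrt(2.0 * param_value * 1e-6)


def worked_example_trace(vm: float, hs: float, seed: int):
    osc = OscillationSpec(
        tones=(
            BandTone("endothelial", 0.010, 5.0e-3),
            BandTone("neurogenic", 0.035, 4.0e-3),
            BandTone("myogenic", 0.100, tone_amplitude(vm)),
            BandTone("respiratory", 0.250, 1.0e-3),
            BandTone("cardiac", 1.000, 2.0e-4),
        ),
        reperfusion_myogenic_gain=math.sqrt(hs / vm),
    )
    return generate_trace(ProtocolSpec(), osc, ResponseSpec(), noise_sd=2e-4, seed=seed)


def main() -> None:
    before = worked_example_trace(WORKED_EXAMPLE["vm_before"], WORKED_EXAMPLE["hs_before"], SEED)
    after = worked_example_trace(WORKED_EXAMPLE["vm_after"], WORKED_EXAMPLE["hs_after"], SEED + 1)
    write_trace_csv(before, RESULTS / "trace_before_iht.csv")
    write_trace_csv(after, RESULTS / "trace_after_iht.csv")
    print(f"wrote worked-example traces ({before.time.size} samples each)")

    cohort = generate_cohort(reference_cohort_model(n_total=10_000, seed=SEED))
    write_cohort_csv(cohort, RESULTS / "cohort.csv")
    counts = cohort["group"].value_counts()
    print(f"wrote cohort.csv: {counts.to_dict()} (153:910 weighting)")


if __name__ == "__main__":
    main()
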