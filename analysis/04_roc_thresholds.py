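"""ROC threshold selection, discordance rates and class distributions.

On the calibrated 153:910 mixture this reproduces the threshold analysis:
ROC of VM predicting a proper hypoxic response (log(HS) >= 1) and an
optimal response (log(HS) >= 1.48), the Youden-optimal cut-offs, the
false-negative/false-positive discordance at the original log(VM)=0.3 cut,
and the impaired/acceptable/optimal distribution under each named scheme.

The mixture AUC is exploratory: the published real-data value is 0.849,
and a two-lognormal mixture calibrated only to group moments and the
log-linear laws is not expected to match it exactly; the measured value is
printed alongside for comparison.  Writes results/roc_thresholds.json.
"""

import json
import math
import pathlib

from fmsflow import distribution_summary, misclassification_rates, roc_curve
from fmsflow.constants import THRESHOLD_SCHEMES, reference_cohort_model
from fmsflow.simulate import generate_cohort

SEED = 2025
RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = generate_cohort(reference_cohort_model(n_total=100_000, seed=SEED))
    out = {"n": len(records)}

    for tag, cut, published_auc in (("proper", 1.0, 0.849), ("optimal", 1.48, 0.81)):
        roc = roc_curve(records, "vm", hs_log_cut=cut)
        log_thr = math.log10(roc.youden_threshold)
        out[f"roc_{tag}"] = {**roc.to_dict(), "youden_log_threshold": log_thr}
        print(
            f"ROC (log(HS) >= {cut}): AUC {roc.auc:.3f} "
            f"[published real-data {published_auc}]  "
            f"Youden log(VM) {log_thr:.2f} (TPR {roc.youden_tpr:.2f}, "
            f"TNR {1 - roc.youden_fpr:.2f})"
        )

    fn, fp = misclassification_rates(records, vm_log_cut=0.3, hs_log_cut=1.0)
    out["discordance"] = {"false_negative": fn, "false_positive": fp}
    print(f"discordance at log(VM)=0.3 vs log(HS)=1: FN {100 * fn:.1f}% "
          f"[published ~10%], FP {100 * fp:.1f}% [published ~16%]")

    for name in ("original", "revised", "youden"):
        summary = distribution_summary(records, THRESHOLD_SCHEMES[name])
        out[f"distribution_{name}"] = summary
        shares = "  ".join(
            f"{label} {entry['percent']}%" for label, entry in summary["overall"].items()
        )
        print(f"{name:>9} scheme: {shares}")

    with open(RESULTS / "roc_thresholds.json", "w") as handle:
        json.dump(out, handle, indent=2, sort_keys=True)
    print("wrote results/roc_thresholds.json")


if __name__ == "__main__":
    main()
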