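# fmsflow

Analysis pipeline for microvascular flowmotion measured by Flow Mediated
Skin Fluorescence with post-occlusive reactive hyperemia (FMSF–PORH).

Skin NADH fluorescence recorded through a baseline / 3-min brachial
occlusion / reperfusion protocol carries small oscillations ("flowmotion")
in the classical endothelial, neurogenic, myogenic, respiratory and cardiac
frequency bands.  Two myogenic-band parameters summarize microvascular
adaptation to hypoxia:

* **VM** — normoxic myogenic activity: the myogenic-band (0.052–0.15 Hz)
  mean-squared amplitude of the normalized baseline signal, × 10⁶;
* **HS** — hypoxia sensitivity: the same statistic on the reperfusion
  segment, where transient hypoxia activates myogenic vasomotion.

Across cohorts, log₁₀(HS) = a·log₁₀(VM) + b with Pearson r ≈ 0.64 in both
healthy controls (a = 0.56, b = 1.11) and cardiovascular/type-2-diabetes
patients (a = 0.62, b = 0.81), so resting VM predicts the hypoxic response
without an occlusion.  The package implements the whole chain: seeded
synthetic trace/cohort generators calibrated to the published group
statistics, the trace pipeline (normalize → segment → detrend → FFT
periodogram → band powers, Parseval-exact), cohort statistics (OLS,
Pearson, t tests, Shapiro–Wilk, age trends), and the diagnostic layer
(impaired/acceptable/optimal threshold schemes, ROC/AUC with
Youden-optimal cut-offs, discordance rates).  It is aimed at researchers
working with vasomotion spectra who need a tested, reproducible reference
implementation of the VM/HS calibration.

## Worked example

```python
import math
from fmsflow import (BandTone, OscillationSpec, ProtocolSpec, ResponseSpec,
                     analyze_trace, generate_trace)

# A subject whose myogenic tone carries VM = 11.6 at baseline and is
# amplified sqrt(150.6/11.6)-fold by reperfusion hypoxia:
osc = OscillationSpec(
    tones=(BandTone("myogenic", 0.1, math.sqrt(2 * 11.6e-6)),),
    reperfusion_myogenic_gain=math.sqrt(150.6 / 11.6),
)
trace = generate_trace(ProtocolSpec(), osc, ResponseSpec(), noise_sd=0.0, seed=1)
r = analyze_trace(trace)
print(f"VM = {r.vm:.1f} (log {r.log_vm:.2f})   HS = {r.hs:.1f} (log {r.log_hs:.2f})")
print(f"IR_max = {r.ir_max:.1f}%   HR_max = {r.hr_max:.1f}%")
```

prints

```
VM = 11.4 (log 1.06)   HS = 148.3 (log 2.17)
IR_max = 16.3%   HR_max = 19.7%
```

VM/HS land within the ~2 % spectral-leakage budget of the constructed
values 11.6/150.6 — an "optimal" subject under every scheme (log(VM) ≥
0.9) — and the envelope parameters round-trip to a tenth of a percentage
point (the amplified myogenic oscillation rides the hyperemic minimum).
The same works from the shell:

```sh
fmsf simulate-trace --seed 1 --out trace.csv
fmsf analyze-trace --in trace.csv --out result.json
fmsf simulate-cohort --n-control 153 --n-patient 910 --seed 2 --out cohort.csv
fmsf analyze-cohort --in cohort.csv --out fits.json
fmsf classify --in cohort.csv --scheme revised --out labels.csv
fmsf roc --in cohort.csv --hs-cut 1.0 --out roc.json
```

## Analysis scripts

`analysis/01_simulate.py` … `04_roc_thresholds.py` run the full study on
synthetic cohorts calibrated to the published group statistics: trace
parameter recovery, per-group log-linear fits, normality of the log scale,
age trends, ROC threshold selection, discordance rates and class
distributions.  Each prints what it finds and writes JSON/CSV under
`results/`.

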