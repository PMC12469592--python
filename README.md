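# mrmval

Validation and quantitation toolkit for SPE-LC-MS/MS urine assays, built for
human-biomonitoring laboratories that quantify trace organic contaminants
(pesticide metabolites, bisphenols, flame-retardant metabolites) from MRM
peak-area exports.

Bioanalytical method validation is mostly arithmetic wrapped in rules — but
the rules are many and easy to get subtly wrong. `mrmval` implements the
computational side of an ICH M10-style validation and application study as a
tested, reusable pipeline:

* **Matrix effects.** The matrix factor of an analyte in urine lot *j* is
  MF<sub>j</sub> = 100 · Ā<sub>matrix,j</sub> / Ā<sub>solvent</sub> from
  post-extraction-spiked replicates; the IS-corrected factor divides it by the
  internal standard's MF, and the CV of the corrected factor across lots
  (sample SD, n−1) measures the relative matrix effect. The candidate IS with
  the lowest CV is assigned per analyte; mean factors are classified into
  soft / medium / strong suppression or enhancement bands.
* **Calibration.** Matrix-matched internal calibration *y = ax + b* on
  analyte/IS response ratios, fitted by weighted least squares with weights
  1, 1/x, or 1/x²; the weighting is chosen to minimize the mean absolute
  relative back-calculation error over replicate curves. Levels pass when
  ≥ 75 % of replicates back-calculate within ±15 % (±20 % at the lowest
  level); the LLOQ is the lowest passing level with all higher levels also
  passing, and R² ≥ 0.9900 is required.
* **Validation rules.** QC accuracy/precision (intra-run n = 5, inter-run
  n = 15; ±15 % and CV ≤ 15 %), 3-of-4 routine-run acceptance, carry-over and
  selectivity interference limits (20 % of the LLOQ response, 5 % of the IS
  response), eightfold dilution integrity, stability verdicts, and pooled
  Student t-tests for method-development recovery comparisons.
* **Quantitation and cohort summaries.** Back-calculation with censoring at
  the LLOQ/ULOQ, specific-gravity adjustment
  C<sub>adj</sub> = C · (SG<sub>ref</sub> − 1)/(SG<sub>sample</sub> − 1),
  detection rates, and left-censored summary statistics (non-detects rank as
  zeros; at exactly 50 % detection the median is the mean of zero and the
  first quantified value; geometric means substitute non-detects by a
  configurable policy).
* **Isotope tools.** Theoretical isotope patterns by per-element multinomial
  convolution, adduct m/z values ([M+H]⁺, [M−H]⁻, [M+HCOO]⁻), and
  observed-vs-predicted spectrum matching — the arithmetic behind identity
  checks such as recognizing the chlorine M/M+2 signature of a formate adduct.
* **Synthetic MRM generator.** Every stage runs without instrument data: the
  generator emits full validation designs and study cohorts with per-lot
  multiplicative suppression, shared analyte/IS suppression, log-normal
  injection noise, and left-censored exposure distributions, with the
  generating truth retained for parameter-recovery checks.

## Worked example

Validate a three-analyte subset of the built-in 16-analyte panel on synthetic
data and summarize a simulated 28-sample cohort:

```python
from mrmval import simulate_validation_suite, simulate_application_cohort, summarize_study
from mrmval.panel import panel_study_config
from mrmval.simulate import SimulationParams
from mrmval.pipeline import run_validation, quantify_study

config = panel_study_config(["FIP", "TEB-OH", "BPS"], seed=0)
params = SimulationParams.from_config(config, seed=0, injection_cv=0.05)
suite = simulate_validation_suite(params, config)
cohort = simulate_application_cohort(params, 28, config)

validation = run_validation(suite.records, config)
for name, entry in validation.items():
    m = entry["calibration"]
    print(f"{name:8s} weighting={m.weighting:4s} R2={m.r_squared:.4f} "
          f"LLOQ={m.lloq:g} pg/mL  QC pass={[q.passed for q in entry['qc']]}")

assessed = {n: e["calibration"] for n, e in validation.items()}
results = quantify_study(cohort.records, assessed, config)
raw, adj = summarize_study(results, config, cohort.sg_by_sample)
for s in raw:
    gm = f"{s.gm:.3g}" if s.gm else "-"
    p50 = f"{s.p50:.3g}" if isinstance(s.p50, float) else (s.p50 or "-")
    print(f"{s.analyte:8s} detected={s.detection_rate:.0f}%  GM={gm}  P50={p50}")
```

Output:

```
FIP      weighting=1/x2 R2=0.9933 LLOQ=1 pg/mL  QC pass=[True, True]
TEB-OH   weighting=1/x2 R2=0.9930 LLOQ=100 pg/mL  QC pass=[True, True]
BPS      weighting=1/x2 R2=0.9951 LLOQ=50 pg/mL  QC pass=[True, True]
FIP      detected=36%  GM=-  P50=-
TEB-OH   detected=43%  GM=-  P50=-
BPS      detected=54%  GM=85.7  P50=65.1
```

Reading it: each analyte's quadruplicate curves passed level acceptance down
to the configured lowest level (so the LLOQ equals it), the 1/x² weighting
won the back-calculation-error comparison under the generator's
concentration-proportional noise, and both QC levels met the ±15 %/CV ≤ 15 %
rules. In the cohort block, summary statistics below the 50 %-detection
reporting floor print as dashes; BPS, detected in 54 % of samples, reports a
geometric mean (non-detects substituted at LLOQ/2) and a median.

The same pipeline is available from the shell:

```bash
mrmval --seed 1 --out-dir out simulate
mrmval --seed 1 --out-dir out validate out/injections.csv
mrmval --seed 1 --out-dir out summarize out/injections.csv --sg-table out/samples_sg.csv
mrmval isotopes --formula C11H5Cl2F3N4O --adduct "[M-H]-"
```

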