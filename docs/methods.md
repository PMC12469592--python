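# Methods

This note documents the models, conventions, and design choices behind
`mrmval`. It covers what each stage computes, why the defaults are what they
are, what the synthetic-data generator does and does not emulate, and the
numerical details that affect results at the margins.

## Data model

An injection table carries one row per measured MRM transition: a sample id,
a design role (solvent, blank, zero, calibrator, QC low/high, dilution QC,
stability QC, study, or post-extraction spike), an analyte name, a peak area
(detector counts), a run id, and — where the role requires it — a nominal
concentration in pg/mL, plus optional dilution factor, urine lot, and
stability timepoint. Internal standards are rows like any other, with the IS
name in the analyte column; an injection of one physical sample therefore
contributes an analyte row and an IS row sharing (sample_id, run_id), and
response ratios are formed by pairing on that key against the configured IS.
IS rows attached to calibrator/QC roles carry a nominal concentration of 0
("not quantitated") to satisfy the role invariant without implying a value.

All acceptance decisions are logged through the `mrmval` logger with the
rule and threshold that produced them. Reporting rounding — integers
(half-up) for matrix factors, CVs, accuracies, and precisions; three
significant figures for concentrations — is applied only when rendering
tables; internal computation is always full precision.

## Matrix effects and internal-standard selection

The per-lot matrix factor uses the mean of the replicate areas per lot (not
the mean of per-replicate factors): triplicate preparations are summarized
per lot first, then ratioed to the mean solvent area. The IS-corrected
factor divides the analyte's factor by the IS's factor in the same lot; its
CV across lots uses the sample (n−1) standard deviation, the convention that
reproduces published row CVs from their printed per-lot values. A corrected
CV ≤ 15 % is logged as satisfactory; the IS with the lowest corrected CV is
assigned, with ties broken by the declared candidate order.

Suppression bands are closed so they tile the positive axis with no gaps:
soft = [80, 120], medium suppression = [50, 80), medium enhancement =
(120, 150], strong elsewhere. The half-open closures at 80 and 120 are a
convention choice; any value is classified into exactly one band.

## Calibration

Curves are fitted per run (quadruplicate curves give four fits), each
calibrator is back-calculated against its own run's model, and level
acceptance is assessed on the pooled per-level accuracies; the reported
coefficients and R² come from a pooled fit over all points. This "fit per
run, assess per run, report the pooled verdict" choice keeps run-to-run
response drift out of the accuracy assessment while still reporting one
equation per analyte.

Weighted least squares minimizes Σ wᵢ(yᵢ − a·xᵢ − b)² with wᵢ ∈ {1, 1/xᵢ,
1/xᵢ²} (statsmodels WLS); the weighted R² is computed about the weighted
mean. Weighting selection — the vendor software's internal procedure in
routine practice — is made explicit here: the scheme minimizing the mean
absolute relative back-calculation error over all standards of all replicate
curves wins, with ties resolved toward the heavier weighting (1/x² over 1/x
over none). On a noise-free line all schemes tie and 1/x² is returned.
No outlier exclusion or iterative refitting is performed: a single fit uses
all points and levels only pass or fail.

The LLOQ is the lowest level that passes (±20 % window, ≥ 75 % of
replicates) such that every higher level also passes (±15 % windows); the
ULOQ is the top configured level. When no level qualifies the model carries
an explicit no-valid-range flag rather than a fabricated limit. Negative
back-calculated concentrations are preserved numerically and censored only
at reporting.

## Validation rules

* **QC accuracy/precision** — accuracy = 100·mean/nominal within [85, 115] %
  and CV ≤ 15 %, for both the designated intra-run set (n = 5; the first run
  in sorted order unless specified) and the pooled inter-run set (n = 15).
  A batch passes only if all four metrics pass; each predicate is monotone
  (worsening a metric can never rescue a verdict).
* **Routine-run acceptance** — of the four bracketing QCs (2 low + 2 high),
  at least three within ±15 %.
* **Selectivity / carry-over** — a blank may show at most 20 % of the
  analyte response at the LLOQ level and at most 5 % of the IS response;
  both bounds inclusive.
* **Dilution integrity** — 8× ULOQ spikes diluted eightfold must read back
  (after re-multiplication) within the QC accuracy/CV rules, and the diluted
  response itself must fall inside the calibration range. Because the design
  puts the diluted response exactly at the ULOQ, the range check allows the
  level acceptance tolerance (15 %); a strict bound would fail about half of
  the replicates from measurement noise alone.
* **Stability** — accuracy at the later timepoint against *nominal* (not
  against measured t0, which is reported alongside for context) within
  [85, 115] % and CV ≤ 15 %; any n ≥ 3 is accepted and recorded.
* **Recovery comparisons** — two-sided two-sample Student t-test with
  pooled (equal-variance) SD by default, Welch optional; on n = 3 per arm
  pooled is the method-development convention. Two constant equal groups
  return t = 0, p = 1 with a degeneracy flag instead of NaN.

## Quantitation and cohort summaries

Study concentrations are back-calculated and censored: strictly below the
LLOQ → "< LLOQ" (non-detect), above the ULOQ × dilution factor → "> ULOQ";
values exactly at either limit are quantifiable. Specific-gravity adjustment
multiplies by (SG_ref − 1)/(SG_sample − 1) — the standard urinary dilution
normalization — with the cohort median SG as the default reference
(configurable to a fixed value). Samples at SG ≤ 1 are rejected.

Summary statistics follow left-censored biomonitoring conventions:

* Non-detects rank as zeros. Percentiles use the averaged inverted-CDF
  order-statistic rule: at an integer rank boundary the two bracketing order
  statistics are averaged, otherwise the next one up is taken. At exactly
  50 % detection this makes the median the arithmetic mean of zero and the
  first quantified value. The rule is implemented directly (numpy's
  `averaged_inverted_cdf` interpolates internally and cannot propagate the
  +∞ sentinel used for censored-high values).
* "> ULOQ" values rank as +∞ and propagate: a percentile landing on one is
  reported as "> ULOQ", never as a number.
* The geometric mean substitutes non-detects by policy: `half_lloq`
  (default), `lloq_over_sqrt2`, or `zero` — the last reports the GM as
  absent whenever a non-detect is present, since log 0 is undefined. The
  default is an assumption, not a derived choice, and is recorded in the
  summary output. Censored-high values contribute their ULOQ (a downward-
  biased stand-in).
* Reporting floors mirror how such tables are published: GM and quartiles
  require ≥ 50 % detection, P95 requires ≥ 18 %, and the maximum is shown
  whenever anything was detected. A quartile that lands in the non-detect
  mass (value 0) is reported absent. Floors are configurable.

## Isotope tools

Isotope patterns are computed by convolving per-element distributions (each
atom an independent draw over its natural isotopes), with per-element binary
exponentiation and peak merging at 10⁻⁹ Da; abundances below the prune floor
(default 10⁻¹⁰) are dropped during accumulation and the final pattern is
renormalized. Nominal aggregation bins at the nearest integer Da with
abundance-weighted mean masses. Isotope masses and abundances are pinned
in-package to the CODATA/CIAAW standard values (H, C, N, O, F, Na, Si, P, S,
Cl, K, Br, I) so results do not depend on any external table.

Adducts are singly charged; the proton mass (1.0072765 Da) is used for ±H
and the formate anion mass for [M+HCOO]⁻. The electron mass (0.00055 Da) is
deliberately ignored — three orders of magnitude below the unit-mass
resolution at which these identity checks operate. The adduct pattern is the
neutral pattern shifted by the adduct delta; the adduct atoms' own minor
isotopes (a < 0.1 % correction for H/CHO₂) are not convolved in.

Spectrum comparison pairs observed peaks greedily with the nearest
unclaimed predicted peak within tolerance, normalizes both patterns to their
base peak, and reports per-pair abundance deviations plus unexplained peaks
on both sides — the computation behind "there is an intense observed signal
with no predicted counterpart" reasoning.

## The synthetic-data generator

The generator produces the statistical structure the analyses assume, not
chromatograms. Its response model per injection is

    analyte area = (slope·conc + intercept) · F_lot · exp(ε),
    IS area      = scale · F_lot^ρ · F_own^(1−ρ) · exp(ε′),

with ε Gaussian on the log scale so that areas stay positive and the noise
CV is scale-free (matching the CV-based acceptance rules). The default
injection CV is 5 %. The heteroscedasticity exponent h sets SD ∝ conc^h;
the default h = 1 is pure multiplicative noise, under which 1/x² weighting
is statistically optimal — which is exactly what the weighting selector
picks on generated curves.

Lot matrix factors F decrease log-linearly with specific gravity (stronger
suppression in more concentrated urine) times a per-analyte susceptibility
drawn once per study (log-uniform on [0.08, 1.4]) times per-lot log-normal
jitter (σ = 0.25), clipped to (0, 1.5]; across a 16-analyte panel the
factors span roughly 0.02–0.9. The seven matrix-effect lots sit at SGs
1.006–1.031, and calibrators/QCs share a single "pool" lot, so matrix-
matched calibration cancels the pool factor exactly.

The IS-correlation parameter ρ ∈ [0, 1] sets how much of the analyte's lot
suppression the IS shares: ρ = 1 makes IS correction perfect, ρ = 0 useless,
spanning the observed contrast between isotope-labeled ISs (corrected CVs of
a few percent) and surrogate ISs (CVs of tens of percent). ρ is a modeling
knob, not an empirically derived quantity; the default 0.9 represents a
well-matched labeled IS. When several analytes share one IS, the single IS
row per sample is generated against the first configured analyte using that
IS, so correction is exact only for that pairing — deliberately so, since
one physical IS cannot track several differently-suppressed analytes at
once. Pipeline-inversion checks therefore use dedicated-IS configurations.
`injection_cv = 0` is accepted as the exact noise-free limit.

The validation design per study: 4 replicate calibration curves over the
configured levels (default 10, log-spaced LLOQ→ULOQ) with a blank and a zero
per run, a ULOQ-then-blank carry-over pair (residual fraction 0.1 % by
default), 5 QC replicates per level per run over 3 runs (15 inter-run), five
8×-ULOQ dilution replicates, post-extraction spikes in 7 lots × 3 replicates
plus 3 solvent replicates, and stability sets at t0/24 h/30 d/12 m × 2
levels × 3 replicates — 133 samples per study, with record counts exposed by
`validation_design_counts` for design-arithmetic checks.

Application cohorts draw per-sample SG uniformly on (1.006, 1.031),
per-sample matrix factors from the same SG-driven model, and true
concentrations from a log-normal (median, GSD) with a point mass at zero for
the non-exposed fraction (defaults: median = 3 × LLOQ, GSD = 3, 75 %
exposed — values chosen once as typical of exposure-biomarker distributions
near an assay's quantification limit). The generating truth and lot factors
are retained for recovery checks. The default cohort size is 28.

What the generator does **not** emulate: chromatographic peak shape and
integration, retention-time drift, deconjugation kinetics, carry-over as an
actual injection-order process, inter-day response drift, and correlation
between repeated samples from one subject. Passing tests therefore certify
the statistical and rule-engine machinery, not instrument behavior.

## Problem sizes used in checks

Simulation-based checks run at sizes where their binomial/Monte-Carlo error
is well inside the asserted margins: 40–50 seeded replicate studies for QC
pass-rate and LLOQ-determination rates, 10,000 null pairs for t-test type-I
error (3 SE ≈ 0.65 points), 400–1000 replicates for matrix-factor
convergence, and n = 500 cohorts for GM/median recovery. The 16-analyte
end-to-end run uses one full validation design plus a 28-sample cohort.

## Known limitations

* Nonlinear (quadratic, 4PL) calibration and signal-to-noise-based detection
  limits are out of scope by design; the LLOQ is accuracy-defined.
* Censored summaries are substitution/rank-based; maximum-likelihood or
  Kaplan–Meier censored estimators are deliberately not provided.
* The isotope module resolves per-element convolution only (no fine
  structure within a nominal mass beyond distinct exact masses, no MS/MS
  fragment prediction).
* Vendor raw files are not parsed; peak areas are inputs.
* The printed-table reference rows used in checks are integer-rounded
  inputs; rows whose published summary statistics do not round-trip from
  their printed cells are not asserted against.
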