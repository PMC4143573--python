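# Methods

## Growth model and doubling-time estimation

Synthetic cultures follow a logistic trajectory

    OD(t) = od_max · od_init · e^{μt} / (od_max + od_init · (e^{μt} − 1))

with the specific growth rate μ (per hour) chosen by temperature
(`mu_30` at the permissive temperature, `mu_hot` under heat, with
0 < mu_hot ≤ mu_30). The logistic was chosen over a pure exponential because
real OD curves saturate; the exponential limit is available by making
`od_max` large. Measurement noise is additive Gaussian on the OD scale,
truncated at 10⁻⁶ so readings stay positive.

Doubling time is defined by T_d = (t₂ − t₁)/log₂(OD₂/OD₁). The package
generalises this to the inverse slope of a least-squares fit of log₂(OD)
against time over a window, which reduces exactly to the two-point formula
for a two-point window; a strict `mode="two-point"` is kept for the
endpoint-only definition. All internal work is on log₂, matching the
formula's base.

The "linear growth phase" is not given a formal definition by standard
practice, so the package defines it operationally: the contiguous window of
at least `min_points` samples maximising the coefficient of determination of
log₂(OD) vs t, ties broken toward longer then earlier windows. A brute-force
all-windows search is the test oracle for this selection. Two numerical
caveats are deliberate: R² is rounded to 12 decimals before comparison so
floating-point jitter cannot override the tie-break, and a flat curve raises
a no-growth error rather than returning a degenerate window.

Under additive OD noise the log-scale noise is heteroscedastic (large at low
OD), and short windows can fit noise with spuriously high R². The recovery
tests therefore use windows of at least half the curve (min_points = 6 of 12
samples at 0.35 h spacing, inoculum OD 0.1, noise SD 0.01): under those
conditions the regression estimate stays within 10 % of ln 2/μ. Deep into
logistic saturation the instantaneous doubling time genuinely lengthens, so
recovery of ln 2/μ is only meaningful while the culture is far from
carrying capacity; the tests sample OD below ~15 % of od_max.

The thermotolerance phenotype is the ratio T_d(low)/T_d(high), oriented so
larger values mean more tolerant; ranking sorts descending and reports exact
ties rather than breaking them silently.

## Expression matrix generator

Per strain, `n_replicates` control and heat samples (default 2, emulating
duplicate arrays from independently grown cultures). Gene baselines are
uniform on log₂ ∈ [4, 12]; noise is i.i.d. Gaussian on log₂ (log-normal
multiplicative on the linear scale) with SD `noise_sd` (default 0.1 log₂
units — a conservative figure for technical-replicate scatter on arrays;
no replicate-variance value is available to inherit, so this is a module
parameter, not a measured one). Background genes have expected fold change 1.
One planted gene receives an extra log₂(induction) in heat samples, with
induction per strain either given explicitly or defaulting to
1.5 + 3·tolerance (strictly increasing in tolerance). The planted gene is
assigned the median baseline so intensity filters treat it as a typical
detected transcript. Detection flags default to "present"; an optional
fraction of the dimmest background genes can be flagged "absent" everywhere.

What the generator does *not* emulate: probe-level structure, spatial or
batch artifacts, correlated noise between genes, strain-specific expression
backgrounds, and heat-responsive background genes (all non-planted genes are
null). Passing screens on this generator therefore demonstrate correctness
of the selection logic and its behaviour under replicate noise — not
robustness to the biological confounders of real arrays.

## Preprocessing and screen

* **75th-percentile shift**: log₂-transform, subtract each sample's 75th
  percentile of log₂ values (linear-interpolation quantile); the chosen
  percentile is exactly 0 afterwards. This removes per-sample global scale
  factors exactly. Note the shift does not cancel perfectly in fold changes
  when samples differ by more than a scale factor: percentile sampling noise
  propagates into the heat/control contrast. That is a property of the
  normalization itself, and the tests assert the exact-cancellation property
  only where it holds (per-sample rescaling of noiseless data).
* **Low-intensity filter** (fraction 0.2): a gene is removed only if it
  ranks in the lowest 20 % of *every* sample — the permissive reading, which
  keeps heat-induced genes that are silent in controls. Min-ranks are used
  so exact ties resolve independently of row order.
* **Flag filter**: kept iff called present/marginal in at least half the
  samples; matrices without calls pass everything. The ≥-half aggregation is
  this package's choice; only the flag vocabulary is standard.
* **Fold change**: geometric mean over replicates (difference of mean log₂
  values, back-transformed), the standard choice for intensity data;
  arithmetic-mean mode is available.
* **Differential (t-test) filter**: per-gene two-sample Student's t on log₂
  values, p < 0.05, no multiple-testing correction. Off by default in
  `run_screen`: with duplicate arrays the test is near-powerless, its
  position in the chain relative to the fold-change stage is a judgement
  call, and the stage-wise screen is meaningful without it. Degenerate tests
  (zero variance, equal means) are assigned p = 1.
* **Stages**: strict inequalities everywhere, so boundary values (a fold of
  exactly 1.5) fail. Stage 1 is evaluated on the tolerant and reference
  strains only and keeps up-regulated genes (a two-sided `absolute` mode
  exists). Stage 2 is an inclusive-or over the two fold-change ratios.
  Stage 3 demands strictly decreasing folds along the tolerance order; ties
  fail and are visible in the audit table.

Detectability of the planted gene at a given noise level is governed by the
stage-2 margin. The published candidate pattern planted in the recovery
tests (3.68/2.18/1.35) has fold-ratios 1.69 and 1.61 against the 1.5
threshold, giving ≥ 95 % recovery at noise SD 0.05 with duplicates; the
generic default induction map yields a first ratio of ~1.27 and is *not*
reliably detectable by stage 2 — a deliberate illustration that the screen
keys on fold-change *gradients*, not induction per se.

## qPCR model and quantification

Amplification is modelled as exact exponential growth with per-cycle gain
1 + E, E ∈ (0, 1]: Cq(c) = cq0 − log(c)/log(1 + E). Standard series use
10-fold dilutions 1/10 … 1/10000 by default. Every reported Cq is the mean
of `n_technical` independent reads (default 2, the usual technical-duplicate
practice) with Gaussian cycle noise. Curves are fit by OLS of Cq on
log₁₀(conc); efficiency is 10^(−1/slope) − 1, and a non-negative slope is an
invalid assay. Quantification inverts the fitted line,
conc = 10^((Cq − intercept)/slope); because the slope is negative, one
decade of *dilution* corresponds to Cq = intercept − slope. Technical
replicates are averaged on the Cq scale before inversion. Relative rates are
target/reference concentration; ratios are heat/control rates. A ΔΔCq
shortcut is provided for cross-checks only (it assumes shared efficiency).

Reference-gene stability compares the heat/control ratios of the primary
reference against a second one condition-by-condition; the pair passes when
every |log₂ deviation| ≤ 0.5 (within ~1.4-fold). The 0.5 tolerance is this
package's default for a qualitative "stable" call.

## Phenotype regression

OLS of expression ratio on T_d ratio on linear scales (a log-log mode
exists), R² = 1 − SS_res/SS_tot, requiring ≥ 3 distinct strains and
variance in the predictor; n = 3 fits are flagged `low_n`. The synthetic
cohort generator draws T_d ratios uniform on [0.3, 0.9] for 8 strains and
sets the response noise SD analytically from the realized predictor sample
variance so the population R² equals the requested value; with n = 8 the
fitted R² is upward-biased by a few hundredths, which the Monte-Carlo
calibration test (200 cohorts, mean R² in [0.7, 0.9] for a planted 0.8)
absorbs.

The published anchor values for this analysis (R² of 0.787 at 37 °C and
0.418 at 39 °C, and the verification ratios 8.50/4.50/3.47) cannot be
recomputed because the per-strain coordinates behind them were never
published; the package uses them as fixture inputs and checks the
qualitative facts they support — the ratio ordering is concordant with the
thermotolerance ranking, and the milder temperature shows the stronger
association.

## Randomness and reproducibility

All generators take one integer seed and derive independent substreams via
`numpy` `SeedSequence` spawn keys (one per generator family), so a single
pipeline seed fixes every stage and repeated calls are bitwise identical.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`: screens on
300–500-gene matrices with 3 strains × 2 conditions × 2 replicates
(recovery over 100 seeds); oracle comparisons on 50 random matrices up to
200 × 12; qPCR efficiency recovery over 200 seeds; regression calibration
over 200 8-strain cohorts; growth-curve recovery over 20–50 curves of 12
points. These sizes put Monte-Carlo error well below the asserted margins
while keeping the whole suite in seconds.

## Known limitations

* The screen's strict-monotonicity stage 3 is brittle to ties by design;
  with many strains a Spearman-threshold variant would be the natural
  relaxation, but only perfect concordance is implemented because that is
  the selection rule being modelled.
* The low-intensity and flag filters assume samples are comparable after
  the percentile shift; gross per-sample quality differences are not
  modelled or corrected.
* qPCR efficiency is assumed constant across the dilution range; real
  assays can show inhibition at high template loads.
* The phenotype regression is a simple per-gene OLS; no multi-gene or
  mixed-effects modelling is attempted.
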