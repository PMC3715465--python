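# Methods

This note documents the models, default parameters, numerical choices and
known limitations of the `mirqpcr` pipeline.

## Normalization model

All relative-abundance arithmetic assumes perfect amplification efficiency
(doubling per cycle): `-ΔCt` is treated as log2 relative abundance and fold
changes are `2^(difference of mean -ΔCt)`. Standard-curve efficiencies
(`10^(-1/slope) - 1`) are reported for QC but never re-scale the ΔCt math;
efficiency-corrected (Pfaffl-style) models are out of scope.

A cell is *valid* iff its Ct is determined and within `[ct_min, ct_max]`
(default 0–40); instrument validity flags supplied with the input may
additionally invalidate a determined cell, never the reverse. Undetermined
cells are NaN everywhere downstream — never zero, never imputed.

The average-Ct reference for the array phase is the arithmetic mean of all
valid Ct values per sample. Spike-in normalization subtracts the
cel-miR-39 Ct per sample and drops the spike column from the output.

## Absolute quantification

Copies per PCR reaction come from inverting the per-assay standard curve.
The volume chain to copies per litre of plasma is

```
copies/L = copies_per_reaction / pcr_fraction_of_rt
           × (eluate_volume / rt_input_volume)
           × (10^6 µl/L / plasma_volume)
```

with defaults: plasma 150 µl, eluate 37.5 µl, 5 µl of eluate into reverse
transcription, and one tenth of the RT product per PCR reaction. The
plasma and eluate volumes follow the extraction protocol being modelled;
the RT/PCR aliquots are declared defaults exposed in `VolumeConfig` and
logged with every concentration table, since the exact aliquoting of any
given protocol varies. Concentration is copies/L divided by Avogadro's
number, reported in pM. The conversion is strictly decreasing in Ct and
linear in 1/plasma-volume, which the tests verify.

## Normalizer stability

geNorm M is computed on log2-scale values (`-ΔCt`), sample SD with the
n−1 denominator throughout. Stepwise ranking removes the highest-M assay
until two remain (the pair shares rank 1); ties are broken by larger
raw-Ct SD, then lexicographically, so outputs are order-independent.
The V(n/n+1) "how many references" statistic is not implemented — the
modelled workflow selects a single normalizer.

NormFinder follows the published model. Values are centered within each
sample (absorbing the per-sample effect, which makes the method exactly
invariant to global shifts); within each group the centered-value
variances `u²` relate to the intra-group error variances by
`u²_j = σ²_j (1 − 2/k) + Σσ²/k²`, which is solved in closed form and
clamped at zero (for k = 2 only the pair variance is identified). The
inter-group bias `d` (group mean of centered values, centered across
groups) is shrunk by the empirical-Bayes factor `γ²/(γ² + σ²/n_g)`, where
`γ²` is the between-group bias variance net of sampling noise, floored at
zero. The stability value is the mean over groups of |shrunk bias| plus
the posterior SD; with one group it reduces to the intra-group SD. The
implementation is tested against a brute-force decomposition oracle that
solves the variance system numerically.

**Limitation** (by construction of both methods): on a small panel where
most assays are regulated in the same direction, the per-sample reference
point absorbs the average shift, so a marker whose effect happens to equal
the panel-average effect is mathematically indistinguishable from a stable
reference. Stability analyses should therefore run on array-scale data or
on a candidate set embedded in a mostly unregulated background, which is
what the shipped normalizer-comparison scenario does (n = 48/48, six
shift-free candidates, three shifted markers, thirty null assays).

## Screening rules

Phase-1 criteria (all two-sided on fold): fold ≥ 4 or ≤ 1/4; case-only
detection (valid in ≥ 50 % of cases — a declared reading of "detected only
in cases" — and in zero controls); equal-variance Student's t p < 0.05.
The manual-inspection rules are codified approximations, on by default and
individually configurable: 0.05 ≤ p < 0.1; mean raw Ct < 30 with fold ≥ 2;
and a leave-one-out rule that fires when omitting a single sample pushes
the fold across the 4-fold bar while the full data do not. Candidate
ordering is deterministic (criterion priority, then p, then assay id).
When a group has fewer than two samples the t-based criteria are skipped
with an explicit warning, never silently.

## ROC and cutoff selection

Thresholds are the observed score values plus a +∞ sentinel, with
"positive if score ≥ t" after direction adjustment; no interpolation, so
reported cutoffs are observed concentrations. AUC is the trapezoidal
area, identical to the Mann–Whitney probability with ties counted half
(verified against exhaustive pair counting). Cutoff selection maximizes
specificity among thresholds whose sensitivity+specificity sum is within
an absolute window (default 0.03) of the maximum; equal-specificity ties
go to the highest threshold (the most conservative call). Widening the
window can only raise the selected specificity, which is tested as a
property.

## Panel model and ePRAM

The panel is a plain maximum-likelihood binomial logistic regression
(statsmodels Newton/IRLS, no regularization). Features enter as raw
concentrations in pM by default, matching the modelled analysis; the
pipeline's evaluation utilities use log10 concentration where a Gaussian
scale is statistically appropriate (correlations, age strata). Perfect
or quasi-separation is detected (saturated fitted probabilities or a
non-converging likelihood climb) and raised as an explicit error; singular
designs (duplicated or constant features) are rejected up front.

Per-feature importance is the drop-one likelihood ratio
`2(ll_full − ll_reduced)` against χ²(1); no multiple-testing correction is
applied across the drop-one tests, mirroring the modelled workflow, and
the output notes this. Panel selection keeps features with LR p < 0.05
and refits; an `addition_check` reports whether any excluded feature would
significantly improve the refit panel.

ePRAM uses the sign convention `x = −η` (η the fitted log-odds of case
status), so `exp(−x)/(1+exp(−x))` *is* the fitted probability of disease
and the default cutoff 0.50 is the natural decision boundary. Models
serialize to flat key-value text with full float precision, so scores are
bit-for-bit reproducible.

Because the logistic model on raw pM is mildly misspecified when the
generative truth is a log-scale shift, the fitted panel's in-sample AUC can
very occasionally fail to exceed the strongest single marker on an
unlucky cohort; across seeds the panel dominates.

## Synthetic cohorts

The generator emulates the data structure of a plasma-miRNA biomarker
study, with Gaussian noise on the Ct scale (the standard qPCR assumption)
and hard censoring at a detection-limit Ct (default 40; a logistic-dropout
variant is deliberately not the default, to keep planted truths exactly
computable).

Default validation cohort: 102 RA, 104 HC, 24 OA, 11 SLE. Eight markers
with between-subject SD 2 cycles; RA shifts are derived from target
binormal AUCs via `Δ = Φ⁻¹(AUC)·σ·√2`, set to 0.92 (miR-125a-5p), 0.85
(miR-24), 0.74 (miR-26a) and descending values for the remaining five.
The published record of the modelled study fixes only the *ordering* of
the top markers; these targets were chosen once so that the ordering is
stable across seeds at the default cohort size (adjacent gaps ≥ 0.07,
comfortably above the ≈ 0.03 sampling SD of an AUC at n ≈ 100/100).
OA and SLE carry per-marker attenuated shifts calibrated to published
true-negative percentages (e.g. OA at 0.32 and 0.25 of the RA shift for
miR-24 and miR-125a-5p). The normalizers miR-30a-5p and miR-301a-5p are
shift-free with raw-Ct SDs 1.12 and 1.36; the spike-in SD is 0.5 cycles
(all three values as summarized for the modelled study).

Clinical covariates use a Gaussian copula on the latent marker noise, so a
planted Pearson correlation is exact in expectation *on the log
(Ct) scale*; correlating with raw concentrations would attenuate r by the
lognormal factor `τ/√(e^{τ²}−1)`. The default plants r = −0.25 between
miR-125a-5p and age in RA, plus disease-activity correlations for miR-24.
ACPA positivity is Bernoulli(0.85) in RA; ages are cohort-specific
Gaussians clipped to [18, 100]; drug flags are independent Bernoullis at
the published usage rates and independent of marker levels (so treatment
association is null by construction).

The 3 vs 3 array phase plants member assays for every screening class —
counts mirror the published lists (10 fold-change, 3 case-only, 7
p < 0.05) — plus six stable normalizer candidates and 250 null assays.
Planted effects are sized so that, after average-Ct normalization (whose
reference moves slightly because planted shifts are a small fraction of
the panel), each class is recovered by its own criterion essentially
always at n = 3/3; null assays still produce the expected handful of
false positives, which the audit table reports.

What the synthetic data do **not** model: plate/batch effects, amplification
efficiency differences between assays, heavy-tailed outliers (available as
an option, not default), stochastic dropout curves, and correlated marker
noise within subjects. Passing tests therefore demonstrate correctness of
the pipeline's statistics and bookkeeping under the stated noise model,
not robustness to those real-data artifacts.

## Problem sizes used in the shipped checks

Simulation-based checks use: 10 000 replicates for t-test and Pearson
type-I calibration; 400 refits for the null-LR moments; 200 replicates at
n = 2000 for logistic coefficient recovery; 10–40 seeds for cohort-level
recovery and ordering checks; exhaustive enumeration for Fisher-exact and
ROC oracles. These sizes give Monte-Carlo standard errors comfortably
below the asserted tolerances while keeping the full suite fast.

## Degenerate inputs and tie-breaks (summary)

- Zero pooled variance in a t-test: p = 1 for equal means, p = 0 with a
  warning otherwise.
- Zero-variance correlation pairs: reported as undefined, not raised.
- Empty panel selection: intercept-only model with a warning.
- Stepwise geNorm ties: larger raw-Ct SD excluded first, then
  lexicographic.
- Cutoff ties: highest threshold; the +∞ sentinel is never selected when a
  finite threshold is eligible.
- Age strata with n < 2 in either group: flagged `insufficient_n`, kept in
  the table.
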