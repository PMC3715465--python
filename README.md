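# mirqpcr

A tested, reusable pipeline for discovering circulating microRNA biomarkers
from qPCR threshold-cycle (Ct) data, modelled on the multi-phase design used
to establish plasma miR-24 and miR-125a-5p as diagnostic markers for
rheumatoid arthritis (RA). It covers the full arc of such a study:

1. **Screen** — a small TaqMan-array-style cohort (3 RA vs 3 healthy
   controls) is normalized to the average Ct of all validly amplified
   assays; candidates are selected by fold change (≥4), case-only
   detection, Student's t (p < 0.05), and codified "manual inspection"
   rules (borderline p, high-abundance two-fold change, leave-one-out
   outlier folds).
2. **Confirm** — candidates are re-tested in a small cohort with spike-in
   (cel-miR-39) normalization; quality-failed assays are delisted with an
   audit trail.
3. **Validate** — absolute concentrations (pM) are computed from per-assay
   standard curves, each marker gets a ROC curve with the study's
   specificity-biased cutoff rule, and a multivariable logistic panel
   produces the **ePRAM** probability score.
4. **Evaluate** — specificity in osteoarthritis (OA) and lupus (SLE)
   cohorts, ACPA-subgroup sensitivity, clinical-covariate correlations,
   age strata, and treatment association.

Because validation-scale plasma qPCR datasets are rarely public, the
package ships a first-class synthetic-cohort generator with planted truths
(effect sizes, detection limits, normalizer stability, covariate
correlations) so every stage is testable end to end.

## The core quantities

With `Ct[s, a]` the threshold cycle of assay *a* in sample *s* and
`ref[s]` a per-sample reference (average Ct or spike-in):

- relative abundance: `-ΔCt[s, a] = ref[s] - Ct[s, a]` (log2 scale;
  fold change between group means is `2^(Δ mean -ΔCt)`);
- absolute quantification: a standard curve
  `Ct = slope · log10(copies) + intercept` (efficiency
  `10^(-1/slope) - 1`) inverts to copies per reaction, scaled through the
  extraction/RT/PCR volume chain to copies per litre of plasma and divided
  by Avogadro's number to picomolar;
- normalizer stability: geNorm `M_j` (mean SD of pairwise log ratios) and
  the NormFinder model-based stability value (intra-group variance plus
  shrunken inter-group bias), lower = more stable;
- cutoff selection: with `J(t) = sensitivity + specificity` and `M = max J`,
  the chosen threshold maximizes **specificity** among thresholds with
  `J ≥ M − 0.03`;
- panel score: `ePRAM = exp(−x) / (1 + exp(−x))`, where `x` is the negated
  linear predictor of a logistic model on marker concentrations, so ePRAM
  is the fitted probability of RA; a sample is called positive when
  ePRAM ≥ 0.50. Per-marker importance is the drop-one likelihood-ratio
  chi-square (1 df).

## Worked example

```python
from mirqpcr.synthetic_data import calibrate_to_paper_defaults, generate_validation_cohort, EPRAM_FEATURES
from mirqpcr.normalization import fit_standard_curve, ct_to_concentration
from mirqpcr.diagnostics import roc_curve, select_cutoff
from mirqpcr.panel_model import fit_logistic, epram_score

cohort = generate_validation_cohort(calibrate_to_paper_defaults(seed=1))
curves = {a: fit_standard_curve(s) for a, s in cohort.dilution_series.items()}
conc = ct_to_concentration(cohort.ct, curves).conc_pm

cc = cohort.groups.isin(["RA", "HC"])
labels = (cohort.groups[cc] == "RA").to_numpy()
roc = select_cutoff(roc_curve(conc.loc[cc, "miR-125a-5p"], labels))
print(f"miR-125a-5p AUC {roc.auc:.3f}, cutoff {roc.cutoff:.3g} pM, "
      f"sens {roc.sens_at_cutoff:.1%}, spec {roc.spec_at_cutoff:.1%}")

model = fit_logistic(conc.loc[cc, list(EPRAM_FEATURES)], labels.astype(float))
scores = epram_score(model, conc.loc[cc, list(EPRAM_FEATURES)])
print(f"ePRAM AUC {roc_curve(scores, labels).auc:.3f}")
```

Output:

```
miR-125a-5p AUC 0.921, cutoff 0.115 pM, sens 71.6%, spec 97.1%
ePRAM AUC 0.956
```

The single-marker AUC reflects the planted binormal separation of
miR-125a-5p (a 3.97-cycle shift at 2 cycles between-subject SD gives
Φ(3.97/(2·√2)) ≈ 0.92); the three-marker ePRAM panel improves on every
single marker. The cutoff sits where specificity is maximal within 0.03 of
the best sensitivity+specificity sum.

The same flow is available from a shell:

```bash
mirqpcr run-all --seed 7 --out run7        # all four phases + manifest
mirqpcr generate --phase array --out arr   # synthetic cohort CSVs + truth JSON
```

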