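# pvpassport

Plasma-volume-aware interpretation of Athlete Biological Passport (ABP)
hematology profiles.

## The problem

The ABP monitors an athlete's hemoglobin concentration [Hb] and OFF-score
against *individual* Bayesian reference limits; values outside the limits
are atypical passport findings (ATPFs) that trigger expert review.  [Hb]
is a concentration: total hemoglobin mass Hb\_mass is diluted in the blood
volume BV = PV + RCV (plasma volume + red-cell volume), so

> [Hb] = 100 · Hb\_mass / BV   (g·dL⁻¹, with mass in g and volumes in mL)

Acute plasma-volume shifts of up to ~25% — hyperhydration, exercise
hemoconcentration, heat or altitude exposure — move [Hb] without any
change in red-cell mass, producing ATPFs that have nothing to do with
doping.  This package implements a PV-aware review pipeline:

1. **PV estimation** — a trainable regression model (OLS, boosted trees,
   or kernel ridge) maps one complete blood count (CBC: [Hb], HCT, RBC,
   RET%, MCV, MCHC) plus sex, age, height and (optionally) weight to
   absolute PV in mL.  A weight-free variant supports settings where body
   weight is unreliable.
2. **PV overlay** — per-sex z-scores of the estimated PV are drawn on a
   second axis of the longitudinal profile.
3. **Limit correction** — between successive visits the relative PV
   change ΔPV\_rel = (PV\_i − PV\_{i−1})/PV\_{i−1} is scaled by a per-sex
   weighting index *R²* (default 0.28 men / 0.42 women, the share of [Hb]
   variance attributable to PV), and both [Hb] limits are translated by
   −ΔPV\_weighted · (lower+upper)/2.  The interval width is preserved
   exactly; a dilution lowers the limits, a contraction raises them.
4. **Reclassification** — an ATPF whose value falls inside the corrected
   limits is re-labelled *explained by PV*; visits pushed outside the
   corrected limits are reported as "new outlier" diagnostics.
5. **Sensitivity analysis** — each CBC marker is perturbed by
   ±0.05/±0.1/±0.2% and the mean change of the PV estimate (mL) is
   tabulated per marker and level.

Individual limits are produced by a normal–normal empirical-Bayes
surrogate of the official ADAMS model: the predictive interval for the
next observation given the subject's history, at configurable
specificity (default 99%).  OFF-score limits are computed and flagged
but never PV-corrected (its reticulocyte term is PV-independent).

A physiologically coupled synthetic-cohort generator (mass-conservation
physiology, AR(1) plasma volume, analyzer noise, and stylized
hyperhydration / exercise / altitude / transfusion / rhEPO events with
ground-truth PV) makes the whole pipeline testable end to end.

## Worked example

Simulate a six-athlete cohort with an acute +15% hyperhydration at
visit 9, train the default estimator on a heterogeneous reference
cohort, and correct the profiles:

```bash
pvpassport simulate --seed 7 --n-subjects 6 \
    --event hyperhydration:9:0.15 --out cohort.csv --truth-out truth.csv
pvpassport simulate --seed 1 --n-subjects 34 --training-mix --out train.csv
pvpassport train --input train.csv --out model.joblib --kind tree_ensemble --seed 1
pvpassport correct --input cohort.csv --model model.joblib --out-dir out
```

which prints

```
INFO profiles: 6 subjects, 72 samples, 0 [Hb] ATPFs, 3 explained by PV, 0 new outliers
{
  "n_subjects": 6,
  "n_samples": 72,
  "n_hb_atpf": 0,
  "n_hb_atpf_explained_by_pv": 3,
  "n_offs_atpf": 0,
  "n_new_outliers": 0
}
```

Three of the six athletes dipped below their individual lower [Hb] limit
at the hyperhydration visit; in every case the estimated PV surge
translated the limits downward far enough to absorb the finding, so all
three ATPFs are explained by PV and none survive as suspicious.  The
per-visit table (`out/corrections.csv`) shows the mechanics, e.g. for
subject S001 at the event visit:

```
subject_id  visit  hb      pv_estimated  delta_pv_rel  delta_pv_wt  shift   lower_orig  lower_corr
S001        9      13.918  4072.2        0.091         0.025        -0.373  13.495      13.122
```

a +9.1% estimated PV jump, weighted by the male index 0.28, lowers both
limits by 0.37 g·dL⁻¹.  `pvpassport render` draws the two profile views
(corrected limits; PV z-score overlay), and `pvpassport validate`
reports Spearman correlation and Bland–Altman agreement when measured PV
is available.

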