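# Methods

## Markers and units

[Hb] is stored in g·dL⁻¹ everywhere; the ×10 in the OFF-score,
OFFs = [Hb]·10 − 60·√RET%, is the g·dL⁻¹ → g·L⁻¹ conversion and is
applied only inside `compute_off_score`.  HCT is %, RBC 10⁶·µL⁻¹, MCV
fL, MCHC g·dL⁻¹, plasma volume mL.  Visits are ordinal (`visit_index`);
real dates are accepted in CSV input and mapped to per-subject order —
no computation uses elapsed time.

## Individual reference limits (surrogate)

Official ABP limits come from a proprietary adaptive Bayesian model
inside ADAMS.  We implement the standard normal–normal empirical-Bayes
surrogate: subject mean θ ~ N(μ_pop, σ_b²), observations x | θ ~
N(θ, σ_w²).  After n samples with mean x̄ the next observation is
predicted as N(m_n, σ_w² + v_n) with

    m_n = (n·x̄/σ_w² + μ_pop/σ_b²) / (n/σ_w² + 1/σ_b²),
    v_n = 1 / (n/σ_w² + 1/σ_b²),

and limits m_n ∓ z_{(1+s)/2}·√(σ_w² + v_n) at specificity s (default
0.99, the conventional ABP operating point).  Limits for visit *i* use
history strictly before *i* (prequential), matching passport usage.
The limits narrow with history and are exactly calibrated when the data
really follow the two-level model; the correction procedure downstream
is agnostic to how the limits were produced.

Default priors (configurable per marker × sex, order-of-magnitude
hematology norms): [Hb] μ = 15.2 / 13.4 g·dL⁻¹ (M/F), σ_b = 0.9,
σ_w = 0.45; OFFs μ = 90 / 80, σ_b = 12, σ_w = 8.  A value is an ATPF iff
it falls strictly outside its limits (boundaries are inside).

## Plasma-volume estimator

Features: the six CBC markers plus sex (male = 1), age, height, weight;
`weight_free=True` drops weight (absolute accuracy falls slightly; the
visit-to-visit PV *changes* the correction consumes are barely
affected).  Three regressor kinds:

* `linear` — scaled OLS.  Kept strictly linear so its sensitivity grid
  is exactly proportional to the perturbation level and realizable
  linear targets are recovered to numerical precision.
* `tree_ensemble` (default) — gradient-boosted trees initialised with
  an OLS baseline: the linear part carries the smooth concentration and
  anthropometric signal, the trees add interaction corrections such as
  discounting hematocrit excursions that co-occur with suppressed
  reticulocytes.  600 trees, depth 3, learning rate 0.05, min leaf 10,
  subsample 0.9, seeded.
* `kernel` — RBF kernel ridge (α = 0.01, γ = 0.05) with standardized
  features and target.

Estimates are deterministic given the fitted artifact; predictions
below a 100 mL floor are clamped with a warning.  Training requires
≥ 30 samples with measured PV.  The default artifact is *regenerated
deterministically* from a seed (120-subject heterogeneous synthetic
cohort, ~1440 points) rather than shipped as a binary, so every run is
reproducible from source.  The training preset mixes controls with
hyperhydration, exercise-hemoconcentration, altitude, transfusion and
rhEPO scenarios, emulating a reference population diverse enough to
expose the estimator to both fluid-shift and erythropoietic states.

Validation uses Spearman rank correlation and Bland–Altman agreement
(bias = mean(estimated − measured); limits of agreement = bias ±
1.96·SD), pooled and per sex.  The sensitivity analysis perturbs one
marker at a time by ±0.05/±0.1/±0.2% and reports the mean change of the
estimate in mL; a zero level is exactly 0 by construction.

## Limit correction

Between successive visits, ΔPV_rel = (PV_i − PV_{i−1})/PV_{i−1} is
multiplied by the per-sex weighting index — the R² of the simple linear
regression between estimated PV and [Hb] (defaults 0.28 men, 0.42
women; refittable from any cohort with `fit_weighting_indices`; R² is
orientation-free for simple regression, so which variable is the
response is immaterial).  Both limits are translated by
−ΔPV_weighted · midpoint: a PV expansion (dilution) lowers the limits,
tracking the expected fall in [Hb].  Corrections are strictly per-visit
against the immediately preceding visit and never accumulate; the first
visit has shift 0.  All arithmetic is kept in full precision; rounding
to 0.1 g·dL⁻¹ happens only at display time.

`CorrectedLimitPair` stores (lower, width, shift) with the upper bound
derived as lower + width, so interval preservation is exact by
construction instead of depending on the rounding of two independently
shifted doubles.

An original-limits ATPF whose value lies inside the corrected limits
becomes `atpf_explained_by_pv`.  A visit inside the original limits but
outside the corrected ones keeps flag `none` and is surfaced as a
"new outlier" diagnostic — the translation should not manufacture
findings.  OFF-score limits are never corrected.

## Synthetic cohorts

Each subject is built from mass conservation: Hb_mass (g) and PV (mL)
are the state variables; red-cell volume is rcv = Hb_mass/(MCHC_cell/100)
with a per-subject cellular hemoglobin concentration ~ N(33.5, 0.8²)
g·dL⁻¹, and [Hb] = 100·Hb_mass/(PV + rcv) pre-noise.  Baselines:
heights/weights N(180, 6²)/N(75, 8²) for men and N(167, 6²)/N(62, 7²)
for women; PV from a linear allometric rule (25 mL·cm⁻¹, 15 mL·kg⁻¹
around per-sex anchors 3600/2800 mL, residual SD 150/130 mL); Hb_mass =
13.3/10.1 g·kg⁻¹ body mass (residual SD 35/30 g), calibrated so cohort
[Hb] means land on 15.2/13.4 g·dL⁻¹.  The tight mass–weight coupling
describes a homogeneous endurance-trained cohort; it is what makes
absolute PV identifiable from a CBC plus anthropometrics at all, since
Hb_mass itself is unobservable from concentrations.

PV follows a stationary log-AR(1) around its baseline (CV 5%,
month-to-month autocorrelation ρ = 0.3); Hb_mass has 1% i.i.d.
within-subject variation.  Markers derive from the state and get
multiplicative analyzer noise (CV: [Hb] 1%, HCT 1%, MCV 0.8%, RBC 0.5%,
RET% 2%); RBC and MCHC are derived from the noised HCT/MCV/[Hb], so the
identities HCT = RBC·MCV/10 and MCHC = [Hb]/HCT·100 hold within the
noise model.  RET% baselines are lognormal (median 1%, log-SD 0.35)
with 0.15 log-SD biological visit noise.  Measured PV, when included,
carries 2% measurement error (CO-rebreathing-like test error).

Event templates (magnitudes are fractions; PV-type magnitudes are
capped at 25%, the acute physiological range): hyperhydration /
exercise-hemoconcentration scale PV up/down for one visit; altitude
lowers PV for three visits and ramps Hb_mass up slowly; transfusion
raises Hb_mass (and rcv) persistently with RET% suppressed ×0.4 for two
visits; rhEPO boosts RET% ×2 for two visits then ramps Hb_mass.  The
default cohort mirrors a monthly one-year monitoring design: 40
subjects (27 men, 13 women) × 12 visits.

What the generator does *not* emulate: pharmacokinetics, seasonal and
training-load trends, analyzer drift between laboratories, and the
within-hours time course of acute events — passing tests show the
pipeline's mechanics and discrimination under idealized physiology, not
field performance.

## Test and experiment problem sizes

The experiment helpers use: ~400 training / ~100 held-out samples for
parameter recovery; 200-subject cohorts for the dilution (+15% PV) and
transfusion (+10% Hb_mass) scenarios with the event at visit 9;
2000 two-level-normal subjects for limit calibration; 20 repeated
40-subject clean cohorts for the new-outlier frequency.  These sizes
give stable Monte-Carlo estimates in seconds while keeping the full
suite fast.

## Known limitations

* **Transfusion masking.**  A transfusion moves [Hb] and HCT in almost
  exactly the same coherent pattern as a plasma-volume contraction, so
  a single-CBC estimator reads it as hemoconcentration and the
  corrected limits absorb a large share of marginal transfusion ATPFs.
  The only discriminating signal in a single CBC is RET% suppression,
  and without the subject's RET% baseline it is diluted by
  between-subject RET% spread.  Corrected limits must therefore never
  be used to dismiss high-[Hb] findings automatically; they are a
  visual aid beside the uncorrected profile.
* **Successive-point referencing.**  ΔPV uses the immediately preceding
  visit.  When PV autocorrelation is low, the previous visit's
  fluctuation acts as noise in the shift and can occasionally push a
  near-limit value outside the corrected interval (~0.25 expected new
  outliers per 480-visit clean cohort).  A rolling-baseline reference
  would suppress this at the cost of deviating from the per-pair
  definition of the fluid shift.
* The male weighting index recovered from synthetic cohorts (~0.05–0.15)
  is smaller than the 0.28 default because male [Hb] variance in the
  generator is dominated by between-subject mass differences; the
  female index (~0.40–0.46) matches its default closely.
* The empirical-Bayes surrogate is not the official ADAMS model;
  absolute ATPF counts are not comparable to official passports.
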