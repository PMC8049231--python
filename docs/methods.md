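# Methods

This note documents the models, estimators and design choices behind
`mechanosep`: what the synthetic cohorts emulate, how the per-cell
deformation waveform and its estimators are closed against each other, how
the score model is trained and banded, and which numerical and statistical
conventions are used. It also states what passing tests do and do not show
about real instrument data.

## 1. Synthetic cohort model

### Latent severity factor

Each subject carries a scalar latent severity `a` — an immune-activation
axis — drawn `a ~ N(m_state, 1)` with state means 0 (healthy), 1.0
(non-septic SIRS) and 2.9 (septic). Every quantity that differs between
disease states depends on the state **only through this factor**:
biophysical metric means, leukocyte differential, within-subject spread and
clinical outcomes. This is the central calibration device of the package.
Because all class information flows through one scalar, the best achievable
septic-vs-SIRS classifier AUC is capped at Φ(1.9/√2) ≈ 0.911 regardless of
how many features are measured, reproducing the redundancy of the real
biomarkers: a model built on such data cannot be unrealistically perfect,
and cross-validated AUCs land around 0.87–0.95 by construction rather than
by tuning the classifier.

The alternative — drawing per-state feature means with a generic
equicorrelation — was rejected on analysis: with per-metric standardized
group shifts of ~1.4–1.8, any fixed correlation structure leaves a
multivariate contrast that cancels the shared variation, and the optimal
AUC exceeds 0.97. Only the proportional-shift (single-factor) structure
caps it at the observed level.

### Biophysical metrics

Subject-level means of size, AR, VEIR and log optical intensity per cell
type are

    mean_i(subject) = state_mean_i + λ_i · (a − m_state) + idio_i(state) · e_i

with loadings `λ_i = (septic_mean_i − healthy_mean_i) / 2.9` fixed by the
healthy→septic group margins, and idiosyncratic SDs topping the total
between-subject SD up to the configured per-state values. Healthy and
septic means/SDs for neutrophil and monocyte AR and VEIR are the published
group statistics (e.g. neutrophil AR 2.55 ± 0.24 → 3.13 ± 0.32, monocyte
VEIR 8.26 ± 0.79 → 10.41 ± 0.90 μm); SIRS means sit on the factor line
(healthy mean + λ). Lymphocyte trends (weak), cell sizes (lymphocyte 7.0,
neutrophil 8.5, monocyte 9.5 μm, +0.3 μm septic shift for the myeloid
types) and optical intensities (gating channel; log-intensity 2.4 / 4.1 /
3.1, SD 0.06) are not published and are package choices. The subject-level
idiosyncratic deviations of (size, AR, VEIR) are equicorrelated with
ρ = 0.8: mechanically stiffer, strongly deforming cells also recoil
further. The same ρ applies to the cell-level deviations.

Cell-level values scatter around the subject means with SD =
`within_sd_factor` (default 2.0, an unvalidated choice — single-cell
scatter plots suggest a broad spread) times a severity-interpolated
between-subject SD. Making the cell-level SD a *deterministic* function of
the factor matters: if it depended on the state label directly, per-subject
SD and percentile features (estimated from 2,000 cells with negligible
error) would identify the state almost perfectly and break the AUC cap.

Per-cell VEIR is composed physically: `VEIR = stretch + margin`, where
`stretch = d(√AR − 1)` is the cell's own stretch amplitude and the recoil
margin is non-negative, centered so the subject's mean VEIR hits its drawn
target. This respects the identity that a full-excursion VEIR can never be
smaller than the stretch itself (Section 2) without clamping bias.
**Known residual**: the published septic monocyte AR SD (0.60) combined
with the VEIR SD (0.90) implies occasional subjects whose mean stretch
exceeds their mean VEIR target, which the margin floor resolves upward;
this inflates the recovered septic monocyte VEIR group mean by roughly
+0.1 μm (~1%), within the Monte-Carlo acceptance tolerance but systematic.

### Leukocyte differential and counts

Type fractions per subject are softmax of base logits (healthy differential
30/60/10 lymphocyte/neutrophil/monocyte) shifted along the factor (septic
expectation ≈ 14/75/11, neutrophilia) plus N(0, 0.4) subject noise. The
noise term is essential: with fixed per-state fractions, the multinomial
standard error at 2,000 cells (~0.01) would make the neutrophil fraction a
near-perfect classifier. WBC concentration is lognormal per cohort,
parameterized by the published median/IQR (healthy 6.0 (4.9–7.0) ×10³/μL;
high acuity 13.8 (10.1–17.5)).

### Clinical outcomes

SOFA (rounded softplus link, clipped 0–24), APACHE-II, PIRO, length of
stay (lognormal), ICU admission and in-hospital death (logistic links) are
monotone functions of `a + cohort_offset`. The low-acuity cohort gets a
clinical-only offset of −0.8 (site acuity affects outcomes and resource
use, not cellular state), so cellular metrics are identical conditioned on
the factor. Link constants were calibrated once by simulation against the
published cohort summaries (high acuity: SOFA median 4 (2, 5), APACHE-II
15 (12, 19), LOS 4 (2, 6), ICU 26.4%, mortality 10.1%, with the low-acuity
counterparts) and frozen in `ClinicalLinks`. Survival is followed for 30
days: deaths get an exponential event time (scale 9 d, truncated), all
others are right-censored at 30 days. Healthy donors carry no clinical
outcomes. Demographics are sampled to the published marginals and have no
effect on any metric.

Cohort compositions are fixed counts, not sampled: exactly 72/307 septic
(high acuity) and 6/94 (low acuity).

## 2. Deformation waveform and estimators

Each event is a 10–15-frame descriptor sequence (centroid, ellipse axes,
orientation; frame count uniform on {10,…,15}):

* frames 0–2 — upstream rest, axial extent `d`;
* frames 3–5 — stretch plateau at the junction, axial `d√AR`,
  area-preserving transverse `d/√AR`;
* frames 6–8 — recoil trough, axial `d + stretch − VEIR`;
* frames 9+ — damped alternation about `d` with per-extremum decay
  exp(−ζπ/√(1−ζ²)), damping ratio ζ = 0.3, with re-expansion capped at
  0.9× the stretch amplitude so the junction peak is always the global
  maximum.

During relaxation the projection is isotropic (the cell is round again; its
apparent diameter rings down), so the stretch plateau is the unique
aspect-ratio maximum. Control beads (8.86 μm carboxylated polystyrene) are
rigid spheres: AR 1, VEIR 0. Gaussian descriptor noise (default SD 0.1 μm)
is added last.

VEIR is operationalized as the **full excursion (max − min) of the axial
extent over the event**, in μm. The instrument's exact definition is not
public; this choice reproduces the published magnitudes (6–10 μm), depends
on size and recoil as described, and makes the generator and estimator a
closed pair. Consequences: feasible VEIR lies in `[d(√AR−1), d(√AR−1) +
0.95 d]`, and out-of-range cells are rejected by the synthesizer with the
offending cell id.

Estimators (identical for the descriptor path and the image path):

* **AR** — max over frames of major/minor after 3-point median smoothing;
* **VEIR** — excursion of the 3-point-median-smoothed axial-extent series
  (the axial extent is reconstructed from axes + orientation; during the
  recoil undershoot it is the *minor* axis);
* **rest size** — median of √(major·minor) over frames up to the peak
  (area-consistent, so the stretch frames do not bias it);
* intensity is carried through from the acquisition (no optical model).

Design notes that make the round trip exact and unbiased: extrema are held
for three frames, so the 3-point median filter passes them unchanged on
clean data and reads an unbiased plateau median on noisy data (a 2-frame
plateau would systematically read the smaller of two noisy samples, a
−0.56σ bias); the median filter itself guards the extremum statistics
against single-frame outliers. Noise-free recovery of (AR, VEIR, size) is
exact to 1e-9 over the entire feasible parameter region (property-tested);
at default noise, group-mean recovery errors are below ~1%.

The image path renders descriptors as supersampled-coverage ellipses
blurred by a 1 px Gaussian PSF; detection is background-subtracted Otsu
thresholding for labeling, then intensity-weighted second-order moments per
component with the known PSF + pixel-integration variance (σ² + 1/12)
removed, giving axes accurate to well under 2% for axes ≥ 4 px. Frame
linking is nearest-centroid with a gate of twice the nominal per-frame
advection and a 5-frame minimum trace length.

Run QC uses the control beads: a run is accepted iff ≥ 95% of beads fly
straight (transverse deviation < 1 μm) and the median bead speed is within
±10% of nominal. These thresholds are package defaults (the instrument's
values are not public) and configurable. Clogged runs (simulated: ≥ 30% of
beads deflected and slowed ≥ 25%) fail the trajectory check.

## 3. Gating and features

Gating fits a 3-component full-covariance Gaussian mixture in (log size,
log intensity) — both positive and right-skewed, and a global intensity
rescale is a pure log shift that leaves assignments invariant. Components
map to types by ordering rules (smallest+dimmest → lymphocyte, largest →
monocyte, remainder → neutrophil), which is deterministic and label-stable.
Degeneracy is detected two ways: a collapsed component (weight < 1%), or a
single Gaussian explaining the cloud at least as well as three by BIC
(events of a single type). Events with maximum posterior < 0.5 are labeled
`uncertain` and excluded from per-type features. Beads are removed before
fitting by flag and by signature (size within 0.3 μm of 8.86 μm, AR < 1.15,
VEIR < 1 μm). On default synthetic cohorts, assignment accuracy is ≥ 0.99.

The feature registry is 48 features: {lymphocyte, neutrophil, monocyte} ×
{size, AR, VEIR} × {mean, median, SD, p25, p75} plus the three type
fractions; percentiles use linear interpolation. The registry is a
reconstruction — the instrument's actual feature list is not public — and
spans the summary-statistic grid that population-level descriptors of this
kind use. Subjects with fewer than 500 typed cells, or any subpopulation
below 10 cells, are flagged `insufficient` and excluded from training.

## 4. Score model

Classification is L1-regularized logistic regression (the penalty is the
feature selector), maximizing Σ log p(y|xβ+β0) − λ‖β‖₁ with an unpenalized
intercept, on features standardized to the training set. The solver is
liblinear with the intercept bundled at scaling 1000 (making its effective
penalty negligible), tolerance 1e-5.

Validation architecture: a stratified sequester split holds out 69/307
subjects; nested cross-validation (5 outer × 5 inner folds; λ grid
logarithmic over [1e-3, 10], 13 points) on the remaining 238 selects the
penalty inside each outer fold and reports held-out outer AUCs; the final
model re-selects λ by 5-fold CV on the full cohort and refits on all 307.
The reported cross-validated AUC averages the outer folds of 3 repeated
outer partitions (a single 5-fold partition of 307 subjects carries ~0.03
partition noise). The repeated 10-fold stability analysis (10 repeats)
refits each fold at the final model's penalty; re-selecting λ in every fold
costs ~50× more and changes the mean by less than the fold noise.

The ISI maps log-odds affinely: `a = IQR_target / IQR(logodds)`,
`b = median_target − a·median(logodds)`, anchored to the published
high-acuity score distribution (median 4.8, IQR 3.7–6.1). This pins the
mapped training median and IQR *width* exactly; individual quartiles match
only up to distributional asymmetry. Scores are rounded to a 0.1 grid and
clipped to [0.1, 10.0]; bands are Green ≤ 5.4, Yellow 5.5–6.7, Red ≥ 6.8 —
a partition with no gaps or overlaps at 0.1 granularity. With this
calibration, the synthetic high-acuity Green-band share lands at 62–66%
across seeds.

## 5. Evaluation statistics

AUC is computed by pair counting with ties at 1/2 (equivalently the
Mann-Whitney statistic; it equals trapezoidal ROC integration, which is
property-tested against an independent implementation). AUC CIs are
percentile bootstrap, resampling subjects with replacement, 1,000
replicates; degenerate one-class resamples are redrawn. Proportion CIs are
exact Clopper–Pearson by beta-quantile inversion (tested against direct
bisection of the binomial tails). Band diagnostics treat Red as
test-positive and Green as test-negative: NPV is the non-septic fraction of
Green, and the diagnostic odds ratio compares the odds of sepsis between
Red and Green, with a Haldane 0.5 correction (flagged) on zero cells.
Cohen's d uses the (n−1)-weighted pooled SD. Group tests are Welch's t
(Satterthwaite df), Mann–Whitney U (normal approximation with tie
correction) or one-way ANOVA, all two-sided. Hospital-free days are
28 − LOS floored at 0, with in-hospital death → 0. Survival uses
Kaplan–Meier product-limit curves with right-censoring and the log-rank
test (chi-square, 1 df for two groups); no multiple-testing correction is
applied anywhere.

## 6. Problem sizes and determinism

Default desk scale is 2,000 cells per subject (a full-scale preset of
47,000 matches the instrument's per-sample throughput); at desk scale the
three cohorts comprise ~950k cell events, synthesized and estimated in
vectorized batches in ~30 s. Every random draw descends from explicit
integer seeds (cohort spec, trace synthesis, validation plan); rerunning a
pipeline with the same config is bit-identical, including CSV artifacts
(floats are written at %.17g so staged CLI runs and in-memory runs agree
exactly).

## 7. What the synthetic data do and do not show

The generator reproduces the published *group-level* structure: cohort
compositions, biophysical group means/SDs and their severity ordering,
leukocyte differentials, score distribution anchors, clinical-outcome
summaries, and a classifier ceiling matching the published AUC. It does
not emulate: real optics or segmentation artifacts (the image path is an
idealized renderer), cell–cell interactions, doublets or debris, the
instrument's true VEIR computation (our excursion definition is a
reconstruction), comorbidity structure, missing data, or any
demographic–metric association. Passing the acceptance suite therefore
demonstrates that the pipeline's measurement, gating, aggregation,
training and evaluation machinery is correct and well-calibrated — not
that the score would achieve these operating characteristics on new
clinical data.

Known limitations worth repeating: the septic monocyte VEIR group mean
carries a ~+1% systematic from reconciling the published AR/VEIR marginals
with the excursion identity; the sequestered-set AUC at n=69 has a
standard error of ~0.045, so single-split agreement checks against it are
intrinsically noisy; and the within-subject spread factor (2×) is an
unvalidated default that materially shapes single-cell scatter plots.
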