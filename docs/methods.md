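# Methods

`empatch` is a digital-twin and analysis stack for a skin-interfaced
microneedle biosensor patch that monitors six interstitial-fluid (ISF)
biomarkers — glucose, uric acid (UA), cholesterol, Na⁺, K⁺ and pH — and
feeds them to a multi-task deep-learning model for health-state assessment.
The animal dataset behind the original device study is not public, so the
package pairs every analysis component with a synthetic generator that
encodes the study design and the device's printed bench characteristics.
This note documents the models, the defaults and their rationale, and what
the synthetic experiments do and do not establish.

## Sensor forward models (`empatch.sensors`)

Three channels are enzymatic and read out by chronoamperometry: the
steady-state current density is linear in concentration,

    j = j0 + S·C,

with sensitivities S of 0.1122 μA cm⁻² mM⁻¹ (glucose), 0.001395 μA cm⁻²
μM⁻¹ (UA) and 0.1637 μA cm⁻² mM⁻¹ (cholesterol). Working in current
*density* means no electrode area ever enters the model. Three channels are
potentiometric: the ion-selective electrodes follow a near-Nernstian decade
law

    E = E0 + S·log10(C / C_ref),      S = 52.87 (Na⁺), 58.46 (K⁺) mV/decade,

anchored at C_ref = 1 mM (the anchor only shifts E0), and the polyaniline
pH electrode is linear at 57.61 mV per pH unit. The potential falls as pH
rises (deprotonation of the PANI surface); only the slope magnitude is
calibrated, so the sign convention is a configurable parameter with default
−1.

Stochastic terms: additive homoscedastic Gaussian noise per channel; a slow
linear drift (units/min); additive interference Δy = Σⱼ αⱼ·Cⱼ over a
channel-specific coefficient table; and optional motion-artifact bursts
(damped 8 Hz oscillations) whose amplitude is a scenario parameter — the
substrate-comparison scenario uses a 4:1 amplitude ratio between a stiff
and an elastomeric backing. The chronoamperometric settling transient is a
single exponential that decays within a 30 s settle window; only the
steady state (trailing-window mean) feeds calibration, so no diffusion
(Cottrell) modelling is attempted.

Noise defaults are back-solved from the device's detection limits through
LOD = 3.3·σ/S (σ = 0.0133, 0.00114 and 0.0258 μA cm⁻² for glucose, UA and
cholesterol give LODs of 0.39 mM, 2.7 μM and 0.52 mM). No LOD is printed
for the potentiometric channels; their σ defaults to 0.5 mV. The default
drift (−0.03 to −0.04 %/min of the operating-point signal) and the
interference coefficients (each panel addition perturbs the signal by
0.5–2.5%, cumulative panel ≤ 6%) are bench-scenario parameters chosen to
sit inside the device's observed selectivity (≤ 6% per addition) and
120-min stability (≥ 88% retention) envelopes; they are asserted as
scenario budgets in the tests, not estimated quantities.

Amperometric channels saturate outside their calibrated range (the emitted
signal corresponds to the range edge and the trace is flagged);
potentiometric channels follow the log law beyond the calibrated window and
are only flagged, since ISE response does not clip sharply.

## Calibration and figures of merit (`empatch.calibration`)

Inverse models are ordinary least-squares fits of readout on concentration
(amperometric), on log10 concentration (ions) or on pH. Reported `r` is the
Pearson correlation of the fit (the convention used on the device's
calibration insets), not R²; for a simple linear fit the two coincide up to
sign. Residual SD uses ddof = 2 (two fitted parameters); RSD uses the
sample SD (ddof = 1). `inverse_concentration` is the exact algebraic
inverse and flags, rather than clamps, estimates outside the calibrated
range. Selectivity drift uses 30 s pre/post windows separated from the
addition event by a 5 s guard, avoiding mixing transients. A noiseless
ladder passed through the forward model and refitted recovers each slope to
machine precision; this round trip is the package's primary correctness
anchor.

## Synthetic chronic cohort (`empatch.cohort`)

The chronic study design: three diet groups — CON (standard chow), HFFD
(high-fat high-fructose), HFFSD (HFFD + 8% w/w NaCl) — measured weekly for
4 weeks after a pre-diet baseline visit. The generator scales the design to
125 animals per group (the statistical structure of the 3-rats/group study
at a size adequate for learning-curve experiments). Each panel is

    x_c = μ_c + δ_c(group, week) + a_c(animal) + σ_c·z,

with: baseline means μ inside the physiological windows (glucose 5.5 mM,
UA 295 μM, cholesterol 4.0 mM, Na⁺ 140 mM, K⁺ 4.2 mM, pH 7.1); biological
SDs σ of 0.25 mM, 20 μM, 0.2 mM, 1.0 mM, 0.2 mM and 0.07 pH — deliberately
tight, as appropriate for age-matched male rats under controlled feeding,
and required for the cohort to be near-separable (below); animal-level
random intercepts a with SD 0.5·σ (repeated measures on the same animal
are correlated); and a shared latent factor giving glucose and cholesterol
a configurable correlation (default ρ = 0.6, echoing their strong metabolic
coupling). Values are clipped to the sensor-operable span with a logged
clip count — mirroring physical saturation rather than rejection sampling.
The UA operable span is [0, 1100] μM, slightly beyond the 1000 μM
calibration ladder, so the hyperuricemic plateau the device observed
(~1015 μM) is representable.

Diet effects. Full-progression (week-4) mean shifts are: HFFD +6 mM
glucose, +180 μM UA, +3.2 mM cholesterol; HFFSD +10 mM glucose, +200 μM UA,
+3.6 mM cholesterol, +6 mM Na⁺, −0.3 pH. K⁺ is untouched by both diets and
serves as a null channel for attribution checks. The weekly expression
fractions are (0, 0.55, 0.70, 0.85, 1.00): a rapid-onset, progressively
saturating response, as expected for high-fat/high-fructose feeding where
postprandial dysregulation appears within the first week. Two properties
drove these defaults, both stated goals of the construction: (i)
*near-separability* — at every on-diet visit the smallest between-group
Mahalanobis distance exceeds ~6, so the Bayes accuracy of the
classification task is > 0.999; (ii) *degree recoverability* — the
adjacent-week feature spacing in each diet arm is large enough
(Σ(Δμ_c/σ_c)² ≳ 18 per week step) that the continuous health degree can in
principle be recovered to ≲ 0.04 RMSE. A purely linear effect ramp cannot
satisfy (i) within the physiological and sensor ranges (week-1 groups
overlap too much), which is why the expression fraction is front-loaded
while the degree *label* remains a linear ramp.

Health degree. The regression target is a latent severity ramp
s = s_max·week/weeks with s_max = 0 (CON), 0.8 (HFFD), 1.0 (HFFSD), plus
Gaussian label noise (SD 0.02), clipped to [0, 1]. The original study never
specifies how its continuous health-degree labels were constructed; this
ramp is a documented stand-in that makes parameter recovery testable.
Clipping at 0 leaves the CON mean a small positive residue (~σ·√(2/π)/2);
tests treat "zero in expectation" accordingly.

Acute interventions. HG: a gamma-like bolus pulse in glucose (baseline
4.5 mM → 12 mM), baseline until onset (2 min), maximum exactly at 20 min,
decayed to < 2% of the excursion within 30 min of the peak (shape
parameter 6). HUA: a logistic rise in UA from 160.2 μM, stable for
~15 min, plateauing at 1015 μM (time constant 1.5 min). NORM: stationary
noise about baselines on all channels. Only peak times and levels are
anchored to device observations; the smooth shapes are the package's
choice. Acute tables store true concentrations; sensor saturation is
applied downstream by the forward models.

## Learning pipeline (`empatch.pipeline`, `empatch.nn`)

Windows. Each on-diet panel is rendered to a 6-channel × 60-sample window
of raw forward-model signals (1 Hz for 1 min, steady state + noise +
drift; the 5-min settling period is assumed elapsed). The pre-diet
baseline visit is excluded from the learning task by default: before the
intervention the groups are exchangeable by construction, so those visits
carry no class signal and including them would cap any classifier near
0.91. A per-sample 6-vector mode (per-channel window means) exists for
baseline parity.

Preprocessing. Z-score standardisation (population SD, ddof = 0) with
statistics computed on each fold's *training split only*, stored on the
trained model with a provenance tag; inference always re-uses train-split
statistics. The degree target is standardised the same way; predictions
are mapped back and clipped to [0, 1] at report time only, keeping training
gradients unsaturated. Statistics are accumulated in float64 so the
standardised training split is mean-0/SD-1 to < 1e-6 even though training
runs in float32.

Cross-validation. Stratified fivefold assignment: within each class, units
are ordered by degree (ties broken by a seeded shuffle) and dealt
round-robin to folds from a seeded offset — balancing class counts and the
degree distribution simultaneously. The dealt unit is the *animal* by
default (all of a rat's windows share a fold), preventing within-subject
leakage; sample-level dealing is available by omitting `subject_ids`.

Network. Hard parameter sharing: five 1-D convolutional layers (channels
16-32-32-64-64, kernel 3, stride 1, ReLU, same padding) over the time
axis, global average pooling, then a linear 64→3 softmax classification
head and a 64→32→1 regression head. The joint loss is cross-entropy +
λ·MSE with λ = 1 (no weighting preference is documented for the original
model). Training: Adam, lr 1e-3 with ×0.3 step decay at 60% and 85% of the
schedule, batch 32, 100 epochs, fully seeded; the implementation is dense
NumPy (im2col convolutions, analytic backprop verified against finite
differences), single-threaded and bit-reproducible per platform. The
hidden layer in the regression head is the one deviation from the smallest
possible head design: a purely linear readout of the pooled features
underfits the degree target by several points of R².

Baselines. KNN, SVM (RBF), decision tree, random forest and XGBoost run on
the per-channel steady-state features with the same folds, as a comparison
harness over scikit-learn/xgboost estimators (classification and
regression variants each).

## Interpretation (`empatch.metrics`, `empatch.shapley`)

Standard multiclass metrics (accuracy, macro precision/recall/F1,
confusion matrix, one-vs-rest PR curves with average precision) and
regression metrics (R², RMSE, MAE) wrap scikit-learn with contract checks.
t-SNE (perplexity 30, 1000 iterations, seeded, PCA init) provides the 2-D
view; the silhouette of the labels on the embedding is the testable
separability surrogate — tests only ever assert silhouette inequalities,
never coordinate geometry.

Shapley attribution treats a whole sensor channel as the attribution unit:
a coalition keeps or replaces all 60 samples of a channel with the
baseline (channel-wise training means — the zero window after
standardisation). With six channels, all 2⁶ = 64 coalitions are enumerated,
so the values are exact and the efficiency, dummy, symmetry and linearity
axioms hold to numerical precision; a permutation-sampling estimator with
standard errors is validated against the exact enumeration. The
classification head is attributed on the predicted-class logit rather than
the softmax probability, which would couple channels through
normalisation. On the default cohort the learned model ranks glucose and
cholesterol as the top two classification features, with the untouched K⁺
channel at the bottom — consistent with how the diet effects were
constructed, and a statement about the synthetic cohort only.

## Orchestration and reproducibility (`empatch.workflow`, `empatch.cli`)

`run_pipeline` chains simulate → sense → calibrate → train → evaluate →
explain, with one `numpy.random.SeedSequence` spawning an independent
stream per stage; no wall-clock state affects outputs. Every run writes a
manifest (config snapshot, per-stage seeds, artifact list, timings,
version); re-running an identical config reproduces identical metric
JSONs. The `empatch` console script is a thin argparse wrapper (exit codes
0/1/2 for ok / validation error / runtime failure). The dynamic-transfer
demonstration streams two consecutive monitoring segments (windows drawn
from two different diet groups at a chosen week) through a trained fold
model and reports the fraction of windows classified as each segment's
generating group.

## Problem sizes and numerical choices

The default experiment uses 1500 windows (125 animals × 3 groups × 4
on-diet weeks), T = 60 samples per window and fivefold CV — a scale at
which the full pipeline (simulation through attribution) completes in a
few minutes on one CPU core. Tests exercise the same code paths at
reduced sizes (15 animals/group, T = 8, narrow networks) except for the
headline cross-validation checks, which run the default configuration
once per session. Degenerate inputs fail loudly: constant features,
classes smaller than k, zero-variance regression targets, non-finite
losses (with the offending epoch and learning rate) and out-of-range
effect shifts (naming the channel) all raise.

## Limitations

The synthetic cohort is Gaussian with a single shared latent factor and
additive diet effects; real ISF biomarker panels have skewed distributions,
circadian structure, within-session autocorrelation and inter-channel
couplings the generator does not emulate. Passing the headline checks
therefore demonstrates that the pipeline — preprocessing, fold hygiene,
the multi-task optimiser, the attribution machinery — behaves correctly
under the documented statistical structure, not that the original in vivo
accuracy would be reproduced on new animals. The health-degree label
construction is a stand-in (none is specified by the original study), the
acute-pulse shapes are anchored only at their printed peak times/levels,
and the interference/drift coefficients are scenario parameters, not
measurements.
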