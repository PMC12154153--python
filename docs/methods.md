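# Methods

## The analysis model

Each walking trial yields three outcome values per outcome measure: the
paretic-limb mean, the non-paretic-limb mean, and a single predicted
individualized value computed from the participant's covariates at that
trial's speed. Stacking trials long-format gives one row per (participant,
speed, limb level) with the limb factor ∈ {paretic, nonparetic, predicted}.
Gait speed is centered on the analysis sample's grand mean, so the model

    outcome_ij = β0 + β1·cspeed + β2·paretic + β3·nonparetic
               + β4·cspeed:paretic + β5·cspeed:nonparetic + b_i + ε_ij,
    b_i ~ N(0, σ_b²),  ε_ij ~ N(0, σ_e²)

has directly interpretable terms with 'predicted' as the reference level:
β2/β3 are limb-minus-predicted offsets *at the average speed*, and β4/β5 are
limb-minus-predicted slope differences (does the gap grow or shrink as
walking gets faster?). The random intercept b_i absorbs the repeated-measures
dependence of a participant's rows across speeds and limb levels.

### Estimation

The random-intercept model is estimated by REML with the variance ratio
ψ = σ_b²/σ_e² profiled: for fixed ψ the per-cluster marginal covariance is
W_i⁻¹ + ψ11ᵀ (W_i = observation weights, identity for the plain fit), which
inverts in closed form by Sherman–Morrison; β is then the GLS solution and
σ_e² is profiled out of the REML criterion, leaving a one-dimensional search
over log ψ (bounded scalar minimization, ψ ∈ [e⁻¹⁵, e¹⁵], with an explicit
check of the ψ→0 boundary). This keeps one fit at ~300 rows in the
10-millisecond range, which is what makes dense bootstrap and coverage
simulation practical. The implementation is cross-checked in the test suite
against an independent general-purpose mixed-model fitter on the same data
(agreement ~10⁻⁵ on coefficients).

Exactly collinear designs raise; datasets whose least-squares residuals are
zero to machine precision (noiseless simulations) short-circuit to the exact
OLS solution with zero variance components, avoiding a degenerate profile.

Wald standard errors, 95% CIs and normal-approximation p-values are reported
per coefficient. Degrees-of-freedom corrections (Satterthwaite,
Kenward–Roger) are out of scope; at ~30 clusters the Wald intervals cover at
≈93–96% in simulation, which the acceptance checks treat as "≈95%".

### Robust variant

Heavy-tailed residuals are handled by iteratively reweighted REML with Huber
weights (tuning constant k = 1.345 on standardized residuals, the
95%-efficiency choice). Each sweep refits the weighted model, predicts the
random intercepts (empirical Bayes), and sets observation weights from the
standardized *conditional* residuals and a per-cluster weight from the
standardized predicted random intercept, so gross outliers influence neither
σ_e nor σ_b nor β. Convergence: max |Δβ| < 1e-8 or 100 sweeps.

Two properties define its intended behaviour, and both are tested. In the
low-noise, outlier-free limit the robust fit matches plain REML to < 1% per
coefficient. On noisy (but clean) data the two estimators differ by a random
amount on the order of a fraction of a standard error — that is the
unavoidable efficiency cost of downweighting, not a bias — so coefficient
agreement should never be asserted at fixed relative tolerance on noisy
data. Under 5% gross contamination (residuals inflated ×10) the robust fit
stays strictly closer to the generative truth than REML.

This is one reasonable operationalization of "a robust linear mixed model";
published robust LMM algorithms differ in detail (e.g. design-adaptive scale
estimation), and results can differ accordingly.

### Bootstrap and contrasts

Confidence intervals that do not lean on normality come from a
participant-level (cluster) non-parametric bootstrap: participants are
resampled with replacement (repeated draws treated as distinct clusters),
the model refit per replicate (robust replicates warm-start from the parent
fit's weights), and 2.5/97.5 percentiles reported per coefficient; the
default is B = 1000 with the count of failed replicate fits logged (> 10%
failures aborts). Percentile intervals at ~30 clusters undercover mildly
(≈91–93% in our simulations); the acceptance band is therefore [89%, 99%].

Per-level speed slopes are linear combinations slope(L) = β1 + β_{cspeed:L},
with variances propagated from the coefficient covariance; pairwise slope
differences are Wald tests on interaction contrasts. These reproduce the
fitted-trend comparisons regardless of reference level (reparameterization
invariance is tested).

### Subgroup analyses

Participants are split by the sign of their self-selected-speed SLA
(positive = longer paretic steps); |SLA| ≤ 0.02 — within the symmetric range
of neurotypical reference data — is excluded from subgroups only. Each
subgroup dataset is re-centered on its own grand-mean speed so that limb
offsets remain interpretable at that subgroup's average speed.

## Signal processing choices

* **Filter**: 2nd-order Butterworth applied forward–backward (zero phase,
  effective 4th order), cutoffs 6 Hz (markers) / 20 Hz (forces). The design
  cutoff is raised by (√2 − 1)^(1/(2·order)) so the dual-pass magnitude is
  −3 dB at the nominal cutoff (Winter's correction).
* **Kinetic events**: the 100 N vertical-force crossing is localized by
  linear interpolation between the bracketing 1 kHz samples; threshold
  excursions shorter than 50 ms are debounced. Analysis starts at the first
  *upward* crossing in the window (a stance already in progress at the
  window start is dropped), and a trailing stance without a toe-off is
  dropped — only complete stances contribute.
* **Kinematic events**: local extrema of the fore-aft malleolus path with a
  minimum peak separation of half the expected stride time (estimated from
  the dominant frequency when not supplied).
* **Window**: 90–120 s, falling back to 60–90 s only when the contamination
  detector flags the primary window. Contamination = both belts
  simultaneously above 100 N for more than 40% of the local stride duration
  (normal double support is 20–30%); the fraction is configurable. Trials
  shorter than 120 s are an error, not a silent fallback — the fallback rule
  exists for dirty force data.
* **Metric/event binding**: step length uses kinematic events, peak AGRF
  uses kinetic events (each metric bound to the event definition stated for
  it); the binding is recorded in the run configuration.
* **Leg length**: trochanter-minus-malleolus vertical distance at the
  temporal midpoint of each right-limb stance, averaged over the window;
  non-positive values are flagged as implausible.

## The synthetic-trial generator

The generator emulates split-belt treadmill walking at the signal features
the pipeline actually consumes:

* **Markers**: the fore-aft malleolus path translates backward at belt speed
  during stance and returns forward along a cosine ease during swing, making
  the most-anterior point exactly the foot-strike and the most-posterior
  exactly the toe-off. The path is C¹ — after contact the fore-aft velocity
  blends from 0 to the belt speed over 80 ms — so its spectral content lies
  essentially below the 6 Hz analysis cutoff. The residual filter bias on the
  detected anterior peak is bounded by the peak curvature (≈v/τ_blend ≈ 10
  m/s²) times the squared effective smoothing width of the 6 Hz dual-pass
  filter (~0.01 s²·rad⁻²): < 2 mm on step length, which is the tolerance the
  full-pipeline round-trip test uses. On unfiltered signals recovery is exact
  (≤ 1e-9).
* **Forces**: stance-only vertical force stepping to 200 N at the stance
  edges and rising as a raised cosine to ~1.1 body weight — because 100 N is
  half the edge step, the threshold crossing sits at the true event under
  both raw interpolation and symmetric zero-phase smoothing. The
  anterior-posterior force is a braking half-sine (0.8× the propulsion
  amplitude) then a propulsion half-sine whose maximum is exactly the
  commanded peak AGRF.
* **Timing**: on a treadmill the two step lengths satisfy
  SL_p + SL_np = v·(T − τ_blend); the generator takes the commanded step
  lengths as primary, quantizes the stride to the 100 Hz grid and the stance
  to multiples of 4 ms (so true events and the propulsion peak coincide with
  samples), and realizes the belt speed (< 1% from commanded) that honours
  the commanded step lengths. The realized speed is reported on the trial
  and used downstream.
* **Contamination**: crossover epochs copy the right belt's vertical load
  onto the left belt, emulating a foot landing on both plates.
* **Noise**: white Gaussian noise added to channels after shape
  construction; identical seeds give bit-identical trials.

Default cohort conditions mirror the study design: three speed conditions
with slow = 50% of self-selected and fast ≈ 130%, self-selected speeds
centred near 0.8 m/s (post-stroke range), per-participant SLA as a
persistent trait, marker noise 2 mm, force noise 2 N. At these realistic
speeds many slow trials genuinely violate the prediction models' training
bounds (speed ≤ 0.36 m/s, step length ≤ 0.32 m) and are excluded — the same
pattern the clinical exclusion logs show. What the generator does **not**
emulate: full-body kinematics, double-support force sharing, spontaneous
speed fluctuations, marker occlusion/gaps, or any pathological waveform
detail beyond per-limb step length and propulsion peak. Passing round-trip
tests therefore validate the pipeline's bookkeeping and numerics, not its
behaviour on every clinical waveform shape.

The limb-level cohort simulator (`generate_cohort`) draws directly from the
mixed model above with commanded fixed effects and variance components; it is
the ground truth for parameter-recovery and coverage testing. The
study-scale generative values used in tests and the acceptance script
(paretic offset −19.4 N, non-paretic +12.8 N, predicted slope 126.6 N·s/m,
paretic slope deficit −40.2 N·s/m; between-participant SD 25 N, residual SD
15 N at n = 30×3) give sampling noise comparable to the reported standard
errors.

## Predictions and exclusions

Predicted individualized values are linear in speed, leg length, mass, sex
(0/1-encoded; the mapping is declared in the coefficient file) and age. The
actual published coefficients are not redistributable here, so the package
ships a clearly-labelled synthetic demonstration file with plausible
magnitudes (step-length speed coefficient 0.29 m·s/m; AGRF speed coefficient
126.6 N·s/m); the file format validates covariate names and carries the
training-domain bounds (defaults 0.36 m/s, 18.2 N, 0.32 m). The exclusion
rule is conservative: a trial is dropped if *either* limb's mean AGRF or
step length is outside the training domain, since the prediction is compared
to both limbs. The speed compared against the bound is the trial's recorded
belt speed.

## Known limitations

* Random slopes, crossed random effects, and multiple-testing corrections
  are out of scope by design.
* The robust estimator is an in-house IRLS scheme; it is validated by its
  limit behaviour and contamination response, not by equivalence to any
  specific published robust-LMM algorithm.
* Wald and percentile-bootstrap intervals carry the small-sample coverage
  biases quantified above; with ≲15 participants they should be read
  cautiously.
* The kinematic and kinetic event definitions agree within ~30 ms on clean
  synthetic gait; on pathological waveforms (e.g., absent anterior
  progression) the two can diverge more, which is why each outcome is bound
  to its stated event source.
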