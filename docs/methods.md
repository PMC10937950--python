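# Methods

## Thermophoretic enrichment model

### Governing equations

The chamber is treated as axisymmetric: a fluid disk of height H = 400 µm and
radius R = 3.5 mm between a 1 mm glass lid (λ = 1.3 W m⁻¹ K⁻¹, c_p = 761 J
kg⁻¹ K⁻¹) and a 1 mm sapphire floor (λ = 35, c_p = 755); water has λ = 0.6,
c_p = 4200. Three fields are solved:

1. **Temperature** (fluid + both solids): steady conservative finite-volume
   conduction–advection, ∇·(λ∇T) − ρc_p **u**·∇T + S = 0, with harmonic-mean
   conductivities across layer interfaces, Dirichlet ambient (25 °C) on the
   exterior z faces and an adiabatic side wall (a Dirichlet side wall is
   available by flag). The source is a Gaussian beam absorbed by Beer–Lambert
   decay, S = (2Pα/πw²) exp(−2r²/w²) exp(−α·depth), P = 150 mW, w = 80 µm,
   α = 2300 m⁻¹ (water near 1480 nm). The beam enters through the glass lid:
   on an inverted microscope the infrared heating path and the fluorescence
   objective sit on opposite sides of the chamber, and this orientation keeps
   the heated core away from the imaged floor. A `bottom` entry flag covers
   the opposite mounting. Because α for the actual optics is uncertain, the
   default mode rescales the source amplitude so the peak fluid temperature
   equals 65 °C (the measured hot-core value); the uncalibrated mode uses the
   nominal absorbed power.
2. **Flow**: steady buoyant Stokes flow in stream function–vorticity form,
   E²ψ = −rω and η(∇²ω − ω/r²) = ∂F_z/∂r, F_z = g(ρ(T_amb) − ρ(T)), solved
   monolithically as one sparse linear system with Thom wall vorticity,
   ψ = 0 on all boundaries and ω = 0 on the axis. Inertia is dropped: at the
   observed speeds (≲ 0.5 mm s⁻¹) the Reynolds number is ~10⁻¹–10⁻², so the
   Stokes balance is accurate and the solve is exact rather than iterative.
   Water density follows the Kell polynomial and viscosity a
   Vogel–Fulcher–Tammann fit; the buoyancy term uses the full ρ(T) difference,
   which is equivalent to a Boussinesq form with temperature-dependent
   expansivity α(T) = −(1/ρ)dρ/dT. The local η(T) multiplies the viscous
   operator; ∇η cross terms are neglected (a few-percent effect on the flow
   over the 25–65 °C range, checked against the magnitude cross-validation
   below).
3. **EV concentration** (per size bin): transient conservative finite-volume
   transport, ∂c/∂t + ∇·(**u**c) = ∇·(D∇c + S_T D c ∇T), with
   D = kT/(3πη(T)a), S_T = 0.03(a/100 nm)² K⁻¹, uniform c = 1 initial
   condition and zero-flux walls. Advection and thermophoretic drift use
   MUSCL (minmod-limited) upwind reconstruction; diffusion is central. Face
   velocities come from stream-function differences, so the discrete field is
   exactly divergence-free and total particle number is conserved to
   round-off (the tests require < 1%; the scheme delivers ~10⁻¹⁴). Time
   stepping is explicit with a CFL-limited dt (auto-substepped when a larger
   dt is requested); an implicit first-order upwind alternative was rejected
   because its numerical diffusion (~u·Δx/2) exceeds the physical D by two
   orders of magnitude and erases the near-wall accumulation layer.

Temperature and flow are coupled by fixed-point iteration (T → buoyancy → u →
advected T) to 10⁻⁴ relative tolerance, with the source recalibrated each
pass; convergence takes 3–5 passes. The thermal and flow time scales (< 1 s)
are far below the 600 s assay, so holding them steady while the species field
evolves is an excellent approximation.

### Grids and detection region

Cells cluster toward the axis (first radial cell ≈ 5 µm against a 160 µm
spot) and toward the chamber floor (first fluid cell ≈ 0.5 µm), because the
accumulation layer has thickness D/v_T of a few µm for the largest EVs. The
production grid is 64 × 32 fluid cells (plus 8 cells per solid); the
documented convergence check against 32 × 16 moves the 600 s weighted
enrichment by < 2%, and a 96 × 48 grid with 3× finer near-wall cells moves
the largest bin by ~3%. Enrichment is reported as the volume-weighted mean
concentration over a bottom-layer cylinder of 100 µm diameter (the imaged
spot); a point-value mode reports the innermost bottom cell instead.
Size-weighted enrichment is Σᵢ wᵢEᵢ(t) over 20 nm bins with centers
50–290 nm; default weights come from a sampled lognormal (median 130 nm,
log-sd 0.35, ~24% of particles below 100 nm, 2000 tracked particles), the
shape nanoparticle-tracking analysis reports for breast-cell-line EVs.

### Behaviour and the dominant uncertainty

With the defaults the calibrated field gives a 65 °C core, a floor below
26 °C (the sapphire's high conductivity shields the imaged surface; the
constraint is staying below 28 °C) and peak circulation ≈ 0.4 mm s⁻¹ —
magnitudes cross-validated against an independent primitive-variable
(MAC staggered-grid) Stokes solver, which agrees within ~15% on matched
coarse grids. EVs accumulate at the bottom-center stagnation region, where
the inward return flow delivers particles and downward thermophoretic drift
(away from the hot core) holds them against the wall; enrichment grows with
particle size as the quadratic Soret law predicts.

The *magnitude* of the steady enrichment is controlled almost entirely by
the thermophoretic mobility D_T = S_T·D. With the default law,
D_T ≈ 0.13–0.45 µm² s⁻¹ K⁻¹ over 100–290 nm, drift speeds are ~0.1–0.4 µm
s⁻¹ — three orders below the convection that feeds and also flushes the trap
— and the 600 s size-weighted enrichment is ≈ 1.2 (largest bin ≈ 2–3).
Colloid thermophoresis measurements on polystyrene spheres of these sizes
report S_T of order 1–10 K⁻¹, ten to a hundred times the default law; in
that regime the same solver produces 10³–10⁵-fold bottom-center
accumulation, matching the strong experimental amplification of this assay
class. The Soret prefactor is therefore the dominant model uncertainty, and
`ParticleSpec` accepts any user-supplied law. EV adsorption to the sapphire
floor (the experimental spot is largely deposited material) is deliberately
out of scope: the model keeps conservative zero-flux walls, so its
enrichment figures are lower bounds for a surface-accumulating readout.

## Quantification layer

Central-spot readout is the mean over a centered 100 µm disk. Calibration is
an ordinary least-squares line of intensity on EV count; the limit of
detection is the count at which the line crosses blank mean + 3·sd (the
standard analytical-chemistry convention). Colocalization fractions k/n are
displayed at one-decimal percent with Clopper–Pearson 95% intervals.

## Signatures

All discriminants are two-class pooled-covariance LDAs: w = Σ⁻¹(μ₊ − μ₋),
score s(x) = wᵀx, threshold at the equal-posterior point
wᵀ(μ₊ + μ₋)/2 − log(π₊/π₋). Priors default to empirical class proportions
(equal priors by flag); a singular pooled covariance is ridge-regularized by
10⁻⁶·trace/p. Orienting w by the positive class makes adverse classes
(TNBC, PD, high risk) score higher automatically.

* **Diagnosis**: intensities are min-max scaled to [0, 1] per lectin on the
  training cohort (validation values clipped — the transform must be frozen
  at fit time); step 1 separates cancer from healthy donors, step 2 (fitted
  only on cancer training samples) separates TNBC from other subtypes.
  Samples called healthy in step 1 are never routed to step 2, and the
  reported score is the discriminant axis that produced the final call.
  Because min-max scaling absorbs any positive affine change of raw units,
  predictions are invariant to per-lectin recalibration (tested).
* **Monitoring**: follow-ups are divided by the same patient's pre-treatment
  baseline per lectin (baseline rows become exactly 1), then one LDA of PD
  against PR/SD follow-ups.
* **η_EV**: 1/s(t_eval) − 1/s(baseline), evaluated at the time of PD for
  non-responders and the 6-month follow-up for responders. A "temporal
  change" could also be read as a per-day rate; the difference form is the
  default and the rate is available by flag. Scores must be positive for the
  reciprocal to be meaningful; the fitted monitoring discriminant satisfies
  this on baseline-normalized data because all three normalized means rise
  under progression.
* **Prognosis**: min-max scaled baseline intensities, one LDA against the
  observed progression-event indicator (the training label is configurable —
  nothing in the assay fixes it uniquely), then a median split with ties
  assigned to "high". Stratification refuses fewer than 4 patients.

## Panel selection

Glycan profiles over five lectins (ConA, WGA, RCA I, SBA, UEA I) are
clustered bottom-up with Euclidean distance and average linkage, cut at two
clusters. The subset search evaluates all C(5,3)+C(5,4)+C(5,5) = 16
combinations of 3–5 lectins (three is the minimum for a 3-group problem),
projects each onto two principal components (columns standardized, both
configurable), and calls a subset feasible when the intra-class distance —
the largest mean sample-to-own-center distance — is below the inter-class
distance — the smallest pairwise center distance, the most conservative
aggregation of "distances between class centers" (the mean is available by
flag). Feasible subsets are ranked by inter-class distance.

## Evaluation statistics

Accuracy = trace/total of the confusion matrix with a Clopper–Pearson
(exact binomial) 95% CI. AUC is the trapezoidal/midrank estimator with a
DeLong CI (implemented here; variance from positive/negative placement
values). Mann–Whitney U is exact for small untied samples and tie-corrected
normal otherwise. Survival uses the product-limit estimator, median = first
time S(t) ≤ 0.5 (undefined when the curve never crosses), the two-sided
log-rank test, and Cox partial likelihood with Efron tie handling (uni- and
multivariate), all via lifelines.

## Synthetic cohorts

Intensities are lognormal — fluorescence is positive and right-skewed — with
log-sd 0.12, between-lectin correlation 0.3, and multiplicative class
effects: cancer raises every lectin (×2.8 / ×2.2 / ×2.0 on ConA / WGA /
RCA I over healthy donors), TNBC further raises WGA (×2.0) and lowers RCA I
(×0.55) relative to other subtypes, so both orderings — cancer above
healthy everywhere, TNBC distinct in opposite directions on WGA and RCA I —
hold. These margins (≥ 5 within-class log-sd on the discriminating lectins)
make the default cohorts separable *by construction*: the pipeline tests
prove recovery of planted structure, not performance on realistic overlap,
and every magnitude is configurable because real per-class distributions
are not identifiable from published figures. Cohort layout mirrors the
pilot-study design: 20/19/25 diagnostic training samples, 13 monitored
patients (5 responders, 8 non-responders; non-responders progress within 6
months, responders complete ≥ 3 months of therapy without progression), 25
baseline patients for survival.

Longitudinal series multiply each patient's baseline by exp(±slope + noise)
(PD +0.55, PR −0.45 in log units, SD flat, noise sd 0.05, identical across
lectins). Survival times are exponential with log-hazard linear in the
standardized true score (ConA + WGA − RCA I in logs), baseline hazard
ln2/205 d⁻¹; a binary-covariate mode applies the hazard ratio across the
median split. Censoring is exponential with per-subject rate λ·q/(1−q), so
the expected event fraction is exactly 1 − q (censoring is independent of
the event time given the covariate). What the generators do **not** emulate:
assay noise floors, batch effects, lipoprotein interference, missing visits,
or informative censoring — results on them bound what the methods can do
under ideal structure, nothing more.

## Numerical conventions and degenerate inputs

Min-max scaling rejects constant columns; baseline normalization rejects
zero or missing baselines; LDA requires two classes with ≥ 2 samples each;
stratification requires ≥ 4 patients and sends ties high; rank-deficient
PCA inputs fall back to the available rank with a warning; the transport
solver refuses negative concentrations beyond 10⁻⁸ and logs when it
substeps a requested dt. All randomness flows through
`numpy.random.default_rng(seed)`; identical spec + seed reproduces outputs
byte-for-byte.

## Known limitations

* Steady thermal/flow fields (no transient spin-up), no ∇η terms, no 3-D
  asymmetries, no optical model of fluorescence collection.
* Zero-flux walls: no EV–surface adhesion, although deposition plainly
  contributes to the real readout; simulated enrichment is accordingly a
  conservative lower bound and highly sensitive to the assumed Soret law
  (see above).
* The quadratic Soret law with a 0.03 K⁻¹ prefactor at 100 nm is an
  empirical input, not derived; mobilities measured for comparable
  synthetic colloids are 10–100× larger.
* Synthetic cohorts are separable by design; accuracy/AUC figures on them
  are structural checks, not clinical performance estimates.
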