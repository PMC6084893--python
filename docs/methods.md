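# Methods

This note documents the models implemented in `pkpet`, their assumptions and
default parameters, what the synthetic data generator does and does not
emulate, and the numerical choices that matter. It makes no empirical claims
beyond what the package itself computes.

## 1. Acquisition model

**Frame schedule.** `FrameSchedule.brain_60min()` is a 22-frame, 60-minute
schedule (4×15 s, 4×30 s, 3×60 s, 2×120 s, 8×300 s, 1×600 s). Frames are
contiguous; all analyses use frame midpoints in minutes. Default voxel size
is 1.082 × 1.082 × 2.025 mm.

**Units.** Activity concentrations are kBq/mL; rate constants are 1/min
(K1 in mL·cm⁻³·min⁻¹ treated as 1/min under unit tissue density); volumes in
cm³; SUV conversion assumes tissue density 1 g/mL.

## 2. Blood input model (`pkpet.input_function`)

The whole-blood curve is piecewise linear from injection (implicit node at
(0, 0)) to the peak and a three-component exponential decay afterwards:

C_p(t) = interp(nodes)  for t ≤ t_peak;  Σᵢ Aᵢ·exp(−λᵢ·(t−t_peak)) for t > t_peak.

Continuity at the peak is enforced at construction (Σ Aᵢ must equal the peak
node value). The time integral is analytic (trapezoid over the linear nodes
plus expm1 tails), which removes quadrature error from the Logan abscissa.

`fit_blood_model` fits this model to sampled data: samples up to the peak
become the linear nodes; the post-peak tail is fitted by bounded nonlinear
least squares (`scipy.optimize.least_squares`) with multistart restarts from
log-normally jittered rate triples around (2.0, 0.3, 0.02) 1/min. The fit
requires ≥ 8 post-peak samples and rejects fits whose median residual
exceeds half the peak (`BloodFitError`). The peak node is replaced by the
fitted Σ Aᵢ so the model stays exactly continuous.

Assumption carried from the tracer's protein binding: whole blood ≈ plasma
(parent fraction defaults to 1); no metabolite correction, no delay or
dispersion correction (delay fixed at 0).

## 3. Tissue kinetics (`pkpet.kinetics`)

The two-tissue compartment model (2TCM) with rate constants K1, k2, k3, k4
and fractional blood volume vB. The impulse response is a sum of two
exponentials with eigenvalues

α₁,₂ = [(k2+k3+k4) ∓ √((k2+k3+k4)² − 4·k2·k4)] / 2,

and the tissue curve is the closed-form convolution of exp(−αt) with the
piecewise-linear + tri-exponential input — evaluated analytically segment by
segment, no ODE solver in the pipeline. (An independent `solve_ivp` oracle
verifies the closed form to ~1e-6 relative in tests.) Repeated eigenvalues
are handled by an epsilon perturbation of k4; |α − λᵢ| degeneracies use the
analytic t·exp limit.

Measured signal: C_meas(t) = (1 − vB)·C_t(t) + vB·C_p(t), averaged over each
frame by dense trapezoid quadrature on per-frame subgrids split at the input
nodes (≥ 9 points per frame, ≥ 30 points/min).

Analytic ground truth: V_T = (K1/k2)(1 + k3/k4) (k3 = 0 ⇒ V_T = K1/k2).

## 4. Graphical estimators (`pkpet.logan`)

**Blood-input Logan.** Y(T) = ∫₀ᵀC_t/C_t(T) against X(T) = ∫₀ᵀC_p/C_t(T);
for T beyond the equilibration time t* the plot is linear with slope V_T.
Defaults: t* = 30 min (membership by frame midpoint ≥ t*), constant
weighting, ordinary least squares via statsmodels (slope, intercept,
standard errors, R²). Tissue integrals are cumulative trapezoids anchored
with an initial triangle at t = 0; blood integrals are analytic when an
`InputFunction` is supplied, trapezoid when a sampled blood TAC is supplied.

**Reference Logan.** X(T) = [∫₀ᵀC_ref + C_ref(T)/k2′]/C_t(T); slope is DVR
and BP_ND = DVR − 1. The C_ref/k2′ term is optional (default omitted); both
variants are exposed and their difference is visible in the results objects.

**Known bias.** Logan slopes are biased low by (a) incomplete equilibration
at t* for slow k4 and (b) noise in C_t(T), which enters both axes
(documented noise-induced underestimation). The noise bias is asserted
directionally in tests; `logan_diagnostics` reports the maximum relative
deviation of fitted points from the line and the earliest time from which
deviations stay under 10 % (a t* adequacy check).

## 5. Phantom generator (`pkpet.phantom`)

**Geometry.** Parametric, not anatomical: an outer cortical-gray ellipsoid
(semi-axes 45 × 41 × 37 mm) containing a white-matter ellipsoid
(33 × 29 × 25 mm), a thalamus-like nucleus (14 × 16 × 12 mm), four rim/core
lesion shells in the white matter with total volumes sampled log-uniformly
over 0.08–1.691 cm³ (core radius 0.6 of the outer radius), and two
4-mm-diameter carotid tubes anterior to the brain. Regions are painted in
listed order (later labels overwrite earlier ones); `background` is
everything unclaimed.

**Kinetics (defaults).** Chosen so that uptake contrast is delivery-limited
and specific binding is concentrated in the thalamus-like region, giving
V_T: TH 3.10 > lesion rim 1.02 > CGM 0.96 > WM 0.90 > lesion core 0.50, with
vB = 0.05 in all tissue. Two deliberate consequences: (a) SUV-level uptake
ordering TH > CGM > WM comes from K1 (0.12 / 0.096 / 0.03), and (b) the
white matter's and lesion rim's V_T sit close to the reference gray's, so
their BP_ND is near zero — the regime in which reference-based TRV becomes
unstable (tiny pair-mean denominators), which is the method-comparison
behavior under study. The carotid label is a pure blood pool (voxel signal =
frame-averaged input).

**Rendering.** Per-label TACs are computed once (a lookup table) and composed
into the 4D image; each frame is blurred with a stationary Gaussian PSF of
6 mm FWHM (σ = FWHM/2.355, `scipy.ndimage.gaussian_filter`, constant-zero
boundary). This emulates reconstruction resolution / partial-volume effects.

**Noise.** White Gaussian, SD = noise_scale · √(max(v, ε)/Δt_min) per
voxel-frame: variance proportional to activity and inversely proportional to
frame duration (the standard post-reconstruction approximation). The default
noise_scale = 0.9 was calibrated once so the late-frame single-voxel
coefficient of variation in white matter is ≈ 30 %. Negative excursions are
kept (clipping would bias region means).

**Test–retest pairs.** The two scans of a "subject" share geometry and
kinetics; the retest is scaled by 1 + u, u ~ Uniform(±0.15), emulating
injected-dose/calibration differences, and the scans receive independent
noise. Because all kinetics are linear in the input, the retest noiseless
image is an exact scalar multiple of the test image — verified as a
scale-propagation test. All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give bit-identical data.

**What is not modeled.** Radioactive decay, attenuation/scatter/randoms,
sinogram or list-mode reconstruction, head motion, anatomical variability
between subjects, metabolites, delay/dispersion of the carotid signal.

## 6. VOI analysis (`pkpet.voi`)

Masks are boolean grids with voxel-size metadata. The erosion series applies
repeated one-voxel 6-connected binary erosion
(`scipy.ndimage.binary_erosion`, `generate_binary_structure(3, 1)`),
largest VOI first, stopping before the volume falls below 1 cm³ — the
"systematically shrunk VOI" design. With the default phantom this yields TH
… TH-4 and WM … WM-6. TAC extraction is the per-frame arithmetic mean;
`extract_idif` returns the carotid-mean TAC with an 8-mm background-ROI TAC
(spheres ~2 cm lateral to each carotid) attached as a spill-in diagnostic
(no correction by default).

Partial-volume directions on the noiseless phantom: the hot TH loses signal
to its surround, so its late-frame mean rises as the VOI erodes inward;
the cold WM gains spill-in from CGM/TH/lesion rims at its border, so its
late-frame mean falls under erosion.

## 7. Supervised-cluster reference extraction (`pkpet.reference`)

The class library holds area-normalized mean curves of four kinetic classes
(reference gray, white, high-binding, blood) on the acquisition time grid;
pairwise-identical classes are rejected. Each brain-mask voxel TAC is
area-normalized and decomposed by non-negative least squares against the
class curves; coefficients are rescaled to sum to 1. Voxels with
reference-class coefficient ≥ 0.9 form the pseudo-reference region, and the
reference TAC is their coefficient-weighted mean **raw** TAC. If fewer than
1 % of mask voxels qualify, the result has status `failed` (a status, not an
exception, so multi-subject pipelines can drop the subject and continue) —
exercised by the widespread-activation phantom, on which extraction fails by
construction.

Numerical choices:

* **NNLS.** One fixed 4-column design against ~10⁴–10⁵ voxel targets is
  solved by enumerating the 15 active sets and selecting the feasible
  candidate with minimal residual — mathematically identical to
  `scipy.optimize.nnls` (cross-checked in tests) but vectorized over voxels.
* **Classification smoothing.** Classification (only) runs on a copy of the
  image smoothed by 4 mm FWHM; single-voxel TACs at realistic noise are too
  noisy for shape decomposition and misclassified white-matter voxels would
  dilute the reference curve. The extracted TAC itself averages raw voxel
  curves, so the smoothing adds no partial-volume bias to the output.
* **Brain-mask erosion.** The default experiment brain mask is the tissue
  labels eroded by 5 voxels: brain-edge voxels diluted by spill-out to air
  keep a reference-like *shape* (adding zeros only rescales a curve) and
  would bias the extracted amplitude low.

## 8. Reliability statistics (`pkpet.reliability`)

For paired values T (test) and RT (retest):

* TRV = 100·(T − RT)/((T + RT)/2); aTRV = |TRV|. Summaries report mean and
  SD (denominator P − 1) of both.
* %RC = 100 · 2.77 · √((1/P)·Σⱼ[(Tⱼ−RTⱼ)²/2]/[(Tⱼ+RTⱼ)/2]²) — the
  repeatability coefficient, 2.77 × within-subject CV with the
  paired-difference variance estimator. Single pair (1.1, 0.9) ⇒
  100·2.77·√0.02 ≈ 39.17.
* IDIF AUC ratios over 20–60, 40–60 and 1–60 min; a paired two-tailed
  t-test wrapper (`scipy.stats.ttest_rel`) is provided as a convenience.

`run_trt_experiment` renders the noiseless phantom once, draws per-subject
seed pairs from a master `default_rng(seed)`, and for each scan: extracts
the IDIF, fits the blood model, runs blood-input Logan on every VOI (TH and
WM erosion series, CGM, lesions), extracts the supervised-cluster reference,
and runs reference-Logan on the same VOIs. Subjects whose reference
extraction fails in either scan are excluded from the BP_ND arm (and
reported); the V_T arm always completes. If every subject fails, the BP_ND
arm is absent and the error recorded. Outputs are a per-(region, method)
reliability table, a per-lesion pair table with volumes, raw pairs, per-
subject IDIF AUC ratios, and a manifest with all seeds.

## 9. Limitations

* The phantom's geometry is one fixed synthetic anatomy; between-subject
  variability is noise and dose jitter only, so reliability statistics
  characterize the estimators on this phantom, not a patient cohort.
* The noise model is Gaussian and spatially white post-PSF; real
  reconstructed PET noise is spatially correlated and non-stationary.
* The IDIF is uncorrected for partial volume and spill-in; it systematically
  underestimates the true blood peak (asserted directionally in tests),
  which propagates into V_T as a common-mode scale factor.
* The supervised-cluster class library is taken from the phantom's own
  ground-truth region curves; with real data it must come from an external
  training set.
* Logan estimates carry the documented equilibration and noise biases; no
  bias-corrected variants (e.g. multilinear reformulations) are included.
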