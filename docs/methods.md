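# Methods

`fsisfdi` implements spatial frequency domain imaging (SFDI) acquired
through Fourier single-pixel imaging (FSI): a bucket detector plus a
programmable projector replace the camera, the scene's Fourier spectrum is
measured coefficient-by-coefficient, and undersampling the spectrum
compresses the measurement. This note records the model, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Measurement model

**Fourier single-pixel acquisition.** The projector displays cosine
patterns `P(x,y) = a + b·cos(2π fx x/M + 2π fy y/N + φ)` with integer
frequencies `(fx, fy)` (whole cycles per frame, so a constant scene has
exactly zero off-DC coefficients). The detector integrates the reflected
light, `D_φ = Σ P·O`. Four phases (0, π/2, π, 3π/2) per frequency give the
complex coefficient

    C(fx, fy) = (D₀ − D_π) + j·(D_{π/2} − D_{3π/2}) = 2b · DFT(O)[fx, fy].

The mean `a` cancels in the differences (asserted by test), and the `j` on
the second difference is required for the identity with the DFT, which is
the package's central correctness oracle: the literal pattern-by-pattern
bucket path and the FFT fast path are both implemented and tested to agree,
and all large simulations use the FFT path.

**Conjugate symmetry and the half-plane.** Real scenes have conjugate-
symmetric spectra, so only one canonical representative per conjugate pair
is measured. We take an index canonical when it is lexicographically ≤ its
DFT-coordinate conjugate; for even M×N this yields `MN/2 + 2` coefficients
(DC and three Nyquist points are self-conjugate and counted once), so exact
full sampling costs `2MN + 8` patterns — the familiar `2MN` count ignores
the O(1) self-conjugate excess. Self-conjugate coefficients have their
imaginary part zeroed after assembly (real-image constraint).

**Sampling schemes.** Three mask generators choose `⌊budget/4⌋` half-plane
coefficients: a deterministic low-frequency disc (ties broken by radius,
then centered fy, fx, making nested budgets nested masks), uniform random
selection (DC always included), and variable-density random selection that
always includes the normalized-radius `r ≤ R` core and fills the remainder
by weighted sampling without replacement with weight `(1−r)^p` (defaults
R = 0.1, p = 6, chosen so ~10% budgets concentrate near DC). Weighted
sampling without replacement was chosen over independent Bernoulli thinning
so the budget is met exactly. The sampling rate is reported as
budget/(M·N): 5,242 patterns on 256² is 8% sampling, i.e. a 92% reduction
relative to the 2·M·N patterns of full acquisition.

**Reconstruction.** Zero-filled inverse DFT (scaled by 1/(2b·MN), imaginary
residue discarded, negatives clipped) is the default. For undersampled
masks a compressed-sensing reconstruction solves

    argmin_t ‖F t − T′‖² + λ₁‖t‖₁ + λ₂ TV(t)

with the fidelity restricted to measured coefficients, by monotone
proximal-gradient descent: soft-thresholding plus an in-house Chambolle
dual iteration for the isotropic TV proximal step, with backtracking that
only accepts objective-decreasing steps (the recorded objective history is
therefore nonincreasing by construction, a tested property). Weights are
relative to the scene's DC-derived mean intensity; defaults λ₁ = 0,
λ₂ = 1e−3, 200 iterations, stopping when the relative objective drop falls
below 1e−6. Non-convergence sets a flag rather than raising.

## SFDI demodulation and inversion

Illumination at spatial frequency `fk` (1/mm) and phase φ₁ is
`0.5·(1 + cos(2π fk x·pitch + φ₁))`; the combined projected pattern is the
pixelwise product of illumination and basis pattern, and measuring through
it equals measuring the illuminated scene (tested equivalence). Three
phases (0, 2π/3, 4π/3 — the set for which the estimators below are exact;
other sets are configurable) at each of two frequencies (0 and 0.2 /mm)
give six modulated images. Demodulation uses

    M_ac = (√2/3)·[(I₁−I₂)² + (I₂−I₃)² + (I₃−I₁)²]^{1/2},   M_dc = (I₁+I₂+I₃)/3,

whose prefactor makes `M_ac` equal the sinusoid amplitude; any constant
prefactor cancels in calibration `Rd = (M/M_ref)·Rd_ref` against a
reference phantom of known reflectance (default μa = 0.0046,
μs′ = 0.7 /mm), which also cancels source intensity and detector gain
(tested to 1e−12).

**Forward model.** Diffuse reflectance under sinusoidal illumination uses
the diffusion approximation for a semi-infinite homogeneous medium:
`Rd = 3A a′ / ((μ′eff/μtr + 1)(μ′eff/μtr + 3A))` with `μtr = μa + μs′`,
`a′ = μs′/μtr`, `μ′eff = sqrt(3 μa μtr + (2π f)²)`, and A from the
effective-reflection polynomial of the refractive index (default n = 1.4,
A ≈ 0.154). A closed-form diffusion model was chosen over Monte Carlo
tables: it is exact to evaluate, differentiable, and self-consistent
between the simulator and the inverter, which is what the package's
end-to-end claims require. Its known bias at low albedo (μs′/μa small) is
irrelevant to self-consistent experiments but means absolute Rd values
differ from transport-accurate tables in that corner. One consequence: at
f = 0.2 /mm the model is not strictly monotone in μa for μs′ below
~0.6 /mm (a shallow ~1e−4 ridge), so the table validator enforces strict
decrease only for the planar-frequency table and allows that model-
intrinsic slack in the modulated one.

**Lookup-table inversion.** The forward model is tabulated on a log-spaced
grid (defaults μa ∈ [0.001, 0.5], μs′ ∈ [0.1, 5] /mm, 100×100). Each pixel
is seeded with the nearest tabulated (Rd_dc, Rd_ac) node via a KD-tree and
refined by a vectorized damped Newton iteration on the closed form
(finite-difference Jacobians, step capped at a factor-of-two per
iteration). Newton refinement was preferred over bilinear interpolation
because it makes the inverse numerically exact: forward–inverse round trips
recover coefficients to machine precision and the inverter is idempotent on
its own output, properties interpolation can only approximate. Pixels with
nonfinite reflectance, a boundary-node seed, or an out-of-grid excursion
are flagged invalid and clamped, never extrapolated.

## Synthetic scenes and what they represent

The package carries no measured data; two generators stand in for the
laboratory objects.

**Two-tone phantom** (piecewise constant): background μa = 0.01,
μs′ = 1.0 /mm with three radius-25 px disks at μa ∈ {0.02, 0.03, 0.04} and
μs′ = 1.5 /mm on 256² at 0.5 mm/px — typical tissue-phantom values placed
well inside the table range. It exercises edge response and inversion
contrast.

**Smooth tissue-like scene**: seeded Gaussian-filtered noise fields
(filter σ = correlation/2, periodic boundaries) min-max mapped into
μa ∈ [0.005, 0.05], μs′ ∈ [0.5, 2] /mm, blended over a soft elliptical
silhouette (edge width 3 px) toward the most-absorbing/least-scattering
corner outside. Correlation defaults to 16 px at 256² and scales with
resolution.

**Geometry.** The smooth scene is imaged at a constant 64 mm field of
view (pixel pitch 64/M mm), which places the 0.2 /mm carrier at 12.8
cycles/frame. This is deliberate: compressive Fourier acquisition of
modulated images only works when the carrier and its modulation sidebands
fit inside the sampled low-frequency disc (radius 29 cycles at the lowest
standard budget), and that is the regime any working FSI-SFDI instrument
must be built in. The phantom keeps its conventional 0.5 mm pitch
(128 mm field, carrier at 25.6 cycles), which puts the carrier at the edge
of the lowest-budget disc — see limitations.

**Forward rendering.** Per pixel, frequency and phase:
`I = S·Rd(μa, μs′, fk)·0.5·(1 + cos(2π fk x·pitch + φ))`, source intensity
S = 10⁴ counts, with optional additive Gaussian noise (σ relative to the
mean DC intensity, seeded; no shot-noise model). The reference stack is
rendered identically from the homogeneous reference phantom. Noiseless
stacks are closed forms, so demodulation + calibration recovers the model
reflectance to 1e−9 (tested).

What passing on these surrogates does **not** show: performance on real
tissue with specular reflections, surface curvature, vignetting, shot
noise, or silhouette edges sharper than the simulated ones; nor agreement
with transport-accurate (Monte Carlo) reflectance at low albedo.

## Experiment drivers and scoring

Sweeps push every one of the twelve images (six sample, six reference)
through acquisition at a mask, reconstruction, demodulation, calibration,
and inversion, and score the compressed optical maps against the
full-sampling pipeline output — the noncompressive ground truth — with two
metrics: RMSE in percent of the reference map's dynamic range (both maps
normalized by the reference min–max before the RMS), and single-window
global SSIM (sample covariance, K₁ = 0.01, K₂ = 0.03, L = the reference
dynamic range; 255 for 8-bit input). A sliding-window SSIM is available
behind a flag but never used for reported scores. Scores against the
generating maps are reported as separate columns for synthetic scenes.
Reports are written as deterministic CSV (fixed column order, `%.10g`
floats), so a fixed config and seed reproduces files byte-for-byte.

Problem sizes used by the shipped experiments: 256² scenes at budgets
5,242–26,214 patterns (8–40% sampling) with 3–5 seeds, and a 512² scene
across the same budgets; the full-sampling references are computed through
the same single-pixel path (proved identical to using the camera images
directly).

## Known limitations

- **Phantom at the lowest budget.** At 5,242 patterns the two-tone phantom
  reconstructs with ~8% worst-map RMSE against full sampling (SSIM ≈ 0.96).
  Two mechanisms dominate: Gibbs ringing of the sharp disk edges under the
  29-cycle low-pass (a ~5.7% floor independent of geometry), and truncation
  of the AC-carrier sidebands at the phantom's 0.5 mm pitch, where the
  carrier (25.6 cycles) nearly touches the disc edge. Piecewise-constant
  targets with radius-25 disks are simply not representable at 8% circular
  sampling; the TV reconstruction trims the μa error but cannot restore the
  unmeasured AC sidebands.
- The three-phase demodulator is exact only for 2π/3-spaced phases; other
  phase sets are accepted but bias the amplitude estimate.
- The diffusion forward model shares the usual inaccuracy of diffusion
  theory near sources and at low albedo; inversions are self-consistent
  with the simulator but not transport-accurate.
- The TV solver is a plain monotone proximal-gradient scheme; it favors
  robustness (guaranteed descent) over speed and typically reports
  `converged=False` at tight tolerances within the default 200 iterations.
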