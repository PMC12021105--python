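# Methods

This note documents the models behind `nirphasor`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic
benchmarks do and do not demonstrate about real instruments.

## Optical model

A variable retarder (retardance R = d·Δn(λ), nm) between two parallel
linear polarizers, both at 45° to the fast axis, transmits
T(R, λ) = ½(1 + cos(2πR/λ)) relative to the light passed by the first
polarizer. `optics.jones_transmission` implements the general
polarizer–retarder–polarizer Jones product for arbitrary angles and is
verified to reduce to the closed form in the parallel-45° geometry to
1e−12; the closed form is what the rest of the package uses.

**Dispersion.** Δn(λ) defaults to a constant, so a setting's retardance
is wavelength independent and T is exactly the closed form. Real liquid
crystal retarders are dispersive; `RetarderModel.dispersion` accepts a
relative birefringence curve when one is available. This choice matters
quantitatively for narrow windows (see Calibration below).

**Calibration.** `calibrate_retardance` grid-searches R from 0 to the
device ceiling (default 10.4 µm, a typical NIR LCVR; `None` means
unbounded and the search cap is set from the slope-matching estimate
R ≈ order·λ_c²/Δλ) in 5 nm steps, scoring the Pearson correlation
between T(R,·) and the ideal target on the window grid, followed by a
bounded golden-section refinement (xatol 1e−4 nm) around the best grid
point; ties break toward smaller R. Both the positive and the negated
target are considered — the sign of the winning correlation is stored
in the `FilterSetting` and undone in the phasor transform. The
procedure is deterministic and seed-free.

Because T oscillates in 1/λ, not λ, the fit is imperfect; it improves
as Δλ/λ_c shrinks. At a 50 nm window centered at 1050 nm with the
10.4 µm cap, the dispersionless model yields r² ≈ 0.940 (cosine) and
r² ≈ 0.674 (sine). A physical device with a dispersive Δn(λ) sweeps
more phase across the same window and fits the sine target better;
reported device values at this window are ≈0.96/0.82. The cosine value
is reproduced closely, the sine value only qualitatively (degraded,
and much worse than cosine) — exact agreement is not expected without
the device's dispersion curve, which is not published. The 50 nm window
is centered at 1050 nm because the narrow-window characterization
measurements cluster there.

**Window phase convention.** x(λ) = 2π(λ − λ_min)/(λ_max − λ_min); the
cosine target starts at +1 at λ_min and the window maps onto one full
turn of the phasor circle (per order). Default wavelength grid: 1 nm
spacing, inclusive of both endpoints; all spectral integrals use the
trapezoid rule. 1 nm is well below the 15 nm FWHM of the narrowest
spectra considered, so discretization error is negligible against every
tolerance asserted.

**The "sine" filter** is realized purely through retardance choice and
optional negation — no extra phase parameter — mirroring the single
degree of freedom of the physical element.

## Phasor transform

`spectral_phasor` is the exact Fourier definition (trapezoid
integration restricted to the window) and serves as the oracle for the
whole imaging chain: with ideal filter curves and noise disabled, the
render → acquire → `phasor_from_frames` pipeline reproduces it to
better than 1e−9 per pixel. Key exact properties, all asserted in the
test suite: mixtures map onto intensity-weighted segments between
component phasors; the modulus of any non-negative spectrum through
single-order filters is ≤ 1, with equality exactly for monochromatic
(single-grid-point) input; negating a filter sign flips the
corresponding coordinate.

**Validity masking.** Pixels with I_total below `min_total` — default
max(10 DN, 1% of the image maximum), since low-signal thresholds in
practice are set per image — are invalid, as are pixels whose modulus
exceeds 1 by more than 0.05 (frame noise can push a valid pixel
slightly outside the circle; anything further is treated as an
artifact and ignored). Invalid pixels carry (0, 0) placeholders and are
excluded from every statistic.

**Distortion correction.** For narrowband input at λ0 the realized
phasor is ((2T_cos(λ0)−1)·sign_c, (2T_sin(λ0)−1)·sign_s) while the
ideal is (cos x0, sin x0). `distortion_map` tabulates both over a probe
grid and interpolates the displacement as a function of realized phase
(requiring the realized phase to be monotone over the probes, which
holds for single-order filters). The correction is exact at the knots
and reduces off-knot displacements by well over 90% with a 5 nm probe
table. It is an optional step — the standard pipeline reports
uncorrected positions, which is also how clusters are usually gated.

**Spatial correction** fields are *additive* per-pixel (ΔG, ΔS)
offsets estimated from repeated acquisitions of a spectrally uniform
reference (mean minus global mean). Additive offsets preserve cluster
shapes and are trivially invertible; a multiplicative convention would
be equally consistent with a uniform-reference estimate but couples the
correction to the cluster position. References with more than 50%
invalid pixels are rejected.

**Gating** uses the even–odd rule with boundary points counted inside,
so gate polygon definitions are portable. Angular color coding wraps
phase modulo 2π (θ = ±π share a color index); invalid pixels get −1.

## Camera model

Photon-transfer (EMVA-1288 style) description: signal variance
σ_y² = K²(σ_d² + σ_q²) + K(µ_y − µ_y,dark) in DN², with defaults from a
cooled InGaAs camera: K = 1.1e−3 DN/e⁻, σ_d² = 1000 e⁻², σ_q² = 1/12
DN² (12 bit), QE = 0.56 (scalar, the value near 990 nm; a curve may be
supplied), pixel area 9e−6 cm², exposure 3 s (fluorescence) with 5–50 ms
typical for reflectance. µ_y,dark defaults to 0 because frames are
assumed background-corrected. Photon flux Φ = µ_y/(K·QE·A·t_exp).

Noise in `acquire_frame` is **Gaussian with the closed-form variance**,
not compound Poisson — shot noise enters only through the linear signal
term. This matches the standard photon-transfer treatment, keeps the
Monte-Carlo statistics analytically checkable (frame variance matches
the closed form within 5% at 1e5 draws; first-order propagation into
(G, S) matches the observed phasor spread within 10%), and is accurate
whenever the per-pixel electron count is large, which holds at every
flux level simulated here. Quantization rounds half-to-even onto
[0, 4095] at 12 bit; clipped-pixel counts are logged and kept in frame
metadata. Rounding adds real variance (~1/12 DN²) beyond the model's
K²σ_q² term, so the Monte-Carlo/closed-form comparisons run with
quantization disabled; at the signal levels of the imaging studies the
difference is immaterial.

**Phasor spread** is SD(G) + SD(S) over valid pixels. The noise-limit
study images a single emission band with a circular-Gaussian intensity
profile (σ = image size/6) and tracks spread versus image-average flux.
Spread falls monotonically from 1e9 to 1e12 photons s⁻¹ cm⁻². "No
identifiable cluster" is operationalized as spread > 0.5 (half the
phasor circle radius); with the default parameters the crossing sits at
~1e8 photons s⁻¹ cm⁻¹·s⁻¹ and moves to ~1e9 for a 0.3 threshold, so the
photon limit is threshold-sensitive at the order-of-magnitude level —
`cluster_loss_flux` therefore always reports the crossing for
thresholds {0.3, 0.5, 0.7} together.

## Synthetic data

The generator produces analytic stand-ins, not digitized measurement
curves; named presets are fixtures chosen to be representative:

* Gaussian monochromator lines, default FWHM 15 nm.
* Five chirality-like emission bands spanning 952–1120 nm (Gaussian or
  truncated-renormalized Lorentzian), including a pair 5 nm apart to
  probe the resolution limit, and a pristine/defect pair (990 → 1040 nm
  red shift with broadening) for the unmixing benchmark.
* Polymer reflectances: identical featureless plateau below 1400 nm,
  distinct absorption dips in 1400–1600 nm.
* Leaf reflectance: scattering plateau over 900–1350 nm multiplied by a
  Gaussian water-absorption band at 1450 nm (width 55 nm) with depth
  1.9·w, so a fully hydrated pixel (w = 1) retains ~15% reflectance at
  the band center; the phasor consequently moves monotonically with
  water content.

Intensities are spectral photon flux densities (photons s⁻¹ cm⁻² nm⁻¹)
so the camera equations apply without conversion. Scenes are lists of
disk/polygon regions with uniform or circular-Gaussian profiles;
rendering is deterministic and flux-conserving. Time series use a 5 s
frame period (0.2 hyperspectral cubes per second) and per-pixel clamped
linear water-uptake ramps.

What this does **not** emulate: radiative-transfer leaf optics,
physically calibrated polymer spectra, excitation/collection optics,
fixed-pattern noise, drift or registration errors. Passing benchmarks
show the *measurement chain and analysis* behave correctly under the
stated noise model, not that a particular real sample would be
resolvable.

## Time-series pipeline

Reference phasor: per-pixel mean over frames within the first `t_ref`
seconds (default 300 s, inclusive boundary); pixels invalid in more
than half of the reference frames stay invalid. Displacement is the
per-frame Euclidean distance to the reference. Rate of change is the
per-pixel OLS slope over a **trailing** window (default 600 s; ≥3
frames enforced) aligned to each output frame — trailing rather than
centered because the use case is causal monitoring, and the choice only
shifts rate curves by a constant lag. Slopes are normalized by the 99th
percentile (linear interpolation between order statistics) of all valid
slopes pooled over frames and pixels. All operators are invariant to a
global time shift.

The packaged benchmark (24×24 leaf, 3-pixel vein column with onset
60 s vs lamina onset 180 s, ramp 1/120 s⁻¹, 5 s frames over 420 s,
60 s regression window scaled down from the defaults to keep the run in
seconds) reproduces the expected spatiotemporal ordering: the vein's
normalized rate peaks at 115 s, the lamina's at 235 s.

## Unmixing convention

The measured phasor is projected orthogonally onto the segment between
the endmember phasors; the projection parameter t ∈ [0, 1] (clamped) is
the **in-window intensity fraction** of endmember b, exact for
noise-free mixtures by phasor linearity. When relative per-amount
brightnesses are supplied, the number fraction is
(t/B_b) / (t/B_b + (1−t)/B_a). The off-segment residual distance is
returned as a quality metric. Intensity fraction is the primary output
because it is the quantity the transform determines without further
assumptions; the brightness conversion is provided but the brightness
pair must come from the user.

## Problem sizes and tolerances

Benchmarks are sized for interactive runs: 64×64 oracle-equivalence
scene, 100 pixels per species and 100-pixel clusters in the resolution
sweep, 48×48 noise-study frames with 3 repeats per flux level, 1e5
draws for Monte-Carlo/closed-form comparisons, 100 traces for the OLS
sampling check. Exact identities are asserted at 1e−12, oracle
equivalences at 1e−9, Monte-Carlo comparisons at 5–10%, and recovery
benchmarks at the tolerances stated inline in the tests.

## Known limitations

* The constant-dispersion retarder understates the sine-fit quality of
  dispersive devices at narrow windows (see Calibration).
* The Gaussian noise model is inaccurate below a few photoelectrons per
  pixel; at such fluxes most pixels are invalid anyway.
* Multi-order filters are supported at acquisition, but the phasor is
  always computed from a single sine/cosine pair, so multi-order phasor
  positions are non-injective by construction.
* The look-up distortion correction assumes narrowband input; for broad
  spectra the cos(1/λ) error is spectrum-dependent and not correctable
  by a 1-D table.
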