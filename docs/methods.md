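# Methods

## Physical model

The tongue is modelled as a homogeneous, semi-infinite (half-space) medium
with uniaxial anisotropy. Each axis carries a complex conductivity
σ*(ω) = σ + jωε₀ε_r (ε₀ = 8.8541878128e-12 F/m), the standard quasi-static
composition for the kHz range; magnetic and wave-propagation effects are
neglected. Electrodes are ideal points on the surface plane. Finite tongue
thickness, curvature, layered structure, electrode contact area and
electrode–tissue polarization impedance are all outside the model.

For a unit point current source on the surface of such a half-space with
fiber axis along x, coordinate scaling of the isotropic Green's function
gives the surface potential at offset (dx, dy):

    φ(dx, dy) = 1 / (2π √(σ*_T (σ*_T dx² + σ*_L dy²))).

A tetrapolar measurement superposes +I at A and −I at B and differences the
potentials at M and N, so Z = φ(AM) − φ(AN) − φ(BM) + φ(BN). For a
collinear quadruple at angle θ from the fiber axis this factorizes into a
purely geometric cell constant k = (1/2π)(1/AM − 1/AN − 1/BM + 1/BN) and

    σ*_app(θ) = √(σ*_T (σ*_T cos²θ + σ*_L sin²θ)),    Z = k / σ*_app.

Both the kernel and the closed form use the principal complex square root;
physically admissible media (Re σ* > 0) keep each factor's argument in
(−π/2, π/2), so the product's argument stays inside (−π, π) and the branch
cut is never crossed. A runtime guard rejects roots landing in the left
half-plane. The equality of the superposed four-term sum and the closed
form is the package's central internal oracle, enforced to 1e-10 relative
in tests over randomized collinear geometries, media and frequencies.

## Array geometry

Default geometry: 16 contacts on concentric circles of radii 4 and 7 mm,
four directions (0°, 45°, 90°, 150°), giving per-direction electrode
separations |AM| = 3, |MN| = 8, |AN| = 11, |AB| = 14 mm and
k = (1/2π)(2/0.003 − 2/0.011) ≈ 77.166 m⁻¹. Which ring carries current is
not dictated by the physics of the closed form; the package defaults to the
outer ring (current outside, sensing inside — the symmetric Wenner-like
arrangement) and exposes `current_ring` as a config field. The fiber axis
is assumed to coincide with the 0° sagittal direction unless overridden.
The fourth direction is kept fully configurable; 150° is the hardware's
choice and the model imposes no constraint on it.

## Apparent and anisotropic VCP

Stage 1 converts each calibrated record through σ*_app = k / z, reporting
σ_app = Re σ*_app and ε_r,app = Im σ*_app / (ωε₀). Stage 2 inverts the
angular model per frequency, independently — no dispersion model is imposed
at reconstruction time, so each frequency's estimate stands on its own.

Two inversion routes are implemented and cross-checked:

- Closed form from the 0°/90° pair: σ*_T = σ*_app(0°) (the paradox of
  anisotropy) and σ*_L = σ*_app(90°)² / σ*_T. Exact, used for
  initialization.
- Nonlinear least squares over all measured directions, minimizing
  Σ_θ |model − meas|² / |meas|² (relative residuals so every direction and
  frequency weighs comparably) over log-parameterized unknowns, which
  guarantees positivity without a constrained solver. Levenberg–Marquardt
  with xtol = ftol = 1e-15, gtol = 1e-12, at most 500 iterations;
  non-convergence raises rather than returning silently. Initialization is
  deterministic (closed form when 0°/90° are present, isotropic mean
  otherwise), so results need no seed.

Permittivity is tied across axes (ε_rL = ε_rT) by default, reflecting the
angular symmetry of tissue permittivity observed in vivo; an anisotropic-
permittivity option remains. Four directions give 8 real equations for 3
(tied) or 4 (untied) unknowns; two oblique directions still determine the
tied fit. A fiber-angle offset is not fitted by default — four directions
barely constrain a fifth parameter.

## Calibration

Each channel (direction) at each frequency is a complex linear map
raw = gain·Z + offset, fitted by least squares from phantom-board readings
with known resistors. One board gives one reference per channel, so only
the gain is identifiable (offset pinned at 0); two or more boards with
distinct resistors determine both. Reference resistors are ideal (real,
frequency-flat). Per-cell residual norms are stored as diagnostics. The
linear model order is the minimal one consistent with per-channel,
per-frequency calibration practice; the module surface would admit a
higher-order map without interface changes.

## Simulator: what it emulates and what it does not

The simulator generates exactly what the hardware would hand the pipeline:
per-direction, per-frequency complex impedances with static channel errors
and additive noise, plus phantom readings for calibration, all from one
integer seed (identical seeds ⇒ byte-identical session files).

Tissue dispersion uses a per-axis Cole model in complex-conductivity form,
σ*(ω) = σ_∞ − (σ_∞ − σ_0)/(1 + (jωτ)^α): the minimal empirical description
of Maxwell–Wagner interfacial polarization of myofiber membranes, for which
(α = 1) conductivity strictly rises and relative permittivity strictly
falls across 8–256 kHz. The healthy-like preset uses τ = 2 µs, α = 1,
σ_0/σ_∞ = 0.6/0.8 S/m longitudinal and 0.3/0.5 S/m transverse. Both axes
share the dispersion magnitude σ_∞ − σ_0 = 0.2 S/m, making the per-axis
permittivities coincide at every frequency — deliberately, because measured
tongue permittivity shows no directional dependence — and placing the
default-array |Z| at 125–255 Ω, inside the 100–300 Ω range reported for
in vivo tongue. These values were chosen once and frozen.

The default noise model is a frozen convention, not a hardware claim:
complex Gaussian noise on Z with total relative std 0.5 % (split evenly
between components), static per-direction complex gain error of std 1 %
and offset error of 1 Ω drawn once per channel. Not modelled: 1/f noise,
quantization, electrode polarization, contact-impedance variation, drift,
and inter-subject anatomical variability. Passing tests therefore
demonstrate correctness of the computational chain under its own stated
model, not accuracy on real tongues.

## Numerical and testing choices

- Noisy-recovery test bounds were frozen from Monte-Carlo calibration runs
  before being asserted: with 1 % relative complex noise on Z
  (truth σ_L = 0.9, σ_T = 0.3 S/m, ε_r = 2e4, 64 kHz, 500 replicates) the
  observed median errors are ≈0.45 % (σ_T), ≈0.9 % (σ_L), ≈1.3 % (ε_r);
  bounds are frozen at 3 %, 5 % and 5 %. The phantom-accuracy threshold for
  the 100–300 Ω band is frozen at 3 % (observed max 1.4 % over 6000 draws);
  the noisy calibration-gain bound at 0.35 % (observed max 0.29 % over
  1000 seeds at relative σ = 1e-3 with four references).
- Problem sizes in the test suite and acceptance script (1000 oracle draws,
  100-point recovery grid × 6 frequencies, 500 noisy replicates) run in a
  few seconds total; each per-frequency fit costs ~1 ms.
- Degenerate inputs: coincident electrodes, zero impedance, non-positive
  frequency, zero gain and singular calibration fits raise `ValueError`
  with named cells; session validation returns the full list of violations
  instead of stopping at the first.
- CSV and JSON outputs write floats at full repr precision and so
  round-trip to the bit; read CSVs back with pandas
  `float_precision="round_trip"` when bit-exact comparison matters.

## Known limitations

Single homogeneous half-space only — no finite-element or layered forward
model; the fiber angle is assumed known; no Cole-model fitting of the
reconstructed spectra; no group-level statistics across subjects; the
session JSON schema is original to this package and not a device-wire
format.
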