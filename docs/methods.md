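# Methods

## Scope and model

`dnpse` implements a steady-state model of solid-effect DNP for a single
electron–nucleus pair under continuous microwave irradiation, with the
dipolar coupling modulated by classical translational motion. The
observables are the DNP enhancement ε(Ω) as a function of the microwave
offset Ω = ω_S − ω and a set of per-offset diagnostics (electronic
polarization factor p, forbidden-transition rates v±, nuclear
cross-polarization factor p_X). Out of scope by design: Overhauser,
cross-effect and thermal-mixing mechanisms, multi-spin systems,
hyperfine/g anisotropy, inhomogeneous EPR lines, and time-dependent
(transient) dynamics.

The derivation chain is:

1. **Classical Bloch steady state** for the electron (module `bloch`):
   line-shape factors f_y, f_x, f_z; p = R_1S f_z; allowed-transition
   rate v₁ = ω_1² f_y / 2. The absorptive component f_y is retained
   throughout — it contributes to the pumping rate v₋ even though it is
   small under power broadening — by lumping it onto the dispersive
   pathway with f_y/f_x = R_2S/Ω.
2. **Electron–nucleus coherences** (module `rates`): their steady state
   is controlled by the generalized Bloch matrix B (the Bloch matrix with
   iω_I added to the diagonal). For an arbitrary normalized spectral
   density j(s) the stationary solution reduces to
   M = U diag(j(λ_n)) U⁻¹ where B = U diag(λ_n) U⁻¹, from which v₊, v₋
   and the dipolar contribution to nuclear relaxation are extracted. In
   the static ("solid") limit j(s) = 1/s, M = B⁻¹ and closed forms in
   the complex line-shape functions F_y, F_x, F_z exist; the eigen path
   and the closed forms are kept as mutually checking implementations.
3. **Enhancement assembly** (module `profile`):
   ε_SE = p v₋/(R_1I + v₊)·|γ_S|/γ_I, p_X = R_1I/(R_1I + v₊),
   ε = ε_SE − (1 − p_X). The sign convention (enhancement positive at
   positive canonical offset) follows from the negative electronic
   gyromagnetic ratio with Ω = ω_S − ω.

### Spectral densities

All rate formulas use ⟨δ²⟩·j(·) with the correlation function normalized
to one at t = 0. This convention reproduces the standard closed forms for
electron-driven nuclear relaxation — ⟨δ²⟩T_1S/(1 + T_1S²ω_I²) in the
static limit and the Lorentzian ⟨δ²⟩τ/(1 + τ²ω_I²) for fast exponential
decay — without extra numerical prefactors.

- `solid`: j(s) = 1/s.
- `exponential`: j(s) = 1/(s + 1/τ). A deliberately crude model kept for
  comparison; it under-broadens the line wings.
- `ffhs` (force-free hard spheres): two spherical molecules carrying the
  spins at their centers, relative diffusion coefficient D, contact
  distance b, τ = b²/D. With x = sτ,
  j(s) = τ(√x + 4)/(x^{3/2} + 4x + 9√x + 9), principal branch. Limits:
  j → (4/9)τ for sτ → 0 and j → 1/s for sτ → ∞.

All evaluations require Re(s) > 0, which holds for the eigenvalues of B
whenever the relaxation times are positive; the precondition is enforced
rather than silently continued past the branch cut.

### Perturbative option

The tilted-frame approximation (module `perturbative`) uses the exact
eigenvectors of the equal-relaxation matrix (rotation about the effective
field, tilt angle α with cos α = Ω/ω_eff) and corrects the eigenvalues to
first order in R_1S − R_2S. The rate extraction from
M̃ = U₀ diag(j(λ̃_n)) U₀^H is shared with the exact path, so the two
coincide identically when T_1S = T_2S. The approximation is accurate for
v₋ (percent level at J-band-like parameters) but fails for v₊ near zero
offset; fits therefore default to `method="exact"`, and the perturbative
path is an optional flag for speed and insight (it exposes the widths
R_2S + 1/τ of the motional solid-effect Lorentzians and the
dispersive-extrema offset Ω_1/2 = ω_1 √(T_1S/T_2S)).

## Units and constants

Internally, times are in ns and angular frequencies in rad/ns,
everywhere; conversions happen only at I/O boundaries (MHz, Gauss, ms).
Physical constants are CODATA-2018, pinned in one table
(`dnpse.CONSTANTS`). The microwave field is converted with the
free-electron gyromagnetic ratio (g = 2), so B₁ = 6 G corresponds to
ω_1/2π ≈ 16.8 MHz. The default |γ_S|/γ_I ≈ 658.21 is the electron–proton
value and can be overridden for other nuclei. The dipolar strength is
⟨δ²⟩ = D_dip²(6π/5)N′/(3b³) with N′ the radical number density; at
N = 0.1 M and b = 1 nm, √⟨δ²⟩/2π ≈ 22 kHz.

## Key parameters

| parameter | meaning | unit | typical (J band, BDPA/lipid) |
|---|---|---|---|
| T_2S | electronic transverse relaxation | ns | 215 |
| T_1S = r₁T_2S | electronic longitudinal relaxation | ns | ~1500 |
| T_1I | nuclear longitudinal relaxation | ms | 50 |
| B₁ | microwave field | G | 6 |
| ω_I/2π | nuclear Larmor frequency | MHz | 400 |
| τ = T_2S/r₂ | dipolar correlation time | ns | ~7 |
| b | contact distance | nm | ~0.5 |
| N | radical concentration | M | 0.1 |

The reference values N_ref = 0.1 M and b_ref = 1 nm fix the scale of the
fit parameter r₃; b is *derived* from r₃ for an assumed N, never fitted
directly (N and b are not separately identifiable from one profile).

## Numerical choices

- The 3×3 complex eigenproblem is solved densely (LAPACK via
  `numpy.linalg.eig`) for all offsets in one batched call; the pointwise
  and vectorized paths share the same code. The decomposition is verified
  by reconstruction (tolerance 1e-9 relative); a defective matrix — a
  measure-zero parameter set — triggers a 1-part-in-1e9 offset nudge and
  a warning.
- T_x (the transfer factor with the absorptive pathway lumped in) has a
  0/0 form at Ω = 0; it is finite by continuity and is evaluated there at
  a relatively tiny offset. The enhancement itself does not use this
  branch (ε_SE(0) = 0 exactly through f_x).
- Fitting minimizes unweighted squared residuals over
  (log r₁, log r₂, log r₃) with `scipy.optimize.least_squares` (TRF,
  bounds r₁, r₂ ≥ 1, r₃ > 0). A deterministic coarse multistart grid
  (default 4×4×4 over the log-bounds) is scored first and the best
  `n_refine` starts are polished; an optional seeded jitter of the start
  grid is clipped to the bounds. The objective is smooth but can trade
  line width against tail amplitude, hence the multistart. The local
  covariance is the Gauss-Newton estimate transformed from log space.
- Weighted fitting is not implemented beyond passing a weight column
  through I/O; profiles are treated as equally reliable at all offsets.

## Diagnostics and conventions

- The supplied 1/T_1I is the *total* measured nuclear relaxation rate.
  The model's dipolar contribution R_1I^A = ⟨δ²⟩ Re j(R_1S + iω_I) is
  reported per profile and a warning is raised if it exceeds 1/T_1I
  (inconsistent inputs). At the J-band fit parameters R_1I^A is ~84% of
  1/T_1I — large but consistent.
- v₊ < 0 can occur for motional models at offsets beyond ω_I (most
  visibly at X band), making p_X > 1; this is expected model behavior and
  is only flagged when it drives R_1I + v₊ ≤ 0.
- The reduction factor ρ(τ) = Re j(1/T_2S)/T_2S measures how solid-like
  the liquid is (canonical-peak amplitude relative to the static limit);
  ρ = 1/2 at τ = T_2S for the exponential model and between τ = 4T_2S
  and 5T_2S for FFHS. The magnification factor
  μ(τ) = T_x^liquid(Ω_1/2)/T_x^solid(Ω_1/2) quantifies the concurrent
  growth of the non-canonical peaks (two to three orders of magnitude for
  FFHS at τ between 0.01 T_2S and T_2S).
- Offsets in all files are Ω/2π in MHz with Ω = ω_S − ω. Externally
  produced data may use the opposite sign convention; the reader's
  `column_map` plus a sign check against the expected odd symmetry of
  ε_SE is the recommended control.

## Synthetic data

The generator (`dnpse.synth`) emulates a measured field profile as the
forward model on a stated offset grid plus i.i.d. additive Gaussian noise
of fixed σ, reproducible per seed, with full provenance in the CSV
header. It reproduces the *structure* of experimental profiles (canonical
and non-canonical peaks, odd symmetry, realistic amplitudes) but not
instrument-specific features: baseline drifts, offset-dependent noise,
calibration errors in B₁ or the offset axis, or temperature gradients.
Passing recovery tests on synthetic data therefore demonstrates the
identifiability and correct implementation of the estimator under the
stated noise model, not robustness to systematic experimental artifacts.
Default study conditions mirror the J-band experiment: T_2S = 215 ns,
T_1I = 50 ms, B₁ = 6 G, ω_I/2π = 400 MHz, ratios (7.2, 30.4, 8.9), grids
spanning ±600 MHz.

## Problem sizes

Forward profiles use a 2001-point default grid (±1.5 ω_I, configurable);
the acceptance script uses 4801 points over ±600 MHz. The
parameter-recovery study runs 100 seeded replicates on an 81-point grid
with a 3×3×3 multistart refined from the best 2 starts — sizes chosen so
the whole study completes in seconds while leaving the estimator's
behavior unchanged (the noiseless self-fit recovers the truth to
optimizer tolerance at these sizes).

## Known limitations

- Single electron–nucleus pair; no nuclear–nuclear spin diffusion, so
  the absolute enhancement scale inherits the ⟨δ²⟩ model assumptions.
- The exponential and FFHS models share a single correlation time; no
  distributions of timescales or rotational/eccentric-spin extensions.
- The perturbative path degrades for T_1S ≫ T_2S and must not be used
  for v₊ at small offsets.
- Error bars are local covariance estimates only; no bootstrap or
  profile-likelihood intervals.
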