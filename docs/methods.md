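# Methods

## The model

`segwave` implements a coarse-grained continuum description of the
vertebrate segmentation clock: the oscillation state of the presomitic
mesoderm (PSM) is a phase field φ(x, t) on a one-dimensional coordinate x
along the body axis (x = 0 at the posterior tip), obeying

    ∂φ/∂t + v(x,t) ∂φ/∂x = ω(x,t) + (ε/2) ∂²φ/∂x²

with no-flux boundary condition ∂φ/∂x|₀ = 0.  Three ingredients shape the
wave pattern:

* an intrinsic frequency profile ω = ω₀ U(x/x̄(t)), maximal at the
  posterior tip, decaying to σω₀ at the anterior end x̄(t) and arrested
  (ω = 0) beyond it — this slowdown is what turns synchronous oscillation
  into anteriorly traveling waves;
* a cell-velocity profile v = v₀ V(x/x̄(t)) with V(ξ) = 1 − e^(−qξ),
  carrying tissue away from the proliferating tip (v(0) = 0);
* diffusive phase coupling of strength ε, the continuum limit of local
  synchronization between neighbouring cellular oscillators.

Both profiles rescale with the instantaneous PSM length
x̄(t) = x₀ + x₁ tanh(η(t − t̄)), which in zebrafish shortens from
≈ 619 µm to ≈ 215 µm (η < 0).  Segments form at the anterior end, one per
completed oscillation cycle there.  Derived observables:

* wave count K(t) = (φ(0,t) − φ(x̄,t)) / 2π,
* segment number N(t) = φ(x̄,t) / 2π,
* segment length S(t): exactly, the distance over which the phase ahead
  of x̄ drops by 2π; approximately, 2π/|∂φ/∂x(x̄,t)|,
* the anterior frequency Ω_A = dφ(x̄(t),t)/dt and its decomposition
  Ω_A = Ω_P + Ω_D + Ω_W into the posterior frequency, a Doppler term
  Ω_D = (dx̄/dt)(∂ψ/∂x) (the anterior end moves into the waves) and a
  dynamic-wavelength term Ω_W = ∂ψ/∂t (the pattern's wavelength changes
  in time), where ψ(x,t) = φ(x,t) − φ(0,t).

For the zebrafish parameter set, Ω_D > 0 and Ω_W < 0 with the Doppler
term larger: segments form *faster* than any local oscillator runs.

## Default parameters

Units package-wide: µm, min, radians.

| name  | value      | meaning                               | units   |
|-------|-----------|----------------------------------------|---------|
| ω₀    | 0.15      | posterior (maximum) frequency          | rad/min |
| v₀    | 0.87      | saturated cell speed                   | µm/min  |
| ε     | 7         | phase-coupling strength                | µm²/min |
| k     | 2.07      | frequency-profile shape                | —       |
| σ     | 0.34      | anterior frequency fraction, U(1)      | —       |
| q     | 1.80      | velocity-profile shape                 | —       |
| t₀    | −256      | start time (φ ≡ 0 imposed there)       | min     |
| x₀, x₁| 417, 202  | PSM length: midpoint, half-span        | µm      |
| η     | −5.09·10⁻³| length-relaxation rate (signed)        | 1/min   |
| t̄    | 192       | inflection time of the shortening      | min     |

η is stored signed; the peak shortening rate |x₁η| ≈ 1.03 µm/min occurs
at t = t̄.  A caveat on published boundary-velocity plots: values quoted
as "q/x̄ = 0.008 µm" are dimensionally inverse lengths (µm⁻¹); this
package treats the combination q/x̄ as an inverse length throughout.
Two published velocity regimes exist (v₀ = 0.87 for segments 10–17,
0.44 for 18–22); the default set uses the single value 0.87.

## Numerics

The solver (this package's own) uses method of lines on a fixed uniform
lab-frame grid [0, L] containing the moving anterior end: first-order
upwind advection (valid since v ≥ 0 everywhere), centred diffusion,
explicit Euler stepping with the combined stability bound
dt = 0.9/(v_max/dx + ε/dx²) when dt = "auto".  The far boundary closes
with zero second derivative (pure outflow); the frequency jump at x̄(t)
is not smoothed — each node is classified by ξ = x/x̄(t) at the current
time, with ξ ≤ 1 counted as inside the PSM.  Coupling is applied on the
whole domain including the arrested region x > x̄ (switchable:
`coupling_beyond_psm`).  The initial condition is φ ≡ 0 at t₀; the
transient is part of the model, since t₀ was calibrated so that the
simulated pattern aligns with experimental staging.  The solver draws no
random numbers; runs are bit-reproducible.

Default production grid: dx = 1 µm, L = 900 µm, output every 8th step
(≈ 0.9 min); the full 756-min zebrafish run takes well under a second.
Halving dx and dt moves φ by amounts consistent with first-order
convergence (tested).  With ε = 7 and dx = 1 the upwind scheme's
numerical diffusion is v dx/2 ≲ 0.44 µm²/min, ~12 % of ε/2; anterior
segment lengths measured by local gradients carry a few-percent bias at
this resolution, while the integral 2π-phase-drop length is converged to
0.01 µm already at dx = 1 (checked against dx = 0.5 and 0.25).

Derivative conventions in the decomposition: temporal derivatives (Ω_P,
Ω_W, Ω_A) are centred differences on the output grid; dx̄/dt is always
the analytic derivative of the tanh law; ∂ψ/∂x at the anterior end
averages the two one-sided estimates over the intervals swept between
output frames, each sampled at the frame when it is swept — a stencil
anchored to grid nodes instead aliases the phase-field kink at x̄ into
Ω_D and inflates the identity defect Ω_A − (Ω_P+Ω_D+Ω_W) thirtyfold.
The anterior phase gradient for S likewise anchors its finite-difference
step at x̄ itself (step h = max(dx, 1 µm), one-sided into the PSM).

Segment events are integer crossings of N(t), located by linear
interpolation between frames.  Raw crossings count from 0 (where φ ≡ 0
was imposed); the staging convention renumbers them so the event nearest
t = 0 is segment 7, matching how developmental time is staged against
the experimentally observed sequence.  The integer offset is reported
alongside the records.  Events staged below 7 fall in the start-up
transient before a full wave pattern exists (the earliest event has no
complete wave anterior of the boundary, so its exact 2π-drop length is
undefined); analyses of the segment-length curve therefore consider the
staged range, where S(N) rises to an interior maximum at the 11–12
segment mark and falls thereafter.  The maximum under the definitional
2π-drop length is at segment 12 at every tested resolution; under the
local-gradient approximation the broad 11–12 plateau can resolve to
either index.

## Periodic states and approximations

At constant length the field relaxes to φ = Ωt + ψ(x).  The relaxation
runs in chunks of five estimated periods until the sup-norm change of ψ
over one period falls below 10⁻⁴ (relative); Ω is the least-squares
slope of the posterior phase over the final three periods, and is
measured identically at interior points (tested).  The weak-coupling
approximation ψ(x) ≈ ∫₀ˣ (ω − Ω)/v dx′ is evaluated with Ω = ω₀ (any
other Ω makes the integrand non-integrable at x = 0 since v(0) = 0); the
x → 0 limit of the integrand, ω₀U′(0)/(v₀q), is inserted analytically.
For the zebrafish parameters at x̄₀ = 417 µm the approximation deviates
from the relaxed solver profile by up to ≈ 0.22·2π rad — dominated by
the collective-frequency shift Ω − ω₀ ≈ −0.002 rad/min that the
approximation neglects (its integral over the PSM accounts for ~1.3 of
the 1.4 rad) — and the deviation shrinks roughly linearly with ε
(0.22·2π → 0.11·2π → 0.04·2π across ε = 7, 0.7, 0.07).  The
clock-and-wavefront relation S ≈ v₀T likewise holds only loosely here
(the measured anterior wavelength exceeds it by ~25 %, consistent with
2π/|ψ′(x̄₀)| = 2πv₀V(1)/(ω₀(1−σ))).

## Classical-wave oracles

The Doppler and dynamic-wavelength effects have exact classical
analogues used as oracles: a plane wave observed while moving toward the
source (Ω = (1 + v̄/c)ω), and a wave in a medium with refractive index
n(t) = rt², u = u₀(1 + rxt/c) sin(ωt/(1 + rxt/c)), whose local
wavelength at fixed x shrinks over time so a static observer is
red-shifted, Ω = ω/(1 + rxt/c)².  The latter is verified symbolically
(sympy: the PDE residual simplifies to 0) and numerically
(complex-step differentiation of the phase).  No wave-equation solver is
implemented; the closed forms are the point.

## Fitting

The three estimation routines mirror how the parameter set is obtained
from data, with objectives chosen by this package (the original
quantification protocols are not public in detail):

* length dynamics: nonlinear least squares (scipy `curve_fit`) of the
  tanh law; sign convention x₁ > 0 with η carrying the direction;
* boundary velocities: per-boundary least-squares slope vs time and mean
  position, then least squares of v₀(1 − e^(−ax)) with a = q/x̄ a single
  inverse-length parameter.  Mean velocities time-average the saturating
  profile, so very long tracks bias a downward (Jensen-type bias
  inherent to the mean-velocity/mean-position quantification); the
  synthetic generator emulates a finite tracking window (150 min) as in
  imaging practice;
* phase profile: (k, σ, q, t₀) from a phase kymograph by forward
  simulation and a circular loss, mean of 1 − cos(ψ_model − ψ_data) over
  the PSM mask 0 ≤ x ≤ x̄(t), with ω₀, v₀, ε held fixed and the length
  dynamics fitted separately first (no joint fit).  The circular loss is
  insensitive to 2π wrapping; referencing ψ to x = 0 removes any
  constant offset.  Optimisation is Nelder-Mead from a coarse grid of 8
  starting points over (k, σ, q) — guarding the σ–k trade-off — with t₀
  initialised by a coarse objective scan over candidate start times
  (the data carry no absolute posterior phase, so t₀ enters only through
  the transient shape of ψ).

## Synthetic data

The fixture generators emulate the study's three data kinds from known
parameters: embryo-averaged PSM-length series (tanh law + Gaussian noise,
default 20 points as in ~30-min sampling of a 700-min window),
boundary tracks (simulate → segment events → advect boundaries with the
cell flow, thinned to the ~10-min frame rate, positional noise), and
phase kymographs (simulate → ψ on a sampling grid → unwrapped phase
noise, with the posterior column kept as the exact reference).  All
generators are deterministic under a fixed seed (NumPy PCG64).  They
emulate *model* data: real kymographs add intensity-to-phase extraction
artefacts, embryo-to-embryo variability, and late-stage deviations from
length-scaling profiles (the real wave patterns beyond ~18 segments are
known not to follow the scaling ansatz), so parameter-recovery results
here certify the estimators, not the biology.

## Known limitations

* First-order upwinding trades accuracy for robustness at the frequency
  jump; local gradients near x̄ need dx ≤ 1 µm for percent-level work.
* The continuum model has no phase noise, no coupling delays, and one
  spatial dimension; left–right somite asymmetry and 2-D/3-D tissue
  geometry are out of scope.
* Fitted ε is not identifiable from the observables used here and is
  treated as a literature value throughout.
* The boundary-velocity fit inherits the mean-velocity bias described
  above when tracks are long relative to the profile's saturation scale.
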