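# segwave

Continuum modelling of the vertebrate segmentation clock: traveling waves
of oscillatory gene expression in a shortening presomitic mesoderm (PSM),
the timing and length of the segments they produce, and the Doppler and
dynamic-wavelength effects that regulate the segmentation rate.

During somitogenesis, genetic oscillations sweep as waves from the
posterior tip of the PSM to its anterior end, where one segment (somite)
forms per completed oscillation cycle.  `segwave` models the tissue's
oscillation phase φ(x, t) with an advection–diffusion phase equation

    ∂φ/∂t + v ∂φ/∂x = ω + (ε/2) ∂²φ/∂x²

on a domain whose frequency profile ω = ω₀U(x/x̄(t)) and cell-velocity
profile v = v₀V(x/x̄(t)) rescale with the time-dependent PSM length
x̄(t) = x₀ + x₁ tanh η(t − t̄).  From the solved field it derives the wave
count K = (φ(0,t) − φ(x̄,t))/2π, the segment number N = φ(x̄,t)/2π, the
segment length S ≃ 2π/|∂φ/∂x(x̄,t)|, and the anterior frequency
decomposition Ω_A = Ω_P + Ω_D + Ω_W, in which the shortening-induced
Doppler term Ω_D and the dynamic-wavelength term Ω_W explain why zebrafish
form segments faster than any local oscillator cycles.

Intended for quantitative developmental biologists and physicists of
pattern formation who want a reproducible implementation of the
shortening-PSM phase model, its analytic approximations, classical-wave
analogues, and estimators for fitting the model to PSM-length series,
segment-boundary tracks and phase kymographs.

## Worked example

```python
import segwave as sw

mp = sw.ModelParameters.zebrafish()           # published parameter set
sc = sw.SimulationConfig(t_end=500.0, dx=1.0, L=900.0, output_stride=8)
pf = sw.simulate(mp, sc)                      # phi == 0 at t0 = -256 min

obs  = sw.compute_observables(pf)
segs = sw.extract_segments(pf)

nearest = min(segs, key=lambda r: abs(r.formation_time))
print(f"staging offset: {segs.staging_offset}")
print(f"segment {nearest.index} forms at t = {nearest.formation_time:+.1f} min")

sel = (obs.t >= 150) & (obs.t <= 300)         # near-linear shortening
print(f"Omega_A = {obs.Omega_A[sel].mean():.4f}, "
      f"Omega_P = {obs.Omega_P[sel].mean():.4f}, "
      f"Omega_D = {obs.Omega_D[sel].mean():+.4f}, "
      f"Omega_W = {obs.Omega_W[sel].mean():+.4f}")

staged = [r for r in segs if r.index >= 7]
big = max(staged, key=lambda r: sw.segment_length_at_anterior(
    pf, r.formation_time, "exact"))
print(f"largest segment: index {big.index}")
print(f"K(0) = {sw.wave_count(pf, 0.0):.2f}, K(450) = {sw.wave_count(pf, 450.0):.2f}")
```

prints

```
staging offset: 3
segment 7 forms at t = +23.4 min
Omega_A = 0.1736, Omega_P = 0.1481, Omega_D = +0.0960, Omega_W = -0.0705
largest segment: index 12
K(0) = 2.56, K(450) = 1.70
```

Reading: formation events are staged so the one nearest t = 0 is segment
7 (the offset against the raw count of the φ ≡ 0 start is reported).
While the PSM shortens at ≈ 1 µm/min, the anterior end forms segments at
Ω_A ≈ 0.174 rad/min even though the fastest oscillators (posterior) run
at Ω_P ≈ 0.148: the positive Doppler contribution (+0.096, the anterior
end moving into the waves) outweighs the negative dynamic-wavelength
contribution (−0.070, the pattern's wavelength shrinking in place).  The
segment-length curve S(N) is non-monotonic with the largest segments near
the 12-segment mark, and the number of waves spanning the PSM decreases
as segmentation proceeds.

A command-line interface mirrors the library:

```
segwave simulate --config params.yml --out run/
segwave observe run/ --out tables/
segwave periodic --xbar0 417
segwave fixture phase_kymograph --seed 1 --noise-sd 0.3 --out kymo.csv
segwave fit profile --data kymo.csv --out fit.json
segwave demo doppler --out fig/
```

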