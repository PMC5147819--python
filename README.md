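# lymphangion

Simulation and stability analysis of the mechanochemical oscillators that
drive pumping in a single **lymphangion** — the segment of a collecting
lymphatic vessel between two one-way valves. Lymphatic vessels have no
central heart: each segment contracts on its own, triggered by local
mechanical and chemical signals. This package is for quantitative
physiologists and modellers who want a small, fast, fully scriptable model
of that process: two coupled noise-triggered oscillators, their linear
stability analysis, stochastic time-domain simulation, and post-processing
for periods, synchronization and phase portraits.

## The model

State variables are the vessel radius `R` (m) and the dimensionless
concentrations of cytosolic Ca²⁺ (`C_Ca`, in the lymphatic muscle) and
nitric oxide (`C_NO`, produced by the endothelium). Neglecting inertia, the
radial force balance and species conservation read

```
D dR/dt    = −(A e^{aR} − p_offset) − F_Ca C_Ca / (1 + α C_NO) + p_m + A_R(t)
dC_Ca/dt   = −K_Ca (1 + β C_NO)(C_Ca − C_thresh) + S_Ca0 + S_Ca1 δ(t)/(1 + γ C_NO) + A_Ca(t)
dC_NO/dt   = −K_NO C_NO + S_NO |dR/dt| / R² + S_NO0 + A_NO(t)
```

* **Stretch-Ca²⁺ oscillator** — when the (noisy) Ca²⁺ signal crosses its
  threshold, a bolus `S_Ca1` is released as an impulse, the muscle contracts,
  and the cell is refractory until Ca²⁺ and radius have returned near
  equilibrium. Linearizing about the equilibrium radius `R1` (stiffness
  `E1 = A a e^{aR1}`) gives the closed-form contraction waveform
  `ΔR(t) ∝ (e^{−t/t_Ca} − e^{−t/t_mech})/(t_mech − t_Ca)` with
  `t_Ca = 1/K_Ca` and `t_mech = D/E1`, and the latency law
  `T = t_c ln(C_max/σ)` with `t_c = max(t_Ca, t_mech)`.
* **Shear-NO oscillator** — wall motion drives flow, flow shears the
  endothelium, and the resulting NO weakens the contractile force. The
  linearized radius/NO subsystem has characteristic polynomial
  `λ² + (E1/D + K_NO − sgn(Ṙ) S_NO F_NO/(D R1²)) λ + E1 K_NO/D = 0` with
  `F_NO = F_Ca C_Ca0 α`: always stable while contracting, and unstable
  during dilation when the vessel is narrow enough
  (`t_mech + t_NO ≲ t_FNO`, with `t_NO = 1/K_NO` and
  `t_FNO = S_NO F_NO/(E1 K_NO R1²)`). The marginal point oscillates at
  `f = √(E1 K_NO/D)/2π`.

Neither oscillator self-sustains: each has one-sided stability and is
re-triggered by noise or by periodic forcing, which produces latency periods
scaling as `ln(1/σ)`, frequency locking at small rational ratios (Arnold
tongues, Devil's staircase), and — when both oscillators are coupled —
contraction/dilation cycles that overshoot baseline when the shear-NO side
is unstable.

Integration uses the explicit Euler–Maruyama scheme (drift × dt, noise ×
√dt, boluses as instantaneous state jumps) with a numba-compiled inner loop;
per-channel noise streams are spawned independently from a single seed, so
runs are bit-reproducible.

## Worked example

Noise-triggered contractions of the stretch-Ca²⁺ oscillator at low
transmural pressure (100 Pa, noise σ = 0.01):

```python
import lymphangion as ly

p = ly.ModelParameters(p_m=100.0, sigma_Ca=0.01)
eq = ly.equilibrium_radius(p)
tc = ly.time_constants(eq, p)
print(f"R1 = {eq.R1:.3e} m, E1 = {eq.E1:.3e} Pa/m, t_mech = {tc.t_mech:.2f} s")

traj = ly.simulate(p, "ca_only", duration=200.0, seed=1)
stats = ly.detect_cycles(traj, "radius")
print(f"{stats.n_cycles} contractions, mean period {stats.mean_period:.2f} s "
      f"(CV {stats.period_cv:.2f}), amplitude {1e6*stats.amplitudes.mean():.1f} um "
      f"(CV {stats.amplitudes.std()/stats.amplitudes.mean():.3f})")
```

prints

```
R1 = 8.553e-05 m, E1 = 2.450e+06 Pa/m, t_mech = 1.22 s
27 contractions, mean period 7.64 s (CV 0.09), amplitude 12.3 um (CV 0.012)
```

The vessel equilibrates at 85.5 µm and contracts by ~12 µm. Successive
contractions are nearly identical in shape (amplitude CV ≈ 1%) but occur at
irregular intervals (period CV ≈ 9%) — the signature of a noise-triggered
rather than self-sustained oscillator. The interval scales as
`t_c ln(C_max/σ)`: halving the noise lengthens the mean period by
`t_c ln 2`, which `tests/test_acceptance.py` verifies quantitatively for
both oscillators.

The same surface is available from the shell:

```
lymphangion table2                 # equilibrium/time-constant report
lymphangion equilibrium --p-m 500  # one operating point as JSON
lymphangion simulate --mode ca_only --p-m 100 --sigma-ca 0.01 --duration 200 --seed 1
lymphangion sweep --mode no_only   # Arnold-tongue locking sweep
```

## Acceptance script

`scripts/acceptance.py` recomputes, from the packaged defaults, the
equilibrium radius, linearized stiffness and the mechanical, NO-shear and
overall time constants at transmural pressures of 100 and 500 Pa — the
model's reference operating table — by solving the radial force balance and
evaluating the linearization at runtime:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
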