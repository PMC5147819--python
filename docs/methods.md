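# Methods

This note documents the model implemented in `lymphangion`, the numerical
choices behind it, and what the test suite does and does not establish.

## Model and assumptions

A single valved lymphatic vessel segment is reduced to three state
variables: radius `R`, cytosolic Ca²⁺ in the muscle layer (`C_Ca`) and
endothelial NO (`C_NO`), both concentrations normalised to nominal levels.
Assumptions inherited from the model class:

* **No inertia.** The radial force balance is first order:
  `D dR/dt = −E(R) − F + p_m + A_R(t)`. The damping coefficient `D` lumps
  visco-elastic wall losses, viscous flow losses and transduction lags; no
  decomposition is attempted.
* **Exponential wall stiffening.** `E(R) = A e^{aR} − p_offset`, with
  coefficients taken as given (no refit of pressure–diameter data). The
  simulator keeps the full nonlinear form; stability analysis linearizes at
  `R1` with `E1 = A a e^{aR1}`.
* **Minimal Ca²⁺ kinetics.** A steady source maintains baseline, clearance
  is first order about the trigger threshold, and threshold crossing
  releases an impulse bolus `S_Ca1/(1 + γ C_NO)`. No intracellular store
  (IP₃/SR) dynamics.
* **Linear shear→NO transduction.** The NO source is
  `S_NO |dR/dt|/R² + S_NO0`; the geometric and viscous constants of the
  shear-stress expression are absorbed into `S_NO`. Thresholds and
  saturation of NO production are not modelled. `mean_shear_stress` is
  provided for diagnostics only.
* **One segment, ideal valves.** Flow enters or leaves against a closed
  valve depending on the sign of `dR/dt`; no valve bias, no axial chain of
  segments, no pumping-efficiency accounting.

Concentrations are treated as increments where it matters: the trigger
threshold `C_CaThresh` is an increment from baseline (default 0), and the
simulator integrates the Ca increment `c = C_Ca − C_Ca0` with clearance
`−K_Ca (1 + β C_NO)(c − C_CaThresh)`. Units are strict SI internally.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| `p_m` | mean transmural pressure | 100 (validated > 0) | Pa |
| `a`, `A`, `p_offset` | wall stiffening exponent/coefficient/offset | 2.45e4, 12.3, 100 | 1/m, Pa, Pa |
| `D` | lumped wall damping | 3e6 | Pa·s/m |
| `F_Ca` | Ca force coefficient | 100 | Pa |
| `C_Ca0`, `S_Ca0`, `S_Ca1` | Ca baseline, steady source, bolus | 1, 1, 0.85 | –, 1/s, – |
| `K_Ca`, `K_NO` | clearance rates | 1, 5 | 1/s |
| `S_NO`, `S_NO0` | shear→NO coefficient, chronic source | 3e-3, 0 | m, 1/s |
| `α`, `β`, `γ` | NO interactions (force, clearance, release) | 1, 0, 0 | – (each in [0,1]) |
| `σ_Ca`, `σ_NO` | channel noise standard deviations | 1e-3 | – |
| `dt` | integration step | 1e-4 | s |

The defaults are the baseline operating point used throughout: with `α = 1`
they give `R1 = 85.5 µm`, `E1 = 2.45e6 Pa/m`, `t_mech = 1.22 s`,
`t_FNO = 3.35 s` (unstable dilation) at 100 Pa, and `R1 = 151 µm`,
`E1 = 1.22e7 Pa/m`, `t_mech = 0.24 s`, `t_FNO = 0.21 s` (stable) at 500 Pa.
Figure-style stochastic experiments raise the noise to `σ = 0.01` per run,
mirroring the stated per-figure settings; synchronization experiments keep
the default `σ = 1e-3` so that the 0.01-amplitude sinusoid dominates the
triggering (with `σ = 0.01` the noise swamps the forcing and no locking
survives — verified both ways).

## Numerical scheme

* **Euler–Maruyama**, fully explicit: drift × `dt`, independent Gaussian
  increments × `√dt` per channel, boluses as instantaneous state jumps (so
  the linearized single-bolus response matches the closed-form double
  exponential exactly up to integration error). The `|dR/dt|` feeding the
  NO source is the previous step's rate — an O(dt) lag that avoids an
  implicit solve.
* **Step size.** `dt = 1e-4 s` (the stated step) for deterministic/oracle
  work; long stochastic runs (period-law statistics, locking sweeps) use
  `dt = 1e-3 s`, where the fastest system rate ≈ 19 s⁻¹ gives `λ·dt ≈ 0.02`
  and the first-order bias is far below the statistical tolerances used.
  A warning is logged when `dt > 0.1·min(t_mech, t_NO, t_Ca)`.
* **Seeding.** One user seed spawns independent per-channel `SeedSequence`
  streams (radius, Ca, NO); adding forcing on one channel cannot perturb
  another channel's noise, and identical seeds give bit-identical output.
* **Equilibrium solve.** The closed-form
  `R1 = ln((p_offset − F_Ca S_Ca0/K_Ca + p_m)/A)/a` is primary; a bracketed
  Brent root-finder cross-checks it to 1e-10 relative on every call.
  Non-positive radii or log arguments raise a configuration error naming the
  offending combination.
* **Stability labels.** Regimes come from the sign of `b` (first-order
  coefficient) and the discriminant; `|b| < 1e-9 s⁻¹` is labelled marginal.
  `sgn(Ṙ) = −1` is used at `Ṙ = 0` (the stable branch), so the turning
  point of a cycle is well-defined. The Jacobian is assembled from the
  physical linearization, whose trace and determinant reproduce the
  characteristic polynomial exactly; `critical_radii` rescans `E1(R)` at
  every radius, treating the operating point parametrically.

## Trigger and refractory logic

A contraction fires when the Ca increment crosses the threshold from below
while the cell is armed. By default noise rides on the concentration; an
option places it on the threshold instead (the model statement allows
either). The cell re-arms when the state has returned near equilibrium,
operationalised as **both**:

* the Ca increment inside a band `ε` of threshold, and
* the radius within `ε·F_Ca/E1` of `R1` (the displacement a band-sized Ca
  offset would produce, converting the band to radius units).

The radius condition matters: with a Ca-only band the latency would be
`t_Ca ln(C_max/σ)` at every pressure, whereas the latency law of this model
class uses the *dominant* time constant `t_c = max(t_Ca, t_mech)` — at low
pressure the mechanically slow wall (t_mech > t_Ca) limits recovery, which
is also what makes contraction frequency rise with transmural pressure.

`ε` defaults to the larger of the trigger-channel noise σ and the
quasi-static concentration response to a sinusoidal input on that channel
(`amp/√(K² + ω²)`). Rationale: re-arming happens when the decaying state
reaches the scale of whatever perturbation can retrigger it; this is the
same substitution (σ → forcing amplitude) used to estimate the autonomous
frequency of a forced run. An optional flag scales `σ_Ca` proportionally to
`p_m` (stretch-sensitised channels); it is off by default.

## Analysis choices

* **Cycle detection** uses the Ca event log when present, otherwise upward
  crossings of a hysteresis band (arm below 10%, fire above 40% of the
  99.5th-percentile excursion) around baseline.
* **Locking** discards the first `max(20% of the run, 10 s)`, estimates the
  output frequency from first-to-last onset spacing (immune to window
  quantisation), and snaps the output/input ratio to the smallest
  denominator `m/n` with `n ≤ 8` within an absolute tolerance of 0.02.
* **Autonomous frequency** for sweep normalisation is the closed form
  `1/(t_c ln(C_max/amplitude))` rather than a calibration run; for the
  shear-NO oscillator `C_max` is measured once from a noise-only run.
* **NO ringing frequency** is measured on the event-triggered average of
  `C_NO` (windows truncated at the next contraction) by fitting an
  exponential recovery trend plus a damped cosine. Successive-extrema
  spacing is *not* used: the contraction half-phase of the ringing is
  overdamped and traversed quickly, so raw extrema spacing reports the
  phase-switching composite cycle (~0.9 Hz at 500 Pa) rather than the
  oscillatory eigenmode; the fit recovers the dilation-phase damped
  eigenfrequency (validated against the linear theory on noise-free data:
  3.93 fitted vs 3.86 rad/s).

## What the stochastic tests establish — and what they do not

The simulator itself is the data generator; its stated world is the
baseline parameter table at 100 and 500 Pa with per-figure noise levels.
Green tests establish that *this model* reproduces the claimed phenomena:
printed equilibrium/time-constant values, the stability dichotomy, the
`ln(1/σ)` period law with the correct slope, small-rational locking with a
monotone staircase, tongue nestedness, and coupled-mode overshoot/ringing
signatures. They do not establish anything about real vessels: the model
omits valve mechanics, axial coupling between segments, upstream flow,
Ca²⁺ store dynamics, NO transport geometry and length-dependent force
generation, and its parameters were chosen to exhibit the full range of
behaviours rather than fitted to a specific preparation.

## Known limitations

* The explicit scheme is first-order; halving `dt` halves the deterministic
  error, and statistical results carry an O(K·dt) variance bias (≈0.25% at
  the settings used).
* Event detection assumes cycles are well separated relative to the output
  stride; pathological parameter sets with near-continuous triggering can
  overflow the event buffer (reported as an error, not silently).
* The threshold-noise option jitters the threshold per step without a
  `√dt` scaling; its crossing statistics therefore depend on `dt`. It is
  off by default and excluded from quantitative claims.
* At 2 significant figures the computed `R1` at 100 Pa is 8.6e-5 m; the
  reference operating table's 8.5e-5 m reflects truncation of the same
  underlying value (8.553e-5 m), which is why reports quote full precision.
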