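"""Post-processing of simulated trajectories.

Cycle detection (event-based when a Ca event log exists, otherwise a
hysteresis band around baseline), period/amplitude statistics, rational
frequency-locking detection for sinusoidally forced runs, Arnold-tongue
sweeps, phase portraits, and the event-triggered estimate of the NO ringing
frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mechanics import ModelParameters, equilibrium_radius, time_constants
from .simulate import ForcingSpec, Trajectory, simulate
from .stretch_ca import predicted_period

__all__ = [
    "CycleStats",
    "LockingResult",
    "detect_cycles",
    "locking_ratio",
    "arnold_sweep",
    "sweep_frame",
    "phase_portrait",
    "ringing_frequency",
    "period_law_slope",
]


@dataclass
class CycleStats:
    """Per-run cycle statistics.

    ``defined`` is False when fewer than two onsets were found, in which case
    the aggregate fields are NaN rather than raising.
    """

    n_cycles: int
    onsets: np.ndarray
    periods: np.ndarray
    mean_period: float
    period_cv: float
    amplitudes: np.ndarray
    C_max: float
    defined: bool = True


@dataclass(frozen=True)
class LockingResult:
    """Outcome of rational frequency-lock detection for one forced run."""

    input_frequency: float
    input_amplitude: float
    output_frequency: float
    ratio_m: int
    ratio_n: int
    locked: bool
    diagnostic: str = ""


def _channel_signal(traj: Trajectory, channel: str):
    """Excursion-from-baseline signal for a named channel."""
    p = traj.params
    if channel == "radius":
        base = traj.meta.get("R1", float(np.median(traj.R)))
        return traj.R - base
    if channel == "calcium":
        return traj.C_Ca - p.C_Ca0
    if channel == "nitric_oxide":
        return traj.C_NO - p.S_NO0 / p.K_NO
    raise ValueError(f"unknown channel {channel!r}")


def _hysteresis_onsets(t: np.ndarray, exc: np.ndarray,
                       high_frac: float = 0.4, low_frac: float = 0.1):
    """Upward crossings of a hysteresis band around baseline.

    The dominant excursion sign is detected automatically; an onset is the
    crossing above ``high_frac`` of the reference amplitude after the signal
    has re-armed below ``low_frac`` of it.
    """
    s = exc if np.nanmax(exc) >= np.nanmax(-exc) else -exc
    ref = float(np.percentile(s, 99.5))
    if ref <= 0:
        return np.empty(0)
    high, low = high_frac * ref, low_frac * ref
    onsets = []
    armed = True
    for i in range(s.size):
        v = s[i]
        if armed and v >= high:
            onsets.append(t[i])
            armed = False
        elif not armed and v <= low:
            armed = True
    return np.asarray(onsets)


def detect_cycles(traj: Trajectory, channel: str = "radius") -> CycleStats:
    """Identify contraction/dilation cycles and summarise them.

    Onsets come from the recorded Ca event log when present, otherwise from
    hysteresis-band crossings of the chosen channel.  Amplitudes are the
    per-cycle peak |excursion| of that channel; ``C_max`` is the mean
    per-cycle peak concentration increment of the active chemical species
    (Ca when boluses are recorded, otherwise NO), which enters the latency
    law T = t_c ln(C_max/sigma).
    """
    exc = _channel_signal(traj, channel)
    if traj.events:
        onsets = traj.event_times()
    else:
        onsets = _hysteresis_onsets(traj.t, exc)

    if traj.events:
        conc = _channel_signal(traj, "calcium")
    else:
        conc = _channel_signal(traj, "nitric_oxide")

    n = onsets.size
    if n < 2:
        return CycleStats(n_cycles=n, onsets=onsets, periods=np.empty(0),
                          mean_period=float("nan"), period_cv=float("nan"),
                          amplitudes=np.empty(0), C_max=float("nan"),
                          defined=False)
    periods = np.diff(onsets)
    amps = np.empty(n - 1)
    cmaxes = np.empty(n - 1)
    for i in range(n - 1):
        m = (traj.t >= onsets[i]) & (traj.t < onsets[i + 1])
        if not m.any():
            amps[i] = np.nan
            cmaxes[i] = np.nan
            continue
        amps[i] = np.nanmax(np.abs(exc[m]))
        cmaxes[i] = np.nanmax(conc[m])
    mean_period = float(np.mean(periods))
    cv = float(np.std(periods) / mean_period) if mean_period > 0 else float("nan")
    return CycleStats(n_cycles=n, onsets=onsets, periods=periods,
                      mean_period=mean_period, period_cv=cv,
                      amplitudes=amps, C_max=float(np.nanmean(cmaxes)))


def _snap_ratio(ratio: float, max_den: int = 8, tol: float = 0.02):
    """Nearest small rational m/n (n <= max_den) within ``tol`` of ``ratio``."""
    best = None
    for den in range(1, max_den + 1):
        num = round(ratio * den)
        if num < 1:
            continue
        err = abs(ratio - num / den)
        if err <= tol:
            g = math.gcd(num, den)
            cand = (num // g, den // g, err)
            if best is None or cand[1] < best[1]:
                best = cand
            break  # smallest denominator within tolerance wins
    return best


def locking_ratio(traj: Trajectory, forcing: ForcingSpec, *,
                  channel: str | None = None, max_den: int = 8,
                  tol: float = 0.02) -> LockingResult:
    """Detect rational locking between the forcing and the output cycles.

    The output frequency is estimated from onset-to-onset spans after a
    transient cut of max(20% of the run, 10 s); the ratio output/input is
    snapped to the nearest m/n with n <= ``max_den`` within ``tol``.
    """
    if forcing.kind != "sinusoid":
        raise ValueError("locking analysis requires a sinusoidal forcing spec")
    if channel is None:
        channel = "calcium" if traj.events else "nitric_oxide"
    stats = detect_cycles(traj, channel)
    t_cut = min(max(0.2 * traj.duration, 10.0), 0.5 * traj.duration)
    onsets = stats.onsets[stats.onsets >= t_cut]
    if onsets.size < 2:
        return LockingResult(forcing.frequency, forcing.amplitude, 0.0, 0, 0,
                             False, "fewer than 2 cycles after transient")
    f_out = (onsets.size - 1) / (onsets[-1] - onsets[0])
    snap = _snap_ratio(f_out / forcing.frequency, max_den, tol)
    if snap is None:
        return LockingResult(forcing.frequency, forcing.amplitude, f_out, 0, 0,
                             False, "no small rational within tolerance")
    m, n, _ = snap
    return LockingResult(forcing.frequency, forcing.amplitude, f_out, m, n, True)


def _autonomous_c_max(params: ModelParameters, mode: str, seed: int) -> float:
    """Peak concentration increment of the free-running noise-triggered
    oscillator, for the sweep's autonomous-frequency estimate."""
    if mode in ("ca_only", "coupled", "linearized"):
        return params.S_Ca1
    cal = simulate(params.replace(sigma_NO=0.01), "no_only",
                   duration=150.0, seed=seed)
    stats = detect_cycles(cal, "nitric_oxide")
    if not stats.defined:
        raise RuntimeError("autonomous calibration run produced no cycles")
    return stats.C_max


def arnold_sweep(params: ModelParameters, mode: str, freq_grid, amp_grid,
                 seed: int = 0, *, duration: float = 300.0):
    """Locking results over a forcing frequency x amplitude grid.

    Runs one simulation per grid point with the sinusoid applied to the
    oscillator's triggering chemical channel (Ca for the stretch-Ca modes, NO
    for ``no_only``).  Returns a nested list ``results[i][j]`` over
    ``amp_grid[i]`` x ``freq_grid[j]``; per-run failures become unlocked
    cells with a diagnostic.  :func:`sweep_frame` flattens the grid and adds
    the autonomous-frequency estimate f = 1/(t_c ln(C_max/amplitude)), the
    noise-law prediction with sigma replaced by the forcing amplitude.
    """
    freq_grid = list(freq_grid)
    amp_grid = list(amp_grid)
    if not freq_grid or not amp_grid:
        raise ValueError("frequency and amplitude grids must be nonempty")
    channel = "nitric_oxide" if mode == "no_only" else "calcium"
    children = np.random.SeedSequence(seed).spawn(len(amp_grid) * len(freq_grid))
    results = []
    k = 0
    for amp in amp_grid:
        row = []
        for f in freq_grid:
            cell_seed = int(children[k].generate_state(1)[0] % (2 ** 31))
            k += 1
            spec = ForcingSpec(channel=channel, kind="sinusoid",
                               amplitude=amp, frequency=f)
            if amp == 0.0:
                spec = ForcingSpec(channel=channel, kind="none")
                row.append(LockingResult(f, 0.0, 0.0, 0, 0, False,
                                         "zero amplitude"))
                continue
            try:
                traj = simulate(params, mode, (spec,), duration=duration,
                                seed=cell_seed)
                row.append(locking_ratio(traj, spec))
            except RuntimeError as err:  # propagate as unlocked with diagnostic
                row.append(LockingResult(f, amp, 0.0, 0, 0, False, str(err)))
        results.append(row)
    return results


def sweep_frame(params: ModelParameters, mode: str, results,
                c_max: float | None = None, seed: int = 0) -> pd.DataFrame:
    """Flatten an :func:`arnold_sweep` grid into a tidy table."""
    eq = equilibrium_radius(params)
    tc = time_constants(eq, params)
    t_c = tc.t_c_no if mode == "no_only" else tc.t_c_ca
    if c_max is None:
        c_max = _autonomous_c_max(params, mode, seed)
    rows = []
    for row in results:
        for r in row:
            f_auto = (1.0 / predicted_period(t_c, c_max, r.input_amplitude)
                      if 0 < r.input_amplitude < c_max else float("nan"))
            rows.append({
                "frequency": r.input_frequency,
                "amplitude": r.input_amplitude,
                "output_frequency": r.output_frequency,
                "ratio_m": r.ratio_m,
                "ratio_n": r.ratio_n,
                "locked": r.locked,
                "f_autonomous": f_auto,
            })
    return pd.DataFrame(rows)


_PORTRAIT_AXES = {("C_Ca", "R"), ("C_NO", "R"), ("R", "dRdt")}


def phase_portrait(traj: Trajectory, axes=("R", "dRdt")):
    """Coordinate pairs for a phase portrait.

    For ``(R, dRdt)`` the rate is recomputed by central differences at the
    output sampling period, emulating what is available from resampled
    experimental diameter traces.
    """
    axes = tuple(axes)
    if axes not in _PORTRAIT_AXES:
        raise ValueError(f"axes must be one of {sorted(_PORTRAIT_AXES)}")
    if axes == ("R", "dRdt"):
        return traj.R, np.gradient(traj.R, traj.t)
    x = getattr(traj, axes[0])
    return x, traj.R


def ringing_frequency(traj: Trajectory, *, window: float = 5.0,
                      skip: float = 0.4) -> float:
    """Frequency (Hz) of the decaying NO oscillation that follows each
    contraction.

    Post-event windows of C_NO (each truncated at the next contraction) are
    averaged — the ringing phase is locked to the contraction, so the
    oscillatory eigenmode survives averaging while noise cancels.  The
    average is then fit with an exponential recovery trend plus a damped
    cosine,

        s(tau) = B e^{-tau/tau1} + A e^{-lam tau} cos(omega tau + phi),

    where the trend absorbs the Ca-driven recovery of the radius and the
    cosine captures the shear-NO eigenmode; the fit with the lowest residual
    over several frequency starts wins.  The first ``skip`` seconds (the
    shear spike driven by the contraction itself) are excluded.
    """
    from scipy.optimize import curve_fit

    if len(traj.events) < 3:
        raise ValueError("ringing analysis requires >= 3 contraction events")
    h = traj.t[1] - traj.t[0]
    nw = int(round(window / h))
    ev = traj.event_times()
    segs = []
    for k, te in enumerate(ev):
        i0 = int(round(te / h))
        if i0 + nw >= traj.t.size:
            continue
        seg = traj.C_NO[i0:i0 + nw].astype(float).copy()
        if k + 1 < len(ev):  # truncate at the next contraction
            cut = int(round((ev[k + 1] - te - 0.1) / h))
            if cut < nw:
                seg[max(cut, 0):] = np.nan
        segs.append(seg)
    if len(segs) < 3:
        raise ValueError("too few complete post-event windows")
    avg = np.nanmean(np.asarray(segs), axis=0)
    tau = np.arange(nw) * h
    m = (tau >= skip) & ~np.isnan(avg)
    tt, ss = tau[m], avg[m]

    def model(t, B, tau1, A, lam, om, ph):
        return B * np.exp(-t / tau1) + A * np.exp(-lam * t) * np.cos(om * t + ph)

    scale = max(np.max(np.abs(ss)), 1e-12)
    best = None
    for om0 in (2.0, 3.0, 4.5, 6.0, 9.0):
        try:
            popt, _ = curve_fit(model, tt, ss,
                                p0=[scale, 1.0, scale, 2.0, om0, 0.0],
                                maxfev=20000)
        except RuntimeError:
            continue
        f = abs(popt[4]) / (2.0 * math.pi)
        if not 0.02 < f < 5.0:
            continue
        res = float(np.mean((model(tt, *popt) - ss) ** 2))
        if best is None or res < best[1]:
            best = (f, res)
    if best is None:
        raise RuntimeError("damped-cosine fit failed to locate a ringing mode")
    return best[0]


def period_law_slope(sigmas, mean_periods, c_maxes) -> float:
    """Least-squares slope of mean period against ln(C_max/sigma).

    Recovers the dominant time constant t_c when the latency law
    T = t_c ln(C_max/sigma) holds.
    """
    x = np.log(np.asarray(c_maxes, dtype=float) / np.asarray(sigmas, dtype=float))
    y = np.asarray(mean_periods, dtype=float)
    return float(np.polyfit(x, y, 1)[0])
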