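"""Time-domain integration of the lymphangion model.

Integrates the full nonlinear system (force balance, Ca and NO conservation
with the shear-driven NO source) or its linearized reduction with the
explicit Euler-Maruyama scheme: deterministic drift advanced with dt, white
noise increments scaled with sqrt(dt), and Ca release boluses applied as
instantaneous state jumps at threshold crossings.  The |dR/dt| feeding the
NO source is the previous step's rate, keeping the scheme fully explicit
(O(dt) consistent).

The hot loop is compiled with numba; :func:`step` exposes the identical
single-step arithmetic for inspection and testing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .mechanics import ModelParameters, equilibrium_radius, time_constants
from .stretch_ca import CaEvent

logger = logging.getLogger("lymphangion")

__all__ = ["SystemState", "ForcingSpec", "Trajectory", "step", "simulate", "MODES"]

MODES = ("ca_only", "no_only", "coupled", "linearized")
CHANNELS = ("radius", "calcium", "nitric_oxide")
KINDS = ("none", "white_noise", "sinusoid", "constant")


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state of the integrator.

    ``C_Ca`` is the Ca increment from baseline (the trigger threshold lives
    on the same scale); ``C_NO`` is the NO level; ``dRdt`` the last computed
    radius rate.
    """

    t: float
    R: float
    dRdt: float
    C_Ca: float
    C_NO: float
    refractory: bool = False


@dataclass(frozen=True)
class ForcingSpec:
    """External input on one channel.

    ``white_noise`` adds a Wiener increment of the given standard deviation
    (combined in quadrature with the channel's baseline sigma); ``sinusoid``
    adds ``amplitude * sin(2 pi f t)`` to the channel's rate equation;
    ``constant`` a steady offset.  Radius-channel amplitudes are pressures
    (Pa, entering the force balance and hence divided by D); chemical-channel
    amplitudes are dimensionless concentrations per second.
    """

    channel: str
    kind: str
    amplitude: float = 0.0
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.kind == "sinusoid" and self.frequency <= 0:
            raise ValueError("sinusoid requires frequency > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ForcingSpec":
        return cls(**d)


@dataclass
class Trajectory:
    """Uniformly sampled simulation output plus the Ca event log.

    Sample spacing is exactly ``dt * stride``; events are recorded at full
    integration resolution.  ``C_Ca`` is stored as a level (baseline plus
    increment) to match the on-disk column convention.
    """

    t: np.ndarray
    R: np.ndarray
    dRdt: np.ndarray
    C_Ca: np.ndarray
    C_NO: np.ndarray
    events: list
    params: ModelParameters
    mode: str
    seed: int
    dt: float
    stride: int
    forcing: tuple = ()
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "R": self.R, "dRdt": self.dRdt,
             "C_Ca": self.C_Ca, "C_NO": self.C_NO}
        )

    def event_times(self) -> np.ndarray:
        return np.array([e.t_trigger for e in self.events])

    def save(self, prefix: str) -> None:
        """Write ``<prefix>.tsv`` (samples), ``<prefix>.events.tsv`` and a
        ``<prefix>.json`` sidecar with parameters, seed and mode."""
        self.to_frame().to_csv(f"{prefix}.tsv", sep="\t", index=False,
                               float_format="%.17g")
        with open(f"{prefix}.events.tsv", "w") as fh:
            fh.write("t_trigger\tbolus\tC_NO_at_trigger\n")
            for e in self.events:
                fh.write(f"{e.t_trigger:.17g}\t{e.bolus:.17g}\t{e.C_NO_at_trigger:.17g}\n")
        sidecar = {
            "parameters": self.params.to_dict(),
            "mode": self.mode,
            "seed": self.seed,
            "dt": self.dt,
            "stride": self.stride,
            "forcing": [f.to_dict() for f in self.forcing],
            "meta": self.meta,
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)


# --------------------------------------------------------------------------
# compiled single-step arithmetic (shared by the kernel and by step())
# --------------------------------------------------------------------------

@njit(cache=True)
def _advance(t, R, cca, cno, drdt_prev, refr, below,
             dt, A, a, p_off, D, p_m, nonlinear_E, E0, E1, R1,
             F_Ca, C_Ca0, F_NO, alpha, linear_force,
             ca_active, K_Ca, beta, gamma, S_Ca1, theta, eps, eps_R, trigger_on,
             sigma_ca, noise_on_threshold,
             no_active, K_NO, S_NOc, S_NO0, C_NO_const, C_NO_base, sigma_no,
             sigma_R,
             amp_R, f_R, const_R, amp_ca, f_ca, const_ca,
             amp_no, f_no, const_no,
             zR, zCa, zNO):
    sq = math.sqrt(dt)
    C_NO_val = cno if no_active else C_NO_const
    if linear_force:
        F = F_Ca * C_Ca0 + F_Ca * cca - F_NO * (C_NO_val - C_NO_base)
    else:
        F = F_Ca * (C_Ca0 + cca) / (1.0 + alpha * C_NO_val)
    if nonlinear_E:
        E = A * math.exp(a * R) - p_off
    else:
        E = E0 + E1 * (R - R1)
    fR = const_R
    if amp_R != 0.0:
        fR += amp_R * math.sin(2.0 * math.pi * f_R * t)
    drdt = (-E - F + p_m + fR) / D
    R_new = R + drdt * dt + (sigma_R / D) * sq * zR

    cca_new = cca
    triggered = False
    bolus = 0.0
    if ca_active:
        dca = -K_Ca * (1.0 + beta * C_NO_val) * (cca - theta) + const_ca
        if amp_ca != 0.0:
            dca += amp_ca * math.sin(2.0 * math.pi * f_ca * t)
        cca_new = cca + dca * dt
        theta_t = theta
        if noise_on_threshold:
            theta_t = theta + sigma_ca * zCa
        else:
            cca_new += sigma_ca * sq * zCa
        if trigger_on:
            if refr:
                # refractory until the whole state is near equilibrium: the
                # Ca increment inside its band AND the radius back within the
                # displacement a band-sized Ca offset would produce
                if cca_new <= theta + eps and abs(R_new - R1) <= eps_R:
                    refr = False
            elif below and cca_new >= theta_t:
                bolus = S_Ca1 / (1.0 + gamma * C_NO_val)
                cca_new += bolus
                refr = True
                triggered = True
        below = cca_new < theta_t

    cno_new = cno
    if no_active:
        src = S_NOc * abs(drdt_prev) / (R * R) + S_NO0
        dno = -K_NO * cno + src + const_no
        if amp_no != 0.0:
            dno += amp_no * math.sin(2.0 * math.pi * f_no * t)
        cno_new = cno + dno * dt + sigma_no * sq * zNO

    return R_new, cca_new, cno_new, drdt, refr, below, triggered, bolus, C_NO_val


@njit(cache=True)
def _kernel(n, dt, stride,
            A, a, p_off, D, p_m, nonlinear_E, E0, E1, R1,
            F_Ca, C_Ca0, F_NO, alpha, linear_force,
            ca_active, K_Ca, beta, gamma, S_Ca1, theta, eps, eps_R, trigger_on,
            sigma_ca, noise_on_threshold,
            no_active, K_NO, S_NOc, S_NO0, C_NO_const, C_NO_base, sigma_no,
            sigma_R,
            amp_R, f_R, const_R, amp_ca, f_ca, const_ca,
            amp_no, f_no, const_no,
            R, cca, cno, drdt_prev, refr,
            noise,
            out_R, out_dRdt, out_cca, out_cno,
            ev_t, ev_bolus, ev_cno):
    below = cca < theta
    out_R[0] = R
    out_dRdt[0] = drdt_prev
    out_cca[0] = cca
    out_cno[0] = cno if no_active else C_NO_const
    nev = 0
    status = 0
    for i in range(n):
        t = i * dt
        (R, cca, cno, drdt, refr, below, triggered, bolus, cno_at) = _advance(
            t, R, cca, cno, drdt_prev, refr, below,
            dt, A, a, p_off, D, p_m, nonlinear_E, E0, E1, R1,
            F_Ca, C_Ca0, F_NO, alpha, linear_force,
            ca_active, K_Ca, beta, gamma, S_Ca1, theta, eps, eps_R, trigger_on,
            sigma_ca, noise_on_threshold,
            no_active, K_NO, S_NOc, S_NO0, C_NO_const, C_NO_base, sigma_no,
            sigma_R,
            amp_R, f_R, const_R, amp_ca, f_ca, const_ca,
            amp_no, f_no, const_no,
            noise[i, 0], noise[i, 1], noise[i, 2])
        if triggered:
            if nev < ev_t.shape[0]:
                ev_t[nev] = (i + 1) * dt
                ev_bolus[nev] = bolus
                ev_cno[nev] = cno_at
                nev += 1
            else:
                status = 2
                break
        if not (R > 0.0) or not math.isfinite(R + cca + cno):
            status = 1
            break
        drdt_prev = drdt
        j = i + 1
        if j % stride == 0:
            k = j // stride
            out_R[k] = R
            out_dRdt[k] = drdt
            out_cca[k] = cca
            out_cno[k] = cno if no_active else C_NO_const
    return status, nev, R, cca, cno, drdt_prev, refr


# --------------------------------------------------------------------------
# setup shared by step() and simulate()
# --------------------------------------------------------------------------

def _prepare(params: ModelParameters, mode: str, forcing, eps, trigger,
             noise_on_threshold, sigma_scales_with_pressure, C_NO_const):
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    eq = equilibrium_radius(params)
    tc = time_constants(eq, params)
    ca_active = mode in ("ca_only", "coupled", "linearized")
    no_active = mode in ("no_only", "coupled", "linearized")
    linear = mode == "linearized"

    if params.dt > 0.1 * min(tc.t_mech, tc.t_NO, tc.t_Ca):
        logger.warning(
            "dt = %g s exceeds 0.1*min(t_mech, t_NO, t_Ca) = %g s; "
            "explicit integration may be inaccurate",
            params.dt, 0.1 * min(tc.t_mech, tc.t_NO, tc.t_Ca))

    var_extra = {"radius": 0.0, "calcium": 0.0, "nitric_oxide": 0.0}
    sin_amp = {"radius": 0.0, "calcium": 0.0, "nitric_oxide": 0.0}
    sin_f = {"radius": 0.0, "calcium": 0.0, "nitric_oxide": 0.0}
    const = {"radius": 0.0, "calcium": 0.0, "nitric_oxide": 0.0}
    for f in forcing:
        if f.kind == "none":
            continue
        if f.kind == "white_noise":
            var_extra[f.channel] += f.amplitude ** 2
        elif f.kind == "sinusoid":
            if sin_amp[f.channel] != 0.0:
                raise ValueError(f"multiple sinusoids on channel {f.channel}")
            sin_amp[f.channel] = f.amplitude
            sin_f[f.channel] = f.frequency
        elif f.kind == "constant":
            const[f.channel] += f.amplitude

    scale = params.p_m / 100.0 if sigma_scales_with_pressure else 1.0
    sigma_ca = math.sqrt((params.sigma_Ca * scale) ** 2 + var_extra["calcium"])
    sigma_no = math.sqrt(params.sigma_NO ** 2 + var_extra["nitric_oxide"])
    sigma_R = math.sqrt(var_extra["radius"])

    C_NO_base = params.S_NO0 / params.K_NO
    if C_NO_const is None:
        C_NO_const = C_NO_base

    if eps is None:
        # refractory band: the scale at which a perturbation can retrigger --
        # the larger of the trigger-channel noise and the quasi-static
        # concentration response to a sinusoidal input on that channel
        resp = 0.0
        if sin_amp["calcium"] > 0.0:
            om = 2.0 * math.pi * sin_f["calcium"]
            resp = sin_amp["calcium"] / math.sqrt(params.K_Ca ** 2 + om ** 2)
        eps = max(sigma_ca, resp)
    # radius-recovery band: displacement a band-sized Ca offset produces
    eps_R = eps * params.F_Ca / eq.E1

    scalars = dict(
        A=params.A, a=params.a, p_off=params.p_offset, D=params.D,
        p_m=params.p_m, nonlinear_E=not linear, E0=eq.E0, E1=eq.E1, R1=eq.R1,
        F_Ca=params.F_Ca, C_Ca0=params.C_Ca0, F_NO=params.F_NO,
        alpha=params.alpha, linear_force=linear,
        ca_active=ca_active, K_Ca=params.K_Ca, beta=params.beta,
        gamma=params.gamma, S_Ca1=params.S_Ca1, theta=params.C_CaThresh,
        eps=eps, eps_R=eps_R, trigger_on=bool(trigger),
        sigma_ca=sigma_ca, noise_on_threshold=bool(noise_on_threshold),
        no_active=no_active, K_NO=params.K_NO, S_NOc=params.S_NO,
        S_NO0=params.S_NO0, C_NO_const=C_NO_const, C_NO_base=C_NO_base,
        sigma_no=sigma_no, sigma_R=sigma_R,
        amp_R=sin_amp["radius"], f_R=sin_f["radius"], const_R=const["radius"],
        amp_ca=sin_amp["calcium"], f_ca=sin_f["calcium"],
        const_ca=const["calcium"],
        amp_no=sin_amp["nitric_oxide"], f_no=sin_f["nitric_oxide"],
        const_no=const["nitric_oxide"],
    )
    return eq, scalars


def step(state: SystemState, params: ModelParameters, forcing=(),
         rng: np.random.Generator | None = None, mode: str = "coupled",
         **options) -> SystemState:
    """Advance one Euler-Maruyama step (reference path for the compiled loop).

    Draws the three channel noise increments (radius, Ca, NO, in that order)
    from ``rng``; with ``rng=None`` the step is deterministic.  Options are
    forwarded to the shared setup (``eps``, ``trigger``,
    ``noise_on_threshold``, ``sigma_scales_with_pressure``, ``C_NO_const``).
    """
    eq, sc = _prepare(
        params, mode, forcing,
        options.get("eps"), options.get("trigger", True),
        options.get("noise_on_threshold", False),
        options.get("sigma_scales_with_pressure", False),
        options.get("C_NO_const"),
    )
    z = rng.standard_normal(3) if rng is not None else np.zeros(3)
    below = state.C_Ca < sc["theta"]
    R, cca, cno, drdt, refr, _, _, _, _ = _advance(
        state.t, state.R, state.C_Ca, state.C_NO, state.dRdt,
        state.refractory, below,
        params.dt, sc["A"], sc["a"], sc["p_off"], sc["D"], sc["p_m"],
        sc["nonlinear_E"], sc["E0"], sc["E1"], sc["R1"],
        sc["F_Ca"], sc["C_Ca0"], sc["F_NO"], sc["alpha"], sc["linear_force"],
        sc["ca_active"], sc["K_Ca"], sc["beta"], sc["gamma"], sc["S_Ca1"],
        sc["theta"], sc["eps"], sc["eps_R"], sc["trigger_on"],
        sc["sigma_ca"], sc["noise_on_threshold"],
        sc["no_active"], sc["K_NO"], sc["S_NOc"], sc["S_NO0"],
        sc["C_NO_const"], sc["C_NO_base"], sc["sigma_no"], sc["sigma_R"],
        sc["amp_R"], sc["f_R"], sc["const_R"],
        sc["amp_ca"], sc["f_ca"], sc["const_ca"],
        sc["amp_no"], sc["f_no"], sc["const_no"],
        z[0], z[1], z[2])
    if R <= 0 or not np.isfinite(R):
        raise RuntimeError(
            f"radius became non-positive or non-finite at t = {state.t + params.dt:g} s; "
            "check parameters and time step")
    cno_out = cno if sc["no_active"] else sc["C_NO_const"]
    return SystemState(t=state.t + params.dt, R=R, dRdt=drdt, C_Ca=cca,
                       C_NO=cno_out, refractory=refr)


def simulate(params: ModelParameters, mode: str, forcing=(),
             duration: float = 100.0, seed: int = 0, *, stride: int = 10,
             initial_state: SystemState | None = None, eps: float | None = None,
             trigger: bool = True, noise_on_threshold: bool = False,
             sigma_scales_with_pressure: bool = False,
             C_NO_const: float | None = None) -> Trajectory:
    """Integrate the model for ``duration`` seconds.

    Modes: ``ca_only`` holds NO constant; ``no_only`` pins Ca at baseline and
    disables boluses; ``coupled`` runs the full nonlinear system with the
    alpha/beta/gamma interactions; ``linearized`` replaces E(R) by
    E0 + E1 (R - R1) and the force by its first-order expansion.  The same
    seed gives a bit-identical trajectory; per-channel noise streams are
    spawned independently from the seed, so adding a forcing channel does not
    perturb the other channels' noise.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    forcing = tuple(forcing)
    eq, sc = _prepare(params, mode, forcing, eps, trigger, noise_on_threshold,
                      sigma_scales_with_pressure, C_NO_const)
    dt = params.dt
    n = int(round(duration / dt))

    if initial_state is None:
        cno0 = sc["C_NO_base"] if sc["no_active"] else sc["C_NO_const"]
        state0 = SystemState(t=0.0, R=eq.R1, dRdt=0.0, C_Ca=0.0, C_NO=cno0,
                             refractory=False)
    else:
        state0 = initial_state

    # independent per-channel noise streams derived from the one seed
    children = np.random.SeedSequence(seed).spawn(3)
    noise = np.zeros((n, 3))
    for j, sig in enumerate((sc["sigma_R"], sc["sigma_ca"], sc["sigma_no"])):
        needed = sig > 0 or (j == 1 and sc["noise_on_threshold"])
        if needed:
            noise[:, j] = np.random.default_rng(children[j]).standard_normal(n)

    n_out = n // stride + 1
    out_R = np.empty(n_out)
    out_dRdt = np.empty(n_out)
    out_cca = np.empty(n_out)
    out_cno = np.empty(n_out)
    max_ev = n // 50 + 256
    ev_t = np.empty(max_ev)
    ev_bolus = np.empty(max_ev)
    ev_cno = np.empty(max_ev)

    status, nev, *_ = _kernel(
        n, dt, stride,
        sc["A"], sc["a"], sc["p_off"], sc["D"], sc["p_m"],
        sc["nonlinear_E"], sc["E0"], sc["E1"], sc["R1"],
        sc["F_Ca"], sc["C_Ca0"], sc["F_NO"], sc["alpha"], sc["linear_force"],
        sc["ca_active"], sc["K_Ca"], sc["beta"], sc["gamma"], sc["S_Ca1"],
        sc["theta"], sc["eps"], sc["eps_R"], sc["trigger_on"],
        sc["sigma_ca"], sc["noise_on_threshold"],
        sc["no_active"], sc["K_NO"], sc["S_NOc"], sc["S_NO0"],
        sc["C_NO_const"], sc["C_NO_base"], sc["sigma_no"], sc["sigma_R"],
        sc["amp_R"], sc["f_R"], sc["const_R"],
        sc["amp_ca"], sc["f_ca"], sc["const_ca"],
        sc["amp_no"], sc["f_no"], sc["const_no"],
        state0.R, state0.C_Ca, state0.C_NO, state0.dRdt, state0.refractory,
        noise,
        out_R, out_dRdt, out_cca, out_cno,
        ev_t, ev_bolus, ev_cno)

    if status == 1:
        raise RuntimeError(
            "integration aborted: radius became non-positive or a state "
            "variable overflowed; check parameters and time step")
    if status == 2:
        raise RuntimeError("integration aborted: event buffer overflow")

    events = [CaEvent(t_trigger=ev_t[i], bolus=ev_bolus[i],
                      C_NO_at_trigger=ev_cno[i]) for i in range(nev)]
    t_out = np.arange(n_out) * (dt * stride)
    return Trajectory(
        t=t_out, R=out_R, dRdt=out_dRdt, C_Ca=params.C_Ca0 + out_cca,
        C_NO=out_cno, events=events, params=params, mode=mode, seed=seed,
        dt=dt, stride=stride, forcing=forcing,
        meta={"eps": sc["eps"], "sigma_ca_effective": sc["sigma_ca"],
              "sigma_no_effective": sc["sigma_no"], "R1": eq.R1, "E1": eq.E1},
    )
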