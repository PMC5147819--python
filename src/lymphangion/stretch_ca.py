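"""Stretch-Ca2+ oscillator: impulse release, clearance and trigger logic.

Cytosolic Ca2+ in the lymphatic muscle cell is kept at a baseline by a steady
source balanced against first-order clearance.  When the (noisy) Ca increment
crosses the trigger threshold from below, a rapid release from intracellular
and extracellular stores is modelled as an impulse adding a bolus
S_Ca1 / (1 + gamma C_NO) to the concentration; the cell is then refractory
until the increment decays back to within a band epsilon of threshold.  For
the linearized mechanics a single bolus produces the closed-form contraction
waveform

    dR(t) = F_Ca S_Ca1 / (E1 K_Ca) * (e^{-t/t_Ca} - e^{-t/t_mech}) / (t_mech - t_Ca)

(a double exponential, <= 0, with removable singularity at t_mech = t_Ca),
and noise of scale sigma retriggers cycles after a latency
T = t_c ln(C_max / sigma).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .mechanics import Equilibrium, ModelParameters, time_constants

__all__ = [
    "CaEvent",
    "ca_clearance_rate",
    "apply_trigger",
    "contraction_waveform",
    "contraction_peak_time",
    "predicted_period",
]


@dataclass(frozen=True)
class CaEvent:
    """One triggered Ca2+ release."""

    t_trigger: float        # time of threshold crossing (s)
    bolus: float            # delivered Ca increment S_Ca1/(1 + gamma C_NO)
    C_NO_at_trigger: float  # NO level at the crossing


def ca_clearance_rate(C_Ca, C_NO, params: ModelParameters):
    """Ca2+ clearance rate K_Ca (1 + beta C_NO) (C_Ca - C_CaThresh).

    ``C_Ca`` is measured on the same scale as the threshold (increments from
    baseline under the default convention); the rate vanishes exactly at
    threshold and is enhanced by NO through beta.
    """
    C_Ca = np.asarray(C_Ca, dtype=float)
    C_NO = np.asarray(C_NO, dtype=float)
    out = params.K_Ca * (1.0 + params.beta * C_NO) * (C_Ca - params.C_CaThresh)
    return float(out) if out.ndim == 0 else out


def apply_trigger(state, params: ModelParameters, *, c_ca_prev: float,
                  eps: float | None = None, threshold: float | None = None):
    """Trigger/refractory step on a system state.

    ``state`` must carry fields ``t``, ``C_Ca`` (noisy increment from
    baseline), ``C_NO`` and ``refractory``; ``c_ca_prev`` is the increment at
    the previous step, needed to detect an upward crossing.  If the cell is
    not refractory and the increment crosses ``threshold`` (default
    ``params.C_CaThresh``) from below, the bolus S_Ca1/(1 + gamma C_NO) is
    added instantaneously and the refractory flag set; the flag clears once
    the increment has decayed to within ``eps`` (default ``params.sigma_Ca``)
    of threshold.

    Returns ``(new_state, CaEvent | None)``.
    """
    theta = params.C_CaThresh if threshold is None else threshold
    band = params.sigma_Ca if eps is None else eps
    if state.refractory:
        if state.C_Ca <= theta + band:
            return dataclasses.replace(state, refractory=False), None
        return state, None
    if c_ca_prev < theta <= state.C_Ca:
        bolus = params.S_Ca1 / (1.0 + params.gamma * state.C_NO)
        new = dataclasses.replace(state, C_Ca=state.C_Ca + bolus, refractory=True)
        return new, CaEvent(t_trigger=state.t, bolus=bolus, C_NO_at_trigger=state.C_NO)
    return state, None


def contraction_waveform(t, eq: Equilibrium, params: ModelParameters):
    """Radius excursion dR(t) <= 0 (m) following a single Ca bolus at t = 0,
    for the linearized mechanics.

    Uses the double-exponential closed form; when t_mech and t_Ca coincide to
    within 1e-9 relative the removable-singularity limit
    -F_Ca S_Ca1/(E1 K_Ca) * t e^{-t/t_Ca} / t_Ca^2 is used instead.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    tc = time_constants(eq, params)
    t_ca, t_mech = tc.t_Ca, tc.t_mech
    amp = params.F_Ca * params.S_Ca1 / (eq.E1 * params.K_Ca)
    if abs(t_mech - t_ca) <= 1e-9 * t_ca:
        out = -amp * t * np.exp(-t / t_ca) / t_ca ** 2
    else:
        out = amp * (np.exp(-t / t_ca) - np.exp(-t / t_mech)) / (t_mech - t_ca)
    return float(out) if out.ndim == 0 else out


def contraction_peak_time(eq: Equilibrium, params: ModelParameters) -> float:
    """Time of the waveform extremum:
    t* = t_Ca t_mech ln(t_mech/t_Ca) / (t_mech - t_Ca), with limit t_Ca when
    the two time constants coincide."""
    tc = time_constants(eq, params)
    t_ca, t_mech = tc.t_Ca, tc.t_mech
    if abs(t_mech - t_ca) <= 1e-9 * t_ca:
        return t_ca
    return t_ca * t_mech * math.log(t_mech / t_ca) / (t_mech - t_ca)


def predicted_period(t_c: float, C_max: float, sigma: float) -> float:
    """Latency law for noise-triggered cycles: T = t_c ln(C_max / sigma).

    The concentration decays exponentially with time constant t_c from its
    peak C_max; a perturbation of scale sigma can retrigger once the decaying
    increment falls to that scale.
    """
    if not (C_max > sigma > 0):
        raise ValueError("require C_max > sigma > 0")
    return t_c * math.log(C_max / sigma)
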