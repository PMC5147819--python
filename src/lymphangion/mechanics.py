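"""Wall mechanics of a single lymphangion.

A lymphangion is the segment of a collecting lymphatic vessel between two
one-way valves.  Neglecting inertia, the radial force balance on the wall is

    D dR/dt = -E(R) - F(C_Ca, C_NO) + p_m + A_R(t)

with an exponentially stiffening passive restoring force

    E(R) = A e^{aR} - p_offset

and an active contractile force generated by the lymphatic muscle cells,
attenuated by nitric oxide,

    F = F_Ca C_Ca / (1 + alpha C_NO).

This module holds the parameter container, the equilibrium solve, the
linearization E1 = A a e^{a R1}, and the characteristic time constants that
organise the dynamics (mechanical lag, Ca/NO clearance, and the NO-shear
force-modulation time).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

logger = logging.getLogger("lymphangion")

__all__ = [
    "ModelParameters",
    "Equilibrium",
    "TimeConstants",
    "elastic_force",
    "equilibrium_radius",
    "linearized_stiffness",
    "time_constants",
    "net_contractile_force",
]


class ConfigurationError(ValueError):
    """Raised when a parameter combination is physically infeasible."""


@dataclass(frozen=True)
class ModelParameters:
    """Model constants, SI units throughout; concentrations are dimensionless
    ratios normalised to nominal levels.

    Defaults are the baseline values used in all worked examples: a vessel of
    reference radius ``R0`` operating at transmural pressure ``p_m``, with the
    NO force-desensitisation interaction switched on (``alpha = 1``) and the
    NO effects on Ca clearance/release switched off (``beta = gamma = 0``).
    """

    R0: float = 1.3e-4          # reference lymphangion radius (m)
    p_m: float = 100.0          # mean transmural pressure (Pa)
    a: float = 2.45e4           # wall stiffening exponent (1/m)
    A: float = 12.3             # wall stiffening coefficient (Pa)
    p_offset: float = 100.0     # offset pressure of the E(R) fit (Pa)
    D: float = 3.0e6            # lumped wall damping coefficient (Pa s/m)
    C_Ca0: float = 1.0          # baseline Ca concentration (-)
    S_Ca0: float = 1.0          # steady Ca source maintaining baseline (1/s)
    S_Ca1: float = 0.85         # Ca release pulse (bolus) size (-)
    C_CaThresh: float = 0.0     # trigger threshold, increment from baseline (-)
    F_Ca: float = 100.0         # Ca force production coefficient (Pa)
    S_NO: float = 3.0e-3        # shear -> NO source coefficient (m)
    S_NO0: float = 0.0          # chronic / through-flow NO source (1/s)
    K_Ca: float = 1.0           # Ca clearance rate constant (1/s)
    K_NO: float = 5.0           # NO clearance rate constant (1/s)
    alpha: float = 1.0          # contraction-force suppression by NO (-)
    beta: float = 0.0           # Ca clearance enhancement by NO (-)
    gamma: float = 0.0          # Ca source blunting by NO (-)
    sigma_Ca: float = 1.0e-3    # Ca noise standard deviation (-)
    sigma_NO: float = 1.0e-3    # NO noise standard deviation (-)
    dt: float = 1.0e-4          # integration time step (s)

    def __post_init__(self) -> None:
        for name in ("a", "A", "D", "F_Ca", "S_NO", "K_Ca", "K_NO", "dt"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.p_m <= 0:
            raise ConfigurationError("p_m must be positive")
        for name in ("sigma_Ca", "sigma_NO", "S_NO0", "S_Ca1"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        """Build parameters from a flat mapping; unknown keys are rejected,
        missing keys fall back to the baseline defaults (logged)."""
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
        missing = fields - set(d)
        if missing:
            logger.info("parameters falling back to defaults: %s", sorted(missing))
        return cls(**{k: float(v) for k, v in d.items()})

    @property
    def F_NO(self) -> float:
        """Effective NO force coefficient F_NO = F_Ca * C_Ca0 * alpha (Pa)."""
        return self.F_Ca * self.C_Ca0 * self.alpha


@dataclass(frozen=True)
class Equilibrium:
    """Linearization point of the wall mechanics.

    ``R1`` solves 0 = -(A e^{aR1} - p_offset) - F_Ca S_Ca0 / K_Ca + p_m;
    ``E1 = A a e^{a R1}`` is the local wall stiffness, ``E0 = E(R1)`` the
    elastic force at equilibrium, and ``F_NO = F_Ca C_Ca0 alpha`` the
    linearized outward-acting NO force coefficient.
    """

    R1: float   # equilibrium radius (m)
    E1: float   # linearized stiffness (Pa/m)
    E0: float   # elastic force at equilibrium (Pa)
    F_NO: float  # effective NO force coefficient (Pa)


@dataclass(frozen=True)
class TimeConstants:
    """Characteristic times of the two oscillators (all seconds).

    t_c_ca = max(t_Ca, t_mech) dominates the stretch-Ca return to baseline;
    t_c_no = t_mech + t_NO + t_FNO approximates the shear-NO stable return.
    """

    t_mech: float
    t_Ca: float
    t_NO: float
    t_FNO: float
    t_c_ca: float
    t_c_no: float


def elastic_force(R, params: ModelParameters):
    """Passive restoring force E(R) = A e^{aR} - p_offset (Pa).

    Strictly increasing in R; accepts scalars or arrays, R must be positive.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("radius must be strictly positive")
    out = params.A * np.exp(params.a * R) - params.p_offset
    return float(out) if out.ndim == 0 else out


def equilibrium_radius(params: ModelParameters) -> Equilibrium:
    """Solve the force balance for the equilibrium radius.

    The equilibrium condition 0 = -(A e^{aR1} - p_offset) - F_Ca S_Ca0/K_Ca + p_m
    has the closed form R1 = ln((p_offset - F_Ca S_Ca0/K_Ca + p_m)/A)/a, used as
    the primary solution; a bracketed root-finder cross-checks it to 1e-10
    relative tolerance.
    """
    baseline_force = params.F_Ca * params.S_Ca0 / params.K_Ca
    arg = (params.p_offset - baseline_force + params.p_m) / params.A
    if arg <= 0:
        raise ConfigurationError(
            "infeasible equilibrium: p_offset - F_Ca*S_Ca0/K_Ca + p_m = "
            f"{params.p_offset - baseline_force + params.p_m:g} Pa must be positive"
        )
    R1 = math.log(arg) / params.a
    if R1 <= 0:
        raise ConfigurationError(
            "infeasible equilibrium: closed-form radius is non-positive "
            f"(log argument {arg:g} <= 1); p_m too low for this wall stiffness"
        )

    def residual(R: float) -> float:
        return -(params.A * math.exp(params.a * R) - params.p_offset) - baseline_force + params.p_m

    # bracketed cross-check of the closed form
    lo, hi = 0.5 * R1, 2.0 * R1
    if R1 > 0 and residual(lo) * residual(hi) < 0:
        R1_root = brentq(residual, lo, hi, xtol=1e-16, rtol=1e-14)
        if abs(R1_root - R1) > 1e-10 * abs(R1):
            raise RuntimeError("root-finder disagrees with closed-form equilibrium")
    if abs(residual(R1)) > 1e-8 * max(1.0, params.p_m):
        raise RuntimeError("equilibrium residual above tolerance")

    E1 = linearized_stiffness(R1, params)
    E0 = float(elastic_force(R1, params)) if R1 > 0 else params.A - params.p_offset
    return Equilibrium(R1=R1, E1=E1, E0=E0, F_NO=params.F_NO)


def linearized_stiffness(R1: float, params: ModelParameters) -> float:
    """Local wall stiffness E1 = A a e^{a R1} (Pa/m) from the Taylor expansion
    of E(R) about R1."""
    if R1 <= 0:
        raise ValueError("radius must be strictly positive")
    return params.A * params.a * math.exp(params.a * R1)


def time_constants(eq: Equilibrium, params: ModelParameters) -> TimeConstants:
    """Characteristic times at an equilibrium point.

    t_mech = D/E1 (mechanical lag), t_Ca = 1/K_Ca and t_NO = 1/K_NO
    (clearance), and t_FNO = S_NO F_NO / (E1 K_NO R1^2), the time scale over
    which shear-produced NO modulates the wall force.
    """
    t_mech = params.D / eq.E1
    t_Ca = 1.0 / params.K_Ca
    t_NO = 1.0 / params.K_NO
    t_FNO = params.S_NO * eq.F_NO / (eq.E1 * params.K_NO * eq.R1 ** 2)
    return TimeConstants(
        t_mech=t_mech,
        t_Ca=t_Ca,
        t_NO=t_NO,
        t_FNO=t_FNO,
        t_c_ca=max(t_Ca, t_mech),
        t_c_no=t_mech + t_NO + t_FNO,
    )


def net_contractile_force(C_Ca, C_NO, params: ModelParameters, linearized: bool = False):
    """Active wall force (Pa) produced by Ca and attenuated by NO.

    Nonlinear form: F = F_Ca C_Ca / (1 + alpha C_NO).  Linearized form (valid
    for small alpha*C_NO): F = F_Ca C_Ca - F_NO C_NO with
    F_NO = F_Ca C_Ca0 alpha.  The two agree to first order in alpha*C_NO.
    """
    C_Ca = np.asarray(C_Ca, dtype=float)
    C_NO = np.asarray(C_NO, dtype=float)
    if linearized:
        out = params.F_Ca * C_Ca - params.F_NO * C_NO
    else:
        if np.any(C_Ca < 0) or np.any(C_NO < 0):
            raise ValueError("concentrations must be non-negative in nonlinear mode")
        out = params.F_Ca * C_Ca / (1.0 + params.alpha * C_NO)
    return float(out) if out.ndim == 0 else out
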