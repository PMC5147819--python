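"""Shear-NO oscillator: linear stability of the radius/NO subsystem.

Wall motion drives lymph flow, flow exerts shear stress on the endothelium,
and shear-stimulated NO reduces the contractile force.  Near a fixed point
(R1, C_NO baseline) the radius increment and NO concentration obey a linear
two-variable system whose characteristic polynomial is

    lambda^2 + b lambda + c = 0,
    b = E1/D + K_NO - sgn(dR/dt) S_NO F_NO / (D R1^2),
    c = E1 K_NO / D.

Because c > 0 always, stability is decided by the sign of b: the system is
always stable while contracting (sgn = -1) and can lose stability while
dilating (sgn = +1) when the vessel is narrow enough that shear-driven NO
production outpaces its dissipation.  The marginal point oscillates at
f = sqrt(E1 K_NO / D) / (2 pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .mechanics import Equilibrium, ModelParameters

__all__ = [
    "StabilityReport",
    "mean_shear_stress",
    "no_source_rate",
    "jacobian",
    "classify_stability",
    "critical_radii",
    "marginal_frequency",
    "generic_form_parameters",
]

#: |b| below this (1/s) is labelled marginal.
MARGINAL_TOL = 1e-9

_PHASES = ("contraction", "dilation")


def _phase_sign(phase: str) -> int:
    if phase not in _PHASES:
        raise ValueError(f"phase must be one of {_PHASES}, got {phase!r}")
    return -1 if phase == "contraction" else +1


@dataclass(frozen=True)
class StabilityReport:
    """Linear stability of the shear-NO subsystem at a fixed point.

    ``b`` and ``c`` are the first- and zeroth-order coefficients of the
    characteristic polynomial; ``regime`` classifies the eigenvalue pair;
    ``criterion_unstable`` is the approximate time-scale test
    t_mech + t_NO <= t_FNO.
    """

    R1: float
    phase: str
    b: float
    c: float
    eigenvalues: tuple
    regime: str
    criterion_unstable: bool

    def to_dict(self) -> dict:
        """JSON-serializable form (eigenvalues as [re, im] pairs)."""
        return {
            "R1": self.R1, "phase": self.phase, "b": self.b, "c": self.c,
            "eigenvalues": [[lam.real, lam.imag] for lam in self.eigenvalues],
            "regime": self.regime,
            "criterion_unstable": self.criterion_unstable,
        }


def mean_shear_stress(R: float, dRdt: float, mu: float, L: float, Q0: float = 0.0) -> float:
    """Mean wall shear stress (Pa) along a lymphangion of length L.

    tau = 4 mu L |dR/dt| / R^2 + 4 mu Q0 / (pi R^3): the first term is flow
    driven by wall motion against a closed valve, the second an imposed
    through-flow Q0.  Diagnostic only -- the dynamics absorb these constants
    into the S_NO coefficient.
    """
    if R <= 0:
        raise ValueError("radius must be strictly positive")
    if mu <= 0 or L <= 0:
        raise ValueError("viscosity and length must be positive")
    if Q0 < 0:
        raise ValueError("imposed flow must be non-negative")
    return 4.0 * mu * L * abs(dRdt) / R ** 2 + 4.0 * mu * Q0 / (math.pi * R ** 3)


def no_source_rate(R: float, dRdt: float, params: ModelParameters) -> float:
    """NO production rate (1/s): S_NO |dR/dt| / R^2 + S_NO0."""
    if R <= 0:
        raise ValueError("radius must be strictly positive")
    return params.S_NO * abs(dRdt) / R ** 2 + params.S_NO0


def _poly_coefficients(R1: float, E1: float, F_NO: float, params: ModelParameters,
                       sgn: int) -> tuple:
    b = E1 / params.D + params.K_NO - sgn * params.S_NO * F_NO / (params.D * R1 ** 2)
    c = E1 * params.K_NO / params.D
    return b, c


def jacobian(R1: float, phase: str, eq: Equilibrium, params: ModelParameters) -> np.ndarray:
    """Jacobian of the (radius increment, NO concentration) subsystem.

    Row 1 is the linearized force balance D d(dR)/dt = -E1 dR + F_NO c_NO;
    row 2 substitutes that rate into the linearized NO source
    dc_NO/dt = sgn * S_NO/R1^2 * dR/dt - K_NO c_NO, so the trace and
    determinant reproduce the characteristic polynomial coefficients exactly.
    """
    if R1 <= 0:
        raise ValueError("radius must be strictly positive")
    sgn = _phase_sign(phase)
    E1, F_NO, D = eq.E1, eq.F_NO, params.D
    k = sgn * params.S_NO / R1 ** 2
    return np.array([
        [-E1 / D, F_NO / D],
        [k * (-E1 / D), k * F_NO / D - params.K_NO],
    ])


def classify_stability(R1: float, phase: str, eq: Equilibrium,
                       params: ModelParameters) -> StabilityReport:
    """Eigenvalue classification of the shear-NO fixed point.

    Regime labels: stable_node / stable_spiral (b > 0, real / complex pair),
    marginal (|b| below tolerance), unstable_spiral / unstable_node (b < 0).
    """
    sgn = _phase_sign(phase)
    b, c = _poly_coefficients(R1, eq.E1, eq.F_NO, params, sgn)
    disc = b * b - 4.0 * c
    if disc >= 0:
        root = math.sqrt(disc)
        eigs = ((-b - root) / 2.0 + 0j, (-b + root) / 2.0 + 0j)
    else:
        root = math.sqrt(-disc)
        eigs = (complex(-b / 2.0, -root / 2.0), complex(-b / 2.0, root / 2.0))
    if abs(b) < MARGINAL_TOL:
        regime = "marginal"
    elif b > 0:
        regime = "stable_spiral" if disc < 0 else "stable_node"
    else:
        regime = "unstable_spiral" if disc < 0 else "unstable_node"
    tmech = params.D / eq.E1
    tno = 1.0 / params.K_NO
    tfno = params.S_NO * eq.F_NO / (eq.E1 * params.K_NO * R1 ** 2)
    return StabilityReport(
        R1=R1, phase=phase, b=b, c=c, eigenvalues=eigs, regime=regime,
        criterion_unstable=(tmech + tno <= tfno),
    )


def critical_radii(params: ModelParameters, window: tuple = (1e-5, 5e-4),
                   n_scan: int = 4000) -> tuple:
    """Radii bounding the dilation-phase eigenvalue regimes.

    Scanning the fixed-point radius parametrically (E1 recomputed as
    A a e^{aR} at each point), returns (R_A, R_B): below R_A the dilation
    eigenvalues are real and positive (non-oscillatory runaway), between R_A
    and R_B they are complex with positive real part (unstable oscillation),
    at R_B the system is marginally stable (b = 0), above R_B stable.
    """
    if params.F_NO <= 0:
        raise ValueError("critical radii require alpha > 0 (F_NO > 0)")

    def b_of(R: float) -> float:
        E1 = params.A * params.a * math.exp(params.a * R)
        return _poly_coefficients(R, E1, params.F_NO, params, +1)[0]

    def g_of(R: float) -> float:
        # b(R) + 2 sqrt(c(R)) = 0 marks where the unstable pair leaves the
        # real axis (b = -2 sqrt(c), i.e. discriminant zero on the b<0 side).
        E1 = params.A * params.a * math.exp(params.a * R)
        b, c = _poly_coefficients(R, E1, params.F_NO, params, +1)
        return b + 2.0 * math.sqrt(c)

    grid = np.linspace(window[0], window[1], n_scan)

    def first_root(f) -> float:
        vals = np.array([f(R) for R in grid])
        sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if sign_change.size == 0:
            raise ValueError("no transition in range: widen the radius window")
        i = sign_change[0]
        return brentq(f, grid[i], grid[i + 1], xtol=1e-14)

    R_A = first_root(g_of)
    R_B = first_root(b_of)
    if not R_A < R_B:
        raise RuntimeError("expected R_A < R_B; scan window may be degenerate")
    return R_A, R_B


def marginal_frequency(E1: float, params: ModelParameters) -> float:
    """Oscillation frequency (Hz) at marginal stability:
    f = sqrt(E1 K_NO / D) / (2 pi)."""
    if E1 <= 0:
        raise ValueError("E1 must be positive")
    return math.sqrt(E1 * params.K_NO / params.D) / (2.0 * math.pi)


def generic_form_parameters(eq: Equilibrium, params: ModelParameters) -> tuple:
    """Map onto the generic second-order oscillator
    x'' + A_coef (1 - sgn(x') B_coef / x^2) x' + (x - x1) = g(t),
    time nondimensionalised by omega0 = sqrt(E1 K_NO / D).

    Returns (A_coef, B_coef, x1).  The fixed point is conditionally unstable
    exactly when x1^2 < B_coef, matching the sign of b in the characteristic
    polynomial.  Unlike the Van der Pol oscillator this system cannot
    self-sustain a limit cycle: for x1^2 > B_coef the damping term is positive
    in both phases, and even for x1^2 < B_coef the contraction phase is
    unconditionally stable, so each cycle must be re-triggered externally.
    """
    omega0 = math.sqrt(eq.E1 * params.K_NO / params.D)
    A_coef = (eq.E1 / params.D + params.K_NO) / omega0
    B_coef = params.S_NO * eq.F_NO / (eq.E1 + params.D * params.K_NO)
    return A_coef, B_coef, eq.R1
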