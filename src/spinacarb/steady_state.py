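"""Analytic fasting steady state of the closed feedback loop.

With no intestinal absorption (W = 0), eliminating the fast signalling
variables reduces the loop to a single relation for the equilibrium glucose
concentration.  Writing

    K1 = G_E*G_R*G3*G_beta / (D_R + G3*G_beta)
    K2 = D_R*D_beta / (D_R + G3*G_beta)

the fixed-point map G <- G1*P / (1 + K1*G/(K2+G)) has the equilibria of the
quadratic

    (1+K1)*G**2 + (K2 - G1*P)*G - G1*K2*P = 0

whose constant term is negative for any positive parameter set, so the two
roots have opposite signs and the positive one is the unique physiological
("equifinal") fasting glucose.  The corresponding insulin concentration
follows from the secretion branch, I = G3*G_beta*G/(D_beta+G).

Both the closed form and an independent fixed-point iteration are exposed;
their agreement is a standing invariant of the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import ParameterSet

__all__ = [
    "SteadyStateSolution",
    "k_coefficients",
    "equifinal_state",
    "fixed_point_iteration",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge."""

    def __init__(self, message: str, last_iterate: float):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class SteadyStateSolution:
    """Equifinal fasting steady state and the algebra that produced it.

    K1 (dimensionless) and K2 (mol/L) are the reduced loop coefficients;
    a, b, c the quadratic coefficients; G_inf and I_inf the equilibrium
    glucose and insulin concentrations (mol/L); discriminant = b**2 - 4ac.
    """

    K1: float
    K2: float
    a: float
    b: float
    c: float
    G_inf: float
    I_inf: float
    discriminant: float


def k_coefficients(params: ParameterSet) -> tuple[float, float]:
    """Reduced loop coefficients (K1, K2) of the steady-state relation."""
    loop_gain = params.G3 * params.G_beta  # mol/L
    denom = params.D_R + loop_gain
    K1 = params.G_E * params.G_R * loop_gain / denom
    K2 = params.D_R * params.D_beta / denom
    return K1, K2


def equifinal_state(params: ParameterSet) -> SteadyStateSolution:
    """Closed-form fasting steady state (W = 0) of the feedback loop.

    Returns the positive root of the steady-state quadratic together with
    the equilibrium insulin concentration.
    """
    K1, K2 = k_coefficients(params)
    g1p = params.G1 * params.P
    a = 1.0 + K1
    b = K2 - g1p
    c = -K2 * g1p
    disc = b * b - 4.0 * a * c
    # c <= 0 and a > 0 force disc >= b**2; equality only in degenerate limits.
    assert disc > 0, "steady-state discriminant must be positive"
    G_inf = (-b + math.sqrt(disc)) / (2.0 * a)
    I_inf = params.G3 * params.G_beta * G_inf / (params.D_beta + G_inf)
    return SteadyStateSolution(
        K1=K1, K2=K2, a=a, b=b, c=c, G_inf=G_inf, I_inf=I_inf, discriminant=disc
    )


def fixed_point_iteration(
    params: ParameterSet,
    G_start: float,
    max_iter: int = 1_000_000,
    tol: float = 1e-12,
) -> float:
    """Iterate the steady-state map to its fixed point (oracle for the root).

    Applies G <- G1*P / (1 + K1*G/(K2+G)) until |dG| < tol (mol/L).  The map
    is a contraction on the positive axis, so any positive start converges
    to the same equilibrium as :func:`equifinal_state`.
    """
    if not G_start > 0:
        raise ValueError(f"G_start must be positive, got {G_start!r}")
    K1, K2 = k_coefficients(params)
    g1p = params.G1 * params.P
    G = float(G_start)
    for _ in range(max_iter):
        G_next = g1p / (1.0 + K1 * G / (K2 + G))
        if abs(G_next - G) < tol:
            return G_next
        G = G_next
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations (last iterate {G})", G
    )
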