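"""Structural relations of the insulin-glucose feedback loop.

The loop couples two first-order pharmacokinetic ("ASIA") elements through
three nonlinear transfer characteristics:

* beta-cell secretion saturates in glucose (Michaelis-Menten type),
  ``S = G_beta * G / (D_beta + G)``;
* insulin-receptor signalling saturates in insulin,
  ``M = G_R * I / (D_R + I)``, amplified by the effector gain to the
  dimensionless distal signal ``N = G_E * M``;
* hepatic glucose production is damped by non-competitive (divisive)
  inhibition, ``Q = P / (1 + N)``.

Glucose arrives at rate ``R = W + Q`` (intestinal absorption plus regulated
endogenous production).  All functions accept scalars or NumPy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "SimulationState",
    "insulin_secretion_rate",
    "insulin_signal",
    "regulated_production",
    "glucose_arrival",
    "asia_derivative",
    "asia_step_response",
]


@dataclass(frozen=True)
class SimulationState:
    """Snapshot of all loop variables at one instant (SI units).

    t: time (s); G: glucose (mol/L); I: insulin (mol/L);
    S: insulin secretion rate (mol/s); M: proximal insulin signal (mol/s);
    N: distal insulin signal (dimensionless); Q: regulated glucose
    production (mol/s); R = W + Q: glucose arrival rate (mol/s);
    W: intestinal absorption rate (mol/s).
    """

    t: float
    G: float
    I: float
    S: float
    M: float
    N: float
    Q: float
    R: float
    W: float

    @classmethod
    def from_concentrations(
        cls, t: float, G: float, I: float, W: float, params: ParameterSet
    ) -> "SimulationState":
        S = insulin_secretion_rate(G, params)
        M, N = insulin_signal(I, params)
        Q = regulated_production(params.P, N)
        return cls(t=t, G=G, I=I, S=S, M=M, N=N, Q=Q, R=W + Q, W=W)


def _check_nonneg(name: str, value) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be non-negative")


def insulin_secretion_rate(G, params: ParameterSet):
    """Beta-cell insulin secretion rate S (mol/s) at glucose G (mol/L).

    Saturating in G with half-maximum at D_beta and supremum G_beta.
    """
    _check_nonneg("glucose concentration", G)
    return params.G_beta * G / (params.D_beta + G)


def insulin_signal(I, params: ParameterSet):
    """Receptor and effector response (M, N) to insulin I (mol/L).

    M = G_R*I/(D_R+I) (mol/s) is the proximal receptor signal; the distal
    signal N = G_E*M is dimensionless with supremum G_E*G_R.
    """
    _check_nonneg("insulin concentration", I)
    M = params.G_R * I / (params.D_R + I)
    return M, params.G_E * M


def regulated_production(P, N):
    """Endogenous glucose production Q = P/(1+N) under divisive inhibition."""
    _check_nonneg("constitutive production P", P)
    _check_nonneg("distal insulin signal N", N)
    return P / (1.0 + N)


def glucose_arrival(W, Q):
    """Total glucose arrival rate R = W + Q (mol/s)."""
    _check_nonneg("intestinal absorption W", W)
    _check_nonneg("regulated production Q", Q)
    return W + Q


def asia_derivative(y, x, alpha: float, beta: float):
    """Rate of change of a first-order dilution/elimination element.

    dy/dt = alpha*x - beta*y, where alpha = 1/V_D converts the input rate x
    (mol/s) into a concentration change and beta is the clearance rate
    constant (1/s).
    """
    return x * alpha - beta * y


def asia_step_response(x_const, alpha: float, beta: float, y0, t):
    """Closed-form response y(t) of an ASIA element to a constant input.

    y(t) = alpha*x/beta + (y0 - alpha*x/beta) * exp(-beta*t); y(0) = y0 and
    y(inf) = alpha*x/beta.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("time must be non-negative")
    y_inf = alpha * x_const / beta
    return y_inf + (y0 - y_inf) * np.exp(-beta * np.asarray(t, dtype=float))
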