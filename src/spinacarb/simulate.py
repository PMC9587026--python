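"""Time-domain simulation of the full feedback loop.

The dynamics are two coupled first-order equations driven by the nonlinear
transfer characteristics of :mod:`spinacarb.model`:

    dG/dt = alpha_G * (W(t) + Q(t)) - beta_G * G
    dI/dt = alpha_I * S(t)          - beta_I * I

integrated with classical fixed-step RK4.  Protocols describe the exogenous
glucose input: fasting (W = 0), an oral load absorbed with first-order
kinetics, or an intravenous bolus applied as an instantaneous concentration
increment of (amount in mol) * alpha_G — the exact dilution semantics of
alpha = 1/V_D.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import insulin_secretion_rate, insulin_signal, regulated_production
from .parameters import ParameterSet
from .steady_state import equifinal_state

__all__ = [
    "Protocol",
    "Trajectory",
    "make_protocol",
    "simulate",
    "summarize_trajectory",
    "IntegrationError",
]

GLUCOSE_MOLAR_MASS = 180.18  # g/mol


class IntegrationError(RuntimeError):
    """Integrator produced a non-finite or negative state."""


@dataclass(frozen=True)
class Protocol:
    """Exogenous glucose input schedule.

    ``W_of_t`` maps time (s) to the intestinal absorption rate (mol/s);
    ``boluses`` are (time s, amount mol) pairs applied as instantaneous
    glucose concentration jumps of amount*alpha_G between integration steps.
    """

    kind: str
    W_of_t: Callable[[float], float] = lambda t: 0.0
    boluses: tuple[tuple[float, float], ...] = ()
    description: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(amount < 0 or t < 0 for t, amount in self.boluses):
            raise ValueError("bolus times and amounts must be non-negative")
        if self.boluses and list(self.boluses) != sorted(self.boluses):
            raise ValueError("boluses must be sorted by onset time")


@dataclass
class Trajectory:
    """Uniformly sampled simulation output.

    ``frame`` has columns t, G, I, S, M, N, Q, R, W in SI units (s, mol/L,
    mol/s); ``metadata`` records parameters, protocol and step size.
    """

    frame: pd.DataFrame
    metadata: dict

    def to_csv(self, path) -> None:
        """Write the trajectory as CSV plus a JSON metadata sidecar."""
        self.frame.to_csv(path, index=False, float_format="%.17g")
        with open(str(path) + ".meta.json", "w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)

    @property
    def terminal(self) -> pd.Series:
        return self.frame.iloc[-1]


def make_protocol(kind: str, dose_g: float | None = None, **options) -> Protocol:
    """Construct a fasting, oGTT or ivGTT protocol.

    fasting: no exogenous input.
    ogtt: oral dose (default 75 g) absorbed as W(t) = f*D*ka*exp(-ka*t) with
    bioavailability f (default 0.8) and absorption rate constant ka
    (default 1/1800 s^-1); D = dose/180.18 mol.
    ivgtt: single instantaneous bolus (default 0.3 g/kg x 70 kg = 21 g) at
    t = 0 (configurable via ``bolus_time``).
    """
    if kind == "fasting":
        return Protocol(kind="fasting", description={"kind": "fasting"})
    if kind == "ogtt":
        dose = 75.0 if dose_g is None else float(dose_g)
        if dose < 0:
            raise ValueError("dose must be non-negative")
        f = float(options.pop("bioavailability", 0.8))
        ka = float(options.pop("ka", 1.0 / 1800.0))
        if options:
            raise TypeError(f"unknown ogtt options: {sorted(options)}")
        D = dose / GLUCOSE_MOLAR_MASS  # mol
        return Protocol(
            kind="ogtt",
            W_of_t=lambda t: f * D * ka * math.exp(-ka * t) if t >= 0 else 0.0,
            description={"kind": "ogtt", "dose_g": dose, "bioavailability": f, "ka": ka},
        )
    if kind == "ivgtt":
        dose = 0.3 * 70.0 if dose_g is None else float(dose_g)
        if dose < 0:
            raise ValueError("dose must be non-negative")
        t0 = float(options.pop("bolus_time", 0.0))
        if options:
            raise TypeError(f"unknown ivgtt options: {sorted(options)}")
        amount = dose / GLUCOSE_MOLAR_MASS
        boluses = ((t0, amount),) if amount > 0 else ()
        return Protocol(
            kind="ivgtt",
            boluses=boluses,
            description={"kind": "ivgtt", "dose_g": dose, "bolus_time": t0},
        )
    raise ValueError(f"unknown protocol kind {kind!r}; supported: fasting, ogtt, ivgtt")


def _derivatives(G: float, I: float, W: float, params: ParameterSet):
    _, N = insulin_signal(I, params)
    Q = regulated_production(params.P, N)
    S = insulin_secretion_rate(G, params)
    dG = params.alpha_G * (W + Q) - params.beta_G * G
    dI = params.alpha_I * S - params.beta_I * I
    return dG, dI


def simulate(
    params: ParameterSet,
    protocol: Protocol,
    t_end: float,
    dt: float = 1.0,
    initial: tuple[float, float] | None = None,
) -> Trajectory:
    """Integrate the closed loop over [0, t_end] with fixed-step RK4.

    ``initial`` is (G0, I0) in mol/L; when omitted the analytic fasting
    steady state is used, so a fasting run starts (and stays) at
    equilibrium.  Boluses are applied between steps as exact concentration
    jumps.  Raises :class:`IntegrationError` on negative or non-finite
    states (the loop itself cannot produce them at any sane step size).
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    if not 0 < dt <= 60.0:
        raise ValueError("dt must be in (0, 60] s")
    if initial is None:
        ss = equifinal_state(params)
        G, I = ss.G_inf, ss.I_inf
    else:
        G, I = float(initial[0]), float(initial[1])
        if G < 0 or I < 0:
            raise ValueError("initial concentrations must be non-negative")

    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    out = np.empty((n_steps + 1, 9))
    bolus_queue = list(protocol.boluses)

    def record(i: int, t: float, G: float, I: float) -> None:
        W = protocol.W_of_t(t)
        S = insulin_secretion_rate(G, params)
        M, N = insulin_signal(I, params)
        Q = regulated_production(params.P, N)
        out[i] = (t, G, I, S, M, N, Q, W + Q, W)

    for i, t in enumerate(times):
        while bolus_queue and bolus_queue[0][0] <= t:
            _, amount = bolus_queue.pop(0)
            G += amount * params.alpha_G
        record(i, t, G, I)
        if i == n_steps:
            break
        # RK4 step
        W1 = protocol.W_of_t(t)
        Wm = protocol.W_of_t(t + dt / 2.0)
        W2 = protocol.W_of_t(t + dt)
        k1G, k1I = _derivatives(G, I, W1, params)
        k2G, k2I = _derivatives(G + dt / 2 * k1G, I + dt / 2 * k1I, Wm, params)
        k3G, k3I = _derivatives(G + dt / 2 * k2G, I + dt / 2 * k2I, Wm, params)
        k4G, k4I = _derivatives(G + dt * k3G, I + dt * k3I, W2, params)
        G += dt / 6.0 * (k1G + 2 * k2G + 2 * k3G + k4G)
        I += dt / 6.0 * (k1I + 2 * k2I + 2 * k3I + k4I)
        if not (math.isfinite(G) and math.isfinite(I)) or G < 0 or I < 0:
            raise IntegrationError(
                f"integration diverged at t={t + dt:g}s (G={G!r}, I={I!r}); "
                "reduce dt"
            )

    frame = pd.DataFrame(
        out, columns=["t", "G", "I", "S", "M", "N", "Q", "R", "W"]
    )
    metadata = {
        "params": params.to_config(),
        "protocol": protocol.description or {"kind": protocol.kind},
        "dt": dt,
        "t_end": t_end,
        "integrator": "rk4-fixed",
        "initial": {"G0": float(out[0, 1]), "I0": float(out[0, 2])},
    }
    return Trajectory(frame=frame, metadata=metadata)


def summarize_trajectory(traj: Trajectory) -> dict:
    """Headline quantities of a simulation run.

    Returns peak glucose and its time, glucose at 120 min (when the run is
    long enough), insulin at 0/30/60/120 min, and the settling time: the
    earliest time after which glucose stays within 1% of its terminal value.
    """
    f = traj.frame
    if len(f) == 0:
        raise ValueError("empty trajectory")
    t = f["t"].to_numpy()
    G = f["G"].to_numpy()
    I = f["I"].to_numpy()
    i_peak = int(np.argmax(G))
    G_end = G[-1]
    outside = np.abs(G - G_end) > 0.01 * abs(G_end)
    settling = 0.0 if not outside.any() else float(t[np.nonzero(outside)[0][-1]] + (t[1] - t[0] if len(t) > 1 else 0.0))
    summary = {
        "peak_G_mol_L": float(G[i_peak]),
        "t_peak_s": float(t[i_peak]),
        "terminal_G_mol_L": float(G_end),
        "terminal_I_mol_L": float(I[-1]),
        "settling_time_s": settling,
    }
    for minutes in (0, 30, 60, 120):
        ts = minutes * 60.0
        if ts <= t[-1]:
            summary[f"G_{minutes}min_mol_L"] = float(np.interp(ts, t, G))
            summary[f"I_{minutes}min_mol_L"] = float(np.interp(ts, t, I))
    return summary
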