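"""Structure parameters of the insulin-glucose feedback loop.

The model is parametrised by a small set of constant gains, EC50 values and
first-order pharmacokinetic constants.  Internally everything is kept in
strict SI-derived units (mol/L, mol/s, s); the published reference values
are usually quoted on mixed scales (pmol/s, mmol/L, nmol/L, umol/s), so
:func:`load_parameters` accepts exactly those conventional scales and
converts once at the boundary.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, fields, replace
from typing import Mapping

__all__ = [
    "ParameterSet",
    "DEFAULT_PARAMETERS",
    "load_parameters",
    "rate_constant_from_half_life",
    "asia_gain",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised for invalid or inconsistent parameter values."""


def rate_constant_from_half_life(t_half: float) -> float:
    """First-order rate constant (1/s) from an elimination half-life (s).

    ``beta = ln(2) / t_half``.
    """
    if not t_half > 0:
        raise ParameterError(f"half-life must be positive, got {t_half!r}")
    return math.log(2.0) / t_half


def asia_gain(alpha: float, beta: float) -> float:
    """Steady-state gain (s/L) of a first-order dilution/elimination element.

    An ASIA element converts a rate x (mol/s) into a concentration via
    dy/dt = alpha*x - beta*y, whose equilibrium is y = (alpha/beta)*x.
    """
    if not alpha > 0:
        raise ParameterError(f"dilution factor alpha must be positive, got {alpha!r}")
    if not beta > 0:
        raise ParameterError(f"rate constant beta must be positive, got {beta!r}")
    return alpha / beta


@dataclass(frozen=True)
class ParameterSet:
    """Constant structure parameters of the feedback loop, in SI units.

    Attributes
    ----------
    alpha_G, beta_G
        Glucose dilution factor (1/L, equal to 1/V_D) and clearance rate
        constant (1/s).
    G_beta, D_beta
        Beta-cell secretory capacity (mol/s) and glucose EC50 at the beta
        cell (mol/L).
    alpha_I, beta_I
        Insulin dilution factor (1/L) and clearance rate constant (1/s).
    G_R, D_R
        Insulin receptor gain (mol/s) and insulin EC50 at the receptor
        (mol/L).
    G_E
        Effector (post-receptor) gain (s/mol).
    P
        Constitutive endogenous glucose production rate (mol/s).
    W
        Intestinal glucose absorption rate (mol/s); 0 in the fasting state.

    The derived ASIA gains ``G1 = alpha_G/beta_G`` and ``G3 = alpha_I/beta_I``
    (s/L) are always recomputed from their defining fields.
    """

    alpha_G: float = 0.11
    beta_G: float = 7.1e-4
    G_beta: float = 2.8e-12
    D_beta: float = 7e-3
    alpha_I: float = 0.2
    beta_I: float = 3.4e-3
    G_R: float = 2.3
    D_R: float = 1.6e-9
    G_E: float = 50.0
    P: float = 150e-6
    W: float = 0.0

    # Gains may legitimately be zero (open-loop limits); everything else is a
    # denominator or kinetic constant and must be strictly positive.
    _STRICT = ("alpha_G", "beta_G", "D_beta", "alpha_I", "beta_I", "D_R", "G_E", "P")
    _NONNEG = ("G_beta", "G_R", "W")

    def __post_init__(self) -> None:
        bad = [n for n in self._STRICT if not getattr(self, n) > 0]
        bad += [n for n in self._NONNEG if not getattr(self, n) >= 0]
        if bad:
            raise ParameterError(
                "invalid parameter value(s) for: " + ", ".join(sorted(bad))
            )

    @property
    def G1(self) -> float:
        """ASIA gain for glucose, alpha_G/beta_G (s/L)."""
        return self.alpha_G / self.beta_G

    @property
    def G3(self) -> float:
        """ASIA gain for insulin, alpha_I/beta_I (s/L)."""
        return self.alpha_I / self.beta_I

    def replace(self, **changes: float) -> "ParameterSet":
        return replace(self, **changes)

    def to_config(self) -> dict[str, float]:
        """Export on the conventional scales accepted by :func:`load_parameters`."""
        return {
            key: getattr(self, _CONFIG_FIELDS[key]) / scale
            for key, scale in _CONFIG_SCALE.items()
        }


DEFAULT_PARAMETERS = ParameterSet()

# Config keys mirror the conventional symbols; values are interpreted on the
# scales the reference values are quoted on (pmol/s, mmol/L, nmol/L, umol/s).
_CONFIG_FIELDS = {
    "alphaG": "alpha_G",
    "betaG": "beta_G",
    "Gbeta": "G_beta",
    "Dbeta": "D_beta",
    "alphaI": "alpha_I",
    "betaI": "beta_I",
    "GR": "G_R",
    "DR": "D_R",
    "GE": "G_E",
    "P": "P",
    "W": "W",
}
_CONFIG_SCALE = {
    "alphaG": 1.0,      # 1/L
    "betaG": 1.0,       # 1/s
    "Gbeta": 1e-12,     # pmol/s
    "Dbeta": 1e-3,      # mmol/L
    "alphaI": 1.0,      # 1/L
    "betaI": 1.0,       # 1/s
    "GR": 1.0,          # mol/s
    "DR": 1e-9,         # nmol/L
    "GE": 1.0,          # s/mol
    "P": 1e-6,          # umol/s
    "W": 1e-6,          # umol/s
}


def load_parameters(
    config: Mapping[str, float] | str | os.PathLike | None = None,
) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a flat mapping or JSON file.

    Keys use the conventional symbol names (``alphaG``, ``betaG``, ``Gbeta``,
    ``Dbeta``, ``alphaI``, ``betaI``, ``GR``, ``DR``, ``GE``, ``P``, ``W``)
    with values on the conventional scales (``Gbeta`` in pmol/s, ``Dbeta`` in
    mmol/L, ``DR`` in nmol/L, ``P`` and ``W`` in umol/s, all others in plain
    SI).  Missing keys fall back to the reference defaults; unknown keys are
    rejected.
    """
    if config is None:
        return ParameterSet()
    if isinstance(config, (str, os.PathLike)):
        with open(config, "r", encoding="utf-8") as fh:
            config = json.load(fh)
    if not isinstance(config, Mapping):
        raise ParameterError(f"expected a mapping or file path, got {type(config)!r}")
    unknown = sorted(set(config) - set(_CONFIG_FIELDS))
    if unknown:
        raise ParameterError(
            f"unknown parameter key(s): {', '.join(unknown)}; "
            f"supported: {', '.join(_CONFIG_FIELDS)}"
        )
    kwargs = {}
    for key, value in config.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ParameterError(f"parameter {key!r} must be a number, got {value!r}")
        kwargs[_CONFIG_FIELDS[key]] = float(value) * _CONFIG_SCALE[key]
    return ParameterSet(**kwargs)


def parameter_provenance(
    config: Mapping[str, float] | None,
) -> dict[str, str]:
    """Record, per config key, whether a value was user-set or defaulted."""
    supplied = set(config or ())
    return {
        key: ("user" if key in supplied else "default") for key in _CONFIG_FIELDS
    }
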