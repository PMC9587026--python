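"""Unit conventions and conversions for glucose and insulin concentrations.

The package computes in mol/L throughout; clinical inputs and the
conventional surrogate indices (HOMA, QUICKI) use mmol/L or mg/dL for
glucose and pmol/L or uU/mL for insulin.  Only the handful of units this
model needs are supported, deliberately: a wrong unit should fail loudly,
not be guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["UnitConvention", "DEFAULT_UNITS", "convert_quantity", "UnitError"]


class UnitError(ValueError):
    """Raised for unknown units or invalid conversion factors."""


@dataclass(frozen=True)
class UnitConvention:
    """Configurable conversion factors between molar and conventional units.

    ``insulin_pmol_per_uU_mL``: pmol/L per uU/mL.  Laboratories disagree on
    this constant (6.0 and 6.945 are both in circulation); 6.0 is the default
    and the factor is configurable so users can match their assay.
    ``glucose_mg_dL_per_mmol_L``: mg/dL per mmol/L, i.e. the molecular weight
    of glucose (180.18 g/mol) divided by ten.
    """

    insulin_pmol_per_uU_mL: float = 6.0
    glucose_mg_dL_per_mmol_L: float = 18.018

    def __post_init__(self) -> None:
        if not self.insulin_pmol_per_uU_mL > 0 or not self.glucose_mg_dL_per_mmol_L > 0:
            raise UnitError("conversion factors must be strictly positive")

    def factors(self, kind: str) -> dict[str, float]:
        """Map unit name -> mol/L per one unit, for the given quantity kind."""
        if kind == "glucose":
            return {
                "mol/L": 1.0,
                "mmol/L": 1e-3,
                "mg/dL": 1e-3 / self.glucose_mg_dL_per_mmol_L,
            }
        if kind == "insulin":
            return {
                "mol/L": 1.0,
                "pmol/L": 1e-12,
                "uU/mL": self.insulin_pmol_per_uU_mL * 1e-12,
                "mU/L": self.insulin_pmol_per_uU_mL * 1e-12,
            }
        raise UnitError(f"unknown quantity kind {kind!r}; supported: glucose, insulin")


DEFAULT_UNITS = UnitConvention()


def convert_quantity(
    value,
    kind: str,
    from_unit: str,
    to_unit: str,
    convention: UnitConvention = DEFAULT_UNITS,
):
    """Linearly rescale a concentration between supported units.

    Works element-wise on array inputs.  Identity when the units coincide.
    """
    factors = convention.factors(kind)
    for unit in (from_unit, to_unit):
        if unit not in factors:
            raise UnitError(
                f"unknown {kind} unit {unit!r}; supported: {', '.join(factors)}"
            )
    if from_unit == to_unit:
        return value
    return value * (factors[from_unit] / factors[to_unit])
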