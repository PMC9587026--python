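"""Static function tests from a single fasting glucose/insulin pair.

The structure-parameter inference approach (SPINA) inverts the fasting
steady state of the feedback model algebraically:

    SPINA-GBeta = I*(D_beta + G) / (G3*G)                  (pmol/s)
    SPINA-GR    = G1*P*(D_R + I)/(G_E*I*G)
                  - D_R/(G_E*I) - 1/G_E                    (mol/s)

so that, evaluated at the model's own equilibrium, they return exactly the
generating secretory capacity G_beta and receptor gain G_R.  The classical
comparators HOMA-Beta, HOMA-IR and QUICKI are provided in their original
conventional units.  HOMA-Beta has a structural blind zone: for fasting
glucose <= 3.5 mmol/L its denominator is non-positive and no sensible value
exists, whereas the SPINA estimators remain defined for all positive
concentrations.

Scalar functions raise on invalid input; :func:`compute_panel` vectorises
over a cohort and encodes invalid results as NaN plus a flag column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parameters import ParameterSet, DEFAULT_PARAMETERS
from .units import UnitConvention, DEFAULT_UNITS, convert_quantity

__all__ = [
    "spina_gbeta",
    "spina_gr",
    "homa_ir",
    "homa_beta",
    "quicki",
    "compute_panel",
    "HOMA_BETA_BLIND_ZONE_MMOL_L",
]

HOMA_BETA_BLIND_ZONE_MMOL_L = 3.5

FLAG_OK = "ok"
FLAG_BLIND = "blind_zone"
FLAG_MISSING = "missing_input"
FLAG_UNDEFINED = "undefined"
FLAG_NEGATIVE = "negative"


def spina_gbeta(G: float, I: float, params: ParameterSet = DEFAULT_PARAMETERS) -> float:
    """Estimated beta-cell secretory capacity (pmol/s) from fasting G, I (mol/L)."""
    if not G > 0:
        raise ValueError(f"glucose must be positive, got {G!r}")
    if I < 0:
        raise ValueError(f"insulin must be non-negative, got {I!r}")
    return I * (params.D_beta + G) / (params.G3 * G) * 1e12


def spina_gr(G: float, I: float, params: ParameterSet = DEFAULT_PARAMETERS) -> float:
    """Estimated insulin receptor gain (mol/s) from fasting G, I (mol/L).

    May be negative for samples inconsistent with the model (e.g. glucose
    above the open-loop value G1*P); such values are reported, not clipped.
    """
    if not G > 0 or not I > 0:
        raise ValueError(f"glucose and insulin must be positive, got G={G!r}, I={I!r}")
    g1p = params.G1 * params.P
    return (
        g1p * (params.D_R + I) / (params.G_E * I * G)
        - params.D_R / (params.G_E * I)
        - 1.0 / params.G_E
    )


def homa_ir(G_mmol_L: float, I_uU_mL: float) -> float:
    """HOMA insulin-resistance index: G[mmol/L] * I[uU/mL] / 22.5."""
    if not G_mmol_L > 0 or not I_uU_mL > 0:
        raise ValueError("HOMA-IR requires positive glucose and insulin")
    return G_mmol_L * I_uU_mL / 22.5


def homa_beta(G_mmol_L: float, I_uU_mL: float) -> float:
    """HOMA beta-cell function index: 20 * I[uU/mL] / (G[mmol/L] - 3.5).

    Undefined (raises) for glucose <= 3.5 mmol/L — the HOMA blind zone.
    """
    if not I_uU_mL > 0:
        raise ValueError("HOMA-Beta requires positive insulin")
    if G_mmol_L <= HOMA_BETA_BLIND_ZONE_MMOL_L:
        raise ValueError(
            f"HOMA-Beta is undefined for glucose <= {HOMA_BETA_BLIND_ZONE_MMOL_L} "
            f"mmol/L (blind zone); got {G_mmol_L!r}"
        )
    return 20.0 * I_uU_mL / (G_mmol_L - HOMA_BETA_BLIND_ZONE_MMOL_L)


def quicki(G_mg_dL: float, I_uU_mL: float) -> float:
    """Quantitative insulin sensitivity check index: 1/(log10 I + log10 G)."""
    if not G_mg_dL > 0 or not I_uU_mL > 0:
        raise ValueError("QUICKI requires positive glucose and insulin")
    denom = np.log10(I_uU_mL) + np.log10(G_mg_dL)
    if denom == 0:
        raise ValueError("QUICKI undefined: log terms cancel")
    return 1.0 / denom


def compute_panel(
    cohort,
    params: ParameterSet = DEFAULT_PARAMETERS,
    units: UnitConvention = DEFAULT_UNITS,
) -> pd.DataFrame:
    """Per-record panel of all five indices with validity flags.

    ``cohort`` is a :class:`spinacarb.io.CohortTable` (or anything with a
    ``frame`` DataFrame and declared ``glucose_unit``/``insulin_unit``).
    Missing inputs propagate as NaN with a ``missing_input`` flag; the HOMA
    blind zone and other undefined results are NaN with explanatory flags.
    Returned columns: subject_id, visit, glucose_mmol_L, insulin_pmol_L,
    spina_gbeta_pmol_s, spina_gr_mol_s, homa_beta, homa_ir, quicki and one
    ``flag_*`` column per index.
    """
    frame = cohort.frame
    G_si = convert_quantity(
        frame["glucose"].to_numpy(dtype=float), "glucose", cohort.glucose_unit,
        "mol/L", units,
    )
    I_si = convert_quantity(
        frame["insulin"].to_numpy(dtype=float), "insulin", cohort.insulin_unit,
        "mol/L", units,
    )
    G_mmol = G_si * 1e3
    I_pmol = I_si * 1e12
    G_mgdl = convert_quantity(G_si, "glucose", "mol/L", "mg/dL", units)
    I_uU = convert_quantity(I_si, "insulin", "mol/L", "uU/mL", units)

    missing = np.isnan(G_si) | np.isnan(I_si)

    with np.errstate(divide="ignore", invalid="ignore"):
        gbeta = np.where(G_si > 0, I_si * (params.D_beta + G_si) / (params.G3 * G_si), np.nan) * 1e12
        g1p = params.G1 * params.P
        gr = np.where(
            (G_si > 0) & (I_si > 0),
            g1p * (params.D_R + I_si) / (params.G_E * I_si * G_si)
            - params.D_R / (params.G_E * I_si)
            - 1.0 / params.G_E,
            np.nan,
        )
        hira = np.where((G_mmol > 0) & (I_uU > 0), G_mmol * I_uU / 22.5, np.nan)
        hbeta = np.where(
            (G_mmol > HOMA_BETA_BLIND_ZONE_MMOL_L) & (I_uU > 0),
            20.0 * I_uU / (G_mmol - HOMA_BETA_BLIND_ZONE_MMOL_L),
            np.nan,
        )
        qdenom = np.log10(np.where(I_uU > 0, I_uU, np.nan)) + np.log10(
            np.where(G_mgdl > 0, G_mgdl, np.nan)
        )
        qk = np.where(qdenom != 0, 1.0 / qdenom, np.nan)

    def flag(defined, blind=None, negative=None):
        out = np.where(defined, FLAG_OK, FLAG_UNDEFINED)
        if blind is not None:
            out = np.where(blind, FLAG_BLIND, out)
        if negative is not None:
            out = np.where(defined & negative, FLAG_NEGATIVE, out)
        return np.where(missing, FLAG_MISSING, out)

    G_pos = np.nan_to_num(G_si) > 0
    I_pos = np.nan_to_num(I_si) > 0
    panel = pd.DataFrame(
        {
            "subject_id": frame["subject_id"].to_numpy(),
            "visit": frame["visit"].to_numpy(),
            "glucose_mmol_L": G_mmol,
            "insulin_pmol_L": I_pmol,
            "spina_gbeta_pmol_s": np.where(missing, np.nan, gbeta),
            "spina_gr_mol_s": np.where(missing, np.nan, gr),
            "homa_beta": np.where(missing, np.nan, hbeta),
            "homa_ir": np.where(missing, np.nan, hira),
            "quicki": np.where(missing, np.nan, qk),
            "flag_spina_gbeta": flag(G_pos),
            "flag_spina_gr": flag(G_pos & I_pos, negative=np.nan_to_num(gr) < 0),
            "flag_homa_beta": flag(
                G_pos & I_pos & (np.nan_to_num(G_mmol) > HOMA_BETA_BLIND_ZONE_MMOL_L),
                blind=I_pos
                & G_pos
                & (np.nan_to_num(G_mmol) <= HOMA_BETA_BLIND_ZONE_MMOL_L),
            ),
            "flag_homa_ir": flag(G_pos & I_pos),
            "flag_quicki": flag(G_pos & I_pos & ~np.isnan(np.where(missing, 0.0, qk))),
        }
    )
    if "group" in frame.columns:
        panel.insert(2, "group", frame["group"].to_numpy())
    return panel
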