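"""Cohort tables: subject x visit fasting glucose/insulin records.

A cohort CSV has one row per subject-visit with columns ``subject_id``,
``visit``, ``glucose``, ``insulin`` and optionally ``group`` plus arbitrary
covariates (passed through untouched).  Units are declared once per file at
read time — never guessed — and attached to the in-memory table.  Missing
concentrations are explicit (empty cells), never encoded as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("spinacarb")

__all__ = ["CohortTable", "read_cohort_csv", "write_cohort_csv", "CohortFormatError"]

REQUIRED_COLUMNS = ("subject_id", "visit", "glucose", "insulin")


class CohortFormatError(ValueError):
    """Raised for malformed cohort files."""


@dataclass
class CohortTable:
    """In-memory cohort with declared measurement units.

    ``frame`` holds the records; ``glucose_unit``/``insulin_unit`` name the
    units of the ``glucose``/``insulin`` columns (see
    :mod:`spinacarb.units` for the supported sets).
    """

    frame: pd.DataFrame
    glucose_unit: str
    insulin_unit: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise CohortFormatError(f"missing required column(s): {', '.join(missing)}")
        dup = self.frame.duplicated(subset=["subject_id", "visit"])
        if dup.any():
            raise CohortFormatError(
                f"duplicate (subject_id, visit) pairs at rows {list(self.frame.index[dup])}"
            )
        for col in ("glucose", "insulin"):
            vals = self.frame[col]
            if (vals.dropna() < 0).any():
                raise CohortFormatError(f"negative values in column {col!r}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_missing(self) -> int:
        return int(self.frame[["glucose", "insulin"]].isna().any(axis=1).sum())


def read_cohort_csv(path, glucose_unit: str, insulin_unit: str) -> CohortTable:
    """Parse a cohort CSV, attaching the declared units.

    Blank glucose/insulin cells become missing values; unparseable numbers
    raise with the offending row index.
    """
    raw = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    for col in ("glucose", "insulin"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        if bad.any():
            raise CohortFormatError(
                f"{path}: unparseable number in column {col!r} at row(s) "
                f"{list(raw.index[bad])}"
            )
        raw[col] = coerced
    raw["visit"] = pd.to_numeric(raw["visit"], errors="raise", downcast="integer")
    table = CohortTable(frame=raw, glucose_unit=glucose_unit, insulin_unit=insulin_unit)
    logger.info(
        "read %d cohort rows from %s (%d with missing concentrations)",
        len(table), path, table.n_missing,
    )
    return table


def write_cohort_csv(table: CohortTable, path) -> None:
    """Write a cohort back to CSV at full precision (17 significant digits)."""
    table.frame.to_csv(path, index=False, float_format="%.17g")
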