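"""Subject metadata: table I/O, levodopa-equivalent dose, motion screening.

The subject table is tab-separated with one row per subject.  Required
columns: ``id``, ``group`` (Ctr or PD) and ``max_displacement_mm``.  The
conventional clinical columns (``age``, ``sex``, ``handedness``,
``disease_duration``, ``hoehn_yahr``, ``mmse``, the seven ``moca_*`` domain
scores, the ``dose_*`` drug columns and ``led``) are validated when present.
Controls do not carry MoCA domain scores (the instrument is administered to
patients only); those cells are left empty.
"""

from __future__ import annotations

from types import MappingProxyType
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "LED_SCHEDULE",
    "MOCA_DOMAINS",
    "compute_led",
    "screen_motion",
    "read_subject_table",
    "write_subject_table",
    "validate_subject_table",
]

#: Levodopa-equivalent conversion factors (mg/day multipliers).  Immutable;
#: pass a custom mapping to :func:`compute_led` for other conventions.
LED_SCHEDULE: Mapping[str, float] = MappingProxyType({
    "levodopa/carbidopa": 1.0,
    "entacapone": 0.35,
    "pramipexole": 100.0,
    "ropinirole": 20.0,
    "rotigotine": 10.0,
    "selegiline": 10.0,
    "amantadine": 1.0,
})

#: MoCA cognitive domains with their integer score ranges on the standard form.
MOCA_DOMAINS: Mapping[str, tuple[int, int]] = MappingProxyType({
    "visuospatial_executive": (0, 5),
    "naming": (0, 3),
    "attention": (0, 6),
    "language": (0, 3),
    "abstraction": (0, 2),
    "delayed_recall": (0, 5),
    "orientation": (0, 6),
})

GROUPS = ("Ctr", "PD")


def compute_led(doses: Mapping[str, float],
                schedule: Mapping[str, float] = LED_SCHEDULE) -> float:
    """Levodopa-equivalent dose: sum of dose x conversion factor over drugs.

    Drug names are matched case-insensitively; combination entries such as
    ``levodopa/carbidopa`` are a single key.  A drug absent from the schedule
    raises :class:`ValidationError` naming the offending key.
    """
    norm = {str(k).strip().lower(): float(v) for k, v in schedule.items()}
    if any(v <= 0 for v in norm.values()):
        raise ValidationError("LED schedule coefficients must be strictly positive")
    total = 0.0
    for drug, dose in doses.items():
        key = str(drug).strip().lower()
        if key not in norm:
            raise ValidationError(f"unknown drug in LED computation: {drug!r}")
        if dose < 0:
            raise ValidationError(f"negative dose for {drug!r}")
        total += float(dose) * norm[key]
    return total


def screen_motion(table: pd.DataFrame, threshold_mm: float = 3.0,
                  column: str = "max_displacement_mm") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition subjects by the head-motion rule.

    A subject is excluded iff its maximum displacement is ``threshold_mm`` or
    more (the threshold itself excludes).  Returns ``(retained, excluded)``;
    the two frames partition the input.
    """
    if column not in table.columns:
        raise ValidationError(f"missing displacement column {column!r}")
    disp = pd.to_numeric(table[column], errors="coerce")
    if disp.isna().any():
        bad = table.loc[disp.isna(), "id"].tolist() if "id" in table else list(disp[disp.isna()].index)
        raise ValidationError(f"missing/invalid displacement for subjects: {bad}")
    excluded_mask = disp.to_numpy(dtype=float) >= threshold_mm
    return table.loc[~excluded_mask].copy(), table.loc[excluded_mask].copy()


def validate_subject_table(table: pd.DataFrame, screened_controls: bool = False) -> pd.DataFrame:
    """Check the documented column contract; returns the table unchanged."""
    for col in ("id", "group", "max_displacement_mm"):
        if col not in table.columns:
            raise ValidationError(f"subject table missing required column {col!r}")
    bad_groups = set(table["group"]) - set(GROUPS)
    if bad_groups:
        raise ValidationError(f"unknown group labels: {sorted(bad_groups)}")
    if table["id"].duplicated().any():
        raise ValidationError("duplicate subject ids")
    disp = pd.to_numeric(table["max_displacement_mm"], errors="raise")
    if (disp < 0).any():
        raise ValidationError("negative displacement values")
    for col in table.columns:
        if col.startswith("dose_"):
            doses = pd.to_numeric(table[col], errors="coerce").fillna(0.0)
            if (doses < 0).any():
                raise ValidationError(f"negative doses in column {col!r}")
    if screened_controls and "mmse" in table.columns:
        ctr = table[table["group"] == "Ctr"]
        mmse = pd.to_numeric(ctr["mmse"], errors="coerce")
        if (mmse < 24).any():
            raise ValidationError("screened controls must have MMSE >= 24")
    return table


def read_subject_table(path, screened_controls: bool = False) -> pd.DataFrame:
    """Read and validate a tab-separated subject table."""
    table = pd.read_csv(path, sep="\t")
    return validate_subject_table(table, screened_controls=screened_controls)


def write_subject_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def led_from_table(table: pd.DataFrame,
                   schedule: Mapping[str, float] = LED_SCHEDULE) -> pd.Series:
    """Compute LED per subject from the ``dose_<drug>`` columns.

    Column names encode drug keys with ``/`` and spaces replaced by ``_``
    (``dose_levodopa_carbidopa``).
    """
    key_by_col = {}
    for drug in schedule:
        col = "dose_" + drug.replace("/", "_").replace(" ", "_").lower()
        key_by_col[col] = drug
    unknown = [c for c in table.columns if c.startswith("dose_") and c not in key_by_col]
    if unknown:
        raise ValidationError(f"unknown drug dose columns: {unknown}")
    led = np.zeros(len(table))
    for col, drug in key_by_col.items():
        if col in table.columns:
            led += pd.to_numeric(table[col], errors="coerce").fillna(0.0).to_numpy() * schedule[drug]
    return pd.Series(led, index=table.index, name="led")
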