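"""Measurement-table I/O and schema validation.

The canonical measurement CSV is long format, one row per flux observation:

    individual_id, species, tissue, tissue_class, quantity,
    T_a_C, T_tissue_C, flux, flux_basis, area_m2, dry_mass_g

``tissue`` is one of {leaf, stem, root}; ``tissue_class`` one of
{photosynthetic, non_photosynthetic}; ``quantity`` one of {rd, vcmax};
temperatures in deg C.  The canonical flux basis is per gram dry mass
(umol g-1 s-1); rows with ``flux_basis = "area"`` (umol m-2 s-1) are
converted at ingest using ``area_m2`` and ``dry_mass_g``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curves import convert_area_to_mass_flux
from .errors import SchemaError

#: schema version for emitted files
SCHEMA_VERSION = "1"

MEASUREMENT_COLUMNS = [
    "individual_id", "species", "tissue", "tissue_class", "quantity",
    "T_a_C", "T_tissue_C", "flux", "flux_basis", "area_m2", "dry_mass_g",
]
_REQUIRED = MEASUREMENT_COLUMNS[:9]

VALID_TISSUES = {"leaf", "stem", "root"}
VALID_CLASSES = {"photosynthetic", "non_photosynthetic"}
VALID_QUANTITIES = {"rd", "vcmax"}
VALID_BASES = {"mass", "area"}


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a measurement CSV; returns mass-basis records.

    All row- and column-level problems found are aggregated into a single
    :class:`~rdacclim.errors.SchemaError` rather than failing one at a time.
    """
    raw = pd.read_csv(path)
    problems: list[str] = []

    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise SchemaError([f"missing required column(s): {', '.join(missing)}"])
    for c in ("area_m2", "dry_mass_g"):
        if c not in raw.columns:
            raw[c] = np.nan

    df = raw.copy()
    for col, valid in (("tissue", VALID_TISSUES), ("tissue_class", VALID_CLASSES),
                       ("quantity", VALID_QUANTITIES), ("flux_basis", VALID_BASES)):
        bad = sorted(set(df[col].astype(str)) - valid)
        if bad:
            problems.append(f"unknown {col} label(s): {', '.join(bad)}")

    for col in ("T_a_C", "T_tissue_C", "flux"):
        vals = pd.to_numeric(df[col], errors="coerce")
        n_bad = int((~np.isfinite(vals)).sum())
        if n_bad:
            problems.append(f"{n_bad} non-finite value(s) in column {col}")
        df[col] = vals

    key = ["individual_id", "tissue", "quantity", "T_tissue_C"]
    dup = df.duplicated(subset=key)
    if dup.any():
        dup_keys = df.loc[dup, key].astype(str).agg("/".join, axis=1).tolist()
        problems.append(f"duplicate measurement key(s): {', '.join(dup_keys[:5])}"
                        + (" ..." if len(dup_keys) > 5 else ""))

    area_rows = df["flux_basis"] == "area"
    if area_rows.any():
        bad_meta = area_rows & ~(
            (pd.to_numeric(df["area_m2"], errors="coerce") > 0)
            & (pd.to_numeric(df["dry_mass_g"], errors="coerce") > 0))
        if bad_meta.any():
            problems.append(
                f"{int(bad_meta.sum())} area-basis row(s) lack positive "
                "area_m2/dry_mass_g")
    if problems:
        raise SchemaError(problems)

    if area_rows.any():
        conv = [convert_area_to_mass_flux(f, a, m) for f, a, m in zip(
            df.loc[area_rows, "flux"], df.loc[area_rows, "area_m2"],
            df.loc[area_rows, "dry_mass_g"])]
        df.loc[area_rows, "flux"] = conv
        df.loc[area_rows, "flux_basis"] = "mass"

    return df[MEASUREMENT_COLUMNS]


def write_measurements(records: pd.DataFrame, path) -> None:
    """Write a measurement table with the canonical column order."""
    out = records.copy()
    for c in MEASUREMENT_COLUMNS:
        if c not in out.columns:
            out[c] = np.nan
    out[MEASUREMENT_COLUMNS].to_csv(path, index=False)
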