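"""Shared column schema for milk composition records.

The seven compositional features reported by FTIR-based milk analysers:
five mass fractions in % w/w, density in g/L, and the freezing-point
depression (FPD) in °C stored as a positive magnitude (genuine milk
freezes ~0.52-0.58 °C below water; dilution moves the value toward 0).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: Compositional feature columns, in canonical order.
FEATURES: tuple[str, ...] = ("protein", "fat", "ts", "snf", "lactose", "density", "fpd")

#: Recognised production-area codes (Chinese macro-regions) plus UNKNOWN.
AREAS: tuple[str, ...] = ("N", "NE", "NW", "E", "S", "UNKNOWN")

#: Sample provenance labels.
ORIGINS: tuple[str, ...] = ("control", "market", "adulterated", "synthetic")

#: Decimal places at which each feature is conventionally printed.
PRINT_DECIMALS: dict[str, int] = {
    "protein": 2, "fat": 2, "ts": 2, "snf": 2, "lactose": 2,
    "density": 0, "fpd": 3,
}

# fat + snf should reconstruct ts; instrument round-off leaves small gaps
MASS_BALANCE_SLACK = 0.3  # % w/w


class SchemaError(ValueError):
    """A record table violates the composition schema."""


def validate_records(table: pd.DataFrame, *, check_area: bool = False) -> pd.DataFrame:
    """Validate a table of composition records against the schema.

    Hard checks raise :class:`SchemaError`; the fat + SNF ≈ TS mass-balance
    check only warns, because printed round-off routinely breaks it.

    Returns the table unchanged (for call chaining).
    """
    missing = [c for c in FEATURES if c not in table.columns]
    if missing:
        raise SchemaError(f"missing feature columns: {missing}")
    X = table.loc[:, list(FEATURES)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise SchemaError("non-finite values in feature columns")
    pct = table.loc[:, ["protein", "fat", "ts", "snf", "lactose"]].to_numpy(dtype=float)
    if (pct < 0).any() or (pct > 100).any():
        raise SchemaError("mass fractions must lie in [0, 100] % w/w")
    dens = table["density"].to_numpy(dtype=float)
    if (dens <= 1000).any() or (dens >= 1060).any():
        raise SchemaError("density must lie in (1000, 1060) g/L")
    fpd = table["fpd"].to_numpy(dtype=float)
    if (fpd <= 0).any() or (fpd >= 1).any():
        raise SchemaError("fpd must lie in (0, 1) °C (positive depression magnitude)")
    if (table["snf"].to_numpy(dtype=float) >= table["ts"].to_numpy(dtype=float)).any():
        raise SchemaError("solids-non-fat must be strictly below total solids")
    gap = np.abs(
        table["fat"].to_numpy(dtype=float)
        + table["snf"].to_numpy(dtype=float)
        - table["ts"].to_numpy(dtype=float)
    )
    if (gap > MASS_BALANCE_SLACK).any():
        warnings.warn(
            f"fat + snf deviates from ts by more than {MASS_BALANCE_SLACK} % w/w "
            f"for {(gap > MASS_BALANCE_SLACK).sum()} record(s)",
            stacklevel=2,
        )
    if check_area and "area" in table.columns:
        bad = set(table["area"].astype(str)) - set(AREAS)
        if bad:
            raise SchemaError(f"unknown area codes: {sorted(bad)}")
    return table


def round_to_print(table: pd.DataFrame) -> pd.DataFrame:
    """Round feature columns to their conventional printed precision."""
    out = table.copy()
    for col, nd in PRINT_DECIMALS.items():
        if col in out.columns:
            out[col] = out[col].astype(float).round(nd)
    return out
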