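"""Bundled reference tables and the seeded synthetic control generator.

The package ships, as plain CSV:

* the three control milk pools (A premium/North, B normal/North,
  C normal/South) and the per-variable mean/SD of the 15-sample control set;
* the two univariate boundary sets (measured and variance-adjusted,
  0.5th/99.5th percentiles);
* the 43 flagged market-survey records with their detection annotations,
  plus per-area survey totals (the 9 never-flagged samples are represented
  only through those totals — they were never published individually);
* the 13 fraud-vulnerability factor mean ranks for the four main
  production areas;
* the 24-adulterant registry used by the adulteration simulator.

The raw 15 control records themselves were never published, so
:func:`generate_controls` provides a seeded stand-in generator whose
pooled dispersion matches the published per-variable SDs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .schema import FEATURES, PRINT_DECIMALS, validate_records

_SURVEY_N_TOTAL = 52


class FixtureError(RuntimeError):
    """A bundled data file is missing or fails its integrity check."""


@dataclass(frozen=True)
class ColumnStats:
    """Mean/SD of one compositional variable over the control set."""

    variable: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass(frozen=True)
class PoolProfile:
    """Per-variable means of one control milk pool."""

    pool_id: str
    quality: str
    region: str
    means: dict[str, float]


def _read_csv(name: str, **kw) -> pd.DataFrame:
    try:
        text = resources.files("milkscreen.data").joinpath(name).read_text()
    except (FileNotFoundError, ModuleNotFoundError) as exc:  # pragma: no cover
        raise FixtureError(f"bundled data file {name!r} not found") from exc
    return pd.read_csv(io.StringIO(text), **kw)


def load_control_pools() -> list[PoolProfile]:
    """The three control milk pools with their per-variable means."""
    df = _read_csv("control_pools.csv")
    pools = [
        PoolProfile(
            pool_id=row["pool_id"],
            quality=row["quality"],
            region=row["region"],
            means={v: float(row[v]) for v in FEATURES},
        )
        for _, row in df.iterrows()
    ]
    if len(pools) != 3:
        raise FixtureError(f"expected 3 control pools, found {len(pools)}")
    return pools


def load_control_stats() -> list[ColumnStats]:
    """Per-variable mean and SD of the 15-sample control set."""
    df = _read_csv("control_stats.csv")
    stats = [
        ColumnStats(row["variable"], float(row["mean"]), float(row["sd"]), int(row["n"]))
        for _, row in df.iterrows()
    ]
    if [s.variable for s in stats] != list(FEATURES):
        raise FixtureError("control stats do not cover the seven features in order")
    return stats


def load_control_boundaries():
    """The measured and variance-adjusted univariate boundary sets.

    Returns
    -------
    (BoundarySet, BoundarySet)
        Measured first, variance-adjusted second.
    """
    from .boundaries import BoundarySet  # local import avoids a cycle

    df = _read_csv("control_boundaries.csv").set_index(["provenance", "bound"])
    out = []
    for prov in ("measured", "variance_adjusted"):
        lower = df.loc[(prov, "lower"), list(FEATURES)].astype(float)
        upper = df.loc[(prov, "upper"), list(FEATURES)].astype(float)
        out.append(BoundarySet(lower=lower, upper=upper, provenance=prov))
    return tuple(out)


def load_market_survey(with_annotations: bool = False):
    """The flagged market-survey records (43 of 52 purchased samples).

    Parameters
    ----------
    with_annotations : bool
        Also return the per-record detection annotations (two univariate
        violation counts and two KNN flags).  The annotations are evaluation
        metadata: detection code never reads them.

    Returns
    -------
    DataFrame, or (DataFrame, DataFrame) when ``with_annotations`` is set.
    """
    records = _read_csv("market_survey.csv", dtype={"sample_id": str})
    if len(records) != 43:
        raise FixtureError(f"market survey must hold 43 records, found {len(records)}")
    records["origin"] = "market"
    validate_records(records, check_area=True)
    if not with_annotations:
        return records
    ann = _read_csv("market_survey_criteria.csv", dtype={"sample_id": str})
    if len(ann) != 43 or not (ann["sample_id"].values == records["sample_id"].values).all():
        raise FixtureError("annotation table out of sync with survey records")
    for col in ("knn_measured", "knn_variance_adjusted"):
        ann[col] = ann[col].map({"yes": True, "no": False}).astype(bool)
    return records, ann


def load_survey_area_totals() -> pd.Series:
    """Number of surveyed samples per production area (sums to 52)."""
    s = _read_csv("survey_area_totals.csv").set_index("area")["n_total"]
    if int(s.sum()) != _SURVEY_N_TOTAL:
        raise FixtureError(f"area totals must sum to {_SURVEY_N_TOTAL}")
    return s


def load_fraud_factors() -> pd.DataFrame:
    """Mean ranks of the 13 fraud-vulnerability factors by area.

    Rows are indexed by ``factor_id`` (1..13); rank columns are the four
    main production areas E, N, NW, NE.  Higher opportunity/motivation
    ranks mean more vulnerable; higher control ranks mean better controlled.
    """
    df = _read_csv("fraud_factors.csv").set_index("factor_id")
    if len(df) != 13:
        raise FixtureError("expected 13 fraud factors")
    return df


def load_adulterant_registry() -> pd.DataFrame:
    """The 24-substance adulterant registry (see :mod:`milkscreen.adulteration`)."""
    df = _read_csv("adulterants.csv").set_index("code")
    if len(df) != 24:
        raise FixtureError(f"adulterant registry must hold 24 entries, found {len(df)}")
    return df


def generate_controls(
    pools: list[PoolProfile],
    stats: list[ColumnStats],
    n: int = 15,
    seed: int | None = None,
    round_values: bool = True,
) -> pd.DataFrame:
    """Draw a synthetic control set around the pool means.

    Each record is assigned to a pool cyclically and each variable drawn
    independently from Normal(pool mean, s), with the within-pool SD ``s``
    seeded at ``s² = max(SD² − between-pool variance, 0)`` and the drawn
    residuals then rescaled so the realised pooled sample SD matches the
    published per-variable control SD (the generator exists to emulate
    those summary statistics, so it conditions on them rather than letting
    an n=15 draw scatter around them).  Total solids is then derived as
    fat + SNF plus the pool-specific instrument gap, keeping each record
    internally mass-balanced; all other variables are drawn independently
    (no covariance was published).

    With all SDs set to zero every record equals its pool means exactly.
    """
    if n < 2:
        raise ValueError("n must be at least 2 (SD undefined below that)")
    rng = np.random.default_rng(seed)
    means = np.array([[p.means[v] for v in FEATURES] for p in pools])  # pools x 7
    target_sd = np.array([s.sd for s in stats])
    between = means.var(axis=0)  # equal-weight population variance of pool means
    within = np.sqrt(np.maximum(target_sd**2 - between, 0.0))
    pool_idx = np.arange(n) % len(pools)
    draws = rng.normal(means[pool_idx], within[None, :])
    # condition the residual scale on the published pooled SD, per variable
    i_fat, i_ts, i_snf = FEATURES.index("fat"), FEATURES.index("ts"), FEATURES.index("snf")
    for j in range(means.shape[1]):
        if j == i_ts:
            continue  # derived below
        m = means[pool_idx, j]
        r = draws[:, j] - m
        vr = r.var(ddof=1)
        if vr <= 0:
            continue
        vm = m.var(ddof=1)
        cmr = np.cov(m, r, ddof=1)[0, 1]
        disc = cmr**2 - vr * (vm - target_sd[j] ** 2)
        c = max((-cmr + np.sqrt(disc)) / vr, 0.0) if disc >= 0 else 0.0
        draws[:, j] = m + c * r
    ts_gap = means[pool_idx, i_ts] - means[pool_idx, i_fat] - means[pool_idx, i_snf]
    draws[:, i_ts] = draws[:, i_fat] + draws[:, i_snf] + ts_gap
    df = pd.DataFrame(draws, columns=list(FEATURES))
    if round_values:
        for col, nd in PRINT_DECIMALS.items():
            df[col] = df[col].round(nd)
    df.insert(0, "sample_id", [f"ctrl-{i + 1}" for i in range(n)])
    df["pool_id"] = [pools[i].pool_id for i in pool_idx]
    df["area"] = "UNKNOWN"
    df["origin"] = "synthetic"
    return df


def write_records(table: pd.DataFrame, path) -> None:
    """Write a record table as CSV at the conventional printed precision."""
    out = table.copy()
    for col, nd in PRINT_DECIMALS.items():
        if col in out.columns:
            out[col] = out[col].astype(float).map(lambda v, nd=nd: f"{v:.{nd}f}")
    out.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    """Read a record table written by :func:`write_records`."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    return validate_records(df)
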