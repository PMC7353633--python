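"""Univariate percentile-boundary anomaly detection.

A sample is flagged when any compositional variable falls strictly below
the lower or strictly above the upper per-variable boundary.  Boundaries
default to the empirical 0.5th/99.5th percentiles of a genuine control
set (linear interpolation between order statistics), or can be supplied
directly, e.g. from a published table.

Comparisons are strict (<, >): a value printed exactly at a boundary is
*within*.  Published tables rounded to 2-3 decimals occasionally resolve
such ties the other way; per-variable counts recomputed from printed
values can therefore differ by one from prose counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin

from .schema import FEATURES


@dataclass
class BoundarySet:
    """Per-variable lower/upper limits with provenance."""

    lower: pd.Series
    upper: pd.Series
    provenance: str = "custom"
    percentiles: tuple[float, float] = (0.5, 99.5)

    def __post_init__(self) -> None:
        self.lower = pd.Series(self.lower, dtype=float)
        self.upper = pd.Series(self.upper, dtype=float)
        if not (self.lower.index == self.upper.index).all():
            raise ValueError("lower/upper must cover the same variables")
        if not (self.lower < self.upper).all():
            raise ValueError("every lower limit must be below its upper limit")

    @property
    def variables(self) -> list[str]:
        return list(self.lower.index)

    def encloses(self, other: "BoundarySet") -> bool:
        """True if every interval of ``self`` contains the matching one of ``other``."""
        return bool(
            (self.lower <= other.lower.values).all()
            and (self.upper >= other.upper.values).all()
        )

    def to_json(self, path=None) -> str:
        payload = {
            "provenance": self.provenance,
            "percentiles": list(self.percentiles),
            "lower": self.lower.to_dict(),
            "upper": self.upper.to_dict(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "BoundarySet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            lower=pd.Series(payload["lower"]),
            upper=pd.Series(payload["upper"]),
            provenance=payload["provenance"],
            percentiles=tuple(payload["percentiles"]),
        )


def compute_boundaries(
    table: pd.DataFrame,
    lower_pct: float = 0.5,
    upper_pct: float = 99.5,
    provenance: str = "measured",
    variables=FEATURES,
) -> BoundarySet:
    """Empirical per-variable percentile boundaries of a control table."""
    if not (0 < lower_pct < 100 and 0 < upper_pct < 100):
        raise ValueError("percentiles must lie strictly inside (0, 100)")
    if lower_pct >= upper_pct:
        raise ValueError("lower percentile must be below the upper percentile")
    if len(table) < 2:
        raise ValueError("need at least 2 rows to set boundaries")
    cols = [v for v in variables if v in table.columns]
    X = table.loc[:, cols].to_numpy(dtype=float)
    lo = np.percentile(X, lower_pct, axis=0, method="linear")
    hi = np.percentile(X, upper_pct, axis=0, method="linear")
    # a constant column yields a zero-width interval; keep it valid but tight
    same = lo >= hi
    if same.any():
        eps = np.maximum(np.abs(hi) * 1e-12, 1e-12)
        lo = np.where(same, hi - eps, lo)
    return BoundarySet(
        lower=pd.Series(lo, index=cols),
        upper=pd.Series(hi, index=cols),
        provenance=provenance,
        percentiles=(lower_pct, upper_pct),
    )


class PercentileBoundaryDetector(OutlierMixin, BaseEstimator):
    """Flag records falling outside per-variable percentile boundaries.

    Parameters
    ----------
    lower_pct, upper_pct : float
        Percentiles used when fitting boundaries from a control table.
    boundaries : BoundarySet, optional
        Preset boundaries; when given, ``fit`` keeps them instead of
        estimating from data.
    """

    def __init__(self, lower_pct: float = 0.5, upper_pct: float = 99.5, boundaries: BoundarySet | None = None):
        self.lower_pct = lower_pct
        self.upper_pct = upper_pct
        self.boundaries = boundaries

    @classmethod
    def from_boundary_set(cls, boundaries: BoundarySet) -> "PercentileBoundaryDetector":
        det = cls(boundaries=boundaries)
        det.boundaries_ = boundaries
        return det

    def fit(self, X, y=None):
        if self.boundaries is not None:
            self.boundaries_ = self.boundaries
        else:
            self.boundaries_ = compute_boundaries(
                pd.DataFrame(X), self.lower_pct, self.upper_pct
            )
        return self

    def _check_table(self, X) -> pd.DataFrame:
        df = pd.DataFrame(X)
        missing = [v for v in self.boundaries_.variables if v not in df.columns]
        if missing:
            raise ValueError(f"record table lacks variables: {missing}")
        return df

    def violation_report(self, X) -> pd.DataFrame:
        """Per-variable status ('below'/'above'/'within') and violation count."""
        df = self._check_table(X)
        bs = self.boundaries_
        out = pd.DataFrame(index=df.index)
        for v in bs.variables:
            vals = df[v].to_numpy(dtype=float)
            status = np.where(
                vals < bs.lower[v], "below", np.where(vals > bs.upper[v], "above", "within")
            )
            out[v] = status
        out["violation_count"] = (out[bs.variables] != "within").sum(axis=1)
        if "sample_id" in df.columns:
            out.insert(0, "sample_id", df["sample_id"].values)
        return out

    def predict(self, X):
        """+1 for records within all boundaries, −1 for flagged records."""
        rep = self.violation_report(X)
        return np.where(rep["violation_count"].to_numpy() > 0, -1, 1)

    def count_flagged(self, X) -> dict:
        """Summary: flagged sample count plus per-variable below/above counts."""
        df = self._check_table(X)
        if len(df) == 0:
            return {"n_samples": 0, "n_flagged": 0, "below": {}, "above": {}}
        rep = self.violation_report(X)
        vars_ = self.boundaries_.variables
        return {
            "n_samples": len(df),
            "n_flagged": int((rep["violation_count"] > 0).sum()),
            "below": {v: int((rep[v] == "below").sum()) for v in vars_},
            "above": {v: int((rep[v] == "above").sum()) for v in vars_},
        }


def flag_record(record, boundaries: BoundarySet) -> pd.Series:
    """Violation report for a single record (Series or mapping)."""
    det = PercentileBoundaryDetector.from_boundary_set(boundaries)
    rep = det.violation_report(pd.DataFrame([pd.Series(record)]))
    return rep.iloc[0]
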