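"""Consensus flagging of survey samples and per-area prevalence.

Four detection criteria are combined per sample: violation of the
measured univariate boundaries, violation of the variance-adjusted
univariate boundaries, and rejection by the KNN one-class models built
from each of the two datasets.  A sample is declared *suspect* when at
least 3 of the 4 criteria fire.

The criteria can come either from live detectors or from a recorded
annotation table (used when reproducing published results whose fitted
models cannot be rebuilt from unpublished raw data).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .preprocessing import Autoscaler
from .schema import FEATURES

CRITERIA = (
    "univariate_measured",
    "univariate_variance_adjusted",
    "knn_measured",
    "knn_variance_adjusted",
)


def build_criteria(
    records: pd.DataFrame,
    detector_measured=None,
    detector_varadj=None,
    knn_measured=None,
    knn_varadj=None,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the samples × 4 boolean criteria matrix plus a vote count.

    Each criterion needs either its live detector or a matching column in
    ``annotations`` (violation counts for the univariate criteria, booleans
    for the KNN ones); otherwise a ``ValueError`` is raised.
    """
    idx = records["sample_id"].astype(str) if "sample_id" in records.columns else records.index.astype(str)
    out = pd.DataFrame(index=pd.Index(idx, name="sample_id"))
    ann = None
    if annotations is not None:
        ann = annotations.copy()
        ann.index = pd.Index(ann["sample_id"].astype(str), name="sample_id")

    def resolve(name, detector, is_knn):
        if detector is not None:
            pred = detector.predict(records)
            return np.asarray(pred) == -1
        if ann is not None and name in ann.columns:
            col = ann.loc[out.index, name]
            return col.astype(bool).to_numpy() if is_knn else (col.to_numpy(dtype=float) >= 1)
        raise ValueError(f"criterion {name!r}: no detector and no annotation column")

    out["univariate_measured"] = resolve("univariate_measured", detector_measured, False)
    out["univariate_variance_adjusted"] = resolve(
        "univariate_variance_adjusted", detector_varadj, False
    )
    out["knn_measured"] = resolve("knn_measured", knn_measured, True)
    out["knn_variance_adjusted"] = resolve("knn_variance_adjusted", knn_varadj, True)
    out["vote"] = out[list(CRITERIA)].sum(axis=1).astype(int)
    return out


def consensus(criteria: pd.DataFrame, min_votes: int = 3) -> list[str]:
    """Sample ids whose criteria vote reaches ``min_votes`` (stable order)."""
    if not 1 <= min_votes:
        raise ValueError("min_votes must be a positive integer")
    votes = criteria["vote"] if "vote" in criteria.columns else criteria[list(CRITERIA)].sum(axis=1)
    return [str(i) for i in criteria.index[votes >= min_votes]]


def prevalence_by_area(
    suspects,
    areas: pd.Series,
    area_totals: pd.Series,
) -> pd.DataFrame:
    """Suspected-sample counts and percentages per production area.

    ``areas`` maps sample_id → area for (at least) every suspect;
    ``area_totals`` gives the full survey denominator per area, so that
    samples never individually published still count in the totals.

    ``percentage`` is exact; ``display_pct`` is rounded half-up to whole
    percent for reporting.
    """
    areas = pd.Series(areas)
    areas.index = areas.index.astype(str)
    counts = pd.Series(0, index=area_totals.index, dtype=int)
    for sid in suspects:
        sid = str(sid)
        if sid not in areas.index:
            raise ValueError(f"suspect {sid!r} has no area assignment")
        area = areas[sid]
        if area not in counts.index:
            raise ValueError(f"suspect {sid!r} in area {area!r} missing from totals")
        counts[area] += 1
    pct = 100.0 * counts / area_totals
    return pd.DataFrame({
        "n_suspected": counts,
        "n_total": area_totals.astype(int),
        "percentage": pct,
        "display_pct": np.floor(pct + 0.5).astype(int),
    })


def pca_project(table: pd.DataFrame, n_components: int = 2, autoscale: bool = True):
    """Autoscaled PCA projection used to visualise control/survey grouping.

    Component signs follow the convention that each component's
    largest-magnitude loading is positive.

    Returns ``(scores, loadings, explained_variance_ratio)``.
    """
    cols = [v for v in FEATURES if v in table.columns]
    X = table.loc[:, cols]
    if autoscale:
        X = Autoscaler().fit(X).transform(X)
    rank = min(len(X) - 1, len(cols))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds the data rank {rank}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    loadings = pca.components_
    flip = np.sign(loadings[np.arange(n_components), np.abs(loadings).argmax(axis=1)])
    scores = scores * flip
    loadings = loadings * flip[:, None]
    idx = table["sample_id"].astype(str) if "sample_id" in table.columns else table.index
    scores = pd.DataFrame(
        scores, index=idx, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    loadings = pd.DataFrame(loadings, index=scores.columns, columns=cols)
    return scores, loadings, pca.explained_variance_ratio_
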