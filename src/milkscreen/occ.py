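"""One-class classifiers with cross-validated score thresholds.

Three classic chemometric one-class classifiers (KNN distance, SIMCA,
RBF one-class SVM) share one calibration scheme: the genuine-milk
training table is autoscaled, subjected to repeated leave-30%-out
cross-validation, and the classification threshold is set at the
(1 − α) empirical quantile of the pooled held-out outlyingness scores
(α = 0.01, i.e. a 1% significance level).  A record scoring above the
threshold is rejected from the genuine class.

All estimators follow the scikit-learn outlier-detector contract:
``predict`` returns +1 (inside the class) or −1 (flagged), and
``decision_function`` is positive inside.  Fitting is deterministic for
a fixed ``random_state`` and invariant to the row and column order of a
DataFrame training table (rows are canonicalised before the CV draws).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin, clone
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import OneClassSVM

from .schema import FEATURES

#: Hyperparameter grids scanned during model selection.
KNN_K_GRID = tuple(range(1, 11))
SIMCA_FACTOR_GRID = tuple(range(1, 8))
SVM_GAMMA_GRID = (1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)

_RANK_TOL = 1e-10


def _holdout_size(n: int, fraction: float) -> int:
    """Round-half-up holdout size (15 samples at 30% → 5)."""
    return int(np.floor(n * fraction + 0.5))


class _CalibratedOneClass(OutlierMixin, BaseEstimator):
    """Shared autoscaling + CV threshold calibration machinery."""

    def __init__(self, alpha=0.01, holdout_fraction=0.30, repetitions=100, random_state=None):
        self.alpha = alpha
        self.holdout_fraction = holdout_fraction
        self.repetitions = repetitions
        self.random_state = random_state

    # -- subclass hooks -------------------------------------------------
    def _check_params(self, n_train: int) -> None:
        raise NotImplementedError

    def _fit_inner(self, Z: np.ndarray):
        raise NotImplementedError

    def _score_inner(self, state, Z: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # -- data handling --------------------------------------------------
    def _canonical_columns(self, df: pd.DataFrame) -> list[str]:
        known = [c for c in FEATURES if c in df.columns]
        numeric = [
            c for c in df.columns
            if c not in known and pd.api.types.is_numeric_dtype(df[c])
        ]
        return known + sorted(map(str, numeric))

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = getattr(self, "_columns_", None)
            if cols is not None:
                missing = [c for c in cols if c not in X.columns]
                if missing:
                    raise ValueError(f"missing feature columns: {missing}")
                return X.loc[:, cols].to_numpy(dtype=float)
            return X.loc[:, self._canonical_columns(X)].to_numpy(dtype=float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        return arr

    # -- fitting --------------------------------------------------------
    def fit(self, X, y=None):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("repetitions must be at least 1")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if isinstance(X, pd.DataFrame):
            self._columns_ = self._canonical_columns(X)
            M = X.loc[:, self._columns_].to_numpy(dtype=float)
        else:
            self._columns_ = None
            M = np.asarray(X, dtype=float)
        n = M.shape[0]
        if n < 5:
            raise ValueError("need at least 5 training samples")
        self._check_params(n_train=n - _holdout_size(n, self.holdout_fraction))
        # canonical row order: CV draws become independent of input row order
        M = M[np.lexsort(M.T[::-1])]

        rng = np.random.default_rng(self.random_state)
        n_hold = _holdout_size(n, self.holdout_fraction)
        pooled = []
        for _ in range(self.repetitions):
            perm = rng.permutation(n)
            hold, train = perm[:n_hold], perm[n_hold:]
            mu = M[train].mean(axis=0)
            sd = M[train].std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise ValueError("zero-variance column in a CV training fold")
            state = self._fit_inner((M[train] - mu) / sd)
            pooled.append(self._score_inner(state, (M[hold] - mu) / sd))
        pooled = np.concatenate(pooled)
        self.threshold_ = float(np.quantile(pooled, 1 - self.alpha))
        self.cv_accuracy_ = float(100.0 * np.mean(pooled <= self.threshold_))
        self.cv_scores_ = pooled

        self.mean_ = M.mean(axis=0)
        self.scale_ = M.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            raise ValueError("zero-variance column cannot be autoscaled")
        self._state_ = self._fit_inner((M - self.mean_) / self.scale_)
        self.n_features_in_ = M.shape[1]
        return self

    # -- scoring --------------------------------------------------------
    def raw_scores(self, X) -> np.ndarray:
        """Outlyingness score; larger means further from the genuine class."""
        Z = (self._matrix(X) - self.mean_) / self.scale_
        return self._score_inner(self._state_, Z)

    def decision_function(self, X) -> np.ndarray:
        """threshold − outlyingness: positive inside the class boundary."""
        return self.threshold_ - self.raw_scores(X)

    def score_samples(self, X) -> np.ndarray:
        return -self.raw_scores(X)

    def predict(self, X) -> np.ndarray:
        return np.where(self.raw_scores(X) <= self.threshold_, 1, -1)

    # -- reporting ------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "kind": type(self).__name__,
            "params": {k: (v if not isinstance(v, np.generic) else v.item())
                       for k, v in self.get_params().items()},
            "columns": self._columns_,
            "scaling": {"mean": self.mean_.tolist(), "sd": self.scale_.tolist()},
            "threshold": self.threshold_,
            "cv_accuracy": self.cv_accuracy_,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class KNNOneClass(_CalibratedOneClass):
    """k-nearest-neighbour one-class classifier.

    The outlyingness of a record is the mean Euclidean distance (in
    autoscaled space) to its k nearest genuine training samples (k = 3 by
    default, the value selected for this screening problem).
    """

    grid_param = "k"

    def __init__(self, k=3, alpha=0.01, holdout_fraction=0.30, repetitions=100, random_state=None):
        super().__init__(alpha, holdout_fraction, repetitions, random_state)
        self.k = k

    def _check_params(self, n_train):
        if not 1 <= self.k:
            raise ValueError("k must be a positive integer")
        if self.k > n_train:
            raise ValueError(f"k={self.k} exceeds the {n_train} samples in a training fold")

    def _fit_inner(self, Z):
        return NearestNeighbors(n_neighbors=self.k).fit(Z)

    def _score_inner(self, state, Z):
        dist, _ = state.kneighbors(Z, n_neighbors=self.k)
        return dist.mean(axis=1)


class SIMCAOneClass(_CalibratedOneClass):
    """SIMCA-style one-class classifier.

    The genuine class is modelled by its leading principal components
    (``n_factors`` of them).  A record's outlyingness combines the
    orthogonal residual distance to the subspace and the Mahalanobis-type
    distance within the score space, each normalised by its training-set
    mean:  score = sqrt((OD/OD̄)² + (SD/S̄D)²).  A component whose training
    mean vanishes (e.g. the residual at full rank) is dropped.
    """

    grid_param = "n_factors"

    def __init__(self, n_factors=3, alpha=0.01, holdout_fraction=0.30, repetitions=100, random_state=None):
        super().__init__(alpha, holdout_fraction, repetitions, random_state)
        self.n_factors = n_factors

    def _check_params(self, n_train):
        if not 1 <= self.n_factors:
            raise ValueError("n_factors must be a positive integer")
        if self.n_factors > n_train - 1:
            raise ValueError("n_factors exceeds the rank of a training fold")

    def _fit_inner(self, Z):
        n = Z.shape[0]
        center = Z.mean(axis=0)
        U, s, Vt = np.linalg.svd(Z - center, full_matrices=False)
        rank = int((s > _RANK_TOL * s[0]).sum()) if s.size else 0
        if self.n_factors > rank:
            raise ValueError(f"n_factors={self.n_factors} exceeds the data rank {rank}")
        A = self.n_factors
        V = Vt[:A].T
        lam = (s[:A] ** 2) / (n - 1)  # per-component score variance
        T = U[:, :A] * s[:A]
        resid = (Z - center) - T @ V.T
        od = np.linalg.norm(resid, axis=1)
        sd = np.sqrt(((T**2) / lam).sum(axis=1))
        return {
            "center": center, "V": V, "lam": lam,
            "od_mean": float(od.mean()), "sd_mean": float(sd.mean()),
        }

    def _score_inner(self, state, Z):
        D = Z - state["center"]
        T = D @ state["V"]
        resid = D - T @ state["V"].T
        od = np.linalg.norm(resid, axis=1)
        sd = np.sqrt(((T**2) / state["lam"]).sum(axis=1))
        total = np.zeros(len(Z))
        if state["od_mean"] > 1e-12:
            total += (od / state["od_mean"]) ** 2
        if state["sd_mean"] > 1e-12:
            total += (sd / state["sd_mean"]) ** 2
        return np.sqrt(total)

    def score_components(self, X):
        """(orthogonal residual distance, score-space distance), unnormalised."""
        Z = (self._matrix(X) - self.mean_) / self.scale_
        D = Z - self._state_["center"]
        T = D @ self._state_["V"]
        od = np.linalg.norm(D - T @ self._state_["V"].T, axis=1)
        sd = np.sqrt(((T**2) / self._state_["lam"]).sum(axis=1))
        return od, sd


class SVMOneClass(_CalibratedOneClass):
    """One-class SVM with a Gaussian RBF kernel.

    The support-vector description evaluates the signed distance of a
    record to the learned class boundary; the sign is flipped so that,
    like the other classifiers, larger scores mean more outlying.  ν
    defaults to α (the 1% expected outlier fraction).
    """

    grid_param = "gamma"

    def __init__(self, gamma=0.1, nu=None, alpha=0.01, holdout_fraction=0.30, repetitions=100, random_state=None):
        super().__init__(alpha, holdout_fraction, repetitions, random_state)
        self.gamma = gamma
        self.nu = nu

    def _check_params(self, n_train):
        if not (np.isscalar(self.gamma) and self.gamma > 0):
            raise ValueError("gamma must be a positive number")

    def _fit_inner(self, Z):
        nu = self.alpha if self.nu is None else self.nu
        return OneClassSVM(kernel="rbf", gamma=self.gamma, nu=nu).fit(Z)

    def _score_inner(self, state, Z):
        return -state.decision_function(Z)


def evaluate(fitted, X) -> float:
    """Percentage of records assigned to the genuine class."""
    if len(X) == 0:
        raise ValueError("empty test set")
    return float(100.0 * np.mean(fitted.predict(X) == 1))


def specificity(fitted, X) -> float:
    """Percentage of (adulterated) records flagged as outside the class."""
    if len(X) == 0:
        raise ValueError("empty test set")
    return float(100.0 * np.mean(fitted.predict(X) == -1))


def select_model(candidates, X_train, X_adulterant):
    """Fit every candidate and pick the best by overall performance.

    Overall performance is the mean of the cross-validation accuracy (on
    the genuine training table) and the rejection rate on the adulterant
    test set.  Ties go to the smaller hyperparameter (fewer neighbours /
    factors, smaller γ).

    Returns ``(best_fitted_estimator, results)`` where ``results`` is one
    row per candidate.
    """
    if not candidates:
        raise ValueError("empty candidate grid")
    rows, fitted_models = [], []
    for est in candidates:
        est = clone(est)
        est.fit(X_train)
        adult_pct = specificity(est, X_adulterant)
        rows.append({
            "kind": type(est).__name__,
            "param": getattr(est, est.grid_param),
            "cv_accuracy": est.cv_accuracy_,
            "adulterant_rejection": adult_pct,
            "overall": (est.cv_accuracy_ + adult_pct) / 2.0,
        })
        fitted_models.append(est)
    results = pd.DataFrame(rows)
    order = np.lexsort((results["param"].to_numpy(), -results["overall"].to_numpy()))
    best = fitted_models[order[0]]
    return best, results


def knn_grid(**kw):
    return [KNNOneClass(k=k, **kw) for k in KNN_K_GRID]


def simca_grid(**kw):
    return [SIMCAOneClass(n_factors=a, **kw) for a in SIMCA_FACTOR_GRID]


def svm_grid(**kw):
    return [SVMOneClass(gamma=g, **kw) for g in SVM_GAMMA_GRID]
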