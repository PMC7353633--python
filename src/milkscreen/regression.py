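"""Principal component regression of fraud prevalence on vulnerability ranks.

Thirteen fraud-vulnerability factor mean ranks (opportunities, motivations
and controls) per production area are the predictors; the percentage of
suspected samples in each area is the response.  With only four areas and
thirteen collinear predictors, ordinary least squares is hopeless, hence
regression on the leading principal components of the autoscaled rank
matrix, with leave-one-out (LOO) cross-validation guiding the component
count.

Both X and y are autoscaled (sample SD, ddof=1); coefficients are reported
as the regression vector in that autoscaled space, the form in which such
chemometric regression vectors are conventionally tabulated.  At full rank
this vector reproduces published values for this dataset to printed
precision.  The LOO PRESS is computed by explicitly refitting scaling, PCA
basis and regression on every leave-one-out split — at these problem sizes
a shortcut would save nothing and hide the fold-rank subtlety (a fold of
3 centred observations has rank 2, so requested components are capped per
fold).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

_RANK_TOL = 1e-10


def _svd_coef(Xs: np.ndarray, ys: np.ndarray, n_components: int) -> np.ndarray:
    """Regression vector of ys on the leading PCs of Xs, in Xs coordinates."""
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    rank = int((s > _RANK_TOL * s[0]).sum()) if s.size and s[0] > 0 else 0
    k = min(n_components, rank)
    if k == 0:
        return np.zeros(Xs.shape[1])
    T = U[:, :k] * s[:k]
    b, *_ = np.linalg.lstsq(T, ys, rcond=None)
    return Vt[:k].T @ b


class PCRRegressor(RegressorMixin, BaseEstimator):
    """Principal component regression with explicit LOO cross-validation.

    Parameters
    ----------
    n_components : int or None
        Number of principal components.  ``None`` selects the PRESS
        minimiser over 1..``max_components`` (ties to the smaller count).
    max_components : int
        Upper end of the selection range (capped at min(n−1, p)).
    scale_y : bool
        Autoscale the response as well as the predictors (default); with
        ``False`` the response is centred only.

    Attributes
    ----------
    coefficients_ : Series
        Regression vector per predictor, autoscaled space.
    n_components_ : int
        Component count actually used.
    loo_press_ : float
        Sum of squared LOO prediction errors (original y units) at
        ``n_components_``.
    press_by_components_ : Series
        PRESS over the scanned component counts.
    chosen_by_ : str
        ``"min_press"`` or ``"fixed"``.
    """

    def __init__(self, n_components: int | None = None, max_components: int = 3,
                 scale_y: bool = True):
        self.n_components = n_components
        self.max_components = max_components
        self.scale_y = scale_y

    def _split(self, X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        X = np.asarray(X, dtype=float)
        return X, list(range(X.shape[1]))

    def _scale_y(self, y: np.ndarray):
        mu = y.mean()
        sd = y.std(ddof=1) if self.scale_y else 1.0
        if sd == 0:
            sd = 1.0  # constant response: centred residuals are all zero
        return mu, sd

    def loo_press(self, X, y, n_components: int) -> float:
        """LOO PRESS at a given component count, by explicit refit."""
        X, _ = self._split(X)
        y = np.asarray(y, dtype=float)
        press = 0.0
        n = len(y)
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            mu = X[mask].mean(axis=0)
            sd = X[mask].std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            ymu, ysd = self._scale_y(y[mask])
            beta = _svd_coef((X[mask] - mu) / sd, (y[mask] - ymu) / ysd, n_components)
            pred = ymu + ysd * ((X[i] - mu) / sd) @ beta
            press += (y[i] - pred) ** 2
        return float(press)

    def fit(self, X, y):
        Xm, cols = self._split(X)
        y = np.asarray(y, dtype=float)
        n, p = Xm.shape
        if len(y) != n:
            raise ValueError("X and y length mismatch")
        if n < 3:
            raise ValueError("LOO PCR needs at least 3 observations")
        rank_cap = min(n - 1, p)
        k_max = min(self.max_components, rank_cap)

        self.x_mean_ = Xm.mean(axis=0)
        self.x_scale_ = Xm.std(axis=0, ddof=1)
        if np.any(self.x_scale_ == 0):
            raise ValueError("zero-variance predictor cannot be autoscaled")
        self.y_mean_, self.y_scale_ = self._scale_y(y)
        Xs = (Xm - self.x_mean_) / self.x_scale_
        ys = (y - self.y_mean_) / self.y_scale_

        self.press_by_components_ = pd.Series(
            {k: self.loo_press(Xm, y, k) for k in range(1, k_max + 1)}, name="press"
        )
        if self.n_components is None:
            self.n_components_ = int(self.press_by_components_.idxmin())
            self.chosen_by_ = "min_press"
        else:
            if not 1 <= self.n_components <= rank_cap:
                raise ValueError(
                    f"n_components must lie in 1..{rank_cap} for this data"
                )
            self.n_components_ = int(self.n_components)
            self.chosen_by_ = "fixed"
        self.loo_press_ = float(
            self.press_by_components_.get(
                self.n_components_, self.loo_press(Xm, y, self.n_components_)
            )
        )
        beta = _svd_coef(Xs, ys, self.n_components_)
        self.coefficients_ = pd.Series(beta, index=cols, name="coefficient")
        self.intercept_ = float(self.y_mean_)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        Xm, _ = self._split(X)
        Xs = (Xm - self.x_mean_) / self.x_scale_
        return self.y_mean_ + self.y_scale_ * (Xs @ self.coefficients_.to_numpy())

    def coefficient_signs(self) -> pd.Series:
        """Sign (+1/0/−1) of each predictor's regression coefficient."""
        return np.sign(self.coefficients_).astype(int)

    def report(self) -> dict:
        return {
            "n_components": self.n_components_,
            "chosen_by": self.chosen_by_,
            "loo_press": self.loo_press_,
            "press_by_components": {int(k): v for k, v in self.press_by_components_.items()},
            "intercept": self.intercept_,
            "coefficients": {str(k): float(v) for k, v in self.coefficients_.items()},
        }


def fit_vulnerability_model(
    factors: pd.DataFrame,
    prevalence: pd.Series,
    n_components: int | None = None,
) -> PCRRegressor:
    """Fit the area-level PCR: factor ranks (areas × factors) → prevalence %.

    ``factors`` is the fraud-factor table (rows factor_id, rank columns per
    area, as loaded by :func:`milkscreen.datasets.load_fraud_factors`);
    ``prevalence`` maps the same area codes to suspected-sample percentages.
    """
    areas = [a for a in factors.columns if a in prevalence.index]
    X = factors.loc[:, areas].T.astype(float)  # areas x 13 factors
    y = prevalence.loc[areas].astype(float)
    model = PCRRegressor(n_components=n_components)
    return model.fit(X, y)
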