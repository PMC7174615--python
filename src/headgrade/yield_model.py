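"""Fresh-weight estimation from segmented head pixel area.

A head's fresh weight is modeled as linear in its top-view pixel area,
``weight = slope * area_px + intercept``, fit by ordinary least squares.
Goodness of fit is summarized by R^2 = 1 - SSE/SST and by NRMSE, the root
mean squared error divided by the mean actual weight.

The evaluation protocol sorts samples by weight, numbers them, and uses the
odd ranks for model fitting and the even ranks for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["YieldSample", "YieldFit", "odd_even_split", "fit_linear",
           "r_squared", "nrmse", "predict_weight", "AreaWeightRegressor"]


@dataclass
class YieldSample:
    area_px: float
    weight_g: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.area_px < 0:
            raise ValueError("area_px must be >= 0")
        if not self.weight_g > 0:
            raise ValueError("weight_g must be > 0")


@dataclass
class YieldFit:
    slope: float       # grams per pixel
    intercept: float   # grams
    r2: float
    nrmse: float
    n: int
    variety: str = ""


def odd_even_split(samples) -> tuple[list, list]:
    """Sort by weight (ties by sample_id), number from 1; odd ranks form the
    model set and even ranks the validation set."""
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    ordered = sorted(samples, key=lambda s: (s.weight_g, s.sample_id))
    return ordered[0::2], ordered[1::2]


def r_squared(actual, predicted) -> float:
    """Coefficient of determination 1 - SSE/SST."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need equal-length arrays of length >= 2")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("R^2 undefined: actual values are constant")
    sse = float(((y - yhat) ** 2).sum())
    return 1.0 - sse / sst


def nrmse(actual, predicted) -> float:
    """RMSE normalized by the mean of the actual values."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 1:
        raise ValueError("need equal-length nonempty arrays")
    ybar = float(y.mean())
    if ybar == 0:
        raise ValueError("NRMSE undefined: mean of actual values is zero")
    return float(np.sqrt(np.mean((y - yhat) ** 2))) / ybar


def fit_linear(samples, variety: str = "") -> YieldFit:
    """Least-squares weight-on-area line with fit metrics on the fitting set."""
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to fit")
    a = np.array([s.area_px for s in samples], dtype=float)
    w = np.array([s.weight_g for s in samples], dtype=float)
    if np.ptp(a) == 0:
        raise ValueError("degenerate design: all areas equal")
    slope, intercept = np.polyfit(a, w, 1)
    pred = slope * a + intercept
    return YieldFit(slope=float(slope), intercept=float(intercept),
                    r2=r_squared(w, pred), nrmse=nrmse(w, pred),
                    n=len(samples), variety=variety)


def predict_weight(fit: YieldFit, area_px) -> float | np.ndarray:
    """Estimated fresh weight, floored at 0 grams."""
    out = np.maximum(fit.slope * np.asarray(area_px, dtype=float)
                     + fit.intercept, 0.0)
    return float(out) if out.ndim == 0 else out


class AreaWeightRegressor(RegressorMixin, BaseEstimator):
    """sklearn-style wrapper around the area-to-weight line.

    ``fit(X, y)`` takes X of shape (n, 1) (or (n,)) pixel areas and y fresh
    weights in grams.  Fitted attributes: ``slope_``, ``intercept_``,
    ``r2_``, ``nrmse_``, ``fit_result_``.
    """

    def __init__(self, variety: str = ""):
        self.variety = variety

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single area feature")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        samples = [YieldSample(area_px=a, weight_g=wg, sample_id=str(i))
                   for i, (a, wg) in enumerate(zip(X, y))]
        self.fit_result_ = fit_linear(samples, variety=self.variety)
        self.slope_ = self.fit_result_.slope
        self.intercept_ = self.fit_result_.intercept
        self.r2_ = self.fit_result_.r2
        self.nrmse_ = self.fit_result_.nrmse
        return self

    def predict(self, X):
        if not hasattr(self, "fit_result_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return np.asarray(predict_weight(self.fit_result_, X))
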