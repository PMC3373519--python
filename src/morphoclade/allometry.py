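"""Length-length allometric regressions for body-size estimation.

Two regressions are chained to size a specimen known only from an
incomplete humerus: the preserved distal portion of the humerus predicts
the complete element's length, and humerus length predicts total body
length across hadrosaurids.  Fits are ordinary least squares on the raw
(untransformed) lengths, with a log-log option for classic allometric
form; prediction intervals come from the t distribution of a new
observation.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = ["AllometricModel", "fit_ols", "predict", "estimate_body_length"]


@dataclasses.dataclass(frozen=True)
class AllometricModel:
    slope: float
    intercept: float
    sigma: float               # residual standard deviation (ddof = 2)
    n: int
    slope_se: float
    intercept_se: float
    x_mean: float
    sxx: float                 # sum of squared predictor deviations
    log_log: bool = False
    x_label: str = "predictor_mm"
    y_label: str = "response"

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("a fitted model needs n >= 3")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AllometricModel":
        return cls(**json.loads(text))


def fit_ols(x, y, log_log: bool = False,
            x_label: str = "predictor_mm",
            y_label: str = "response") -> AllometricModel:
    """OLS fit of y on x (optionally of log y on log x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite input")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("lengths must be positive")
    if np.ptp(x) == 0:
        raise ValueError("zero predictor variance")
    xf, yf = (np.log(x), np.log(y)) if log_log else (x, y)
    res = sm.OLS(yf, sm.add_constant(xf)).fit()
    sigma = float(np.sqrt(max(res.ssr, 0.0) / (x.size - 2)))
    return AllometricModel(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        sigma=sigma, n=int(x.size),
        slope_se=float(res.bse[1]), intercept_se=float(res.bse[0]),
        x_mean=float(xf.mean()), sxx=float(np.sum((xf - xf.mean()) ** 2)),
        log_log=log_log, x_label=x_label, y_label=y_label)


def predict(model: AllometricModel, x0: float, with_interval: bool = False,
            level: float = 0.95):
    """Point estimate at x0; optionally a prediction interval for a new
    observation."""
    if x0 <= 0:
        raise ValueError("x0 must be positive")
    xf = np.log(x0) if model.log_log else x0
    yhat = model.intercept + model.slope * xf
    out = np.exp(yhat) if model.log_log else yhat
    if not with_interval:
        return float(out)
    t = stats.t.ppf(0.5 + level / 2, model.n - 2)
    se = model.sigma * np.sqrt(
        1.0 + 1.0 / model.n + (xf - model.x_mean) ** 2 / model.sxx)
    lo, hi = yhat - t * se, yhat + t * se
    if model.log_log:
        lo, hi = np.exp(lo), np.exp(hi)
    return float(out), (float(lo), float(hi))


def estimate_body_length(humerus_mm: float,
                         model_body: AllometricModel) -> float:
    """Body length in meters from humerus length in mm, through a fitted
    humerus(mm) -> body(m) regression.  Never rounded here."""
    if humerus_mm <= 0:
        raise ValueError("humerus length must be positive")
    return float(predict(model_body, humerus_mm))
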