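"""Evaluation metrics for trait-imputation models.

Seven standard regression metrics are reported together: MSE, RMSE, MAE,
MedAE, MAPE, MSLE and the coefficient of determination R². A report carries
a ``scale`` tag because the imputation models are trained on natural-log
trait values but imputed values are delivered on the original measurement
scale; both views of the same predictions are routinely emitted side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MetricsReport", "compute_metrics"]


@dataclass
class MetricsReport:
    """Bundle of the seven evaluation metrics for one prediction vector.

    ``mape`` and ``msle`` may be NaN when their domain requirements are not
    met (zero true values for MAPE, values at or below -1 for MSLE); the
    violation is then recorded in ``flags`` rather than raised, so a single
    ill-conditioned metric never invalidates the rest of the report.
    MAPE and the flagged exclusion count follow the convention that rows with
    a true value of exactly zero are excluded from MAPE only.
    """

    mse: float
    rmse: float
    mae: float
    medae: float
    mape: float
    msle: float
    r2: float
    n: int
    scale: str
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "mse": self.mse,
            "rmse": self.rmse,
            "mae": self.mae,
            "medae": self.medae,
            "mape": self.mape,
            "msle": self.msle,
            "r2": self.r2,
            "n": self.n,
            "scale": self.scale,
        }


def compute_metrics(y, yhat, scale: str = "log") -> MetricsReport:
    """Compute all seven metrics of ``yhat`` against the truth ``y``.

    Parameters
    ----------
    y, yhat
        Equal-length 1-D arrays of true and predicted values.
    scale
        Tag recorded in the report: ``"log"`` for natural-log trait values,
        ``"original"`` for back-transformed measurements.

    Raises
    ------
    ValueError
        If lengths differ, n < 2, or ``y`` has zero variance (R² undefined).
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: y has {y.size}, yhat has {yhat.size}")
    n = y.size
    if n < 2:
        raise ValueError("at least 2 observations are required")

    resid = y - yhat
    mse = float(np.mean(resid**2))
    rmse = float(np.sqrt(mse))
    abs_resid = np.abs(resid)
    mae = float(np.mean(abs_resid))
    medae = float(np.median(abs_resid))

    flags: dict = {}

    nonzero = y != 0
    n_excluded = int(n - nonzero.sum())
    if n_excluded > 0:
        flags["mape_excluded_zero_y"] = n_excluded
    if nonzero.any():
        mape = float(np.mean(np.abs(resid[nonzero] / y[nonzero])))
    else:
        mape = float("nan")
        flags["mape_undefined"] = "all true values are zero"

    if np.all(1.0 + y > 0) and np.all(1.0 + yhat > 0):
        msle = float(np.mean((np.log1p(y) - np.log1p(yhat)) ** 2))
    else:
        msle = float("nan")
        flags["msle_undefined"] = "values at or below -1 present"

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero variance in y: R^2 is undefined")
    ss_res = float(np.sum(resid**2))
    r2 = 1.0 - ss_res / ss_tot

    return MetricsReport(
        mse=mse, rmse=rmse, mae=mae, medae=medae, mape=mape, msle=msle,
        r2=r2, n=n, scale=scale, flags=flags,
    )
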