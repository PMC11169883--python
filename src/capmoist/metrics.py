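"""Evaluation metrics for calibration-style regression models.

The model comparison rests on three numbers per data split: the Pearson
correlation coefficient R between measured and predicted moisture, the root
mean square error (RMSE, in moisture percent), and the ratio performance
deviation RPD.  RPD is defined here as a function of R alone,

    RPD = 1 / sqrt(1 - R^2),

with the chemometrics reliability reading: RPD <= 1.4 unreliable,
1.4 < RPD <= 2.0 relatively reliable, RPD > 2.0 highly reliable.  The
classical chemometrics ratio SD(y)/RMSE is offered separately as
:func:`classical_rpd` and is never mixed with the R-based definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "pearson_r",
    "rmse",
    "rpd_from_r",
    "classical_rpd",
    "reliability_band",
    "summarize_dataset",
    "DatasetSummary",
    "ModelReport",
    "report_frame",
    "summary_frame",
]

#: RPD reliability thresholds; boundary values belong to the lower band.
RPD_UNRELIABLE_BELOW = 1.4
RPD_HIGH_ABOVE = 2.0


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient between two equal-length vectors.

    Computed as sum((x-xbar)(y-ybar)) / sqrt(sum((x-xbar)^2) * sum((y-ybar)^2));
    raises on vectors shorter than 2 or with zero variance.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("pearson_r requires at least 2 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("pearson_r undefined: zero variance in an argument")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    # Guard against rounding pushing |r| infinitesimally past 1.
    return float(np.clip(r, -1.0, 1.0))


def rmse(y, y_hat) -> float:
    """Root mean square error sqrt(mean((y - y_hat)^2))."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.size} vs {y_hat.size}")
    if y.size == 0:
        raise ValueError("rmse requires at least 1 observation")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def rpd_from_r(r: float) -> float:
    """Ratio performance deviation 1/sqrt(1 - R^2); requires |R| < 1."""
    r = float(r)
    if not abs(r) < 1:
        raise ValueError(f"rpd_from_r requires |R| < 1, got {r}")
    return 1.0 / np.sqrt(1.0 - r * r)


def classical_rpd(y_true, y_pred, ddof: int = 1) -> float:
    """Classical chemometrics RPD: SD of the reference values over RMSE."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    return float(np.std(y_true, ddof=ddof)) / rmse(y_true, y_pred)


def reliability_band(rpd: float) -> str:
    """Reliability class of a model given its RPD.

    Closed-below convention: 1.4 is still 'unreliable', 2.0 is still
    'relatively_reliable'.
    """
    rpd = float(rpd)
    if not rpd > 0:
        raise ValueError(f"RPD must be positive, got {rpd}")
    if rpd <= RPD_UNRELIABLE_BELOW:
        return "unreliable"
    if rpd <= RPD_HIGH_ABOVE:
        return "relatively_reliable"
    return "highly_reliable"


@dataclass(frozen=True)
class DatasetSummary:
    """Count, extremes, mean and SD of a moisture (%) vector."""

    n_samples: int
    maximum: float
    minimum: float
    mean: float
    std: float


def summarize_dataset(moisture_percent, ddof: int = 1) -> DatasetSummary:
    """Summary statistics of a moisture vector (sample SD by default)."""
    m = np.asarray(moisture_percent, dtype=float).ravel()
    if m.size == 0:
        raise ValueError("summarize_dataset requires a nonempty vector")
    return DatasetSummary(
        n_samples=int(m.size),
        maximum=float(m.max()),
        minimum=float(m.min()),
        mean=float(m.mean()),
        std=float(np.std(m, ddof=ddof)) if m.size > 1 else 0.0,
    )


@dataclass(frozen=True)
class ModelReport:
    """Six-metric evaluation row: (R, RMSE, RPD) on training and prediction sets."""

    model_name: str
    r_train: float
    rmse_train: float
    rpd_train: float
    r_test: float
    rmse_test: float
    rpd_test: float

    @classmethod
    def from_predictions(cls, model_name, y_train, yhat_train, y_test, yhat_test) -> "ModelReport":
        """Build a report row; RPD is always recomputed from the row's own R."""
        r_c = pearson_r(y_train, yhat_train)
        r_p = pearson_r(y_test, yhat_test)
        for label, r in (("training", r_c), ("prediction", r_p)):
            if r < 0:
                warnings.warn(
                    f"{model_name}: negative {label}-set correlation R={r:.4f}; "
                    "reported verbatim",
                    stacklevel=2,
                )
        def rpd(r):
            # A numerically perfect fit (|R| = 1 to float precision) has
            # unbounded RPD; report the limit instead of failing.
            return float("inf") if abs(r) >= 1.0 else rpd_from_r(r)

        return cls(
            model_name=str(model_name),
            r_train=r_c,
            rmse_train=rmse(y_train, yhat_train),
            rpd_train=rpd(r_c),
            r_test=r_p,
            rmse_test=rmse(y_test, yhat_test),
            rpd_test=rpd(r_p),
        )


def report_frame(reports) -> pd.DataFrame:
    """Stack ModelReports into a model x six-metric table."""
    return pd.DataFrame(
        [
            {
                "Models": r.model_name,
                "R_C": r.r_train,
                "RMSE_C": r.rmse_train,
                "RPD_C": r.rpd_train,
                "R_P": r.r_test,
                "RMSE_P": r.rmse_test,
                "RPD_P": r.rpd_test,
            }
            for r in reports
        ]
    )


def summary_frame(train: DatasetSummary, test: DatasetSummary) -> pd.DataFrame:
    """Two-row dataset summary table (training / prediction sets)."""
    rows = []
    for name, s in (("Training set", train), ("Prediction set", test)):
        rows.append(
            {"Data set": name, "NS": s.n_samples, "XV": s.maximum, "NV": s.minimum,
             "AV": s.mean, "SD": s.std}
        )
    return pd.DataFrame(rows)
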