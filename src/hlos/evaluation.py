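"""Model evaluation: summary-statistic rows, Taylor-diagram statistics and
the cross-model comparison report.

Each model row carries mean, sample standard deviation, rounded min/max,
coefficient of variation (sd/mean), adjusted R-squared (x100), RMSE and MAE
of its test predictions; the actual test target gets the descriptive subset.
Taylor statistics are (Pearson correlation, sd of predictions, centered RMS
difference), which satisfy the law-of-cosines identity
``crmsd^2 = sd_p^2 + sd_a^2 - 2 sd_p sd_a r``.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["MetricsRow", "TaylorRow", "compute_metrics", "actual_row",
           "taylor_stats", "build_report"]


@dataclasses.dataclass
class MetricsRow:
    name: str
    mean: float
    sd: float
    min: int           # rounded days
    max: int           # rounded days
    cv: float
    adj_r2: float | None   # x100; None for the actual row
    rmse: float | None
    mae: float | None


@dataclasses.dataclass
class TaylorRow:
    name: str
    correlation: float
    sd_pred: float
    centered_rmsd: float


def _check_pair(actual, predicted):
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted lengths differ")
    if len(actual) < 2:
        raise ValueError("need at least 2 observations")
    return actual, predicted


def compute_metrics(actual, predicted, p: int, name: str = "model") -> MetricsRow:
    """Summary-statistic row for one model's test predictions.

    ``p`` is the number of predictors entering the adjusted R-squared
    correction; it must satisfy p < n - 1.
    """
    actual, predicted = _check_pair(actual, predicted)
    n = len(actual)
    if p >= n - 1:
        raise ValueError("adjusted R-squared requires p < n - 1")
    mean = predicted.mean()
    if mean == 0:
        raise ZeroDivisionError("CV undefined: mean of predictions is 0")
    sd = predicted.std(ddof=1)
    rmse = float(np.sqrt(np.mean((actual - predicted) ** 2)))
    mae = float(np.mean(np.abs(actual - predicted)))
    ss_res = float(((actual - predicted) ** 2).sum())
    ss_tot = float(((actual - actual.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R-squared undefined: actual values have zero variance")
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = (1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)) * 100.0
    return MetricsRow(name=name, mean=float(mean), sd=float(sd),
                      min=int(round(predicted.min())), max=int(round(predicted.max())),
                      cv=float(sd / mean), adj_r2=float(adj_r2),
                      rmse=rmse, mae=mae)


def actual_row(actual, name: str = "Actual") -> MetricsRow:
    """Descriptive row for the observed test target (no error metrics)."""
    actual = np.asarray(actual, dtype=float)
    if len(actual) < 2:
        raise ValueError("need at least 2 observations")
    mean = actual.mean()
    if mean == 0:
        raise ZeroDivisionError("CV undefined: mean is 0")
    sd = actual.std(ddof=1)
    return MetricsRow(name=name, mean=float(mean), sd=float(sd),
                      min=int(round(actual.min())), max=int(round(actual.max())),
                      cv=float(sd / mean), adj_r2=None, rmse=None, mae=None)


def taylor_stats(actual, predicted, name: str = "model") -> TaylorRow:
    """(correlation, sd of predictions, centered RMS difference)."""
    actual, predicted = _check_pair(actual, predicted)
    sd_a = actual.std(ddof=1)
    sd_p = predicted.std(ddof=1)
    if sd_a == 0 or sd_p == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(actual, predicted)[0, 1])
    dev = (predicted - predicted.mean()) - (actual - actual.mean())
    crmsd = float(np.sqrt((dev ** 2).sum() / (len(actual) - 1)))
    return TaylorRow(name=name, correlation=r, sd_pred=float(sd_p),
                     centered_rmsd=crmsd)


def build_report(actual, predictions: dict, p: int,
                 record_ids: dict | None = None) -> pd.DataFrame:
    """Comparison table: actual row first, models ordered by RMSE ascending
    (alphabetical tie-break).

    ``record_ids`` optionally maps model name to the record-id vector its
    predictions were computed on; mismatched id vectors raise, guarding
    against mixing test splits.
    """
    if record_ids is not None:
        ref = None
        for name, ids in record_ids.items():
            ids = np.asarray(ids)
            if ref is None:
                ref = ids
            elif ids.shape != ref.shape or np.any(ids != ref):
                raise ValueError(f"test-split mismatch for model {name!r}")
    rows = [actual_row(actual)]
    model_rows = [compute_metrics(actual, pred, p=p, name=name)
                  for name, pred in predictions.items()]
    model_rows.sort(key=lambda r: (r.rmse, r.name))
    rows.extend(model_rows)
    frame = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    for col in ("adj_r2", "rmse", "mae"):
        frame[col] = frame[col].astype(object).where(frame[col].notna(), "-")
    return frame


def format_report(frame: pd.DataFrame) -> str:
    """Human-readable rendering; RMSE/MAE to 2 decimals, min/max whole days."""
    show = frame.copy()
    for col in ("mean", "sd", "cv"):
        show[col] = show[col].map(lambda v: f"{v:.2f}")
    for col in ("adj_r2", "rmse", "mae"):
        show[col] = show[col].map(lambda v: v if v == "-" else f"{v:.2f}")
    return show.to_string(index=False)
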