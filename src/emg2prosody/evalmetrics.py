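"""Evaluation metrics: MAPE, Pearson r, Lin's CCC, RMSE, MBE.

Sign conventions: MBE = mean(predicted - observed), so positive MBE means
overestimation.  CCC uses population variances (Lin's original definition).
MAPE excludes (and counts) samples whose observed magnitude is below 1e-6 in
the operative unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvalReport",
    "compute_metrics",
    "select_final_fold",
    "summarize_folds",
]

_MAPE_GUARD = 1e-6
_METRIC_KEYS = ("mape", "pearson_r", "ccc", "rmse", "mbe")


@dataclass
class EvalReport:
    mape: float
    pearson_r: float
    ccc: float
    rmse: float
    mbe: float
    n_frames: int
    unit: str
    dataset_tag: str = ""
    undefined: dict[str, str] = field(default_factory=dict)
    n_mape_excluded: int = 0

    def as_dict(self) -> dict:
        return {
            "mape": self.mape,
            "pearson_r": self.pearson_r,
            "ccc": self.ccc,
            "rmse": self.rmse,
            "mbe": self.mbe,
            "n_frames": self.n_frames,
            "unit": self.unit,
            "dataset_tag": self.dataset_tag,
            "n_mape_excluded": self.n_mape_excluded,
        }


def compute_metrics(
    observed,
    predicted,
    unit: str,
    dataset_tag: str = "",
) -> EvalReport:
    """All five metrics for one (observed, predicted) series.

    Zero-variance series leave r/CCC flagged as undefined (NaN) rather than
    silently zeroed; same for MAPE when every observed value is below the
    magnitude guard.
    """
    o = np.asarray(observed, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed/predicted must be matching 1-D arrays")
    if o.size < 2:
        raise ValueError("need at least 2 samples")
    undefined: dict[str, str] = {}

    resid = p - o
    mbe = float(np.mean(resid))
    rmse = float(np.sqrt(np.mean(resid**2)))

    usable = np.abs(o) >= _MAPE_GUARD
    n_excluded = int((~usable).sum())
    if usable.any():
        mape = float(100.0 * np.mean(np.abs(resid[usable]) / np.abs(o[usable])))
    else:
        mape = float("nan")
        undefined["mape"] = "all observed values below magnitude guard"

    var_o = float(np.var(o))  # population variances, per Lin
    var_p = float(np.var(p))
    if var_o <= 0 or var_p <= 0:
        r = float("nan")
        ccc = float("nan")
        undefined["pearson_r"] = "zero-variance series"
        undefined["ccc"] = "zero-variance series"
    else:
        cov = float(np.mean((o - o.mean()) * (p - p.mean())))
        r = cov / np.sqrt(var_o * var_p)
        ccc = 2.0 * cov / (var_o + var_p + (o.mean() - p.mean()) ** 2)
    return EvalReport(
        mape=mape,
        pearson_r=r,
        ccc=ccc,
        rmse=rmse,
        mbe=mbe,
        n_frames=o.size,
        unit=unit,
        dataset_tag=dataset_tag,
        undefined=undefined,
        n_mape_excluded=n_excluded,
    )


def select_final_fold(validation_reports: list[EvalReport]) -> int:
    """Index of the fold with the highest validation CCC.

    Ties break toward lower validation RMSE, then lowest fold index.
    """
    if not validation_reports:
        raise ValueError("no fold reports")
    defined = [
        (i, rep)
        for i, rep in enumerate(validation_reports)
        if np.isfinite(rep.ccc)
    ]
    if not defined:
        raise ValueError("CCC undefined for every fold")
    return min(defined, key=lambda ir: (-ir[1].ccc, ir[1].rmse, ir[0]))[0]


def summarize_folds(reports: list[EvalReport]) -> dict[str, tuple[float, float]]:
    """Per-metric mean and sample standard deviation across folds."""
    if len(reports) < 2:
        raise ValueError("need at least 2 fold reports")
    out = {}
    for key in _METRIC_KEYS:
        vals = np.array([getattr(rep, key) for rep in reports], dtype=float)
        out[key] = (float(np.mean(vals)), float(np.std(vals, ddof=1)))
    return out
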