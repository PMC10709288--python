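"""ROI extraction and group-level statistics.

ROI means of maps and time series, and the one-sample / paired t-tests used
to compare ROI-level glucoCEST and DGE values.  Tests are two-sided with
alpha = 0.05 and no multiple-testing correction by default; a Bonferroni
helper is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ROIMask:
    """A named boolean region on the map grid."""

    name: str
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    dof: int
    p_value: float
    n: int


def roi_mean(data: np.ndarray, mask: ROIMask | np.ndarray):
    """Mean and standard deviation over in-mask, non-missing voxels.

    For a map matching the mask's dimensionality, returns
    ``(mean, sd, n_missing)``; for a series with one trailing time axis,
    per-time arrays are returned instead.
    """
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty ROI mask")
    data = np.asarray(data, dtype=float)
    if data.ndim == m.ndim:
        vals = data[m]
        missing = int(np.isnan(vals).sum())
        return (float(np.nanmean(vals)), float(np.nanstd(vals)), missing)
    if data.ndim == m.ndim + 1:
        vals = data[m]  # (n_voxels, n_times)
        missing = np.isnan(vals).sum(axis=0).astype(int)
        return (np.nanmean(vals, axis=0), np.nanstd(vals, axis=0), missing)
    raise ValueError("data must match the mask, optionally with one "
                     "trailing time axis")


def one_sample_ttest(values, popmean: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test: ``t = mean / (sd / sqrt(n))``,
    dof = n - 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.std(v, ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(v, popmean)
    return TTestResult(float(res.statistic), int(v.size - 1),
                       float(res.pvalue), int(v.size))


def paired_ttest(a, b) -> TTestResult:
    """Two-sided paired t-test, i.e. a one-sample test on ``a - b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_ttest(a - b)


def bonferroni(p_values, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values (optional; off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if n_tests is None else n_tests
    return np.minimum(p * m, 1.0)


def roi_table(maps: dict, masks: list) -> pd.DataFrame:
    """Summarize a set of maps over a set of ROIs.

    ``maps`` maps a label (e.g. block index or contrast name) to a map;
    returns a tidy frame with columns roi, map, n, mean, sd, n_missing.
    """
    rows = []
    for roi in masks:
        for name, m in maps.items():
            mean, sd, miss = roi_mean(m, roi)
            rows.append((roi.name, name, roi.n_voxels, mean, sd, miss))
    return pd.DataFrame(rows, columns=["roi", "map", "n", "mean", "sd",
                                       "n_missing"])
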