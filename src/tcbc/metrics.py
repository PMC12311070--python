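"""Benchmark evaluation: RMSE, regression R-squared, Bland-Altman."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, UndefinedFitError
from .geometry import PARAM_NAMES

__all__ = ["rmse", "r_squared", "bland_altman", "summarize_benchmark",
           "rmse_percent_change", "bland_altman_plot"]


def _paired(estimated, truth) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(estimated, dtype=float).ravel()
    tru = np.asarray(truth, dtype=float).ravel()
    if est.size == 0 or est.size != tru.size:
        raise InvalidArgumentError("series must be equal-length and non-empty")
    return est, tru


def rmse(estimated, truth) -> float:
    """Root mean squared difference between paired series."""
    est, tru = _paired(estimated, truth)
    return float(np.sqrt(np.mean((est - tru) ** 2)))


def r_squared(estimated, truth) -> float:
    """Coefficient of determination of the OLS fit of estimated on truth."""
    est, tru = _paired(estimated, truth)
    if est.size < 3:
        raise InvalidArgumentError("need at least 3 points for regression")
    if np.ptp(tru) == 0:
        raise UndefinedFitError("truth series is constant; fit undefined")
    fit = stats.linregress(tru, est)
    return float(fit.rvalue ** 2)


def bland_altman(estimated, truth) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high) of differences d = truth - estimated.

    Limits of agreement are bias +/- 1.96 * sample SD (ddof=1); with n = 1
    the LoA collapse to the bias.
    """
    est, tru = _paired(estimated, truth)
    if est.size < 2:
        raise InvalidArgumentError("need at least 2 points")
    d = tru - est
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def summarize_benchmark(results: pd.DataFrame,
                        min_trials: int = 3) -> pd.DataFrame:
    """Per method x duration x parameter metrics of a benchmark table.

    Cells with fewer than ``min_trials`` successful trials are emitted with
    NaN metrics and ``flagged=True`` rather than raising.
    """
    if "failed" in results.columns:
        ok = results[~results["failed"].astype(bool)]
    else:
        ok = results
    rows = []
    group_keys = ["method", "duration_s"]
    for (method, duration), cell in ok.groupby(group_keys, dropna=False):
        for name in PARAM_NAMES:
            est = cell[f"est_{name}"].to_numpy(dtype=float)
            tru = cell[f"true_{name}"].to_numpy(dtype=float)
            row = {"method": method, "duration_s": duration, "param": name,
                   "n": len(cell), "flagged": len(cell) < min_trials}
            if len(cell) >= min_trials:
                bias, lo, hi = bland_altman(est, tru)
                row.update({"rmse": rmse(est, tru),
                            "r_squared": r_squared(est, tru),
                            "bias": bias, "loa_low": lo, "loa_high": hi})
            else:
                row.update({"rmse": np.nan, "r_squared": np.nan,
                            "bias": np.nan, "loa_low": np.nan,
                            "loa_high": np.nan})
            rows.append(row)
    return pd.DataFrame(rows)


def rmse_percent_change(metrics: pd.DataFrame, method: str = "tcbc",
                        baseline: str = "nmi") -> pd.DataFrame:
    """Percent RMSE reduction of ``method`` relative to ``baseline``.

    Positive values mean the method improved on the baseline.
    """
    a = metrics[metrics["method"] == method].set_index(["duration_s", "param"])
    b = metrics[metrics["method"] == baseline].set_index(["duration_s", "param"])
    common = a.index.intersection(b.index)
    if common.empty:
        raise InvalidArgumentError("no overlapping cells between methods")
    pct = 100.0 * (b.loc[common, "rmse"] - a.loc[common, "rmse"]) \
        / b.loc[common, "rmse"]
    out = pct.rename("rmse_reduction_pct").reset_index()
    return out


def bland_altman_plot(estimated, truth, path: str | Path,
                      title: str = "") -> None:
    """Write a Bland-Altman scatter (difference vs mean) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    est, tru = _paired(estimated, truth)
    bias, lo, hi = bland_altman(est, tru)
    d = tru - est
    mean = 0.5 * (tru + est)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(mean, d, s=8, alpha=0.6)
    ax.axhline(bias, color="green", linestyle="--", label="bias")
    ax.axhline(lo, color="red", linestyle=":", label="95% LoA")
    ax.axhline(hi, color="red", linestyle=":")
    ax.set_xlabel("mean of truth and estimate")
    ax.set_ylabel("truth - estimate")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
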