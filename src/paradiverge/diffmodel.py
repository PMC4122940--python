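"""Interaction model linking paralog divergence to differentiation.

For each CpG site i belonging to a paralogous pair, let

* ``x1``: methylation level in the base (stem) cell type, in [0, 1];
* ``x2``: signed change in methylation between the base and the
  differentiated cell type, in [-1, 1];
* ``y``:  absolute difference in methylation level to the paralogous
  site within the base cell type.

The model is ordinary least squares with an interaction term::

    y_i = b0 + b1*x1_i + b2*x2_i + b3*x1_i*x2_i + e_i

Sites with regulated methylation changes during differentiation (large
|x2|) tend to show larger paralog divergence, especially at lowly
methylated sites, and the fit quantifies that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

TERMS = ("const", "x1", "x2", "x1:x2")


@dataclass
class InteractionFit:
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    nobs: int

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return tuple(self.params[t] for t in TERMS)  # type: ignore[return-value]


def _design(data: pd.DataFrame) -> pd.DataFrame:
    x = pd.DataFrame(
        {
            "const": 1.0,
            "x1": data["x1"].to_numpy(dtype=float),
            "x2": data["x2"].to_numpy(dtype=float),
        }
    )
    x["x1:x2"] = x["x1"] * x["x2"]
    return x


def fit_interaction_model(data: pd.DataFrame) -> InteractionFit:
    """OLS of y on x1, x2 and their interaction, with intercept.

    ``data`` must hold complete-case columns x1, x2, y.  A constant
    explanatory column makes the design rank-deficient and raises an
    error naming the degenerate column.
    """
    data = data.dropna(subset=["x1", "x2", "y"])
    if len(data) <= 10:
        raise ValueError("need more than 10 complete-case rows")
    for col in ("x1", "x2"):
        if data[col].nunique() == 1:
            raise ValueError(f"column {col!r} is constant; design is rank-deficient")
    x = _design(data)
    res = sm.OLS(data["y"].to_numpy(dtype=float), x).fit()
    return InteractionFit(
        params={t: float(res.params[t]) for t in TERMS},
        bse={t: float(res.bse[t]) for t in TERMS},
        pvalues={t: float(res.pvalues[t]) for t in TERMS},
        r_squared=float(res.rsquared),
        nobs=int(res.nobs),
    )


def equal_count_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to one of ``n_bins`` near-equal-count bins.

    Ties are resolved rank-then-split with a stable sort, so bin sizes
    differ by at most 1 and the assignment is deterministic.
    """
    n = len(values)
    if n_bins < 1 or n_bins > n:
        raise ValueError("n_bins must be in [1, len(values)]")
    order = np.argsort(values, kind="mergesort")
    bins = np.empty(n, dtype=int)
    base, extra = divmod(n, n_bins)
    start = 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        bins[order[start : start + size]] = b
        start += size
    return bins


def binned_divergence_summary(
    data: pd.DataFrame, level_bins: int = 4, change_bins: int = 4
) -> pd.DataFrame:
    """Mean paralog divergence per (level bin x change bin) cell.

    Bin edges are chosen so each axis category holds approximately the
    same number of sites (equal-count/quantile binning); empty cells are
    NaN.  Returns a long-format frame with counts per cell.
    """
    data = data.dropna(subset=["x1", "x2", "y"])
    if len(data) < max(level_bins, change_bins):
        raise ValueError("fewer rows than requested bins")
    lb = equal_count_bins(data["x1"].to_numpy(), level_bins)
    cb = equal_count_bins(data["x2"].to_numpy(), change_bins)
    df = pd.DataFrame({"level_bin": lb, "change_bin": cb, "y": data["y"].to_numpy()})
    grouped = df.groupby(["level_bin", "change_bin"])["y"].agg(["mean", "count"])
    full_index = pd.MultiIndex.from_product(
        [range(level_bins), range(change_bins)], names=["level_bin", "change_bin"]
    )
    grouped = grouped.reindex(full_index)
    grouped["count"] = grouped["count"].fillna(0).astype(int)
    return grouped.reset_index().rename(columns={"mean": "mean_y", "count": "n"})
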