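"""Statistical analysis of the four-arm run table.

Given 15 runs per arm, the analysis consists of

* per-arm means and sample (n-1) standard deviations for AC/SE/SP/AUOC;
* one-sided 95% lower confidence bounds for variance ratios,
  ``(s_x^2 / s_y^2) / F_{1-a; n_x-1, n_y-1}``, with an F-test p-value —
  used to show that cheat-sheet arms are more precise (smaller variance);
* one-sided 95% lower confidence bounds for mean differences under the
  pooled-variance two-sample t model,
  ``(xbar - ybar) - t_{1-a; n_x+n_y-2} * s_p * sqrt(1/n_x + 1/n_y)`` —
  used to show that cheat-sheet arms are more accurate.

``reproduce_published_analysis`` recomputes the whole published analysis from the
packaged run-table fixture and flags the cells whose printed values do not
regenerate under these formulas.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["CIBound", "load_run_table", "summarize", "var_ratio_lower_bound",
           "mean_diff_lower_bound", "reproduce_published_analysis",
           "normal_probability_points", "quartiles"]

METRICS = ("AC", "SE", "SP", "AUOC")
ARMS = ("OS", "DA", "CS", "DACS")


@dataclass
class CIBound:
    """A one-sided 95% lower confidence bound with its test descriptor."""

    comparison: Tuple[str, str, str]  # (x, y, statistic)
    alpha: float
    bound: float
    p_value: float
    statistic: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not np.isfinite(self.bound):
            raise ValueError("bound must be finite")


def load_run_table() -> pd.DataFrame:
    """The packaged 4-arm x 15-run performance table (long format)."""
    with resources.files("mammocad.data").joinpath("run_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def _column(table: pd.DataFrame, arm: str, metric: str) -> np.ndarray:
    vals = table.loc[table["arm"] == arm, metric].to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError(f"no rows for arm {arm!r}")
    return vals


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-arm mean and sample standard deviation for each metric.

    Full precision is kept; callers round to 1 decimal for reporting.
    """
    rows = []
    for arm in table["arm"].unique():
        sub = table[table["arm"] == arm]
        if len(sub) < 2:
            raise ValueError(f"arm {arm!r} needs >= 2 runs to summarise")
        for metric in METRICS:
            v = sub[metric].to_numpy(dtype=float)
            rows.append({"arm": arm, "metric": metric,
                         "mean": float(v.mean()),
                         "stdev": float(v.std(ddof=1))})
    return pd.DataFrame(rows)


def var_ratio_lower_bound(x: Sequence[float], y: Sequence[float],
                          alpha: float = 0.05,
                          alternative: str = "greater",
                          names: Tuple[str, str] = ("x", "y")) -> CIBound:
    """Lower 95% bound for sigma_x^2 / sigma_y^2 and the F-test p-value.

    ``alternative`` picks the one-sided p-value direction ('greater' tests
    sigma_x^2 > sigma_y^2).  Scaling x by c scales the bound by c^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs length >= 2")
    if y.var(ddof=1) == 0:
        raise ZeroDivisionError("zero variance in the denominator sample")
    f = x.var(ddof=1) / y.var(ddof=1)
    dfx, dfy = len(x) - 1, len(y) - 1
    bound = f / sps.f.ppf(1 - alpha, dfx, dfy)
    if alternative == "greater":
        p = float(sps.f.sf(f, dfx, dfy))
    elif alternative == "less":
        p = float(sps.f.cdf(f, dfx, dfy))
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return CIBound(comparison=(names[0], names[1], "var_ratio"), alpha=alpha,
                   bound=float(bound), p_value=p, statistic=float(f))


def mean_diff_lower_bound(x: Sequence[float], y: Sequence[float],
                          alpha: float = 0.05,
                          names: Tuple[str, str] = ("x", "y")) -> CIBound:
    """Lower 95% bound for mu_x - mu_y (pooled-variance two-sample t).

    The p-value is one-sided for the alternative mu_x > mu_y.  Shifting x
    by +d shifts the bound by exactly +d.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs length >= 2")
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    d = x.mean() - y.mean()
    tstat = d / se if se > 0 else np.inf * np.sign(d)
    bound = d - sps.t.ppf(1 - alpha, df) * se
    return CIBound(comparison=(names[0], names[1], "mean_diff"), alpha=alpha,
                   bound=float(bound), p_value=float(sps.t.sf(tstat, df)),
                   statistic=float(tstat))


#: published values for the flagging layer of ``reproduce_published_analysis``;
#: H05/H06 (and H07 at 2 decimals) do not regenerate under the pooled-t
#: formula that reproduces H04 exactly, so they are flagged, not asserted.
_PRINTED_BOUNDS = {"H01": 0.1, "H02": 2.3, "H03": 2.2,
                   "H04": 8.56, "H05": 13.25, "H06": 1.45, "H07": -4.56}

#: (x arm, y arm, statistic, alternative) per hypothesis
_HYPOTHESES = {
    "H01": ("CS", "OS", "var_ratio", "less"),
    "H02": ("DA", "DACS", "var_ratio", "greater"),
    "H03": ("OS", "DACS", "var_ratio", "greater"),
    "H04": ("CS", "OS", "mean_diff", "greater"),
    "H05": ("DACS", "DA", "mean_diff", "greater"),
    "H06": ("DACS", "CS", "mean_diff", "greater"),
    "H07": ("DA", "OS", "mean_diff", "greater"),
}


def hypothesis_bound(table: pd.DataFrame, name: str,
                     alpha: float = 0.05) -> CIBound:
    """Compute one of the seven published accuracy comparisons."""
    xa, ya, stat, alt = _HYPOTHESES[name]
    x, y = _column(table, xa, "AC"), _column(table, ya, "AC")
    if stat == "var_ratio":
        return var_ratio_lower_bound(x, y, alpha, alternative=alt,
                                     names=(xa, ya))
    return mean_diff_lower_bound(x, y, alpha, names=(xa, ya))


def reproduce_published_analysis(table: Optional[pd.DataFrame] = None) -> Dict:
    """Recompute the full published analysis from a run table.

    Returns the per-arm summary, the seven hypothesis bounds, the two
    headline bounds (accuracy gain of DACS over OS; precision gain as the
    OS/DACS variance ratio), and per-hypothesis flags comparing each
    recomputed bound with its printed value at the printed precision.
    """
    if table is None:
        table = load_run_table()
    summary = summarize(table)
    bounds = {name: hypothesis_bound(table, name) for name in _HYPOTHESES}
    flags = {}
    for name, cib in bounds.items():
        printed = _PRINTED_BOUNDS[name]
        decimals = 2 if name in ("H04", "H05", "H06", "H07") else 1
        flags[name] = {"printed": printed,
                       "recomputed": round(cib.bound, decimals),
                       "reproduces": round(cib.bound, decimals) == printed}
    headline = {
        "accuracy_gain_lower_bound": mean_diff_lower_bound(
            _column(table, "DACS", "AC"), _column(table, "OS", "AC"),
            names=("DACS", "OS")).bound,
        "precision_gain_lower_bound": bounds["H03"].bound,
    }
    return {"summary": summary, "bounds": bounds, "flags": flags,
            "headline": headline}


def normal_probability_points(x: Sequence[float]
                              ) -> Tuple[np.ndarray, np.ndarray]:
    """Ordered values vs normal quantiles (Blom plotting positions)."""
    v = np.sort(np.asarray(x, dtype=float))
    n = len(v)
    q = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    return v, q


def quartiles(x: Sequence[float]) -> Dict[str, float]:
    """Five-number summary backing a boxplot."""
    v = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"min": float(v.min()), "q1": float(q1), "median": float(med),
            "q3": float(q3), "max": float(v.max())}
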