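"""Retention scores and the significance procedure for calling retained IESs.

The retention score (RS) of an IES in a sample is the fraction of
junction-spanning reads that still contain the IES:

    RS = IES+ / (IES+ + IES-)

so RS = 0 means complete excision and RS = 1 complete retention.  To decide
whether an IES is *significantly* retained in an experimental sample relative
to a control, the caller

1. forms the exact (Clopper-Pearson) two-sided confidence interval of the
   control RS at confidence ``alpha`` (default 0.95);
2. computes a one-sided binomial tail p-value for the experimental IES+ count
   against the *upper bound* of that control interval as the null proportion
   — a deliberately conservative null that absorbs residual excision noise in
   the control;
3. adjusts the p-values across all tested IESs with the Benjamini-Hochberg
   step-up procedure; and
4. calls an IES retained when its adjusted p-value is strictly below the
   significance threshold (default 0.05).

IESs without junction coverage in either sample have an undefined RS there
and are excluded from testing (they never enter the BH family).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class RetentionResult:
    """Per-IES outcome of the retention call."""

    ies_id: str
    rs_experiment: float  # NaN when the experimental sample has no coverage
    rs_control: float  # NaN when the control has no coverage
    ci_low: float
    ci_high: float
    pvalue: float
    padj: float
    retained: bool


def retention_score(n_plus: int, n_minus: int) -> float:
    """IES+ / (IES+ + IES-); NaN when the denominator is zero."""
    if n_plus < 0 or n_minus < 0:
        raise ValueError("counts must be non-negative")
    denominator = n_plus + n_minus
    if denominator == 0:
        return math.nan
    return n_plus / denominator


def clopper_pearson(x: int, n: int, alpha: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval at confidence ``alpha``.

    Computed by inverting the binomial CDF through the beta quantile
    identity; the lower bound is 0 when ``x == 0`` and the upper bound 1 when
    ``x == n``.
    """
    if not 0 <= x <= n or n < 1:
        raise ValueError("need 0 <= x <= n and n >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    tail = (1.0 - alpha) / 2.0
    low = 0.0 if x == 0 else float(stats.beta.ppf(tail, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1.0 - tail, x + 1, n - x))
    return low, high


def binomial_tail_pvalue(x: int, n: int, p0: float) -> float:
    """One-sided upper tail P(X >= x) for X ~ Binomial(n, p0).

    Returns 1 when ``x == 0`` (the whole sample space) and never returns 0.
    """
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    if x == 0:
        return 1.0
    p = float(stats.binom.sf(x - 1, n, p0))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def call_retention(
    exp_counts: pd.DataFrame,
    ctrl_counts: pd.DataFrame,
    alpha: float = 0.95,
    threshold: float = 0.05,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Run the full retention-calling procedure over matched count tables.

    Parameters
    ----------
    exp_counts, ctrl_counts
        Frames with columns ``ies_id  n_plus  n_minus`` over the same IES
        catalog (any order).
    alpha
        Confidence level of the control Clopper-Pearson interval.
    threshold
        Adjusted-p cutoff; retained means ``padj < threshold`` (strict).
    min_coverage
        Minimal junction coverage (IES+ + IES-) required in *both* samples
        for an IES to be tested; untested IESs are reported with NA
        statistics and excluded from the BH family.

    Returns
    -------
    DataFrame with columns ``ies_id rs_ctrl ci_low ci_high rs_exp pvalue padj
    retained``, in control-table order.
    """
    for name, df in (("experiment", exp_counts), ("control", ctrl_counts)):
        missing = {"ies_id", "n_plus", "n_minus"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} counts lack columns {missing}")
        if (df[["n_plus", "n_minus"]] < 0).any().any():
            raise ValueError(f"{name} counts contain negative values")
    if set(exp_counts["ies_id"]) != set(ctrl_counts["ies_id"]):
        raise ValueError("experiment and control tables cover different IESs")
    min_coverage = max(1, int(min_coverage))

    merged = ctrl_counts.merge(
        exp_counts, on="ies_id", suffixes=("_ctrl", "_exp"), validate="1:1"
    )
    n_ctrl = (merged["n_plus_ctrl"] + merged["n_minus_ctrl"]).to_numpy()
    n_exp = (merged["n_plus_exp"] + merged["n_minus_exp"]).to_numpy()
    tested = (n_ctrl >= min_coverage) & (n_exp >= min_coverage)

    rows: list[dict] = []
    pvalues: list[float] = []
    for i, row in enumerate(merged.itertuples()):
        xc, nc = int(row.n_plus_ctrl), int(n_ctrl[i])
        xe, ne = int(row.n_plus_exp), int(n_exp[i])
        rs_ctrl = retention_score(xc, int(row.n_minus_ctrl))
        rs_exp = retention_score(xe, int(row.n_minus_exp))
        if tested[i]:
            ci_low, ci_high = clopper_pearson(xc, nc, alpha)
            pvalue = binomial_tail_pvalue(xe, ne, ci_high)
            pvalues.append(pvalue)
        else:
            ci_low = ci_high = pvalue = math.nan
        rows.append(
            {
                "ies_id": row.ies_id,
                "rs_ctrl": rs_ctrl,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "rs_exp": rs_exp,
                "pvalue": pvalue,
            }
        )

    result = pd.DataFrame(rows)
    result["padj"] = math.nan
    if pvalues:
        result.loc[tested, "padj"] = bh_adjust(pvalues)
    result["retained"] = (result["padj"] < threshold).fillna(False)
    return result


def summarize_calls(results: pd.DataFrame) -> dict:
    """One-line summary: tested, retained, retained fraction (of tested)."""
    tested = int(results["pvalue"].notna().sum())
    retained = int(results["retained"].sum())
    return {
        "tested": tested,
        "retained": retained,
        "retained_fraction": retained / tested if tested else math.nan,
    }


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write the results table with 6-decimal fixed precision (stable diffs)."""
    out = results.copy()
    for col in ("rs_ctrl", "ci_low", "ci_high", "rs_exp", "pvalue", "padj"):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else f"{v:.6f}")
    out["retained"] = out["retained"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)


def results_from_records(records: Sequence[RetentionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ies_id": [r.ies_id for r in records],
            "rs_ctrl": [r.rs_control for r in records],
            "ci_low": [r.ci_low for r in records],
            "ci_high": [r.ci_high for r in records],
            "rs_exp": [r.rs_experiment for r in records],
            "pvalue": [r.pvalue for r in records],
            "padj": [r.padj for r in records],
            "retained": [r.retained for r in records],
        }
    )
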