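"""Summary and validation statistics.

Covers the descriptive tables (mean, median, SD, quartiles, stratified by
gender), the inter-rater agreement statistics used to validate automated
counts against manual annotations — ICC(3,k) with its exact-F confidence
interval, the mean-normalized min–max range, and the within-range check of
mask-adjusted automatic counts — plus the Pearson correlation matrix with
p < 0.001 flags and the ordinary least-squares age trend.
"""

from __future__ import annotations

import warnings
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


def summarize(values, strata=None) -> pd.DataFrame:
    """Descriptive statistics per stratum plus the pooled total.

    Reports mean, median, sample SD, and the 25th/75th percentiles (linear
    interpolation between order statistics).  Empty strata are omitted with
    a warning.
    """
    values = np.asarray(values, dtype=float)
    if strata is None:
        strata = np.full(len(values), "all")
    strata = np.asarray(strata)
    rows = []
    labels = list(pd.unique(strata)) + ["total"]
    for lab in labels:
        sel = values if lab == "total" else values[strata == lab]
        sel = sel[~np.isnan(sel)]
        if len(sel) == 0:
            warnings.warn(f"stratum {lab!r} is empty; omitted", stacklevel=2)
            continue
        rows.append(
            {
                "stratum": lab,
                "n": len(sel),
                "mean": float(np.mean(sel)),
                "median": float(np.median(sel)),
                "std": float(np.std(sel, ddof=1)) if len(sel) > 1 else 0.0,
                "p25": float(np.percentile(sel, 25)),
                "p75": float(np.percentile(sel, 75)),
            }
        )
    return pd.DataFrame(rows)


def icc3k(counts: np.ndarray, alpha: float = 0.05) -> Tuple[float, Tuple[float, float]]:
    """ICC(3,k): two-way mixed, consistency, average of k raters.

    From the two-way ANOVA decomposition of an n x k matrix (targets by
    raters)::

        ICC(3,k) = (MS_targets - MS_error) / MS_targets

    with the (1 - alpha) confidence interval from the exact F bounds of
    Shrout & Fleiss.  Consistency form: invariant under per-rater additive
    offsets and common rescaling.

    Raises
    ------
    ValueError
        When fewer than 2 targets or raters, or when the between-target
        variance is zero (the coefficient is undefined).
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("counts must be an n x k matrix with n, k >= 2")
    if np.isnan(x).any():
        raise ValueError("counts must have no missing entries")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_err = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    df_rows = n - 1
    df_err = (n - 1) * (k - 1)
    msr = ss_rows / df_rows
    mse = ss_err / df_err
    if msr <= 0:
        raise ValueError("zero between-target variance: ICC undefined")
    icc = (msr - mse) / msr
    if mse == 0:
        return 1.0, (1.0, 1.0)
    f_obs = msr / mse
    fl = f_obs / sps.f.ppf(1 - alpha / 2, df_rows, df_err)
    fu = f_obs * sps.f.ppf(1 - alpha / 2, df_err, df_rows)
    return float(icc), (float(1 - 1 / fl), float(1 - 1 / fu))


def normalized_range(counts) -> float:
    """Min–max range of one patch's counts, normalized by their mean."""
    c = np.asarray(counts, dtype=float)
    m = c.mean()
    if m <= 0:
        raise ValueError("mean count must be positive")
    return float((c.max() - c.min()) / m)


def within_range_check(
    auto_count: float, manual_counts, unmasked_fraction: float = 1.0
) -> bool:
    """Whether the mask-adjusted automatic count falls inside the manual range.

    The automatic count is taken over the unmasked part of the patch only,
    so it is projected to a full-patch count by dividing by the unmasked
    fraction before comparing against [min, max] of the manual counts.
    """
    if not 0 < unmasked_fraction <= 1:
        raise ValueError("unmasked_fraction must lie in (0, 1]")
    m = np.asarray(manual_counts, dtype=float)
    adjusted = auto_count / unmasked_fraction
    return bool(m.min() <= adjusted <= m.max())


def pearson_matrix(
    data: pd.DataFrame, flag_p: float = 0.001
) -> Dict[str, pd.DataFrame]:
    """Pairwise Pearson correlations with significance flags.

    Uses pairwise-complete observations.  Returns ``{"r", "p", "flag"}``
    DataFrames; ``flag`` is True where p < ``flag_p``.  Pairs involving a
    zero-variance column (or fewer than 3 complete pairs) are NaN.
    """
    cols = list(data.columns)
    m = len(cols)
    r = pd.DataFrame(np.eye(m), index=cols, columns=cols)
    p = pd.DataFrame(np.full((m, m), np.nan), index=cols, columns=cols)
    for i in range(m):
        for j in range(i + 1, m):
            xy = data[[cols[i], cols[j]]].dropna().to_numpy(dtype=float)
            if len(xy) < 3 or np.std(xy[:, 0]) == 0 or np.std(xy[:, 1]) == 0:
                rij, pij = np.nan, np.nan
            else:
                res = sps.pearsonr(xy[:, 0], xy[:, 1])
                rij, pij = float(res.statistic), float(res.pvalue)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    flag = p < flag_p
    return {"r": r, "p": p, "flag": flag}


def age_trend(density, age):
    """Ordinary least-squares linear trend of density against age.

    Returns the :func:`scipy.stats.linregress` result (slope, intercept,
    rvalue, pvalue, stderr); the sign of the slope is the quantity of
    interest.
    """
    density = np.asarray(density, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(age) < 3:
        raise ValueError("need at least 3 eyes for an age trend")
    if np.std(age) == 0:
        raise ValueError("degenerate age variable: no variance")
    return sps.linregress(age, density)
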