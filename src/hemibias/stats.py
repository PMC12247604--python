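"""Paired tests, effect sizes, and Holm-Bonferroni family correction.

The bias analysis compares Fisher-z connectivity values across subjects
with paired-sample t-tests and reports the paired effect size

    d_avg = mean(a - b) / ((sd(a) + sd(b)) / 2),

which scales the mean difference by the average of the two conditions'
standard deviations rather than the SD of the differences, so it is not
inflated when the two conditions are highly correlated.

Holm-Bonferroni families are sized per network as ``n_regions * 2`` (two
intrahemispheric comparison types per region: vs. the network average and
vs. the highest-correlating pairing): 8 for the four-region face network,
6 for the three-region scene network, 12 for the six-region early visual
network.  ``family_size`` may exceed the number of p-values actually
supplied, in which case the step-down factors start at the full family
size (a list shorter than its family is corrected as conservatively as the
full family would be).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def paired_t_davg(a, b) -> tuple[float, int, float, float]:
    """Two-sided paired t-test with the averaged-SD effect size.

    Returns ``(t, df, p, d_avg)`` with ``t = mean(d) / (sd(d)/sqrt(n))``,
    ``d = a - b``, ``df = n - 1`` and sample SDs using n-1 denominators.

    Raises
    ------
    ValueError
        If fewer than 3 pairs, unequal lengths, or zero-variance
        differences (degenerate contrast).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D arrays of equal length")
    n = a.size
    if n < 3:
        raise ValueError("paired t-test needs at least 3 pairs")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("inputs contain NaN")
    d = a - b
    sd_d = d.std(ddof=1)
    if sd_d == 0:
        raise ValueError("degenerate contrast: differences have zero variance")
    t = d.mean() / (sd_d / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    denom = 0.5 * (a.std(ddof=1) + b.std(ddof=1))
    d_avg = d.mean() / denom if denom > 0 else np.nan
    return float(t), int(df), float(p), float(d_avg)


def holm_adjust(pvals, family_size: int | None = None) -> np.ndarray:
    """Step-down Holm-Bonferroni adjustment against a family of given size.

    The k-th smallest p-value (1-based) is multiplied by
    ``family_size - k + 1``; a running maximum enforces monotonicity and
    values are capped at 1.  Output is in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if family_size is None else int(family_size)
    if m < p.size:
        raise ValueError("family_size must be >= the number of p-values")
    order = np.argsort(p, kind="stable")
    adjusted = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):  # rank 0 => multiplier m
        running = max(running, min(1.0, p[idx] * (m - rank)))
        adjusted[idx] = running
    return adjusted


def family_size(layout) -> int:
    """Holm family size for a network: regions x 2 comparison types."""
    return layout.n_regions * 2


def welch_t(a, b) -> tuple[float, float, float]:
    """Two-sided Welch unequal-variance t-test; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        raise ValueError("degenerate contrast: both groups have zero variance")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def within_between_contrast(within, between, method: str = "paired") -> dict:
    """Compare within-subject and between-subject bias differences.

    ``within`` and ``between`` are per-subject difference vectors (e.g.
    interhemispheric Zr minus highest intrahemispheric Zr from each
    analysis).  ``method="paired"`` (default) pairs the two vectors subject
    by subject — appropriate because the same subjects appear in both
    analyses; ``method="welch"`` treats them as independent groups with
    unequal variances.  The method used is recorded in the result.
    """
    if method == "paired":
        t, df, p, d_avg = paired_t_davg(within, between)
        return {"t": t, "df": df, "p": p, "d_avg": d_avg, "method": "paired"}
    if method == "welch":
        t, df, p = welch_t(within, between)
        return {"t": t, "df": df, "p": p, "d_avg": np.nan, "method": "welch"}
    raise ValueError("method must be 'paired' or 'welch'")
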