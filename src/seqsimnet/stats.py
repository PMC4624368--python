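"""Report statistics: two-sample KS and two-proportion comparisons.

The tested contract is the statistic itself (implemented explicitly so the
direction convention is unambiguous); p-values are delegated to scipy.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps


def ks_statistic(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two_sided",
) -> float:
    """Two-sample Kolmogorov–Smirnov D.

    ``alternative``:

    * ``"a_below_b"`` — D⁺ = sup_x (F_a(x) − F_b(x)), large when sample a is
      stochastically *smaller* (its ECDF sits above b's);
    * ``"b_below_a"`` — the mirror image;
    * ``"two_sided"`` — sup of the absolute difference.
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    diff = fa - fb
    if alternative == "a_below_b":
        return float(np.max(diff))
    if alternative == "b_below_a":
        return float(np.max(-diff))
    if alternative == "two_sided":
        return float(np.max(np.abs(diff)))
    raise ValueError(f"unknown alternative {alternative!r}")


def ks_test(sample_a, sample_b, alternative: str = "two_sided") -> tuple[float, float]:
    """(D, p) with the p-value delegated to scipy's two-sample test."""
    d = ks_statistic(sample_a, sample_b, alternative)
    scipy_alt = {"two_sided": "two-sided", "a_below_b": "greater", "b_below_a": "less"}
    res = sps.ks_2samp(sample_a, sample_b, alternative=scipy_alt[alternative])
    return d, float(res.pvalue)


def proportion_report(counts: Sequence[Sequence[int]]) -> dict:
    """Compare the 'positive' proportion across two strata.

    ``counts`` is a 2x2 table: rows = strata, columns = (positive, negative).
    Returns proportions, their difference (row 0 minus row 1), and the
    Pearson chi-square statistic without continuity correction (the plain
    textbook statistic); a zero row/column margin is flagged and leaves the
    statistic undefined.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    row_totals = table.sum(axis=1)
    p = [table[i, 0] / row_totals[i] if row_totals[i] else float("nan") for i in range(2)]
    out = {
        "proportion_a": p[0],
        "proportion_b": p[1],
        "difference": p[0] - p[1],
        "chi2": None,
        "pvalue": None,
        "zero_margin": bool((row_totals == 0).any() or (table.sum(axis=0) == 0).any()),
    }
    if not out["zero_margin"]:
        chi2, pval, _, _ = sps.chi2_contingency(table, correction=False)
        out["chi2"] = float(chi2)
        out["pvalue"] = float(pval)
    return out
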