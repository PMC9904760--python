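"""Cell-type composition summaries and proportion-shift testing.

Between-condition shifts in cell-type proportions are assessed with a
pooled two-proportion z-test (Yates continuity correction, the classical
prop-test default) per cell type, with step-down Holm adjustment across the
types of one comparison and significance called at adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class CompositionError(ValueError):
    pass


def compute_composition(
    annotations: pd.Series, metadata: pd.DataFrame, by: str = "donor"
) -> pd.DataFrame:
    """Counts and within-group proportions of each label per donor (or other
    grouping column); "not assigned" is kept as its own category."""
    if by not in metadata.columns:
        raise CompositionError(f"metadata lacks a {by!r} column")
    if not annotations.index.equals(metadata.index):
        missing = annotations.index.difference(metadata.index)
        if len(missing) or not annotations.index.isin(metadata.index).all():
            raise CompositionError("metadata does not cover all annotated cells")
        metadata = metadata.loc[annotations.index]
    groups = metadata[by]
    if groups.isna().any():
        raise CompositionError(f"cells with missing {by!r} metadata")
    counts = (
        pd.crosstab(groups, annotations)
        .rename_axis(index=by, columns="cell_type")
    )
    if (counts.sum(axis=1) == 0).any():
        empty = counts.index[counts.sum(axis=1) == 0][0]
        raise CompositionError(f"group {empty!r} has no cells")
    long = counts.stack().rename("count").reset_index()
    totals = counts.sum(axis=1)
    long["proportion"] = long["count"] / long[by].map(totals).to_numpy()
    return long


def pooled_counts(table: pd.DataFrame, by: str = "donor") -> pd.Series:
    """Pool counts over donors: one total per cell type."""
    return table.groupby("cell_type", observed=True)["count"].sum()


def _two_prop_z(s1, n1, s2, n2, continuity=True):
    """Vectorized pooled two-proportion z-test p-value."""
    s1, n1, s2, n2 = (np.asarray(a, dtype=float) for a in (s1, n1, s2, n2))
    p1, p2 = s1 / n1, s2 / n2
    pool = (s1 + s2) / (n1 + n2)
    var = pool * (1 - pool) * (1 / n1 + 1 / n2)
    diff = np.abs(p1 - p2)
    if continuity:
        diff = np.maximum(diff - 0.5 * (1 / n1 + 1 / n2), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, diff / np.sqrt(var), 0.0)
    return np.clip(2 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)


def two_proportion_test(
    a: tuple, b: tuple, continuity: bool = True, method: str = "z"
) -> float:
    """Two-sided test of equal proportions for (successes, total) pairs.

    ``method='z'`` is the pooled z-test with Yates continuity correction
    (chi-square equivalent); ``method='fisher'`` uses Fisher's exact test.
    """
    (s1, n1), (s2, n2) = a, b
    for s, n in ((s1, n1), (s2, n2)):
        if n <= 0:
            raise CompositionError("totals must be positive")
        if s < 0 or s > n:
            raise CompositionError("successes must lie in [0, total]")
    if method == "fisher":
        table = [[s1, n1 - s1], [s2, n2 - s2]]
        return float(stats.fisher_exact(table)[1])
    if method != "z":
        raise CompositionError(f"unknown method {method!r}")
    return float(_two_prop_z(s1, n1, s2, n2, continuity)[()])


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm (Bonferroni-Holm) adjustment.

    Sort ascending, multiply the i-th smallest by (m - i), enforce
    monotonicity by running maximum, cap at 1, restore input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise CompositionError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    m = p.size
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class ProportionTestResult:
    cell_type: str
    a: tuple
    b: tuple
    p_raw: float
    p_adjusted: float
    significant: bool


def test_composition_shift(
    a: pd.DataFrame,
    b: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "z",
) -> pd.DataFrame:
    """Per-type two-proportion test on pooled condition counts, Holm-adjusted
    across the cell types of the comparison.

    ``a`` and ``b`` are composition tables from :func:`compute_composition`.
    """
    ca, cb = pooled_counts(a), pooled_counts(b)
    if len(ca.index.intersection(cb.index)) == 0:
        raise CompositionError("the two tables share no cell types")
    types = sorted(ca.index.union(cb.index))
    ca = ca.reindex(types, fill_value=0)
    cb = cb.reindex(types, fill_value=0)
    na, nb = int(ca.sum()), int(cb.sum())
    raw = np.array(
        [
            two_proportion_test((int(ca[t]), na), (int(cb[t]), nb), method=method)
            for t in types
        ]
    )
    adj = holm_adjust(raw)
    return pd.DataFrame(
        {
            "cell_type": types,
            "count_a": ca.to_numpy(),
            "total_a": na,
            "count_b": cb.to_numpy(),
            "total_b": nb,
            "p_raw": raw,
            "p_adjusted": adj,
            "significant": adj < alpha,
        }
    ).set_index("cell_type")
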