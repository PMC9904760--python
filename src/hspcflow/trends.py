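"""Gene-expression trends along pseudotime with branch-probability weights.

Trends are penalized cubic smoothing splines of expression on a provided
pseudotime, with each cell weighted by its probability of reaching the
branch's terminal state (the smoothing penalty is chosen by generalized
cross-validation).  Fitted trends are evaluated on a fixed grid, clustered
by correlation distance, and compared between conditions with a two-sample
Wilcoxon rank-sum test on the grid values, Holm-adjusted across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import BSpline
from scipy.spatial.distance import pdist

from .composition import holm_adjust

FLAT_CLUSTER = "flat"


class TrendError(ValueError):
    pass


@dataclass
class GeneTrend:
    gene: str
    branch: str
    grid: np.ndarray
    values: np.ndarray
    condition: str = ""


def _penalized_spline(t, y, w, n_basis: int = 25, lam_grid=None):
    """Weighted cubic P-spline (second-difference penalty) with the penalty
    strength chosen by generalized cross-validation over a log grid.

    Returns a callable evaluating the fitted curve.  Constants and straight
    lines lie in the penalty null space, so noiseless constant/linear data
    are reproduced exactly at any penalty.
    """
    lo, hi = float(t[0]), float(t[-1])
    m = int(min(n_basis, max(4, np.unique(t).size - 1)))
    degree = 3
    inner = np.linspace(lo, hi, m - degree + 1)
    knots = np.concatenate([np.full(degree, lo), inner, np.full(degree, hi)])
    B = BSpline.design_matrix(t, knots, degree).toarray()
    ws = w / w.mean()  # conditioning only; the fit is scale-invariant in w
    BtW = B.T * ws
    A = BtW @ B
    D = np.diff(np.eye(m), n=2, axis=0)
    P = D.T @ D
    A_flat = A + 1e-10 * np.eye(m)
    if lam_grid is None:
        lam_grid = np.logspace(-6, 4, 31)
    n_eff = ws.sum()
    best = (np.inf, None)
    Bty = BtW @ y
    for lam in lam_grid:
        C = A_flat + lam * P
        try:
            Cinv = np.linalg.inv(C)
        except np.linalg.LinAlgError:  # pragma: no cover
            continue
        coef = Cinv @ Bty
        resid = y - B @ coef
        rss = float(np.sum(ws * resid**2))
        edf = float(np.trace(Cinv @ A))
        denom = max(n_eff - edf, 1e-8)
        gcv = n_eff * rss / denom**2
        if gcv < best[0]:
            best = (gcv, coef)
    if best[1] is None:  # pragma: no cover - defensive
        raise TrendError("penalized spline fit failed on every penalty")
    coef = best[1]
    spline = BSpline(knots, coef, degree, extrapolate=False)

    def evaluate(x):
        return spline(np.clip(x, lo, hi))

    return evaluate


def fit_trend(
    expression,
    pseudotime,
    weights=None,
    branch: str = "",
    gene: str = "",
    condition: str = "",
    grid_size: int = 500,
    min_cells: int = 30,
) -> GeneTrend:
    """Weighted penalized-spline fit of one gene's expression on pseudotime.

    ``weights`` are the branch probabilities, used as observation weights;
    cells with zero weight do not influence the fit.  The smoothing penalty
    is chosen by generalized cross-validation.  The trend is evaluated on
    ``grid_size`` equally spaced points spanning the weighted support of
    pseudotime.
    """
    expr = np.asarray(expression, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    if not np.isfinite(t).all():
        raise TrendError("pseudotime contains non-finite values")
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise TrendError("weights must be non-negative")
    mask = w > 0
    if not mask.any():
        raise TrendError("all branch weights are zero")
    expr, t, w = expr[mask], t[mask], w[mask]
    if t.size < min_cells:
        raise TrendError(
            f"only {t.size} cells with positive branch weight (minimum {min_cells})"
        )
    if np.ptp(t) == 0:
        raise TrendError("pseudotime is constant over the weighted cells")

    order = np.argsort(t, kind="mergesort")
    t, expr, w = t[order], expr[order], w[order]
    if np.unique(t).size < 5:
        raise TrendError("need at least 5 distinct pseudotime values")

    spline = _penalized_spline(t, expr, w)
    grid = np.linspace(t[0], t[-1], grid_size)
    values = spline(grid)
    return GeneTrend(
        gene=gene, branch=branch, grid=grid, values=np.asarray(values),
        condition=condition,
    )


def fit_trends(
    expression: pd.DataFrame,
    trajectory: pd.DataFrame,
    branch: str,
    genes=None,
    condition: str = "",
    grid_size: int = 500,
) -> dict:
    """Fit trends for many genes.

    ``expression`` is cells x genes (normalized); ``trajectory`` carries a
    ``pseudotime`` column and one branch-probability column per branch
    (``bp_<branch>`` or the bare branch name).
    """
    bp_col = f"bp_{branch}" if f"bp_{branch}" in trajectory.columns else branch
    if bp_col not in trajectory.columns:
        raise TrendError(f"trajectory lacks branch probabilities for {branch!r}")
    if "pseudotime" not in trajectory.columns:
        raise TrendError("trajectory lacks a pseudotime column")
    traj = trajectory.loc[expression.index]
    t = traj["pseudotime"].to_numpy()
    w = traj[bp_col].to_numpy()
    genes = list(genes) if genes is not None else list(expression.columns)
    return {
        g: fit_trend(
            expression[g].to_numpy(), t, w, branch=branch, gene=g,
            condition=condition, grid_size=grid_size,
        )
        for g in genes
    }


def trend_matrix(trends: dict) -> pd.DataFrame:
    """Stack trends sharing a grid into a genes x grid-points frame."""
    genes = list(trends)
    grid = trends[genes[0]].grid
    for g in genes[1:]:
        if not np.array_equal(trends[g].grid, grid):
            raise TrendError("trends do not share a grid")
    return pd.DataFrame(
        np.vstack([trends[g].values for g in genes]), index=genes, columns=grid
    )


def cluster_trends(trends: dict, k: int) -> pd.Series:
    """Group trends by shape: z-score each across the grid, cluster by
    correlation distance with average-linkage hierarchy cut at ``k``.

    Constant trends go to a dedicated "flat" group (with a warning); other
    cluster labels are "1".."k"."""
    if k < 2:
        raise TrendError("k must be at least 2")
    mat = trend_matrix(trends)
    vals = mat.to_numpy()
    sd = vals.std(axis=1)
    flat = sd < 1e-12
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant trend(s) assigned to the 'flat' group",
            UserWarning,
        )
    labels = pd.Series(index=mat.index, dtype=object)
    labels[mat.index[flat]] = FLAT_CLUSTER
    active = mat.index[~flat]
    if len(active) == 1:
        labels[active] = "1"
    elif len(active) > 1:
        z = (vals[~flat] - vals[~flat].mean(axis=1, keepdims=True)) / sd[
            ~flat, None
        ]
        kk = min(k, len(active))
        link = linkage(pdist(z, metric="correlation"), method="average")
        assign = fcluster(link, t=kk, criterion="maxclust")
        labels[active] = assign.astype(str)
    return labels.rename("cluster")


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

def _wilcoxon_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p over all C(n+m, n) group assignments.

    Handles ties (mid-ranks); the null distribution of the rank sum is built
    by dynamic programming over doubled ranks (integers even with ties);
    p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks2 = np.round(2 * stats.rankdata(pooled)).astype(np.int64)
    s_obs = int(ranks2[:n].sum())
    max_sum = int(ranks2.sum())
    # dp[k, s] = number of size-k subsets of the pooled ranks with doubled
    # rank sum s
    dp = np.zeros((n + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(n, 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    dist = dp[n]
    total = dist.sum()
    count_le = dist[: s_obs + 1].sum()
    count_ge = dist[s_obs:].sum()
    return float(min(1.0, 2.0 * min(count_le, count_ge) / total))


def trend_wilcoxon(a, b, exact_max: int = 10) -> float:
    """Two-sample Wilcoxon rank-sum p-value between two vectors of fitted
    trend values: exact enumeration when both lengths are at most
    ``exact_max``, tie-corrected normal approximation with continuity
    correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise TrendError("inputs must be one-dimensional")
    if len(a) <= exact_max and len(b) <= exact_max:
        return _wilcoxon_exact_p(a, b)
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")[1]
    )


def significance_tier(p_adjusted: float) -> str:
    if p_adjusted < 0.001:
        return "***"
    if p_adjusted < 0.01:
        return "**"
    if p_adjusted < 0.05:
        return "*"
    return "NS"


def compare_trends(trends_a: dict, trends_b: dict) -> pd.DataFrame:
    """Per-gene Wilcoxon comparison of fitted trend curves between two
    conditions, Holm-adjusted across the shared gene set."""
    genes = [g for g in trends_a if g in trends_b]
    if not genes:
        raise TrendError("no shared genes between the two trend sets")
    raw = []
    for g in genes:
        ta, tb = trends_a[g], trends_b[g]
        if len(ta.values) != len(tb.values):
            raise TrendError(f"grid length mismatch for gene {g!r}")
        raw.append(trend_wilcoxon(ta.values, tb.values))
    raw = np.asarray(raw)
    adj = holm_adjust(raw)
    return pd.DataFrame(
        {
            "gene": genes,
            "p_raw": raw,
            "p_adjusted": adj,
            "tier": [significance_tier(p) for p in adj],
        }
    ).set_index("gene")


def compare_trend_pair(trend_a: GeneTrend, trend_b: GeneTrend):
    """Single-gene comparison (a family of one); returns (p, tier)."""
    if len(trend_a.values) != len(trend_b.values):
        raise TrendError("grid length mismatch")
    p = trend_wilcoxon(trend_a.values, trend_b.values)
    return p, significance_tier(p)
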