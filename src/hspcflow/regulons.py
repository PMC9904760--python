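"""Post-inference regulon analytics.

Operates on regulon-by-cell AUC activity matrices and TF->target edge lists
produced by an upstream GRN pipeline: batch centering, two-component
Gaussian-mixture binarization of activity, percent-active summaries per
cluster, regulon specificity scores (RSS, a Jensen-Shannon-based score in
[0, 1]), top-k regulon selection, and third-quartile network trimming.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import jensenshannon
from scipy.stats import norm
from sklearn.mixture import GaussianMixture


class RegulonError(ValueError):
    pass


def _check_labels(auc: pd.DataFrame, labels: pd.Series, what: str) -> pd.Series:
    labels = labels.reindex(auc.columns)
    if labels.isna().any():
        raise RegulonError(f"every cell needs a {what} label")
    return labels


def batch_center(auc: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Remove per-batch offsets from each regulon's activity.

    Per regulon, subtracts the batch mean and restores the original grand
    mean (exact removal of additive batch main effects, the one-factor
    analogue of the usual linear-model batch correction).
    """
    batches = _check_labels(auc, batches, "batch")
    sizes = batches.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        warnings.warn(
            f"batch(es) {list(small.index)} have fewer than 2 cells; offsets "
            "are still estimated",
            UserWarning,
        )
    vals = auc.to_numpy(dtype=float)
    out = np.empty_like(vals)
    grand = vals.mean(axis=1, keepdims=True)
    for b in sizes.index:
        cols = np.flatnonzero((batches == b).to_numpy())
        bmean = vals[:, cols].mean(axis=1, keepdims=True)
        out[:, cols] = vals[:, cols] - bmean + grand
    return pd.DataFrame(out, index=auc.index, columns=auc.columns)


def _gmm_threshold(x: np.ndarray, random_state: int = 0):
    """Two-component 1D Gaussian mixture threshold, or None if BIC favors a
    single component (unimodal column)."""
    X = x.reshape(-1, 1)
    gm2 = GaussianMixture(n_components=2, random_state=random_state, n_init=3).fit(X)
    gm1 = GaussianMixture(n_components=1, random_state=random_state).fit(X)
    if gm1.bic(X) <= gm2.bic(X):
        return None
    means = gm2.means_.ravel()
    sds = np.sqrt(gm2.covariances_.ravel())
    wts = gm2.weights_
    lo, hi = np.argsort(means)

    def resp_hi(v):
        d_hi = wts[hi] * norm.pdf(v, means[hi], sds[hi])
        d_lo = wts[lo] * norm.pdf(v, means[lo], sds[lo])
        return d_hi / (d_hi + d_lo) - 0.5

    m_lo, m_hi = means[lo], means[hi]
    try:
        if resp_hi(m_lo) < 0 < resp_hi(m_hi):
            return float(brentq(resp_hi, m_lo, m_hi))
    except ValueError:  # pragma: no cover - numerical corner
        pass
    return float((m_lo + m_hi) / 2)


def binarize(auc: pd.DataFrame, random_state: int = 0):
    """Per-regulon on/off states from a bimodal fit of the AUC values.

    A two-component Gaussian mixture is fitted per regulon; the threshold is
    where the posterior responsibility of the high component crosses 0.5,
    and a cell is active (1) iff its value exceeds the threshold.  Columns
    that a BIC check deems unimodal (or constant) are all-zero, with a
    warning.  Returns (binary frame, per-regulon thresholds; NaN where no
    threshold was fitted).
    """
    if auc.shape[1] < 20:
        raise RegulonError("binarization needs at least 20 cells")
    binary = pd.DataFrame(
        0, index=auc.index, columns=auc.columns, dtype=np.int8
    )
    thresholds = pd.Series(np.nan, index=auc.index, name="threshold")
    for r in auc.index:
        x = auc.loc[r].to_numpy(dtype=float)
        if x.std() < 1e-12:
            warnings.warn(f"regulon {r!r} is constant; all cells set to 0",
                          UserWarning)
            continue
        thr = _gmm_threshold(x, random_state)
        if thr is None:
            warnings.warn(
                f"regulon {r!r} looks unimodal; all cells set to 0", UserWarning
            )
            continue
        thresholds[r] = thr
        binary.loc[r] = (x > thr).astype(np.int8)
    return binary, thresholds


def percent_active(binary: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """Percent of cells with state 1 per regulon and cluster (0-100)."""
    clusters = _check_labels(binary, clusters, "cluster")
    sizes = clusters.value_counts()
    if (sizes == 0).any():
        raise RegulonError("empty cluster")
    out = {}
    for c in sorted(sizes.index):
        cols = clusters.index[(clusters == c).to_numpy()]
        # 100 * count / size, kept in this exact form so the result matches
        # direct counting bit for bit
        out[c] = 100.0 * binary[cols].sum(axis=1) / len(cols)
    return pd.DataFrame(out)


def rss(auc: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """Regulon specificity score per regulon and cluster.

    RSS(R, C) = 1 - sqrt(JSD(p_R, p_C)) with base-2 Jensen-Shannon
    divergence, where p_R is the regulon's activity normalized to a
    probability vector over cells and p_C the normalized indicator of
    membership in cluster C.  All-zero regulons yield NaN.
    """
    clusters = _check_labels(auc, clusters, "cluster")
    vals = auc.to_numpy(dtype=float)
    if (vals < 0).any():
        raise RegulonError("RSS requires non-negative activity values")
    names = sorted(clusters.unique())
    out = pd.DataFrame(np.nan, index=auc.index, columns=names)
    indicators = {
        c: ((clusters == c).to_numpy(dtype=float) / (clusters == c).sum())
        for c in names
    }
    for i, r in enumerate(auc.index):
        total = vals[i].sum()
        if total == 0:
            warnings.warn(f"regulon {r!r} has all-zero activity; RSS undefined",
                          UserWarning)
            continue
        p_r = vals[i] / total
        for c in names:
            out.loc[r, c] = 1.0 - jensenshannon(p_r, indicators[c], base=2)
    return out


def top_regulons(rss_table: pd.DataFrame, k: int = 5) -> dict:
    """The k regulons with highest RSS per cluster; ties broken by name."""
    if k < 1:
        raise RegulonError("k must be at least 1")
    avail = rss_table.dropna(how="all")
    if len(avail) < k:
        warnings.warn(
            f"only {len(avail)} regulons available for top-{k} selection",
            UserWarning,
        )
    out = {}
    for c in rss_table.columns:
        col = avail[c].dropna()
        ranked = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
        out[c] = [name for name, _ in ranked[:k]]
    return out


def trim_network(edges: pd.DataFrame):
    """Keep, per regulon, only targets with importance strictly above the
    regulon's third quartile (linear-interpolation quantile).

    If the strict filter would empty a regulon, its single highest-importance
    target is kept (warning).  Returns (trimmed edge frame, DiGraph); the
    quantile convention is recorded in ``frame.attrs``.
    """
    required = {"TF", "target", "importance"}
    if not required.issubset(edges.columns):
        raise RegulonError(f"edge list needs columns {sorted(required)}")
    if (edges["importance"] <= 0).any():
        raise RegulonError("importance scores must be positive")
    dup = edges.duplicated(subset=["TF", "target"])
    if dup.any():
        raise RegulonError("duplicate targets within a regulon")
    kept = []
    for tf, grp in edges.groupby("TF", sort=True):
        q3 = float(np.quantile(grp["importance"].to_numpy(), 0.75))
        sel = grp[grp["importance"] > q3]
        if sel.empty:
            warnings.warn(
                f"Q3 trim empties regulon {tf!r}; keeping its top target",
                UserWarning,
            )
            sel = grp.sort_values(
                ["importance", "target"], ascending=[False, True]
            ).head(1)
        kept.append(sel)
    trimmed = pd.concat(kept).reset_index(drop=True)
    trimmed.attrs["quantile_method"] = "linear interpolation between order statistics"
    graph = nx.from_pandas_edgelist(
        trimmed, source="TF", target="target", edge_attr="importance",
        create_using=nx.DiGraph,
    )
    return trimmed, graph
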