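"""Cell filtering, library-size log-normalization, and HVG selection.

Filtering removes presumed doublets via per-sample gene/UMI ceilings and
dying or anomalous cells via mitochondrial-content bounds.  Normalization
divides counts by the per-cell total, multiplies by a fixed scale factor
(default 10,000) and applies log1p.  Highly variable genes are ranked by
standardized variance after a variance-stabilizing mean-variance fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess


class QCError(ValueError):
    pass


@dataclass
class QCThresholds:
    """Per-sample QC rules.

    ``max_genes_per_cell`` and ``max_umis_per_cell`` are the doublet ceilings
    (chosen per sample from the observed distributions); cells with
    mitochondrial content above ``mito_max_pct`` (dying cells) or, when set,
    below ``mito_min_pct`` (an anomalous low-mito population) are removed.
    """

    max_genes_per_cell: int
    max_umis_per_cell: int
    mito_max_pct: float = 5.0
    mito_min_pct: float | None = None
    mito_gene_prefix: str = "MT-"

    def __post_init__(self):
        if self.max_genes_per_cell <= 0 or self.max_umis_per_cell <= 0:
            raise QCError("gene/UMI ceilings must be positive")
        if not 0 < self.mito_max_pct <= 100:
            raise QCError("mito_max_pct must lie in (0, 100]")
        if self.mito_min_pct is not None:
            if not 0 <= self.mito_min_pct < 100:
                raise QCError("mito_min_pct must lie in [0, 100)")
            if self.mito_min_pct >= self.mito_max_pct:
                raise QCError("mito_min_pct must be below mito_max_pct")


def _mito_mask(adata: ad.AnnData, prefix: str) -> np.ndarray:
    if "is_mito" in adata.var.columns:
        return adata.var["is_mito"].to_numpy(dtype=bool)
    return np.array([g.startswith(prefix) for g in adata.var_names])


def cell_stats(adata: ad.AnnData, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell detected genes, total UMIs and mitochondrial percentage."""
    X = sp.csr_matrix(adata.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    mito = _mito_mask(adata, mito_prefix)
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros(X.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(totals > 0, 100.0 * mito_counts / totals, 0.0)
    return pd.DataFrame(
        {"n_genes": n_genes, "n_umis": totals.astype(np.int64), "mito_pct": mito_pct},
        index=adata.obs_names,
    )


def suggest_thresholds(
    adata: ad.AnnData, by: str = "donor", quantile: float = 0.99
) -> pd.DataFrame:
    """Suggest per-sample gene/UMI ceilings at a high quantile of the
    per-sample distributions (a starting point for the customized ceilings)."""
    stats = cell_stats(adata)
    stats[by] = adata.obs[by].to_numpy()
    q = stats.groupby(by)[["n_genes", "n_umis"]].quantile(quantile)
    return q.rename(
        columns={"n_genes": "max_genes_per_cell", "n_umis": "max_umis_per_cell"}
    ).round().astype(int)


def filter_cells(adata: ad.AnnData, thresholds: QCThresholds):
    """Apply QC rules; returns (filtered AnnData, per-cell report).

    The report has one row per input cell with its statistics, whether it was
    kept, and the semicolon-joined names of every rule it failed.
    """
    stats = cell_stats(adata, thresholds.mito_gene_prefix)
    mito = _mito_mask(adata, thresholds.mito_gene_prefix)
    has_mito = bool(mito.any())
    if not has_mito:
        warnings.warn(
            "no mitochondrial genes found; mitochondrial rules skipped", UserWarning
        )

    reasons = [[] for _ in range(adata.n_obs)]
    empty = stats["n_umis"].to_numpy() == 0
    too_many_genes = stats["n_genes"].to_numpy() > thresholds.max_genes_per_cell
    too_many_umis = stats["n_umis"].to_numpy() > thresholds.max_umis_per_cell
    for i in np.flatnonzero(empty):
        reasons[i].append("empty")
    for i in np.flatnonzero(too_many_genes & ~empty):
        reasons[i].append("max_genes")
    for i in np.flatnonzero(too_many_umis & ~empty):
        reasons[i].append("max_umis")
    if has_mito:
        pct = stats["mito_pct"].to_numpy()
        for i in np.flatnonzero((pct > thresholds.mito_max_pct) & ~empty):
            reasons[i].append("mito_high")
        if thresholds.mito_min_pct is not None:
            for i in np.flatnonzero((pct < thresholds.mito_min_pct) & ~empty):
                reasons[i].append("mito_low")

    keep = np.array([not r for r in reasons])
    report = stats.copy()
    report["kept"] = keep
    report["failed_rules"] = [";".join(r) for r in reasons]
    report.index.name = "cell_id"
    return adata[keep].copy(), report


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """value[g,c] = ln(1 + count[g,c] * scale_factor / library_size_c).

    Library sizes are stored in ``obs['library_size']`` so the transform is
    invertible.  Raises on any zero-count cell, naming it.
    """
    if scale_factor <= 0:
        raise QCError("scale_factor must be positive")
    X = sp.csr_matrix(adata.X, dtype=np.float64)
    lib = np.asarray(X.sum(axis=1)).ravel()
    if (lib == 0).any():
        bad = adata.obs_names[np.flatnonzero(lib == 0)[0]]
        raise QCError(f"cell {bad!r} has zero library size; filter first")
    scaled = sp.diags(scale_factor / lib) @ X
    scaled.data = np.log1p(scaled.data)
    out = ad.AnnData(X=scaled.tocsr(), obs=adata.obs.copy(), var=adata.var.copy())
    out.obs["library_size"] = lib
    out.uns["scale_factor"] = float(scale_factor)
    out.uns["log_base"] = "e"
    return out


def invert_log_normalize(norm: ad.AnnData) -> np.ndarray:
    """Round-trip back to raw counts using the stored library sizes."""
    lib = norm.obs["library_size"].to_numpy()
    scale = float(norm.uns["scale_factor"])
    X = sp.csr_matrix(norm.X, dtype=np.float64).copy()
    X.data = np.expm1(X.data)
    return np.asarray((sp.diags(lib / scale) @ X).todense())


def select_hvg(counts: ad.AnnData, n_genes: int = 2000, span: float = 0.3):
    """Rank genes by standardized variance (variance-stabilizing transform).

    A lowess curve of log10(variance) on log10(mean) over raw counts predicts
    each gene's expected standard deviation; per-cell standardized values are
    clipped at sqrt(n_cells) and genes are ranked by the variance of the
    clipped values.  Returns (ordered gene list, per-gene score table).
    """
    if n_genes < 1:
        raise QCError("n_genes must be >= 1")
    X = sp.csc_matrix(counts.X, dtype=np.float64)
    n_cells, n_total = X.shape
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = (ex2 - mean**2) * n_cells / max(n_cells - 1, 1)

    fit_mask = (mean > 0) & (var > 0)
    if fit_mask.sum() < 3:
        raise QCError("need at least 3 genes with positive variance")
    log_mean = np.log10(mean[fit_mask])
    log_var = np.log10(var[fit_mask])
    pred = lowess(
        log_var, log_mean, frac=span, xvals=log_mean, return_sorted=False
    )
    exp_sd = np.zeros(n_total)
    exp_sd[fit_mask] = np.sqrt(10.0**pred)

    clip = np.sqrt(n_cells)
    std_var = np.zeros(n_total)
    idx = np.flatnonzero(fit_mask)
    for start in range(0, idx.size, 256):
        cols = idx[start:start + 256]
        block = np.asarray(X[:, cols].todense())
        z = (block - mean[cols]) / exp_sd[cols]
        np.clip(z, -clip, clip, out=z)
        std_var[cols] = z.var(axis=0, ddof=1)

    scores = pd.DataFrame(
        {
            "mean": mean,
            "variance": var,
            "variance_expected": exp_sd**2,
            "variance_standardized": std_var,
        },
        index=counts.var_names,
    )
    # deterministic tie-break by gene name so the ranking is invariant to
    # input gene order
    order = scores.assign(_name=scores.index).sort_values(
        by=["variance_standardized", "_name"], ascending=[False, True],
        kind="mergesort",
    )
    if n_genes > n_total:
        warnings.warn(
            f"requested {n_genes} HVGs but only {n_total} genes available",
            UserWarning,
        )
    top = list(order.index[: min(n_genes, n_total)])
    return top, scores
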