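"""Reading and writing of the plain-text formats used across the pipeline.

Count matrices travel as a Matrix Market ``matrix.mtx`` (genes x cells, the
features-by-barcodes convention) with ``barcodes.tsv`` / ``features.tsv``
sidecars; tabular outputs are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

FLOAT_FORMAT = "%.10g"


def write_mtx_dir(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write an AnnData (cells x genes) as a 10x-style MTX directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.csc_matrix(adata.X.T)  # genes x cells
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    feats = adata.var.reset_index().rename(columns={"index": "gene"})
    feats.to_csv(outdir / "features.tsv", sep="\t", header=True, index=False)
    if len(adata.obs.columns):
        adata.obs.reset_index(names="cell_id").to_csv(
            outdir / "metadata.tsv", sep="\t", index=False
        )
    return outdir


def read_mtx_dir(indir: str | Path) -> ad.AnnData:
    """Read a directory written by :func:`write_mtx_dir` back into AnnData."""
    indir = Path(indir)
    mat = scipy.io.mmread(str(indir / "matrix.mtx")).tocsr().T.tocsr()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    feats = pd.read_csv(indir / "features.tsv", sep="\t")
    var = feats.set_index(feats.columns[0])
    var.index = var.index.astype(str)
    var.index.name = None
    adata = ad.AnnData(
        X=sp.csr_matrix(mat, dtype=np.int64),
        obs=pd.DataFrame(index=pd.Index(barcodes.to_numpy(), name=None)),
        var=var,
    )
    meta_path = indir / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t").set_index("cell_id")
        meta.index = meta.index.astype(str)
        adata.obs = meta.loc[adata.obs_names]
    return adata


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
    return path


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
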