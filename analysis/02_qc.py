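#!/usr/bin/env python
"""Quality control: per-sample ceilings, mitochondrial bounds, HVG selection.

Ceilings are suggested from the 99th percentile of each donor's gene/UMI
distributions (the "customized superior threshold" recipe), then applied
together with the 10% / 1% mitochondrial bounds.  Writes filtered matrices,
QC reports and ranked HVG lists under results/qc/.
"""

from pathlib import Path

import pandas as pd

from hspcflow import io, qc

ROOT = Path(__file__).resolve().parents[1] / "results"


def process(label: str) -> None:
    adata = io.read_mtx_dir(ROOT / "data" / label)
    suggested = qc.suggest_thresholds(adata, by="donor", quantile=0.99)
    thresholds = qc.QCThresholds(
        max_genes_per_cell=int(suggested["max_genes_per_cell"].max()),
        max_umis_per_cell=int(suggested["max_umis_per_cell"].max()),
        mito_max_pct=10.0,
        mito_min_pct=1.0,
    )
    filtered, report = qc.filter_cells(adata, thresholds)
    hvg, scores = qc.select_hvg(filtered, 2000)

    io.write_mtx_dir(filtered, ROOT / "qc" / f"{label}_filtered")
    io.write_tsv(report, ROOT / "qc" / f"qc_report_{label}.tsv")
    io.write_tsv(suggested, ROOT / "qc" / f"suggested_ceilings_{label}.tsv")
    pd.Series(hvg, name="gene").to_csv(
        ROOT / "qc" / f"hvg_{label}.tsv", sep="\t", index=False
    )

    removed = report[~report["kept"]]
    by_rule = removed["failed_rules"].str.split(";").explode().value_counts()
    print(f"{label}: kept {filtered.n_obs}/{adata.n_obs} cells "
          f"(ceilings: {thresholds.max_genes_per_cell} genes, "
          f"{thresholds.max_umis_per_cell} UMIs)")
    for rule, n in by_rule.items():
        print(f"  removed by {rule}: {n}")


def main() -> None:
    for label in ("reference", "query"):
        process(label)
    print(f"wrote {ROOT / 'qc'}")


if __name__ == "__main__":
    main()
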