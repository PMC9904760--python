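#!/usr/bin/env python
"""Simulate the study cohort: a labeled young reference and an elderly query.

The elderly condition carries the aging-like perturbations the downstream
stages are meant to recover: an expanded HSC compartment at the expense of
committed lymphoid/monocytic output, a delayed monocytic-differentiation
gene, and a dampened one.  Writes count matrices (MTX), per-cell metadata,
trajectory ground truth, regulon activity, and the applied effects under
results/data/.
"""

from pathlib import Path

from hspcflow import io, simdata

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20230111


def main() -> None:
    config = simdata.SimConfig(
        n_cells_per_donor=600,
        donors_per_condition={"young": 5, "elderly": 3},
        seed=SEED,
    )
    reference, ref_truth = simdata.generate_reference(config)

    sigmoids = sorted(
        g for g, f in ref_truth.trend_functions.items() if f.kind == "sigmoid"
    )
    delayed, dampened = sigmoids[0], sigmoids[1]
    effects = simdata.PerturbationEffects(
        proportion_shift={"HSC": 0.10, "CLP": -0.03, "Mono_prog": -0.04},
        trend_shift={
            delayed: {"midpoint_shift": 0.2},
            dampened: {"amplitude_scale": 0.6},
        },
    )
    query, qry_truth = simdata.generate_query(config, ref_truth, effects)

    simdata.write_dataset(reference, ref_truth, OUT / "reference", config)
    simdata.write_dataset(query, qry_truth, OUT / "query", config)
    auc = simdata.generate_auc_matrix(config, ref_truth)
    io.write_tsv(auc, OUT / "auc.tsv")
    edges = simdata.generate_regulon_edges(config)
    io.write_tsv(edges, OUT / "regulon_edges.tsv", index=False)
    io.write_json(
        {
            "seed": SEED,
            "proportion_shift": effects.proportion_shift,
            "trend_shift": {g: dict(v) for g, v in effects.trend_shift.items()},
        },
        OUT / "effects.json",
    )

    print(f"reference: {reference.n_obs} cells "
          f"({int(ref_truth.doublet_flags.sum())} doublets), "
          f"{reference.n_vars} genes, "
          f"{ref_truth.cell_labels.nunique()} cell types")
    print(f"query:     {query.n_obs} cells "
          f"({int(qry_truth.doublet_flags.sum())} doublets)")
    print(f"injected proportion shifts: {effects.proportion_shift}")
    print(f"perturbed trend genes: {delayed} (midpoint +0.2), "
          f"{dampened} (amplitude x0.6)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
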