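"""Self-contained validation studies over the pipeline's own machinery.

Each function simulates its inputs with :mod:`hspcflow.simdata` (or builds
deterministic fixtures), runs the relevant stage end to end, and returns the
measured quantities.  They power both the validation test suite and the
reproduction script, so every reported number is recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify, composition, qc, regulons, simdata, trends
from ._glmnet import fit_path, lambda_max

# ---------------------------------------------------------------------------
# classifier recovery and ambiguity
# ---------------------------------------------------------------------------

#: study conditions for the classifier recovery experiment: 8 types,
#: 200 cells/type per condition (4 donors x 400 cells), marker fold 4
CLASSIFIER_STUDY_CONFIG = dict(
    n_types=8,
    n_cells_per_donor=400,
    donors_per_condition={"young": 4, "elderly": 4},
    marker_fold=4.0,
)


def classifier_recovery_study(seed: int = 1, n_mixtures: int = 200) -> dict:
    """Full train/predict round trip on simulated reference and query.

    Returns overall accuracy, worst per-type recall and the "not assigned"
    rate on pure query cells, plus the not-assigned rate of depth-matched
    50/50 two-type mixture cells and its ratio to the pure-cell rate.
    """
    cfg = simdata.SimConfig(seed=seed, **CLASSIFIER_STUDY_CONFIG)
    ref, ref_truth = simdata.generate_reference(cfg)
    qry, qry_truth = simdata.generate_query(cfg, ref_truth)
    thresholds = qc.QCThresholds(
        max_genes_per_cell=10**9, max_umis_per_cell=12_000, mito_max_pct=10.0
    )
    ref_f, _ = qc.filter_cells(ref, thresholds)
    qry_f, _ = qc.filter_cells(qry, thresholds)
    ref_norm = qc.log_normalize(ref_f)
    qry_norm = qc.log_normalize(qry_f)
    hvg_ref, _ = qc.select_hvg(ref_f, 500)
    hvg_qry, _ = qc.select_hvg(qry_f, 500)
    labels = ref_truth.cell_labels.loc[ref_f.obs_names].to_numpy()
    ensemble = classify.train_ensemble(
        ref_norm, labels, hvg_ref, hvg_qry,
        classify.ElasticNetSpec(), seed=seed + 10,
    )
    annotation = classify.predict(ensemble, qry_norm)

    truth = qry_truth.cell_labels.loc[qry_f.obs_names]
    pure = ~qry_truth.doublet_flags.loc[qry_f.obs_names].to_numpy()
    pred = annotation.labels.to_numpy()[pure]
    true = truth.to_numpy()[pure]
    correct = pred == true
    recall = pd.Series(correct).groupby(true).mean()
    pure_na = float((pred == classify.NOT_ASSIGNED).mean())

    mixtures, _ = simdata.generate_mixture_cells(
        qry, qry_truth, n_mixtures, seed=seed + 2
    )
    ann_mix = classify.predict(ensemble, qc.log_normalize(mixtures))
    mix_na = float((ann_mix.labels == classify.NOT_ASSIGNED).mean())
    floor = 1.0 / int(pure.sum())  # avoid a zero denominator
    return {
        "accuracy": float(correct.mean()),
        "min_type_recall": float(recall.min()),
        "pure_not_assigned_rate": pure_na,
        "mixture_not_assigned_rate": mix_na,
        "mixture_to_pure_ratio": mix_na / max(pure_na, floor),
        "n_query_cells": int(pure.sum()),
    }


# ---------------------------------------------------------------------------
# elastic-net limiting behavior
# ---------------------------------------------------------------------------

def elasticnet_limits_study(seed: int = 1, n_permutations: int = 20) -> dict:
    """Null-model limit and permutation behavior of the penalized fit.

    At lambda >= lambda_max with alpha = 1 every coefficient must vanish;
    fits on permuted labels must give validation AUC compatible with 0.5.
    """
    rng = np.random.default_rng(seed)
    n, p = 200, 40
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:5] = [1.5, -1.0, 0.8, -0.6, 0.5]
    y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
    Xs = (X - X.mean(0)) / X.std(0)
    lmax = lambda_max(Xs, y, 1.0)
    coefs, _, _ = fit_path(Xs, y, 1.0, np.array([lmax * 1.001]))
    nnz_at_lmax = int(np.count_nonzero(coefs[0]))

    spec = classify.ElasticNetSpec(n_lambda=12)
    features = [f"g{j}" for j in range(p)]
    aucs = []
    for rep in range(n_permutations):
        perm = rng.permutation(y)
        split = rng.permutation(n)
        tr, va = split[: 3 * n // 4], split[3 * n // 4:]
        model = classify.fit_binary_model(
            X[tr], perm[tr], X[va], perm[va], alpha=1.0, spec=spec,
            seed=int(rng.integers(2**31)), feature_names=features,
        )
        aucs.append(model.metrics.auc)
    aucs = np.asarray(aucs)
    se = aucs.std(ddof=1) / np.sqrt(len(aucs))
    return {
        "nnz_at_lambda_max": nnz_at_lmax,
        "permuted_mean_auc": float(aucs.mean()),
        "permuted_auc_se": float(se),
        "permuted_auc_z": float(abs(aucs.mean() - 0.5) / max(se, 1e-12)),
    }


# ---------------------------------------------------------------------------
# model-selection cascade
# ---------------------------------------------------------------------------

def _candidate(nnz, auc, fpr=0.1, fnr=0.1, alpha=1.0):
    return classify.BinaryModel(
        target_type="T", feature_names=["g"], coef=np.zeros(1), intercept=0.0,
        alpha=alpha, lambda_=0.1, n_nonzero=nnz,
        metrics=classify.ValidationMetrics(auc, fpr, fnr, 50),
    )


def selection_cascade_checks() -> dict:
    """Table-driven checks of the eligibility window and tie cascade."""
    spec = classify.ElasticNetSpec()
    cases = [
        # (candidates, expected n_nonzero of the pick)
        ([_candidate(10, 0.99), _candidate(50, 0.90), _candidate(200, 0.99)],
         50),    # only the in-window model is eligible
        ([_candidate(20, 0.9), _candidate(150, 0.91)], 150),  # window edges
        ([_candidate(5, 0.99), _candidate(400, 0.90)], 5),    # fallback
        ([_candidate(30, 0.90), _candidate(40, 0.95)], 40),   # max AUC
        ([_candidate(30, 0.95, fpr=0.2), _candidate(40, 0.95, fpr=0.1)],
         40),    # min FPR on AUC tie
        ([_candidate(30, 0.95, fnr=0.2), _candidate(40, 0.95, fnr=0.1)],
         40),    # min FNR next
        ([_candidate(30, 0.95), _candidate(40, 0.95)], 40),   # max variables
    ]
    passed = sum(
        classify.select_model(c, spec).n_nonzero == want for c, want in cases
    )
    tie = classify.select_model(
        [_candidate(30, 0.95, alpha=0.5), _candidate(30, 0.95, alpha=1.0)],
        spec,
    )
    passed += tie.alpha == 1.0  # residual tie -> first alpha on the grid
    return {"n_cases": len(cases) + 1, "n_passed": int(passed)}


# ---------------------------------------------------------------------------
# multiple testing and rank tests
# ---------------------------------------------------------------------------

def _brute_force_holm(p):
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[i]))
        adj[i] = running
    return adj


def holm_agreement(seed: int = 1, n_vectors: int = 1000) -> dict:
    """Exact agreement of the Holm adjustment with the step-down definition
    on random p-vectors of length 1-50."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_vectors):
        p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 51))
        agree += np.array_equal(
            composition.holm_adjust(p), _brute_force_holm(p)
        )
    return {"n_vectors": n_vectors, "agreement_fraction": agree / n_vectors}


def _wilcoxon_enumeration(a, b):
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = rankdata(pooled)
    u_obs = ranks[:n].sum()
    sums = np.array([
        sum(ranks[i] for i in comb)
        for comb in combinations(range(len(pooled)), n)
    ])
    p_le = (sums <= u_obs + 1e-9).mean()
    p_ge = (sums >= u_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_agreement(seed: int = 1, n_pairs: int = 500) -> dict:
    """Exact agreement of the small-sample Wilcoxon p with full enumeration
    over random integer vectors (ties included), n, m <= 8."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_pairs):
        n, m = rng.integers(2, 9, size=2)
        a = rng.integers(0, 7, n).astype(float)
        b = rng.integers(0, 7, m).astype(float)
        ours = trends.trend_wilcoxon(a, b)
        agree += bool(np.isclose(ours, _wilcoxon_enumeration(a, b)))
    worked = trends.trend_wilcoxon([1, 2, 3], [4, 5, 6])
    return {
        "n_pairs": n_pairs,
        "agreement_fraction": agree / n_pairs,
        "worked_example_p": float(worked),
    }


# ---------------------------------------------------------------------------
# proportion-test calibration and power
# ---------------------------------------------------------------------------

def composition_calibration(seed: int = 1, n_replicates: int = 10_000) -> dict:
    """Type-I error of the raw two-proportion test under the null."""
    rng = np.random.default_rng(seed)
    n = 5000
    s1 = rng.binomial(n, 0.2, n_replicates)
    s2 = rng.binomial(n, 0.2, n_replicates)
    pvals = composition._two_prop_z(s1, n, s2, n)
    return {
        "n_replicates": n_replicates,
        "null_rejection_rate": float((pvals < 0.05).mean()),
    }


def composition_shift_power(seed: int = 1, n_replicates: int = 100) -> dict:
    """Detection rate of a +0.10 shift in one type at 5,000 cells/condition,
    Holm-adjusted across 8 types."""
    rng = np.random.default_rng(seed)
    base = np.array([0.25, 0.15, 0.15, 0.12, 0.10, 0.10, 0.08, 0.05])
    shifted = base.copy()
    shifted[0] += 0.10
    shifted[1:] *= (1 - shifted[0]) / base[1:].sum()
    types = [f"T{i}" for i in range(base.size)]
    hits = 0
    for _ in range(n_replicates):
        ca = rng.multinomial(5000, base)
        cb = rng.multinomial(5000, shifted)
        ta = pd.DataFrame({"donor": "a", "cell_type": types, "count": ca,
                           "proportion": ca / 5000})
        tb = pd.DataFrame({"donor": "b", "cell_type": types, "count": cb,
                           "proportion": cb / 5000})
        res = composition.test_composition_shift(ta, tb)
        hits += bool(res.loc["T0", "significant"])
    return {"n_replicates": n_replicates, "detection_rate": hits / n_replicates}


# ---------------------------------------------------------------------------
# trend recovery
# ---------------------------------------------------------------------------

def trend_linear_recovery(seed: int = 1) -> dict:
    """Noiseless linear expression: maximum deviation of the fitted trend
    from the identity line on the grid interior."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.random(500))
    fitted = trends.fit_trend(t.copy(), t, None)
    inner = slice(12, -12)
    err = float(np.abs(fitted.values[inner] - fitted.grid[inner]).max())
    return {"max_abs_error": err}


#: trend-comparison experiment: 2,000 cells/condition, batch effects zero
#: (emulating the batch-corrected matrices trends are fitted on), one
#: sigmoid gene's midpoint delayed by 0.2
TREND_STUDY_CONFIG = dict(
    n_types=8,
    n_cells_per_donor=500,
    donors_per_condition={"young": 4, "elderly": 4},
    doublet_rate=0.0,
    batch_shift_sd=0.0,
)


def trend_perturbation_study(seed: int = 1, branch: str = "monocytic") -> dict:
    """Sigmoid midpoint-shift perturbation: tier of the perturbed gene and
    the NS fraction among unperturbed dynamic genes."""
    cfg = simdata.SimConfig(seed=seed, **TREND_STUDY_CONFIG)
    ref, ref_truth = simdata.generate_reference(cfg)
    perturbed = sorted(
        g for g, f in ref_truth.trend_functions.items() if f.kind == "sigmoid"
    )[0]
    effects = simdata.PerturbationEffects(
        trend_shift={perturbed: {"midpoint_shift": 0.2}}
    )
    qry, qry_truth = simdata.generate_query(cfg, ref_truth, effects)
    genes = sorted(ref_truth.trend_functions)

    def _fit(adata, truth, condition):
        norm = qc.log_normalize(adata)
        expr = pd.DataFrame(
            np.asarray(norm[:, genes].X.todense()),
            index=norm.obs_names, columns=genes,
        )
        traj = pd.concat(
            [truth.pseudotime, truth.branch_probabilities.add_prefix("bp_")],
            axis=1,
        )
        return trends.fit_trends(
            expr, traj, branch, genes=genes, condition=condition
        )

    result = trends.compare_trends(
        _fit(ref, ref_truth, "reference"), _fit(qry, qry_truth, "query")
    )
    others = result.drop(index=perturbed)
    return {
        "perturbed_gene": perturbed,
        "perturbed_tier": str(result.loc[perturbed, "tier"]),
        "perturbed_p_adjusted": float(result.loc[perturbed, "p_adjusted"]),
        "unperturbed_ns_fraction": float((others["tier"] == "NS").mean()),
        "n_genes": int(len(result)),
    }


# ---------------------------------------------------------------------------
# regulon stack
# ---------------------------------------------------------------------------

def regulon_stack_study(seed: int = 1) -> dict:
    """Binarization error on the two-mode reference simulation, brute-force
    agreement of percent_active, the indicator-regulon RSS, and the Q3 trim
    of importances 1..8."""
    rng = np.random.default_rng(seed)
    n = 1000
    x = np.concatenate([rng.normal(0.1, 0.05, n // 2),
                        rng.normal(0.8, 0.05, n // 2)])
    truth = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    auc = pd.DataFrame(x[None, :], index=["R1"],
                       columns=[f"c{i}" for i in range(n)])
    binary, _ = regulons.binarize(auc)
    misassignment = float((binary.loc["R1"].to_numpy() != truth).mean())

    clusters = pd.Series(rng.choice(["a", "b", "c"], n), index=auc.columns)
    pct = regulons.percent_active(binary, clusters)
    exact = True
    for c in ["a", "b", "c"]:
        cells = clusters.index[(clusters == c).to_numpy()]
        manual = 100.0 * binary.loc["R1", cells].sum() / len(cells)
        exact &= pct.loc["R1", c] == manual

    ind = pd.DataFrame([[0.2, 0.2, 0.2, 0.0, 0.0]], index=["R"],
                       columns=list("abcde"))
    cl = pd.Series(["C1", "C1", "C1", "C2", "C2"], index=list("abcde"))
    rss_value = float(regulons.rss(ind, cl).loc["R", "C1"])

    edges = pd.DataFrame({
        "TF": "R1", "target": [f"g{i}" for i in range(1, 9)],
        "importance": np.arange(1.0, 9.0),
    })
    trimmed, _ = regulons.trim_network(edges)
    return {
        "binarize_misassignment": misassignment,
        "percent_active_exact": bool(exact),
        "indicator_rss": rss_value,
        "q3_trim_retained": sorted(trimmed["importance"].astype(int).tolist()),
    }


# ---------------------------------------------------------------------------
# QC fixture and normalization round trip
# ---------------------------------------------------------------------------

def build_qc_fixture(seed: int = 10):
    """100-cell count matrix with known violations: 3 high-mito, 2 low-mito,
    2 doublet-like cells; thresholds under which exactly 93 cells pass."""
    import anndata as ad
    import scipy.sparse as sp

    rng = np.random.default_rng(seed)
    n_genes, n_mito = 40, 3
    genes = [f"G{i:03d}" for i in range(n_genes - n_mito)] + [
        f"MT-{i + 1}" for i in range(n_mito)
    ]

    def make_cell(total, mito_frac, n_expressed):
        cell = np.zeros(n_genes, dtype=np.int64)
        mito_total = int(round(total * mito_frac))
        body = rng.multinomial(total - mito_total,
                               np.ones(n_expressed) / n_expressed)
        idx = rng.choice(n_genes - n_mito, size=n_expressed, replace=False)
        cell[idx] = body
        cell[n_genes - n_mito:] = rng.multinomial(
            mito_total, np.ones(n_mito) / n_mito
        )
        return cell

    rows = (
        [make_cell(2000, 0.03, 25) for _ in range(93)]
        + [make_cell(2000, 0.08, 25) for _ in range(3)]    # high mito
        + [make_cell(2000, 0.005, 25) for _ in range(2)]   # low mito
        + [make_cell(9000, 0.03, 36) for _ in range(2)]    # doublet-like
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(np.array(rows)),
        obs=pd.DataFrame(index=[f"cell{i:03d}" for i in range(100)]),
        var=pd.DataFrame(index=genes),
    )
    thresholds = qc.QCThresholds(
        max_genes_per_cell=33, max_umis_per_cell=5000,
        mito_max_pct=5.0, mito_min_pct=1.0,
    )
    return adata, thresholds


def qc_fixture_study(seed: int = 10) -> dict:
    adata, thresholds = build_qc_fixture(seed)
    kept, report = qc.filter_cells(adata, thresholds)
    removed = report[~report["kept"]]
    rules = ";".join(removed["failed_rules"])
    return {
        "cells_retained": int(kept.n_obs),
        "cells_removed": int(len(removed)),
        "every_removal_named": bool((removed["failed_rules"] != "").all()),
        "rules_seen": sorted(
            set(r for r in rules.split(";") if r)
        ),
    }


def normalization_roundtrip(seed: int = 1) -> dict:
    """Maximum relative error of log-normalize followed by its inverse on a
    random count matrix."""
    import anndata as ad
    import scipy.sparse as sp

    rng = np.random.default_rng(seed)
    counts = rng.poisson(4.0, size=(80, 120))
    counts[counts.sum(axis=1) == 0, 0] = 1
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(80)]),
        var=pd.DataFrame(index=[f"g{i}" for i in range(120)]),
    )
    norm = qc.log_normalize(adata)
    back = qc.invert_log_normalize(norm)
    rel = np.abs(back - counts) / np.maximum(counts, 1)
    return {"max_relative_error": float(rel.max())}
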