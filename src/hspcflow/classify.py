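"""Reference-based cell-type classification by one-vs-rest elastic-net
logistic regression ensembles.

For every cell type in the labeled reference, a balanced training/validation
set is drawn (all positives plus an equal-size random negative sample,
split 75/25), binary elastic-net logistic models are fitted over a grid of
mixing parameters with the penalty strength chosen by cross-validated
deviance, and the best model is selected by a validation cascade
(variable-count window, then AUC, FPR, FNR, variable count).  The whole
procedure is repeated (default 10 times) and per-type probabilities are
averaged at prediction; a cell whose best averaged probability does not
exceed 0.5 is labeled "not assigned".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import _glmnet

NOT_ASSIGNED = "not assigned"


class ClassifierError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ElasticNetSpec:
    alpha_grid: tuple = (1.0, 0.75, 0.5, 0.25, 0.1)
    n_cv_folds: int = 10
    min_vars: int = 20
    max_vars: int = 150
    train_fraction: float = 0.75
    n_repetitions: int = 10
    assign_threshold: float = 0.5
    lambda_rule: str = "min"  # or "1se"
    n_lambda: int = 30
    lambda_min_ratio: float = 0.01

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ClassifierError("train_fraction must lie in (0, 1)")
        if self.min_vars > self.max_vars:
            raise ClassifierError("min_vars must not exceed max_vars")
        if any(not 0 < a <= 1 for a in self.alpha_grid):
            raise ClassifierError("every alpha must lie in (0, 1]")
        if self.lambda_rule not in ("min", "1se"):
            raise ClassifierError("lambda_rule must be 'min' or '1se'")


@dataclass
class ValidationMetrics:
    auc: float
    fpr: float
    fnr: float
    n_validation: int


@dataclass
class BinaryModel:
    target_type: str
    feature_names: list
    coef: np.ndarray  # dense, original (unstandardized) scale
    intercept: float
    alpha: float
    lambda_: float
    n_nonzero: int
    metrics: ValidationMetrics

    @property
    def coefficients(self) -> dict:
        nz = np.flatnonzero(self.coef)
        return {self.feature_names[j]: float(self.coef[j]) for j in nz}

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _glmnet.predict_proba(X, self.coef, self.intercept)


@dataclass
class CellAnnotation:
    probabilities: pd.DataFrame  # cells x types, averaged over repetitions
    labels: pd.Series
    assign_threshold: float = 0.5

    def to_frame(self) -> pd.DataFrame:
        out = self.probabilities.copy()
        out.insert(0, "label", self.labels)
        out.index.name = "cell_id"
        return out


@dataclass
class EnsembleClassifier:
    cell_types: list
    features: list
    models: dict  # type -> list[BinaryModel], one per repetition
    spec: ElasticNetSpec
    seed: int

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "cell_types": list(self.cell_types),
            "features": list(self.features),
            "seed": int(self.seed),
            "spec": {
                **{k: getattr(self.spec, k) for k in (
                    "n_cv_folds", "min_vars", "max_vars", "train_fraction",
                    "n_repetitions", "assign_threshold", "lambda_rule",
                    "n_lambda", "lambda_min_ratio",
                )},
                "alpha_grid": list(self.spec.alpha_grid),
            },
            "models": {
                t: [
                    {
                        "coefficients": m.coefficients,
                        "intercept": m.intercept,
                        "alpha": m.alpha,
                        "lambda": m.lambda_,
                        "n_nonzero": m.n_nonzero,
                        "metrics": vars(m.metrics),
                    }
                    for m in ms
                ]
                for t, ms in self.models.items()
            },
        }
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        spec_kw = dict(payload["spec"])
        spec_kw["alpha_grid"] = tuple(spec_kw["alpha_grid"])
        spec = ElasticNetSpec(**spec_kw)
        features = list(payload["features"])
        fidx = {g: j for j, g in enumerate(features)}
        models = {}
        for t, ms in payload["models"].items():
            lst = []
            for m in ms:
                coef = np.zeros(len(features))
                for g, v in m["coefficients"].items():
                    coef[fidx[g]] = v
                lst.append(
                    BinaryModel(
                        target_type=t,
                        feature_names=features,
                        coef=coef,
                        intercept=m["intercept"],
                        alpha=m["alpha"],
                        lambda_=m["lambda"],
                        n_nonzero=m["n_nonzero"],
                        metrics=ValidationMetrics(**m["metrics"]),
                    )
                )
            models[t] = lst
        return cls(
            cell_types=list(payload["cell_types"]),
            features=features,
            models=models,
            spec=spec,
            seed=payload["seed"],
        )


# ---------------------------------------------------------------------------
# training-set construction and features
# ---------------------------------------------------------------------------

def build_training_set(
    labels: np.ndarray,
    target_type: str,
    rng: np.random.Generator,
    train_fraction: float = 0.75,
):
    """All target cells plus an equal number of random non-target cells,
    split into train/validation stratified by class.

    Returns (train_idx, val_idx, y_train, y_val) as index arrays into
    ``labels`` and binary outcome arrays.
    """
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == target_type)
    if pos.size == 0:
        raise ClassifierError(f"target type {target_type!r} absent from labels")
    if pos.size < 8:
        raise ClassifierError(
            f"target type {target_type!r} has only {pos.size} cells (minimum 8)"
        )
    pool = np.flatnonzero(labels != target_type)
    n_neg = min(pos.size, pool.size)
    if pool.size < pos.size:
        warnings.warn(
            f"only {pool.size} non-target cells available for {target_type!r}; "
            "using all of them",
            UserWarning,
        )
    neg = rng.choice(pool, size=n_neg, replace=False)

    def _split(idx):
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        return idx[:n_train], idx[n_train:]

    pos_tr, pos_va = _split(pos)
    neg_tr, neg_va = _split(neg)
    train_idx = np.concatenate([pos_tr, neg_tr])
    val_idx = np.concatenate([pos_va, neg_va])
    y_train = (labels[train_idx] == target_type).astype(float)
    y_val = (labels[val_idx] == target_type).astype(float)
    return train_idx, val_idx, y_train, y_val


def intersect_features(reference_hvg, query_hvg):
    """Intersection of the two HVG lists, in reference order."""
    if not len(reference_hvg) or not len(query_hvg):
        raise ClassifierError("HVG lists must be non-empty")
    qset = set(query_hvg)
    out = [g for g in reference_hvg if g in qset]
    if not out:
        raise ClassifierError("reference and query HVG lists share no genes")
    return out


# ---------------------------------------------------------------------------
# model fitting and selection
# ---------------------------------------------------------------------------

def fit_binary_model(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    alpha: float,
    spec: ElasticNetSpec,
    seed: int,
    feature_names,
    target_type: str = "",
) -> BinaryModel:
    """Fit one penalized logistic model at mixing parameter ``alpha``.

    lambda is chosen on a warm-started path by ``n_cv_folds``-fold
    stratified cross-validation minimizing mean held-out binomial deviance
    (or the 1-SE variant); metrics come from the held-out validation split.
    """
    y_train = np.asarray(y_train, dtype=float)
    if len(np.unique(y_train)) < 2 or len(np.unique(y_val)) < 2:
        raise ClassifierError("both classes must be present in train and validation")
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X_train - mu) / sd
    lambdas = _glmnet.lambda_path(
        Xs, y_train, alpha, n_lambda=spec.n_lambda,
        min_ratio=spec.lambda_min_ratio,
    )

    skf = StratifiedKFold(
        n_splits=spec.n_cv_folds, shuffle=True, random_state=int(seed) % (2**31)
    )
    dev = np.zeros((spec.n_cv_folds, len(lambdas)))
    for fi, (tr, te) in enumerate(skf.split(Xs, y_train)):
        coefs, b0s, _ = _glmnet.fit_path(Xs[tr], y_train[tr], alpha, lambdas)
        for li in range(len(lambdas)):
            prob = _glmnet.predict_proba(Xs[te], coefs[li], b0s[li])
            dev[fi, li] = _glmnet.binomial_deviance(y_train[te], prob)
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    if spec.lambda_rule == "1se":
        se = dev[:, best].std(ddof=1) / np.sqrt(spec.n_cv_folds)
        eligible = np.flatnonzero(mean_dev <= mean_dev[best] + se)
        best = int(eligible[0])  # lambdas are decreasing: first = largest

    coefs, b0s, ok = _glmnet.fit_path(Xs, y_train, alpha, lambdas)
    if not ok[best]:
        raise ConvergenceError(
            f"coordinate descent did not converge (type={target_type!r}, "
            f"alpha={alpha}, lambda={lambdas[best]:.3g})"
        )
    beta_std = coefs[best]
    coef = beta_std / sd
    intercept = float(b0s[best] - np.sum(beta_std * mu / sd))

    prob_val = _glmnet.predict_proba(X_val, coef, intercept)
    pred = prob_val > 0.5
    tn = int(np.sum((~pred) & (y_val == 0)))
    fp = int(np.sum(pred & (y_val == 0)))
    fn = int(np.sum((~pred) & (y_val == 1)))
    tp = int(np.sum(pred & (y_val == 1)))
    metrics = ValidationMetrics(
        auc=float(roc_auc_score(y_val, prob_val)),
        fpr=fp / max(fp + tn, 1),
        fnr=fn / max(fn + tp, 1),
        n_validation=len(y_val),
    )
    return BinaryModel(
        target_type=target_type,
        feature_names=list(feature_names),
        coef=coef,
        intercept=intercept,
        alpha=float(alpha),
        lambda_=float(lambdas[best]),
        n_nonzero=int(np.count_nonzero(beta_std)),
        metrics=metrics,
    )


def select_model(candidates, spec: ElasticNetSpec) -> BinaryModel:
    """Pick the best candidate: restrict to models with ``min_vars`` to
    ``max_vars`` variables when any qualify, then maximize AUC with ties
    broken by min FPR, min FNR, max variable count, then smallest
    alpha-grid index."""
    if not candidates:
        raise ClassifierError("empty candidate list")
    eligible = [
        m for m in candidates if spec.min_vars <= m.n_nonzero <= spec.max_vars
    ]
    if not eligible:
        eligible = list(candidates)
    alpha_index = {a: i for i, a in enumerate(spec.alpha_grid)}

    def key(m: BinaryModel):
        return (
            -m.metrics.auc,
            m.metrics.fpr,
            m.metrics.fnr,
            -m.n_nonzero,
            alpha_index.get(m.alpha, len(alpha_index)),
        )

    return min(eligible, key=key)


# ---------------------------------------------------------------------------
# ensemble training and prediction
# ---------------------------------------------------------------------------

def _expression_matrix(norm: ad.AnnData, features) -> np.ndarray:
    missing = [g for g in features if g not in norm.var_names]
    X = np.zeros((norm.n_obs, len(features)))
    present = [g for g in features if g not in missing]
    if missing:
        warnings.warn(
            f"{len(missing)} model features absent from matrix; imputed as 0",
            UserWarning,
        )
    if present:
        sub = norm[:, present].X
        sub = np.asarray(sub.todense()) if sp.issparse(sub) else np.asarray(sub)
        pos = {g: j for j, g in enumerate(features)}
        cols = [pos[g] for g in present]
        X[:, cols] = sub
    return X


def train_ensemble(
    reference: ad.AnnData,
    labels,
    reference_hvg,
    query_hvg,
    spec: ElasticNetSpec | None = None,
    seed: int = 0,
) -> EnsembleClassifier:
    """Train ``n_repetitions`` selected binary models per cell type.

    ``reference`` holds log-normalized expression (cells x genes); features
    are the reference/query HVG intersection, computed once and shared by all
    binary models.
    """
    spec = spec or ElasticNetSpec()
    labels = np.asarray(labels)
    if labels.shape[0] != reference.n_obs:
        raise ClassifierError("labels must align with reference cells")
    features = intersect_features(reference_hvg, query_hvg)
    X_all = _expression_matrix(reference, features)
    types = sorted(pd.unique(labels))
    models: dict[str, list] = {}
    for k, t in enumerate(types):
        per_type = []
        for rep in range(spec.n_repetitions):
            ss = np.random.SeedSequence(seed, spawn_key=(k, rep))
            rng = np.random.default_rng(ss)
            fold_seed = int(ss.generate_state(1)[0] % (2**31))
            try:
                tr, va, y_tr, y_va = build_training_set(
                    labels, t, rng, spec.train_fraction
                )
                candidates = [
                    fit_binary_model(
                        X_all[tr], y_tr, X_all[va], y_va, a, spec,
                        seed=fold_seed, feature_names=features, target_type=t,
                    )
                    for a in spec.alpha_grid
                ]
            except (ClassifierError, ConvergenceError) as err:
                raise type(err)(f"[{t}] {err}") from err
            per_type.append(select_model(candidates, spec))
        models[t] = per_type
    return EnsembleClassifier(
        cell_types=types, features=features, models=models, spec=spec, seed=seed
    )


def predict(ensemble: EnsembleClassifier, query: ad.AnnData) -> CellAnnotation:
    """Average per-repetition probabilities per type and assign labels.

    The label is the argmax type when its averaged probability strictly
    exceeds the assignment threshold, else "not assigned".
    """
    X = _expression_matrix(query, ensemble.features)
    probs = {}
    for t in ensemble.cell_types:
        reps = ensemble.models[t]
        acc = np.zeros(X.shape[0])
        for m in reps:
            acc += m.predict_proba(X)
        probs[t] = acc / len(reps)
    prob_df = pd.DataFrame(probs, index=query.obs_names)
    best = prob_df.to_numpy().argmax(axis=1)
    best_p = prob_df.to_numpy()[np.arange(len(best)), best]
    labels = np.where(
        best_p > ensemble.spec.assign_threshold,
        prob_df.columns.to_numpy()[best],
        NOT_ASSIGNED,
    )
    return CellAnnotation(
        probabilities=prob_df,
        labels=pd.Series(labels, index=query.obs_names, name="label"),
        assign_threshold=ensemble.spec.assign_threshold,
    )


def confusion_proportions(predicted: pd.Series, truth: pd.Series) -> pd.DataFrame:
    """Row-normalized confusion table: true types x predicted types plus
    "not assigned"; each row sums to 1."""
    if not predicted.index.equals(truth.index):
        raise ClassifierError("predicted and true labels cover different cells")
    tab = pd.crosstab(truth, predicted, normalize="index")
    cols = sorted(c for c in tab.columns if c != NOT_ASSIGNED)
    for c in sorted(set(truth.unique()) - set(cols)):
        if c not in tab.columns:
            tab[c] = 0.0
            cols.append(c)
    cols = sorted(set(cols))
    if NOT_ASSIGNED not in tab.columns:
        tab[NOT_ASSIGNED] = 0.0
    tab = tab[cols + [NOT_ASSIGNED]]
    tab.index.name = "true_type"
    tab.columns.name = "predicted_type"
    return tab
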