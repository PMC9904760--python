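"""Synthetic CD34+ HSPC scRNA-seq data with ground truth.

The generator emulates the statistical structure the downstream analyses
assume: ~14 stem/progenitor/committed cell types with type-specific marker
genes, negative-binomial UMI counts with per-cell library-size scaling,
mitochondrial gene content, per-donor batch effects, doublets, a latent
pseudotime with branch structure, regulon activity (AUC) matrices, and
condition effects expressed as cell-type proportion shifts and pseudotime
trend perturbations.  Every draw is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as _io


class SimConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


#: canonical cell-type panel: stem -> progenitor -> committed states
CELL_TYPES_14 = (
    "HSC",
    "LMPP",
    "MEP",
    "GMP",
    "CLP",
    "Mono_prog",
    "DC_prog",
    "Ery_early",
    "Ery_late",
    "Mk_prog",
    "Baso_prog",
    "ProB",
    "Lymph_NK",
    "Cycling_prog",
)

#: terminal differentiation branches (monocytic, dendritic, erythroid,
#: megakaryocytic, basophil, lymphoid), mirroring the six committed lineages
BRANCHES = (
    "monocytic",
    "dendritic",
    "erythroid",
    "megakaryocytic",
    "basophil",
    "lymphoid",
)

# mean position of each type along the latent pseudotime axis
_TYPE_POSITION = {
    "HSC": 0.05,
    "LMPP": 0.25,
    "MEP": 0.25,
    "GMP": 0.50,
    "CLP": 0.50,
    "Mono_prog": 0.85,
    "DC_prog": 0.85,
    "Ery_early": 0.55,
    "Ery_late": 0.85,
    "Mk_prog": 0.80,
    "Baso_prog": 0.80,
    "ProB": 0.85,
    "Lymph_NK": 0.70,
    "Cycling_prog": 0.30,
}

# branch affinity scores; branch probabilities are a softmax of these plus
# per-cell noise, so any monotone distance-to-terminal scheme is reproduced
_TYPE_BRANCH_AFFINITY = {
    "HSC": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    "LMPP": (1.2, 1.2, -1.0, -1.0, -1.0, 1.2),
    "MEP": (-1.0, -1.0, 1.5, 1.2, 1.0, -1.0),
    "GMP": (2.0, 1.5, -1.5, -1.5, -1.5, -1.5),
    "CLP": (-1.5, -1.5, -1.5, -1.5, -1.5, 2.5),
    "Mono_prog": (4.0, -2.0, -2.0, -2.0, -2.0, -2.0),
    "DC_prog": (-2.0, 4.0, -2.0, -2.0, -2.0, -2.0),
    "Ery_early": (-2.0, -2.0, 2.5, 0.5, -2.0, -2.0),
    "Ery_late": (-2.0, -2.0, 4.0, -2.0, -2.0, -2.0),
    "Mk_prog": (-2.0, -2.0, -2.0, 4.0, -2.0, -2.0),
    "Baso_prog": (-2.0, -2.0, -2.0, -2.0, 4.0, -2.0),
    "ProB": (-2.0, -2.0, -2.0, -2.0, -2.0, 4.0),
    "Lymph_NK": (-2.0, -2.0, -2.0, -2.0, -2.0, 3.5),
    "Cycling_prog": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
}

_DEFAULT_PROPORTIONS_14 = (
    0.20, 0.10, 0.12, 0.10, 0.06, 0.08, 0.04,
    0.10, 0.06, 0.04, 0.03, 0.04, 0.02, 0.01,
)


@dataclass
class TrendFunction:
    """A named parametric expression trend on pseudotime [0, 1].

    The trend acts as a multiplicative factor on a gene's base mean.
    Kinds: ``constant`` (value), ``linear`` (intercept, slope),
    ``sigmoid`` (lo, hi, midpoint, scale), ``transient``
    (baseline, amplitude, center, width).
    """

    kind: str
    params: dict

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.kind == "constant":
            return np.full_like(t, p["value"], dtype=float)
        if self.kind == "linear":
            return p["intercept"] + p["slope"] * t
        if self.kind == "sigmoid":
            z = (t - p["midpoint"]) / p["scale"]
            return p["lo"] + (p["hi"] - p["lo"]) / (1.0 + np.exp(-z))
        if self.kind == "transient":
            return p["baseline"] + p["amplitude"] * np.exp(
                -0.5 * ((t - p["center"]) / p["width"]) ** 2
            )
        raise ValueError(f"unknown trend kind {self.kind!r}")

    def perturbed(self, midpoint_shift: float = 0.0, amplitude_scale: float = 1.0):
        """Return a shifted/scaled copy (midpoint shift applies to sigmoid
        midpoints and transient centers)."""
        p = dict(self.params)
        if midpoint_shift:
            if self.kind == "sigmoid":
                p["midpoint"] = p["midpoint"] + midpoint_shift
            elif self.kind == "transient":
                p["center"] = p["center"] + midpoint_shift
            else:
                raise ValueError(
                    f"midpoint shift undefined for {self.kind!r} trends"
                )
        if amplitude_scale != 1.0:
            if self.kind == "sigmoid":
                p["hi"] = p["lo"] + (p["hi"] - p["lo"]) * amplitude_scale
            elif self.kind == "transient":
                p["amplitude"] = p["amplitude"] * amplitude_scale
            elif self.kind == "linear":
                p["slope"] = p["slope"] * amplitude_scale
            else:
                p["value"] = p["value"] * amplitude_scale
        return TrendFunction(self.kind, p)


@dataclass
class PerturbationEffects:
    """Condition effects applied by :func:`generate_query`.

    ``proportion_shift`` maps cell type -> additive delta on its expected
    proportion; unshifted types are rescaled to keep the vector on the
    simplex.  ``trend_shift`` maps gene -> kwargs for
    :meth:`TrendFunction.perturbed` (or ``{"replace": TrendFunction}``).
    """

    proportion_shift: dict = field(default_factory=dict)
    trend_shift: dict = field(default_factory=dict)


@dataclass
class SimConfig:
    n_types: int = 14
    n_genes: int = 2000
    markers_per_type: int = 20
    n_cells_per_donor: int = 500
    donors_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {"young": 5, "elderly": 3}
    )
    type_proportions: Mapping[str, np.ndarray] | None = None
    marker_fold: float = 4.0
    # NB size parameter; theta = 10 matches the BCV ~ 0.3 convention of
    # droplet scRNA-seq count simulators
    nb_dispersion: float = 10.0
    library_size_lognormal: tuple = (8.5, 0.35)
    mito_fraction: tuple = (0.05, 0.02)
    doublet_rate: float = 0.03
    batch_shift_sd: float = 0.05
    seed: int = 0
    # structural extensions with fixed defaults
    n_mito_genes: int = 13
    n_dynamic_genes: int = 60
    pseudotime_jitter: float = 0.08
    n_regulons: int = 20
    n_ubiquitous_regulons: int = 2
    regulon_targets: int = 30
    auc_modes: tuple = (0.1, 0.8)
    auc_sd: float = 0.05

    def __post_init__(self):
        if self.type_proportions is None:
            base = self.default_proportions(self.n_types)
            self.type_proportions = {
                cond: base.copy() for cond in self.donors_per_condition
            }
        else:
            self.type_proportions = {
                cond: np.asarray(p, dtype=float)
                for cond, p in self.type_proportions.items()
            }
        self.validate()

    @staticmethod
    def default_proportions(n_types: int) -> np.ndarray:
        p = np.asarray(_DEFAULT_PROPORTIONS_14[:n_types], dtype=float)
        if n_types > len(_DEFAULT_PROPORTIONS_14):
            extra = np.full(n_types - len(_DEFAULT_PROPORTIONS_14), 0.02)
            p = np.concatenate([p, extra])
        return p / p.sum()

    @property
    def cell_types(self) -> tuple:
        names = list(CELL_TYPES_14[: self.n_types])
        for i in range(len(names), self.n_types):
            names.append(f"Type_{i + 1:02d}")
        return tuple(names)

    def validate(self) -> None:
        pos_int = {
            "n_types": self.n_types,
            "n_genes": self.n_genes,
            "markers_per_type": self.markers_per_type,
            "n_cells_per_donor": self.n_cells_per_donor,
            "n_mito_genes": self.n_mito_genes,
            "n_regulons": self.n_regulons,
        }
        for name, val in pos_int.items():
            if int(val) != val or val <= 0:
                raise SimConfigError(f"{name} must be a positive integer, got {val}")
        if self.marker_fold <= 1:
            raise SimConfigError("marker_fold must exceed 1")
        if self.nb_dispersion <= 0:
            raise SimConfigError("nb_dispersion must be positive")
        if not 0 <= self.doublet_rate <= 1:
            raise SimConfigError("doublet_rate must be a probability")
        if self.batch_shift_sd < 0:
            raise SimConfigError("batch_shift_sd must be non-negative")
        m, s = self.mito_fraction
        if not (0 <= m <= 1) or s < 0:
            raise SimConfigError("mito_fraction mean must be in [0,1], sd >= 0")
        if set(self.type_proportions) != set(self.donors_per_condition):
            raise SimConfigError(
                "type_proportions must cover exactly the configured conditions"
            )
        for cond, p in self.type_proportions.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (self.n_types,):
                raise SimConfigError(
                    f"type_proportions[{cond!r}] must have length n_types"
                )
            if (p < 0).any() or (p > 1).any():
                raise SimConfigError(f"type_proportions[{cond!r}] outside [0,1]")
            if abs(p.sum() - 1.0) > 1e-9:
                raise SimConfigError(
                    f"type_proportions[{cond!r}] sums to {p.sum()}, expected 1"
                )
        n_special = self.n_types * self.markers_per_type + self.n_dynamic_genes
        if n_special + self.n_mito_genes > self.n_genes:
            raise SimConfigError(
                "n_genes too small for the requested markers/dynamic/mito genes"
            )


@dataclass
class GroundTruth:
    """Latent state of a simulated dataset (one entry per cell)."""

    condition: str
    cell_labels: pd.Series
    donors: pd.Series
    doublet_flags: pd.Series
    pseudotime: pd.Series
    branch_probabilities: pd.DataFrame
    trend_functions: dict
    active_regulon_map: dict
    effects: PerturbationEffects | None = None

    def validate(self) -> None:
        assert self.cell_labels.notna().all()
        bp = self.branch_probabilities.to_numpy()
        assert ((bp >= 0) & (bp <= 1)).all()
        assert ((self.pseudotime >= 0) & (self.pseudotime <= 1)).all()


# ---------------------------------------------------------------------------
# gene-level parameters (shared between reference and query)
# ---------------------------------------------------------------------------

def _gene_params(config: SimConfig):
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(17,)))
    n = config.n_genes
    n_mito = config.n_mito_genes
    names = np.array(
        [f"G{i + 1:05d}" for i in range(n - n_mito)]
        + [f"MT-{i + 1}" for i in range(n_mito)]
    )
    is_mito = np.zeros(n, dtype=bool)
    is_mito[n - n_mito:] = True
    base_mean = rng.lognormal(0.0, 1.2, n)
    # mitochondrial genes get their own relative abundances but their summed
    # share per cell is rescaled to the configured fraction later
    non_mito_idx = np.flatnonzero(~is_mito)
    # marker genes come from the dropout-prone low-abundance half of the
    # transcriptome (where 10x discriminative markers live); trajectory-
    # dynamic genes from the well-expressed half (differentiation programs)
    med = np.median(base_mean[non_mito_idx])
    low_pool = non_mito_idx[base_mean[non_mito_idx] <= med]
    high_pool = non_mito_idx[base_mean[non_mito_idx] > med]
    n_marker = config.n_types * config.markers_per_type
    if n_marker > low_pool.size or config.n_dynamic_genes > high_pool.size:
        raise SimConfigError("n_genes too small for the requested marker pool")
    markers = rng.choice(low_pool, size=n_marker, replace=False)
    marker_idx = {
        t: np.sort(
            markers[k * config.markers_per_type:(k + 1) * config.markers_per_type]
        )
        for k, t in enumerate(config.cell_types)
    }
    dynamic_idx = np.sort(
        rng.choice(high_pool, size=config.n_dynamic_genes, replace=False)
    )

    trend_functions: dict[str, TrendFunction] = {}
    kinds = rng.choice(["linear", "sigmoid", "transient"], size=dynamic_idx.size)
    for gi, kind in zip(dynamic_idx, kinds):
        if kind == "linear":
            fn = TrendFunction(
                "linear",
                {"intercept": 0.5, "slope": float(rng.uniform(0.8, 2.0))},
            )
        elif kind == "sigmoid":
            fn = TrendFunction(
                "sigmoid",
                {
                    "lo": 0.3,
                    "hi": float(rng.uniform(1.5, 3.0)),
                    "midpoint": float(rng.uniform(0.3, 0.7)),
                    "scale": 0.08,
                },
            )
        else:
            fn = TrendFunction(
                "transient",
                {
                    "baseline": 0.4,
                    "amplitude": float(rng.uniform(1.0, 2.5)),
                    "center": float(rng.uniform(0.3, 0.7)),
                    "width": 0.12,
                },
            )
        trend_functions[names[gi]] = fn
    return {
        "names": names,
        "is_mito": is_mito,
        "base_mean": base_mean,
        "marker_idx": marker_idx,
        "dynamic_idx": dynamic_idx,
        "trend_functions": trend_functions,
    }


def _active_regulon_map(config: SimConfig) -> dict:
    regs = [f"R{i + 1:02d}" for i in range(config.n_regulons)]
    types = config.cell_types
    amap = {t: set(regs[: config.n_ubiquitous_regulons]) for t in types}
    for i, r in enumerate(regs[config.n_ubiquitous_regulons:]):
        amap[types[i % len(types)]].add(r)
    return amap


def _donor_batch_factor(config: SimConfig, cond_idx: int, donor_idx: int, n_genes):
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(31, cond_idx, donor_idx))
    )
    return np.exp(rng.normal(0.0, config.batch_shift_sd, n_genes))


def _softmax(x):
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


def _type_positions(types):
    return np.array([_TYPE_POSITION.get(t, 0.5) for t in types])


def _type_affinities(types):
    return np.array(
        [_TYPE_BRANCH_AFFINITY.get(t, (0.0,) * len(BRANCHES)) for t in types]
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _generate_dataset(
    config: SimConfig,
    condition: str,
    proportions: np.ndarray,
    trend_functions: dict,
    effects: PerturbationEffects | None,
):
    genes = _gene_params(config)
    types = config.cell_types
    cond_idx = list(config.donors_per_condition).index(condition)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1, cond_idx))
    )
    positions = _type_positions(types)
    affinities = _type_affinities(types)
    theta = config.nb_dispersion
    mu_l, sd_l = config.library_size_lognormal
    mito_mean, mito_sd = config.mito_fraction
    is_mito = genes["is_mito"]
    n_genes = config.n_genes

    trend_cols = {
        gene: int(np.flatnonzero(genes["names"] == gene)[0])
        for gene in trend_functions
    }

    blocks, labels_all, donors_all, t_all, bp_all, ids_all = [], [], [], [], [], []
    n_donors = config.donors_per_condition[condition]
    for d in range(n_donors):
        donor = f"{condition}{d + 1}"
        n = config.n_cells_per_donor
        batch = _donor_batch_factor(config, cond_idx, d, n_genes)
        lab = rng.choice(len(types), size=n, p=proportions)
        t = np.clip(
            positions[lab] + rng.normal(0.0, config.pseudotime_jitter, n), 0.0, 1.0
        )
        bp = _softmax(affinities[lab] + rng.normal(0.0, 0.25, (n, len(BRANCHES))))
        lib = rng.lognormal(mu_l, sd_l, n)
        frac = np.clip(rng.normal(mito_mean, mito_sd, n), 1e-4, 0.5)

        mean = np.tile(genes["base_mean"] * batch, (n, 1))
        for k, tname in enumerate(types):
            rows = np.flatnonzero(lab == k)
            if rows.size:
                cols = genes["marker_idx"][tname]
                mean[np.ix_(rows, cols)] *= config.marker_fold
        for gene, col in trend_cols.items():
            mean[:, col] = mean[:, col] * trend_functions[gene](t)

        nm_sum = mean[:, ~is_mito].sum(axis=1)
        m_sum = mean[:, is_mito].sum(axis=1)
        mean[:, ~is_mito] *= ((1.0 - frac) * lib / nm_sum)[:, None]
        mean[:, is_mito] *= (frac * lib / m_sum)[:, None]

        lam = rng.gamma(theta, mean / theta)
        counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts))
        labels_all.append(np.asarray(types)[lab])
        donors_all.append(np.repeat(donor, n))
        t_all.append(t)
        bp_all.append(bp)
        ids_all.append(np.array([f"{donor}_{i + 1:05d}" for i in range(n)]))

    X = sp.vstack(blocks).tocsr()
    labels = np.concatenate(labels_all)
    donors = np.concatenate(donors_all)
    t = np.concatenate(t_all)
    bp = np.vstack(bp_all)
    ids = np.concatenate(ids_all)
    doublet = np.zeros(len(ids), dtype=bool)

    n_dbl = int(round(config.doublet_rate * len(ids)))
    if n_dbl:
        parents = rng.choice(len(ids), size=(n_dbl, 2))
        same = parents[:, 0] == parents[:, 1]
        parents[same, 1] = (parents[same, 1] + 1) % len(ids)
        Xd = X[parents[:, 0]] + X[parents[:, 1]]
        X = sp.vstack([X, Xd]).tocsr()
        labels = np.concatenate([labels, labels[parents[:, 0]]])
        donors = np.concatenate([donors, donors[parents[:, 0]]])
        t = np.concatenate([t, (t[parents[:, 0]] + t[parents[:, 1]]) / 2.0])
        bp = np.vstack([bp, (bp[parents[:, 0]] + bp[parents[:, 1]]) / 2.0])
        dbl_ids = np.array(
            [f"{donors[parents[i, 0]]}_DBL{i + 1:04d}" for i in range(n_dbl)]
        )
        ids = np.concatenate([ids, dbl_ids])
        doublet = np.concatenate([doublet, np.ones(n_dbl, dtype=bool)])

    index = pd.Index(ids, name=None)
    obs = pd.DataFrame(
        {"donor": donors, "condition": condition, "cell_type": labels,
         "is_doublet": doublet},
        index=index,
    )
    var = pd.DataFrame(index=pd.Index(genes["names"], name=None))
    var["is_mito"] = is_mito
    marker_of = np.full(n_genes, "", dtype=object)
    for tname, cols in genes["marker_idx"].items():
        marker_of[cols] = tname
    var["marker_of"] = marker_of
    adata = ad.AnnData(X=sp.csr_matrix(X, dtype=np.int64), obs=obs, var=var)

    truth = GroundTruth(
        condition=condition,
        cell_labels=pd.Series(labels, index=index, name="cell_type"),
        donors=pd.Series(donors, index=index, name="donor"),
        doublet_flags=pd.Series(doublet, index=index, name="is_doublet"),
        pseudotime=pd.Series(t, index=index, name="pseudotime"),
        branch_probabilities=pd.DataFrame(bp, index=index, columns=list(BRANCHES)),
        trend_functions=dict(trend_functions),
        active_regulon_map=_active_regulon_map(config),
        effects=effects,
    )
    truth.validate()
    return adata, truth


def generate_reference(config: SimConfig):
    """Generate the labeled reference dataset (first configured condition)."""
    config.validate()
    condition = next(iter(config.donors_per_condition))
    genes = _gene_params(config)
    return _generate_dataset(
        config,
        condition,
        np.asarray(config.type_proportions[condition], dtype=float),
        genes["trend_functions"],
        effects=None,
    )


def shift_proportions(p: np.ndarray, types, shift: Mapping[str, float]) -> np.ndarray:
    """Apply additive deltas to selected types, rescaling the rest onto the
    simplex.  Raises :class:`SimConfigError` if the result leaves [0,1]."""
    p = np.asarray(p, dtype=float).copy()
    types = list(types)
    for t in shift:
        if t not in types:
            raise SimConfigError(f"proportion shift references unknown type {t!r}")
    shifted = np.array([types.index(t) for t in shift], dtype=int)
    deltas = np.array([shift[types[i]] for i in shifted])
    new_vals = p[shifted] + deltas
    if (new_vals < 0).any() or (new_vals > 1).any():
        raise SimConfigError("shifted proportions leave the [0,1] interval")
    rest = np.setdiff1d(np.arange(len(p)), shifted)
    rest_mass = 1.0 - new_vals.sum()
    if rest_mass < -1e-12 or (rest.size == 0 and abs(rest_mass) > 1e-12):
        raise SimConfigError("shifted proportions leave the simplex")
    out = p.copy()
    out[shifted] = new_vals
    if rest.size:
        base = p[rest].sum()
        if base <= 0 and rest_mass > 0:
            raise SimConfigError("cannot redistribute mass over zero-weight types")
        out[rest] = p[rest] / base * rest_mass if base > 0 else 0.0
    return out


def generate_query(
    config: SimConfig,
    reference_truth: GroundTruth,
    effects: PerturbationEffects | None = None,
    condition: str | None = None,
):
    """Generate a query dataset sharing the reference's gene universe, with
    optional proportion shifts and trend perturbations recorded in truth."""
    config.validate()
    effects = effects or PerturbationEffects()
    conds = list(config.donors_per_condition)
    if condition is None:
        condition = conds[1] if len(conds) > 1 else conds[0]
    if condition not in conds:
        raise SimConfigError(f"unknown condition {condition!r}")
    props = shift_proportions(
        np.asarray(config.type_proportions[condition], dtype=float),
        config.cell_types,
        effects.proportion_shift,
    )
    trend_functions = dict(reference_truth.trend_functions)
    for gene, spec in effects.trend_shift.items():
        if gene not in trend_functions:
            raise SimConfigError(f"trend perturbation references unknown gene {gene!r}")
        if "replace" in spec:
            trend_functions[gene] = spec["replace"]
        else:
            trend_functions[gene] = trend_functions[gene].perturbed(**spec)
    return _generate_dataset(config, condition, props, trend_functions, effects)


def generate_mixture_cells(
    adata: ad.AnnData,
    truth: GroundTruth,
    n_mixtures: int,
    seed: int = 0,
):
    """Synthetic 50/50 two-type mixture cells at standard sequencing depth.

    Each mixture pools the UMI counts of two random cells of *different*
    types and binomially thins the pooled profile to half, i.e. the read
    depth of a single cell — what a two-cell mixture looks like when
    sequenced at normal depth.  Returns (AnnData of mixtures, frame with the
    two parent types per mixture).
    """
    rng = np.random.default_rng(seed)
    labels = truth.cell_labels.to_numpy()
    types = sorted(pd.unique(labels))
    if len(types) < 2:
        raise SimConfigError("need at least two cell types to form mixtures")
    X = sp.csr_matrix(adata.X)
    rows, pairs = [], []
    for _ in range(n_mixtures):
        t1, t2 = rng.choice(types, size=2, replace=False)
        c1 = rng.choice(np.flatnonzero(labels == t1))
        c2 = rng.choice(np.flatnonzero(labels == t2))
        pooled = np.asarray((X[c1] + X[c2]).todense(), dtype=np.int64).ravel()
        rows.append(rng.binomial(pooled, 0.5))
        pairs.append((t1, t2))
    obs = pd.DataFrame(
        pairs, columns=["parent_type_a", "parent_type_b"],
        index=pd.Index([f"mixture_{i + 1:04d}" for i in range(n_mixtures)]),
    )
    mix = ad.AnnData(
        X=sp.csr_matrix(np.array(rows, dtype=np.int64)),
        obs=obs,
        var=adata.var.copy(),
    )
    return mix, obs


# ---------------------------------------------------------------------------
# regulon activity
# ---------------------------------------------------------------------------

def generate_auc_matrix(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Regulon x cell AUC activity matrix.

    Cells of clusters where a regulon is truly active draw from the high
    Gaussian mode, all others from the low mode; per-donor additive offsets
    emulate batch effects; values are clipped to [0, 1].
    """
    config.validate()
    if truth.active_regulon_map is None or truth.cell_labels is None:
        raise SimConfigError("truth must carry labels and an active_regulon_map")
    cond_idx = list(config.donors_per_condition).index(truth.condition)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(5, cond_idx))
    )
    regs = [f"R{i + 1:02d}" for i in range(config.n_regulons)]
    lo, hi = config.auc_modes
    labels = truth.cell_labels.to_numpy()
    donors = truth.donors.to_numpy()
    donor_names = list(dict.fromkeys(donors))
    n_cells = len(labels)
    offsets = rng.normal(0.0, config.batch_shift_sd, (len(donor_names), len(regs)))
    donor_ix = np.array([donor_names.index(d) for d in donors])
    out = np.empty((len(regs), n_cells))
    for ri, r in enumerate(regs):
        active_types = {
            t for t, active in truth.active_regulon_map.items() if r in active
        }
        mode = np.where(np.isin(labels, list(active_types)), hi, lo)
        vals = rng.normal(mode, config.auc_sd) + offsets[donor_ix, ri]
        out[ri] = np.clip(vals, 0.0, 1.0)
    return pd.DataFrame(out, index=regs, columns=truth.cell_labels.index)


def generate_regulon_edges(config: SimConfig) -> pd.DataFrame:
    """TF -> target edge list with importance scores for each regulon."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(7,)))
    genes = _gene_params(config)["names"]
    rows = []
    for i in range(config.n_regulons):
        tf = f"R{i + 1:02d}"
        targets = rng.choice(genes, size=config.regulon_targets, replace=False)
        imps = rng.lognormal(0.0, 1.0, config.regulon_targets)
        rows.extend(
            {"TF": tf, "target": t, "importance": float(w)}
            for t, w in zip(targets, imps)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk representation
# ---------------------------------------------------------------------------

def config_to_dict(config: SimConfig) -> dict:
    """JSON-serializable view of a configuration."""
    out = {}
    for key, value in vars(config).items():
        if isinstance(value, dict):
            out[key] = {
                k: (list(np.asarray(v, dtype=float)) if hasattr(v, "__len__")
                    and not isinstance(v, (str, int)) else v)
                for k, v in value.items()
            }
        elif isinstance(value, tuple):
            out[key] = list(value)
        else:
            out[key] = value
    return out


def write_dataset(
    adata: ad.AnnData,
    truth: GroundTruth,
    outdir: str | Path,
    config: SimConfig | None = None,
) -> Path:
    """Write counts (MTX dir), metadata, and trajectory ground truth as text."""
    outdir = Path(outdir)
    _io.write_mtx_dir(adata, outdir)
    traj = pd.concat(
        [truth.pseudotime, truth.branch_probabilities.add_prefix("bp_")], axis=1
    )
    traj.index.name = "cell_id"
    _io.write_tsv(traj, outdir / "trajectory.tsv")
    trends = {
        g: {"kind": fn.kind, "params": fn.params}
        for g, fn in truth.trend_functions.items()
    }
    _io.write_json(trends, outdir / "trend_functions.json")
    _io.write_json(
        {t: sorted(v) for t, v in truth.active_regulon_map.items()},
        outdir / "active_regulons.json",
    )
    if config is not None:
        _io.write_json(config_to_dict(config), outdir / "config.json")
    return outdir
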