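"""Class-weighted random-forest classifiers with out-of-bag validation.

The classifiers are ensembles of CART trees grown on bootstrap samples.
Because the training set is heavily imbalanced (roughly ten inactive
compounds per active one), category weights can act at two levels: at
the split level (default), where weights enter each tree's impurity
criterion over a uniform bootstrap, or at the bootstrap level
(``weight_mode="bootstrap"``), where each record's selection probability
is proportional to its category weight.  Split-level weighting is the
default because strongly up-weighted bootstrap draws put minority
records in nearly every tree's training sample, which starves them of
out-of-bag votes (see :func:`train`).

Every training compound receives an out-of-bag (OOB) probability vector:
the share of trees that did NOT see it during training and voted for each
category.  These OOB vectors provide an unbiased performance estimate
without a held-out split, and the class-probability vector doubles as the
applicability-domain measure downstream (diffuse vectors mean the
structure is not resolved by the predictors).

Five model configurations are used in practice: M_ALL 2/3 trained on all
compounds (2 or 3 activity categories) and M_arom 2/3/4 trained on
aromatic compounds only, where the better class balance supports up to
four categories.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .curation import CATEGORY_RANK, ActivityCategory
from .features import DescriptorMatrix, ImportanceVector
from .metrics import MetricsReport, collapse_to_binary, compute_metrics, confusion_grid

__all__ = [
    "Hyperparameters",
    "TrainedModel",
    "PredictionResult",
    "MODEL_TAGS",
    "train",
    "tune",
    "predict",
    "route_and_predict",
    "oob_importance",
    "oob_binary_metrics",
    "make_class_weights",
    "save_model",
    "load_model",
]

MODEL_TAGS = ("M_ALL_2", "M_ALL_3", "M_arom_2", "M_arom_3", "M_arom_4")


def _as_category(label) -> ActivityCategory:
    return label if isinstance(label, ActivityCategory) else ActivityCategory(label)


def _ladder_sort(categories) -> list[ActivityCategory]:
    return sorted(set(categories), key=lambda c: (CATEGORY_RANK[c], c.value))


@dataclass
class Hyperparameters:
    """Forest configuration: trees, predictors tried per split, terminal
    node size, and one positive weight per category."""

    n_trees: int = 300
    predictors_per_split: int | None = None  # None = floor(sqrt(p))
    min_node_size: int = 1
    class_weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.predictors_per_split is not None and self.predictors_per_split < 1:
            raise ValueError("predictors_per_split must be positive")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be positive")
        self.class_weights = {
            _as_category(k): float(v) for k, v in self.class_weights.items()
        }
        if any(w <= 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be strictly positive")

    def resolve_mtry(self, n_predictors: int) -> int:
        if self.predictors_per_split is None:
            return max(1, int(np.sqrt(n_predictors)))
        if self.predictors_per_split > n_predictors:
            raise ValueError(
                f"predictors_per_split {self.predictors_per_split} exceeds "
                f"{n_predictors} available predictors"
            )
        return self.predictors_per_split


def make_class_weights(categories, active_weight: float) -> dict:
    """Weight every non-inactive category ``active_weight``, inactive 1."""
    return {
        _as_category(c): (1.0 if _as_category(c) is ActivityCategory.INACTIVE else float(active_weight))
        for c in categories
    }


@dataclass
class PredictionResult:
    compound_id: str
    model_tag: str
    probabilities: dict  # ActivityCategory -> float, sums to 1
    predicted_category: ActivityCategory


@dataclass
class TrainedModel:
    model_tag: str
    categories: list  # ladder-ordered ActivityCategory
    hyperparameters: Hyperparameters
    predictor_names: list
    trees: list
    oob_indices: list  # per tree, row indices that were out-of-bag
    oob_probabilities: pd.DataFrame  # index compound ids, columns category values
    oob_missing: list  # compound ids never out-of-bag
    seed: int
    weight_mode: str
    training_ids: list

    def oob_predicted(self) -> pd.Series:
        """OOB majority-vote category per training compound (ties go to the
        less active category); NaN-row compounds are omitted."""
        probs = self.oob_probabilities.dropna()
        idx = probs.to_numpy().argmax(axis=1)
        return pd.Series(
            [self.categories[i] for i in idx], index=probs.index, name="oob_category"
        )


def _validate_training(labels) -> list[ActivityCategory]:
    cats = [_as_category(l) for l in labels]
    if len(set(cats)) < 2:
        raise ValueError("training labels contain a single category")
    return cats


def train(
    matrix: DescriptorMatrix,
    labels,
    hp: Hyperparameters | None = None,
    seed: int = 0,
    model_tag: str = "model",
    weight_mode: str = "split",
) -> TrainedModel:
    """Grow the weighted forest and compute the OOB probability matrix.

    ``weight_mode="split"`` (default) draws uniform bootstrap samples and
    passes the category weights to each tree's impurity criterion;
    ``"bootstrap"`` instead multiplies each record's bootstrap selection
    probability by its category weight.  Split-level weighting is the
    default because heavily up-weighted bootstrap draws place minority
    records in nearly every tree's sample, starving them of out-of-bag
    votes and biasing the OOB estimate for exactly the class the weights
    are meant to protect.
    """
    hp = hp or Hyperparameters()
    if weight_mode not in ("bootstrap", "split"):
        raise ValueError("weight_mode must be 'bootstrap' or 'split'")
    cats = _validate_training(labels)
    if len(cats) != matrix.values.shape[0]:
        raise ValueError("label count does not match matrix rows")
    categories = _ladder_sort(cats)
    weights = {c: hp.class_weights.get(c, 1.0) for c in categories}

    X = matrix.values.to_numpy(dtype=float)
    y = np.array([categories.index(c) for c in cats])
    n, p = X.shape
    mtry = hp.resolve_mtry(p)
    record_w = np.array([weights[categories[i]] for i in y])
    boot_p = record_w / record_w.sum()

    rng = np.random.default_rng(seed)
    votes = np.zeros((n, len(categories)))
    trees, oob_indices = [], []
    all_rows = np.arange(n)
    for _ in range(hp.n_trees):
        if weight_mode == "bootstrap":
            idx = rng.choice(n, size=n, replace=True, p=boot_p)
            sample_weight = None
        else:
            idx = rng.choice(n, size=n, replace=True)
            sample_weight = record_w[idx]
        tree_seed = int(rng.integers(2**31))
        tree = DecisionTreeClassifier(
            max_features=mtry,
            min_samples_leaf=hp.min_node_size,
            random_state=tree_seed,
        )
        tree.fit(X[idx], y[idx], sample_weight=sample_weight)
        oob = np.setdiff1d(all_rows, idx, assume_unique=False)
        if oob.size:
            pred = tree.predict(X[oob]).astype(int)
            votes[oob, pred] += 1
        trees.append(tree)
        oob_indices.append(oob)

    counts = votes.sum(axis=1)
    with np.errstate(invalid="ignore"):
        probs = votes / counts[:, None]
    ids = matrix.compound_ids
    oob_df = pd.DataFrame(
        probs, index=ids, columns=[c.value for c in categories]
    )
    missing = [ids[i] for i in np.flatnonzero(counts == 0)]
    return TrainedModel(
        model_tag=model_tag,
        categories=categories,
        hyperparameters=hp,
        predictor_names=matrix.predictor_names,
        trees=trees,
        oob_indices=oob_indices,
        oob_probabilities=oob_df,
        oob_missing=missing,
        seed=seed,
        weight_mode=weight_mode,
        training_ids=ids,
    )


def predict(model: TrainedModel, features: pd.DataFrame) -> list[PredictionResult]:
    """Predict category probabilities as the fraction of trees voting each
    category; argmax with ties broken toward the less active category.

    ``features`` columns must be a superset of the model's predictors; a
    missing column raises with its name.  Note a training compound
    re-predicted here uses ALL trees, which legitimately differs from its
    OOB vector.
    """
    missing = [c for c in model.predictor_names if c not in features.columns]
    if missing:
        raise KeyError(f"missing predictor column(s): {missing}")
    X = features[model.predictor_names].to_numpy(dtype=float)
    votes = np.zeros((X.shape[0], len(model.categories)))
    for tree in model.trees:
        pred = tree.predict(X).astype(int)
        votes[np.arange(X.shape[0]), pred] += 1
    probs = votes / len(model.trees)
    results = []
    for i, cid in enumerate(features.index):
        vec = {c: float(probs[i, j]) for j, c in enumerate(model.categories)}
        best = model.categories[int(np.argmax(probs[i]))]  # first max = least active
        results.append(
            PredictionResult(
                compound_id=str(cid),
                model_tag=model.model_tag,
                probabilities=vec,
                predicted_category=best,
            )
        )
    return results


def route_and_predict(
    features: pd.DataFrame,
    ring_classes: pd.Series,
    m_all3: TrainedModel,
    m_arom4: TrainedModel,
) -> dict:
    """Route each compound to its model(s).

    Non-aromatic compounds get the all-compound 3-category result only;
    aromatic compounds additionally get the aromatic 4-category result,
    which reduces false positives at the high-potency end.  Returns
    ``{compound_id: {model_tag: PredictionResult}}``.
    """
    out: dict[str, dict[str, PredictionResult]] = {}
    all3 = {r.compound_id: r for r in predict(m_all3, features)}
    arom_ids = [cid for cid in features.index if ring_classes.get(cid) == "aromatic_ring"]
    arom4 = {}
    if arom_ids:
        arom4 = {
            r.compound_id: r for r in predict(m_arom4, features.loc[arom_ids])
        }
    for cid in features.index:
        cid = str(cid)
        out[cid] = {m_all3.model_tag: all3[cid]}
        if cid in arom4:
            out[cid][m_arom4.model_tag] = arom4[cid]
    return out


def oob_binary_metrics(model: TrainedModel, labels) -> MetricsReport:
    """Binary (active/inactive collapse) panel from the OOB predictions."""
    cats = pd.Series([_as_category(l) for l in labels], index=model.training_ids)
    oob = model.oob_predicted()
    cats = cats.loc[oob.index]
    grid = confusion_grid(cats, oob, categories=model.categories)
    active = {c for c in model.categories if c is not ActivityCategory.INACTIVE}
    return compute_metrics(collapse_to_binary(grid, active))


def _default_grid(n_predictors: int) -> dict:
    """Grid axes: category weights, terminal node size, predictors per
    split, and number of trees."""
    mtry = max(1, int(np.sqrt(n_predictors)))
    return {
        "n_trees": [200, 400],
        "predictors_per_split": sorted({mtry // 2 or 1, mtry, 2 * mtry}),
        "min_node_size": [1, 5],
        "active_weight": [1.0, 5.0, 10.0],
    }


def _hp_from_point(point: dict, categories) -> Hyperparameters:
    return Hyperparameters(
        n_trees=int(point["n_trees"]),
        predictors_per_split=int(point["predictors_per_split"]),
        min_node_size=int(point["min_node_size"]),
        class_weights=make_class_weights(categories, float(point["active_weight"])),
    )


def tune(
    matrix: DescriptorMatrix,
    labels,
    search_space: dict | None = None,
    seed: int = 0,
    budget: int | None = None,
    n_refine: int = 0,
) -> tuple[Hyperparameters, pd.DataFrame]:
    """Hyperparameter search maximising OOB binary WOA.

    A systematic grid over ``search_space`` (axes: n_trees,
    predictors_per_split, min_node_size, active_weight) is evaluated
    first, each configuration trained with the same seed; ``n_refine``
    additional configurations are then proposed by a Gaussian-process
    surrogate (expected improvement over a seeded candidate pool).  Ties
    resolve to the smaller configuration (fewest trees first).  Returns
    the winning configuration and the full evaluation trace.
    """
    cats = _validate_training(labels)
    categories = _ladder_sort(cats)
    space = search_space or _default_grid(matrix.values.shape[1])
    keys = ("n_trees", "predictors_per_split", "min_node_size", "active_weight")
    missing = [k for k in keys if k not in space or not space[k]]
    if missing:
        raise ValueError(f"search space missing axes: {missing}")
    grid = [
        dict(zip(keys, combo))
        for combo in itertools.product(*(space[k] for k in keys))
    ]
    if budget is None:
        budget = len(grid) + n_refine
    if budget < 1:
        raise ValueError("optimizer budget must be at least 1")
    grid = grid[: max(1, budget - n_refine)]

    def _evaluate(point: dict) -> float:
        hp = _hp_from_point(point, categories)
        model = train(matrix, labels, hp, seed=seed)
        return float(oob_binary_metrics(model, labels).woa)

    trace_rows = []
    for point in grid:
        woa = _evaluate(point)
        trace_rows.append({**point, "woa": woa, "stage": "grid"})

    n_refine = min(n_refine, max(0, budget - len(grid)))
    if n_refine > 0:
        trace_rows += _gp_refine(
            trace_rows, space, keys, _evaluate, n_refine, seed
        )

    trace = pd.DataFrame(trace_rows)
    order = trace.sort_values(
        ["woa", "n_trees", "predictors_per_split", "min_node_size"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    best_row = order.iloc[0]
    best = _hp_from_point(best_row.to_dict(), categories)
    return best, trace


def _gp_refine(trace_rows, space, keys, evaluate, n_refine, seed):
    """Expected-improvement proposals from a GP surrogate fitted to the
    evaluated configurations (encoded on [0, 1] per axis)."""
    from scipy.stats import norm
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    lo = np.array([min(space[k]) for k in keys], dtype=float)
    hi = np.array([max(space[k]) for k in keys], dtype=float)
    span = np.where(hi > lo, hi - lo, 1.0)

    def _encode(point):
        return (np.array([point[k] for k in keys], dtype=float) - lo) / span

    rng = np.random.default_rng(seed + 1)
    rows = list(trace_rows)
    new_rows = []
    for _ in range(n_refine):
        Xs = np.array([_encode(r) for r in rows])
        ys = np.array([r["woa"] for r in rows])
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), normalize_y=True, alpha=1e-4,
            random_state=int(rng.integers(2**31)),
        )
        gp.fit(Xs, ys)
        cand = rng.uniform(size=(128, len(keys)))
        mu, sd = gp.predict(cand, return_std=True)
        best_y = ys.max()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best_y) / sd
            ei = np.where(sd > 0, (mu - best_y) * norm.cdf(z) + sd * norm.pdf(z), 0.0)
        pick = cand[int(np.argmax(ei))]
        point = {
            k: (float(v) if k == "active_weight" else int(round(v)))
            for k, v in zip(keys, lo + pick * span)
        }
        point = {
            k: max(point[k], 1) if k != "active_weight" else max(point[k], 1e-3)
            for k in keys
        }
        woa = evaluate(point)
        row = {**point, "woa": woa, "stage": "bayesian"}
        rows.append(row)
        new_rows.append(row)
    return new_rows


def oob_importance(
    model: TrainedModel, matrix: DescriptorMatrix, labels, seed: int = 0
) -> ImportanceVector:
    """Permutation importance on the OOB samples.

    For each tree, the misclassification rate on its OOB rows is compared
    with the rate after permuting one predictor at a time; the mean
    decrease in accuracy over trees is the predictor's importance
    (negative means clipped to zero).
    """
    cats = [_as_category(l) for l in labels]
    y = np.array([model.categories.index(c) for c in cats])
    X = matrix.values[model.predictor_names].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    drops = np.zeros(p)
    counts = np.zeros(p)
    for tree, oob in zip(model.trees, model.oob_indices):
        if oob.size == 0:
            continue
        Xo, yo = X[oob], y[oob]
        base = float(np.mean(tree.predict(Xo).astype(int) == yo))
        for j in range(p):
            perm = rng.permutation(oob.size)
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            acc = float(np.mean(tree.predict(Xp).astype(int) == yo))
            drops[j] += base - acc
            counts[j] += 1
    mean_drop = np.where(counts > 0, drops / np.maximum(counts, 1), 0.0)
    return ImportanceVector(list(model.predictor_names), np.clip(mean_drop, 0, None))


def save_model(model: TrainedModel, path: str) -> None:
    """Versioned archive: a joblib dump plus a JSON metadata sidecar."""
    joblib.dump(model, path)
    meta = {
        "format": "ahrqsar-model/1",
        "model_tag": model.model_tag,
        "categories": [c.value for c in model.categories],
        "n_predictors": len(model.predictor_names),
        "predictor_names": list(model.predictor_names),
        "seed": model.seed,
        "weight_mode": model.weight_mode,
        "hyperparameters": {
            "n_trees": model.hyperparameters.n_trees,
            "predictors_per_split": model.hyperparameters.predictors_per_split,
            "min_node_size": model.hyperparameters.min_node_size,
            "class_weights": {
                c.value: w for c, w in model.hyperparameters.class_weights.items()
            },
        },
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path: str) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise TypeError(f"{path} is not a serialized model archive")
    return model
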