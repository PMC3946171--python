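"""Comparator pipelines and the learning-curve benchmark harness.

The comparison set mirrors the standard supervised alternatives to the
active-learning classifier: logistic regression trained on randomly sampled
labels with no feature selection, and logistic regression after offline
feature selection by PCA (top principal components), univariate Welch
t-tests (smallest p-values) or MRMR (greedy mutual-information relevance
minus mean redundancy, MID form).  The harness replays each method over
independent replicates, growing the training set one label at a time to a
fixed budget and scoring accuracy on all remaining cells after each
addition, and reports mean and standard-error-of-mean curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mutual_info_score

from . import active
from .exceptions import ParameterError, ValidationError

__all__ = [
    "BenchmarkResult",
    "pca_select",
    "ttest_select",
    "mrmr_select",
    "random_sampling_lr",
    "benchmark_learning_curves",
    "BENCHMARK_METHODS",
]

BENCHMARK_METHODS = ("al", "random", "pca", "ttest", "mrmr")


@dataclass
class BenchmarkResult:
    """Learning curves of one method over replicates.

    ``accuracies`` has shape (replicates, steps); ``n_train[j]`` is the
    training-set size at step j.  ``sem_curve`` = sd/sqrt(replicates) (ddof=1
    when more than one replicate, else 0).
    """

    method: str
    accuracies: np.ndarray
    n_train: np.ndarray
    seeds: list[int]

    @property
    def mean_curve(self) -> np.ndarray:
        return self.accuracies.mean(axis=0)

    @property
    def sem_curve(self) -> np.ndarray:
        r = self.accuracies.shape[0]
        if r < 2:
            return np.zeros(self.accuracies.shape[1])
        return self.accuracies.std(axis=0, ddof=1) / np.sqrt(r)

    def to_long_frame(self) -> pd.DataFrame:
        reps, steps = self.accuracies.shape
        return pd.DataFrame(
            {
                "method": self.method,
                "replicate": np.repeat(np.arange(reps), steps),
                "n_train": np.tile(self.n_train, reps),
                "accuracy": self.accuracies.ravel(),
            }
        )


@dataclass
class PCATransform:
    """Top-k principal-component projection (components ordered by explained
    variance, descending)."""

    mean: np.ndarray
    components: np.ndarray  # (k, n_features)
    explained_variance: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.components.T


def pca_select(X: np.ndarray, k: int) -> PCATransform:
    """Fit the top-k PCA projection (data are centered internally)."""
    X = np.asarray(X, dtype=float)
    if not 1 <= k <= X.shape[1]:
        raise ParameterError(f"k must lie in [1, {X.shape[1]}]")
    pca = PCA(n_components=k, svd_solver="full").fit(X)
    return PCATransform(
        mean=pca.mean_,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
    )


def ttest_select(X: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    """Indices of the k features with the smallest Welch t-test p-values
    between the two classes; ties broken by feature index."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 0 or k > X.shape[1]:
        raise ParameterError(f"k must lie in [0, {X.shape[1]}]")
    a, b = X[y == 1], X[y == -1]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each class needs at least two members")
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(a, b, equal_var=False)
    pvals = np.nan_to_num(pvals, nan=1.0)
    order = np.lexsort((np.arange(len(pvals)), pvals))
    return [int(i) for i in order[:k]]


def _discretize(X: np.ndarray) -> np.ndarray:
    """3 bins per feature at mean ± sd (standard MRMR discretization)."""
    mu, sd = X.mean(axis=0), X.std(axis=0)
    out = np.ones_like(X, dtype=int)
    out[X < mu - sd] = 0
    out[X > mu + sd] = 2
    return out


def mrmr_select(X: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    """Greedy MRMR (MID form): first pick maximizes MI(f; y); each later pick
    maximizes MI(f; y) - mean MI(f; s) over already-selected s.  Ties broken
    by feature index."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = X.shape[1]
    if k < 0 or k > d:
        raise ParameterError(f"k must lie in [0, {d}]")
    Xd = _discretize(X)
    relevance = np.array([mutual_info_score(Xd[:, j], y) for j in range(d)])
    selected: list[int] = []
    redundancy = np.zeros(d)
    for _ in range(k):
        crit = relevance - (redundancy / len(selected) if selected else 0.0)
        crit[selected] = -np.inf
        pick = int(np.argmax(crit))  # argmax takes the first -> lowest index
        selected.append(pick)
        for j in range(d):
            if j not in selected:
                redundancy[j] += mutual_info_score(Xd[:, j], Xd[:, pick])
    return selected


def _lr() -> LogisticRegression:
    return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)


def _balanced_init(ids: np.ndarray, oracle, rng) -> list[tuple[int, int]]:
    """One labeled example per class, scanning ids in a seeded random order."""
    order = rng.permutation(np.sort(ids))
    got: dict[int, int] = {}
    for cid in order:
        lab = int(oracle(int(cid)))
        if lab not in got:
            got[lab] = int(cid)
        if len(got) == 2:
            return [(got[1], 1), (got[-1], -1)]
    raise ValidationError("pool does not contain both classes")


def random_sampling_lr(
    pool: pd.DataFrame,
    oracle,
    budget: int,
    seed: int,
    feature_matrix: np.ndarray | None = None,
):
    """Passive learning: uniform label sampling + unpenalized logistic fit.

    Starts from a class-balanced pair, then draws labels uniformly without
    replacement up to ``budget``.  After each addition the classifier is
    refit (skipped, carrying the previous fit, if the training set is
    single-class) and accuracy is recorded over all cells not yet in the
    training set.  Returns (final fitted model, accuracy trace, n_train).
    """
    ids = pool["cell_id"].to_numpy()
    if budget > len(ids):
        raise ParameterError("budget exceeds pool size")
    X = (
        feature_matrix
        if feature_matrix is not None
        else pool[active.feature_columns(pool)].to_numpy(dtype=float)
    )
    pos_of = {int(c): i for i, c in enumerate(ids)}
    rng = np.random.default_rng(seed)
    labeled = _balanced_init(ids, oracle, rng)
    chosen = {c for c, _ in labeled}
    order = [int(c) for c in rng.permutation(np.sort(ids)) if int(c) not in chosen]

    truth = {int(c): int(oracle(int(c))) for c in ids}  # evaluation labels
    clf = None
    accs, sizes = [], []

    def _record():
        # evaluate on cells outside the training set; when the budget has
        # consumed the whole pool, fall back to full-pool (training) accuracy
        rest = [i for i in range(len(ids)) if int(ids[i]) not in chosen]
        if not rest:
            rest = list(range(len(ids)))
        if clf is None:
            accs.append(np.nan)
        else:
            pred = clf.predict(X[rest])
            accs.append(float(np.mean([pred[j] == truth[int(ids[i])] for j, i in enumerate(rest)])))
        sizes.append(len(chosen))

    def _refit():
        nonlocal clf
        y = np.array([l for _, l in labeled])
        if len(np.unique(y)) < 2:
            return
        rows = [pos_of[c] for c, _ in labeled]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf = _lr().fit(X[rows], y)

    _refit()
    _record()
    while len(chosen) < budget and order:
        cid = order.pop(0)
        labeled.append((cid, truth[cid]))
        chosen.add(cid)
        _refit()
        _record()
    return clf, np.array(accs), np.array(sizes)


class _TableOracle:
    """Oracle over a labeled table (used internally by the harness)."""

    def __init__(self, table: pd.DataFrame):
        self._labels = dict(
            zip(table["cell_id"].astype(int), table["label"].astype(int))
        )

    def __call__(self, cid: int) -> int:
        return self._labels[int(cid)]


def _al_curve(pool, budget, seed):
    """Active-learning accuracy curve: accuracy over non-training cells after
    each labeled example from 2 (one per class) up to ``budget``."""
    oracle = _TableOracle(pool)
    truth = pool.set_index("cell_id")["label"]
    accs, sizes = [], []

    def cb(_it, state):
        rest = pool[~pool["cell_id"].isin(state.labeled_ids)]
        _, pred = active.predict_table(state.model, rest)
        accs.append(float(np.mean(pred == truth.loc[rest["cell_id"]].to_numpy())))
        sizes.append(len(state.labeled))

    cfg = active.ALConfig(
        seed=seed, max_iterations=max(budget - 2, 0), plateau_patience=10**6
    )
    active.run_active_learning(pool, oracle, cfg, callback=cb)
    return np.array(accs), np.array(sizes)


def benchmark_learning_curves(
    dataset: pd.DataFrame,
    methods=BENCHMARK_METHODS,
    n_replicates: int = 25,
    budget: int = 50,
    seeds: list[int] | None = None,
    k_select: int = 5,
    preselect_on_full: bool = True,
) -> list[BenchmarkResult]:
    """Replay each method over replicates and collect learning curves.

    Feature-selection baselines (pca/ttest/mrmr) select features offline on
    the full labeled design (set ``preselect_on_full=False`` to select on
    each replicate's sampled labels instead), then train logistic regression
    on randomly sampled labels; ``al`` runs the sequential D-optimal loop.
    """
    unknown = [m for m in methods if m not in BENCHMARK_METHODS]
    if unknown:
        raise ParameterError(f"unknown methods: {unknown}")
    if "label" not in dataset.columns:
        raise ValidationError("benchmark dataset needs hidden ground-truth labels")
    if seeds is None:
        seeds = [int(s) for s in range(1, n_replicates + 1)]
    if len(seeds) != n_replicates:
        raise ParameterError("need one seed per replicate")

    feats = active.feature_columns(dataset)
    X_full = dataset[feats].to_numpy(dtype=float)
    y_full = dataset["label"].to_numpy()

    transforms: dict[str, np.ndarray | None] = {}
    if preselect_on_full:
        if "pca" in methods:
            transforms["pca"] = pca_select(X_full, k_select).transform(X_full)
        if "ttest" in methods:
            transforms["ttest"] = X_full[:, ttest_select(X_full, y_full, k_select)]
        if "mrmr" in methods:
            transforms["mrmr"] = X_full[:, mrmr_select(X_full, y_full, k_select)]

    results = []
    for method in methods:
        curves = []
        for seed in seeds:
            if method == "al":
                accs, sizes = _al_curve(dataset, budget, seed)
            else:
                if method == "random":
                    Xm = X_full
                elif method in transforms:
                    Xm = transforms[method]
                else:
                    sel_seed_rng = np.random.default_rng(seed)
                    rows = sel_seed_rng.choice(len(dataset), size=budget, replace=False)
                    if method == "pca":
                        Xm = pca_select(X_full[rows], k_select).transform(X_full)
                    elif method == "ttest":
                        Xm = X_full[:, ttest_select(X_full[rows], y_full[rows], k_select)]
                    else:
                        Xm = X_full[:, mrmr_select(X_full[rows], y_full[rows], k_select)]
                _, accs, sizes = random_sampling_lr(
                    dataset, _TableOracle(dataset), budget, seed, feature_matrix=Xm
                )
            curves.append(accs)
        n_steps = min(len(c) for c in curves)
        acc_mat = np.vstack([c[:n_steps] for c in curves])
        results.append(
            BenchmarkResult(
                method=method,
                accuracies=acc_mat,
                n_train=np.arange(2, 2 + n_steps),
                seeds=list(seeds),
            )
        )
    return results
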