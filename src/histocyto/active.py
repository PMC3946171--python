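"""Active learning for sparse logistic regression via D-optimal design.

The classifier is a binary logistic regression with labels y in {-1, +1},
P(y=+1 | x) = sigma(beta^T x) with a leading intercept column of ones.  An
L1 penalty on the non-intercept coefficients promotes sparse solutions so
uninformative features receive (nearly) zero weight; the non-differentiable
|b| is smoothed as sqrt(b^2 + eps_s) ("eps-L1") and the smooth penalized
log-likelihood is maximized by a quasi-Newton optimizer.

Training examples are chosen sequentially: at each iteration the candidate
that maximizes the determinant of the regularized Fisher information matrix

    I(beta) = sum_i sigma(beta^T x_i)(1 - sigma(beta^T x_i)) x_i x_i^T + eps*D

is queried for its label (D-optimal experimental design: the inverse FIM
lower-bounds the coefficient covariance, so maximizing det I shrinks
parameter uncertainty fastest).  By the matrix determinant lemma,
det(I + w x x^T) = det(I) * (1 + w x^T I^{-1} x), so candidates are ranked by
the score w(x) * x^T I^{-1} x without forming any candidate determinant
explicitly.  Convergence is declared when the information gain ln det I
plateaus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datatypes import META_COLUMNS
from .exceptions import (
    ConflictError,
    ParameterError,
    QueryError,
    TrainingError,
    ValidationError,
)

__all__ = [
    "ClassifierModel",
    "ALConfig",
    "ALState",
    "fit_logistic",
    "train_on_table",
    "log_likelihood",
    "fisher_information",
    "information_gain",
    "select_query",
    "update_state",
    "check_convergence",
    "run_active_learning",
    "predict",
    "predict_table",
    "selected_features",
    "feature_columns",
]

DEFAULT_L1_EPS = 1e-6
DEFAULT_FIM_EPS = 1e-9


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic sigmoid."""
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=float)))


@dataclass
class ClassifierModel:
    """A fitted sparse logistic-regression model.

    ``beta[0]`` is the intercept; ``beta[1:]`` aligns with ``feature_names``.
    ``mean``/``scale`` are the per-feature standardization parameters applied
    before the dot product (features are z-scored with unlabeled-pool
    statistics so the L1 penalty acts on comparable scales).
    """

    beta: np.ndarray
    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    lam: float = 0.0
    l1_eps: float = DEFAULT_L1_EPS
    fim_eps: float = DEFAULT_FIM_EPS

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.beta.shape != (len(self.feature_names) + 1,):
            raise ValidationError("beta must have one entry per feature plus intercept")
        if np.any(self.scale <= 0):
            raise ValidationError("standardization scales must be positive")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature column names of a table (everything that is not metadata)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def _design_from_table(table: pd.DataFrame, model: ClassifierModel) -> np.ndarray:
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise ValidationError(f"table lacks feature columns: {missing}")
    X = table[model.feature_names].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite feature values")
    Z = (X - model.mean) / model.scale
    return np.column_stack([np.ones(len(Z)), Z])


def _check_design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("design matrix must be 2-D")
    if not np.isfinite(X).all():
        raise ValidationError("non-finite entries in design matrix")
    return X


def _penalized_negloglik(beta, X, y, lam, l1_eps):
    z = y * (X @ beta)
    nll = np.logaddexp(0.0, -z).sum()
    smooth_abs = np.sqrt(beta[1:] ** 2 + l1_eps)
    f = nll + lam * smooth_abs.sum()
    # gradient
    s = sigmoid(-z)  # = 1 - sigma(y z)
    g = -(X.T @ (y * s))
    g[1:] += lam * beta[1:] / smooth_abs
    return f, g


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float = 0.0,
    l1_eps: float = DEFAULT_L1_EPS,
    beta0: np.ndarray | None = None,
) -> ClassifierModel:
    """Maximize the eps-L1-penalized log-likelihood.

    ``X`` is the design matrix *including* the leading column of ones; the
    intercept is never penalized.  Returns a :class:`ClassifierModel` with
    generic feature names and identity standardization (table-level training
    goes through :func:`train_on_table` / :func:`run_active_learning`, which
    attach real names and pool statistics).
    """
    X = _check_design(X)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(X):
        raise ValidationError("X and y lengths differ")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValidationError("labels must be -1 or +1")
    if len(np.unique(y)) < 2:
        raise TrainingError("training requires at least one example of each class")
    if lam < 0:
        raise ParameterError("lambda must be >= 0")

    d = X.shape[1]
    x0 = np.zeros(d) if beta0 is None else np.asarray(beta0, dtype=float)
    res = minimize(
        _penalized_negloglik,
        x0,
        args=(X, y, lam, l1_eps),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta = res.x
    p = d - 1
    return ClassifierModel(
        beta=beta,
        feature_names=[f"x{j + 1}" for j in range(p)],
        mean=np.zeros(p),
        scale=np.ones(p),
        lam=lam,
        l1_eps=l1_eps,
    )


def _beta_of(model) -> np.ndarray:
    return model.beta if isinstance(model, ClassifierModel) else np.asarray(model, float)


def log_likelihood(model: ClassifierModel | np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Unpenalized log-likelihood sum_i ln sigma(y_i beta^T x_i); always <= 0."""
    beta = _beta_of(model)
    X = _check_design(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[1] != beta.shape[0] or len(y) != len(X):
        raise ValidationError("shape mismatch between beta, X and y")
    return float(-np.logaddexp(0.0, -y * (X @ beta)).sum())


def fisher_information(
    model: ClassifierModel | np.ndarray,
    X: np.ndarray,
    fim_eps: float | None = None,
) -> np.ndarray:
    """Regularized Fisher information sum_i w_i x_i x_i^T + eps*D.

    ``w_i = sigma(beta^T x_i) (1 - sigma(beta^T x_i))``.  D is the identity;
    the tiny ridge eps keeps the matrix positive definite (and its
    log-determinant finite) even before any example is labeled.  ``X`` may
    have zero rows.
    """
    beta = _beta_of(model)
    eps = fim_eps if fim_eps is not None else (
        model.fim_eps if isinstance(model, ClassifierModel) else DEFAULT_FIM_EPS
    )
    d = beta.shape[0]
    X = np.asarray(X, dtype=float).reshape(-1, d) if np.size(X) else np.empty((0, d))
    X = _check_design(X) if len(X) else X
    if len(X) and X.shape[1] != d:
        raise ValidationError("X column count does not match beta")
    p = sigmoid(X @ beta)
    w = p * (1.0 - p)
    fim = (X * w[:, None]).T @ X + eps * np.eye(d)
    return 0.5 * (fim + fim.T)  # enforce exact symmetry


def information_gain(fim: np.ndarray) -> float:
    """ln det of the (regularized) Fisher information matrix.

    Log scale is monotone in the determinant and numerically stable for the
    near-singular matrices that occur early in a run.
    """
    fim = np.asarray(fim, dtype=float)
    if fim.ndim != 2 or fim.shape[0] != fim.shape[1]:
        raise ValidationError("FIM must be square")
    if not np.allclose(fim, fim.T, rtol=1e-8, atol=1e-12):
        raise ValidationError("FIM must be symmetric")
    sign, logdet = np.linalg.slogdet(fim)
    if sign <= 0 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError(
            f"FIM is not positive definite (sign={sign}, logdet={logdet})"
        )
    return float(logdet)


@dataclass(frozen=True)
class ALConfig:
    """Knobs of the active-learning loop.

    ``lam_scale`` sets the L1 weight through the schedule
    ``lambda = lam_scale * sqrt(n_labeled)``, which keeps the penalty
    comparable to the sampling noise of the per-feature score as labels
    accrue.  ``plateau_tol``/``plateau_patience`` define the convergence
    plateau on the information-gain history.
    """

    n_init_per_class: int = 1
    max_iterations: int = 50
    batch_size: int = 1
    plateau_tol: float = 1e-3
    plateau_patience: int = 5
    lam_scale: float = 1.0
    l1_eps: float = DEFAULT_L1_EPS
    fim_eps: float = DEFAULT_FIM_EPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_init_per_class < 1 or self.batch_size < 1:
            raise ParameterError("counts must be >= 1")
        if self.max_iterations < 0:
            raise ParameterError("max_iterations must be >= 0")
        if self.plateau_tol <= 0:
            raise ParameterError("plateau_tol must be > 0")
        if self.plateau_patience < 1:
            raise ParameterError("plateau_patience must be >= 1")

    def lam_for(self, n_labeled: int) -> float:
        return self.lam_scale * math.sqrt(max(n_labeled, 1))


@dataclass
class ALState:
    """Snapshot of an active-learning run after some number of iterations."""

    model: ClassifierModel
    labeled: list[tuple[int, int]]
    fim: np.ndarray
    gain_history: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def labeled_ids(self) -> set[int]:
        return {i for i, _ in self.labeled}


def _labeled_design(pool: pd.DataFrame, model: ClassifierModel, labeled):
    idx = pool.set_index("cell_id")
    rows = idx.loc[[i for i, _ in labeled]].reset_index()
    X = _design_from_table(rows, model)
    y = np.array([l for _, l in labeled], dtype=float)
    return X, y


def select_query(
    state: ALState, pool: pd.DataFrame, batch_size: int = 1
) -> list[int]:
    """Pick the next cells to label by greedy D-optimal scoring.

    Every unlabeled candidate x is scored by ``w(x) * x^T I^{-1} x`` with
    ``w(x) = sigma(beta^T x)(1 - sigma(beta^T x))``, equivalent (via the
    matrix determinant lemma) to ranking by det(I + w x x^T).  For batches,
    the FIM is updated with each pick's expected contribution (no label
    needed) before re-scoring.  Ties go to the smallest cell id.
    """
    unlabeled = pool[~pool["cell_id"].isin(state.labeled_ids)]
    if unlabeled.empty:
        raise QueryError("no unlabeled candidates remain in the pool")
    unlabeled = unlabeled.sort_values("cell_id")
    ids = unlabeled["cell_id"].to_numpy()
    X = _design_from_table(unlabeled, state.model)
    p = sigmoid(X @ state.model.beta)
    w = p * (1.0 - p)

    fim = state.fim.copy()
    remaining = np.ones(len(ids), dtype=bool)
    picks: list[int] = []
    for _ in range(min(batch_size, len(ids))):
        sol = np.linalg.solve(fim, X.T)
        scores = w * np.einsum("ij,ji->i", X, sol)
        scores[~remaining] = -np.inf
        k = int(np.argmax(scores))  # first max -> smallest cell id on ties
        picks.append(int(ids[k]))
        remaining[k] = False
        fim = fim + w[k] * np.outer(X[k], X[k])
    return picks


def update_state(
    state: ALState,
    new_labels: list[tuple[int, int]],
    pool: pd.DataFrame,
    config: ALConfig,
) -> ALState:
    """Absorb new labels: refit the model, recompute the FIM, log the gain."""
    known = dict(state.labeled)
    pool_ids = set(pool["cell_id"].astype(int))
    for cid, lab in new_labels:
        if lab not in (-1, 1):
            raise ValidationError(f"label for cell {cid} must be -1 or +1")
        if int(cid) not in pool_ids:
            raise ValidationError(f"cell id {cid} is not in the pool")
        if cid in known and known[cid] != lab:
            raise ConflictError(
                f"cell {cid} already labeled {known[cid]}, got {lab}"
            )
    labeled = list(state.labeled) + [(int(c), int(l)) for c, l in new_labels]

    X, y = _labeled_design(pool, state.model, labeled)
    lam = config.lam_for(len(labeled))
    fitted = fit_logistic(
        X, y, lam=lam, l1_eps=config.l1_eps, beta0=state.model.beta
    )
    model = replace(
        state.model, beta=fitted.beta, lam=lam, l1_eps=config.l1_eps
    )
    fim = fisher_information(model, X, fim_eps=config.fim_eps)
    gain = information_gain(fim)
    return ALState(
        model=model,
        labeled=labeled,
        fim=fim,
        gain_history=list(state.gain_history) + [gain],
        converged=state.converged,
    )


def check_convergence(
    gain_history: list[float], plateau_tol: float, plateau_patience: int
) -> bool:
    """True iff the last ``plateau_patience`` relative gain increases are all
    below ``plateau_tol`` (relative to max(|previous|, 1))."""
    if len(gain_history) < plateau_patience + 1:
        return False
    g = np.asarray(gain_history, dtype=float)
    rel = (g[1:] - g[:-1]) / np.maximum(np.abs(g[:-1]), 1.0)
    return bool(np.all(rel[-plateau_patience:] < plateau_tol))


def _init_model(pool: pd.DataFrame, config: ALConfig) -> ClassifierModel:
    names = feature_columns(pool)
    X = pool[names].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite feature values in pool")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    keep = scale > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        names = [n for n, k in zip(names, keep) if k]
        mean, scale = mean[keep], scale[keep]
    if not names:
        raise ValidationError("no non-constant features in the pool")
    return ClassifierModel(
        beta=np.zeros(len(names) + 1),
        feature_names=names,
        mean=mean,
        scale=scale,
        lam=0.0,
        l1_eps=config.l1_eps,
        fim_eps=config.fim_eps,
    )


def _initial_labels(pool, oracle, config, init_ids):
    """Find n_init_per_class seed examples per class.

    If ``init_ids`` is given the caller chose the seeds (their labels still
    come from the oracle).  Otherwise cell ids are scanned in a seeded random
    order and the first n per class are kept; labels obtained for surplus
    scanned cells are discarded so the labeled set stays class-balanced.
    """
    if init_ids is not None:
        return [(int(i), int(oracle(i))) for i in init_ids]
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(np.sort(pool["cell_id"].to_numpy()))
    need = {-1: config.n_init_per_class, 1: config.n_init_per_class}
    out: list[tuple[int, int]] = []
    for cid in order:
        lab = int(oracle(int(cid)))
        if need.get(lab, 0) > 0:
            out.append((int(cid), lab))
            need[lab] -= 1
        if all(v == 0 for v in need.values()):
            return out
    raise TrainingError("pool does not contain enough examples of both classes")


def run_active_learning(
    pool: pd.DataFrame,
    oracle,
    config: ALConfig | None = None,
    init_ids: list[int] | None = None,
    callback=None,
) -> ALState:
    """Run the full query/label/refit loop.

    Seeds with ``n_init_per_class`` examples per class, then repeats
    select -> oracle -> refit until the information gain plateaus or
    ``max_iterations`` iterations have been performed.  Deterministic given
    the config seed and a deterministic oracle.  ``callback(iteration,
    state)``, if given, is invoked after every update (used by the CLI to log
    per-iteration information gain).
    """
    config = config or ALConfig()
    model = _init_model(pool, config)
    seed_state = ALState(model=model, labeled=[], fim=np.empty(0), gain_history=[])
    init = _initial_labels(pool, oracle, config, init_ids)
    state = update_state(seed_state, init, pool, config)
    if callback is not None:
        callback(0, state)

    for it in range(1, config.max_iterations + 1):
        try:
            picks = select_query(state, pool, config.batch_size)
        except QueryError:
            break  # pool exhausted
        try:
            answers = [(cid, int(oracle(cid))) for cid in picks]
        except Exception as exc:  # annotate, then propagate
            raise type(exc)(f"oracle failed at iteration {it}: {exc}") from exc
        state = update_state(state, answers, pool, config)
        if callback is not None:
            callback(it, state)
        if check_convergence(
            state.gain_history, config.plateau_tol, config.plateau_patience
        ):
            state.converged = True
            break
    return state


def train_on_table(
    table: pd.DataFrame, lam: float = 0.0, l1_eps: float = DEFAULT_L1_EPS
) -> ClassifierModel:
    """Fit on a fully labeled table (passive training convenience)."""
    if "label" not in table.columns:
        raise ValidationError("table has no label column")
    cfg = ALConfig(l1_eps=l1_eps)
    model = _init_model(table, cfg)
    X = _design_from_table(table, model)
    y = table["label"].to_numpy(dtype=float)
    fitted = fit_logistic(X, y, lam=lam, l1_eps=l1_eps)
    return replace(model, beta=fitted.beta, lam=lam)


def predict(model: ClassifierModel, X: np.ndarray):
    """Probabilities and ±1 labels for a raw design matrix (leading ones)."""
    X = _check_design(X)
    if X.shape[1] != model.beta.shape[0]:
        raise ValidationError("design width does not match model")
    p = sigmoid(X @ model.beta)
    labels = np.where(p > 0.5, 1, -1)  # strict: p == 0.5 -> negative
    return p, labels


def predict_table(model: ClassifierModel, table: pd.DataFrame):
    """Probabilities and ±1 labels for a feature table (applies the model's
    stored standardization)."""
    X = _design_from_table(table, model)
    return predict(model, X)


def selected_features(model: ClassifierModel, zero_tol: float = 1e-3) -> list[str]:
    """Feature names with |beta| above ``zero_tol``, largest first.

    With the eps-L1 penalty, truly uninformative features settle at
    magnitudes far below ``zero_tol`` while retained features keep O(1)
    weights on the standardized scale, so a fixed small tolerance separates
    the two regimes.
    """
    mags = np.abs(model.beta[1:])
    order = np.argsort(-mags, kind="stable")
    return [model.feature_names[j] for j in order if mags[j] > zero_tol]
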