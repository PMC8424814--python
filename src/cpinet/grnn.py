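"""Exemplar-based regression network (a generalized regression network).

The model keeps every training record as an exemplar ("pattern" node)
and predicts with a two-node summation pair -- a numerator
``sum_i y_i K(x, x_i)`` over a denominator ``sum_i K(x, x_i)`` with a
Gaussian kernel ``K(x, x_i) = exp(-||x - x_i||^2 / (2 sigma^2))``.
Mathematically this is Nadaraya-Watson kernel regression; predictions
are convex combinations of training targets.  The categorical analog (a
probabilistic network) accumulates kernel mass per class and predicts
the heaviest class.

The only trained quantity is the kernel bandwidth.  It minimizes a
leave-one-out criterion: mean squared leave-one-out prediction error
for continuous targets, leave-one-out misclassification rate for
classes.  Two parameterizations are available:

* ``shared``      -- one sigma for all inputs, chosen on a 32-point
  logarithmic grid over [1e-3, 1e3] (scaled-feature units) followed by
  golden-section refinement;
* ``per_feature`` -- one inverse squared bandwidth ("relevance") per
  input, optimized by L-BFGS on the leave-one-out criterion with an
  analytic gradient, started from the best shared sigma.  Irrelevant
  inputs are driven toward zero relevance, which matters in wide
  feature spaces where an equal-weight distance dilutes any single
  input's influence.

Training stops when the cycle budget (criterion evaluations), the
wall-clock budget, or convergence (no further error reduction) is
reached, whichever comes first; the model records which condition
fired.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .records import FeatureMatrix

__all__ = [
    "SplitSpec",
    "StopConditions",
    "GRNNModel",
    "EvalMetrics",
    "split",
    "fit",
    "predict",
    "predict_posterior",
    "loo_criterion",
    "evaluate",
    "save_model",
    "load_model",
]

_TINY = 1e-300


@dataclass(frozen=True)
class SplitSpec:
    """Train/test/holdout partition: the holdout "scenarios" are drawn
    first at random, the remainder splits train/test by fraction with
    largest-remainder rounding."""

    train_fraction: float = 0.80
    test_fraction: float = 0.20
    n_holdout: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train_fraction + self.test_fraction - 1.0) > 1e-9:
            raise ValueError("train and test fractions must sum to 1")
        if self.n_holdout < 0:
            raise ValueError("n_holdout must be >= 0")


@dataclass(frozen=True)
class StopConditions:
    """Training budgets: criterion evaluations ("cycles"), wall-clock
    seconds, and the minimum criterion improvement that still counts as
    progress."""

    max_cycles: int = 1_000_000
    max_seconds: float = 120.0
    min_improvement: float = 1e-10

    def __post_init__(self) -> None:
        if self.max_cycles <= 0 or self.max_seconds <= 0 or self.min_improvement <= 0:
            raise ValueError("all stop conditions must be positive")


@dataclass
class GRNNModel:
    """Fitted exemplar network.

    ``bandwidth`` is a positive scalar (shared) or a per-feature array
    of sigmas.  ``classes`` is None for the continuous task.  Feature
    metadata (column names and frozen scaling) travels with the model so
    any conforming query row can be checked and encoded consistently.
    """

    task: str  # "continuous" | "categorical"
    exemplars: np.ndarray
    targets: np.ndarray
    bandwidth: float | np.ndarray
    column_names: tuple[str, ...]
    scaling: dict[str, tuple[float, float]]
    classes: tuple | None = None
    exemplar_groups: tuple | None = None  # e.g. admission key per exemplar
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in ("continuous", "categorical"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.exemplars.ndim != 2 or len(self.exemplars) < 1:
            raise ValueError("exemplars must be a non-empty 2-D array")
        bw = np.asarray(self.bandwidth, dtype=float)
        if np.any(bw <= 0):
            raise ValueError("bandwidth must be positive")

    @property
    def n_exemplars(self) -> int:
        return len(self.exemplars)

    def _relevance(self) -> np.ndarray:
        """Per-feature inverse 2*sigma^2 used inside the kernel."""
        bw = np.asarray(self.bandwidth, dtype=float)
        if bw.ndim == 0:
            bw = np.full(self.exemplars.shape[1], float(bw))
        return 1.0 / (2.0 * bw**2)


def split(records: Sequence, spec: SplitSpec) -> tuple[list, list, list]:
    """Partition records into (train, test, holdout), disjoint and
    exhaustive, deterministic given ``spec.seed``."""
    n = len(records)
    if n < spec.n_holdout + 2:
        raise ValueError(f"{n} records cannot support {spec.n_holdout} holdout scenarios")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    holdout_idx = sorted(order[: spec.n_holdout])
    rest = np.sort(order[spec.n_holdout:])
    m = len(rest)
    n_train = int(math.floor(m * spec.train_fraction))
    n_test = int(math.floor(m * spec.test_fraction))
    leftover = m - n_train - n_test
    # largest-remainder rounding, train first on ties
    rema = [(m * spec.train_fraction) % 1.0, (m * spec.test_fraction) % 1.0]
    add = sorted(range(2), key=lambda i: (-rema[i], i))[:leftover]
    n_train += int(0 in add)
    n_test += int(1 in add)
    shuffled = rng.permutation(rest)
    train_idx = sorted(shuffled[:n_train])
    test_idx = sorted(shuffled[n_train: n_train + n_test])
    pick = lambda idx: [records[i] for i in idx]
    return pick(train_idx), pick(test_idx), pick(holdout_idx)


# ---------------------------------------------------------------------------
# Kernel machinery
# ---------------------------------------------------------------------------

def _as_matrix(features) -> tuple[np.ndarray, tuple[str, ...], dict]:
    if isinstance(features, FeatureMatrix):
        return features.matrix, features.column_names, features.scaling
    arr = np.asarray(features, dtype=float)
    if arr.ndim != 2:
        raise ValueError("feature array must be 2-D")
    return arr, tuple(f"x{i}" for i in range(arr.shape[1])), {}


def _energy(Q: np.ndarray, X: np.ndarray, rel: np.ndarray) -> np.ndarray:
    """Relevance-weighted squared distances via matrix products."""
    sq = np.sqrt(rel)
    Qr, Xr = Q * sq, X * sq
    a = (Qr**2).sum(axis=1)
    b = (Xr**2).sum(axis=1)
    E = a[:, None] + b[None, :] - 2.0 * Qr @ Xr.T
    np.maximum(E, 0.0, out=E)
    return E


def _weights(E: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        W = np.exp(-(E - E.min(axis=1, keepdims=True)))
    return np.nan_to_num(W, nan=0.0, posinf=0.0)


def predict(model: GRNNModel, x, exclude_groups=None) -> np.ndarray | float:
    """Kernel-weighted prediction for one row or a 2-D block of rows.

    Continuous: the normalized kernel average of training targets (a
    convex combination, so always within [min y, max y]).  Categorical:
    the class with the largest kernel mass, ties broken toward the more
    frequent training class then lexicographically.

    ``exclude_groups`` (one label per query row, matched against the
    model's ``exemplar_groups``) hides same-group exemplars from each
    query -- used for out-of-admission scenario predictions.
    """
    single = np.asarray(x).ndim == 1
    Q = np.atleast_2d(np.asarray(x, dtype=float))
    if Q.shape[1] != model.exemplars.shape[1]:
        raise ValueError(
            f"query has {Q.shape[1]} features, model expects {model.exemplars.shape[1]}")
    E = _energy(Q, model.exemplars, model._relevance())
    if exclude_groups is not None:
        if model.exemplar_groups is None:
            raise ValueError("model has no exemplar groups to exclude against")
        qg = np.asarray(exclude_groups)
        eg = np.asarray(model.exemplar_groups)
        E[qg[:, None] == eg[None, :]] = np.inf
    W = _weights(E)
    denom = np.maximum(W.sum(axis=1), _TINY)
    if model.task == "continuous":
        out = (W @ model.targets) / denom
        return float(out[0]) if single else out
    mass = _class_mass(model, W)
    out = np.array([model.classes[i] for i in _argmax_class(model, mass)])
    return out[0] if single else out


def predict_posterior(model: GRNNModel, x) -> tuple[np.ndarray, np.ndarray]:
    """Categorical posterior: (predicted classes, per-class kernel-mass
    fractions, columns ordered like ``model.classes``)."""
    if model.task != "categorical":
        raise ValueError("posterior is defined for the categorical task only")
    Q = np.atleast_2d(np.asarray(x, dtype=float))
    E = _energy(Q, model.exemplars, model._relevance())
    W = _weights(E)
    mass = _class_mass(model, W)
    probs = mass / np.maximum(mass.sum(axis=1, keepdims=True), _TINY)
    labels = np.array([model.classes[i] for i in _argmax_class(model, mass)])
    return labels, probs


def _class_mass(model: GRNNModel, W: np.ndarray) -> np.ndarray:
    onehot = np.stack([(model.targets == c).astype(float) for c in model.classes], axis=1)
    return W @ onehot


def _argmax_class(model: GRNNModel, mass: np.ndarray) -> np.ndarray:
    # ties: more frequent training class, then lexicographic (class order
    # is frozen that way at fit time)
    best = np.zeros(len(mass), dtype=int)
    for r, row in enumerate(mass):
        top = row.max()
        cands = [i for i, v in enumerate(row) if v >= top - 1e-12 * max(top, 1.0)]
        best[r] = cands[0]
    return best


def _exclusion_mask(n: int, groups) -> np.ndarray:
    """Boolean (n, n) mask of exemplars to hide from each held-out row.

    Plain leave-one-out hides only the row itself.  With ``groups``
    (one hashable label per row) all rows of the held-out row's group
    are hidden: an admission can contribute an accepted and a rejected
    record sharing the same observed outcome, and predicting one from
    its twin would leak that outcome and reward bandwidths that ignore
    the status-linked inputs.
    """
    if groups is None:
        return np.eye(n, dtype=bool)
    g = np.asarray(groups)
    if len(g) != n:
        raise ValueError("groups must provide one label per row")
    return g[:, None] == g[None, :]


def loo_criterion(features, targets, bandwidth, task: str = "continuous",
                  groups=None) -> float:
    """Leave-one-out criterion at a given bandwidth.

    Continuous: mean squared leave-one-out prediction error.
    Categorical: leave-one-out misclassification rate.  With ``groups``
    the whole group of the held-out row is excluded
    (leave-one-admission-out for paired consolidated records).
    """
    X, _, _ = _as_matrix(features)
    if len(X) < 2:
        raise ValueError("leave-one-out needs at least 2 rows")
    bw = np.asarray(bandwidth, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("bandwidth must be positive")
    rel = 1.0 / (2.0 * (np.full(X.shape[1], float(bw)) if bw.ndim == 0 else bw) ** 2)
    y = np.asarray(targets)
    mask = _exclusion_mask(len(X), groups)
    if task == "continuous":
        return _loo_mse(X, y.astype(float), rel, mask)
    classes = _ordered_classes(y)
    onehot = np.stack([(y == c).astype(float) for c in classes], axis=1)
    E = _energy(X, X, rel)
    E[mask] = np.inf
    W = np.exp(-(E - E.min(axis=1, keepdims=True)))
    W[~np.isfinite(E)] = 0.0
    mass = W @ onehot
    pred = mass.argmax(axis=1)
    truth = np.array([list(classes).index(c) for c in y])
    return float((pred != truth).mean())


def _loo_mse(X: np.ndarray, y: np.ndarray, rel: np.ndarray, mask: np.ndarray) -> float:
    E = _energy(X, X, rel)
    E[mask] = np.inf
    W = np.exp(-(E - E.min(axis=1, keepdims=True)))
    W[~np.isfinite(E)] = 0.0
    s = np.maximum(W.sum(axis=1), _TINY)
    pred = (W @ y) / s
    return float(((pred - y) ** 2).mean())


def _loo_mse_grad(X: np.ndarray, y: np.ndarray, log_rel: np.ndarray,
                  mask: np.ndarray) -> tuple[float, np.ndarray]:
    """LOO MSE and its gradient w.r.t. log relevances (matrix-product form)."""
    n = len(X)
    rel = np.exp(log_rel)
    E = _energy(X, X, rel)
    E[mask] = np.inf
    # per-row shift: cancels in pred and in the gradient, avoids underflow
    shift = E.min(axis=1, keepdims=True)
    W = np.exp(-(E - shift))
    W[~np.isfinite(E)] = 0.0
    s = np.maximum(W.sum(axis=1), _TINY)
    pred = (W @ y) / s
    res = pred - y
    mse = float((res**2).mean())
    B = (2.0 / n) * res[:, None] * (W * (y[None, :] - pred[:, None]) / s[:, None])
    X2 = X**2
    rowB = B.sum(axis=1)
    colB = B.sum(axis=0)
    cross = ((B @ X) * X).sum(axis=0)
    grad = -(rowB @ X2 + colB @ X2 - 2.0 * cross)
    return mse, grad * rel


def _ordered_classes(y: np.ndarray) -> tuple:
    """Classes ordered by descending training frequency, then value."""
    vals, counts = np.unique(y, return_counts=True)
    order = sorted(range(len(vals)), key=lambda i: (-counts[i], vals[i]))
    return tuple(vals[i] for i in order)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class _BudgetExhausted(Exception):
    def __init__(self, reason: str):
        self.reason = reason


class _Budget:
    def __init__(self, stop: StopConditions):
        self.stop = stop
        self.cycles = 0
        self.t0 = time.monotonic()

    def tick(self) -> None:
        self.cycles += 1
        if self.cycles >= self.stop.max_cycles:
            raise _BudgetExhausted("cycles")
        if time.monotonic() - self.t0 > self.stop.max_seconds:
            raise _BudgetExhausted("time")

    @property
    def seconds(self) -> float:
        return time.monotonic() - self.t0


_GRID = np.logspace(-3.0, 3.0, 32)
_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


#: Candidate pruning levels for per-feature relevances, on the scale of a
#: feature's expected squared-distance contribution between random rows.
_PRUNE_GRID = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)


def fit(
    features,
    targets,
    task: str = "continuous",
    stop: StopConditions = StopConditions(),
    seed: int = 0,
    bandwidth_mode: str = "shared",
    groups=None,
    val_features=None,
    val_targets=None,
) -> GRNNModel:
    """Train the network: store exemplars and select the bandwidth.

    ``bandwidth_mode="shared"`` searches one sigma on the log grid with
    golden-section refinement; ``"per_feature"`` (continuous task only)
    refines a relevance per input by L-BFGS from the shared optimum.
    ``groups`` (one hashable label per row, e.g. the admission key)
    switches the criterion to leave-one-group-out, which prevents a
    record's leave-one-out prediction from leaning on a same-admission
    twin that shares its observed outcome.

    With a validation set (``val_features``/``val_targets``, rows
    disjoint from training) the per-feature relevances are additionally
    *pruned*: features whose learned contribution to a typical squared
    distance falls below a candidate threshold are dropped, the most
    parsimonious candidate whose validation error is within one
    standard error of the best is kept (the usual 1-SE rule), and the
    surviving relevances are refit.  The relevance optimizer chases
    small spurious
    correlations in wide feature spaces; pruning removes them so that a
    genuinely irrelevant input has exactly zero influence on
    predictions.

    Deterministic given the data; ``seed`` is recorded in the metadata
    and reserved for stochastic extensions.
    """
    X, names, scaling = _as_matrix(features)
    if len(X) < 2:
        raise ValueError("need at least 2 training rows")
    if bandwidth_mode not in ("shared", "per_feature"):
        raise ValueError(f"unknown bandwidth_mode {bandwidth_mode!r}")
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("degenerate features: every column has zero variance")
    y = np.asarray(targets)
    if len(y) != len(X):
        raise ValueError("targets and features disagree in length")
    classes: tuple | None = None
    if task == "categorical":
        classes = _ordered_classes(y)
        if bandwidth_mode == "per_feature":
            raise ValueError("per-feature bandwidths support the continuous task only")
    elif task != "continuous":
        raise ValueError(f"unknown task {task!r}")

    budget = _Budget(stop)
    crit = lambda sig: loo_criterion(X, y, sig, task, groups=groups)
    best_sig, best_val, reason = _search_shared(crit, budget, stop)

    bandwidth: float | np.ndarray = best_sig
    prune_level = None
    if bandwidth_mode == "per_feature" and reason == "converged":
        rel0 = np.full(X.shape[1], 1.0 / (2.0 * best_sig**2))
        mask = _exclusion_mask(len(X), groups)
        log_rel, best_val, reason = _refine_per_feature(
            X, y.astype(float), np.log(rel0), mask, budget, stop)
        rel = np.exp(log_rel)
        if val_features is not None:
            Xv, _, _ = _as_matrix(val_features)
            yv = np.asarray(val_targets, dtype=float)
            rel, prune_level = _prune_relevances(X, y.astype(float), rel, Xv, yv)
            alive = rel > 0.0
            if alive.any() and not alive.all():
                # refit the surviving relevances so signal carried by a
                # pruned (correlated) input can be re-absorbed
                sub_log, best_val, reason = _refine_per_feature(
                    X[:, alive], y.astype(float), np.log(rel[alive]), mask,
                    budget, stop)
                rel = rel.copy()
                rel[alive] = np.exp(sub_log)
        with np.errstate(divide="ignore"):
            bandwidth = 1.0 / np.sqrt(2.0 * rel)  # pruned features: sigma = inf

    model = GRNNModel(
        task=task,
        exemplars=X.copy(),
        targets=y.copy(),
        bandwidth=bandwidth,
        column_names=names,
        scaling=dict(scaling),
        classes=classes,
        exemplar_groups=tuple(groups) if groups is not None else None,
        metadata={
            "seed": seed,
            "cycles": budget.cycles,
            "seconds": round(budget.seconds, 6),
            "criterion": best_val,
            "stop_reason": reason,
            "bandwidth_mode": bandwidth_mode,
            "prune_level": prune_level,
        },
    )
    return model


def _prune_relevances(
    X: np.ndarray, y: np.ndarray, rel: np.ndarray, Xv: np.ndarray, yv: np.ndarray
) -> tuple[np.ndarray, float]:
    """Validation-selected relevance pruning (1-SE parsimony rule).

    A feature's ``contribution`` is ``2 * relevance * variance``: the
    expected amount it adds to the squared distance between two random
    training rows.  Candidates zero out all features below a threshold;
    the most aggressive candidate whose validation MSE stays within one
    standard error of the minimum wins.  Parsimony matters downstream:
    a spuriously learned relevance on an edited input biases any
    input-editing (what-if) analysis, while a genuinely predictive
    input costs more than a standard error when dropped.
    """
    contrib = 2.0 * rel * X.var(axis=0)

    def val_mse(r: np.ndarray) -> tuple[float, float]:
        E = _energy(Xv, X, r)
        W = np.exp(-(E - E.min(axis=1, keepdims=True)))
        pred = (W @ y) / np.maximum(W.sum(axis=1), _TINY)
        errs = (pred - yv) ** 2
        return float(errs.mean()), float(errs.std(ddof=1) / math.sqrt(len(errs)))

    candidates: list[tuple[float, np.ndarray]] = [(0.0, rel)]
    for level in _PRUNE_GRID:
        pruned = np.where(contrib < level, 0.0, rel)
        if not pruned.any():
            break
        candidates.append((level, pruned))
    scores = [val_mse(r) for _, r in candidates]
    best_mse, best_se = min(scores, key=lambda s: s[0])
    keep = max(
        (i for i, (mse, _) in enumerate(scores) if mse <= best_mse + best_se),
        key=lambda i: candidates[i][0],
    )
    return candidates[keep][1], candidates[keep][0]


def _search_shared(crit, budget: _Budget, stop: StopConditions) -> tuple[float, float, str]:
    best_sig, best_val = None, np.inf
    try:
        vals = []
        for sig in _GRID:
            budget.tick()
            v = crit(sig)
            vals.append(v)
            if v < best_val - 0.0:  # strict: first (smaller sigma) wins ties
                best_sig, best_val = float(sig), v
        i = int(np.argmin(vals))
        lo = _GRID[max(i - 1, 0)]
        hi = _GRID[min(i + 1, len(_GRID) - 1)]
        # golden-section refinement on log sigma
        a, b = math.log(lo), math.log(hi)
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
        budget.tick(); fc = crit(math.exp(c))
        budget.tick(); fd = crit(math.exp(d))
        while b - a > 1e-3:
            if fc <= fd:
                b, d, fd = d, c, fc
                c = b - _GOLDEN * (b - a)
                budget.tick(); fc = crit(math.exp(c))
            else:
                a, c, fc = c, d, fd
                d = a + _GOLDEN * (b - a)
                budget.tick(); fd = crit(math.exp(d))
            cand_sig, cand_val = (math.exp(c), fc) if fc <= fd else (math.exp(d), fd)
            if cand_val < best_val - stop.min_improvement or (
                cand_val <= best_val and cand_sig < best_sig):
                best_sig, best_val = cand_sig, cand_val
        return best_sig, best_val, "converged"
    except _BudgetExhausted as exc:
        if best_sig is None:
            best_sig, best_val = 1.0, crit(1.0)
        return best_sig, best_val, exc.reason


def _refine_per_feature(
    X: np.ndarray, y: np.ndarray, log_rel0: np.ndarray, mask: np.ndarray,
    budget: _Budget, stop: StopConditions
) -> tuple[np.ndarray, float, str]:
    best = {"x": log_rel0, "f": np.inf, "reason": "converged"}

    def objective(lg):
        try:
            budget.tick()
        except _BudgetExhausted as exc:
            best["reason"] = exc.reason
            raise
        f, g = _loo_mse_grad(X, y, lg, mask)
        if f < best["f"]:
            best["x"], best["f"] = lg.copy(), f
        return f, g

    try:
        # bounded so exp(log relevance) can never overflow
        minimize(objective, np.clip(log_rel0, -40.0, 40.0), jac=True,
                 method="L-BFGS-B", bounds=[(-40.0, 40.0)] * len(log_rel0),
                 options={"maxiter": 500, "ftol": stop.min_improvement, "gtol": 1e-9})
    except _BudgetExhausted:
        pass
    if not np.isfinite(best["f"]):
        f, _ = _loo_mse_grad(X, y, log_rel0, mask)
        best["x"], best["f"] = log_rel0, f
    return best["x"], best["f"], best["reason"]


# ---------------------------------------------------------------------------
# Evaluation and serialization
# ---------------------------------------------------------------------------

@dataclass
class EvalMetrics:
    """Fit quality on a row set.

    Continuous: ``r2`` against the evaluation rows' own mean, ``rmse``,
    and the (predicted, observed) pairs.  Categorical: ``accuracy`` and
    a confusion dict keyed (observed, predicted)."""

    task: str
    n: int
    r2: float | None = None
    rmse: float | None = None
    pairs: np.ndarray | None = None
    accuracy: float | None = None
    confusion: dict | None = None


def evaluate(model: GRNNModel, features, targets) -> EvalMetrics:
    X, _, _ = _as_matrix(features)
    if len(X) == 0:
        raise ValueError("cannot evaluate on an empty row set")
    y = np.asarray(targets)
    pred = predict(model, X)
    if model.task == "continuous":
        y = y.astype(float)
        sse = float(((pred - y) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)
        return EvalMetrics(task="continuous", n=len(y), r2=r2,
                           rmse=math.sqrt(sse / len(y)),
                           pairs=np.column_stack([pred, y]))
    conf: dict = {}
    for obs, p in zip(y, pred):
        conf[(obs, p)] = conf.get((obs, p), 0) + 1
    acc = float(np.mean([p == obs for obs, p in zip(y, pred)]))
    return EvalMetrics(task="categorical", n=len(y), accuracy=acc, confusion=conf)


def save_model(model: GRNNModel, path) -> None:
    """Serialize a model to a single JSON document."""
    doc = {
        "format": "cpinet-grnn-1",
        "task": model.task,
        "bandwidth": np.asarray(model.bandwidth).tolist(),
        "column_names": list(model.column_names),
        "scaling": {k: list(v) for k, v in model.scaling.items()},
        "classes": list(model.classes) if model.classes is not None else None,
        "exemplar_groups": (list(model.exemplar_groups)
                            if model.exemplar_groups is not None else None),
        "exemplars": model.exemplars.tolist(),
        "targets": model.targets.tolist(),
        "metadata": model.metadata,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> GRNNModel:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != "cpinet-grnn-1":
        raise ValueError(f"not a serialized model: {path}")
    bw = doc["bandwidth"]
    return GRNNModel(
        task=doc["task"],
        exemplars=np.asarray(doc["exemplars"], dtype=float),
        targets=np.asarray(doc["targets"]),
        bandwidth=np.asarray(bw, dtype=float) if isinstance(bw, list) else float(bw),
        column_names=tuple(doc["column_names"]),
        scaling={k: (float(v[0]), float(v[1])) for k, v in doc["scaling"].items()},
        classes=tuple(doc["classes"]) if doc["classes"] is not None else None,
        exemplar_groups=(tuple(doc["exemplar_groups"])
                         if doc.get("exemplar_groups") is not None else None),
        metadata=doc.get("metadata", {}),
    )
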