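"""Variable impacts: per-input percentage contributions to predictions.

The headline method is permutation importance: shuffle one input
column (one-hot groups jointly) across records, measure the mean
increase in prediction error over repeats, floor negative values at
zero and normalize the result to sum to 100 %.  A "range sweep"
alternative varies one input over its observed quantiles while holding
each record's other inputs fixed and scores the induced output spread;
it is reported under its own method tag for robustness comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .grnn import GRNNModel, predict
from .records import FeatureMatrix

__all__ = ["VariableImpact", "variable_impacts", "grouped_impact"]


@dataclass(frozen=True)
class VariableImpact:
    """Impact percentages (non-negative, summing to 100) per variable."""

    impacts: Mapping[str, float]
    method: str
    n_repeats: int
    seed: int

    def __post_init__(self) -> None:
        total = sum(self.impacts.values())
        if self.impacts and abs(total - 100.0) > 1e-9:
            raise ValueError(f"impacts sum to {total}, expected 100")
        if any(v < -1e-9 for v in self.impacts.values()):
            raise ValueError("impacts must be non-negative")

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.impacts.items(), key=lambda kv: (-kv[1], kv[0]))


def _error(model: GRNNModel, X: np.ndarray, y: np.ndarray) -> float:
    pred = predict(model, X)
    if model.task == "continuous":
        return float(((np.asarray(pred, dtype=float) - y) ** 2).mean())
    return float((np.asarray(pred) != y).mean())


def _column_blocks(features) -> tuple[np.ndarray, list[tuple[str, list[int]]]]:
    if isinstance(features, FeatureMatrix):
        X = features.matrix
        grouped: set[int] = set()
        blocks: list[tuple[str, list[int]]] = []
        for gname, idx in features.groups.items():
            blocks.append((gname, list(idx)))
            grouped.update(idx)
        for i, name in enumerate(features.column_names):
            if i not in grouped:
                blocks.append((name, [i]))
        blocks.sort(key=lambda b: b[1][0])
        return X, blocks
    X = np.asarray(features, dtype=float)
    return X, [(f"x{i}", [i]) for i in range(X.shape[1])]


def variable_impacts(
    model: GRNNModel,
    features,
    targets,
    n_repeats: int = 5,
    seed: int = 0,
    method: str = "permutation",
) -> VariableImpact:
    """Impact percentage per input variable.

    ``features`` is a :class:`FeatureMatrix` (one-hot groups are then
    permuted as a block and reported as one variable) or a plain array.
    Requires at least 10 records for a stable baseline.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if method not in ("permutation", "range_sweep"):
        raise ValueError(f"unknown method {method!r}")
    X, blocks = _column_blocks(features)
    if len(X) < 10:
        raise ValueError("need at least 10 records for impact estimation")
    y = np.asarray(targets)
    if model.task == "continuous":
        y = y.astype(float)
    rng = np.random.default_rng(seed)

    raw: dict[str, float] = {}
    if method == "permutation":
        base = _error(model, X, y)
        for name, cols in blocks:
            bumps = []
            for _ in range(n_repeats):
                Xp = X.copy()
                perm = rng.permutation(len(X))
                Xp[:, cols] = X[np.ix_(perm, cols)]
                bumps.append(_error(model, Xp, y) - base)
            raw[name] = max(float(np.mean(bumps)), 0.0)
    else:
        if model.task != "continuous":
            raise ValueError("range sweep is defined for continuous predictions")
        qs = np.linspace(0.05, 0.95, 7)
        sub = X if len(X) <= 200 else X[rng.choice(len(X), 200, replace=False)]
        for name, cols in blocks:
            settings = np.quantile(X[:, cols], qs, axis=0)  # (q, |cols|)
            preds = []
            for srow in settings:
                Xq = sub.copy()
                Xq[:, cols] = srow
                preds.append(np.asarray(predict(model, Xq), dtype=float))
            raw[name] = float(np.mean(np.std(np.stack(preds), axis=0)))

    total = sum(raw.values())
    if total <= 0.0:
        # a flat model spreads its 100 % evenly
        impacts = {name: 100.0 / len(raw) for name in raw}
    else:
        impacts = {name: 100.0 * v / total for name, v in raw.items()}
    drift = 100.0 - sum(impacts.values())
    top = max(impacts, key=impacts.get)
    impacts[top] += drift  # absorb float round-off where it cannot flip a sign
    return VariableImpact(impacts=impacts, method=method, n_repeats=n_repeats, seed=seed)


def grouped_impact(vi: VariableImpact, groups: Mapping[str, str]) -> dict[str, float]:
    """Sum member impacts per group; ungrouped variables report as "other".

    ``groups`` maps variable name -> group label and must reference only
    known variables.
    """
    unknown = set(groups) - set(vi.impacts)
    if unknown:
        raise KeyError(f"unknown variable(s) in group map: {sorted(unknown)}")
    out: dict[str, float] = {}
    other = 0.0
    for name, pct in vi.impacts.items():
        if name in groups:
            out[groups[name]] = out.get(groups[name], 0.0) + pct
        else:
            other += pct
    if other or not groups:
        out["other"] = other
    return out
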