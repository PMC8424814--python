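"""Univariate group comparisons and sample-size calculators.

Accepted and rejected consolidated records are compared variable by
variable -- Mann-Whitney U for continuous inputs (the stays, ages,
CPI counts and the ordinal scores are far from normal) and Pearson
chi-squared without continuity correction for categorical ones.  No
multiple-testing correction is applied across the table; treat the
per-variable p-values descriptively.

Two sample-size calculators are included: the paired mean-change
formula (z approximation, or the self-consistent t iteration started
from the z solution) and the rule-of-thumb for exemplar networks --
inputs x 10 x second-layer neurons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.stats

from .records import ConsolidatedRecord, FULL_SCHEMA, Status, _GETTERS

__all__ = [
    "TestResult",
    "SampleSizeSpec",
    "mann_whitney_u",
    "chi_squared",
    "paired_mean_change_n",
    "ann_sample_heuristic",
    "compare_groups",
]


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n: int | tuple[int, int]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class SampleSizeSpec:
    """Paired mean-change design: two-tailed ``alpha``, target
    ``power``, standard deviation of the paired change ``sd_change``
    (days) and the difference to detect ``effect`` (days)."""

    alpha: float = 0.05
    power: float = 0.80
    sd_change: float = 1.05
    effect: float = 0.125
    statistic: str = "z"  # "z" | "t"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must be in (0, 1)")
        if self.sd_change <= 0:
            raise ValueError("sd_change must be positive")
        if self.effect <= 0:
            raise ValueError("effect must be positive")
        if self.statistic not in ("z", "t"):
            raise ValueError("statistic must be 'z' or 't'")


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test for two unpaired samples.

    Exact null distribution for small untied samples (min n <= 8),
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if np.all(pooled == pooled[0]):
        # both samples constant and equal: no evidence of a shift
        return TestResult("mann_whitney_u", statistic=a.size * b.size / 2.0,
                          p_value=1.0, n=(a.size, b.size))
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("mann_whitney_u", statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)), n=(a.size, b.size))


def chi_squared(table) -> TestResult:
    """Pearson chi-squared on a 2 x k contingency table, no continuity
    correction, df = k - 1."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2 x k")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal")
    stat, p, dof, _ = scipy.stats.chi2_contingency(t, correction=False)
    return TestResult("chi_squared", statistic=float(stat), p_value=float(p),
                      n=int(t.sum()))


def paired_mean_change_n(spec: SampleSizeSpec) -> int:
    """Sample size for a paired mean-change design, rounded up.

    z: ``n = ceil(((z_{1-alpha/2} + z_power) sd / effect)^2)``.
    t: iterate ``n -> ceil(((t_{1-alpha/2, n-1} + t_{power, n-1}) sd /
    effect)^2)`` from the z solution until self-consistent.
    """
    ratio = spec.sd_change / spec.effect
    z = scipy.stats.norm.ppf(1 - spec.alpha / 2) + scipy.stats.norm.ppf(spec.power)
    n_z = math.ceil((z * ratio) ** 2)
    if spec.statistic == "z":
        return int(n_z)
    def requirement(n: int) -> float:
        q = (scipy.stats.t.ppf(1 - spec.alpha / 2, n - 1)
             + scipy.stats.t.ppf(spec.power, n - 1))
        return (q * ratio) ** 2

    # the requirement shrinks as df grow, so stepping up from the z
    # solution finds the smallest self-consistent n (jumping by the
    # requirement itself could overshoot it at small df)
    n = max(n_z, 3)
    while n < requirement(n):
        n += 1
    return int(n)


def ann_sample_heuristic(n_inputs: int, n_second_layer: int = 2) -> int:
    """Rule-of-thumb training-set size: inputs x 10 x second-layer neurons."""
    if n_inputs < 1 or n_second_layer < 1:
        raise ValueError("both arguments must be >= 1")
    return int(n_inputs) * 10 * int(n_second_layer)


# ---------------------------------------------------------------------------
# Group comparison table
# ---------------------------------------------------------------------------

_OUTCOME_GETTERS: dict[str, tuple[str, Callable[[ConsolidatedRecord], float]]] = {
    "los_total": ("continuous", lambda r: r.admission.outcomes.los_total),
    "los_icu_total": ("continuous", lambda r: r.admission.outcomes.los_icu_total),
    "losta": ("continuous", lambda r: r.admission.outcomes.losta),
    "losicua": ("continuous", lambda r: r.admission.outcomes.losicua),
    "readmitted_30d": ("binary", lambda r: float(r.admission.outcomes.readmitted_30d)),
    "died": ("binary", lambda r: float(r.admission.outcomes.died)),
    "cost": ("continuous", lambda r: r.admission.outcomes.cost),
}


def _display(kind: str, values: np.ndarray) -> str:
    if kind == "binary":
        return f"Yes: {int(values.sum())} ({100.0 * values.mean():.0f}%)"
    return f"{np.median(values):g} ({values.min():g}-{values.max():g})"


def compare_groups(
    records: Sequence[ConsolidatedRecord],
    include_outcomes: bool = True,
    p_display_threshold: float = 0.10,
):
    """Accepted-versus-rejected comparison across the model inputs.

    Returns a pandas DataFrame (index = variable) with each group's
    summary in the study's display convention, the test used, the
    statistic, the machine-readable p-value, and a ``display_p`` that
    is blank for p at or above ``p_display_threshold`` (descriptive
    tables traditionally omit those).  Continuous and score variables
    go to Mann-Whitney; binary ones to chi-squared on the 2 x 2 table.
    Degenerate variables (a zero marginal) get a NaN p-value.
    """
    import pandas as pd

    acc = [r for r in records if r.status == Status.ACCEPTED]
    rej = [r for r in records if r.status == Status.REJECTED]
    if not acc or not rej:
        raise ValueError("need both an accepted and a rejected group")

    items: list[tuple[str, str, Callable]] = [
        (spec.name, spec.kind, _GETTERS[spec.name]) for spec in FULL_SCHEMA
    ]
    if include_outcomes:
        items += [(name, kind, get) for name, (kind, get) in _OUTCOME_GETTERS.items()]

    rows = []
    for name, kind, get in items:
        va = np.array([float(get(r)) for r in acc])
        vr = np.array([float(get(r)) for r in rej])
        if kind == "binary":
            table = [[va.sum(), len(va) - va.sum()], [vr.sum(), len(vr) - vr.sum()]]
            try:
                res = chi_squared(table)
                stat, p = res.statistic, res.p_value
            except ValueError:
                stat, p = float("nan"), float("nan")
            method = "chi_squared"
        else:
            res = mann_whitney_u(va, vr)
            stat, p, method = res.statistic, res.p_value, "mann_whitney_u"
        rows.append({
            "variable": name,
            "kind": kind,
            "accepted": _display(kind, va),
            "rejected": _display(kind, vr),
            "method": method,
            "statistic": stat,
            "p_value": p,
            "display_p": f"{p:.3f}" if p == p and p < p_display_threshold else "",
        })
    return pd.DataFrame(rows).set_index("variable")
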