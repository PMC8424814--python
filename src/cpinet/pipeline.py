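"""End-to-end orchestration: simulate/load -> consolidate -> train ->
reassign -> impacts -> report.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence.spawn``, so each stage is independently
reproducible.  Rerunning with the same configuration and seed
reproduces the report payload bit-identically except for timestamps
and wall-times.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .consolidate import consolidate_dataset
from .counterfactual import ReassignmentPolicy, run_counterfactual
from .grnn import SplitSpec, StopConditions, evaluate, fit, save_model, split
from .impacts import variable_impacts
from .records import (
    FULL_SCHEMA,
    ConsolidatedRecord,
    encode_features,
    read_cpi_log,
    validate_dataset,
    write_consolidated,
    write_cpi_log,
)
from .stats import compare_groups
from .synth import SynthConfig, default_config, generate

__all__ = ["RunConfig", "run_pipeline", "OUTCOME_KINDS"]

#: Outcome name -> (kind, extractor)
OUTCOME_KINDS = {
    "losta": ("continuous", lambda r: r.admission.outcomes.losta),
    "losicua": ("continuous", lambda r: r.admission.outcomes.losicua),
    "cost": ("continuous", lambda r: r.admission.outcomes.cost),
    "readmission": ("categorical", lambda r: "yes" if r.admission.outcomes.readmitted_30d else "no"),
    "mortality": ("categorical", lambda r: "died" if r.admission.outcomes.died else "alive"),
}


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    synth: SynthConfig | None = None  # None -> read input_log
    input_log: str | None = None
    out_dir: str | None = None
    outcomes: tuple[str, ...] = ("losta", "losicua", "cost", "readmission", "mortality")
    split: SplitSpec = field(default_factory=SplitSpec)
    stop: StopConditions = field(default_factory=StopConditions)
    policy: str = "both"  # "default" | "extended" | "both"
    bandwidth_mode: str = "per_feature"  # continuous outcomes; categorical use shared
    score_scope: str = "mixed"
    impact_repeats: int = 3
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.outcomes) - set(OUTCOME_KINDS)
        if unknown:
            raise ValueError(f"unknown outcome(s): {sorted(unknown)}")
        if self.policy not in ("default", "extended", "both"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.synth is None and self.input_log is None:
            raise ValueError("either a synthetic config or an input log is required")


def _stage_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, tuple):
            return list(o)
        return str(o)
    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the report document.

    With ``out_dir`` set, the raw log, the consolidated table, each
    outcome's model and the report (JSON + text summary) are written
    there; every reported number traces to one of those artifacts.
    """
    config.validate()
    t_start = time.time()
    seeds = _stage_seeds(config.seed, 4)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage: data -------------------------------------------------------
    if config.synth is not None:
        synth_cfg = config.synth
        dataset = generate(synth_cfg)
        cpis, admissions = dataset.cpis, dataset.admissions
        if out:
            write_cpi_log(out / "cpi_log.csv", cpis, admissions)
    else:
        cpis, admissions = read_cpi_log(config.input_log)
    issues = validate_dataset(cpis, admissions)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise ValueError(f"stage 'validate' failed: {errors[0].key}: {errors[0].message}")

    # --- stage: consolidate ------------------------------------------------
    records = consolidate_dataset(cpis, admissions, score_scope=config.score_scope)
    if out:
        write_consolidated(out / "consolidated.csv", records)

    # --- stage: univariate table ------------------------------------------
    univariate = compare_groups(records)

    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "stage_seeds": seeds,
            "config_hash": _config_hash(config),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        "counts": {
            "patients": len({a.patient_id for a in admissions}),
            "admissions": len(admissions),
            "cpis": len(cpis),
            "consolidated": len(records),
            "accepted": sum(r.status.value == "accepted" for r in records),
            "rejected": sum(r.status.value == "rejected" for r in records),
            "acceptance_rate": float(np.mean([c.accepted for c in cpis])),
        },
        "univariate": json.loads(univariate.to_json(orient="index")),
        "outcomes": {},
    }

    # --- stage: per-outcome model + counterfactual + impacts ---------------
    policies = {
        "default": [ReassignmentPolicy.default()],
        "extended": [ReassignmentPolicy.extended()],
        "both": [ReassignmentPolicy.default(), ReassignmentPolicy.extended()],
    }[config.policy]
    split_spec = SplitSpec(
        train_fraction=config.split.train_fraction,
        test_fraction=config.split.test_fraction,
        n_holdout=config.split.n_holdout,
        seed=seeds[1],
    )
    train, test, holdout = split(records, split_spec)

    for outcome in config.outcomes:
        kind, extract = OUTCOME_KINDS[outcome]
        y_train = [extract(r) for r in train]
        fm_train = encode_features(train, FULL_SCHEMA, include_status=True)
        fm_test = encode_features(test, FULL_SCHEMA, include_status=True,
                                  scaling=fm_train.scaling)
        y_test = [extract(r) for r in test]
        mode = config.bandwidth_mode if kind == "continuous" else "shared"
        admission_groups = [f"{r.patient_id}/{r.admission_id}" for r in train]
        model = fit(fm_train, y_train, task=kind, stop=config.stop,
                    seed=seeds[2], bandwidth_mode=mode, groups=admission_groups,
                    val_features=fm_test if mode == "per_feature" else None,
                    val_targets=y_test if mode == "per_feature" else None)
        if out:
            save_model(model, out / f"model_{outcome}.json")

        test_metrics = evaluate(model, fm_test, y_test)
        holdout_metrics = None
        if holdout:
            fm_hold = encode_features(holdout, FULL_SCHEMA, include_status=True,
                                      scaling=model.scaling)
            holdout_metrics = evaluate(model, fm_hold, [extract(r) for r in holdout])

        section: dict = {
            "kind": kind,
            "n_train": len(train),
            "n_test": len(test),
            "n_holdout": len(holdout),
            "model": dict(model.metadata),
            "test": _metrics_doc(test_metrics),
            "holdout": _metrics_doc(holdout_metrics) if holdout_metrics else None,
            "counterfactual": {},
        }
        for policy in policies:
            cf = run_counterfactual(model, records, policy, outcome=outcome,
                                    outcome_kind=kind)
            section["counterfactual"][policy.name] = {
                "factual_summary": cf.factual_summary,
                "counterfactual_summary": cf.counterfactual_summary,
                "mean_difference": cf.mean_difference if kind == "continuous" else None,
                "mean_difference_affected": (
                    cf.mean_difference_affected if kind == "continuous" else None),
                "test": {"method": cf.test.method, "statistic": cf.test.statistic,
                         "p_value": cf.test.p_value, "n": cf.test.n},
                "line": cf.scenario_line() if kind == "continuous" else None,
            }
        vi = variable_impacts(model, fm_train, y_train,
                              n_repeats=config.impact_repeats, seed=seeds[3])
        section["variable_impacts"] = dict(vi.ranked()[:15])
        report["outcomes"][outcome] = section

    report["provenance"]["wall_seconds"] = round(time.time() - t_start, 3)
    if out:
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, default=str)
        with open(out / "summary.txt", "w", encoding="utf-8") as fh:
            fh.write(render_summary(report))
    return report


def _metrics_doc(m) -> dict:
    doc = {"task": m.task, "n": m.n}
    if m.task == "continuous":
        doc.update({"r2": m.r2, "rmse": m.rmse})
    else:
        doc.update({"accuracy": m.accuracy,
                    "confusion": {f"{a}->{b}": v for (a, b), v in m.confusion.items()}})
    return doc


def render_summary(report: dict) -> str:
    """Human-readable digest mirroring the 'mean ± sd, median (range)'
    display convention."""
    c = report["counts"]
    lines = [
        f"cpinet run (seed {report['provenance']['seed']}, "
        f"config {report['provenance']['config_hash']})",
        f"{c['patients']} patients, {c['admissions']} admissions, {c['cpis']} CPI "
        f"({100 * c['acceptance_rate']:.0f}% accepted) -> "
        f"{c['consolidated']} consolidated records "
        f"({c['accepted']} accepted / {c['rejected']} rejected)",
        "",
    ]
    for outcome, sec in report["outcomes"].items():
        lines.append(f"== {outcome} ({sec['kind']}) ==")
        t = sec["test"]
        if sec["kind"] == "continuous":
            lines.append(f"  test fit: R2 = {t['r2']:.4f}, RMSE = {t['rmse']:.3f} (n={t['n']})")
        else:
            lines.append(f"  test fit: accuracy = {t['accuracy']:.3f} (n={t['n']})")
        for pol, cf in sec["counterfactual"].items():
            if sec["kind"] == "continuous":
                f, cfs = cf["factual_summary"], cf["counterfactual_summary"]
                lines.append(
                    f"  [{pol}] 100% acceptance {cfs['mean']:.1f} ± {cfs['sd']:.1f}, "
                    f"{cfs['median']:g} ({cfs['min']:g}-{cfs['max']:g}) versus 80% "
                    f"{f['mean']:.1f} ± {f['sd']:.1f}, {f['median']:g} "
                    f"({f['min']:g}-{f['max']:g}), P = {cf['test']['p_value']:.3f}; "
                    f"mean difference {cf['mean_difference']:.3f} "
                    f"(affected admissions {cf['mean_difference_affected']:.3f})")
            else:
                lines.append(
                    f"  [{pol}] factual {cf['factual_summary']} vs counterfactual "
                    f"{cf['counterfactual_summary']}, McNemar P = {cf['test']['p_value']:.3f}")
        top = list(sec["variable_impacts"].items())[:5]
        lines.append("  top variable impacts: "
                     + ", ".join(f"{k} {v:.1f}%" for k, v in top))
        lines.append("")
    return "\n".join(lines)
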