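"""Synthetic CPI/admission data with the study's statistical structure.

The generator emulates an eight-month, 100-bed acute-care hospital
dataset: about 542 patients, 574 admissions and 1700 CPI, three
clinical pharmacists with very different acceptance rates (57 / 95 /
86 percent, overall 84 percent), right-skewed hospital stays, and
admission-level risk flags whose marginal prevalences follow the
study's descriptive tables.  Correlation among risk flags is induced by
a latent per-admission "frailty" scalar; marginal prevalences are
preserved exactly by solving each flag's logistic intercept against the
standard-normal frailty distribution.

The causal structure is explicit and recorded in a ground-truth ledger:
post-index hospital stay (LOSTA) is a deterministic function of
*observed* covariates plus a small residual (the fitted model in the
study explained over 99 percent of outcome variance, so the emulated
outcome is likewise highly predictable), and an admission containing at
least one rejected CPI has ``delta_reject`` days added.  The ledger
stores each admission's factual and all-accepted counterfactual LOSTA,
enabling parameter-recovery tests of the counterfactual pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .records import (
    AdmissionRecord,
    CPIRecord,
    Outcomes,
    Phase,
    RISK_FLAG_NAMES,
    TYPE_FLAG_NAMES,
)

__all__ = [
    "PharmacistSpec",
    "SynthConfig",
    "LedgerEntry",
    "SynthDataset",
    "default_config",
    "null_config",
    "generate",
    "summarize",
]


@dataclass(frozen=True)
class PharmacistSpec:
    """One clinical pharmacist: acceptance probability and workload share
    per study phase (shares are normalized within each phase)."""

    pharmacist_id: str
    acceptance_prob: float
    share_phase1: float
    share_phase2: float


@dataclass(frozen=True)
class LedgerEntry:
    """Ground truth for one admission."""

    n_rejected: int
    treated: bool  # admission contains >= 1 rejected CPI
    losta_factual: float
    losta_counterfactual: float  # all CPI accepted


@dataclass
class SynthDataset:
    cpis: list[CPIRecord]
    admissions: list[AdmissionRecord]
    ledger: dict[tuple[str, str], LedgerEntry]


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults reproduce the study's scale.

    ``delta_reject`` is the causal estimand knob: days added to LOSTA
    when an admission contains at least one rejected CPI (or per
    rejected CPI with ``per_cpi_effect``).  ``dependence`` scales the
    latent-frailty loading of the risk flags (0 = independent flags).
    """

    n_patients: int = 542
    readmission_prob: float = 0.059
    phase2_prob: float = 0.49
    # CPI count per admission: 1 + negative binomial, frailty-scaled mean
    cpi_negbin_r: float = 0.7
    cpi_mean_extra: float = 1.85
    cpi_frailty_coef: float = 0.35
    cpi_max: int = 38
    # demographics
    pediatric_prob: float = 0.265
    age_adult_mean: float = 52.0
    age_adult_sd: float = 19.0
    age_max: float = 92.0
    age_min: float = 0.05
    prevalence: Mapping[str, float] = field(default_factory=dict)
    dependence: float = 0.6
    # providers
    pharmacists: tuple[PharmacistSpec, ...] = (
        PharmacistSpec("CP1", 0.57, 0.22, 0.085),
        PharmacistSpec("CP2", 0.95, 0.28, 0.28),
        PharmacistSpec("CP3", 0.86, 0.50, 0.635),
    )
    n_physicians: int = 40
    physician_propensity_sd: float = 0.4  # lognormal sigma, mean-one multipliers
    rejection_mode: str = "provider"  # or "uniform"
    uniform_reject_prob: float = 0.16
    # per-CPI categorical judgments
    complexity_probs: tuple[float, float, float] = (0.12, 0.15, 0.73)  # simple/follow-up/complex
    intention_problem_prob: float = 0.90
    domain_clinical_prob: float = 0.88
    consult_prob: float = 0.16
    outcomes_driven_prob: float = 0.25
    type_flag_probs: Mapping[str, float] = field(default_factory=dict)
    # diagnoses
    diagnosis_mean_extra: float = 1.2
    diagnosis_revision_prob: float = 0.12
    # outcome model: LOSTA = b0 + coef . covariates + delta * treated + noise
    losta_intercept: float = 0.4
    losta_coefs: Mapping[str, float] = field(default_factory=dict)
    losta_noise_sd: float = 0.3
    losta_base_max: float = 42.0
    delta_reject: float = 0.4
    per_cpi_effect: bool = False
    # pre-index stay
    losbi_mu: float = 0.3
    losbi_frailty_coef: float = 0.4
    losbi_sigma: float = 1.0
    losbi_shift: float = 0.4
    losbi_max: float = 38.0
    # cost model (Jordanian dinars)
    cost_intercept: float = 230.0
    cost_slope: float = 420.0
    cost_lognoise_sd: float = 0.32
    # secondary outcome logits
    readmission_base: float = 0.125
    readmission_coefs: Mapping[str, float] = field(default_factory=dict)
    mortality_base: float = 0.006
    mortality_coefs: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "readmission_prob": self.readmission_prob,
            "phase2_prob": self.phase2_prob,
            "pediatric_prob": self.pediatric_prob,
            "uniform_reject_prob": self.uniform_reject_prob,
            "intention_problem_prob": self.intention_problem_prob,
            "domain_clinical_prob": self.domain_clinical_prob,
            "consult_prob": self.consult_prob,
            "outcomes_driven_prob": self.outcomes_driven_prob,
            "diagnosis_revision_prob": self.diagnosis_revision_prob,
            "readmission_base": self.readmission_base,
            "mortality_base": self.mortality_base,
        }
        probs.update({f"prevalence[{k}]": v for k, v in self.prevalence.items()})
        probs.update({f"type_flag_probs[{k}]": v for k, v in self.type_flag_probs.items()})
        for ph in self.pharmacists:
            probs[f"acceptance_prob[{ph.pharmacist_id}]"] = ph.acceptance_prob
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"config field {name} = {v} is not a probability")
        if self.delta_reject < 0:
            raise ValueError("config field delta_reject must be >= 0")
        if abs(sum(self.complexity_probs) - 1.0) > 1e-9:
            raise ValueError("config field complexity_probs must sum to 1")
        if self.rejection_mode not in ("provider", "uniform"):
            raise ValueError(f"config field rejection_mode invalid: {self.rejection_mode!r}")
        if self.losta_noise_sd < 0 or self.cost_lognoise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


#: Admission-level boolean prevalences (fraction of admissions), chosen to
#: track the study's descriptive tables; risk flags load on frailty.
_DEFAULT_PREVALENCE: dict[str, float] = {
    "gender_male": 0.55,
    "nationality_jordan": 0.92,
    "insured": 0.675,
    "critical": 0.30,
    "anticholinergic": 0.003,
    "antiarrhythmic": 0.015,
    "dementia": 0.069,
    "anemia": 0.051,
    "heart_failure": 0.034,
    "two_antihypertensives": 0.082,
    "three_antihypertensives": 0.032,
    "beta_blocker": 0.110,
    "benzodiazepine": 0.039,
    "tricyclic": 0.0,
    "non_green_antibiotic": 0.481,
    "surgical": 0.108,
    "polypharmacy_ge8": 0.175,
    "multi_comorbidity": 0.278,
    "vascular": 0.089,
    "acei_arb": 0.107,
    "diuretic": 0.094,
    "renal": 0.196,
    "liver": 0.037,
    "high_alert_med": 0.387,
}

#: Per-CPI recommendation-type probabilities (OR-aggregation over a
#: subgroup of 2-3 CPI then matches the consolidated-table prevalences).
_DEFAULT_TYPE_PROBS: dict[str, float] = {
    "non_drug": 0.23,
    "change_form": 0.075,
    "change_dose": 0.47,
    "change_frequency": 0.35,
    "change_route": 0.14,
    "change_duration": 0.065,
    "safety_related": 0.175,
    "efficacy_related": 0.21,
    "stop_medication": 0.165,
    "add_medication": 0.12,
    "drug_prescribing_step": 0.42,
    "miscellaneous": 0.34,
    "not_determined": 0.03,
}

# The default outcome truth is deliberately low-dimensional and driven by
# covariates that are independent of the rejection process: remaining stay
# tracks the stay already accrued and ICU status.  Comorbidity flags
# correlate with the outcome through frailty (they share its latent
# driver with los_before_index) but carry no conditional effect, and the
# CPI count carries none either -- a direct CPI-count effect would be
# confounded with rejection by construction (more CPI mechanically means
# a higher chance that at least one is rejected), leaving no overlap for
# any adjustment method at high CPI counts.
_DEFAULT_LOSTA_COEFS: dict[str, float] = {
    "los_before_index": 0.45,
    "critical": 1.2,
}

_DEFAULT_READMISSION_COEFS = {"polypharmacy_ge8": 0.5, "multi_comorbidity": 0.4, "renal": 0.3}
_DEFAULT_MORTALITY_COEFS = {"critical": 1.2, "heart_failure": 0.8, "elderly_gt84": 0.7}


def default_config(seed: int = 0) -> SynthConfig:
    """The study-scale configuration (about 542 / 574 / 1700)."""
    return SynthConfig(
        prevalence=dict(_DEFAULT_PREVALENCE),
        type_flag_probs=dict(_DEFAULT_TYPE_PROBS),
        losta_coefs=dict(_DEFAULT_LOSTA_COEFS),
        readmission_coefs=dict(_DEFAULT_READMISSION_COEFS),
        mortality_coefs=dict(_DEFAULT_MORTALITY_COEFS),
        seed=seed,
    )


def null_config(seed: int = 0) -> SynthConfig:
    """A calibration configuration with no signal anywhere.

    Physician decisions are independent coin flips (probability 0.5, so
    accepted and rejected subgroup sizes are exchangeable), pharmacists
    are interchangeable, risk flags are mutually independent
    (``dependence = 0``) with prevalences pulled into [0.1, 0.9] so
    group-comparison tests are non-degenerate, and the rejection effect
    on LOSTA is zero.  Used for type-I-error calibration of the
    univariate comparisons and for null runs of the counterfactual
    pipeline.
    """
    cfg = default_config(seed)
    prev = {k: min(max(v, 0.10), 0.90) for k, v in cfg.prevalence.items()}
    return replace(
        cfg,
        prevalence=prev,
        dependence=0.0,
        pharmacists=tuple(
            replace(p, acceptance_prob=0.5) for p in cfg.pharmacists
        ),
        physician_propensity_sd=0.0,
        rejection_mode="uniform",
        uniform_reject_prob=0.5,
        delta_reject=0.0,
        # one CPI per admission: each admission then contributes exactly
        # one consolidated record, so the accepted and rejected groups
        # are independent samples (an admission contributing a record to
        # both groups would couple them and break the nominal test level)
        cpi_mean_extra=0.0,
        cpi_frailty_coef=0.0,
    )


# ---------------------------------------------------------------------------
# Frailty-preserving flag sampling
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(40)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _solve_intercept(p: float, coef: float) -> float:
    """Intercept b with E_z[expit(b + coef z)] = p for z ~ N(0, 1)."""
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    if coef == 0.0:
        return float(logit(p))
    f = lambda b: float(np.dot(_GH_WEIGHTS, expit(b + coef * _GH_NODES))) - p
    lo, hi = logit(p) - abs(coef) * 6 - 1, logit(p) + abs(coef) * 6 + 1
    return float(brentq(f, lo, hi, xtol=1e-12))


def _round_half_day(x: float) -> float:
    return round(x * 2.0) / 2.0


#: Flags whose occurrence tracks overall patient frailty.
_FRAILTY_LINKED = set(RISK_FLAG_NAMES) | {"critical"}


def generate(config: SynthConfig) -> SynthDataset:
    """Draw a complete raw dataset plus ground-truth ledger.

    Deterministic given ``config.seed``; every record satisfies the
    domain invariants checked by :func:`cpinet.records.validate_dataset`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    prev = config.prevalence or _DEFAULT_PREVALENCE
    type_probs = config.type_flag_probs or _DEFAULT_TYPE_PROBS
    losta_coefs = config.losta_coefs or _DEFAULT_LOSTA_COEFS
    readm_coefs = config.readmission_coefs or _DEFAULT_READMISSION_COEFS
    mort_coefs = config.mortality_coefs or _DEFAULT_MORTALITY_COEFS

    intercepts = {
        name: _solve_intercept(p, config.dependence if name in _FRAILTY_LINKED else 0.0)
        for name, p in prev.items()
    }
    physicians = [f"MD{i + 1:02d}" for i in range(config.n_physicians)]
    if config.physician_propensity_sd > 0:
        raw = rng.lognormal(0.0, config.physician_propensity_sd, config.n_physicians)
        propensity = dict(zip(physicians, raw / raw.mean()))
    else:
        propensity = {d: 1.0 for d in physicians}
    shares = {
        Phase.I: np.array([p.share_phase1 for p in config.pharmacists], dtype=float),
        Phase.II: np.array([p.share_phase2 for p in config.pharmacists], dtype=float),
    }
    for ph in shares:
        shares[ph] = shares[ph] / shares[ph].sum()

    cpis: list[CPIRecord] = []
    admissions: list[AdmissionRecord] = []
    ledger: dict[tuple[str, str], LedgerEntry] = {}

    for ip in range(config.n_patients):
        patient_id = f"P{ip + 1:04d}"
        n_adm = 1 + int(rng.random() < config.readmission_prob)
        for ia in range(n_adm):
            admission_id = f"{patient_id}A{ia + 1}"
            frailty = float(rng.normal())
            phase = Phase.II if rng.random() < config.phase2_prob else Phase.I

            # demographics
            if rng.random() < config.pediatric_prob:
                age = float(np.clip(rng.lognormal(1.1, 1.1), config.age_min, 17.9))
            else:
                age = float(np.clip(rng.normal(config.age_adult_mean, config.age_adult_sd),
                                    18.0, config.age_max))
            flags = {
                name: bool(rng.random() < expit(
                    intercepts[name]
                    + (config.dependence if name in _FRAILTY_LINKED else 0.0) * frailty))
                if np.isfinite(intercepts[name]) else intercepts[name] > 0
                for name in prev
            }
            risk = {name: flags[name] for name in RISK_FLAG_NAMES}

            # pre-index stays
            losbi = _round_half_day(min(max(
                rng.lognormal(config.losbi_mu + config.losbi_frailty_coef * frailty,
                              config.losbi_sigma) - config.losbi_shift, 0.0),
                config.losbi_max))
            losicubi = _round_half_day(losbi * rng.beta(2, 5)) if flags["critical"] else 0.0

            # CPI count
            mean_extra = config.cpi_mean_extra * math.exp(config.cpi_frailty_coef * frailty)
            p_nb = config.cpi_negbin_r / (config.cpi_negbin_r + mean_extra)
            k = 1 + int(rng.negative_binomial(config.cpi_negbin_r, p_nb))
            k = min(k, config.cpi_max)

            physician = physicians[int(rng.integers(config.n_physicians))]
            pharm_idx = rng.choice(len(config.pharmacists), size=k, p=shares[phase])

            n_rejected = 0
            for j in range(k):
                pharm = config.pharmacists[int(pharm_idx[j])]
                if config.rejection_mode == "provider":
                    p_rej = min((1.0 - pharm.acceptance_prob) * propensity[physician], 0.95)
                else:
                    p_rej = config.uniform_reject_prob
                rejected = rng.random() < p_rej
                n_rejected += int(rejected)
                cx = float(("0", "0.5", "1")[int(rng.choice(3, p=config.complexity_probs))])
                cpis.append(CPIRecord(
                    patient_id=patient_id,
                    admission_id=admission_id,
                    cpi_order=j + 1,
                    phase=phase,
                    pharmacist_id=pharm.pharmacist_id,
                    physician_id=physician,
                    accepted=not rejected,
                    type_flags={f: bool(rng.random() < type_probs.get(f, 0.0))
                                for f in TYPE_FLAG_NAMES},
                    complexity_code=cx,
                    intention_code=float(rng.random() < config.intention_problem_prob),
                    domain_code=float(rng.random() < config.domain_clinical_prob),
                    consult_initiated=bool(rng.random() < config.consult_prob),
                    outcomes_driven=bool(rng.random() < config.outcomes_driven_prob),
                ))

            # post-index stay: observed-covariate base + rejection effect
            base = config.losta_intercept
            for name, coef in losta_coefs.items():
                if name == "los_before_index":
                    base += coef * losbi
                elif name == "total_cpi_extra":
                    base += coef * (k - 1)
                elif name == "critical":
                    base += coef * flags["critical"]
                elif name == "age_years":
                    base += coef * age
                else:
                    base += coef * risk[name]
            base = min(base, config.losta_base_max)
            noise = float(rng.normal(0.0, config.losta_noise_sd)) if config.losta_noise_sd else 0.0
            while base + noise < 0.0:  # truncate so stays are non-negative
                noise = float(rng.normal(0.0, config.losta_noise_sd))
            effect = config.delta_reject * (n_rejected if config.per_cpi_effect else int(n_rejected > 0))
            losta = _round_half_day(base + noise + effect)
            losicua = _round_half_day(losta * rng.beta(2, 4)) if flags["critical"] else 0.0

            los_total = losbi + losta
            los_icu_total = losicubi + losicua

            lo = lambda p0, coefs: expit(
                logit(max(p0, 1e-9)) + sum(
                    c * (flags[n] if n in flags else float(age > 84))
                    for n, c in coefs.items()))
            readmitted = bool(rng.random() < lo(config.readmission_base, readm_coefs))
            died = bool(rng.random() < lo(config.mortality_base, mort_coefs))
            cost = float((config.cost_intercept + config.cost_slope * los_total)
                         * rng.lognormal(0.0, config.cost_lognoise_sd))

            admissions.append(AdmissionRecord(
                patient_id=patient_id,
                admission_id=admission_id,
                age_years=age,
                gender="M" if flags["gender_male"] else "F",
                nationality="Jordan" if flags["nationality_jordan"] else "Other",
                age_group="adult" if age >= 18.0 else "pediatric",
                critical=flags["critical"],
                elderly_gt84=age > 84.0,
                insured=flags["insured"],
                los_before_index=losbi,
                los_icu_before_index=losicubi,
                risk_flags=risk,
                diagnoses=tuple(
                    (f"dx{m + 1}", bool(rng.random() < config.diagnosis_revision_prob))
                    for m in range(1 + int(rng.poisson(config.diagnosis_mean_extra)))
                ),
                outcomes=Outcomes(
                    los_total=los_total,
                    los_icu_total=los_icu_total,
                    losta=losta,
                    losicua=losicua,
                    readmitted_30d=readmitted,
                    died=died,
                    cost=cost,
                ),
            ))
            ledger[(patient_id, admission_id)] = LedgerEntry(
                n_rejected=n_rejected,
                treated=n_rejected > 0,
                losta_factual=losta,
                losta_counterfactual=losta - effect,
            )

    return SynthDataset(cpis=cpis, admissions=admissions, ledger=ledger)


# ---------------------------------------------------------------------------
# Descriptive summary
# ---------------------------------------------------------------------------

def _fmt_num(x: float) -> str:
    return f"{x:g}"


def summarize(dataset: SynthDataset):
    """Marginal summaries in the study's display conventions.

    Returns a pandas DataFrame indexed by variable with a ``summary``
    column: continuous variables as ``median (min-max)``, booleans as
    ``Yes: n (p%)``.  Intended for eyeball comparison against the
    published descriptive tables.
    """
    import pandas as pd

    if not dataset.admissions:
        raise ValueError("cannot summarize an empty dataset")
    rows: dict[str, str] = {}

    def cont(name: str, values) -> None:
        v = np.asarray(values, dtype=float)
        rows[name] = f"{_fmt_num(float(np.median(v)))} ({_fmt_num(v.min())}-{_fmt_num(v.max())})"

    def boolean(name: str, values) -> None:
        v = np.asarray(values, dtype=bool)
        rows[name] = f"Yes: {int(v.sum())} ({100.0 * v.mean():.0f}%)"

    adm = dataset.admissions
    cont("age_years", [a.age_years for a in adm])
    cont("los_before_index", [a.los_before_index for a in adm])
    cont("los_icu_before_index", [a.los_icu_before_index for a in adm])
    cont("los_total", [a.outcomes.los_total for a in adm])
    cont("los_icu_total", [a.outcomes.los_icu_total for a in adm])
    cont("losta", [a.outcomes.losta for a in adm])
    cont("losicua", [a.outcomes.losicua for a in adm])
    cont("cost", [a.outcomes.cost for a in adm])
    boolean("critical", [a.critical for a in adm])
    boolean("elderly_gt84", [a.elderly_gt84 for a in adm])
    boolean("insured", [a.insured for a in adm])
    boolean("gender_male", [a.gender == "M" for a in adm])
    boolean("nationality_jordan", [a.nationality == "Jordan" for a in adm])
    boolean("age_group_adult", [a.age_group == "adult" for a in adm])
    boolean("readmitted_30d", [a.outcomes.readmitted_30d for a in adm])
    boolean("died", [a.outcomes.died for a in adm])
    for f in RISK_FLAG_NAMES:
        boolean(f"risk_{f}", [a.risk_flags[f] for a in adm])
    cpis = dataset.cpis
    if cpis:
        boolean("accepted", [c.accepted for c in cpis])
        counts: dict[tuple[str, str], int] = {}
        for c in cpis:
            counts[(c.patient_id, c.admission_id)] = counts.get((c.patient_id, c.admission_id), 0) + 1
        cont("total_cpi", list(counts.values()))
    return pd.DataFrame({"summary": pd.Series(rows)})
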