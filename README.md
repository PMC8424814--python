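# cpinet

Counterfactual analysis of clinical pharmacy intervention (CPI)
acceptance with an exemplar-based regression network.

Hospital clinical pharmacists recommend changes to drug therapy —
stop a medication, change a dose, switch a route — and the treating
physician accepts or rejects each recommendation. Acceptance rates sit
around 80 %. The question this package addresses: **what would happen
to patient outcomes (post-intervention length of stay, ICU stay,
readmission, mortality, hospitalization cost) if physicians accepted
100 % of CPI instead?** It is aimed at clinical-pharmacy and
health-services researchers who hold per-intervention logs of usual
care and want a reproducible what-if pipeline rather than an
unattainable randomized design.

## The method

1. **Consolidation.** Raw data are one row per CPI. All CPI of one
   patient-admission collapse into at most one *accepted* and one
   *rejected* record carrying ten ordinal scores in [0, 1] (means of
   per-CPI judgments such as problem complexity; the fraction of the
   admission's CPI rejected; study-period provider rates averaged over
   the admission) and OR-aggregated recommendation-type flags. 54 input
   variables plus the accepted/rejected status.

2. **Exemplar network (GRNN).** A general regression network keeps one
   pattern node per training record and predicts through a
   numerator/denominator summation pair — Nadaraya–Watson kernel
   regression,

   ŷ(x) = Σᵢ yᵢ·exp(−d²(x, xᵢ)/2) / Σᵢ exp(−d²(x, xᵢ)/2),
   d²(x, xᵢ) = Σₖ rₖ (xₖ − xᵢₖ)²,

   with per-feature relevances rₖ = 1/(2σₖ²) (or one shared σ) chosen
   to minimize a leave-one-admission-out squared error, pruned against
   a validation split (1-SE rule), and refit. A kernel-mass analog
   handles categorical outcomes.

3. **Reassignment.** Every record is edited as if all CPI had been
   accepted (status → accepted, rejection score → 0; the extended
   policy also sets combined CP success → 1 and physician rejection
   → 0, their definitional values under full acceptance). Both
   scenarios are predicted out-of-admission and compared pairwise:
   Wilcoxon signed-rank for continuous outcomes, continuity-corrected
   McNemar for categorical ones. Permutation variable impacts
   (normalized to 100 %) rank the inputs.

4. **Supporting statistics.** Accepted-vs-rejected univariate tables
   (Mann–Whitney U / Pearson χ²), the paired mean-change sample-size
   calculator (z and self-consistent t forms), and the
   inputs × 10 × second-layer-neurons network sizing rule.

Because the study's hospital data are not public, a **synthetic
generator** reproduces the study conditions — ~542 patients / ~574
admissions / ~1700 CPI, three pharmacists with 57/95/86 % acceptance
(84 % overall), table-calibrated prevalences and right-skewed stays —
with an explicit, configurable causal effect of rejection on
post-intervention stay and a ground-truth ledger for parameter-recovery
testing.

## Worked example

```sh
cpinet run-all --seed 1 --out runs/demo
```

prints (abridged):

```
cpinet run (seed 1, config 2ebf84b1fc70f34d)
542 patients, 574 admissions, 1600 CPI (83% accepted) -> 713 consolidated records (528 accepted / 185 rejected)

== losta (continuous) ==
  test fit: R2 = 0.9571, RMSE = 0.326 (n=142)
  [extended] 100% acceptance 1.6 ± 1.4, 1.27 (0.5-11.5) versus 80%
             1.8 ± 1.4, 1.34 (0.5-11.5), P = 0.000;
             mean difference 0.119 (affected admissions 0.263)
  top variable impacts: los_before_index 83.8%, critical 13.5%, score_rejection 1.5%, ...
```

Reading this: the fitted network explains ~96 % of the variance in
post-intervention stay on held-out records. Accepting the ~17 % of CPI
that physicians rejected would shorten the average stay by 0.12 days
per consolidated record — 0.26 days per admission that actually
contained a rejection (this generator run planted a 0.4-day true
effect; kernel smoothing attenuates what-if contrasts, see
`docs/methods.md`). The paired Wilcoxon confirms the scenario shift
(P < 0.001), and the impact ranking shows stay-before-index and
criticality dominating the prediction with the rejection score third.

The same steps are available as a library API (see `examples/` for
one short script per capability: simulation, consolidation, training,
reassignment, variable impacts, tables and sample sizes).

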