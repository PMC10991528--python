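# fairdep

Fairness auditing and bias mitigation for binary clinical risk
prediction on tabular cohort data.

Risk models trained on observational health cohorts routinely inherit
the structural inequalities present in the data: when one subgroup has a
higher outcome prevalence, a standard classifier learns to assign that
whole subgroup higher scores, so at a fixed decision threshold the
low-prevalence subgroup is systematically under-detected. In screening
settings (the motivating case here is depression risk), that means the
people least likely to be flagged are the ones already least served.
`fairdep` is for ML practitioners and epidemiologists who want to
*measure* that behavior and *repair* it, with the full audit loop in one
place: cohort handling, synthetic cohorts with controlled bias
structure, fairness metrics, five mitigation techniques, and a
cross-validated scenario runner.

## The statistics

For a cohort D = (X, Y, C) with protected attribute X, features Y and
binary outcome C, and per-subgroup rates
TPR_x = E[Ĉ | C=1, X=x], FPR_x = E[Ĉ | C=0, X=x]:

- **EOD** = min_x TPR_x − max_x TPR_x (equal opportunity; 0 is fair,
  more negative is more biased)
- **AOD** = ½[min_x(TPR_x+FPR_x) − max_x(TPR_x+FPR_x)] (equalized odds)
- **BAcc** = (sensitivity + specificity)/2, **AUC-ROC**
- **Δ** = (1+β²)·BAcc·(1−|EOD|) / (β²·BAcc + (1−|EOD|)), the weighted
  harmonic mean of performance and fairness (β = 0.5 favors performance)

Mitigation techniques, all model-agnostic:

| method | stage | idea |
|---|---|---|
| SUP | pre  | delete the protected attribute |
| RW  | pre  | weight each (group, label) cell by P(C=c)/P(C=c\|X=x) |
| DIR | pre  | map every numeric feature through within-group quantiles onto a common distribution |
| CPP | post | randomized score mixing equalizing generalized false-negative rates |
| PSTA | post | per-group decision thresholds aligning each under-detected group's training sensitivity with the overall population's, under an FPR cap |

PSTA (population sensitivity-guided threshold adjustment) searches each
under-detected group's observed positive scores for the largest
threshold t ≤ t₀ with group sensitivity ≥ the overall sensitivity at t₀
and group FPR ≤ overall FPR + δ. It intervenes only on the disadvantaged
groups, leaving the rest at t₀ = 0.5. See `docs/methods.md` for the
full procedure and its rationale.

## Worked example

```python
from fairdep import (
    CVScheme, ScenarioSpec, SyntheticConfig, generate_cohort, run_scenario,
)

# cohort with the canonical biased structure: 10% vs 4% outcome
# prevalence across sexes, proxy features correlated with sex
cohort = generate_cohort(SyntheticConfig(
    n=20000, prevalence={"female": 0.10, "male": 0.04},
    proxy_strength=0.5, seed=1,
))

for mitigation in ("none", "rw", "psta"):
    spec = ScenarioSpec(model="logistic", mitigation=mitigation,
                        attribute="sex", cv=CVScheme(k=10, seed=1), seed=1)
    res = run_scenario(spec, cohort)
    print(f"{mitigation:5s} BAcc={res.mean('sex', 'bacc'):.3f} "
          f"EOD={res.mean('sex', 'eod'):+.3f} "
          f"Delta={res.mean('sex', 'delta'):.3f}")
```

prints

```
none  BAcc=0.621 EOD=-0.168 Delta=0.653
rw    BAcc=0.609 EOD=-0.082 Delta=0.653
psta  BAcc=0.634 EOD=-0.093 Delta=0.674
```

Read: the untreated logistic model finds 17 percentage points fewer of
the true positives in the male (low-prevalence) group than in the female
group. Reweighing halves that gap at a small BAcc cost; PSTA halves it
while *raising* BAcc (lower thresholds recover true positives in the
under-detected group), giving the best fairness-accuracy score Δ.

The same flows are available from the shell:

```bash
fairdep simulate --config cfg.yaml --out cohort.csv
fairdep run --cohort cohort.csv --schema cohort.schema.yaml \
            --config scenario.yaml --out result.json
fairdep compare --results results/ --beta 0.5 --out winners.csv
fairdep spillover --base base.json --result psta.json --attrs grp --out spill.csv
```

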