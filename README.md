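# lungscreen

A Markov cohort cost-effectiveness model of lung cancer screening with
low-dose computed tomography (LDCT) for **never smokers**, with annual chest
X-ray (CXR) and no screening as comparators.

Never smokers — especially women in East Asia — carry a substantial and
growing share of lung cancer, mostly adenocarcinoma, which LDCT detects well
at stage I.  Whether population-based LDCT screening of never smokers is
worth paying for depends critically on incidence: this package models four
cohorts of 60-year-old never smokers (Japan and the United States, men and
women) from a healthcare-payer perspective over a lifetime horizon and asks
which strategy maximizes net monetary benefit at US$100,000 per QALY.

It is aimed at health-economics and screening-policy researchers who want a
transparent, scriptable implementation of the full analysis: base-case
incremental cost-effectiveness, one-way/tornado sensitivity analysis with
threshold search, 10,000-draw probabilistic sensitivity analysis with
acceptability curves, and population-level lifetime impact.

## Model in brief

Seven health states — no lung cancer, NSCLC stage I–IV, cured, dead — with a
one-year cycle, half-cycle correction, and 3 %/yr discounting.  Screening
applies the test's sensitivity/specificity each year; true positives are
diagnosed with the route-specific stage distribution (96 % stage I for
LDCT vs 61 % for CXR and 22 % symptomatically in Japan), pay a diagnostic
workup and annual stage-specific treatment costs, and face an annual cancer
death probability d with (1 − d)⁵ = stage-specific 5-year survival for five
years before moving to the cured state (utility 0.9).  Repeated LDCT adds a
small radiogenic lung-cancer incidence increment.  Strategies are compared
by dominance frontier, ICER (Δcost/ΔQALY), and NMB = WTP·QALYs − cost.

Background mortality comes from a Gompertz–Makeham life table,
qx = 1 − exp(−(a + b·e^{c·age})), calibrated per cohort so the discounted
life expectancy at 60 matches the analysis' published life-year scale
(15.26–18.07 discounted LYs); any real national life table can be
substituted as an `age,qx` CSV.  See `docs/methods.md` for the full model
description and conventions.

## Worked example

```bash
$ lungscreen basecase --cohort japan_male
ldct          cost       19,621  QALYs 17.5709  LYs 17.7281  frontier
cxr           cost       25,162  QALYs 17.2735  LYs 17.4001  dominated
no_screening  cost       48,968  QALYs 16.6921  LYs 16.7917  dominated
```

For Japanese men (annual incidence 0.009), LDCT is both the cheapest and the
most effective strategy — it strictly dominates CXR and no screening: the
extra screening cost is more than repaid by finding cancers at stage I,
which are far cheaper to treat and rarely fatal.  Scaled to Japan's 5.46
million 60-year-old men:

```bash
$ lungscreen cohort --cohort japan_male
LDCT vs cxr: saves US$30,275,757,137, +1,624,752 QALYs, +1,792,366 LYs, 224,863 lung cancer deaths averted
LDCT vs no_screening: saves US$160,347,244,960, +4,801,138 QALYs, +5,116,259 LYs, 583,498 lung cancer deaths averted
```

In the low-incidence US cohorts the picture reverses: the frontier runs
no screening → CXR → LDCT and the ICER of LDCT over CXR exceeds one million
US$/QALY (e.g. `lungscreen basecase --cohort us_male` reports ≈ US$3.6 M per
QALY), so LDCT is not cost-effective at conventional thresholds.  One-way
analysis (`lungscreen tornado --cohort us_female`) shows the decision is
driven by incidence, with CXR overtaking no screening at ≈ 0.00015/yr;
`lungscreen psa --cohort us_female` quantifies the uncertainty (CXR is the
most likely cost-effective strategy at US$100,000/QALY).

The same pipeline is available as a library:

```python
import lungscreen as ls

ps = ls.default_parameters("us", "female")
table = ls.default_life_table(ps)              # calibrated synthetic table
results = ls.run_strategy_set(ps, table)
for row in ls.incremental_analysis(results):
    print(row.strategy, row.status, row.icer_qaly)
```

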