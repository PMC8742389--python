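# Methods

## The decision problem

`lungscreen` implements a state-transition (Markov) cohort model comparing
three lung-cancer screening strategies for 60-year-old never smokers —
annual low-dose CT (LDCT), annual chest X-ray (CXR), and no screening — in
two epidemiological settings: Japan (high incidence in never smokers,
predominantly adenocarcinoma) and the United States (low incidence).  The
analysis takes a healthcare-payer perspective over a lifetime horizon with a
one-year cycle, half-cycle correction, and 3%/year discounting of both costs
and health outcomes.  Outcomes are discounted lifetime cost (US$), QALYs,
life-years (LYs), and the fraction of the cohort dying of lung cancer.
Cost-effectiveness is judged by net monetary benefit (NMB = WTP·QALYs −
cost) at a willingness to pay of US$100,000 per QALY gained.

## Health states and within-cycle event order

Seven health states: no lung cancer, NSCLC stage I–IV, cured lung cancer,
and death.  Internally the engine refines these with bookkeeping substates:
an *undiagnosed cancer* pool (screen false negatives, re-screened every
subsequent cycle), a per-stage *time-since-diagnosis* counter driving the
five-year cure clock, a prior-workup flag on the cancer-free pool, and death
split into lung-cancer and other-cause substates so that "deaths from lung
cancer" is well defined.  The small-cell fraction is fixed at 0 (all cancers
NSCLC) and screening adherence at 100%.

Events within each yearly cycle occur in a fixed order:

1. **Screening** (LDCT/CXR strategies): every alive, undiagnosed individual
   is screened and the test cost accrues.  False positives among the
   cancer-free receive the diagnostic workup (bronchoscopy with CT-guided
   biopsy) according to the workup policy below.  True positives among
   undiagnosed cancers receive the workup and move to a stage state drawn
   from the strategy's stage-at-detection distribution.
2. **Incidence**: cancer-free individuals develop lung cancer with the
   cohort's annual probability.  Under screening strategies the incident
   cancer joins the undiagnosed pool (first screened the following cycle);
   under no screening it is diagnosed symptomatically in the same cycle with
   the no-screening stage distribution.
3. **Mortality**: background all-cause probability qx(age) applies to every
   alive state; stage occupants within five years of diagnosis additionally
   face the stage-specific annual cancer death probability, added on the
   probability scale with an overflow guard (an error, not a clamp).  At the
   life table's absorbing final age (qx = 1) the cancer increment takes its
   share and the remainder dies of other causes.
4. **Cure clock**: stage occupants completing their fifth post-diagnosis
   year move to the cured state (utility 0.9, background mortality only).

Costs of discrete events (tests, workups) are discounted at the cycle in
which they occur.  State-membership payoffs — utilities, life-years, and the
annual treatment cost — accrue on the cycle-boundary trace with the standard
trapezoidal half-cycle correction (half weight on the first and last rows).

## Key modelling conventions and why

Three conventions are not forced by the inputs; the package fixes them by
requiring the model to reproduce the *structure* of the published base case
(cost ordering, dominance pattern, and ICER scale) rather than by fiat:

* **Treatment cost accrues annually while in a stage state** (up to the
  five-year cure window), not once at diagnosis.  One-time charging leaves
  every strategy's lifetime cost two- to three-fold below the published
  scale; annual charging reproduces the published LDCT and CXR cost cells
  within a few percent.  `treatment_cost="once"` is retained as an option.
* **The false-positive workup is charged at the baseline (prevalence)
  screen only** (`fp_workup="baseline"`).  Most false-positive findings of
  chest imaging are stable benign nodules present from the first scan; they
  are biopsied once and not re-biopsied at every annual round.  Charging the
  workup on every positive cycle (`"every"`) adds a recurring cost stream
  that is arithmetically incompatible with the published incremental cost of
  CXR over no screening, which is smaller than even the bare test-cost
  stream.  An intermediate `"first"` policy (one workup per lifetime at the
  first false positive, whenever it occurs) is also available.
* **Radiogenic risk is spread over the scheduled screening course.**  The
  cumulative excess cancer risk of repeated annual LDCT (0.30% women, 0.13%
  men) is read as the risk of a full course of annual scans from the start
  age to the model horizon; the per-cycle incidence increment is the total
  divided by the number of scheduled screens (40), applied while screening
  with LDCT.  Individuals who die early accrue proportionally less excess
  risk.  Spreading the total over the mortality-weighted expected number of
  screens instead inflates the per-screen increment enough to make LDCT
  QALY-dominated by CXR in the low-incidence US cohorts, contradicting the
  published positive incremental QALYs of LDCT.

Other fixed conventions:

* **Annualization of stage-specific five-year survival** uses the constant
  cancer-specific hazard d with (1 − d)^5 = s5, which is exactly invertible;
  s5 = 0 maps to d = 1.  The excess hazard applies for the first five cycles
  after diagnosis; survivors are cured.
* **Stage at detection** is drawn at diagnosis from the route-specific
  distribution (LDCT, CXR, or symptomatic).  The LDCT and CXR distributions
  are shared between countries (equal reader capability); the symptomatic
  distribution is country-specific.  The stage-I-heavy LDCT shares are
  packaged proportionally normalized (0.96/0.01/0.03/0.01 → /1.01) so the
  distribution sums to one, which probability conservation requires.
* **No stage progression while undiagnosed.**  No progression rule is part
  of the model inputs, so none is invented: false negatives wait at utility
  1 under background mortality and receive the screen-detected stage mix at
  detection.  A consequence worth knowing: detection *timing* has no benefit
  channel, so raising test sensitivity alone very slightly *reduces* QALYs
  (the morbidity clock starts earlier under discounting); the entire benefit
  of screening is the stage shift at diagnosis.  With a progression model
  sensitivity would matter positively; this artifact is bounded by the
  discounting of a one-to-two-cycle delay (< 0.01 QALYs across the whole
  sensitivity range).

## Parameters

Packaged per cohort (Japan/US × male/female): annual lung-cancer incidence
at/after age 60; stage-specific five-year survival; stage-at-detection
distributions for the three routes; LDCT and CXR sensitivity/specificity
(stored as probabilities); unit costs in 2019-adjusted US$ (screening tests,
diagnostic workup, per-stage annual treatment); health-state utilities
(healthy 1, stage I/II 0.87, stage III 0.77, stage IV 0.57, cured 0.9, dead
0); cumulative radiogenic risk; discount rate 0.03/yr; WTP US$100,000/QALY;
start age 60 and horizon age 100.  Every scalar carries a one-way
sensitivity range; base values always lie inside their ranges.  The annual
incidence reading follows the yearly cycle (the only consistent one),
although applied over 40 years it implies a high cumulative incidence for
Japan; results should be read as conditional on that input.

## Synthetic life tables

National period life tables are inputs the package does not ship.  A
Gompertz–Makeham stand-in generates them:

    qx(x) = 1 − exp(−(a + b·e^(c·x))),  a = 5·10⁻⁴, c = 0.098/yr,

with the final age absorbing (qx = 1 at 100).  The scale parameter b is
calibrated by bisection so the discounted, half-cycle-corrected cancer-free
life expectancy at age 60 matches a per-cohort anchor taken from the
published discounted life-year scale (the strategy least distorted by
lung-cancer deaths in each country): 18.0655 (Japan men), 17.9603 (Japan
women), 15.2639 (US men), 16.9346 (US women), to within 0.01 years.  The
generator reproduces the *scale* of background survival, not the shape of
any specific national table; users can substitute a real table as an
`age,qx` CSV.  Consequently the per-cohort absolute cost/QALY/LY levels are
approximate while orderings, dominance patterns, thresholds and ICER scales
are the quantities the test suite asserts.

## Sensitivity analyses

*One-way / tornado*: each scalar is set to its range endpoints with all else
at base; the optimal-strategy NMB at both endpoints is recorded and, when
the optimum differs between endpoints, the switching value is located by
deterministic bisection to 10⁻⁶ of the range width.  Tornado entries are
sorted by descending NMB span.

*Probabilistic*: second-order Monte Carlo (default 10,000 draws, seed
20220108).  Bounded quantities (probabilities, accuracies, utilities, stage
shares) are drawn from beta distributions with mean equal to the base value
and SD = (high − low)/3.92, reading each one-way range as an approximate 95%
central interval — the only dispersion information available; stage
distributions are renormalized per draw.  Costs are drawn log-normal with
median at the base value and σ = (ln high − ln low)/3.92.  All strategies
are evaluated on the same draw (common random parameters), so incremental
quantities propagate parameter correlation.  Acceptability curves report,
per WTP, the fraction of draws in which each strategy attains the maximum
NMB, with exact ties split equally.

## Population scaling

Per-person incremental outcomes (full precision) are multiplied by national
counts of 60-year-old never smokers (5,463,770 / 7,588,028 Japanese men /
women; 14,904,704 / 16,977,059 American men / women); person- and
person-year-valued totals are rounded half away from zero, money is kept at
full precision.  `verify_cohort_scaling` (CLI: `lungscreen verify-tables`)
checks this arithmetic against published reference cells: all eight
cumulative QALY/LY gains of LDCT versus CXR are reproduced exactly.

## Verification

The test suite includes, beyond unit tests: probability conservation of the
cohort trace (rows sum to 1) over 1,000 randomly sampled parameter sets; an
independent individual-level microsimulation oracle (100,000 simulees, same
event ordering, no shared code with the cohort engine) agreeing with the
deterministic trace within 3 Monte-Carlo standard errors on cost, QALYs and
LYs for every strategy; exact zero-discount, zero-incidence, unit-utility
and immediate-death identities; the annualization inversion property to
1e-12; frontier consistency of the NMB optimum; and bitwise reproducibility
of the PSA under a fixed seed.

## Known limitations

* Background mortality is synthetic (calibrated scale, parametric shape);
  exact published cost/QALY/LY values are not reproducible desk-side and are
  asserted directionally.
* Lung-cancer incidence and stage-specific mortality do not increase with
  age beyond the life table.
* No stage progression while undiagnosed (see above); interval cancers and
  nodule-management protocols are out of scope.
* The undiscounted incidence threshold at which LDCT overtakes CXR in Japan
  falls at ≈ 0.0008/yr under these conventions, below the lower end of the
  published one-way range (0.001), so a one-way analysis restricted to that
  range reports no switch for the Japanese cohorts; the US switches
  (≈ 0.00016 men, ≈ 0.00015 women) fall inside their ranges.
* Indirect and non-medical costs are excluded; costs are used as printed
  without currency or CPI re-derivation.
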