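# Methods

## The score and its triage logic

The Tardivo score multiplies three ordinal clinical axes — Wagner grade
(1–4), PAD class (1–2) and ulcer-site grade (1–4) — giving the 12-value
image set {1, 2, 3, 4, 6, 8, 9, 12, 16, 18, 24, 32}. The score is
monotone in each axis by construction.

**Threshold inclusivity.** The high-risk class is defined as *score ≥ 12*.
The study's prose sometimes says "above 12", but the statistical grouping
actually validated partitions the cohort at "0 to 11" versus "equal or
higher than 12", and the odds ratio is defined on that partition; the
implementation follows the validated grouping. `classify_risk` accepts any
non-negative integer (not only attainable scores) so that the whole
"0 to 11" band can be classified.

**Domain.** Wagner 0 (no ulcer) and Wagner 5 (fully gangrenous foot) are
rejected with a distinct `EligibilityError` rather than scored: neither is
a candidate for conservative treatment, and the score was developed on
grades 1–4 only.

**PAD from criteria.** The six listed ischemia signs carry no published
combination rule; since each sign is individually an ischemic finding, any
single sign present implies PAD 2 (`PADClass.from_criteria`). Direct entry
of the class is also accepted, bypassing itemised criteria.

**Management routing.** PAD evaluation precedes score-based routing: a
PAD-2 patient is referred for angiographic work-up before any
conservative/surgical decision, because ischemia is the most urgent
concern and revascularization can return the patient to the conservative
pathway. With good perfusion, scores below 12 are managed conservatively
and scores of 12 or higher warrant surgical consideration; for PAD-2
patients at high scores the surgical consideration is recorded in the
recommendation rationale alongside the vascular pathway. Only these
branches of the published flowchart are implemented; finer branches are
not enumerated in the source material.

## Threshold validation statistics

`build_contingency` cross-tabulates 1{score ≥ threshold} against
amputation versus clinical cure, **excluding** records whose outcome was a
referral (orthopedic treatment, revascularization). Referred patients left
the conservative pathway without reaching a cure/amputation endpoint, and
this restriction is the unique outcome coding under which the published
stratification and odds-ratio tables are simultaneously consistent
(a, b, c, d = 8, 2, 1, 38 on the study cohort; 49 of 62 records
analysable). The exclusion is the documented default and can be changed
via the `event`/`comparator` arguments.

`odds_ratio_woolf` computes OR = ad/bc with Woolf's normal-theory interval
on the log odds ratio using z = Φ⁻¹(1 − α/2) (1.959964 at α = 0.05). The
source material names only "logistic regression" for its interval; Woolf's
interval reproduces the printed bounds (12.2, 1886.5) exactly at
one-decimal rounding and is the default. The logistic Wald route is
identical for a saturated 2×2 and is exposed as `logistic_or_2x2`, which
fits an intercept-plus-exposure binomial GLM by iteratively reweighted
least squares (statsmodels, frequency-weighted Bernoulli rows,
convergence tolerance 1e-12); exp(β̂) equals the cross-product OR to
better than 1e-6 relative error whenever all four cells are positive, and
a zero cell raises (the MLE is not finite).

**Zero cells.** Default policy `NONE`: a zero cell yields OR of 0,
infinity, or NaN (both cross products zero), with NaN interval bounds —
the Woolf variance is infinite, so no side is defined. Policy
`HALDANE_ANSCOMBE` adds 0.5 to every cell before both the estimate and
the interval; it is needed e.g. for an odds ratio on the PAD table, whose
PAD-1 amputation cell is zero. No published statistic forces either
policy, so the uncorrected estimate is the default.

**Rounding.** All printed percentages and interval bounds use
round-half-away-from-zero at one decimal (`round_half_up`), the convention
that matches every published value checked (9/14 → 64.3, 53/62 → 85.5,
19/23 → 82.6, 28/62 → 45.2). Python's builtin half-to-even rounding would
differ on exact halves.

**Stratification.** The default score bins are (1–4), 6, (8–9), 12,
(16–32), highest first. The published low bin is "2 to 4", but score 1 is
attainable (all axes at 1); the bin is widened to (1, 4) so the
stratification is total. Bins are validated as disjoint, and a cohort
record whose score no bin covers is an error naming the score.

## The deterministic study cohort

No per-patient data were deposited; only aggregate tables exist. The
62-record fixture is one canonical solution of all published constraints
at once:

* outcome totals 9 amputations / 40 cures / 11 orthopedic referrals /
  2 revascularization referrals;
* PAD 2: 9 amputated + 5 not; PAD 1: 48, no amputation;
* the full score-bin × outcome table (16–32: 10 = 7 + 0 + 3 other;
  12: 5 = 1 + 2 + 2; 8–9: 7 = 1 + 4 + 2; 6: 23 = 0 + 19 + 4;
  1–4: 17 = 0 + 15 + 2);
* Wagner marginals 3/9/45/5 and site marginals 13/28/12/9;
* every amputee in PAD class 2, and every score **above** 12 in PAD
  class 2.

Two ambiguities the aggregates leave open are resolved canonically and
flagged here: (1) the single amputee in the 8-and-9 bin is assigned score
8 — score 9 is an odd product, impossible under PAD 2, while every amputee
must be PAD 2, so 8 is in fact forced; (2) the two revascularization
referrals are placed in the score-12 bin as its PAD-2 non-amputees, which
is the only placement reconciling the 14-patient PAD-2 total with the 15
records at score ≥ 12 (the two score-12 cures are PAD 1; requiring PAD 2
at score 12 as well would need a 15th PAD-2 patient and contradict the
PAD table). Any alternative record list satisfying the same constraints
would reproduce the same tables; the tests assert the constraints, not
the particular assignment.

Days-to-outcome are attached to clinically cured records only (the
published durations are labelled "for clinical cure"), as a deterministic
±10-day paired spread around the site means 80/118/123/234 days
(FF1/FF2/MF3/HF4) whose per-site arithmetic mean equals those values
exactly.

## The stochastic simulator

`simulate_cohort` draws, per patient: the three axes, the score, the
outcome, and (for cures) a healing time. Defaults are the study
conditions — n = 62, the axis marginals above, and the bin-conditional
outcome mixes of the stratification table. Choices where the source gives
none:

* **Axis independence.** Only marginals are published, so Wagner, PAD and
  site are sampled independently by default. This ignores real clinical
  correlation (e.g. gangrene implies ischemia), so simulated cohorts can
  contain combinations such as score 16 at PAD 1 that the study cohort
  never shows; an `axis_joint` distribution over (wagner, pad, site)
  triples can impose any correlation structure.
* **Healing-time law.** Only per-site means are published. A gamma
  distribution with shape 4 (coefficient of variation 0.5, a realistic
  right-skew for wound-healing durations) and the site's mean is used;
  the means, not the law, are the tested contract. Durations are rounded
  to whole days.
* **Outcome model.** Outcomes depend on the score only through its bin,
  exactly as parameterised; within-bin heterogeneity and covariate
  effects are not modelled.

A single integer seed drives one `numpy.random.Generator` for the whole
cohort; identical spec and seed give an identical record list on any
platform. Consequently, passing parameter-recovery tests shows the
generator is a faithful sampler of its own spec under independence — it
does not validate the score against real patients, and simulated
confidence intervals will be narrower than reality wherever the
independence assumption hides correlation.

Parameter recovery is checked at n = 50,000 (binomial standard errors
≈ 0.002, so a 3-SE band is a sharp test that still runs in seconds); the
unit suite uses n = 20,000 for the same check to keep the default run
fast.

## Numerical notes and limitations

* The odds-ratio CI depends on scipy's normal quantile; all comparisons
  to published values are made at their printed one-decimal precision.
* Percentages are ratios of exact integer counts; no floating error can
  affect table cells.
* The published outcome table prints 3.3% for the 2/62 revascularization
  row; 2/62 = 3.2258, and this package prints 3.2. No downstream
  statistic depends on the discrepancy.
* The CLI maps input-validation failures to exit code 2 and computation
  failures to exit code 3; reports go to stdout (or `--out`), log lines
  to stderr.
* The package performs no survival analysis of healing times and no
  multivariable regression — a single pre-specified 2×2 contrast is the
  whole inferential content, as in the source study.
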