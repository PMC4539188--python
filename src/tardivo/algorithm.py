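"""Tardivo algorithm: prognostic scoring of the diabetic foot.

The Tardivo score is the product of three ordinal clinical axes assessed on
a patient with a diabetic foot ulcer:

* **Wagner grade** (1–4): depth/severity of the ulcer. Grade 0 (no ulcer)
  and grade 5 (whole-foot gangrene) are outside the score's domain.
* **PAD class** (1 or 2): 1 = good peripheral perfusion, 2 = clinical signs
  of ischemia (pallor, absent distal pulses, ankle-brachial index < 0.7,
  absent digital perfusion, fixed cyanosis, dry gangrene).
* **Ulcer site grade** (1–4): forefoot phalanges (FF1), forefoot
  metatarsals (FF2), midfoot (MF3), hindfoot/heel (HF4).

The product ranges over the 12-value set {1,2,3,4,6,8,9,12,16,18,24,32};
scores of 12 or higher mark a high amputation risk. The module also
provides the cohort statistics used to validate the threshold (2x2 odds
ratio with Woolf's log interval, logistic-regression equivalence,
stratification tables), a deterministic 62-record study cohort consistent
with the published aggregate tables, a seeded stochastic cohort simulator,
and plain-text / JSON report rendering.

Sections, in the order the method runs: configuration; scoring axes and
score computation; cohort records and CSV I/O; cohort statistics;
synthetic cohorts (fixture and simulator); reporting.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    # scoring
    "EligibilityError",
    "WagnerGrade",
    "PADClass",
    "ISCHEMIA_SIGNS",
    "UlcerSite",
    "FootAssessment",
    "RiskCategory",
    "TardivoScore",
    "ManagementAction",
    "ManagementRecommendation",
    "SCORE_IMAGE",
    "HIGH_RISK_THRESHOLD",
    "compute_tardivo_score",
    "classify_risk",
    "recommend_management",
    "enumerate_score_grid",
    # cohort records and I/O
    "Outcome",
    "CohortRecord",
    "read_cohort",
    "write_cohort",
    "read_assessments",
    # statistics
    "ContingencyTable2x2",
    "ZeroCellPolicy",
    "OddsRatioResult",
    "DEFAULT_SCORE_BINS",
    "build_contingency",
    "odds_ratio_woolf",
    "logistic_or_2x2",
    "stratify_scores",
    "pad_outcome_table",
    "healing_time_by_site",
    "round_half_up",
    # synthetic cohorts
    "CohortSpec",
    "fixture_study_cohort",
    "simulate_cohort",
    # reporting
    "RunConfig",
    "cohort_report",
    "render_report",
]

# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

#: Attainable score values: the image of wagner * pad * site over the
#: 4 x 2 x 4 assessment grid.
SCORE_IMAGE = frozenset({1, 2, 3, 4, 6, 8, 9, 12, 16, 18, 24, 32})

#: Scores at or above this value carry a high amputation risk.  The value
#: partitions cohorts into the validated "0 to 11" / ">= 12" groups.
HIGH_RISK_THRESHOLD = 12

#: Default score strata for cohort tables, low bin widened to include the
#: attainable score 1.  (lo, hi) bounds are inclusive.
DEFAULT_SCORE_BINS: tuple[tuple[int, int], ...] = (
    (1, 4),
    (6, 6),
    (8, 9),
    (12, 12),
    (16, 32),
)

#: Default two-sided confidence level complement for odds-ratio intervals.
DEFAULT_ALPHA = 0.05

#: Decimal places used when printing percentages.
PERCENT_DECIMALS = 1


def round_half_up(x: float, decimals: int = PERCENT_DECIMALS) -> float:
    """Round half away from zero (the convention of printed clinical tables).

    Python's built-in ``round`` rounds half to even, which would print
    9/14 as 64.3 but 53/62 as 85.5 only by accident; clinical tables round
    .05 upward consistently.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _percent(num: int, denom: int, decimals: int = PERCENT_DECIMALS) -> float:
    return round_half_up(100.0 * num / denom, decimals) if denom else 0.0


# --------------------------------------------------------------------------
# Scoring axes
# --------------------------------------------------------------------------


class EligibilityError(ValueError):
    """Raised for feet that are outside the score's domain.

    Wagner grade 0 means no ulcer and grade 5 a fully gangrenous foot;
    neither is eligible for the score (or for conservative treatment).
    """


@dataclass(frozen=True)
class WagnerGrade:
    """Wagner ulcer grade, restricted to the scoreable range 1-4."""

    grade: int

    def __post_init__(self) -> None:
        if self.grade in (0, 5):
            raise EligibilityError(
                f"Wagner grade {self.grade} is not eligible for the score: "
                "grade 0 means no ulcer and grade 5 a fully gangrenous foot"
            )
        if self.grade not in (1, 2, 3, 4):
            raise ValueError(f"Wagner grade must be 1-4, got {self.grade!r}")


#: Clinical signs of limb ischemia that place a foot in PAD class 2.
ISCHEMIA_SIGNS = frozenset(
    {
        "pallor of extremities",
        "no palpable distal pulses",
        "ankle-brachial index < 0.7",
        "no digital perfusion",
        "fixed cyanosis",
        "dry gangrene",
    }
)


@dataclass(frozen=True)
class PADClass:
    """Peripheral-arterial-disease class: 1 = good perfusion, 2 = ischemia.

    ``criteria_met`` may record which ischemia signs were observed.  Any
    single sign is sufficient for class 2 (each sign is individually an
    ischemic finding).  ``criteria_met=None`` means the class was entered
    directly without itemised criteria.
    """

    pad: int
    criteria_met: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.pad not in (1, 2):
            raise ValueError(f"PAD class must be 1 or 2, got {self.pad!r}")
        if self.criteria_met is not None:
            unknown = set(self.criteria_met) - ISCHEMIA_SIGNS
            if unknown:
                raise ValueError(f"unknown ischemia signs: {sorted(unknown)}")
            expected = 2 if self.criteria_met else 1
            if self.pad != expected:
                raise ValueError(
                    f"PAD class {self.pad} inconsistent with "
                    f"{len(self.criteria_met)} ischemia sign(s) recorded"
                )

    @classmethod
    def from_criteria(cls, signs: Iterable[str]) -> "PADClass":
        """Derive the class from observed ischemia signs (any sign => PAD 2)."""
        signs = frozenset(signs)
        return cls(pad=2 if signs else 1, criteria_met=signs)


class UlcerSite(enum.Enum):
    """Anatomical ulcer site; the enum value is the site grade.

    The grade follows the site only — it is independent of ulcer depth and
    of dorsal/plantar position.
    """

    FF1 = 1  # forefoot, phalanges
    FF2 = 2  # forefoot, metatarsals
    MF3 = 3  # midfoot (cuneiform/cuboid/navicular, Lisfranc-Chopart)
    HF4 = 4  # hindfoot (calcaneus, talus)

    @property
    def grade(self) -> int:
        return self.value

    @classmethod
    def parse(cls, token: str) -> "UlcerSite":
        try:
            return cls[str(token).strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown ulcer site {token!r}; expected one of "
                f"{', '.join(s.name for s in cls)}"
            ) from None


@dataclass(frozen=True)
class FootAssessment:
    """One patient's three ordinal ratings — the input of the score."""

    wagner: WagnerGrade
    pad: PADClass
    site: UlcerSite
    patient_id: str = ""

    @classmethod
    def from_values(
        cls, wagner: int, pad: int, site: Union[str, UlcerSite], patient_id: str = ""
    ) -> "FootAssessment":
        site = site if isinstance(site, UlcerSite) else UlcerSite.parse(site)
        return cls(WagnerGrade(wagner), PADClass(pad), site, patient_id)


class RiskCategory(enum.Enum):
    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class TardivoScore:
    """Score value with its risk category; values outside the image set of
    the 4 x 2 x 4 grid are rejected."""

    value: int
    risk: RiskCategory = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        if self.value not in SCORE_IMAGE:
            raise ValueError(
                f"{self.value} is not an attainable Tardivo score "
                f"(attainable: {sorted(SCORE_IMAGE)})"
            )
        object.__setattr__(self, "risk", classify_risk(self.value))


def compute_tardivo_score(assessment: FootAssessment) -> TardivoScore:
    """Multiply the three axis grades into the prognostic score.

    The higher the score (1-32), the worse the prognosis for the foot.
    """
    value = assessment.wagner.grade * assessment.pad.pad * assessment.site.grade
    return TardivoScore(value)


def classify_risk(score: Union[int, TardivoScore]) -> RiskCategory:
    """HIGH iff the score is 12 or higher, LOW otherwise.

    Accepts a plain integer so that the whole "0 to 11" band can be
    classified, not only attainable score values.
    """
    value = score.value if isinstance(score, TardivoScore) else int(score)
    if value < 0:
        raise ValueError(f"score must be non-negative, got {value}")
    return RiskCategory.HIGH if value >= HIGH_RISK_THRESHOLD else RiskCategory.LOW


class ManagementAction(enum.Enum):
    CONSERVATIVE_TREATMENT = "conservative treatment"
    VASCULAR_EVALUATION_FIRST = "vascular evaluation first"
    SURGICAL_CONSIDERATION = "surgical consideration"


@dataclass(frozen=True)
class ManagementRecommendation:
    action: ManagementAction
    rationale: str
    score: TardivoScore


def recommend_management(assessment: FootAssessment) -> ManagementRecommendation:
    """Route a patient through the management flowchart.

    PAD 2 is the first and most urgent concern regardless of the score:
    those patients go to angiographic evaluation (angioplasty or bypass)
    before any conservative/surgical decision, and can return to
    conservative treatment after revascularization.  With good perfusion,
    scores below 12 go to conservative treatment and scores of 12 or more
    warrant surgical consideration.
    """
    score = compute_tardivo_score(assessment)
    high = score.risk is RiskCategory.HIGH
    if assessment.pad.pad == 2:
        rationale = (
            f"Score {score.value} (threshold {HIGH_RISK_THRESHOLD}). PAD 2: "
            "angiographic evaluation with angioplasty or bypass before any "
            "other management; conservative treatment may resume after "
            "revascularization."
        )
        if high:
            rationale += (
                f" Score >= {HIGH_RISK_THRESHOLD}: high amputation risk — "
                f"{ManagementAction.SURGICAL_CONSIDERATION.value} alongside "
                "the vascular pathway."
            )
        return ManagementRecommendation(
            ManagementAction.VASCULAR_EVALUATION_FIRST, rationale, score
        )
    if high:
        return ManagementRecommendation(
            ManagementAction.SURGICAL_CONSIDERATION,
            f"Score {score.value} >= {HIGH_RISK_THRESHOLD} with good "
            "perfusion: high amputation risk, surgical consideration.",
            score,
        )
    return ManagementRecommendation(
        ManagementAction.CONSERVATIVE_TREATMENT,
        f"Score {score.value} < {HIGH_RISK_THRESHOLD} with good perfusion: "
        "high chance of healing under conservative treatment.",
        score,
    )


def enumerate_score_grid() -> list[tuple[int, int, UlcerSite, int]]:
    """All 32 (wagner, pad, site, score) combinations of the assessment grid."""
    return [
        (w, p, s, compute_tardivo_score(FootAssessment.from_values(w, p, s)).value)
        for w in (1, 2, 3, 4)
        for p in (1, 2)
        for s in UlcerSite
    ]


# --------------------------------------------------------------------------
# Cohort records and CSV I/O
# --------------------------------------------------------------------------


class Outcome(enum.Enum):
    """Study outcome taxonomy (CSV tokens as values)."""

    AMPUTATION = "amputation"
    CLINICAL_CURE = "clinical_cure"
    ORTHOPEDIC_TREATMENT = "orthopedic"
    REVASCULARIZATION_REFERRAL = "revascularization"

    @classmethod
    def parse(cls, token: str) -> "Outcome":
        try:
            return cls(str(token).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown outcome {token!r}; expected one of "
                f"{', '.join(o.value for o in cls)}"
            ) from None


@dataclass(frozen=True)
class CohortRecord:
    """An assessed patient with observed outcome; the analytics input.

    ``score`` is always derived from the assessment (passing an
    inconsistent value raises).  ``days_to_outcome`` is optional.
    """

    patient_id: str
    assessment: FootAssessment
    outcome: Outcome
    days_to_outcome: Optional[int] = None
    score: TardivoScore = None  # type: ignore[assignment]  # derived

    def __post_init__(self) -> None:
        derived = compute_tardivo_score(self.assessment)
        if self.score is not None and self.score != derived:
            raise ValueError(
                f"score {self.score.value} inconsistent with assessment "
                f"(computes to {derived.value})"
            )
        object.__setattr__(self, "score", derived)
        if self.days_to_outcome is not None and self.days_to_outcome < 0:
            raise ValueError("days_to_outcome must be non-negative")


_COHORT_COLUMNS = ["patient_id", "wagner", "pad", "site", "outcome", "days_to_outcome"]
_ASSESSMENT_COLUMNS = ["patient_id", "wagner", "pad", "site"]


def write_cohort(records: Sequence[CohortRecord], path: Union[str, Path]) -> None:
    """Write cohort records to CSV (``days_to_outcome`` blank when absent)."""
    rows = [
        {
            "patient_id": r.patient_id,
            "wagner": r.assessment.wagner.grade,
            "pad": r.assessment.pad.pad,
            "site": r.assessment.site.name,
            "outcome": r.outcome.value,
            "days_to_outcome": "" if r.days_to_outcome is None else r.days_to_outcome,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, index=False)


def _parse_row(line_no: int, field_name: str, parser, raw):
    try:
        return parser(raw)
    except (ValueError, EligibilityError) as exc:
        raise ValueError(f"line {line_no}, field '{field_name}': {exc}") from None


def _parse_int(raw) -> int:
    try:
        f = float(raw)
    except (TypeError, ValueError):
        raise ValueError(f"not an integer: {raw!r}") from None
    if not f.is_integer():
        raise ValueError(f"not an integer: {raw!r}")
    return int(f)


def read_cohort(path: Union[str, Path]) -> list[CohortRecord]:
    """Read a cohort CSV, validating every row.

    Errors name the offending line (1-based, counting the header) and field.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_COHORT_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV is missing columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        ln = i + 2  # header is line 1
        wagner = _parse_row(ln, "wagner", lambda v: WagnerGrade(_parse_int(v)), row.wagner)
        pad = _parse_row(ln, "pad", lambda v: PADClass(_parse_int(v)), row.pad)
        site = _parse_row(ln, "site", UlcerSite.parse, row.site)
        outcome = _parse_row(ln, "outcome", Outcome.parse, row.outcome)
        raw_days = getattr(row, "days_to_outcome", "")
        days = None
        if str(raw_days).strip() != "":
            days = _parse_row(ln, "days_to_outcome", _parse_int, raw_days)
            if days < 0:
                raise ValueError(
                    f"line {ln}, field 'days_to_outcome': must be non-negative"
                )
        records.append(
            CohortRecord(
                patient_id=str(row.patient_id),
                assessment=FootAssessment(wagner, pad, site, str(row.patient_id)),
                outcome=outcome,
                days_to_outcome=days,
            )
        )
    return records


def read_assessments(path: Union[str, Path]) -> list[FootAssessment]:
    """Read a batch-scoring CSV (``patient_id,wagner,pad,site``)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_ASSESSMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assessment CSV is missing columns: {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        ln = i + 2
        out.append(
            FootAssessment(
                _parse_row(ln, "wagner", lambda v: WagnerGrade(_parse_int(v)), row.wagner),
                _parse_row(ln, "pad", lambda v: PADClass(_parse_int(v)), row.pad),
                _parse_row(ln, "site", UlcerSite.parse, row.site),
                str(row.patient_id),
            )
        )
    return out


# --------------------------------------------------------------------------
# Cohort statistics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure-by-event counts: a,b = exposed event/non-event; c,d = unexposed."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell count in {cells}")
        if sum(cells) <= 0:
            raise ValueError("empty 2x2 table")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


class ZeroCellPolicy(enum.Enum):
    NONE = "none"
    HALDANE_ANSCOMBE = "haldane"  # add 0.5 to every cell


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    alpha: float
    zero_cell_policy: ZeroCellPolicy


def build_contingency(
    cohort: Sequence[CohortRecord],
    threshold: int = HIGH_RISK_THRESHOLD,
    event: Outcome = Outcome.AMPUTATION,
    comparator: Outcome = Outcome.CLINICAL_CURE,
) -> ContingencyTable2x2:
    """Cross-tabulate score >= threshold against event vs comparator outcome.

    Records with outcomes other than ``event``/``comparator`` are excluded:
    referred patients (orthopedic, revascularization) left the conservative
    pathway without a cure/amputation endpoint, and the published threshold
    validation contrasts amputation against clinical cure only.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if threshold not in SCORE_IMAGE:
        raise ValueError(
            f"threshold {threshold} is not an attainable score "
            f"(attainable: {sorted(SCORE_IMAGE)})"
        )
    a = b = c = d = 0
    for r in cohort:
        if r.outcome not in (event, comparator):
            continue
        exposed = r.score.value >= threshold
        if r.outcome == event:
            a, c = (a + 1, c) if exposed else (a, c + 1)
        else:
            b, d = (b + 1, d) if exposed else (b, d + 1)
    if a + b + c + d == 0:
        raise ValueError(
            "no analysable outcomes: no record has the event or comparator outcome"
        )
    return ContingencyTable2x2(a, b, c, d)


def odds_ratio_woolf(
    table: ContingencyTable2x2,
    alpha: float = DEFAULT_ALPHA,
    zero_cell_policy: ZeroCellPolicy = ZeroCellPolicy.NONE,
) -> OddsRatioResult:
    """Sample odds ratio (a*d)/(b*c) with Woolf's log-scale interval.

    CI = exp(ln OR +/- z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d)).

    With ``ZeroCellPolicy.NONE`` a zero cell yields OR of 0, infinity or
    NaN (when both cross products vanish) and NaN interval bounds; with
    ``HALDANE_ANSCOMBE`` 0.5 is added to every cell before both formulas.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    a, b, c, d = table.cells
    if zero_cell_policy is ZeroCellPolicy.HALDANE_ANSCOMBE:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ad, bc = a * d, b * c
    if bc == 0:
        orr = math.nan if ad == 0 else math.inf
    else:
        orr = ad / bc
    if min(a, b, c, d) == 0:
        return OddsRatioResult(orr, math.nan, math.nan, alpha, zero_cell_policy)
    z = norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(orr)
    return OddsRatioResult(
        orr,
        math.exp(log_or - z * se),
        math.exp(log_or + z * se),
        alpha,
        zero_cell_policy,
    )


def logistic_or_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Logistic regression of the event on the binary exposure.

    Fits an intercept + slope binomial model by iteratively reweighted
    maximum likelihood and returns ``(beta, exp(beta))`` for the exposure
    coefficient.  The model is saturated, so exp(beta) equals the sample
    cross-product odds ratio; the iterative fit and the closed form agree
    to numerical precision.  Requires all four cells positive (otherwise
    the MLE is not finite).
    """
    if min(table.cells) <= 0:
        raise ValueError(
            "non-finite MLE: logistic regression on a 2x2 table requires all "
            "four cells to be positive"
        )
    a, b, c, d = table.cells
    # four covariate patterns with frequency weights (exposed/unexposed x event/non-event)
    endog = np.array([1.0, 0.0, 1.0, 0.0])
    exog = sm.add_constant(np.array([[1.0], [1.0], [0.0], [0.0]]))
    weights = np.array([a, b, c, d], dtype=float)
    model = sm.GLM(endog, exog, family=sm.families.Binomial(), freq_weights=weights)
    fit = model.fit(tol=1e-12)
    beta = float(fit.params[1])
    return beta, math.exp(beta)


def _bin_label(lo: int, hi: int) -> str:
    attainable = sorted(v for v in SCORE_IMAGE if lo <= v <= hi)
    if len(attainable) == 1:
        return str(attainable[0])
    if len(attainable) == 2:
        return f"{attainable[0]} and {attainable[1]}"
    return f"{lo} to {hi}"


def stratify_scores(
    cohort: Sequence[CohortRecord],
    bins: Sequence[tuple[int, int]] = DEFAULT_SCORE_BINS,
) -> pd.DataFrame:
    """Per-score-bin patient counts with cure and amputation breakdowns.

    Returns one row per bin, highest scores first: bin label, n, percent of
    cohort, cure count and within-bin percent, amputation count and
    within-bin percent.  Bins are inclusive ``(lo, hi)`` intervals; a
    record whose score falls outside every bin is an error.
    """
    if not cohort:
        raise ValueError("empty cohort")
    spans = sorted(bins, key=lambda b: b[0], reverse=True)
    for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
        if hi2 >= lo1:
            raise ValueError(f"overlapping score bins ({lo2},{hi2}) and ({lo1},{hi1})")
    total = len(cohort)
    counts = {span: [] for span in spans}
    for r in cohort:
        for lo, hi in spans:
            if lo <= r.score.value <= hi:
                counts[(lo, hi)].append(r)
                break
        else:
            raise ValueError(f"score {r.score.value} falls outside all bins")
    rows = []
    for lo, hi in spans:
        members = counts[(lo, hi)]
        n = len(members)
        cures = sum(r.outcome is Outcome.CLINICAL_CURE for r in members)
        amps = sum(r.outcome is Outcome.AMPUTATION for r in members)
        rows.append(
            {
                "scores": _bin_label(lo, hi),
                "n": n,
                "pct": _percent(n, total),
                "cure_n": cures,
                "cure_pct": _percent(cures, n),
                "amputation_n": amps,
                "amputation_pct": _percent(amps, n),
            }
        )
    return pd.DataFrame(rows)


def pad_outcome_table(cohort: Sequence[CohortRecord]) -> pd.DataFrame:
    """Amputated / not-amputated counts and row percents per PAD class.

    "Not amputated" pools all non-amputation outcomes.  A Total row is
    appended.
    """
    if not cohort:
        raise ValueError("empty cohort")
    rows = []
    for pad in (1, 2):
        members = [r for r in cohort if r.assessment.pad.pad == pad]
        amp = sum(r.outcome is Outcome.AMPUTATION for r in members)
        rows.append(("PAD " + str(pad), amp, len(members) - amp, len(members)))
    amp_total = sum(r[1] for r in rows)
    rows.append(("Total", amp_total, len(cohort) - amp_total, len(cohort)))
    return pd.DataFrame(
        {
            "group": [r[0] for r in rows],
            "amputated_n": [r[1] for r in rows],
            "amputated_pct": [_percent(r[1], r[3]) for r in rows],
            "not_amputated_n": [r[2] for r in rows],
            "not_amputated_pct": [_percent(r[2], r[3]) for r in rows],
        }
    )


def healing_time_by_site(cohort: Sequence[CohortRecord]) -> pd.Series:
    """Mean days to outcome per ulcer site, over records carrying a duration.

    Sites present in the cohort but with no recorded durations are omitted
    with a warning.  Returns a Series indexed by site name, in anatomical
    order (FF1, FF2, MF3, HF4).
    """
    if not cohort:
        raise ValueError("empty cohort")
    means: dict[str, float] = {}
    for site in UlcerSite:
        members = [r for r in cohort if r.assessment.site is site]
        days = [r.days_to_outcome for r in members if r.days_to_outcome is not None]
        if days:
            means[site.name] = float(np.mean(days))
        elif members:
            warnings.warn(
                f"site {site.name}: {len(members)} record(s) but no recorded "
                "days_to_outcome; omitted from healing-time means",
                stacklevel=2,
            )
    return pd.Series(means, dtype=float, name="mean_days")


# --------------------------------------------------------------------------
# Synthetic cohorts: study fixture and stochastic simulator
# --------------------------------------------------------------------------

# The published study reports only aggregate tables; the fixture below is
# one canonical 62-record cohort satisfying every printed aggregate
# simultaneously:
#   * outcome totals 9 amputations / 40 cures / 11 orthopedic / 2
#     revascularization referrals;
#   * PAD x amputation: PAD 2 = 9 amputated + 5 not, PAD 1 = 48 with no
#     amputation;
#   * score-bin x outcome cells of the score-distribution table
#     (16-32: 10 = 7 amp + 3 other; 12: 5 = 1 amp + 2 cure + 2 other;
#     8-9: 7 = 1 amp + 4 cure + 2 other; 6: 23 = 19 cure + 4 other;
#     1-4: 17 = 15 cure + 2 other);
#   * Wagner marginals 3/9/45/5 (grades 1-4) and site marginals
#     13/28/12/9 (FF1/FF2/MF3/HF4);
#   * every amputee is PAD 2, and every score above 12 requires PAD 2.
# Ambiguities the aggregates leave open (exactly which triples realise
# each bin, and whether the single 8-or-9 amputee scored 8 or 9) are
# resolved canonically: the amputee scores 8 (score 9 is an odd product,
# impossible under PAD 2, and all amputees are PAD 2); the two
# revascularization referrals sit in the score-12 bin as its PAD-2
# non-amputees.  Any alternative satisfying the same constraints would
# reproduce the same tables.
_A, _C, _O, _R = (
    Outcome.AMPUTATION,
    Outcome.CLINICAL_CURE,
    Outcome.ORTHOPEDIC_TREATMENT,
    Outcome.REVASCULARIZATION_REFERRAL,
)
_FIXTURE_GROUPS: tuple[tuple[int, int, int, str, Outcome], ...] = (
    # (count, wagner, pad, site, outcome)
    # -- bin 16-32 (10 records, all PAD 2) -------------------------------
    (1, 4, 2, "HF4", _A),  # 32
    (2, 3, 2, "HF4", _A),  # 24
    (1, 4, 2, "MF3", _A),  # 24
    (3, 3, 2, "MF3", _A),  # 18
    (1, 3, 2, "MF3", _O),  # 18
    (1, 2, 2, "HF4", _O),  # 16
    (1, 4, 2, "FF2", _O),  # 16
    # -- bin 12 (5 records) ----------------------------------------------
    (1, 3, 2, "FF2", _A),  # 12
    (1, 3, 2, "FF2", _R),  # 12
    (1, 2, 2, "MF3", _R),  # 12
    (2, 3, 1, "HF4", _C),  # 12
    # -- bin 8-9 (7 records) ---------------------------------------------
    (1, 4, 2, "FF1", _A),  # 8 (the single amputee of this bin)
    (3, 3, 1, "MF3", _C),  # 9
    (1, 2, 1, "HF4", _C),  # 8
    (1, 2, 1, "HF4", _O),  # 8
    (1, 4, 1, "FF2", _O),  # 8
    # -- bin 6 (23 records) ----------------------------------------------
    (18, 3, 1, "FF2", _C),  # 6
    (3, 3, 1, "FF2", _O),  # 6
    (1, 2, 1, "MF3", _C),  # 6
    (1, 2, 1, "MF3", _O),  # 6
    # -- bin 1-4 (17 records) --------------------------------------------
    (10, 3, 1, "FF1", _C),  # 3
    (1, 3, 1, "FF1", _O),  # 3
    (1, 2, 1, "FF1", _C),  # 2
    (1, 2, 1, "FF2", _C),  # 4
    (1, 2, 1, "FF2", _O),  # 4
    (1, 1, 1, "FF2", _C),  # 2
    (1, 1, 1, "MF3", _C),  # 3
    (1, 1, 1, "HF4", _C),  # 4
)

#: Mean days to outcome per site for clinically cured feet (hindfoot
#: lesions heal slowest).
DEFAULT_HEALING_TIME_MEANS: Mapping[str, float] = {
    "FF1": 80.0,
    "FF2": 118.0,
    "MF3": 123.0,
    "HF4": 234.0,
}


def fixture_study_cohort() -> list[CohortRecord]:
    """The deterministic 62-record study cohort (see module constants).

    Days to outcome are attached to clinically cured records only, as a
    deterministic spread (+/-10-day pairs around the site mean) whose
    per-site arithmetic mean equals the published site means exactly
    (FF1 80, FF2 118, MF3 123, HF4 234 days).
    """
    records: list[CohortRecord] = []
    pid = 0
    for count, wagner, pad, site, outcome in _FIXTURE_GROUPS:
        for _ in range(count):
            pid += 1
            patient_id = f"P{pid:02d}"
            records.append(
                CohortRecord(
                    patient_id=patient_id,
                    assessment=FootAssessment.from_values(wagner, pad, site, patient_id),
                    outcome=outcome,
                )
            )
    # zero-sum duration offsets per site so means are exact
    for site in UlcerSite:
        cured = [
            i
            for i, r in enumerate(records)
            if r.assessment.site is site and r.outcome is Outcome.CLINICAL_CURE
        ]
        mean = DEFAULT_HEALING_TIME_MEANS[site.name]
        n_paired = len(cured) - (len(cured) % 2)
        for j, i in enumerate(cured):
            offset = 0 if j >= n_paired else (10 if j % 2 == 0 else -10)
            records[i] = dataclasses.replace(
                records[i], days_to_outcome=int(mean) + offset, score=None
            )
    return records


def _study_marginals() -> tuple[dict, dict, dict, dict]:
    """Study-cohort marginals and bin-conditional outcome mixes (n = 62)."""
    wagner = {1: 3 / 62, 2: 9 / 62, 3: 45 / 62, 4: 5 / 62}
    pad = {1: 48 / 62, 2: 14 / 62}
    site = {"FF1": 13 / 62, "FF2": 28 / 62, "MF3": 12 / 62, "HF4": 9 / 62}
    outcome_by_bin = {
        (1, 4): {_C: 15 / 17, _O: 2 / 17},
        (6, 6): {_C: 19 / 23, _O: 4 / 23},
        (8, 9): {_C: 4 / 7, _A: 1 / 7, _O: 2 / 7},
        (12, 12): {_C: 2 / 5, _A: 1 / 5, _R: 2 / 5},
        (16, 32): {_A: 7 / 10, _O: 3 / 10},
    }
    return wagner, pad, site, outcome_by_bin


def _check_probs(name: str, probs: Mapping, tol: float = 1e-9) -> None:
    total = sum(probs.values())
    if abs(total - 1.0) > tol:
        raise ValueError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{name} contains a negative probability")


@dataclass
class CohortSpec:
    """Parameters of the stochastic cohort simulator.

    Defaults reproduce the study conditions: the study's axis marginals,
    the score-bin-conditional outcome mixes of the published
    score-distribution table, gamma-distributed healing times (shape 4)
    with the published per-site means, and a cohort of 62 patients.  The
    three axes are sampled independently unless ``axis_joint`` supplies a
    full joint distribution over (wagner, pad, site) triples (the study
    publishes only marginals, but users may want correlated axes, e.g.
    gangrene implying ischemia).
    """

    n: int = 62
    wagner_probs: Mapping[int, float] = field(default_factory=lambda: _study_marginals()[0])
    pad_probs: Mapping[int, float] = field(default_factory=lambda: _study_marginals()[1])
    site_probs: Mapping[str, float] = field(default_factory=lambda: _study_marginals()[2])
    outcome_probs_by_bin: Mapping[tuple[int, int], Mapping[Outcome, float]] = field(
        default_factory=lambda: _study_marginals()[3]
    )
    healing_time_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HEALING_TIME_MEANS)
    )
    healing_time_shape: float = 4.0
    seed: int = 0
    axis_joint: Optional[Mapping[tuple[int, int, str], float]] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        if self.healing_time_shape <= 0:
            raise ValueError("healing_time_shape must be positive")
        if self.axis_joint is not None:
            _check_probs("axis_joint", self.axis_joint)
        else:
            _check_probs("wagner_probs", self.wagner_probs)
            _check_probs("pad_probs", self.pad_probs)
            _check_probs("site_probs", self.site_probs)
        for span, probs in self.outcome_probs_by_bin.items():
            _check_probs(f"outcome_probs_by_bin[{span}]", probs)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CohortSpec":
        """Load a spec from JSON (bin keys ``"lo-hi"``, outcome tokens as in CSV)."""
        raw = json.loads(Path(path).read_text())
        kwargs: dict = {}
        for key in ("n", "seed", "healing_time_shape"):
            if key in raw:
                kwargs[key] = raw[key]
        if "wagner_probs" in raw:
            kwargs["wagner_probs"] = {int(k): v for k, v in raw["wagner_probs"].items()}
        if "pad_probs" in raw:
            kwargs["pad_probs"] = {int(k): v for k, v in raw["pad_probs"].items()}
        if "site_probs" in raw:
            kwargs["site_probs"] = {
                UlcerSite.parse(k).name: v for k, v in raw["site_probs"].items()
            }
        if "healing_time_means" in raw:
            kwargs["healing_time_means"] = {
                UlcerSite.parse(k).name: float(v)
                for k, v in raw["healing_time_means"].items()
            }
        if "outcome_probs_by_bin" in raw:
            parsed = {}
            for span, probs in raw["outcome_probs_by_bin"].items():
                lo, _, hi = str(span).partition("-")
                parsed[(int(lo), int(hi or lo))] = {
                    Outcome.parse(o): p for o, p in probs.items()
                }
            kwargs["outcome_probs_by_bin"] = parsed
        return cls(**kwargs)


def simulate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Draw a synthetic cohort from the spec's distributions.

    Axes are sampled per patient (independently, or jointly when
    ``axis_joint`` is given), the score computed, the outcome drawn from
    the score bin's outcome mix, and a gamma-distributed days-to-outcome
    attached to clinically cured records (shape ``healing_time_shape``,
    mean from the record's site).  The same spec and seed always produce
    the identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.axis_joint is not None:
        triples = list(spec.axis_joint)
        probs = np.array([spec.axis_joint[t] for t in triples], dtype=float)
        idx = rng.choice(len(triples), size=spec.n, p=probs / probs.sum())
        drawn = [triples[i] for i in idx]
    else:
        def _draw(probs: Mapping) -> list:
            keys = list(probs)
            p = np.array([probs[k] for k in keys], dtype=float)
            return [keys[i] for i in rng.choice(len(keys), size=spec.n, p=p / p.sum())]

        drawn = list(zip(_draw(spec.wagner_probs), _draw(spec.pad_probs), _draw(spec.site_probs)))

    bins = sorted(spec.outcome_probs_by_bin, key=lambda s: s[0])
    records = []
    for i, (wagner, pad, site) in enumerate(drawn):
        patient_id = f"S{i + 1:05d}"
        assessment = FootAssessment.from_values(wagner, pad, site, patient_id)
        score = compute_tardivo_score(assessment)
        span = next(((lo, hi) for lo, hi in bins if lo <= score.value <= hi), None)
        if span is None:
            raise ValueError(
                f"score {score.value} not covered by outcome_probs_by_bin; "
                "spec must cover every attainable score"
            )
        mix = spec.outcome_probs_by_bin[span]
        outcomes = list(mix)
        p = np.array([mix[o] for o in outcomes], dtype=float)
        outcome = outcomes[rng.choice(len(outcomes), p=p / p.sum())]
        days = None
        if outcome is Outcome.CLINICAL_CURE:
            mean = spec.healing_time_means[assessment.site.name]
            shape = spec.healing_time_shape
            days = int(round(rng.gamma(shape, mean / shape)))
        records.append(CohortRecord(patient_id, assessment, outcome, days))
    return records


# --------------------------------------------------------------------------
# Reporting
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Knobs of a cohort analysis run."""

    threshold: int = HIGH_RISK_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    zero_cell_policy: ZeroCellPolicy = ZeroCellPolicy.NONE
    decimals: int = PERCENT_DECIMALS
    fmt: str = "table"  # table | json | csv

    def __post_init__(self) -> None:
        if self.threshold not in SCORE_IMAGE:
            raise ValueError(
                f"threshold {self.threshold} is not an attainable score"
            )
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fmt not in ("table", "json", "csv"):
            raise ValueError(f"unknown output format {self.fmt!r}")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "zero_cell_policy" in raw:
            raw["zero_cell_policy"] = ZeroCellPolicy(raw["zero_cell_policy"])
        return cls(**raw)


def cohort_report(
    cohort: Sequence[CohortRecord], config: Optional[RunConfig] = None
) -> dict:
    """All five summary tables of a cohort as one JSON-serialisable dict.

    Sections: outcome distribution, PAD x amputation, healing time by
    site, score strata, and the threshold odds ratio with its confidence
    interval.  The text rendering (:func:`render_report`) is generated
    from this dict, so both carry identical numbers.
    """
    config = config or RunConfig()
    if not cohort:
        raise ValueError("empty cohort")
    total = len(cohort)
    outcome_rows = []
    labels = {
        Outcome.AMPUTATION: "Amputations",
        Outcome.CLINICAL_CURE: "Clinical cure",
        Outcome.ORTHOPEDIC_TREATMENT: "Orthopedic treatment",
        Outcome.REVASCULARIZATION_REFERRAL: "Referral for revascularization",
    }
    for outcome, label in labels.items():
        n = sum(r.outcome is outcome for r in cohort)
        outcome_rows.append({"outcome": label, "n": n, "pct": _percent(n, total, config.decimals)})
    outcome_rows.append({"outcome": "Total", "n": total, "pct": 100.0})

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        healing = healing_time_by_site(cohort)
    table = build_contingency(cohort, threshold=config.threshold)
    orr = odds_ratio_woolf(table, alpha=config.alpha, zero_cell_policy=config.zero_cell_policy)
    return {
        "outcomes": outcome_rows,
        "pad_amputation": pad_outcome_table(cohort).to_dict(orient="records"),
        "healing_time_days": {k: round_half_up(v, config.decimals) for k, v in healing.items()},
        "score_strata": stratify_scores(cohort).to_dict(orient="records"),
        "odds_ratio": {
            "threshold": config.threshold,
            "contingency": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
            "odds_ratio": round_half_up(orr.odds_ratio, config.decimals)
            if math.isfinite(orr.odds_ratio)
            else orr.odds_ratio,
            "ci_low": round_half_up(orr.ci_low, config.decimals)
            if math.isfinite(orr.ci_low)
            else None,
            "ci_high": round_half_up(orr.ci_high, config.decimals)
            if math.isfinite(orr.ci_high)
            else None,
            "alpha": orr.alpha,
            "zero_cell_policy": orr.zero_cell_policy.value,
        },
    }


def _frame_to_text(df: pd.DataFrame) -> str:
    return df.to_string(index=False)


def render_report(
    cohort: Sequence[CohortRecord], config: Optional[RunConfig] = None
) -> str:
    """Plain-text rendering of :func:`cohort_report` (five sections)."""
    config = config or RunConfig()
    rep = cohort_report(cohort, config)
    orr = rep["odds_ratio"]
    ci = (
        f"({orr['ci_low']}-{orr['ci_high']})"
        if orr["ci_low"] is not None and orr["ci_high"] is not None
        else "(CI undefined: zero cell)"
    )
    ct = orr["contingency"]
    sections = [
        "== Outcome distribution ==",
        _frame_to_text(pd.DataFrame(rep["outcomes"])),
        "",
        "== PAD class x amputation ==",
        _frame_to_text(pd.DataFrame(rep["pad_amputation"])),
        "",
        "== Mean days to outcome by ulcer site ==",
        _frame_to_text(
            pd.DataFrame(
                {"site": list(rep["healing_time_days"]), "mean_days": list(rep["healing_time_days"].values())}
            )
        )
        if rep["healing_time_days"]
        else "(no recorded durations)",
        "",
        "== Outcomes by score stratum ==",
        _frame_to_text(pd.DataFrame(rep["score_strata"])),
        "",
        f"== Amputation odds ratio, score >= {orr['threshold']} vs below ==",
        f"2x2 (amputation vs clinical cure): a={ct['a']} b={ct['b']} c={ct['c']} d={ct['d']}",
        f"Odds ratio {orr['odds_ratio']} {ci}   [alpha={orr['alpha']}, "
        f"zero-cell policy: {orr['zero_cell_policy']}]",
    ]
    return "\n".join(sections)
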