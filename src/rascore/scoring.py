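"""The reproductive ageing score: age modifiers, fuzzy union, scoring.

The score for one woman is the probabilistic-sum fuzzy union of her two
membership values,

    RAS = mu_A + mu_B - mu_A * mu_B,

with mu_A evaluated at her reported period count and mu_B at her
*modified* age: current smoking advances the age by two years and
unilateral oophorectomy by one (both are associated with earlier
menopause), giving m_age = age, age+1, age+2 or age+3. The modifiers are
optional and can be disabled on the model.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .cohort import (
    EligibilityReason,
    Oophorectomy,
    ParticipantRecord,
    eligibility_report,
)
from .membership import (
    PUBLISHED_MU_A,
    PUBLISHED_MU_B,
    MuAParams,
    MuBParams,
    eval_mu_a,
    eval_mu_b,
)

#: Years added to the age of a current smoker / after unilateral oophorectomy.
SMOKING_OFFSET_YEARS = 2
UNILATERAL_OOPHORECTOMY_OFFSET_YEARS = 1


@dataclass(frozen=True)
class RASModel:
    """Parameter sets and modifier offsets sufficient to score a record."""

    mu_a: MuAParams = PUBLISHED_MU_A
    mu_b: MuBParams = PUBLISHED_MU_B
    smoking_offset: float = SMOKING_OFFSET_YEARS
    unilateral_oophorectomy_offset: float = UNILATERAL_OOPHORECTOMY_OFFSET_YEARS
    modifiers_enabled: bool = True

    def __post_init__(self):
        if self.smoking_offset < 0 or self.unilateral_oophorectomy_offset < 0:
            raise ValueError("modifier offsets must be >= 0")


@dataclass(frozen=True)
class ScoredRecord:
    """A scored woman: the RAS plus every intermediate quantity.

    ``ras`` is ``None`` when the record was ineligible, in which case
    ``excluded_reasons`` says why.
    """

    id: str
    ras: Optional[float]
    mu_a_value: Optional[float] = None
    mu_b_value: Optional[float] = None
    m_age: Optional[float] = None
    excluded_reasons: tuple[EligibilityReason, ...] = ()
    warnings: tuple[str, ...] = ()


def modified_age(
    age: float,
    smoker_current: bool,
    oophorectomy: Oophorectomy,
    smoking_offset: float = SMOKING_OFFSET_YEARS,
    unilateral_offset: float = UNILATERAL_OOPHORECTOMY_OFFSET_YEARS,
) -> float:
    """Age advanced for current smoking (+2 y) and one ovary (+1 y)."""
    if oophorectomy is Oophorectomy.BILATERAL:
        raise ValueError(
            "bilateral oophorectomy is an eligibility exclusion; "
            "modified age is undefined"
        )
    m_age = float(age)
    if smoker_current:
        m_age += smoking_offset
    if oophorectomy is Oophorectomy.UNILATERAL:
        m_age += unilateral_offset
    return m_age


def fuzzy_union(a: float, b: float) -> float:
    """Probabilistic sum ``a + b - a*b`` of two membership values.

    Commutative, with 0 neutral and 1 absorbing. Inputs must already lie
    in [0, 1]; clamping is the membership evaluators' job, not this one's.
    """
    if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
        raise ValueError(f"membership values must lie in [0, 1], got {a}, {b}")
    return a + b - a * b


def score(record: ParticipantRecord, model: RASModel = RASModel()) -> ScoredRecord:
    """Score one eligible record; raises on an ineligible one."""
    report = eligibility_report(record)
    if not report.eligible:
        reasons = ", ".join(r.value for r in report.reasons)
        raise ValueError(f"record {record.id} is ineligible: {reasons}")
    warnings: list[str] = []
    if model.modifiers_enabled:
        m_age = modified_age(
            record.age,
            record.smoker_current,
            record.oophorectomy,
            model.smoking_offset,
            model.unilateral_oophorectomy_offset,
        )
    else:
        m_age = float(record.age)
    if record.periods_last_12m > 15:
        warnings.append("period count clamped to 15 for mu_A")
    mu_a = float(eval_mu_a(record.periods_last_12m, model.mu_a))
    mu_b = float(eval_mu_b(m_age, model.mu_b))
    return ScoredRecord(
        id=record.id,
        ras=fuzzy_union(mu_a, mu_b),
        mu_a_value=mu_a,
        mu_b_value=mu_b,
        m_age=m_age,
        warnings=tuple(warnings),
    )


def score_batch(
    records: Sequence[ParticipantRecord], model: RASModel = RASModel()
) -> list[ScoredRecord]:
    """Score a cohort, keeping input order.

    Ineligible records produce a null score carrying the exclusion
    reasons instead of aborting the batch.
    """
    out: list[ScoredRecord] = []
    for rec in records:
        report = eligibility_report(rec)
        if report.eligible:
            out.append(score(rec, model))
        else:
            out.append(
                ScoredRecord(id=rec.id, ras=None, excluded_reasons=report.reasons)
            )
    return out


def display_score(ras: float) -> str:
    """Two-decimal presentation of a score (presentation only; scoring
    keeps full float precision)."""
    return f"{ras:.2f}"
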