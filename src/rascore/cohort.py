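"""Participant records, validation, and study eligibility filters.

A :class:`ParticipantRecord` holds one woman's questionnaire answers —
age, number of periods in the last twelve months, menstrual regularity —
plus the flags and optional serum hormone panel used downstream for
eligibility filtering and biomarker validation.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)


class Regularity(Enum):
    """Answer to "Do you have regular periods?"."""

    REGULAR = "regular"
    IRREGULAR_FEW_MONTHS = "irregular"
    STOPPED = "stopped"


class Oophorectomy(Enum):
    NONE = "none"
    UNILATERAL = "unilateral"
    BILATERAL = "bilateral"


class EligibilityReason(Enum):
    HORMONE_USE = "hormone_use"
    PREGNANT = "pregnant"
    BREASTFEEDING = "breastfeeding"
    IRREGULAR_UNRELATED = "irregular_unrelated"
    BILATERAL_OOPHORECTOMY = "bilateral_oophorectomy"


@dataclass(frozen=True)
class ParticipantRecord:
    """One woman's questionnaire answers plus optional hormone panel.

    Hormone fields (``fsh`` in IU/L, ``estradiol`` in pmol/L) are ``None``
    when not measured; they are never silently coerced to zero.
    """

    id: str
    age: int
    periods_last_12m: int
    regularity: Regularity
    smoker_current: bool = False
    oophorectomy: Oophorectomy = Oophorectomy.NONE
    exogenous_hormone_use: bool = False
    pregnant: bool = False
    breastfeeding: bool = False
    irregular_unrelated_to_menopause: bool = False
    fsh: Optional[float] = None
    estradiol: Optional[float] = None

    def __post_init__(self):
        # Cross-tabulations are by whole year of age; truncate fractional ages.
        if isinstance(self.age, float) and not self.age.is_integer():
            logger.warning(
                "record %s: fractional age %s truncated toward zero", self.id, self.age
            )
            object.__setattr__(self, "age", math.trunc(self.age))
        else:
            object.__setattr__(self, "age", int(self.age))


@dataclass(frozen=True)
class EligibilityReport:
    """Why a record was excluded; ``eligible`` iff ``reasons`` is empty."""

    eligible: bool
    reasons: tuple[EligibilityReason, ...] = ()

    def __post_init__(self):
        if self.eligible != (len(self.reasons) == 0):
            raise ValueError("eligible must be true iff reasons is empty")


@dataclass(frozen=True)
class ValidationIssue:
    field: str
    message: str
    advisory: bool = False

    def __str__(self) -> str:  # pragma: no cover - display only
        kind = "advisory" if self.advisory else "error"
        return f"{self.field}: {self.message} [{kind}]"


def validate_record(record: ParticipantRecord) -> list[ValidationIssue]:
    """Check a record's field constraints, returning issues (never raising).

    Constraints: nonnegative age and period count; at most 12 periods for
    women whose menses have stopped (the development data show stopped
    answers with 1-12 recent periods, never more); nonnegative hormone
    values; an advisory when only one of the FSH/estradiol pair is present,
    since validation needs both and will ignore a lone value.
    """
    issues: list[ValidationIssue] = []
    if record.age < 0:
        issues.append(ValidationIssue("age", "must be >= 0"))
    if record.periods_last_12m < 0:
        issues.append(ValidationIssue("periods_last_12m", "must be >= 0"))
    if record.regularity is Regularity.STOPPED and record.periods_last_12m > 12:
        issues.append(
            ValidationIssue(
                "periods_last_12m",
                "stopped menses with more than 12 periods in the last year",
            )
        )
    for name in ("fsh", "estradiol"):
        value = getattr(record, name)
        if value is not None:
            if not math.isfinite(value):
                issues.append(ValidationIssue(name, "must be finite"))
            elif value < 0:
                issues.append(ValidationIssue(name, "must be >= 0"))
    if (record.fsh is None) != (record.estradiol is None):
        present = "fsh" if record.fsh is not None else "estradiol"
        issues.append(
            ValidationIssue(
                "fsh/estradiol",
                f"only {present} present; hormone validation needs both and "
                "will skip this record",
                advisory=True,
            )
        )
    return issues


def eligibility_report(record: ParticipantRecord) -> EligibilityReport:
    """Apply the study exclusion rules to a single record.

    Exclusions: current exogenous sex-hormone use (including intermittent
    progestin therapy), pregnancy, breastfeeding, irregular menstruation
    unrelated to menopause, and bilateral oophorectomy (surgical menopause
    is outside the natural-transition model's support).
    """
    reasons: list[EligibilityReason] = []
    if record.exogenous_hormone_use:
        reasons.append(EligibilityReason.HORMONE_USE)
    if record.pregnant:
        reasons.append(EligibilityReason.PREGNANT)
    if record.breastfeeding:
        reasons.append(EligibilityReason.BREASTFEEDING)
    if record.irregular_unrelated_to_menopause:
        reasons.append(EligibilityReason.IRREGULAR_UNRELATED)
    if record.oophorectomy is Oophorectomy.BILATERAL:
        reasons.append(EligibilityReason.BILATERAL_OOPHORECTOMY)
    return EligibilityReport(eligible=not reasons, reasons=tuple(reasons))


def apply_eligibility_filters(
    records: Sequence[ParticipantRecord],
) -> tuple[list[ParticipantRecord], list[EligibilityReport]]:
    """Split a cohort into the analysis set and per-record reports.

    Returns ``(kept, reports)``: ``kept`` preserves input order and contains
    exactly the records whose report is eligible; ``reports`` is parallel to
    the input. Exclusion counts by reason are logged.
    """
    reports = [eligibility_report(r) for r in records]
    kept = [r for r, rep in zip(records, reports) if rep.eligible]
    counts: dict[EligibilityReason, int] = {}
    for rep in reports:
        for reason in rep.reasons:
            counts[reason] = counts.get(reason, 0) + 1
    if counts:
        logger.info(
            "excluded %d/%d records: %s",
            len(records) - len(kept),
            len(records),
            ", ".join(f"{k.value}={v}" for k, v in counts.items()),
        )
    return kept, reports
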