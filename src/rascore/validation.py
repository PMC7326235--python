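"""Hormone-based validation: classification, ROC/AUC, quartile summaries.

Women with a complete serum panel are classified by joint FSH and
17β-estradiol cut-offs (nonmenopausal: FSH ≤ 20 IU/L and E2 ≥ 147 pmol/L;
postmenopausal: FSH ≥ 80 IU/L and E2 ≤ 73 pmol/L; everyone else
perimenopausal), and the score's ability to separate the classes is
measured with ROC curves. Two contrasts are evaluated: nonmenopausal
women against everyone else, and postmenopausal women against everyone
else. AUC equals the Mann-Whitney pair statistic (ties count one half);
its 95% confidence interval uses the DeLong variance estimate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_curve

from .cohort import ParticipantRecord, Regularity
from .scoring import ScoredRecord

logger = logging.getLogger(__name__)


class MenopausalClass(Enum):
    NONMENOPAUSAL = "nonmenopausal"
    PERIMENOPAUSAL = "perimenopausal"
    POSTMENOPAUSAL = "postmenopausal"


@dataclass(frozen=True)
class HormoneCutoffs:
    """Joint FSH/estradiol thresholds defining the two anchor classes."""

    fsh_nonmeno_max: float = 20.0     # IU/L
    e2_nonmeno_min: float = 147.0     # pmol/L
    fsh_postmeno_min: float = 80.0    # IU/L
    e2_postmeno_max: float = 73.0     # pmol/L

    def __post_init__(self):
        if not self.fsh_nonmeno_max < self.fsh_postmeno_min:
            raise ValueError("fsh_nonmeno_max must be below fsh_postmeno_min")
        if not self.e2_postmeno_max < self.e2_nonmeno_min:
            raise ValueError("e2_postmeno_max must be below e2_nonmeno_min")


@dataclass(frozen=True)
class ROCResult:
    """ROC curve points (FPR, TPR), AUC, and its DeLong 95% CI."""

    points: tuple[tuple[float, float], ...]
    auc: float
    ci_low: float
    ci_high: float
    n_positive: int
    n_negative: int
    ci_method: str = "DeLong"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["fpr", "tpr"])


def classify_by_hormones(
    fsh: float, estradiol: float, cutoffs: HormoneCutoffs = HormoneCutoffs()
) -> MenopausalClass:
    """Classify one woman from her FSH (IU/L) and estradiol (pmol/L)."""
    if fsh is None or estradiol is None:
        raise ValueError("both FSH and estradiol are required for classification")
    if fsh < 0 or estradiol < 0:
        raise ValueError("hormone concentrations must be >= 0")
    if fsh <= cutoffs.fsh_nonmeno_max and estradiol >= cutoffs.e2_nonmeno_min:
        return MenopausalClass.NONMENOPAUSAL
    if fsh >= cutoffs.fsh_postmeno_min and estradiol <= cutoffs.e2_postmeno_max:
        return MenopausalClass.POSTMENOPAUSAL
    return MenopausalClass.PERIMENOPAUSAL


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float, level: float = 0.95):
    """DeLong variance of the AUC via midrank structural components."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    # V10[i] = P(pos_i > neg) + 0.5 P(tie); V01[j] symmetric.
    all_scores = np.concatenate([pos, neg])
    ranks = pd.Series(all_scores).rank(method="average").to_numpy()
    ranks_pos = pd.Series(pos).rank(method="average").to_numpy()
    ranks_neg = pd.Series(neg).rank(method="average").to_numpy()
    v10 = (ranks[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks[m:] - ranks_neg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = norm.ppf(0.5 + level / 2) * np.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def roc(
    scores: Sequence[float], positive_labels: Sequence[bool]
) -> ROCResult:
    """ROC curve and AUC of a score against binary labels.

    The AUC equals the Mann-Whitney pair statistic
    ``P(score_pos > score_neg) + 0.5 * P(tie)``; the curve is the usual
    threshold sweep starting at (0, 0) and ending at (1, 1).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(positive_labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")

    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    # Mann-Whitney form of the AUC, exact with ties.
    ranks = pd.Series(s).rank(method="average").to_numpy()
    auc = float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    ci_low, ci_high = _delong_ci(s, y, auc)
    points = tuple(zip(fpr.tolist(), tpr.tolist()))
    return ROCResult(
        points=points,
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def validate_against_hormones(
    scored: Sequence[ScoredRecord],
    records: Sequence[ParticipantRecord],
    cutoffs: HormoneCutoffs = HormoneCutoffs(),
) -> tuple[ROCResult, ROCResult]:
    """Run both validation contrasts of the score against hormone classes.

    Contrast 1 separates nonmenopausal women (negatives) from peri- and
    postmenopausal women (positives); contrast 2 separates postmenopausal
    women (positives) from nonmenopausal and perimenopausal women
    (negatives). Records without a score or a complete hormone panel are
    skipped with a logged count.
    """
    by_id = {r.id: r for r in records}
    scores: list[float] = []
    classes: list[MenopausalClass] = []
    skipped = 0
    for sr in scored:
        rec = by_id.get(sr.id)
        if (
            sr.ras is None
            or rec is None
            or rec.fsh is None
            or rec.estradiol is None
        ):
            skipped += 1
            continue
        scores.append(sr.ras)
        classes.append(classify_by_hormones(rec.fsh, rec.estradiol, cutoffs))
    if skipped:
        logger.info("skipped %d records without score or complete hormone panel", skipped)
    present = set(classes)
    if len(present) < 2:
        raise ValueError("need at least two menopausal classes for validation")
    labels1 = [c is not MenopausalClass.NONMENOPAUSAL for c in classes]
    labels2 = [c is MenopausalClass.POSTMENOPAUSAL for c in classes]
    return roc(scores, labels1), roc(scores, labels2)


_BIN_LABELS = ("0.00-0.25", "0.26-0.50", "0.51-0.75", "0.76-1.00")
_BIN_EDGES = (0.25, 0.50, 0.75)


def _bin_index(ras: float) -> int:
    # Bins match the printed labels: the score is rounded to 2 decimals
    # first, then binned closed on the right at 0.25/0.50/0.75.
    r = round(ras, 2)
    for i, edge in enumerate(_BIN_EDGES):
        if r <= edge:
            return i
    return 3


def quartile_summary(
    scored: Sequence[ScoredRecord], records: Sequence[ParticipantRecord]
) -> pd.DataFrame:
    """Reproductive characteristics by score quartile bin.

    Returns a table with one column per bin (0.00-0.25 ... 0.76-1.00) and
    rows: n; mean/SD age; mean/SD periods in the last year; percentage
    with regular, irregular and stopped menses; median/IQR FSH and
    estradiol (hormone rows use only complete panels).
    """
    by_id = {r.id: r for r in records}
    cols = {}
    rows_per_bin: list[list[ParticipantRecord]] = [[] for _ in _BIN_LABELS]
    for sr in scored:
        if sr.ras is None or sr.id not in by_id:
            continue
        rows_per_bin[_bin_index(sr.ras)].append(by_id[sr.id])
    if not any(rows_per_bin):
        raise ValueError("no scored records to summarise")

    def iqr_str(values: np.ndarray) -> str:
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        return f"{med:.0f} ({q1:.0f}-{q3:.0f})"

    for label, members in zip(_BIN_LABELS, rows_per_bin):
        n = len(members)
        if n == 0:
            cols[label] = {
                "n": 0, "age_mean": np.nan, "age_sd": np.nan,
                "periods_mean": np.nan, "periods_sd": np.nan,
                "pct_regular": np.nan, "pct_irregular": np.nan,
                "pct_amenorrhea": np.nan, "fsh_median_iqr": "",
                "e2_median_iqr": "",
            }
            continue
        ages = np.array([m.age for m in members], float)
        periods = np.array([m.periods_last_12m for m in members], float)
        reg = np.array([m.regularity for m in members])
        fsh = np.array(
            [m.fsh for m in members if m.fsh is not None and m.estradiol is not None],
            float,
        )
        e2 = np.array(
            [m.estradiol for m in members if m.fsh is not None and m.estradiol is not None],
            float,
        )
        cols[label] = {
            "n": n,
            "age_mean": ages.mean(),
            "age_sd": ages.std(ddof=1) if n > 1 else 0.0,
            "periods_mean": periods.mean(),
            "periods_sd": periods.std(ddof=1) if n > 1 else 0.0,
            "pct_regular": 100.0 * np.mean(reg == Regularity.REGULAR),
            "pct_irregular": 100.0 * np.mean(reg == Regularity.IRREGULAR_FEW_MONTHS),
            "pct_amenorrhea": 100.0 * np.mean(reg == Regularity.STOPPED),
            "fsh_median_iqr": iqr_str(fsh) if len(fsh) else "",
            "e2_median_iqr": iqr_str(e2) if len(e2) else "",
        }
    return pd.DataFrame(cols)
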