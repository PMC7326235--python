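"""Model/results facade for developing and applying the ageing score.

:class:`ReproductiveAgeingScore` is built from development data (raw
records, the two cross-tabulations, or the two proportion series);
``fit()`` performs both membership-curve fits and returns a
:class:`RASResults` carrying the parameter estimates, per-curve fit
diagnostics and a ``summary()`` table. Scoring, validation and plotting
hang off the results object. ``RASResults.published()`` gives the results
object for the published coefficient set without refitting.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import ParticipantRecord, apply_eligibility_filters
from .crosstab import (
    AgeCrosstab,
    GridKind,
    PeriodCrosstab,
    ProportionSeries,
    build_age_crosstab,
    build_period_crosstab,
    load_development_age_crosstab,
    load_development_period_crosstab,
    proportion_regular,
    proportion_stopped,
)
from .membership import (
    PUBLISHED_MU_A,
    PUBLISHED_MU_B,
    FitResult,
    eval_mu_a,
    eval_mu_b,
    fit_mu_a,
    fit_mu_b,
    mse_against_series,
)
from .scoring import RASModel, ScoredRecord, fuzzy_union, score_batch
from .validation import HormoneCutoffs, ROCResult, validate_against_hormones


class ReproductiveAgeingScore:
    """Development-side model: two proportion series to be approximated."""

    def __init__(self, period_series: ProportionSeries, age_series: ProportionSeries):
        if period_series.kind is not GridKind.PERIODS:
            raise ValueError("period_series must be over period counts")
        if age_series.kind is not GridKind.AGE:
            raise ValueError("age_series must be over ages")
        self.period_series = period_series
        self.age_series = age_series

    @classmethod
    def from_records(
        cls, records: Sequence[ParticipantRecord], apply_filters: bool = True
    ) -> "ReproductiveAgeingScore":
        """Build the development series from raw questionnaire records."""
        if apply_filters:
            records, _ = apply_eligibility_filters(records)
        return cls.from_crosstabs(
            build_period_crosstab(records), build_age_crosstab(records)
        )

    @classmethod
    def from_crosstabs(
        cls, period_tab: PeriodCrosstab, age_tab: AgeCrosstab
    ) -> "ReproductiveAgeingScore":
        return cls(proportion_regular(period_tab), proportion_stopped(age_tab))

    @classmethod
    def from_development_data(cls) -> "ReproductiveAgeingScore":
        """Model over the packaged development cross-tabulations (n=3107)."""
        return cls.from_crosstabs(
            load_development_period_crosstab(), load_development_age_crosstab()
        )

    def fit(self) -> "RASResults":
        """Least-squares fits of both membership curves."""
        fit_a = fit_mu_a(self.period_series)
        fit_b = fit_mu_b(self.age_series)
        model = RASModel(mu_a=fit_a.params, mu_b=fit_b.params)
        return RASResults(model=model, fit_a=fit_a, fit_b=fit_b, source=self)


@dataclass
class RASResults:
    """Fitted (or published) score model plus fit diagnostics."""

    model: RASModel
    fit_a: Optional[FitResult] = None
    fit_b: Optional[FitResult] = None
    source: Optional[ReproductiveAgeingScore] = None

    @classmethod
    def published(cls) -> "RASResults":
        """Results wrapping the published coefficient set (no refit)."""
        return cls(model=RASModel(mu_a=PUBLISHED_MU_A, mu_b=PUBLISHED_MU_B))

    # -- application -----------------------------------------------------
    def predict(self, periods, age) -> np.ndarray:
        """Score on a grid of (periods, modified age); vectorised."""
        mu_a = np.atleast_1d(eval_mu_a(periods, self.model.mu_a))
        mu_b = np.atleast_1d(eval_mu_b(age, self.model.mu_b))
        return (mu_a + mu_b - mu_a * mu_b)[()]

    def score_cohort(self, records: Sequence[ParticipantRecord]) -> list[ScoredRecord]:
        return score_batch(records, self.model)

    def validate(
        self,
        records: Sequence[ParticipantRecord],
        cutoffs: HormoneCutoffs = HormoneCutoffs(),
    ) -> tuple[ROCResult, ROCResult]:
        """Both hormone-validation ROC contrasts on a scored cohort."""
        scored = self.score_cohort(records)
        return validate_against_hormones(scored, records, cutoffs)

    # -- diagnostics -----------------------------------------------------
    @property
    def mse_a(self) -> Optional[float]:
        return self.fit_a.mse if self.fit_a else None

    @property
    def mse_b(self) -> Optional[float]:
        return self.fit_b.mse if self.fit_b else None

    def mse_against(self, other: ReproductiveAgeingScore) -> tuple[float, float]:
        """MSEs of this model's curves against another model's series."""
        return (
            mse_against_series(self.model.mu_a, other.period_series),
            mse_against_series(self.model.mu_b, other.age_series),
        )

    def summary(self) -> str:
        """Plain-text summary table of parameters and fit diagnostics."""
        a, b = self.model.mu_a, self.model.mu_b
        lines = [
            "Reproductive Ageing Score model",
            "=" * 46,
            "mu_A: 1 - exp(quartic in period - shift), clamped to [0, 1]",
            f"  shift  {a.shift:>12.6g}",
        ]
        for name, v in zip(("c4", "c3", "c2", "c1", "c0"), a.coefficients()):
            lines.append(f"  {name:<6} {v:>12.6g}")
        if self.fit_a:
            lines.append(
                f"  fit: mse={self.fit_a.mse:.6f} over {self.fit_a.n_points} points,"
                f" converged={self.fit_a.converged}"
            )
        lines.append("mu_B: logistic(quadratic in modified age)")
        for name, v in zip(("b2", "b1", "b0"), b.coefficients()):
            lines.append(f"  {name:<6} {v:>12.6g}")
        if self.fit_b:
            lines.append(
                f"  fit: mse={self.fit_b.mse:.6f} over {self.fit_b.n_points} points,"
                f" converged={self.fit_b.converged}"
            )
        lines.append(
            f"modifiers: smoking +{self.model.smoking_offset:g} y, "
            f"unilateral oophorectomy +{self.model.unilateral_oophorectomy_offset:g} y"
            f" ({'enabled' if self.model.modifiers_enabled else 'disabled'})"
        )
        return "\n".join(lines)

    # -- plotting --------------------------------------------------------
    def plot_membership(self, ax_pair=None):
        """Plot both fitted curves against their development series."""
        import matplotlib.pyplot as plt

        if ax_pair is None:
            _, ax_pair = plt.subplots(1, 2, figsize=(9, 3.5))
        ax_a, ax_b = ax_pair
        if self.source is not None:
            ps = self.source.period_series
            ax_a.plot(ps.grid, 1 - np.asarray(ps.proportions), "ko", ms=4, label="1 - P(period)")
            asrs = self.source.age_series
            ax_b.plot(asrs.grid, asrs.proportions, "ko", ms=4, label="P(age)")
        pgrid = np.linspace(0, 15, 200)
        ax_a.plot(pgrid, eval_mu_a(pgrid, self.model.mu_a), "b-", label="mu_A")
        ax_a.set_xlabel("periods in last 12 months")
        ax_a.set_ylabel("membership")
        ax_a.legend()
        agrid = np.linspace(38, 66, 200)
        ax_b.plot(agrid, eval_mu_b(agrid, self.model.mu_b), "b-", label="mu_B")
        ax_b.set_xlabel("age [y]")
        ax_b.legend()
        return ax_pair
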