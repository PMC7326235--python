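"""Seeded synthetic mid-life cohorts with a latent reproductive-ageing stage.

The generator emulates the statistical structure the score assumes rather
than any real population: each woman gets a latent stage ``u`` in [0, 1],
a noisy logistic transform of her age centred near the observed
transition midpoint (~51 y). The stage then drives everything downstream:

* menses stop with probability ``u``; stopped women report mostly zero
  periods in the last year;
* among menstruating women, irregularity peaks at intermediate stage, and
  period counts drift down from 12 — with occasional counts of 13-15 at
  intermediate stage, since both lengthening and shortening cycles mark
  the early transition;
* log FSH rises and log estradiol falls linearly in ``u`` between the
  anchor medians of the nonmenopausal and postmenopausal groups, with
  lognormal noise (hormone spreads are strongly right-skewed).

Eligibility flags (hormone use, pregnancy, breastfeeding, irregularity
unrelated to menopause, oophorectomy) and smoking default to small
nonzero prevalences so filtering is exercised. Same seed and config give
a byte-identical cohort.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
from scipy.special import expit

from .cohort import Oophorectomy, ParticipantRecord, Regularity
from .crosstab import (
    AgeCrosstab,
    PeriodCrosstab,
    build_age_crosstab,
    build_period_crosstab,
)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n: int = 5000
    seed: int = 0
    age_min: int = 38
    age_max: int = 66
    stage_age_midpoint: float = 51.0   # years; observed transition midpoint
    stage_age_scale: float = 3.0       # years per logit unit
    stage_noise_sd: float = 1.0        # SD of logit-scale stage noise
    fsh_nonmeno_median: float = 11.0   # IU/L
    fsh_postmeno_median: float = 124.0 # IU/L
    e2_nonmeno_median: float = 264.0   # pmol/L
    e2_postmeno_median: float = 12.0   # pmol/L
    lognormal_sigma: float = 0.5
    hormone_use_rate: float = 0.08
    pregnancy_rate: float = 0.005
    breastfeeding_rate: float = 0.005
    irregular_unrelated_rate: float = 0.01
    smoking_prevalence: float = 0.25
    unilateral_oophorectomy_rate: float = 0.02
    bilateral_oophorectomy_rate: float = 0.01

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n: cohort size must be >= 1")
        if self.age_min >= self.age_max:
            raise ValueError("age_min: must be below age_max")
        if self.stage_age_scale <= 0:
            raise ValueError("stage_age_scale: must be > 0")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma: must be >= 0")
        for f in fields(self):
            if f.name.endswith(("_rate", "_prevalence")):
                v = getattr(self, f.name)
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{f.name}: must be a probability in [0, 1]")
        for f in ("fsh_nonmeno_median", "fsh_postmeno_median",
                  "e2_nonmeno_median", "e2_postmeno_median"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f}: must be > 0")


def generate_cohort(
    config: SyntheticCohortConfig = SyntheticCohortConfig(),
) -> list[ParticipantRecord]:
    """Draw a synthetic cohort of :class:`ParticipantRecord` objects."""
    rng = np.random.default_rng(config.seed)
    n = config.n

    ages = rng.integers(config.age_min, config.age_max + 1, size=n)
    logit_stage = (
        (ages - config.stage_age_midpoint) / config.stage_age_scale
        + rng.normal(0.0, config.stage_noise_sd, size=n)
    )
    stage = expit(logit_stage)

    records: list[ParticipantRecord] = []
    log_fsh_lo, log_fsh_hi = np.log(config.fsh_nonmeno_median), np.log(config.fsh_postmeno_median)
    log_e2_lo, log_e2_hi = np.log(config.e2_nonmeno_median), np.log(config.e2_postmeno_median)

    for i in range(n):
        u = float(stage[i])
        stopped = rng.random() < u
        if stopped:
            regularity = Regularity.STOPPED
            # mostly full amenorrhea, a tail of 1-6 recent periods
            periods = 0 if rng.random() < 0.93 else int(rng.integers(1, 7))
        else:
            # cycles both lengthen (count drifts below 12 as the stage
            # advances) and shorten (occasional 13-15 mid-transition)
            if rng.random() < 0.10 * 4.0 * u * (1.0 - u):
                periods = int(rng.integers(13, 16))
            else:
                periods = int(np.clip(
                    round(12.0 - 13.0 * max(0.0, u - 0.12) + rng.normal(0, 1.2)),
                    0, 12,
                ))
            # probability of answering "regular" rises with the period
            # count, mirroring the development table's gradient
            if periods <= 12:
                p_reg = 0.03 + 0.93 * expit((periods - 10.6) / 0.9)
            else:
                p_reg = {13: 0.90, 14: 0.72, 15: 0.50}[periods]
            regularity = (
                Regularity.REGULAR if rng.random() < p_reg
                else Regularity.IRREGULAR_FEW_MONTHS
            )

        log_fsh = (1 - u) * log_fsh_lo + u * log_fsh_hi + rng.normal(0, config.lognormal_sigma)
        log_e2 = (1 - u) * log_e2_lo + u * log_e2_hi + rng.normal(0, config.lognormal_sigma)

        oo = rng.random()
        if oo < config.bilateral_oophorectomy_rate:
            oophorectomy = Oophorectomy.BILATERAL
        elif oo < config.bilateral_oophorectomy_rate + config.unilateral_oophorectomy_rate:
            oophorectomy = Oophorectomy.UNILATERAL
        else:
            oophorectomy = Oophorectomy.NONE

        records.append(
            ParticipantRecord(
                id=f"syn{i:06d}",
                age=int(ages[i]),
                periods_last_12m=periods,
                regularity=regularity,
                smoker_current=bool(rng.random() < config.smoking_prevalence),
                oophorectomy=oophorectomy,
                exogenous_hormone_use=bool(rng.random() < config.hormone_use_rate),
                pregnant=bool(rng.random() < config.pregnancy_rate and u < 0.5),
                breastfeeding=bool(rng.random() < config.breastfeeding_rate and u < 0.5),
                irregular_unrelated_to_menopause=bool(
                    rng.random() < config.irregular_unrelated_rate
                ),
                fsh=float(np.exp(log_fsh)),
                estradiol=float(np.exp(log_e2)),
            )
        )
    return records


def generate_crosstab_fixture(
    config: SyntheticCohortConfig = SyntheticCohortConfig(),
) -> tuple[PeriodCrosstab, AgeCrosstab]:
    """Generate a cohort and tabulate it; convenience for fit tests."""
    records = generate_cohort(config)
    return build_period_crosstab(records), build_age_crosstab(records)
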