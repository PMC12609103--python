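"""Configuration models for the synthetic-claims generator and the pipeline.

All models are pydantic with ``extra="forbid"``: unknown keys are rejected
before any stage runs, and validation errors name the offending field.
Dates are ISO-8601; time inside the generator is integer days since
1970-01-01 and follow-up months are 30-day bins from time zero.
"""

from __future__ import annotations

import datetime as dt
from typing import Literal

import pydantic
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError

DX_WINDOW_MIN = dt.date(2008, 1, 1)
DX_WINDOW_MAX = dt.date(2019, 12, 31)

#: Comorbidity covariates carried by the generator; order is part of the
#: reproducibility contract (streams draw in this order).
CONFOUNDER_NAMES = ("diabetes", "chf", "cerebrovascular", "hypertension", "depression")

#: Diagnosis codes that contraindicate metformin at eligibility screening.
#: CHF is deliberately excluded here: the eligible population retains
#: prevalent CHF as a baseline comorbidity, while *new-onset* CHF during
#: follow-up still counts toward ``contraindication_any`` (see exposure
#: module), which exempts a subsequent discontinuation.
BASELINE_CONTRAINDICATIONS = ("hepatic_failure", "severe_renal", "metabolic_acidosis")
FOLLOWUP_CONTRAINDICATIONS = BASELINE_CONTRAINDICATIONS + ("chf",)

#: Planted eligibility-violation classes, in screening order.
VIOLATION_CLASSES = (
    "under_66", "no_adt", "prior_metformin", "contraindication",
    "coverage_gap", "early_death",
)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ConfounderEffect(_Model):
    """One binary baseline confounder.

    prevalence      P(L=1) at baseline.
    logit_treat     additive effect of L on the initiation log-odds.
    log_hazard      additive effect of L on the monthly death log-hazard.
    """

    prevalence: float = Field(ge=0.0, le=1.0)
    logit_treat: float = 0.0
    log_hazard: float = 0.0


class AdherenceSpec(_Model):
    """Monthly treatment-deviation processes.

    Initiators discontinue with monthly probability
    expit(logit(monthly_disc_prob) + disc_logit_diabetes * diabetes(t)
    + disc_logit_contraindication * contraindication(t)); discontinuation
    after a contraindication onset is protocol-compliant.  Non-initiators
    start metformin off-protocol with probability ``noninit_start_prob``
    per month (``noninit_start_prob_indicated`` once diabetes has onset,
    which is an indication and therefore not a deviation).
    """

    monthly_disc_prob: float = Field(default=0.05, ge=0.0, le=1.0)
    disc_logit_diabetes: float = 0.5
    disc_logit_contraindication: float = 2.0
    noninit_start_prob: float = Field(default=0.001, ge=0.0, le=1.0)
    noninit_start_prob_indicated: float = Field(default=0.02, ge=0.0, le=1.0)


class LtfuSpec(_Model):
    """Monthly probability of disenrollment (loss to follow-up)."""

    monthly_prob: float = Field(default=0.002, ge=0.0, le=1.0)


class GapBehavior(_Model):
    """Distribution of the delay between a fill's supply end and the next fill.

    Delays are uniform integers on [0, max_delay_days].  A fraction
    ``long_gap_fraction`` of initiators additionally receive one planted
    delay of ``long_gap_days`` at refill index ``long_gap_at_fill`` — used
    to exercise the 30- vs 60-day discontinuation windows.
    """

    max_delay_days: int = Field(default=10, ge=0)
    long_gap_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    long_gap_days: int = Field(default=45, ge=0)
    long_gap_at_fill: int = Field(default=3, ge=1)


class ViolationFractions(_Model):
    """Fractions of patients planted with exactly one eligibility violation."""

    under_66: float = Field(default=0.02, ge=0.0, le=1.0)
    no_adt: float = Field(default=0.03, ge=0.0, le=1.0)
    prior_metformin: float = Field(default=0.02, ge=0.0, le=1.0)
    contraindication: float = Field(default=0.02, ge=0.0, le=1.0)
    coverage_gap: float = Field(default=0.02, ge=0.0, le=1.0)
    early_death: float = Field(default=0.02, ge=0.0, le=1.0)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in VIOLATION_CLASSES}

    @model_validator(mode="after")
    def _total(self):
        if sum(self.as_dict().values()) > 1.0:
            raise ValueError("violation fractions sum to more than 1")
        return self


def _default_confounders() -> dict[str, ConfounderEffect]:
    # Prevalences follow the non-initiator column of the study population;
    # treatment effects make diabetes the dominant initiation driver
    # (metformin's indication), hazard effects are modest comorbidity loads.
    return {
        "diabetes": ConfounderEffect(prevalence=0.106, logit_treat=2.0, log_hazard=0.35),
        "chf": ConfounderEffect(prevalence=0.035, logit_treat=0.3, log_hazard=0.5),
        "cerebrovascular": ConfounderEffect(prevalence=0.066, logit_treat=0.1, log_hazard=0.3),
        "hypertension": ConfounderEffect(prevalence=0.673, logit_treat=0.2, log_hazard=0.1),
        "depression": ConfounderEffect(prevalence=0.078, logit_treat=0.2, log_hazard=0.15),
    }


class SimulationConfig(_Model):
    """Full parameterization of one synthetic claims dataset.

    The defaults emulate the study conditions: diagnoses 2008–2019 with
    administrative end 2020-12-31, age 75.4 (SD 6.8) truncated at 66,
    ~1.5% metformin initiation driven mainly by baseline diabetes, 3-year
    all-cause mortality ≈ 42% (monthly hazard 0.015) with ≈ 63% of deaths
    cancer-specific, and null treatment effects.
    """

    n_patients: int = Field(ge=0)
    seed: int = 0

    dx_window: tuple[dt.date, dt.date] = (DX_WINDOW_MIN, DX_WINDOW_MAX)
    admin_end: dt.date = dt.date(2020, 12, 31)

    age_mean: float = 75.4
    age_sd: float = Field(default=6.8, gt=0)

    true_hr_allcause: float = Field(default=1.0, gt=0)
    true_hr_pca: float = Field(default=1.0, gt=0)
    baseline_monthly_hazard: float = Field(default=0.015, ge=0.0, le=1.0)
    pca_death_fraction: float = Field(default=0.63, ge=0.0, le=1.0)

    treat_intercept: float = -4.6
    confounders: dict[str, ConfounderEffect] = Field(default_factory=_default_confounders)

    race_probs: dict[str, float] = Field(default_factory=lambda: {
        "hispanic": 0.071, "nh_black": 0.085, "nh_white": 0.777, "other": 0.067})
    marital_probs: dict[str, float] = Field(default_factory=lambda: {
        "divorced_widowed": 0.158, "married": 0.655, "never_married": 0.117,
        "unknown": 0.070})
    pcp_visit_mean: float = Field(default=4.9, ge=0)
    orchiectomy_fraction: float = Field(default=0.05, ge=0.0, le=1.0)

    # maximum days from diagnosis to ADT start and to the first metformin
    # fill.  Validation scenarios set both small so the two strategies share
    # the same time-zero anchor relative to diagnosis (avoiding differential
    # immortal time from the survive-6-months eligibility condition).
    adt_max_delay_days: int = Field(default=60, ge=0, le=183)
    fill_max_delay_days: int = Field(default=150, ge=0, le=183)

    diabetes_onset_monthly: float = Field(default=0.003, ge=0.0, le=1.0)
    contraindication_onset_monthly: float = Field(default=0.002, ge=0.0, le=1.0)
    contraindication_log_hazard: float = 0.5
    # days after the last supply end during which the drug effect persists;
    # set to the allowed refill gap so the generating exposure period
    # coincides with the protocol's definition of continuous use
    exposure_carryover_days: int = Field(default=30, ge=0)

    adherence: AdherenceSpec = Field(default_factory=AdherenceSpec)
    ltfu: LtfuSpec = Field(default_factory=LtfuSpec)
    gap_behavior: GapBehavior = Field(default_factory=GapBehavior)
    supply_days: int = Field(default=30, ge=1)
    violations: ViolationFractions = Field(default_factory=ViolationFractions)

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.dx_window
        if lo > hi:
            raise ValueError("dx_window: start after end")
        if lo < DX_WINDOW_MIN or hi > DX_WINDOW_MAX:
            raise ValueError("dx_window: outside 2008-01-01..2019-12-31")
        if self.admin_end < hi:
            raise ValueError("admin_end: before end of diagnosis window")
        probs_sum = sum(self.race_probs.values())
        if abs(probs_sum - 1.0) > 1e-9:
            raise ValueError("race_probs: must sum to 1")
        if abs(sum(self.marital_probs.values()) - 1.0) > 1e-9:
            raise ValueError("marital_probs: must sum to 1")
        for name in self.confounders:
            if name not in CONFOUNDER_NAMES:
                raise ValueError(f"confounders: unknown covariate {name!r}")
        # mixture share of cancer deaths among the treated must stay a probability
        p1 = self.pca_death_fraction * self.true_hr_pca / self.true_hr_allcause
        if p1 > 1.0:
            raise ValueError(
                "pca_death_fraction * true_hr_pca / true_hr_allcause exceeds 1; "
                "the death-cause mixture cannot represent this combination")
        return self


class PipelineConfig(_Model):
    """One end-to-end emulation run."""

    seed: int = 0
    gap_days: int = Field(default=30, ge=1)
    truncation_pct: float = Field(default=99.0, gt=0.0, le=100.0)
    analyses: list[Literal["itt", "per_protocol", "per_protocol_ltfu",
                           "per_protocol_gap60"]] = Field(
        default_factory=lambda: ["itt", "per_protocol", "per_protocol_ltfu",
                                 "per_protocol_gap60"])
    outcomes: list[Literal["allcause", "pca_specific"]] = Field(
        default_factory=lambda: ["allcause", "pca_specific"])
    simulation: SimulationConfig | None = None
    suppress_below: int = Field(default=11, ge=0)


def validate_config(data: dict, model: type[_Model]) -> _Model:
    """Build a config model, rewrapping pydantic errors as ConfigurationError."""
    try:
        return model.model_validate(data)
    except pydantic.ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigurationError(f"{loc}: {first['msg']}") from exc
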