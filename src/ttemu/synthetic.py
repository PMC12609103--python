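"""Synthetic claims generator with known causal structure.

Generates the five claims tables (patients, coverage, fills, events, deaths)
from a :class:`~ttemu.config.SimulationConfig`, together with a ``truth``
table recording the generative plan per patient: planted eligibility
violations, the true discontinuation process, deviation and exit months.
Every downstream pipeline stage is testable against this bookkeeping.

Generative model (time unit: days; follow-up months are 30-day bins from
time zero):

* Diagnosis date uniform over the configured window; age truncated normal
  (≥ 66) except for planted under-66 violators.
* Binary comorbidity confounders with configured prevalences; metformin
  initiation is Bernoulli with logit = intercept + Σ βⱼ Lⱼ (βⱼ from the
  confounder spec), producing measured baseline confounding.
* All patients (except planted no-ADT violators) receive ADT 0–60 days
  after diagnosis — a hormonal fill or, for a small fraction, an
  orchiectomy.  Initiators fill metformin 0–150 days after diagnosis; time
  zero is max(ADT date, first fill) for initiators, the ADT date otherwise.
* Death is a discrete-time monthly logistic hazard from time zero:
  logit p = logit(h₀) + log(HR)·on_treat(m) + Σ γⱼ Lⱼ(m), where on_treat
  is derived from the *generated fill coverage* (any month whose start lies
  within the continuous-use episode counts as treated), so the pooled
  logistic per-protocol estimand equals the generating HR by construction.
  Death cause is a mixture: P(cancer death) = pca_death_fraction, scaled by
  true_hr_pca / true_hr_allcause for deaths occurring on treatment, so both
  cause-specific hazard ratios are configurable.
* Initiators discontinue via a monthly logistic process depending on
  time-varying diabetes and contraindication onset (informative adherence);
  fills stop at the true discontinuation day.  Non-initiators may start
  metformin off-protocol (a deviation) or after diabetes onset (indicated,
  protocol-compliant).
* Loss to follow-up is a geometric monthly disenrollment; coverage spans
  end at disenrollment or death.

Determinism: one named substream per stochastic component, drawn in
patient-major order (see :mod:`ttemu.rng`), so identical configs give
byte-identical datasets and the first n patients do not change when more
are appended.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .config import (
    BASELINE_CONTRAINDICATIONS,
    CONFOUNDER_NAMES,
    FOLLOWUP_CONTRAINDICATIONS,
    VIOLATION_CLASSES,
    SimulationConfig,
)
from .datamodel import ClaimsDataset
from .rng import substream

BIG = 10**9  # sentinel "never happens" day / month
T_MAX = 37   # max 30-day months within 1095 days of follow-up
K_MAX = 42   # max fills per treated episode

FOLLOWUP_DAYS = 1095       # "3 years" after diagnosis
HALF_YEAR_DAYS = 183       # "6 months"
YEAR_DAYS = 365            # "1 year"

#: Screening criterion attributed to each planted/emergent violation class.
VIOLATION_TO_CRITERION = {
    "under_66": "age_ge_66",
    "no_adt": "adt_within_6mo",
    "prior_metformin": "no_prior_metformin_6mo",
    "contraindication": "no_contraindication",
    "coverage_gap": "one_year_prior_AB_no_HMO",
    "early_death": "alive_enrolled_D_6mo_post",
    "early_disenroll": "alive_enrolled_D_6mo_post",
}


def _day(d: dt.date) -> int:
    return (d - dt.date(1970, 1, 1)).days


def _logit(p):
    with np.errstate(divide="ignore"):
        return np.log(p) - np.log1p(-p)


def _geometric_month(u: np.ndarray, p: float) -> np.ndarray:
    """First-success month (>= 1) of a monthly Bernoulli(p) process."""
    if p <= 0:
        return np.full(u.shape, BIG, dtype=np.int64)
    if p >= 1:
        return np.ones(u.shape, dtype=np.int64)
    k = np.floor(np.log(u) / np.log1p(-p)).astype(np.int64) + 1
    return np.minimum(k, BIG)


def _first_true(mask: np.ndarray) -> np.ndarray:
    """Per-row index of first True, BIG where none."""
    idx = mask.argmax(axis=1)
    idx = np.where(mask.any(axis=1), idx, BIG)
    return idx.astype(np.int64)


def _empty_dataset() -> ClaimsDataset:
    def df(cols):
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in cols})

    d = "datetime64[ns]"
    return ClaimsDataset(
        patients=df([("patient_id", "int64"), ("birth_date", d), ("diagnosis_date", d),
                     ("race_ethnicity", "object"), ("marital_status", "object"),
                     ("education_quartile", "int64"), ("poverty_quartile", "int64"),
                     ("rurality", "object")]),
        coverage=df([("patient_id", "int64"), ("part", "object"), ("start_date", d),
                     ("end_date", d)]),
        fills=df([("patient_id", "int64"), ("drug", "object"), ("fill_date", d),
                  ("days_supply", "int64")]),
        events=df([("patient_id", "int64"), ("event_code", "object"), ("event_date", d)]),
        deaths=df([("patient_id", "int64"), ("death_date", d), ("cause", "object")]),
        truth=pd.DataFrame(),
    )


def generate_population(config: SimulationConfig) -> ClaimsDataset:
    """Generate one synthetic claims dataset under ``config``.

    Returns a validated :class:`ClaimsDataset` whose ``truth`` table holds
    the generative bookkeeping (one row per patient).
    """
    n = config.n_patients
    if n == 0:
        return _empty_dataset()
    seed = config.seed
    supply = config.supply_days

    dx_lo, dx_hi = _day(config.dx_window[0]), _day(config.dx_window[1])
    admin_end = _day(config.admin_end)

    pid = np.arange(1, n + 1, dtype=np.int64)

    # --- diagnosis date, planted violation class, age -------------------
    u = substream(seed, "diagnosis").random(n)
    dx = dx_lo + np.floor(u * (dx_hi - dx_lo + 1)).astype(np.int64)

    u = substream(seed, "violation").random(n)
    fracs = config.violations.as_dict()
    edges = np.cumsum([fracs[c] for c in VIOLATION_CLASSES])
    vio_idx = np.searchsorted(edges, u, side="right")  # == len -> none
    violation = np.array(list(VIOLATION_CLASSES) + ["none"], dtype=object)[vio_idx]

    u = substream(seed, "age").random(n)
    a = (66.0 - config.age_mean) / config.age_sd
    age = truncnorm.ppf(u, a, np.inf, loc=config.age_mean, scale=config.age_sd)
    under = violation == "under_66"
    age[under] = 60.0 + 5.9 * u[under]
    birth = dx - np.round(age * 365.25).astype(np.int64)

    # --- baseline confounders and demographics --------------------------
    u5 = substream(seed, "confounders").random((n, len(CONFOUNDER_NAMES)))
    L = {}
    beta_treat, gamma_haz = {}, {}
    for j, name in enumerate(CONFOUNDER_NAMES):
        spec = config.confounders.get(name)
        if spec is None:
            L[name] = np.zeros(n, dtype=bool)
            beta_treat[name] = gamma_haz[name] = 0.0
        else:
            L[name] = u5[:, j] < spec.prevalence
            beta_treat[name] = spec.logit_treat
            gamma_haz[name] = spec.log_hazard

    ud = substream(seed, "demographics").random((n, 5))

    def _cat(u_col, probs: dict[str, float]):
        keys = list(probs)
        edges_ = np.cumsum([probs[k] for k in keys])
        return np.array(keys, dtype=object)[np.searchsorted(edges_, u_col, side="right").clip(0, len(keys) - 1)]

    race = _cat(ud[:, 0], config.race_probs)
    marital = _cat(ud[:, 1], config.marital_probs)
    education = 1 + np.floor(ud[:, 2] * 4).astype(np.int64)
    poverty = 1 + np.floor(ud[:, 3] * 4).astype(np.int64)
    rurality = _cat(ud[:, 4], {"metro": 0.822, "urban": 0.155, "rural": 0.023})

    pcp = substream(seed, "pcp_visits").poisson(config.pcp_visit_mean, n).astype(np.int64)

    # --- treatment assignment, ADT, time zero ---------------------------
    logit_a = np.full(n, config.treat_intercept)
    for name in CONFOUNDER_NAMES:
        logit_a += beta_treat[name] * L[name]
    initiator = substream(seed, "initiation").random(n) < expit(logit_a)

    ua = substream(seed, "adt").random((n, 2))
    adt_day = dx + np.floor(ua[:, 0] * (config.adt_max_delay_days + 1)).astype(np.int64)
    adt_day[violation == "no_adt"] = dx[violation == "no_adt"] + 200  # outside window
    orchiectomy = ua[:, 1] < config.orchiectomy_fraction

    uf = substream(seed, "first_fill").random((n, 2))
    f0 = dx + np.floor(uf[:, 0] * (config.fill_max_delay_days + 1)).astype(np.int64)  # initiators
    prior_fill_day = dx - 1 - np.floor(uf[:, 1] * 180).astype(np.int64)

    tz = np.where(initiator, np.maximum(adt_day, f0), adt_day)
    fu_end = np.minimum(dx + FOLLOWUP_DAYS, admin_end)
    n_months = (fu_end - tz) // 30 + 1          # months 0 .. n_months-1
    month_idx = np.arange(T_MAX)
    active = month_idx[None, :] < n_months[:, None]
    mstart = tz[:, None] + 30 * month_idx[None, :]

    # --- time-varying covariate onsets ----------------------------------
    # onset day offsets are 1..29 within the onset month, so an onset event is
    # always strictly inside its month and never collides with a month-start
    # fill date (keeps generator truth and claim-derived rules equivalent)
    uo = substream(seed, "diabetes_onset").random((n, 2))
    dia_onset_m = _geometric_month(uo[:, 0], config.diabetes_onset_monthly)
    dia_onset_m[L["diabetes"]] = 0
    dia_onset_day = tz + 30 * np.minimum(dia_onset_m, BIG // 60) \
        + 1 + np.floor(uo[:, 1] * 29).astype(np.int64)
    diab_t = dia_onset_m[:, None] < month_idx[None, :]
    diab_t |= L["diabetes"][:, None]

    uc = substream(seed, "contra_onset").random((n, 2))
    con_onset_m = _geometric_month(uc[:, 0], config.contraindication_onset_monthly)
    con_onset_day = tz + 30 * np.minimum(con_onset_m, BIG // 60) \
        + 1 + np.floor(uc[:, 1] * 29).astype(np.int64)
    contra_t = con_onset_m[:, None] < month_idx[None, :]
    ucc = substream(seed, "contra_code").random((n, 2))
    con_code = np.array(FOLLOWUP_CONTRAINDICATIONS, dtype=object)[
        np.floor(ucc[:, 0] * len(FOLLOWUP_CONTRAINDICATIONS)).astype(np.int64)]
    vio_con_code = np.array(BASELINE_CONTRAINDICATIONS, dtype=object)[
        np.floor(ucc[:, 1] * len(BASELINE_CONTRAINDICATIONS)).astype(np.int64)]

    # --- adherence processes --------------------------------------------
    ad = config.adherence
    p_disc = expit(_logit(ad.monthly_disc_prob)
                   + ad.disc_logit_diabetes * diab_t
                   + ad.disc_logit_contraindication * contra_t)
    udisc = substream(seed, "discontinuation").random((n, T_MAX))
    disc_hit = (udisc < p_disc) & (month_idx[None, :] >= 1) & active
    disc_hit &= initiator[:, None]
    disc_m = _first_true(disc_hit)
    disc_day = np.where(disc_m < BIG, tz + 30 * np.minimum(disc_m, BIG // 60), BIG)

    p_start = np.where(diab_t, ad.noninit_start_prob_indicated, ad.noninit_start_prob)
    ustart = substream(seed, "noninit_start").random((n, T_MAX))
    # off-protocol fills must begin after the 6-month classification window
    start_hit = (ustart < p_start) & (mstart > (dx + HALF_YEAR_DAYS)[:, None]) & active
    start_hit &= ~initiator[:, None]
    start_m = _first_true(start_hit)
    start_indicated = np.zeros(n, dtype=bool)
    has_start = start_m < BIG
    start_indicated[has_start] = (
        diab_t[np.nonzero(has_start)[0], start_m[has_start]])
    start_day = np.where(has_start, tz + 30 * np.minimum(start_m, BIG // 60), BIG)

    # --- fill chains for treated episodes -------------------------------
    gap_cfg = config.gap_behavior
    udel = substream(seed, "fill_delays").random((n, K_MAX))
    delays = np.floor(udel * (gap_cfg.max_delay_days + 1)).astype(np.int64)
    planted_gap = np.zeros(n, dtype=bool)
    if gap_cfg.long_gap_fraction > 0:
        planted_gap = initiator & (udel[:, K_MAX - 1] < gap_cfg.long_gap_fraction) \
            & (disc_m > gap_cfg.long_gap_at_fill + 2)
        delays[planted_gap, gap_cfg.long_gap_at_fill] = gap_cfg.long_gap_days

    episode_start = np.where(initiator, f0, start_day)
    has_episode = initiator | has_start
    steps = supply + delays
    fill_days = episode_start[:, None] + np.concatenate(
        [np.zeros((n, 1), dtype=np.int64), np.cumsum(steps[:, :-1], axis=1)], axis=1)

    # --- death process (hazard uses fill-coverage treatment status) -----
    # stop issuing fills at true discontinuation or follow-up end
    fill_stop = np.where(initiator, np.minimum(disc_day, fu_end + supply), fu_end + supply)
    fill_valid = has_episode[:, None] & (fill_days < fill_stop[:, None])
    lse = np.where(fill_valid.any(axis=1),
                   (np.where(fill_valid, fill_days, -BIG)).max(axis=1) + supply - 1,
                   -BIG)
    # the treated period matches the protocol's definition of continuous
    # use: drug effect persists through the allowed refill gap, ending when
    # a 30-day gap after the last supply is exhausted
    on_treat = (mstart <= (lse + config.exposure_carryover_days)[:, None]) \
        & (mstart + 29 >= episode_start[:, None])

    log_hr = np.log(config.true_hr_allcause)
    base = _logit(config.baseline_monthly_hazard)
    lin = np.full((n, T_MAX), base)
    lin += log_hr * on_treat
    for name in ("chf", "cerebrovascular", "hypertension", "depression"):
        lin += gamma_haz[name] * L[name][:, None]
    lin += gamma_haz["diabetes"] * diab_t
    lin += config.contraindication_log_hazard * contra_t
    p_death = expit(lin) if config.baseline_monthly_hazard > 0 else np.zeros((n, T_MAX))

    udeath = substream(seed, "death").random((n, T_MAX))
    death_hit = (udeath < p_death) & active
    death_m = _first_true(death_hit)
    offs = np.floor(substream(seed, "death_offset").random(n) * 30).astype(np.int64)
    death_day = np.where(death_m < BIG, tz + 30 * np.minimum(death_m, BIG // 60) + offs, BIG)
    death_day = np.where(death_day > fu_end, BIG, death_day)  # beyond window: unobserved
    death_m = np.where(death_day < BIG, (death_day - tz) // 30, BIG)

    # planted early deaths (before 6 months post-diagnosis)
    early = violation == "early_death"
    ed_day = dx + 30 + np.floor(substream(seed, "early_death").random(n) * 150).astype(np.int64)
    death_day = np.where(early, ed_day, death_day)
    death_m = np.where(early, np.maximum((death_day - tz) // 30, 0), death_m)

    died_on_treat = np.zeros(n, dtype=bool)
    has_death = death_m < BIG
    rows = np.nonzero(has_death & ~early)[0]
    died_on_treat[rows] = on_treat[rows, np.minimum(death_m[rows], T_MAX - 1)]
    p_pca = np.where(died_on_treat,
                     min(1.0, config.pca_death_fraction * config.true_hr_pca / config.true_hr_allcause),
                     config.pca_death_fraction)
    cause = np.where(substream(seed, "cause").random(n) < p_pca, "pca", "other").astype(object)

    # --- loss to follow-up ----------------------------------------------
    ul = substream(seed, "ltfu").random((n, 2))
    ltfu_m = _geometric_month(ul[:, 0], config.ltfu.monthly_prob)
    ltfu_day = np.where(ltfu_m < BIG,
                        tz + 30 * np.minimum(ltfu_m, BIG // 60) + np.floor(ul[:, 1] * 30).astype(np.int64),
                        BIG)
    ltfu_day = np.where(ltfu_day > fu_end, BIG, ltfu_day)

    # =====================================================================
    # Ground-truth bookkeeping
    # =====================================================================
    alive_end = np.minimum.reduce([fu_end, death_day, ltfu_day])

    # eligibility: planted class, else emergent early death / disenrollment
    truth_violation = violation.copy()
    none_mask = truth_violation == "none"
    emergent_death = none_mask & (death_day <= dx + HALF_YEAR_DAYS)
    truth_violation[emergent_death] = "early_death"
    none_mask = truth_violation == "none"
    emergent_ltfu = none_mask & (ltfu_day < dx + HALF_YEAR_DAYS)
    truth_violation[emergent_ltfu] = "early_disenroll"
    eligible = truth_violation == "none"

    # deviation under each gap rule (initiators: uncompensated gap in fills;
    # non-initiators: off-protocol start without indication)
    dev30_day = np.full(n, BIG, dtype=np.int64)
    dev60_day = np.full(n, BIG, dtype=np.int64)
    # true discontinuation tail: uncovered run starts at lse+1, unbounded
    tail_start = np.where(initiator & (disc_m < BIG), lse + 1, BIG)
    # planted mid-chain hole: run starts after the gapped fill's supply end
    hole_start = np.full(n, BIG, dtype=np.int64)
    if gap_cfg.long_gap_fraction > 0:
        k = gap_cfg.long_gap_at_fill
        # the long delay sits between fill k and fill k+1
        hole_start = np.where(planted_gap & fill_valid[:, k],
                              fill_days[:, k] + supply, BIG)
    for gap_days, dev in ((30, dev30_day), (60, dev60_day)):
        cand = np.minimum(
            np.where(tail_start < BIG, tail_start + gap_days, BIG),
            np.where((hole_start < BIG) & (gap_cfg.long_gap_days > gap_days),
                     hole_start + gap_days, BIG))
        # contraindication before the detected date exempts the deviation
        exempt = con_onset_day <= cand
        ok = initiator & (cand < BIG) & ~exempt & (cand <= alive_end)
        dev[ok] = cand[ok]
        # non-initiator off-protocol start
        ni = ~initiator & has_start & ~start_indicated & (start_day <= alive_end)
        dev[ni] = start_day[ni]

    def _exit(dev_day):
        cand_days = np.stack([death_day, dev_day, ltfu_day, fu_end])
        cand_m = np.where(cand_days < BIG, (cand_days - tz[None, :]) // 30, BIG)
        cand_m[3] = (fu_end - tz) // 30
        # priority at month ties: death > deviation > ltfu > admin
        key = cand_m * 10 + np.arange(4)[:, None]
        reason_idx = key.argmin(axis=0)
        exit_m = cand_m[reason_idx, np.arange(n)]
        reasons = np.array(["death", "deviation", "ltfu", "admin"], dtype=object)
        return exit_m, reasons[reason_idx]

    pp_exit_m, pp_exit_reason = _exit(dev30_day)
    itt_exit_m, itt_exit_reason = _exit(np.full(n, BIG, dtype=np.int64))

    truth = pd.DataFrame({
        "patient_id": pid, "violation": truth_violation, "eligible": eligible,
        "initiator": initiator, "dx_day": dx, "tz_day": tz, "adt_day": adt_day,
        "first_fill_day": np.where(initiator, f0, BIG), "fu_end_day": fu_end,
        "disc_month": disc_m, "lse_day": lse,
        "noninit_start_month": start_m, "start_indicated": start_indicated,
        "diabetes_onset_month": dia_onset_m, "contra_onset_month": con_onset_m,
        "contra_onset_day": np.where(con_onset_m < BIG, con_onset_day, BIG),
        "death_day": death_day, "death_month": death_m, "cause": cause,
        "ltfu_day": ltfu_day,
        "dev30_day": dev30_day, "dev60_day": dev60_day,
        "dev30_month": np.where(dev30_day < BIG, (dev30_day - tz) // 30, BIG),
        "dev60_month": np.where(dev60_day < BIG, (dev60_day - tz) // 30, BIG),
        "pp_exit_month": pp_exit_m, "pp_exit_reason": pp_exit_reason,
        "itt_exit_month": itt_exit_m, "itt_exit_reason": itt_exit_reason,
        "planted_gap": planted_gap,
    })
    for name in CONFOUNDER_NAMES:
        truth[name] = L[name]

    # =====================================================================
    # Claims tables
    # =====================================================================
    D = lambda arr: pd.to_datetime(np.asarray(arr, dtype="int64"), unit="D")

    patients = pd.DataFrame({
        "patient_id": pid, "birth_date": D(birth), "diagnosis_date": D(dx),
        "race_ethnicity": race, "marital_status": marital,
        "education_quartile": education, "poverty_quartile": poverty,
        "rurality": rurality,
    })

    # --- coverage: parts A, B, D from dx-500 to disenrollment/death/admin
    cov_end = np.minimum.reduce([np.full(n, admin_end), death_day, ltfu_day])
    cov_start = dx - 500
    gap_vio = violation == "coverage_gap"
    parts, starts, ends, cpids = [], [], [], []
    for part in ("A", "B", "D"):
        if part in ("A", "B"):
            # planted 59-day hole inside the 1-year lookback for violators
            s1 = np.where(gap_vio, cov_start, cov_start)
            e1 = np.where(gap_vio, dx - 260, cov_end)
            cpids.append(pid); parts.append(np.full(n, part, dtype=object))
            starts.append(s1); ends.append(e1)
            if gap_vio.any():
                cpids.append(pid[gap_vio])
                parts.append(np.full(gap_vio.sum(), part, dtype=object))
                starts.append(dx[gap_vio] - 200); ends.append(cov_end[gap_vio])
        else:
            cpids.append(pid); parts.append(np.full(n, part, dtype=object))
            starts.append(np.full(n, 0) + cov_start); ends.append(cov_end)
    coverage = pd.DataFrame({
        "patient_id": np.concatenate(cpids), "part": np.concatenate(parts),
        "start_date": D(np.concatenate(starts)),
        "end_date": D(np.maximum(np.concatenate(ends), np.concatenate(starts))),
    })

    # --- fills: metformin chains, prior-use violations, ADT hormonal ----
    fill_obs = fill_valid & (fill_days <= np.minimum(death_day, ltfu_day)[:, None])
    rows, cols = np.nonzero(fill_obs)
    met_pid, met_day = pid[rows], fill_days[rows, cols]
    pm = violation == "prior_metformin"
    adt_pid = pid[~orchiectomy]
    fills = pd.DataFrame({
        "patient_id": np.concatenate([met_pid, pid[pm], adt_pid]),
        "drug": np.concatenate([
            np.full(len(met_pid), "metformin", dtype=object),
            np.full(pm.sum(), "metformin", dtype=object),
            np.full(len(adt_pid), "adt_hormonal", dtype=object)]),
        "fill_date": D(np.concatenate([met_day, prior_fill_day[pm], adt_day[~orchiectomy]])),
        "days_supply": np.concatenate([
            np.full(len(met_pid), supply), np.full(pm.sum(), supply),
            np.full(len(adt_pid), 90)]).astype(np.int64),
    }).sort_values(["patient_id", "fill_date"], kind="stable").reset_index(drop=True)

    # --- events: baseline comorbidities, onsets, orchiectomy, PCP visits
    ub = substream(seed, "baseline_event_days").random((n, len(CONFOUNDER_NAMES) + 1))
    ev_pid, ev_code, ev_day = [], [], []
    for j, name in enumerate(CONFOUNDER_NAMES):
        m = L[name]
        ev_pid.append(pid[m]); ev_code.append(np.full(m.sum(), name, dtype=object))
        ev_day.append(dx[m] - 1 - np.floor(ub[m, j] * 364).astype(np.int64))
    con_vio = violation == "contraindication"
    ev_pid.append(pid[con_vio])
    ev_code.append(vio_con_code[con_vio])
    ev_day.append(dx[con_vio] - 1 - np.floor(ub[con_vio, -1] * 364).astype(np.int64))
    dia_new = (dia_onset_m >= 1) & (dia_onset_m < BIG) & (dia_onset_day <= alive_end)
    ev_pid.append(pid[dia_new])
    ev_code.append(np.full(dia_new.sum(), "diabetes", dtype=object))
    ev_day.append(dia_onset_day[dia_new])
    con_new = (con_onset_m < BIG) & (con_onset_day <= alive_end)
    ev_pid.append(pid[con_new]); ev_code.append(con_code[con_new])
    ev_day.append(con_onset_day[con_new])
    orch = orchiectomy & (violation != "no_adt")
    ev_pid.append(pid[orch])
    ev_code.append(np.full(orch.sum(), "orchiectomy", dtype=object))
    ev_day.append(adt_day[orch])
    # PCP visits: k visits spread over the pre-diagnosis year (toy spacing)
    reps = np.repeat(np.arange(n), pcp)
    within = np.concatenate([np.arange(k) for k in pcp]) if len(reps) else np.array([], dtype=np.int64)
    ev_pid.append(pid[reps])
    ev_code.append(np.full(len(reps), "pcp_visit", dtype=object))
    ev_day.append(dx[reps] - 1 - (within * 360 // np.maximum(pcp[reps], 1)))
    events = pd.DataFrame({
        "patient_id": np.concatenate(ev_pid),
        "event_code": np.concatenate(ev_code),
        "event_date": D(np.concatenate(ev_day)),
    }).sort_values(["patient_id", "event_date"], kind="stable").reset_index(drop=True)

    dead = death_day < BIG
    deaths = pd.DataFrame({
        "patient_id": pid[dead], "death_date": D(death_day[dead]),
        "cause": cause[dead],
    })

    ds = ClaimsDataset(patients=patients, coverage=coverage, fills=fills,
                       events=events, deaths=deaths, truth=truth)
    ds.validate()
    return ds


def simulate_fills(start_day: int, stop_day: int, supply_days: int = 30,
                   delays=0) -> np.ndarray:
    """Fill sequence for one treated episode.

    Fills begin at ``start_day``; each next fill follows the previous
    supply end by a delay (scalar or per-interval sequence).  No fill is
    issued on or after ``stop_day`` (the true discontinuation or exit day).
    """
    out = []
    day = int(start_day)
    k = 0
    while day < stop_day and k < 1000:
        out.append(day)
        d = delays[k] if np.ndim(delays) else delays
        day = day + supply_days + int(d)
        k += 1
    return np.asarray(out, dtype=np.int64)


def make_table2_fixture() -> dict:
    """Published baseline-characteristics tables of the eligible cohort.

    Contingency tables (rows = categories, columns = [non-initiators,
    initiators]) for the characteristics with no suppressed cells, plus the
    reported mean/SD summaries.  Column margins are 7252 and 109.
    """
    t = {
        "diabetes": np.array([[6483, 59], [769, 50]]),
        "charlson": np.array([[4433, 47], [1487, 33], [725, 13], [607, 16]]),
        "depression": np.array([[6690, 98], [562, 11]]),
        "hypertension": np.array([[2370, 31], [4882, 78]]),
        "allcause_mortality": np.array([[4200, 57], [3052, 52]]),
        "pca_mortality": np.array([[5333, 73], [1919, 36]]),
    }
    t["age_summary"] = {"noninit": (75.4, 6.8, 7252), "init": (74.3, 6.4, 109)}
    t["pcp_summary"] = {"noninit": (4.9, 5.5, 7252), "init": (5.0, 5.7, 109)}
    return t
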