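"""Seeded synthetic IPMN-surveillance cohort generator.

Emulates the statistical structure the analysis pipeline assumes: 6-monthly
surveillance visits with co-scheduled labs and imaging, per-patient marker
set-points with log-normal measurement noise, prediagnostic CA19-9 /
HbA1c / enzyme rises with configurable lead times, emergence of worrisome
features and high-risk stigmata with type-dependent probabilities, and
stage-dependent postdiagnosis survival.

Default parameters encode the published surveillance series of 100
carcinoma cases (50 IPMN-derived, 50 concomitant PDAC): the per-(type,
stage-stratum) CA19-9 aberrant-elevation probabilities, the 11% rate of
missing in-window CA19-9, HbA1c (3%) and enzyme (16%/20%) elevation rates,
high-risk-stigmata prevalence (86%/16%), the one-in-fifty feature-negative
concomitant case, and lead-time log-normals fitted to the printed
median/IQR anchors.

Every case carries ground-truth labels (intended pattern, elevation onset
days, feature emergence days) so the pipeline's recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date as Date, timedelta

import numpy as np
import pandas as pd

from .cohort import (DAYS_PER_YEAR, CarcinomaDiagnosis, ClinicalEvent,
                     FollowUpOutcome, ImagingAssessment, LabSeries,
                     PatientRecord)

DERIVED = "ipmn_derived"
CONCOMITANT = "concomitant_pdac"
_EARLY = ("0", "I", "II")


def _lognormal_from_median_iqr(median: float, q25: float, q75: float
                               ) -> tuple[float, float]:
    """(mu, sigma) of a log-normal matching the printed median and IQR width.

    mu is set from the median; sigma from the IQR ratio (the printed
    quartiles need not be log-symmetric around the median, so only the
    ratio is matched).
    """
    mu = math.log(median)
    sigma = (math.log(q75) - math.log(q25)) / (2 * 0.6744897501960817)
    return mu, sigma


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Probabilities and distribution anchors default to the published
    cohort's values; assay-level noise parameters (not published) are
    stated assumptions.
    """

    n_carcinoma_cases: int = 100
    derived_fraction: float = 0.5
    n_noncancer_patients: int = 100

    # surveillance schedule: 6-monthly visits with jitter
    visit_interval_days: float = 182.6
    visit_jitter_sd_days: float = 15.0

    # time from IPMN baseline to carcinoma diagnosis / end of follow-up
    followup_median_years: float = 5.7
    followup_log_sd: float = 0.9
    followup_min_years: float = 0.75
    followup_max_years: float = 25.6

    # clinical stage composition per carcinoma type (stages 0,I,II,III,IV)
    stage_probs: dict = field(default_factory=lambda: {
        DERIVED: (0.36, 0.20, 0.30, 0.10, 0.04),
        CONCOMITANT: (0.02, 0.16, 0.54, 0.12, 0.16)})

    # CA19-9 trajectory assignment
    p_aberrant: dict = field(default_factory=lambda: {
        (DERIVED, "early"): 0.23, (DERIVED, "late"): 0.71,
        (CONCOMITANT, "early"): 0.41, (CONCOMITANT, "late"): 1.00})
    #: fraction with no in-window CA19-9 (the table's n=11/100 exclusion)
    p_missing_ca19_9_window: float = 0.11
    #: P(high-to-high | neither aberrant nor missing), per type
    p_high_to_high_rest: dict = field(default_factory=lambda: {
        DERIVED: 10 / 33, CONCOMITANT: 2 / 17})
    #: fraction of aberrant cases that start from an already-elevated
    #: set-point (trigger = doubling of the cumulative average)
    p_aberrant_high_start: float = 0.2
    lewis_negative_fraction: float = 0.08

    p_hba1c_elevation: float = 0.03
    p_enzyme_elevation: dict = field(default_factory=lambda: {
        DERIVED: 0.16, CONCOMITANT: 0.20})
    p_acute_pancreatitis: dict = field(default_factory=lambda: {
        DERIVED: 0.04, CONCOMITANT: 0.06})

    # morphology
    p_hrs: dict = field(default_factory=lambda: {
        DERIVED: 0.86, CONCOMITANT: 0.16})
    p_any_wf_or_hrs: dict = field(default_factory=lambda: {
        DERIVED: 1.0, CONCOMITANT: 49 / 50})

    # lead-time log-normals (years), fitted to median [IQR]
    ca19_9_lead: dict = field(default_factory=lambda: {
        DERIVED: _lognormal_from_median_iqr(0.4, 0.1, 0.5),
        CONCOMITANT: _lognormal_from_median_iqr(0.1, 0.1, 0.7)})
    feature_lead: dict = field(default_factory=lambda: {
        DERIVED: _lognormal_from_median_iqr(1.6, 0.7, 3.7),
        CONCOMITANT: _lognormal_from_median_iqr(0.2, 0.1, 1.9)})
    #: lead of the rule-qualifying enzyme spike (must sit inside the
    #: 1-year window; the published multi-year "latency" figures describe
    #: first-ever elevation, not the qualifying spike)
    enzyme_lead: tuple = (math.log(0.4), 0.8)

    # marker noise model (assumptions; the study reports no assay CVs)
    ca19_9_cv: float = 0.20
    ca19_9_rise_cv: float = 0.08
    ca19_9_low_median: float = 8.0
    ca19_9_low_log_sd: float = 0.40
    ca19_9_low_cap: float = 18.0
    ca19_9_high_median: float = 75.0
    ca19_9_high_log_sd: float = 0.25
    ca19_9_high_floor: float = 55.0
    ca19_9_detection_limit: float = 2.0
    hba1c_mean_pct: float = 6.0
    hba1c_between_sd_pct: float = 0.30
    hba1c_within_sd_pct: float = 0.08
    hba1c_rise_pct: float = 0.60
    enzyme_cv: float = 0.20
    p_amylase_setpoint_median: float = 28.0
    lipase_setpoint_median: float = 42.0
    enzyme_setpoint_log_sd: float = 0.35

    # postdiagnosis overall survival (exponential, stage-ordered medians, y)
    survival_median_years: dict = field(default_factory=lambda: {
        "0": 12.0, "I": 8.0, "II": 3.0, "III": 1.3, "IV": 0.6})
    postdx_censor_range_years: tuple = (0.5, 6.0)

    seed: int | None = None

    def __post_init__(self) -> None:
        for d in (self.p_aberrant, self.p_high_to_high_rest, self.p_hrs,
                  self.p_any_wf_or_hrs, self.p_enzyme_elevation,
                  self.p_acute_pancreatitis):
            for v in d.values():
                if not 0 <= v <= 1:
                    raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.p_missing_ca19_9_window <= 1:
            raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# low-level draws
# ---------------------------------------------------------------------------

def _trunc_lognormal(rng, mu: float, sigma: float, lo: float, hi: float,
                     max_tries: int = 200) -> float:
    if hi <= lo:
        return lo
    for _ in range(max_tries):
        x = float(rng.lognormal(mu, sigma))
        if lo <= x <= hi:
            return x
    return float(np.clip(math.exp(mu), lo, hi))


def _visit_days(rng, end_day: int, cfg: GeneratorConfig) -> list[int]:
    """Jittered 6-monthly visit grid from baseline, with a final diagnostic
    visit at ``end_day``."""
    days = [0]
    t = 0.0
    while True:
        t += max(60.0, rng.normal(cfg.visit_interval_days,
                                  cfg.visit_jitter_sd_days))
        if t >= end_day - 45:
            break
        days.append(int(round(t)))
    if days[-1] != end_day:
        days.append(int(end_day))
    return days


def _noisy(rng, setpoint: float, n: int, cv: float) -> np.ndarray:
    return setpoint * rng.lognormal(0.0, cv, size=n)


@dataclass
class _CaseTruth:
    patient_id: str
    is_carcinoma: bool
    carcinoma_type: str | None = None
    clinical_stage: str | None = None
    dx_day: float | None = None
    intended_pattern: str | None = None
    lewis_negative: bool = False
    ca_onset_day: float | None = None
    ca_high_start: bool = False
    hba1c_elevated: bool = False
    enzyme_elevated: bool = False
    enzyme_analyte: str | None = None
    enzyme_onset_day: float | None = None
    hrs_positive: bool = False
    any_wf_or_hrs: bool = False
    intended_first_wf_day: float | None = None
    intended_first_hrs_day: float | None = None


# ---------------------------------------------------------------------------
# per-patient simulation pieces
# ---------------------------------------------------------------------------

def simulate_marker_series(rng, lab_days: np.ndarray, setpoint: float,
                           onset_day: float | None, dx_day: float | None,
                           cfg: GeneratorConfig, start_value: float | None = None,
                           rise_factor: float = 5.0) -> np.ndarray:
    """CA19-9-style series: log-normal noise around a set-point, with a
    multiplicative exponential rise from ``onset_day`` to ``dx_day``
    starting at ``start_value`` (calibrated so the classification rule
    triggers at the onset measurement)."""
    vals = _noisy(rng, setpoint, len(lab_days), cfg.ca19_9_cv)
    if onset_day is not None:
        assert dx_day is not None and start_value is not None
        span = max(dx_day - onset_day, 1.0)
        rising = lab_days >= onset_day
        frac = (lab_days[rising] - onset_day) / span
        vals[rising] = (start_value * rise_factor ** frac
                        * rng.lognormal(0.0, cfg.ca19_9_rise_cv,
                                        size=int(rising.sum())))
    return vals


def _simulate_ca19_9(rng, visit_days: list[int], truth: _CaseTruth,
                     cfg: GeneratorConfig) -> LabSeries:
    pattern = truth.intended_pattern
    dx = truth.dx_day
    if truth.lewis_negative:
        days = np.asarray(visit_days, dtype=float)
        vals = cfg.ca19_9_detection_limit * rng.uniform(0.3, 1.0, len(days))
        return LabSeries("ca19_9", "U/mL", days, np.round(vals, 1),
                         detection_limit=cfg.ca19_9_detection_limit)

    low_sp = min(float(rng.lognormal(math.log(cfg.ca19_9_low_median),
                                     cfg.ca19_9_low_log_sd)), cfg.ca19_9_low_cap)
    high_sp = max(float(rng.lognormal(math.log(cfg.ca19_9_high_median),
                                      cfg.ca19_9_high_log_sd)),
                  cfg.ca19_9_high_floor)

    days = [float(d) for d in visit_days]
    onset, start, sp = None, None, low_sp
    if pattern == "insufficient_data":
        days = [d for d in days if d <= dx - 380]
    elif pattern == "high_to_high":
        sp = high_sp
    elif pattern == "aberrant_elevation":
        # an already-elevated start needs prior out-of-window history,
        # otherwise the first in-window documentation trivially qualifies
        high_start = (rng.random() < cfg.p_aberrant_high_start
                      and dx > 1.5 * DAYS_PER_YEAR)
        truth.ca_high_start = high_start
        mu, sigma = cfg.ca19_9_lead[truth.carcinoma_type]
        lead_y = _trunc_lognormal(rng, mu, sigma, 7 / DAYS_PER_YEAR,
                                  min(0.95, 0.8 * dx / DAYS_PER_YEAR))
        onset = float(int(dx - lead_y * DAYS_PER_YEAR))
        if onset not in days:
            days = sorted(days + [onset])
        if high_start:
            sp, start = high_sp, 2.5 * high_sp
        else:
            sp, start = low_sp, max(1.5 * 37.0, 2.2 * low_sp)
        truth.ca_onset_day = onset
    days_arr = np.asarray(days, dtype=float)
    vals = simulate_marker_series(rng, days_arr, sp, onset, dx, cfg,
                                  start_value=start)
    return LabSeries("ca19_9", "U/mL", days_arr, np.round(vals, 1),
                     detection_limit=cfg.ca19_9_detection_limit)


def _simulate_hba1c(rng, visit_days: list[int], truth: _CaseTruth,
                    cfg: GeneratorConfig) -> LabSeries:
    days = np.asarray(visit_days, dtype=float)
    sp = float(np.clip(rng.normal(cfg.hba1c_mean_pct, cfg.hba1c_between_sd_pct),
                       5.2, 7.5))
    vals = sp + rng.normal(0.0, cfg.hba1c_within_sd_pct, len(days))
    if truth.hba1c_elevated:
        onset = truth.dx_day - rng.uniform(30, 300)
        vals[days >= onset] += cfg.hba1c_rise_pct
    return LabSeries("hba1c", "%", days, np.round(vals, 1))


def _simulate_enzymes(rng, visit_days: list[int], truth: _CaseTruth,
                      cfg: GeneratorConfig) -> list[LabSeries]:
    ulns = {"p_amylase": 50.0, "lipase": 60.0}
    medians = {"p_amylase": cfg.p_amylase_setpoint_median,
               "lipase": cfg.lipase_setpoint_median}
    caps = {"p_amylase": 75.0, "lipase": 90.0}
    series = []
    for analyte in ("amylase", "p_amylase", "lipase"):
        if analyte == "amylase":
            sp = float(rng.lognormal(math.log(80.0), cfg.enzyme_setpoint_log_sd))
            days = np.asarray(visit_days, dtype=float)
            vals = _noisy(rng, sp, len(days), cfg.enzyme_cv)
            series.append(LabSeries(analyte, "U/L", days, np.round(vals, 0)))
            continue
        sp = min(float(rng.lognormal(math.log(medians[analyte]),
                                     cfg.enzyme_setpoint_log_sd)), caps[analyte])
        days = [float(d) for d in visit_days]
        spike_day = None
        if truth.enzyme_elevated and truth.enzyme_analyte == analyte:
            mu, sigma = cfg.enzyme_lead
            lead_y = _trunc_lognormal(rng, mu, sigma, 7 / DAYS_PER_YEAR,
                                      min(0.9, 0.8 * truth.dx_day / DAYS_PER_YEAR))
            spike_day = float(int(truth.dx_day - lead_y * DAYS_PER_YEAR))
            if spike_day not in days:
                days = sorted(days + [spike_day])
            truth.enzyme_onset_day = spike_day
        days_arr = np.asarray(days, dtype=float)
        vals = _noisy(rng, sp, len(days_arr), cfg.enzyme_cv)
        if spike_day is not None:
            # transient pancreatitis-like spike: > 3x ULN and > 2x cumavg
            peak = 3.0 * ulns[analyte] * rng.uniform(1.4, 1.9)
            vals[days_arr == spike_day] = peak
        series.append(LabSeries(analyte, "U/L", days_arr, np.round(vals, 0)))
    return series


def simulate_morphology_timeline(rng, visit_days: list[int], truth: _CaseTruth,
                                 location: str | None, cfg: GeneratorConfig
                                 ) -> tuple[list[ImagingAssessment],
                                            list[ClinicalEvent]]:
    """Imaging assessments and clinical events for one case.

    Derived-type cases progress through MPD dilatation (worrisome feature)
    toward high-risk stigmata; concomitant cases become feature-positive
    close to diagnosis, mostly via CA19-9 or late morphological findings.
    Emergence days are snapped to the visit grid and recorded in ``truth``.
    """
    ctype = truth.carcinoma_type
    dx = truth.dx_day
    base_size = float(np.clip(rng.lognormal(math.log(18.0), 0.35), 6.0, 27.5))
    base_mpd = float(rng.uniform(1.5, 4.5))

    wf_day = hrs_day = None
    hrs_item = None
    wf_item = None
    if truth.is_carcinoma and (truth.hrs_positive or truth.any_wf_or_hrs):
        mu, sigma = cfg.feature_lead[ctype]
        lead_y = _trunc_lognormal(rng, mu, sigma, 30 / DAYS_PER_YEAR,
                                  0.95 * dx / DAYS_PER_YEAR)
        emerge = dx - lead_y * DAYS_PER_YEAR
        v_emerge = float(min(d for d in visit_days if d >= emerge))
        if ctype == DERIVED:
            wf_day, wf_item = v_emerge, "mpd_dilated"
            if truth.hrs_positive:
                target = dx - lead_y * DAYS_PER_YEAR * rng.uniform(0.1, 0.7)
                later = [d for d in visit_days
                         if d > v_emerge and d >= target]
                if not later:
                    later = [d for d in visit_days if d > v_emerge]
                hrs_day = float(min(later)) if later else v_emerge
        else:
            if truth.hrs_positive:
                hrs_day = v_emerge
            else:
                wf_day = v_emerge
                wf_item = str(rng.choice(["lymphadenopathy",
                                          "abrupt_caliber_change",
                                          "thickened_wall"]))
        if truth.hrs_positive:
            choices, probs = (["mpd", "nodule", "jaundice"],
                              [0.6, 0.35, 0.05] if ctype == DERIVED
                              else [0.5, 0.3, 0.2])
            hrs_item = str(rng.choice(choices, p=probs))
            if hrs_item == "jaundice" and location != "head":
                hrs_item = "mpd"
            if hrs_item == "mpd" and wf_day is not None and hrs_day is not None \
                    and hrs_day <= wf_day:
                # duct jumps straight past 10 mm: no 5-9.9 mm stage exists
                wf_day, wf_item = None, None

    mpd_wf_level = float(rng.uniform(6.0, 9.0))
    mpd_hrs_level = float(rng.uniform(10.5, 14.0))

    assessments = []
    for i, d in enumerate(visit_days):
        mpd = base_mpd
        nodule = "absent"
        thick = caliber = lymph = False
        if wf_day is not None and d >= wf_day:
            if wf_item == "mpd_dilated":
                mpd = mpd_wf_level
            elif wf_item == "lymphadenopathy":
                lymph = True
            elif wf_item == "abrupt_caliber_change":
                caliber = True
            elif wf_item == "thickened_wall":
                thick = True
        if hrs_day is not None and d >= hrs_day:
            if hrs_item == "mpd":
                mpd = mpd_hrs_level
            elif hrs_item == "nodule":
                nodule = "present_ge5mm_enhancing"
        size = base_size + float(rng.normal(0.0, 0.5))
        if mpd == base_mpd:
            mpd_obs = float(np.clip(mpd + rng.normal(0.0, 0.15), 0.5, 4.9))
        elif mpd == mpd_wf_level:
            mpd_obs = float(np.clip(mpd + rng.normal(0.0, 0.2), 5.05, 9.8))
        else:
            mpd_obs = float(max(mpd + rng.normal(0.0, 0.3), 10.05))
        is_dx_visit = truth.is_carcinoma and d == visit_days[-1]
        assessments.append(ImagingAssessment(
            day=float(d),
            modality="CT" if is_dx_visit else "MRI_MRCP",
            cyst_size_mm=round(max(size, 2.0), 1),
            mpd_diameter_mm=round(mpd_obs, 1),
            mural_nodule=nodule,
            thickened_enhanced_wall=thick,
            abrupt_caliber_change_with_atrophy=caliber,
            lymphadenopathy=lymph,
            solid_mass_detected=bool(is_dx_visit and ctype == CONCOMITANT)))

    events = []
    if hrs_item == "jaundice" and hrs_day is not None:
        events.append(ClinicalEvent(day=float(hrs_day), kind="obstructive_jaundice"))
    if truth.is_carcinoma and truth.any_wf_or_hrs and \
            rng.random() < cfg.p_acute_pancreatitis[ctype]:
        ap_day = float(int(rng.uniform(0.3, 0.9) * dx))
        events.append(ClinicalEvent(day=ap_day, kind="acute_pancreatitis"))
        ap_visit = [d for d in visit_days if d >= ap_day]
        if ap_visit:
            wf_day = ap_visit[0] if wf_day is None else min(wf_day, float(ap_visit[0]))

    truth.intended_first_wf_day = wf_day
    truth.intended_first_hrs_day = hrs_day
    return assessments, events


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _draw_demographics(rng) -> dict:
    return {
        "age_at_baseline": float(np.clip(rng.normal(70.9, 8.0), 43, 88)),
        "sex": "male" if rng.random() < 0.58 else "female",
        "ipmn_type": str(rng.choice(["branch_duct", "main_duct", "mixed"],
                                    p=[0.80, 0.06, 0.14])),
        "smoking": "past_current" if rng.random() < 0.53 else "never",
        "bmi": float(np.clip(rng.normal(21.9, 3.3), 14, 35)),
        "diabetes": str(rng.choice(
            ["absent", "recent_onset_lt2y", "unknown_onset",
             "long_standing_ge2y"], p=[0.51, 0.09, 0.03, 0.37])),
        "family_history_pc": bool(rng.random() < 0.07),
    }


def generate_cohort(cfg: GeneratorConfig
                    ) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate the cohort; returns ``(records, truth)``.

    Reproducible given ``cfg.seed`` (mandatory).  Carcinoma cases come
    first (derived then concomitant), followed by non-cancer surveillance
    patients.
    """
    if cfg.seed is None:
        raise ValueError("GeneratorConfig.seed is mandatory")
    rng = np.random.default_rng(cfg.seed)

    n_ca = cfg.n_carcinoma_cases
    n_derived = int(round(n_ca * cfg.derived_fraction))
    types = [DERIVED] * n_derived + [CONCOMITANT] * (n_ca - n_derived)

    # pass 1: discrete case labels
    truths: list[_CaseTruth] = []
    for i, ctype in enumerate(types):
        t = _CaseTruth(patient_id=f"P{i + 1:04d}", is_carcinoma=True,
                       carcinoma_type=ctype)
        t.clinical_stage = str(np.asarray(["0", "I", "II", "III", "IV"])[
            rng.choice(5, p=cfg.stage_probs[ctype])])
        stratum = "early" if t.clinical_stage in _EARLY else "late"
        missing = rng.random() < cfg.p_missing_ca19_9_window
        if missing:
            t.intended_pattern = "insufficient_data"
        elif rng.random() < cfg.p_aberrant[(ctype, stratum)]:
            t.intended_pattern = "aberrant_elevation"
        elif rng.random() < cfg.p_high_to_high_rest[ctype]:
            t.intended_pattern = "high_to_high"
        else:
            t.intended_pattern = "low_to_low"
        t.hba1c_elevated = rng.random() < cfg.p_hba1c_elevation
        if rng.random() < cfg.p_enzyme_elevation[ctype]:
            t.enzyme_elevated = True
            t.enzyme_analyte = "p_amylase" if rng.random() < 0.5 else "lipase"
        # HRS drawn marginally; feature-negativity among the non-HRS rest
        t.hrs_positive = rng.random() < cfg.p_hrs[ctype]
        if t.hrs_positive:
            t.any_wf_or_hrs = True
        else:
            p_rest = 1.0 - (1.0 - cfg.p_any_wf_or_hrs[ctype]) / \
                max(1.0 - cfg.p_hrs[ctype], 1e-12)
            t.any_wf_or_hrs = rng.random() < p_rest
        if not t.any_wf_or_hrs and t.intended_pattern in (
                "aberrant_elevation", "high_to_high"):
            # an elevated CA19-9 is itself a worrisome feature; the rare
            # all-negative case must therefore stay within normal limits
            t.intended_pattern = "low_to_low"
        truths.append(t)

    # Lewis-negative flags only among intended low-to-low cases (a Lewis
    # antigen-negative patient cannot mount CA19-9 elevation)
    low_idx = [i for i, t in enumerate(truths)
               if t.intended_pattern == "low_to_low"]
    if low_idx:
        p_lewis = min(1.0, cfg.lewis_negative_fraction * n_ca / len(low_idx))
        for i in low_idx:
            truths[i].lewis_negative = rng.random() < p_lewis

    records: list[PatientRecord] = []
    epoch = Date(2000, 1, 1)
    for t in truths:
        demo = _draw_demographics(rng)
        baseline = epoch + timedelta(days=int(rng.integers(0, 4000)))
        dx_years = _trunc_lognormal(rng, math.log(cfg.followup_median_years),
                                    cfg.followup_log_sd,
                                    cfg.followup_min_years,
                                    cfg.followup_max_years)
        dx_day = int(round(dx_years * DAYS_PER_YEAR))
        t.dx_day = float(dx_day)
        visits = _visit_days(rng, dx_day, cfg)

        location = ("head" if rng.random() <
                    (0.54 if t.carcinoma_type == DERIVED else 0.48)
                    else "body_tail")
        labs = [_simulate_ca19_9(rng, visits, t, cfg),
                _simulate_hba1c(rng, visits, t, cfg)]
        labs.extend(_simulate_enzymes(rng, visits, t, cfg))
        imaging, events = simulate_morphology_timeline(rng, visits, t,
                                                       location, cfg)
        # an elevated CA19-9 is itself a worrisome feature: fold the first
        # visit documenting it into the intended first-WF time
        ca_wf_day = None
        if t.intended_pattern == "aberrant_elevation" and t.ca_onset_day is not None:
            if t.ca_high_start:
                # already above the limit at baseline: the CA19-9 worrisome
                # feature is documented from the first visit
                ca_wf_day = float(visits[0])
            else:
                later = [d for d in visits if d >= t.ca_onset_day]
                if later:
                    ca_wf_day = float(later[0])
        elif t.intended_pattern == "high_to_high":
            ca_wf_day = float(visits[0])
        if ca_wf_day is not None:
            t.intended_first_wf_day = (
                ca_wf_day if t.intended_first_wf_day is None
                else min(t.intended_first_wf_day, ca_wf_day))
        # postdiagnosis overall survival: exponential with stage-ordered
        # medians, administratively censored
        med = cfg.survival_median_years[t.clinical_stage]
        death_y = float(rng.exponential(med / math.log(2.0)))
        censor_y = float(rng.uniform(*cfg.postdx_censor_range_years))
        if death_y <= censor_y:
            status, surv_y = "dead", death_y
        else:
            status, surv_y = "alive_censored", censor_y
        last_day = dx_day + max(int(round(surv_y * DAYS_PER_YEAR)), 1)

        path_stage = t.clinical_stage if rng.random() < 0.68 else None
        records.append(PatientRecord(
            patient_id=t.patient_id, baseline_date=baseline,
            labs=labs, imaging=imaging, events=events,
            diagnosis=CarcinomaDiagnosis(
                day=float(dx_day), carcinoma_type=t.carcinoma_type,
                clinical_stage=t.clinical_stage,
                pathological_stage=path_stage, location=location),
            outcome=FollowUpOutcome(last_day=float(last_day), status=status),
            **demo))

    # non-cancer surveillance patients
    for j in range(cfg.n_noncancer_patients):
        t = _CaseTruth(patient_id=f"N{j + 1:04d}", is_carcinoma=False)
        truths.append(t)
        demo = _draw_demographics(rng)
        baseline = epoch + timedelta(days=int(rng.integers(0, 4000)))
        fu_years = _trunc_lognormal(rng, math.log(cfg.followup_median_years),
                                    cfg.followup_log_sd, 0.6,
                                    cfg.followup_max_years)
        end_day = int(round(fu_years * DAYS_PER_YEAR))
        visits = _visit_days(rng, end_day, cfg)
        t.lewis_negative = rng.random() < cfg.lewis_negative_fraction
        t.intended_pattern = None
        labs = [_simulate_ca19_9(rng, visits, _CaseTruth(
                    patient_id=t.patient_id, is_carcinoma=False,
                    lewis_negative=t.lewis_negative,
                    intended_pattern="low_to_low"), cfg),
                _simulate_hba1c(rng, visits, t, cfg)]
        labs.extend(_simulate_enzymes(rng, visits, t, cfg))
        imaging, _ = simulate_morphology_timeline(rng, visits, t, None, cfg)
        records.append(PatientRecord(
            patient_id=t.patient_id, baseline_date=baseline,
            labs=labs, imaging=imaging, events=[],
            diagnosis=None,
            outcome=FollowUpOutcome(last_day=float(end_day),
                                    status="alive_censored"),
            **demo))

    truth = pd.DataFrame([asdict(t) for t in truths])
    return records, truth
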