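"""Worrisome-feature / high-risk-stigmata rules engine.

Evaluates, at each imaging visit, the 2017 international consensus
guideline's tiers for IPMNs:

High-risk stigmata (HRS)
    (1) obstructive jaundice with a head lesion, (2) an enhancing mural
    nodule >= 5 mm, (3) main pancreatic duct (MPD) diameter >= 10 mm.

Worrisome features (WF)
    (1) cyst size >= 30 mm, (2) enhancing mural nodule < 5 mm,
    (3) thickened enhanced wall, (4) MPD 5-9.9 mm, (5) abrupt caliber
    change of the MPD with distal atrophy, (6) lymphadenopathy,
    (7) serum CA19-9 > 37 U/mL, (8) growth rate > 5 mm / 2 years,
    (9) acute pancreatitis.

Feature sets at a visit depend only on data dated on or before that visit
(no look-ahead).  First-occurrence times and lead times to diagnosis are
derived per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import DAYS_PER_YEAR, ImagingAssessment, PatientRecord
from .markers import MarkerRuleConfig

WF_ITEMS = ("size_ge_30mm", "nodule_lt5mm_enhancing", "thickened_wall",
            "mpd_5_to_9_9mm", "abrupt_caliber_change_atrophy",
            "lymphadenopathy", "ca19_9_gt_37", "growth_gt_5mm_per_2y",
            "acute_pancreatitis")
HRS_ITEMS = ("obstructive_jaundice_head_lesion", "enhancing_nodule_ge_5mm",
             "mpd_ge_10mm")

GROWTH_WINDOW_DAYS = 2 * DAYS_PER_YEAR  # 730.5
GROWTH_THRESHOLD_MM = 5.0


@dataclass
class FeatureTimeline:
    """Per-visit WF/HRS sets plus first-occurrence and lead times."""

    patient_id: str
    visit_days: list[float] = field(default_factory=list)
    wf_sets: list[frozenset[str]] = field(default_factory=list)
    hrs_sets: list[frozenset[str]] = field(default_factory=list)
    t_first_wf_day: float | None = None
    t_first_hrs_day: float | None = None
    wf_lead_years: float | None = None
    hrs_lead_years: float | None = None


def _visit_imaging(record: PatientRecord, visit_day: float) -> ImagingAssessment:
    for a in record.imaging:
        if a.day == visit_day:
            return a
    raise ValueError(f"no imaging assessment on day {visit_day} "
                     f"for patient {record.patient_id}")


def _lesion_location(record: PatientRecord) -> str | None:
    # diagnosis location when available; the record keeps no separate
    # per-lesion bookkeeping (dominant-lesion model)
    if record.diagnosis is not None:
        return record.diagnosis.location
    return None


def growth_exceeds_threshold(size_pairs, visit_day: float) -> bool:
    """Growth rate > 5 mm / 2 years.

    True iff the size at ``visit_day`` exceeds by more than 5 mm any size
    measured within the trailing 2-year window (comparison against each
    in-window measurement, not a fitted slope).
    """
    days = np.asarray([d for d, _ in size_pairs], dtype=float)
    sizes = np.asarray([s for _, s in size_pairs], dtype=float)
    at = days == visit_day
    if not at.any():
        return False
    current = sizes[at][-1]
    mask = (days < visit_day) & (days >= visit_day - GROWTH_WINDOW_DAYS)
    if not mask.any():
        return False
    return bool(np.any(current - sizes[mask] > GROWTH_THRESHOLD_MM))


def _size_series(record: PatientRecord):
    return [(a.day, a.cyst_size_mm) for a in record.imaging
            if a.cyst_size_mm is not None]


def eval_worrisome_features(record: PatientRecord, visit_day: float,
                            cfg: MarkerRuleConfig | None = None
                            ) -> frozenset[str]:
    """WF set at one imaging visit.

    Imaging items come from the assessment dated ``visit_day``; the CA19-9
    item uses the most recent value on or before the visit; event items
    (acute pancreatitis) accumulate from any earlier occurrence.
    """
    cfg = cfg or MarkerRuleConfig()
    a = _visit_imaging(record, visit_day)
    items = set()
    if a.cyst_size_mm is not None and a.cyst_size_mm >= 30:
        items.add("size_ge_30mm")
    if a.mural_nodule == "present_lt5mm_enhancing":
        items.add("nodule_lt5mm_enhancing")
    if a.thickened_enhanced_wall:
        items.add("thickened_wall")
    if a.mpd_diameter_mm is not None and 5 <= a.mpd_diameter_mm < 10:
        items.add("mpd_5_to_9_9mm")
    if a.abrupt_caliber_change_with_atrophy:
        items.add("abrupt_caliber_change_atrophy")
    if a.lymphadenopathy:
        items.add("lymphadenopathy")
    ca = record.lab("ca19_9")
    if ca is not None and len(ca):
        mask = ca.days <= visit_day
        if mask.any() and ca.values[mask][-1] > cfg.ca19_9_uln:
            items.add("ca19_9_gt_37")
    if growth_exceeds_threshold(_size_series(record), visit_day):
        items.add("growth_gt_5mm_per_2y")
    if any(e.kind == "acute_pancreatitis" and e.day <= visit_day
           for e in record.events):
        items.add("acute_pancreatitis")
    return frozenset(items)


def eval_high_risk_stigmata(record: PatientRecord, visit_day: float
                            ) -> frozenset[str]:
    """HRS set at one imaging visit.

    The jaundice item is a conjunction: an obstructive-jaundice event on or
    before the visit AND a head lesion.  Non-enhancing nodules trigger
    neither nodule item.
    """
    a = _visit_imaging(record, visit_day)
    items = set()
    jaundice = any(e.kind == "obstructive_jaundice" and e.day <= visit_day
                   for e in record.events)
    if jaundice and _lesion_location(record) == "head":
        items.add("obstructive_jaundice_head_lesion")
    if a.mural_nodule == "present_ge5mm_enhancing":
        items.add("enhancing_nodule_ge_5mm")
    if a.mpd_diameter_mm is not None and a.mpd_diameter_mm >= 10:
        items.add("mpd_ge_10mm")
    return frozenset(items)


def first_feature_times(record: PatientRecord,
                        cfg: MarkerRuleConfig | None = None) -> FeatureTimeline:
    """Evaluate every prediagnostic visit and record first-occurrence times.

    Visits after the carcinoma diagnosis date are not evaluated (the rules
    describe the *prediagnostic* timeline).  Lead times are years from the
    first documentation to diagnosis; absent when the patient never shows a
    feature or has no diagnosis.
    """
    cfg = cfg or MarkerRuleConfig()
    dx_day = record.diagnosis.day if record.diagnosis is not None else None
    tl = FeatureTimeline(patient_id=record.patient_id)
    for a in record.imaging:
        if dx_day is not None and a.day > dx_day:
            continue
        wf = eval_worrisome_features(record, a.day, cfg)
        hrs = eval_high_risk_stigmata(record, a.day)
        tl.visit_days.append(a.day)
        tl.wf_sets.append(wf)
        tl.hrs_sets.append(hrs)
        if wf and tl.t_first_wf_day is None:
            tl.t_first_wf_day = a.day
        if hrs and tl.t_first_hrs_day is None:
            tl.t_first_hrs_day = a.day
    if dx_day is not None:
        if tl.t_first_wf_day is not None:
            tl.wf_lead_years = (dx_day - tl.t_first_wf_day) / DAYS_PER_YEAR
        if tl.t_first_hrs_day is not None:
            tl.hrs_lead_years = (dx_day - tl.t_first_hrs_day) / DAYS_PER_YEAR
    return tl


def features_cohort(records: list[PatientRecord],
                    cfg: MarkerRuleConfig | None = None):
    """Run the rules engine over a cohort.

    Returns ``(features, firsts)`` DataFrames: the per-visit feature sets
    (semicolon-joined) and the per-patient first-occurrence / lead-time
    summary.
    """
    import pandas as pd

    cfg = cfg or MarkerRuleConfig()
    frows, srows = [], []
    for r in records:
        tl = first_feature_times(r, cfg)
        for day, wf, hrs in zip(tl.visit_days, tl.wf_sets, tl.hrs_sets):
            frows.append({
                "patient_id": r.patient_id,
                "visit_day": day,
                "wf_items": ";".join(sorted(wf)),
                "hrs_items": ";".join(sorted(hrs))})
        srows.append({
            "patient_id": r.patient_id,
            "t_first_wf_years": (None if tl.t_first_wf_day is None
                                 else tl.t_first_wf_day / DAYS_PER_YEAR),
            "t_first_hrs_years": (None if tl.t_first_hrs_day is None
                                  else tl.t_first_hrs_day / DAYS_PER_YEAR),
            "wf_lead_years": tl.wf_lead_years,
            "hrs_lead_years": tl.hrs_lead_years,
            "any_wf": tl.t_first_wf_day is not None,
            "any_hrs": tl.t_first_hrs_day is not None})
    features = pd.DataFrame(frows, columns=["patient_id", "visit_day",
                                            "wf_items", "hrs_items"])
    firsts = pd.DataFrame(srows, columns=["patient_id", "t_first_wf_years",
                                          "t_first_hrs_years", "wf_lead_years",
                                          "hrs_lead_years", "any_wf", "any_hrs"])
    return features, firsts
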