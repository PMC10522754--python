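"""Domain types and tidy-table I/O for IPMN surveillance cohorts.

A cohort is interchanged as four tidy CSV tables (patients, labs, imaging,
events).  In memory, each patient is a :class:`PatientRecord` whose
time-stamped entries carry *days since baseline* as floats; calendar dates
appear only at the file boundary (ISO-8601).  Years reported downstream are
``days / 365.25``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25
#: minimum follow-up for study eligibility (6 months)
MIN_FOLLOWUP_DAYS = DAYS_PER_YEAR / 2.0

ANALYTES = ("ca19_9", "cea", "hba1c", "amylase", "p_amylase", "lipase")
MODALITIES = ("MRI_MRCP", "CT", "AUS", "EUS")
EVENT_KINDS = ("acute_pancreatitis", "obstructive_jaundice", "diabetes_onset",
               "symptom_onset")
SEXES = ("male", "female")
IPMN_TYPES = ("branch_duct", "main_duct", "mixed")
SMOKING = ("never", "past_current")
DIABETES = ("absent", "recent_onset_lt2y", "unknown_onset", "long_standing_ge2y")
CARCINOMA_TYPES = ("ipmn_derived", "concomitant_pdac")
STAGES = ("0", "I", "II", "III", "IV")
LOCATIONS = ("head", "body_tail")
MURAL_NODULE = ("absent", "present_lt5mm_enhancing", "present_ge5mm_enhancing",
                "present_nonenhancing")
OUTCOME_STATUS = ("dead", "alive_censored")


class CohortFormatError(ValueError):
    """Raised when an interchange table violates the documented dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LabSeries:
    """Irregularly sampled series of one analyte for one patient.

    ``days`` are days since the patient's baseline, strictly increasing;
    values are non-negative and share one unit.  ``detection_limit`` (same
    unit) is the assay floor, used by the Lewis-antigen-negative flag.
    """

    analyte: str
    unit: str
    days: np.ndarray
    values: np.ndarray
    detection_limit: float | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.shape != self.values.shape:
            raise ValueError("days and values must have equal length")

    def __len__(self) -> int:
        return len(self.days)


@dataclass
class ImagingAssessment:
    day: float
    modality: str
    cyst_size_mm: float | None = None
    mpd_diameter_mm: float | None = None
    mural_nodule: str = "absent"
    thickened_enhanced_wall: bool = False
    abrupt_caliber_change_with_atrophy: bool = False
    lymphadenopathy: bool = False
    solid_mass_detected: bool = False


@dataclass
class ClinicalEvent:
    day: float
    kind: str


@dataclass
class CarcinomaDiagnosis:
    day: float
    carcinoma_type: str
    clinical_stage: str
    pathological_stage: str | None = None
    location: str | None = None


@dataclass
class FollowUpOutcome:
    last_day: float
    status: str


@dataclass
class PatientRecord:
    """One surveilled patient: baseline descriptors plus dated entries."""

    patient_id: str
    baseline_date: Date
    age_at_baseline: float
    sex: str
    ipmn_type: str
    smoking: str
    bmi: float
    diabetes: str
    family_history_pc: bool
    labs: list[LabSeries] = field(default_factory=list)
    imaging: list[ImagingAssessment] = field(default_factory=list)
    events: list[ClinicalEvent] = field(default_factory=list)
    diagnosis: CarcinomaDiagnosis | None = None
    outcome: FollowUpOutcome | None = None

    def lab(self, analyte: str) -> LabSeries | None:
        """Return this patient's series for ``analyte``, or None."""
        for s in self.labs:
            if s.analyte == analyte:
                return s
        return None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_BOOL_TRUE = {"true", "1", "yes"}
_BOOL_FALSE = {"false", "0", "no"}


def _parse_bool(v, table: str, row: int) -> bool:
    s = str(v).strip().lower()
    if s in _BOOL_TRUE:
        return True
    if s in _BOOL_FALSE:
        return False
    raise CohortFormatError(f"{table} row {row}: invalid boolean {v!r}")


def _parse_date(v, table: str, row: int) -> Date:
    try:
        return Date.fromisoformat(str(v).strip())
    except ValueError as exc:
        raise CohortFormatError(f"{table} row {row}: invalid date {v!r}") from exc


def _check_code(v, allowed: Sequence[str], table: str, row: int, col: str) -> str:
    s = str(v).strip()
    if s not in allowed:
        raise CohortFormatError(
            f"{table} row {row}: unknown {col} code {v!r} (allowed: {allowed})")
    return s


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == ""


def _read_table(src) -> pd.DataFrame:
    if isinstance(src, pd.DataFrame):
        return src.copy()
    return pd.read_csv(src, dtype=str, keep_default_na=False)


def read_cohort(patient_table, lab_table, imaging_table, event_table) -> list[PatientRecord]:
    """Assemble :class:`PatientRecord` objects from the four tidy tables.

    Each argument is a CSV path or a DataFrame.  Within-patient entries are
    returned date-sorted.  Unknown category codes and duplicate
    (patient, date, analyte) lab rows are rejected with the offending row
    number (1-based, excluding the header).
    """
    patients = _read_table(patient_table)
    labs = _read_table(lab_table)
    imaging = _read_table(imaging_table)
    events = _read_table(event_table)

    records: dict[str, PatientRecord] = {}
    for i, row in enumerate(patients.itertuples(index=False), start=1):
        pid = str(row.patient_id)
        if pid in records:
            raise CohortFormatError(f"patients row {i}: duplicate patient_id {pid!r}")
        baseline = _parse_date(row.baseline_date, "patients", i)
        diagnosis = None
        if not _is_missing(row.dx_date):
            dx = _parse_date(row.dx_date, "patients", i)
            diagnosis = CarcinomaDiagnosis(
                day=float((dx - baseline).days),
                carcinoma_type=_check_code(row.carcinoma_type, CARCINOMA_TYPES,
                                           "patients", i, "carcinoma_type"),
                clinical_stage=_check_code(row.clinical_stage, STAGES,
                                           "patients", i, "clinical_stage"),
                pathological_stage=(None if _is_missing(row.pathological_stage)
                                    else _check_code(row.pathological_stage, STAGES,
                                                     "patients", i, "pathological_stage")),
                location=(None if _is_missing(row.location)
                          else _check_code(row.location, LOCATIONS,
                                           "patients", i, "location")),
            )
        outcome = None
        if not _is_missing(row.last_date):
            last = _parse_date(row.last_date, "patients", i)
            outcome = FollowUpOutcome(
                last_day=float((last - baseline).days),
                status=_check_code(row.status, OUTCOME_STATUS, "patients", i, "status"),
            )
        records[pid] = PatientRecord(
            patient_id=pid,
            baseline_date=baseline,
            age_at_baseline=float(row.age_at_baseline),
            sex=_check_code(row.sex, SEXES, "patients", i, "sex"),
            ipmn_type=_check_code(row.ipmn_type, IPMN_TYPES, "patients", i, "ipmn_type"),
            smoking=_check_code(row.smoking, SMOKING, "patients", i, "smoking"),
            bmi=float(row.bmi),
            diabetes=_check_code(row.diabetes, DIABETES, "patients", i, "diabetes"),
            family_history_pc=_parse_bool(row.family_history_pc, "patients", i),
            diagnosis=diagnosis,
            outcome=outcome,
        )

    # labs: group into per-analyte series, reject duplicates
    seen: set[tuple[str, str, str]] = set()
    buckets: dict[tuple[str, str], dict] = {}
    for i, row in enumerate(labs.itertuples(index=False), start=1):
        pid = str(row.patient_id)
        if pid not in records:
            raise CohortFormatError(f"labs row {i}: unknown patient_id {pid!r}")
        analyte = _check_code(row.analyte, ANALYTES, "labs", i, "analyte")
        key = (pid, str(row.date), analyte)
        if key in seen:
            raise CohortFormatError(
                f"labs row {i}: duplicate measurement of {analyte} for "
                f"patient {pid} on {row.date}")
        seen.add(key)
        d = _parse_date(row.date, "labs", i)
        day = float((d - records[pid].baseline_date).days)
        b = buckets.setdefault((pid, analyte), {
            "unit": str(row.unit).strip(), "days": [], "values": [],
            "detection_limit": None})
        unit = str(row.unit).strip()
        if unit != b["unit"]:
            raise CohortFormatError(
                f"labs row {i}: unit {unit!r} differs from earlier "
                f"{b['unit']!r} for {analyte} of patient {pid}")
        b["days"].append(day)
        b["values"].append(float(row.value))
        if not _is_missing(row.detection_limit):
            b["detection_limit"] = float(row.detection_limit)

    for (pid, analyte), b in buckets.items():
        order = np.argsort(b["days"], kind="stable")
        records[pid].labs.append(LabSeries(
            analyte=analyte, unit=b["unit"],
            days=np.asarray(b["days"])[order],
            values=np.asarray(b["values"])[order],
            detection_limit=b["detection_limit"]))

    for i, row in enumerate(imaging.itertuples(index=False), start=1):
        pid = str(row.patient_id)
        if pid not in records:
            raise CohortFormatError(f"imaging row {i}: unknown patient_id {pid!r}")
        d = _parse_date(row.date, "imaging", i)
        records[pid].imaging.append(ImagingAssessment(
            day=float((d - records[pid].baseline_date).days),
            modality=_check_code(row.modality, MODALITIES, "imaging", i, "modality"),
            cyst_size_mm=None if _is_missing(row.cyst_size_mm) else float(row.cyst_size_mm),
            mpd_diameter_mm=(None if _is_missing(row.mpd_diameter_mm)
                             else float(row.mpd_diameter_mm)),
            mural_nodule=_check_code(row.mural_nodule, MURAL_NODULE,
                                     "imaging", i, "mural_nodule"),
            thickened_enhanced_wall=_parse_bool(row.thickened_enhanced_wall, "imaging", i),
            abrupt_caliber_change_with_atrophy=_parse_bool(
                row.abrupt_caliber_change_with_atrophy, "imaging", i),
            lymphadenopathy=_parse_bool(row.lymphadenopathy, "imaging", i),
            solid_mass_detected=_parse_bool(row.solid_mass_detected, "imaging", i),
        ))

    for i, row in enumerate(events.itertuples(index=False), start=1):
        pid = str(row.patient_id)
        if pid not in records:
            raise CohortFormatError(f"events row {i}: unknown patient_id {pid!r}")
        d = _parse_date(row.date, "events", i)
        records[pid].events.append(ClinicalEvent(
            day=float((d - records[pid].baseline_date).days),
            kind=_check_code(row.kind, EVENT_KINDS, "events", i, "kind")))

    for rec in records.values():
        rec.imaging.sort(key=lambda a: a.day)
        rec.events.sort(key=lambda e: e.day)
    return list(records.values())


def _fmt_num(x: float | None) -> str:
    if x is None:
        return ""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def write_cohort(records: Iterable[PatientRecord], out_dir) -> dict[str, Path]:
    """Write the four tidy CSVs to ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prows, lrows, irows, erows = [], [], [], []
    for r in records:
        dx = r.diagnosis
        oc = r.outcome

        def to_date(day: float) -> str:
            return (r.baseline_date + timedelta(days=round(day))).isoformat()

        prows.append({
            "patient_id": r.patient_id,
            "baseline_date": r.baseline_date.isoformat(),
            "age_at_baseline": _fmt_num(r.age_at_baseline),
            "sex": r.sex, "ipmn_type": r.ipmn_type, "smoking": r.smoking,
            "bmi": _fmt_num(r.bmi), "diabetes": r.diabetes,
            "family_history_pc": str(r.family_history_pc).lower(),
            "dx_date": to_date(dx.day) if dx else "",
            "carcinoma_type": dx.carcinoma_type if dx else "",
            "clinical_stage": dx.clinical_stage if dx else "",
            "pathological_stage": (dx.pathological_stage or "") if dx else "",
            "location": (dx.location or "") if dx else "",
            "last_date": to_date(oc.last_day) if oc else "",
            "status": oc.status if oc else "",
        })
        for s in r.labs:
            for day, v in zip(s.days, s.values):
                lrows.append({
                    "patient_id": r.patient_id, "date": to_date(day),
                    "analyte": s.analyte, "value": _fmt_num(v), "unit": s.unit,
                    "detection_limit": _fmt_num(s.detection_limit)})
        for a in r.imaging:
            irows.append({
                "patient_id": r.patient_id, "date": to_date(a.day),
                "modality": a.modality,
                "cyst_size_mm": _fmt_num(a.cyst_size_mm),
                "mpd_diameter_mm": _fmt_num(a.mpd_diameter_mm),
                "mural_nodule": a.mural_nodule,
                "thickened_enhanced_wall": str(a.thickened_enhanced_wall).lower(),
                "abrupt_caliber_change_with_atrophy":
                    str(a.abrupt_caliber_change_with_atrophy).lower(),
                "lymphadenopathy": str(a.lymphadenopathy).lower(),
                "solid_mass_detected": str(a.solid_mass_detected).lower()})
        for e in r.events:
            erows.append({"patient_id": r.patient_id, "date": to_date(e.day),
                          "kind": e.kind})

    paths = {}
    specs = [
        ("patients", prows, ["patient_id", "baseline_date", "age_at_baseline",
                             "sex", "ipmn_type", "smoking", "bmi", "diabetes",
                             "family_history_pc", "dx_date", "carcinoma_type",
                             "clinical_stage", "pathological_stage", "location",
                             "last_date", "status"]),
        ("labs", lrows, ["patient_id", "date", "analyte", "value", "unit",
                         "detection_limit"]),
        ("imaging", irows, ["patient_id", "date", "modality", "cyst_size_mm",
                            "mpd_diameter_mm", "mural_nodule",
                            "thickened_enhanced_wall",
                            "abrupt_caliber_change_with_atrophy",
                            "lymphadenopathy", "solid_mass_detected"]),
        ("events", erows, ["patient_id", "date", "kind"]),
    ]
    for name, rows, cols in specs:
        p = out / f"{name}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(p, index=False)
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    rule: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.rule}: {self.detail}"


def validate_record(record: PatientRecord) -> list[Violation]:
    """Check type invariants and study-eligibility rules.

    Returns an empty list iff the record is internally consistent and
    eligible: follow-up of at least 6 months, no carcinoma diagnosis within
    6 months of baseline, all dated entries inside the follow-up interval.
    Violations are data, not exceptions.
    """
    v: list[Violation] = []
    oc, dx = record.outcome, record.diagnosis
    end = oc.last_day if oc is not None else np.inf

    if oc is None:
        v.append(Violation("missing_outcome", "record has no follow-up outcome"))
    else:
        if oc.last_day < MIN_FOLLOWUP_DAYS:
            v.append(Violation("followup_lt_6_months",
                               f"follow-up {oc.last_day:.0f} d < {MIN_FOLLOWUP_DAYS:.0f} d"))
        if dx is not None and oc.last_day < dx.day:
            v.append(Violation("outcome_before_diagnosis",
                               f"last date {oc.last_day:.0f} d precedes diagnosis "
                               f"{dx.day:.0f} d"))
    if dx is not None and dx.day < MIN_FOLLOWUP_DAYS:
        v.append(Violation("diagnosis_within_6_months",
                           f"diagnosis at {dx.day:.0f} d after baseline"))

    for s in record.labs:
        if len(s) and np.any(np.diff(s.days) <= 0):
            v.append(Violation("lab_dates_not_increasing",
                               f"{s.analyte} series has non-increasing dates"))
        if len(s) and np.any(s.values < 0):
            v.append(Violation("negative_lab_value",
                               f"{s.analyte} series has a negative value"))
        for day in s.days:
            if day < 0 or day > end:
                v.append(Violation("entry_after_followup_end",
                                   f"{s.analyte} measurement at {day:.0f} d outside "
                                   f"[0, {end:.0f}]"))
    for a in record.imaging:
        if a.day < 0 or a.day > end:
            v.append(Violation("entry_after_followup_end",
                               f"imaging at {a.day:.0f} d outside [0, {end:.0f}]"))
        for name, size in (("cyst_size_mm", a.cyst_size_mm),
                           ("mpd_diameter_mm", a.mpd_diameter_mm)):
            if size is not None and not (0 <= size <= 300):
                v.append(Violation("size_out_of_range",
                                   f"{name}={size} at {a.day:.0f} d"))
    for e in record.events:
        if e.day < 0 or e.day > end:
            v.append(Violation("entry_after_followup_end",
                               f"event {e.kind} at {e.day:.0f} d outside [0, {end:.0f}]"))
    return v


def validate_cohort(records: Iterable[PatientRecord]) -> dict[str, list[Violation]]:
    """Per-patient violations for every record that has any."""
    out = {}
    for r in records:
        vs = validate_record(r)
        if vs:
            out[r.patient_id] = vs
    return out
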