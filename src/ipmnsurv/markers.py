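"""Prediagnostic blood-marker rules.

Implements the CA19-9 trajectory-pattern classification, HbA1c and
pancreatic-enzyme aberrant-elevation detection, elevation lead times, and
the Lewis-antigen-negative flag.  All rules use the *cumulative average* of
a patient's prior measurements as the individualized reference value, and
evaluate elevation inside a 1-year window preceding carcinoma diagnosis.

CA19-9 trajectory patterns
--------------------------
aberrant_elevation
    First documentation of CA19-9 above the upper limit of normal
    (> 37 U/mL), or a doubling of the cumulative average with the value
    itself above the limit, within 1 year preceding diagnosis.
low_to_low
    CA19-9 within normal limits throughout the prediagnostic period.
high_to_high
    Elevated at baseline, never doubling before diagnosis.
residual_unclassified
    First crossed the limit more than 1 year before diagnosis and never
    doubled in-window (kept explicit rather than coerced into a group).
insufficient_data
    No CA19-9 measurement within the 1-year window.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .cohort import DAYS_PER_YEAR, LabSeries, PatientRecord

PATTERNS = ("aberrant_elevation", "high_to_high", "low_to_low",
            "residual_unclassified", "insufficient_data")
TRIGGERS = ("above_uln_first_time", "doubling_of_cumavg")

# NGSP(%) -> IFCC(mmol/mol) master-equation coefficients
_IFCC_SLOPE = 10.93
_IFCC_INTERCEPT = -23.50


@dataclass
class MarkerRuleConfig:
    """Thresholds of the marker rules.

    The CA19-9 limit (37 U/mL), the 4 mmol/mol HbA1c delta, the triple-ULN
    and doubling factors, and the 1-year window are the study's values.
    Enzyme upper limits of normal are laboratory-dependent and not published
    by the study; the defaults (p-amylase 50 U/L, lipase 60 U/L) are common
    assay limits and are overridable.
    """

    ca19_9_uln: float = 37.0
    window_years: float = 1.0
    hba1c_delta_mmol_mol: float = 4.0
    enzyme_uln_multiple: float = 3.0
    enzyme_doubling_factor: float = 2.0
    p_amylase_uln: float = 50.0
    lipase_uln: float = 60.0
    doubling_inclusive: bool = True

    def __post_init__(self) -> None:
        for f in ("ca19_9_uln", "window_years", "hba1c_delta_mmol_mol",
                  "enzyme_uln_multiple", "enzyme_doubling_factor",
                  "p_amylase_uln", "lipase_uln"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerRuleConfig":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrajectoryClassification:
    pattern: str
    #: years before diagnosis of the first qualifying elevation
    #: (present iff pattern == aberrant_elevation)
    first_elevation_years: float | None = None
    trigger: str | None = None


@dataclass
class ElevationDetection:
    elevated: bool
    first_elevation_years: float | None = None
    analyte: str | None = None


def cumulative_average(series: LabSeries, t: float) -> float | None:
    """Mean of all values strictly before day ``t``; None if no prior value."""
    mask = series.days < t
    if not mask.any():
        return None
    return float(series.values[mask].mean())


def _doubles(v: float, ref: float, factor: float, inclusive: bool) -> bool:
    return v >= factor * ref if inclusive else v > factor * ref


def classify_ca19_9_trajectory(series: LabSeries, dx_day: float,
                               cfg: MarkerRuleConfig | None = None
                               ) -> TrajectoryClassification:
    """Assign the prediagnostic CA19-9 trajectory pattern for one patient.

    ``series`` must be the patient's CA19-9 series; ``dx_day`` the carcinoma
    diagnosis day.  The 1-year window is the half-open interval
    ``(dx - 365.25 * window_years, dx]``.
    """
    cfg = cfg or MarkerRuleConfig()
    if series.analyte != "ca19_9":
        raise ValueError(f"expected a ca19_9 series, got {series.analyte!r}")
    uln = cfg.ca19_9_uln
    pre = series.days <= dx_day  # prediagnostic portion
    days, values = series.days[pre], series.values[pre]

    window_lo = dx_day - cfg.window_years * DAYS_PER_YEAR
    in_window = days > window_lo
    if not in_window.any():
        return TrajectoryClassification("insufficient_data")

    for i in np.flatnonzero(in_window):
        v, d = values[i], days[i]
        if v <= uln:
            continue
        first_crossing = np.all(values[:i] <= uln)
        cavg = float(values[:i].mean()) if i > 0 else None
        doubled = cavg is not None and _doubles(v, cavg, 2.0, cfg.doubling_inclusive)
        if first_crossing:
            return TrajectoryClassification(
                "aberrant_elevation",
                first_elevation_years=(dx_day - d) / DAYS_PER_YEAR,
                trigger="above_uln_first_time")
        if doubled:
            return TrajectoryClassification(
                "aberrant_elevation",
                first_elevation_years=(dx_day - d) / DAYS_PER_YEAR,
                trigger="doubling_of_cumavg")

    if np.all(values <= uln):
        return TrajectoryClassification("low_to_low")

    if values[0] > uln:
        doubled_in_window = False
        for i in np.flatnonzero(in_window):
            if i == 0:
                continue
            cavg = float(values[:i].mean())
            if _doubles(values[i], cavg, 2.0, cfg.doubling_inclusive):
                doubled_in_window = True
                break
        if not doubled_in_window:
            return TrajectoryClassification("high_to_high")

    return TrajectoryClassification("residual_unclassified")


def hba1c_to_mmol_mol(values: np.ndarray, unit: str) -> np.ndarray:
    """Convert HbA1c values to IFCC mmol/mol (identity if already IFCC)."""
    u = unit.strip().lower()
    if u in ("mmol/mol", "mmol_mol", "ifcc"):
        return np.asarray(values, dtype=float)
    if u in ("%", "percent", "percent_ngsp", "ngsp"):
        return _IFCC_SLOPE * np.asarray(values, dtype=float) + _IFCC_INTERCEPT
    raise ValueError(f"unrecognized HbA1c unit {unit!r}")


def detect_hba1c_elevation(series: LabSeries, dx_day: float,
                           cfg: MarkerRuleConfig | None = None
                           ) -> ElevationDetection:
    """HbA1c elevation: an in-window value at least ``hba1c_delta_mmol_mol``
    (default 4 mmol/mol) above the cumulative average, both on the IFCC
    scale.  Percent-NGSP series are converted via IFCC = 10.93*NGSP - 23.50.
    """
    cfg = cfg or MarkerRuleConfig()
    if series.analyte != "hba1c":
        raise ValueError(f"expected an hba1c series, got {series.analyte!r}")
    vals = hba1c_to_mmol_mol(series.values, series.unit)
    pre = series.days <= dx_day
    days, vals = series.days[pre], vals[pre]
    window_lo = dx_day - cfg.window_years * DAYS_PER_YEAR
    for i in np.flatnonzero(days > window_lo):
        if i == 0:
            continue
        cavg = float(vals[:i].mean())
        if vals[i] - cavg >= cfg.hba1c_delta_mmol_mol:
            return ElevationDetection(True, (dx_day - days[i]) / DAYS_PER_YEAR,
                                      "hba1c")
    return ElevationDetection(False)


def detect_enzyme_elevation(series_map: dict[str, LabSeries], dx_day: float,
                            cfg: MarkerRuleConfig | None = None
                            ) -> ElevationDetection:
    """Pancreatic-enzyme aberrant elevation.

    True iff some in-window value of pancreatic amylase or lipase is above
    triple the (analyte-specific) upper limit of normal AND doubles the
    cumulative average.  Returns the earliest qualifying (analyte, time).
    Total amylase is deliberately not consulted.
    """
    cfg = cfg or MarkerRuleConfig()
    ulns = {"p_amylase": cfg.p_amylase_uln, "lipase": cfg.lipase_uln}
    if not any(a in series_map for a in ulns):
        raise ValueError("need a p_amylase or lipase series")
    window_lo = dx_day - cfg.window_years * DAYS_PER_YEAR
    best: tuple[float, str] | None = None
    for analyte, uln in ulns.items():
        s = series_map.get(analyte)
        if s is None:
            continue
        if s.analyte != analyte:
            raise ValueError(f"series under key {analyte!r} is {s.analyte!r}")
        pre = s.days <= dx_day
        days, vals = s.days[pre], s.values[pre]
        for i in np.flatnonzero(days > window_lo):
            v = vals[i]
            if v <= cfg.enzyme_uln_multiple * uln:
                continue
            if i == 0:
                continue
            cavg = float(vals[:i].mean())
            if _doubles(v, cavg, cfg.enzyme_doubling_factor, cfg.doubling_inclusive):
                if best is None or days[i] < best[0]:
                    best = (days[i], analyte)
                break  # earliest qualifying point of this analyte found
    if best is None:
        return ElevationDetection(False)
    return ElevationDetection(True, (dx_day - best[0]) / DAYS_PER_YEAR, best[1])


def elevation_lead_time(result: TrajectoryClassification | ElevationDetection,
                        ) -> float:
    """Years from the first qualifying elevation to diagnosis.

    The classification/detection objects already carry the lead in years
    (computed as days/365.25, unrounded); this accessor enforces the
    contract that the patient was actually elevated.
    """
    if isinstance(result, TrajectoryClassification):
        if result.pattern != "aberrant_elevation":
            raise ValueError("lead time is defined only for aberrant elevation")
        assert result.first_elevation_years is not None
        return result.first_elevation_years
    if not result.elevated:
        raise ValueError("lead time is defined only for elevated patients")
    assert result.first_elevation_years is not None
    return result.first_elevation_years


def flag_lewis_negative(series: LabSeries) -> bool:
    """Plausible Lewis-antigen-negative: every CA19-9 value at or below the
    assay detection limit (such patients produce no CA19-9 regardless of
    tumor burden and are excluded in sensitivity analyses)."""
    if series.detection_limit is None:
        raise ValueError("detection_limit required for the Lewis-negative flag")
    if len(series) == 0:
        return False
    return bool(np.all(series.values <= series.detection_limit))


def classify_cohort(records: list[PatientRecord],
                    cfg: MarkerRuleConfig | None = None):
    """Run all marker rules over diagnosed patients; returns a DataFrame
    with one row per patient holding pattern, trigger, lead times and flags
    (the ``trajectories.csv`` layout)."""
    import pandas as pd

    cfg = cfg or MarkerRuleConfig()
    rows = []
    for r in records:
        if r.diagnosis is None:
            continue
        dx = r.diagnosis.day
        ca = r.lab("ca19_9")
        if ca is None or len(ca) == 0:
            tc = TrajectoryClassification("insufficient_data")
            lewis = False
        else:
            tc = classify_ca19_9_trajectory(ca, dx, cfg)
            lewis = (flag_lewis_negative(ca)
                     if ca.detection_limit is not None else False)
        hb = r.lab("hba1c")
        hb_det = (detect_hba1c_elevation(hb, dx, cfg)
                  if hb is not None and len(hb) else ElevationDetection(False))
        enz_map = {a: s for a in ("p_amylase", "lipase")
                   if (s := r.lab(a)) is not None and len(s)}
        enz_det = (detect_enzyme_elevation(enz_map, dx, cfg)
                   if enz_map else ElevationDetection(False))
        rows.append({
            "patient_id": r.patient_id,
            "pattern": tc.pattern,
            "trigger": tc.trigger or "",
            "first_elevation_years_before_dx": tc.first_elevation_years,
            "hba1c_elevated": hb_det.elevated,
            "hba1c_lead_years": hb_det.first_elevation_years,
            "enzyme_elevated": enz_det.elevated,
            "enzyme_analyte": enz_det.analyte or "",
            "enzyme_lead_years": enz_det.first_elevation_years,
            "lewis_negative_flag": lewis,
        })
    return pd.DataFrame(rows, columns=[
        "patient_id", "pattern", "trigger", "first_elevation_years_before_dx",
        "hba1c_elevated", "hba1c_lead_years", "enzyme_elevated",
        "enzyme_analyte", "enzyme_lead_years", "lewis_negative_flag"])
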