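"""Cohort-level statistics: contingency analyses and survival.

Contingency tables compare trajectory patterns with carcinoma type and
stage; continuous variables use the Wilcoxon rank-sum test; postdiagnosis
overall survival (diagnosis to death of any cause, censored at last
follow-up) is estimated by the Kaplan-Meier product-limit method and
compared across trajectory patterns with the log-rank test.

Pearson chi-square is computed without continuity correction; Fisher's
exact two-sided p sums hypergeometric probabilities no larger than the
observed table's.  The chi-square/Fisher choice follows the usual rule:
Fisher for 2x2 tables with any expected cell below 5, Pearson otherwise
(r x c tables with small expected counts are flagged, not Fisher-tested).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray
    #: patients dropped because either variable was undefined
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        """Percent of each row total, NaN for empty rows."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / totals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)


@dataclass
class SurvivalCurve:
    """Product-limit estimate: step function with at-risk bookkeeping."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def probability_at(self, t: float) -> float:
        """S(t): survival just after time t (right-continuous step)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


UNDEFINED = {"", "nan", "none", "insufficient_data"}


def _defined(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip()
    return ~(series.isna() | s.str.lower().isin(UNDEFINED))


def crosstab(df: pd.DataFrame, row_var: str, col_var: str,
             row_order: list[str] | None = None,
             col_order: list[str] | None = None) -> ContingencyTable:
    """Cross-classify two categorical columns.

    Patients with an undefined value in either variable (missing, or the
    ``insufficient_data`` trajectory class) are excluded and counted in
    ``n_excluded`` — mirroring the exclusion footnote of the study's
    pattern-by-type table.
    """
    ok = _defined(df[row_var]) & _defined(df[col_var])
    sub = df.loc[ok]
    rows = row_order or sorted(sub[row_var].astype(str).unique())
    cols = col_order or sorted(sub[col_var].astype(str).unique())
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    for (rv, cv), k in sub.groupby([row_var, col_var], observed=True).size().items():
        if str(rv) in rows and str(cv) in cols:
            counts[rows.index(str(rv)), cols.index(str(cv))] = k
    return ContingencyTable(rows, cols, counts, n_excluded=int((~ok).sum()))


def pearson_chi_square(table: ContingencyTable | np.ndarray):
    """Pearson chi-square without continuity correction.

    Returns ``(statistic, df, p)``; a zero row/column margin makes the
    statistic undefined and yields ``(nan, df, nan)``.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    r, c = counts.shape
    df = (r - 1) * (c - 1)
    if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
        return float("nan"), df, float("nan")
    stat, p, dof, _ = sps.chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)


def expected_counts(table: ContingencyTable | np.ndarray) -> np.ndarray:
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    n = counts.sum()
    return np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n


def fisher_exact_2x2(table: ContingencyTable | np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability-mass summation)."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    return float(sps.fisher_exact(counts, alternative="two-sided")[1])


def choose_categorical_test(table: ContingencyTable):
    """'As appropriate' resolution: Fisher for a 2x2 with any expected cell
    < 5, else Pearson.  Returns ``(test_name, p, flag)`` where ``flag``
    notes small expected counts in an r x c table."""
    exp = expected_counts(table)
    small = bool((exp < 5).any())
    if table.counts.shape == (2, 2) and small:
        return "fisher_exact", fisher_exact_2x2(table), False
    _, _, p = pearson_chi_square(table)
    return "pearson_chi_square", p, small and table.counts.shape != (2, 2)


def wilcoxon_rank_sum(x, y):
    """Wilcoxon rank-sum (Mann-Whitney) with midrank ties.

    Exact p when the combined sample has at most 10 untied observations,
    otherwise the normal approximation with tie correction.  Returns
    ``(U, p)`` with U the Mann-Whitney statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and len(pooled) <= 10:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def km_curve(times, event_flags) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    ``event_flags`` is 1/True for death, 0/False for censoring; subjects
    censored at an event time are handled as censored after the events
    (the standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags, dtype=bool)
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.sort(np.unique(times[events])) if events.any() else np.array([])
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0])
                     for t in event_times])
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=int)
    return SurvivalCurve(times=event_times, survival=surv, at_risk=at_risk,
                         censor_times=np.sort(times[~events]))


def log_rank_test(groups):
    """Log-rank comparison of two or more groups.

    ``groups`` is a sequence of ``(times, event_flags)`` pairs.  Returns
    ``(statistic, df, p)``.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    all_t, all_e, all_g = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if len(t) == 0:
            raise ValueError(f"group {gi} has no subjects")
        all_t.append(t)
        all_e.append(e)
        all_g.append(np.full(len(t), gi))
    res = multivariate_logrank_test(np.concatenate(all_t), np.concatenate(all_g),
                                    np.concatenate(all_e))
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles (linear interpolation), unrounded."""
    v = np.asarray([x for x in values if x is not None and np.isfinite(x)],
                   dtype=float)
    if len(v) == 0:
        return float("nan"), float("nan"), float("nan")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return float(q50), float(q25), float(q75)


def _fmt_miqr(values) -> str:
    m, lo, hi = median_iqr(values)
    if np.isnan(m):
        return "-"
    return f"{m:.1f} (IQR {lo:.1f}-{hi:.1f})"


def cohort_report(patients: pd.DataFrame, trajectories: pd.DataFrame,
                  firsts: pd.DataFrame) -> dict:
    """Assemble the cohort-level report.

    ``patients`` is the patients.csv frame (diagnosed cases are the rows
    with a ``carcinoma_type``), ``trajectories`` the classifier output and
    ``firsts`` the morphology first-occurrence table.  Returns a dict of
    DataFrames plus a rendered plain-text report under ``"text"``.
    """
    dx = patients.loc[_defined(patients["carcinoma_type"])].copy()
    merged = dx.merge(trajectories, on="patient_id", how="left") \
               .merge(firsts, on="patient_id", how="left")
    out: dict = {}
    lines: list[str] = []
    lines.append(f"Carcinoma cases: {len(dx)}")
    if len(dx) == 0:
        out["text"] = "\n".join(lines) + "\n"
        return out

    pattern_order = ["aberrant_elevation", "high_to_high", "low_to_low",
                     "residual_unclassified"]
    type_order = ["ipmn_derived", "concomitant_pdac"]

    # pattern x type (rows = carcinoma type, mirroring the published layout)
    tab_type = crosstab(merged, "carcinoma_type", "pattern",
                        row_order=type_order,
                        col_order=[p for p in pattern_order
                                   if p in set(merged["pattern"].dropna())])
    out["pattern_by_type"] = tab_type.to_frame()
    test_name, p, _ = (choose_categorical_test(tab_type)
                       if tab_type.n else ("pearson_chi_square", float("nan"), False))
    lines.append("\nCA19-9 trajectory pattern by carcinoma type "
                 f"(n={tab_type.n}, {tab_type.n_excluded} excluded for missing "
                 "in-window CA19-9):")
    pct = tab_type.row_percentages()
    for i, rl in enumerate(tab_type.row_labels):
        cells = ", ".join(
            f"{cl}: {tab_type.counts[i, j]} ({pct[i, j]:.0f}%)"
            for j, cl in enumerate(tab_type.col_labels))
        lines.append(f"  {rl} (n={tab_type.counts[i].sum()}): {cells}")
    lines.append(f"  {test_name} P = {p:.3g}")

    # aberrant vs not, by type (the 60% vs 30% comparison)
    merged["aberrant"] = np.where(
        _defined(merged["pattern"]),
        np.where(merged["pattern"] == "aberrant_elevation", "aberrant",
                 "not_aberrant"), "")
    tab_ab = crosstab(merged, "carcinoma_type", "aberrant",
                      row_order=type_order,
                      col_order=["aberrant", "not_aberrant"])
    out["aberrant_by_type"] = tab_ab.to_frame()
    stat, dfree, p_ab = pearson_chi_square(tab_ab)
    pct = tab_ab.row_percentages()
    lines.append("\nAberrant CA19-9 elevation by carcinoma type:")
    for i, rl in enumerate(tab_ab.row_labels):
        lines.append(f"  {rl}: {tab_ab.counts[i, 0]}/{tab_ab.counts[i].sum()} "
                     f"({pct[i, 0]:.0f}%)")
    lines.append(f"  chi2 = {stat:.2f} (df={dfree}), P = {p_ab:.3g}")

    # pattern x stage
    if "clinical_stage" in merged:
        merged["stage_group"] = merged["clinical_stage"].map(
            {"0": "0/I", "I": "0/I", "II": "II", "III": "III", "IV": "IV"})
        tab_stage = crosstab(merged, "stage_group", "pattern",
                             row_order=["0/I", "II", "III", "IV"],
                             col_order=tab_type.col_labels)
        out["pattern_by_stage"] = tab_stage.to_frame()

    # HRS prevalence by type
    if "any_hrs" in merged:
        lines.append("\nHigh-risk stigmata before diagnosis:")
        hrs_frame = []
        for t in type_order:
            sub = merged.loc[merged["carcinoma_type"] == t, "any_hrs"].dropna()
            if len(sub):
                k = int(sub.astype(bool).sum())
                lines.append(f"  {t}: {k}/{len(sub)} ({100 * k / len(sub):.0f}%)")
                hrs_frame.append({"carcinoma_type": t, "n": len(sub),
                                  "n_hrs": k, "pct": 100 * k / len(sub)})
        out["hrs_by_type"] = pd.DataFrame(hrs_frame)

    # lead times
    lines.append("\nLead times (years before diagnosis):")
    for label, col in (("CA19-9 elevation", "first_elevation_years_before_dx"),
                       ("first WF/HRS", None)):
        for t in type_order:
            sub = merged.loc[merged["carcinoma_type"] == t]
            if col is not None:
                vals = sub[col].dropna().tolist()
            else:
                # earliest documentation of either tier = the larger lead
                leads = sub[["wf_lead_years", "hrs_lead_years"]].astype(float)
                vals = [v for v in leads.max(axis=1, skipna=True)
                        if np.isfinite(v)] if len(sub) else []
            lines.append(f"  {label}, {t}: {_fmt_miqr(vals)} [n={len(vals)}]")

    out["cases"] = merged
    out["text"] = "\n".join(lines) + "\n"
    return out


def survival_by_pattern(patients: pd.DataFrame, trajectories: pd.DataFrame):
    """Postdiagnosis overall survival grouped by aberrant vs non-aberrant
    CA19-9 trajectory.  Returns ``(curves, (stat, df, p))`` where curves is
    ``{group: SurvivalCurve}``; the test is None with fewer than 2 groups.
    """
    dx = patients.loc[_defined(patients["carcinoma_type"])].copy()
    merged = dx.merge(trajectories, on="patient_id", how="left")
    merged = merged.loc[_defined(merged["pattern"])]
    merged["group"] = np.where(merged["pattern"] == "aberrant_elevation",
                               "aberrant", "not_aberrant")
    t_dx = pd.to_datetime(merged["dx_date"])
    t_last = pd.to_datetime(merged["last_date"])
    merged["surv_years"] = (t_last - t_dx).dt.days / 365.25
    merged["event"] = merged["status"] == "dead"
    curves, groups = {}, []
    for g, sub in merged.groupby("group"):
        curves[g] = km_curve(sub["surv_years"].to_numpy(),
                             sub["event"].to_numpy())
        groups.append((sub["surv_years"].to_numpy(), sub["event"].to_numpy()))
    test = log_rank_test(groups) if len(groups) >= 2 else None
    return curves, test
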