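"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each rule or statistic from its plain
definition (enumeration, closed formula, direct scan) without sharing code
with the package, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

DAYS_PER_YEAR = 365.25
ULN = 37.0


def oracle_classify_ca19_9(days, values, dx, uln=ULN):
    """Direct prose transcription of the CA19-9 trajectory rules."""
    pts = [(d, v) for d, v in zip(days, values) if d <= dx]
    in_window = [(d, v) for d, v in pts if dx - DAYS_PER_YEAR < d <= dx]
    if not in_window:
        return "insufficient_data", None, None
    for i, (d, v) in enumerate(pts):
        if not (dx - DAYS_PER_YEAR < d <= dx):
            continue
        prior = [pv for _, pv in pts[:i]]
        if v > uln and all(p <= uln for p in prior):
            return ("aberrant_elevation", (dx - d) / DAYS_PER_YEAR,
                    "above_uln_first_time")
        if v > uln and prior and v >= 2 * (sum(prior) / len(prior)):
            return ("aberrant_elevation", (dx - d) / DAYS_PER_YEAR,
                    "doubling_of_cumavg")
    if all(v <= uln for _, v in pts):
        return "low_to_low", None, None
    if pts[0][1] > uln:
        doubled = False
        for i, (d, v) in enumerate(pts):
            if i == 0 or not (dx - DAYS_PER_YEAR < d <= dx):
                continue
            prior = [pv for _, pv in pts[:i]]
            if v >= 2 * (sum(prior) / len(prior)):
                doubled = True
        if not doubled:
            return "high_to_high", None, None
    return "residual_unclassified", None, None


def oracle_enzyme(days, values, dx, uln, uln_multiple=3.0, doubling=2.0):
    """Scan every point against both conjuncts of the enzyme rule."""
    pts = [(d, v) for d, v in zip(days, values) if d <= dx]
    for i, (d, v) in enumerate(pts):
        if not (dx - DAYS_PER_YEAR < d <= dx):
            continue
        prior = [pv for _, pv in pts[:i]]
        if v > uln_multiple * uln and prior and \
                v >= doubling * (sum(prior) / len(prior)):
            return True, (dx - d) / DAYS_PER_YEAR
    return False, None


def oracle_fisher_2x2(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


def oracle_wilcoxon_perm(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_v = pooled[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1  # midranks
        i = j + 1
    obs = ranks[:nx].sum()
    mean = nx * (n + 1) / 2
    count = total = 0
    for idx in itertools.combinations(range(n), nx):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


def oracle_km(times):
    """Survival function with no censoring = empirical survival 1 - ECDF."""
    times = np.sort(np.asarray(times, dtype=float))

    def s(t):
        return float((times > t).mean())

    return s


def oracle_logrank_2group(t1, e1, t2, e2):
    """Textbook two-group log-rank chi-square; also returns (O1-E1)."""
    t1, e1 = np.asarray(t1, float), np.asarray(e1, bool)
    t2, e2 = np.asarray(t2, float), np.asarray(e2, bool)
    all_event_times = np.unique(np.concatenate([t1[e1], t2[e2]]))
    o1 = ex1 = var = 0.0
    for t in all_event_times:
        n1 = (t1 >= t).sum()
        n2 = (t2 >= t).sum()
        d1 = ((t1 == t) & e1).sum()
        d2 = ((t2 == t) & e2).sum()
        n, d = n1 + n2, d1 + d2
        if n < 1:
            continue
        o1 += d1
        ex1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 0.0
    return (o1 - ex1) ** 2 / var, o1 - ex1


def oracle_wf_set(cyst, mpd, nodule, wall, caliber, lymph, ca, growth, ap):
    """WF set assembled directly from the guideline item list."""
    s = set()
    if cyst is not None and cyst >= 30:
        s.add("size_ge_30mm")
    if nodule == "present_lt5mm_enhancing":
        s.add("nodule_lt5mm_enhancing")
    if wall:
        s.add("thickened_wall")
    if mpd is not None and 5 <= mpd < 10:
        s.add("mpd_5_to_9_9mm")
    if caliber:
        s.add("abrupt_caliber_change_atrophy")
    if lymph:
        s.add("lymphadenopathy")
    if ca is not None and ca > 37:
        s.add("ca19_9_gt_37")
    if growth:
        s.add("growth_gt_5mm_per_2y")
    if ap:
        s.add("acute_pancreatitis")
    return frozenset(s)


def oracle_hrs_set(jaundice, head, nodule, mpd):
    s = set()
    if jaundice and head:
        s.add("obstructive_jaundice_head_lesion")
    if nodule == "present_ge5mm_enhancing":
        s.add("enhancing_nodule_ge_5mm")
    if mpd is not None and mpd >= 10:
        s.add("mpd_ge_10mm")
    return frozenset(s)
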