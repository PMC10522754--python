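# Methods

This note documents the models, rule semantics, parameter choices and
known limitations of `ipmnsurv`. It is the place where design decisions
that were genuinely open are recorded.

## Time and data model

Time is represented internally as *days since each patient's baseline*
(floats); years in all outputs are `days / 365.25`. Calendar dates appear
only in the CSV interchange files (ISO-8601). A patient record holds one
series per analyte, per-visit imaging assessments, clinical events, at
most one carcinoma diagnosis and a follow-up outcome; multifocal disease
is collapsed onto the dominant lesion, which is what published per-patient
tables do. Duplicate same-day measurements of one analyte are rejected at
read time rather than averaged: the classification rules hinge on "first
documentation", so ambiguity must surface, not dissolve. Missing values
are empty cells, never sentinels.

Study-eligibility rules are validators, not filters: a record with less
than 6 months of follow-up, or a diagnosis within 6 months of baseline,
yields named violations that the caller decides how to handle.

## Marker rule semantics

Several boundary choices are not fully pinned down by the prose the rules
come from; the implementation fixes them as follows and exposes them in
`MarkerRuleConfig`:

- **Cumulative average is a strict prefix mean** (values strictly before
  the index time). A reference that included the index value would dilute
  the doubling signal; "reference value" semantics imply prior data.
- **The 1-year window is half-open**: (dx − 365.25·w, dx].
- **ULN comparison is strict** (`> 37`), matching the stated inequality;
  **doubling is inclusive** (`≥ 2×`, configurable via
  `doubling_inclusive`).
- **The doubling clause requires the value itself to exceed the ULN**, per
  the parenthetical qualification in the source definition.
- A patient who first exceeded the ULN more than a year before diagnosis
  and never doubles in-window is **residual_unclassified**. The published
  three-group accounting leaves no such case, but coercing the class
  silently would hide real data problems.
- A transient elevation that normalized before the window still disquali-
  fies **low to low** ("within normal throughout follow-up" is read
  literally); such a patient is residual unless aberrant or high-to-high.
- **Enzyme ULNs are laboratory constants that the source never states**;
  defaults are p-amylase 50 U/L and lipase 60 U/L, both overridable.
  Total amylase is carried in the data model but deliberately not used by
  the elevation rule, which names pancreatic amylase and lipase.
- HbA1c conversion uses the NGSP/IFCC master equation
  IFCC = 10.93·NGSP − 23.50.
- The Lewis-antigen-negative flag is *all* measured values at or below the
  assay detection limit; it feeds a sensitivity analysis (exclusion), not
  the classifier.

The morphology engine evaluates feature sets strictly from data dated on
or before the visit (no look-ahead; property-tested by truncation
equivalence). The growth item compares the current size against *every*
measurement in the trailing 2-year window (> 5 mm over any of them) rather
than fitting a slope: that matches the "5 mm / 2 years" phrasing and is
reproducible without regression choices. The CA19-9 worrisome feature uses
the most recent value on or before the visit. Lesion location for the
jaundice stigma comes from the diagnosis record; for undiagnosed patients
the item cannot fire — a documented limitation of the per-patient model.
Non-enhancing nodules trigger neither nodule item (both printed items say
"enhancing").

## Statistics

Chi-square is Pearson's statistic without continuity correction — the
uncorrected statistic is what reproduces the published P = 0.005 for the
14/47-vs-25/42 aberrant-by-type comparison (Yates gives ≈ 0.009). "Fisher
as appropriate" is resolved as: Fisher's exact test (two-sided by
probability-mass summation) for 2×2 tables with any expected cell < 5;
Pearson otherwise, with a flag when an r×c table has small expected
counts (r×c exact tests are out of scope). The Wilcoxon rank-sum test uses
midranks, an exact null for ≤ 10 untied observations and otherwise the
tie-corrected normal approximation without continuity shift (so identical
samples give p = 1 under both conventions). Kaplan–Meier and the log-rank
test are delegated to `lifelines`; the test suite checks them against an
ECDF identity and a textbook log-rank implementation, not against
`lifelines` itself. Medians/IQRs use linear interpolation and are rounded
to one decimal only at presentation.

## Synthetic cohort generator

The generator is the package's stand-in for unreleased patient-level
surveillance data. Its defaults encode a published 100-case series (50
IPMN-derived, 50 concomitant):

| parameter | default | origin |
|---|---|---|
| visit interval | 182.6 d, jitter sd 15 d | 6-monthly surveillance; jitter assumed |
| time to diagnosis | log-normal, median 5.7 y, clipped 0.75–25.6 y | published follow-up summary |
| clinical stage mix | derived (36/20/30/10/4)%, concomitant (2/16/54/12/16)% for stages 0/I/II/III/IV | published stage table |
| P(aberrant CA19-9) | derived 0.23 / 0.71, concomitant 0.41 / 1.00 for stage 0–II / III–IV | published stage gradient |
| P(no in-window CA19-9) | 0.11 | published exclusion (11/100) |
| P(high-to-high \| rest) | derived 10/33, concomitant 2/17 | published pattern counts |
| P(HbA1c elevation) | 0.03 | published (3/100) |
| P(enzyme elevation) | derived 0.16, concomitant 0.20 | published |
| P(high-risk stigmata) | derived 0.86, concomitant 0.16 | published |
| P(any WF or HRS) | derived 1.0, concomitant 49/50 | published ("all but one") |
| CA19-9 lead | log-normal fit to 0.4 [0.1–0.5] y (derived), 0.1 [0.1–0.7] y (concomitant), truncated to the 1-y window | published medians/IQRs |
| WF/HRS lead | log-normal fit to 1.6 [0.7–3.7] y / 0.2 [0.1–1.9] y | published |
| measurement CV | CA19-9 20%, enzymes 20%, HbA1c sd 0.08% | assumed (no assay CVs published) |
| Lewis-negative fraction | 0.08 | published (8/100) |
| survival | exponential by stage, medians 12/8/3/1.3/0.6 y, administrative censoring U(0.5, 6) y | stage-ordered medians assumed |

Mechanics worth knowing:

- **Labels first, data second.** Each case draws stage, pattern, elevation
  and feature indicators; the series are then *calibrated so the rules
  trigger at the intended times* (an elevating case gets a documented
  measurement at its onset day whose value satisfies the intended clause
  with margin; feature emergence snaps to the visit grid). Ground truth is
  emitted alongside, and the test suite requires the pipeline to recover
  patterns in ≥ 95% of cases and elevation/emergence times essentially
  exactly.
- **High-risk stigmata are drawn marginally** at the published prevalence;
  feature-negativity is drawn among the non-HRS remainder so both the HRS
  marginal and the "all but one" rate are preserved. A case drawn
  feature-negative cannot carry an elevated CA19-9 pattern (the elevation
  is itself a worrisome feature), so such draws are forced to low-to-low —
  a ~0.5-case correction per 100 concomitant cases.
- **Lewis-negative patients are drawn among intended low-to-low cases**
  (rescaled to the 8% marginal): a Lewis-negative patient cannot mount a
  CA19-9 response, so planting the flag elsewhere would contradict the
  intended pattern.
- **Lead-time fits.** The published lead quartile triplets are more
  left-skewed than any log-normal (which is log-symmetric) can represent,
  so the fit matches the median and the IQR *ratio*; window truncation
  then pulls the realized CA19-9 lead median from 0.4 to ≈ 0.28 y
  (derived). Tests therefore compare recovered medians against the
  truncated distribution, not the raw printed median.
- **Enzyme spikes sit inside the 1-year window** (log-normal lead, median
  ≈ 0.4 y, truncated below 1 y). The published multi-year enzyme
  "latency" figures describe first-ever elevation and cannot describe the
  rule-qualifying spike, which is in-window by definition.

What the generator does **not** emulate, hence what passing tests do not
establish about real data: baseline worrisome features (all cases start
with MPD < 5 mm so that configured emergence leads are recoverable; real
cohorts have ~20–25% baseline-positive patients whose leads equal their
entire follow-up), inter-visit symptomatic presentations, assay changes
over 25 years of follow-up, competing mortality before diagnosis, and any
correlation between marker noise and tumor biology beyond the coded stage
and type effects. The concomitant combined WF/HRS lead median lands above
the published 0.2 y because baseline-elevated CA19-9 cases (high-to-high
and high-start aberrant) are worrisome-feature-positive from the first
visit; the published cohort evidently contained fewer such cases than the
20% high-start share assumed here.

## Numerical and degenerate-input choices

Truncated log-normals are drawn by rejection (200 tries, then clipped
median). Visit grids always include day 0 and a diagnostic visit at the
diagnosis day; intervals are floored at 60 days. Zero-margin contingency
tables return NaN chi-square rather than raising. An empty cohort produces
an empty, well-formed report. KM handles censor-at-event times by the
standard events-first convention. All randomness flows from a single
mandatory seed through `numpy.random.default_rng`; identical seeds give
byte-identical output tables.

## Problem sizes

The shipped test suite simulates cohorts of 80–1000 carcinoma cases
(seconds each); the acceptance script uses 6000 cases so that each
reported percentage carries a Monte-Carlo standard error below one point.
These sizes were chosen to make sampling noise small relative to the
quantities reported, and run in seconds on a single CPU.
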