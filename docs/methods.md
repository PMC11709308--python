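# Methods

## The measurement model

`fpscope` treats a physician's scope of practice as a binary 18-vector of
service indicators derived from one year of fee-for-service billing claims.
The identifying assumption is that each of the 18 services has *sentinel*
fee codes — codes unique to that service in the fee schedule — so that the
annual volume of sentinel claims measures activity in the service without
needing diagnosis codes, patient identifiers or setting information.

For physician *i* and service *s*:

    c_is = sum of n_events over claims of i whose code matches s
    y_is = 1 if c_is >= t_s else 0

with the annual threshold `t_s` taken from the shipped taxonomy. The
threshold is read as *inclusive*: the published description fixes only the
exclusion side ("fewer than threshold" does not qualify), and `>=` is the
reading consistent with it. "Patient interactions" are operationalized as
claim events (`n_events`-weighted claim lines), not distinct patients or
service dates: the claims schema carries no patient identifiers, so
same-day multiple billings for one patient are counted separately. This is
a measurement assumption, not a modelling choice, and it biases `c_is`
upward relative to a distinct-patient count; with thresholds calibrated on
the same event scale the binary indicators are unaffected.

Code matching is exact on normalized strings (trimmed, uppercased).
Precedence is explicit codes and ranges first, suffix rules last, because
several anaesthesia codes carry a `C` suffix yet are explicitly listed —
generic suffix capture must never override explicit ownership. Codes
matching nothing are tallied as *unclassified* and reported in the run log:
under a sentinel design all activity in unlisted codes is invisible, so
provider counts are lower bounds, and the unclassified tally is the
magnitude of that caveat for a given dataset.

## Stratification

* **Geography**: north iff the physician's health-region code is in the
  configured north set (default: the two former northern LHINs,
  `LHIN-13`/`LHIN-14`). Membership is configuration, not geometry, so other
  jurisdictions can redefine it without code changes.
* **Rurality**: rural iff RIO score >= `rural_cutoff` (default 40, the
  conventional cutoff for this index; inclusive per its published use).
* **Career stage**: years in practice binned [0,10), [10,20), [20,30),
  [30,∞). Fractional years are allowed; the integer bin labels are read as
  half-open intervals.

The four regions and four stages each partition the cohort by construction
(tested as properties).

## Summary tables and disclosure control

Cross-tabulations report counts with integer percentages of the stratum
denominator, where the denominator is *all* physicians assigned to the
stratum, including those providing zero defined services (such physicians
appear in a separate diagnostic row, not in the published-style 1..>=8
distribution). Percentages round half-up; this convention reproduces every
checkable percentage in the packaged reference summary, which is why it was
adopted.

Suppression follows the single-cell rule used for small counts in Ontario
health-administrative reporting: counts in [1, 6] display as `<=6`; zeros
are genuine zeros and are displayed. A total over a row with k suppressed
cells becomes the range `[unsuppressed_sum + k, unsuppressed_sum + 6k]`,
the exact interval implied by each suppressed cell lying in [1, 6]; this
rule reproduces all four range totals in the reference summary. Raw counts
remain attached to cells internally, so suppression is a pure display
transformation and idempotent. Percentages are computed from the raw count
even for suppressed cells (as the reference table itself does); the
suppression masks the count display only. No complementary suppression
across rows or columns is attempted.

## Service combinations

Combination analysis restricts each physician's provided set to the k
most-provided services (default k = 6, ranked by total provider count over
the whole cohort; ties break by taxonomy order). Counting is *exclusive* —
each physician contributes to exactly one combination, the one equal to
their restricted set — so combination counts partition the stratum,
including an explicit empty combination. Global top-k selection is the
default because the published analysis captions every regional plot with
the same six services; per-region selection is available via the `scope`
argument. Inclusive ("at least these services") counting exists behind a
flag for sensitivity analyses and deliberately breaks the partition law.
The exporter emits a boolean membership matrix with counts, proportions and
career-stage composition, the structure UpSet plotting tools consume;
figure rendering is out of scope.

## The reference fixture

`fpscope/data/reference_summary.yaml` transcribes the published 2017
Ontario regional summary (counts, printed percentages, suppressed markers,
range totals) and is sha256-checked at load. Suppressed cells have unknown
raw counts; everything derivable from the printed numbers — row totals,
percentages, ranges, block consistency, the northern share — is recomputed
by `run_validate_fixture` (167 checks). The fixture records both the
province-wide cohort figure (14,443) and the stratum sum (12,984) without
reconciling them; the gap is unexplained in the source and plausibly
reflects physicians unassignable to a region stratum.

## The synthetic-cohort generator

The generator emulates the statistical shape of the analysis inputs:

* stratum sizes, sex shares, career-stage mixes and per-stratum
  provision probabilities default to the reference summary's exact cell
  ratios (e.g. clinic in the north-rural stratum: 259/293). Count ratios
  are used instead of the printed integer percentages because the printed
  south-urban stage percentages sum to 99%, while the counts are exactly
  consistent. A suppressed reference cell gets the nominal small
  probability 0.5 × 6 / stratum size.
* provider status is drawn independently per service. The real joint
  distribution of services is unpublished; independence is a declared
  simplification. Consequently synthetic combination profiles have no
  built-in service correlations (e.g. emergency medicine with hospital
  medicine), and passing combination tests demonstrates counting
  correctness, not realism of the joint distribution.
* annual counts: a provider of service s draws
  `t_s + NegBin(mean = 2·t_s, dispersion 1.5)` (overdispersed annual
  volumes); a non-provider draws 0 with probability 0.7, else uniform on
  [1, t_s − 1]. This guarantees exact agreement between planted provider
  flags and pipeline classifications, which is what makes truth-table
  tests sharp; "leaky" count models for boundary stress-tests are
  constructed in the tests by perturbing claims.
* counts are spread multinomially over the service's explicit codes;
  surgical assisting (defined only by the suffix rule) samples from three
  synthetic suffix-`B` codes verified to match no other service; noise
  claims (Poisson, mean 5 per physician) use codes verified non-sentinel.
* RIO scores are uniform on [40, 100] for rural and [0, 39] for urban
  physicians; years in practice are uniform within the drawn career bin
  (30–45 for the open bin). Neither distribution is published; only the
  bin/cutoff semantics matter downstream.

All randomness flows from a single integer seed through one NumPy
generator; identical configs yield identical cohorts byte for byte.

What the generator does **not** emulate: patient-level structure (visit
timing, repeat patients), dollar amounts, shadow billing, specialist
contamination of the cohort, regional differences in coding practice, and
service-service correlation. Tests passing on synthetic data therefore
validate the pipeline's logic and statistical recovery under the stated
model, not the substantive accuracy of any real-world profile.

## Numerical and degenerate-input choices

* Percentage rounding: decimal half-up at the requested precision; a zero
  denominator raises rather than returning 0 or NaN.
* Range notation `Z491-Z499` is matched symbolically by prefix + fixed-width
  numeric comparison (never pre-expanded for matching, only for uniqueness
  validation), so the shipped registry stays auditable.
* Duplicate codes *within* one service's list are collapsed silently
  (the shipped list repeats two codes — transcription artifacts); the same
  code under two *different* services is a hard configuration error.
* Empty cohorts produce all-zero tables; an empty combination record is
  emitted explicitly so the partition law is visible even when no
  physician matches.
* Registry rows failing field validation are rejected individually with
  row-numbered diagnostics; duplicated physician ids and missing columns
  abort the read.

## Problem sizes

The test suite exercises cohorts of 250–5,000 physicians per stratum.
The parameter-recovery experiment uses 5,000 physicians per stratum
(~1.2M claim rows), at which the 99% binomial intervals for all 72
region × service provision cells are a few tenths of a percentage point
wide — tight enough to detect classification or bookkeeping errors while
keeping a full run under a minute.

## Known limitations

* Exact-match semantics: suffixed variants of listed codes (e.g. a
  hypothetical `A001A`) do not match `A001`. How such variants were handled
  upstream is unspecified; exact match is the conservative choice.
* Single-year scope: thresholds are annual, so multi-year inputs must be
  run per year; no longitudinal linkage is provided.
* The sentinel design cannot see services billed under non-sentinel codes,
  under capitation without shadow billing, or outside the public plan;
  provider counts are lower bounds by construction.
* Disclosure control implements the single-cell rule only; a release
  process requiring complementary suppression needs additional tooling.
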