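# Methods

This note records the models, defaults, and design choices behind
`seasonwatch`, and what the synthetic benchmark does and does not show.

## Query language and matching

Queries are conjunctions of OR-groups over words and quoted phrases.  OR
binds tighter than AND (`a OR b AND c` ≡ `(a OR b) AND c`), and AND nested
inside an OR-group is rejected so every query stays in
conjunction-of-disjunctions form and serializes canonically.  Curly and
straight quotes both delimit phrases.

Matching is **exact-token**: text is case-folded, URLs removed, `#` and
`@` stripped (so a hashtag like `#mothapocalypse` is one opaque token that
matches nothing), and tokens are maximal Unicode-letter runs.  A word term
matches a whole token; a phrase matches consecutive tokens.  We
deliberately do not stem at match time — platform search engines behave
inconsistently on morphology, and exact-token semantics are deterministic
and documentable.  An opt-in `stem_match=True` stems both sides.  One
consequence worth knowing: usernames containing separators
(`@koel_fan`) split into their pieces and can match, which is precisely
the username-noise contamination observed with short vernacular names.

## Term mining for symptomatic queries

The seed corpus (hits of a common-name query) is preprocessed in a fixed
order: lowercase → remove digits → remove punctuation → whitespace
tokenize → drop stopwords → stem.  The stemmer is an in-package
implementation of the classic Porter (1980) English algorithm, tested
against the algorithm's published rule examples.  The stopword list is a
pinned file shipped with the package — a snowball-style English function-word
list extended with the one-letter/contraction fragments that punctuation
stripping leaves behind (`100s` → `s`, `don't` → `dont`).  Content-ish
high-frequency words (`just`, `one`, `now`, `can`, `time`, …) are *not*
stopwords: in practice they survive this kind of pipeline and show up in
mined vocabularies, and removing them would silently change which
symptomatic queries get built.  Terms appearing at least 5 times qualify
as frequent (threshold boundary inclusive); ties in the frequency ranking
break lexicographically.

Note the mined table is stemmed (`calling` → `call`), while query terms
are stored unstemmed; both stemmed and raw tables can be inspected.

## Signal-to-noise ratio

SNR = n_relevant / n_hits on manually labelled hits; undefined (an error,
reported as "–") for zero-hit queries.  Percentages round half away from
zero (88/98 → 89.8 → 90).  For hit sets too large to label, a subsample
stratified by calendar (year, month) is drawn: s_m = round(f·n_m) per
month, minimum 1 for a non-empty month, simple random sampling without
replacement inside each month, reproducible from a named seeded generator
(NumPy PCG64).  The default estimator on the labelled subsample is the
plain ratio — under proportional allocation it coincides with the
stratum-weighted estimator Σ_m (n_m/N)(rel_m/s_m), which is also available.
One known discrepancy in the motivating material: the first moth
symptomatic query's SNR is quoted as 55% in prose but its labelled counts
give 308/520 = 59%; we follow the counts.

## Weekly aggregation and coverage gaps

Weeks start Monday and are half-open; counts are zero-filled.  A week
whose every in-period day lies inside a declared unreliable-capture gap is
masked *missing* (its zero means "no data", not "no tweets"); a week
partially covered by a gap keeps the count from its available days and is
flagged *partial*.  AR fitting uses the longest contiguous non-missing
segment and requires n ≥ 5p + 10; how the original analysis handled its
capture gap is not stated, and this rule is our own conservative choice.

## AR prewhitening

ACF uses the biased autocovariance denominator (lag-0), PACF the
Durbin–Levinson recursion on those autocorrelations, so pacf[1] ≡ acf[1]
identically; both are cross-checked against statsmodels in the tests.
The approximate 95% white-noise band is ±1.96/√n.

AR(p) is fit by conditional least squares — OLS of y_t on
(1, y_{t−1}, …, y_{t−p}) — via `statsmodels.tsa.ar_model.AutoReg`, giving
n − p residuals with mean zero by the normal equations; p = 0 degenerates
to mean-centering.  CLS rather than exact MLE because it is closed-form
and oracle-checkable against a direct normal-equations solve; at these
series lengths the difference is negligible.  Residuals are standardized
by the residual sample standard deviation (ddof = 1), so the z series has
unit sample sd exactly.  Diagnostics report residual-ACF exceedances over
10 lags plus a Ljung–Box portmanteau at lag 10 (df = 10, undadjusted for
fitted parameters, matching the brute formula n(n+2)Σ r_k²/(n−k));
"independent" means ≤ 1 exceedance and p > 0.05.

### Automatic order selection

The automated stand-in for reading a PACF plot takes the largest lag
whose |PACF| clears the significance band, with the band
Bonferroni-adjusted for the `max_lag` (default 8) lags inspected jointly:
z_{1−0.025/max_lag}/√n.  With the unadjusted per-lag band the rule is
structurally unreliable — the chance of *some* spurious exceedance among
the lags above the true order is 1 − 0.95^(max_lag−p) ≈ 23% for p = 3,
max_lag = 8 — whereas an analyst looking at the plot discounts exactly
those isolated marginal spikes.  The adjusted rule recovers p = 3 for
simulated AR(3) at n = 1000 in ≈ 97% of replicates and still returns 0
for white noise ≈ 95% of the time.  Hand-chosen orders (as used for the
real weekly series, lags 1–5) bypass the rule entirely via
`fit_ar(series, p)` or `detect_arrivals(weeks, order=p)`.

## CUSUM chart

Two-sided tabular CUSUM on z with reference value k = 0.5 and decision
interval h = 5 — the conventional defaults for detecting a 1 sd shift
(k = shift/2) with a five-sigma decision interval, and the defaults of the
standard quality-control packages.  A violation is recorded at *every*
index where C⁺ > h or C⁻ < −h, so a sustained excursion produces a run of
alarms; event timing uses the first.  Violations map back to calendar
weeks offset by the AR order (the conditional fit consumes the first p
weeks as lags).  Seasonal scoring uses upper violations only: arrivals
add posts, and the validation question is specifically whether the
increase falls in Spring.  A +2σ step shift accrues C⁺ by 1.5 per point
and therefore first alarms at the 4th shifted point (C⁺ = 6 > 5).

## Seasonal scoring

Spring windows are 1 September – 30 November inclusive, one per year
intersecting the coverage period, labelled by their year.  A season is
detected iff an upper-violation week overlaps its window; detection delay
is counted from the true arrival date to the *start* of the first such
week (the original analysis reports no delay metric; synthetic
benchmarking needs one, and week-start is the conservative anchor
available without daily resolution).  Upper violations overlapping no
window count as out-of-season alarms.  Ground-truth normalizations —
percent of total patch volume per survey, and the 12-month sighting
profile — are over the season's total, so each series sums to 100.

## Synthetic streams

Text is bag-of-words from fixed vocabularies — enough for token-boundary
matching, with no pretence of language.  Independent Poisson processes
per day: background chatter (default 20–30 posts/day at the scale of a
city-filtered topic stream), an arrival pulse per arrival date (linear
rise over 7 days to 20 posts/day, then exponential decay with 10-day
half-life — attention captures the arrival only), and optional confounder
bursts whose posts always carry their full shared vocabulary so they
collide with a symptomatic query at the nominal burst rate.  Decoy
channels inject query tokens into background posts with configured
probability; when a target SNR is given the collision probability is
calibrated in expectation from q = R(1 − s)/(sB).  Relevance labels are
structural (pulse membership), and gap-day posts are dropped with exact
bookkeeping.  Surveys draw patch counts Poisson in a logistic occupancy
curve (zero before arrival) with log-normal patch dimensions.

The canonical two-season study (`two_season_study`) fixes the conditions
for the headline contrast: a 23-month window spanning two Springs, first
arrival anchored at 7 September 2013, pulse posts carrying both the
species name and call-description tokens so that a common-name query
("koel", target SNR 0.9) and a symptomatic query ("bird AND call",
background collision 0.9, realized SNR ≈ 0.04) retrieve *identical*
relevant volume, plus a 3-week February confounder burst.  Under these
conditions the common-name route detects essentially every Spring arrival
while the symptomatic route detects almost none and alarms at the
confounder instead.

What this does **not** show: real streams have non-stationary background
attention, media-feedback cascades (second waves of reporting), retweet
duplication, and vocabulary drift, none of which the generator emulates.
Passing the synthetic benchmark demonstrates that the pipeline detects
what it is designed to detect under its stated assumptions — not that any
particular real query will enjoy a 90% SNR.

## Numerical choices and degenerate inputs

Constant series raise rather than return NaN autocorrelations; zero
residual sd blocks standardization; zero-hit queries have undefined SNR;
all-zero survey volumes and all-zero monthly counts are rejected.
Zero-inflated weekly counts are charted as-is (no transformation), since
the procedure applies the chart to residuals of the raw counts.  All
random draws in the package come from `numpy.random.default_rng` (PCG64)
seeded explicitly; streams, truths, and test series are pure functions of
(config, seed).

## Known limitations

* Exact-token matching understates hit counts relative to a platform
  search engine that does morphological expansion; `stem_match` is the
  escape hatch, and neither mode is claimed to reproduce any platform's
  retrieval.
* The automatic order selector is one mechanization of plot-reading;
  hand-chosen orders for real series are first-class inputs, and the two
  paths are not asserted to agree.
* The CUSUM h and k are fixed defaults; the package does not tune them,
  and raising h cannot rescue a low-SNR query whose alarms are driven by
  confounders.
* Location inference, deduplication/retweet semantics, and live API
  ingestion are out of scope; streams are accepted as already filtered to
  the region of interest.
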