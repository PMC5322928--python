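# seasonwatch

Can the arrival of a migratory species be detected from a social-media text
stream?  `seasonwatch` is a pipeline for that question, built around two
model systems: an insect that migrates to a city every Southern-Hemisphere
Spring and is a beloved local phenomenon, and a migratory cuckoo the same
public mostly knows only by its call.  The same machinery applies to any
syndromic-surveillance setting where posts mentioning an organism are
sparse, noisy, and seasonal — e.g. early warning for biosecurity
incursions.

The pipeline has four stages:

1. **Queries** (`seasonwatch.querylang`) — boolean keyword queries
   (conjunctions of OR-groups of words and quoted phrases) in three
   styles: *taxonomic* (scientific name), *common-name* (vernacular), and
   *symptomatic* (descriptive words indicating presence without naming the
   species).  Symptomatic queries are built by mining frequent terms
   (Porter-stemmed, stopword-filtered, threshold ≥ 5 occurrences) from the
   hits of a common-name search.
2. **Relevance** (`seasonwatch.relevance`) — query quality as a
   signal-to-noise ratio, SNR = (relevant hits) / (total hits), computed
   exactly from labelled hits or estimated from a month-stratified random
   subsample when the hit set is too large to label.
3. **Detection** (`seasonwatch.surveillance`) — weekly hit counts are
   prewhitened with an autoregressive model fit by conditional least
   squares (order read off the PACF, or supplied by hand), and a two-sided
   tabular CUSUM is run on the standardized residuals
   z<sub>t</sub> = e<sub>t</sub>/σ̂:

   C⁺<sub>t</sub> = max(0, C⁺<sub>t−1</sub> + z<sub>t</sub> − k),  C⁻<sub>t</sub> = min(0, C⁻<sub>t−1</sub> + z<sub>t</sub> + k),

   with reference value k = 0.5 and decision interval h = 5.  The process
   is out of control above the upper decision bound (C⁺ > h) or below the
   lower one (C⁻ < −h).
4. **Validation** (`seasonwatch.validation`) — an upper alarm during
   Spring (September–November) counts as detecting that season's arrival;
   upper alarms outside every Spring window are out-of-season false
   alarms.  Ground truth comes from transect surveys (patch volumes as
   percent of the season total) or historical monthly counts (12-month
   percentage profile).

A synthetic-data module (`seasonwatch.synthetic`) generates streams with
the structure the analysis assumes — Poisson background chatter, an
arrival pulse with sharp onset and exponential decay, decoy vocabulary
collisions at a calibrated rate, and out-of-season confounder bursts — so
the entire pipeline runs and is tested without any external data.

## Worked example

```python
from seasonwatch.querylang import parse_query, run_query
from seasonwatch.relevance import compute_snr
from seasonwatch.surveillance import detect_arrivals, weekly_counts
from seasonwatch.synthetic import STUDY_ARRIVALS, generate_stream, two_season_study
from seasonwatch.validation import evaluate, spring_windows

cfg = two_season_study(seed=7)          # 23-month stream, two Spring arrivals
records, manifest = generate_stream(cfg)
print(f"stream: {manifest.n_records} posts, {manifest.n_pulse} from the arrival pulse")

query = parse_query("koel")
hits = run_query(query, records)
n_rel = sum(r.relevance == "relevant" for r in hits)
print(f"query 'koel': {len(hits)} hits, SNR {compute_snr(n_rel, len(hits)).snr_percent}%")

weeks = weekly_counts(hits, cfg.period)
result = detect_arrivals(weeks)         # PACF order -> AR fit -> CUSUM
metrics = evaluate(result["events"], spring_windows(cfg.period), list(STUDY_ARRIVALS))
for season in metrics.seasons:
    print(f"Spring {season.year}: detected={season.detected}, delay={season.delay_days} days")
```

prints

```
stream: 22345 posts, 744 from the arrival pulse
query 'koel': 825 hits, SNR 90%
Spring 2013: detected=True, delay=2 days
Spring 2014: detected=True, delay=2 days
```

The common-name query keeps 90% of its hits relevant, and the CUSUM flags
both Spring arrivals within days.  Running the symptomatic query
`bird AND call` on the *same* stream (identical relevant posts) drops the
SNR below 5%: the arrival signal drowns in generic chatter, detection
fails, and a February confounder burst sharing the query's vocabulary
raises out-of-season alarms — the failure mode that makes low-SNR
symptomatic surveillance unreliable.

A CLI mirrors the stages: `seasonwatch simulate | query | snr | detect |
validate` (see `seasonwatch --help`).

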