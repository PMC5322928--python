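"""Synthetic tweet streams, ground truth, and raw test series.

The generator reproduces the statistical structure the detection pipeline
assumes, so the whole analysis runs with no external data:

* a low-rate background stream of irrelevant chatter (Poisson per day)
  drawn from a filler vocabulary, with *decoy channels* that inject
  query-colliding tokens into background posts at a configurable rate;
* a seasonal arrival pulse of relevant posts — sharp onset at the arrival
  date, short rise, then exponential decay (public attention captures the
  arrival only, not the species' continued presence);
* optional out-of-season confounder bursts whose vocabulary shares tokens
  with the queries (the "popular game with 'bird' in its name" effect);
* transect-style surveys whose patch volumes follow a logistic occupancy
  curve after arrival, and a 12-month sighting profile.

Text is bag-of-words: sufficient for token-boundary query matching, with
no pretence of grammar.  All draws come from one seeded NumPy generator
per call, so every output is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Sequence

import numpy as np

from .tweetstore import CoveragePeriod, TweetRecord
from .validation import (
    GroundTruthSeries,
    MonthlyProfile,
    SurveyRecord,
    monthly_profile,
    percent_volume,
)

__all__ = [
    "DecoyChannel",
    "ConfounderBurst",
    "StreamConfig",
    "TruthConfig",
    "StreamManifest",
    "generate_stream",
    "generate_truth",
    "generate_ar",
    "inject_shift",
    "two_season_study",
    "STUDY_ARRIVALS",
    "STUDY_COMMON_QUERY",
    "STUDY_SYMPTOMATIC_QUERY",
]

_FILLER = (
    "today", "work", "coffee", "rain", "weekend", "game", "footy", "traffic",
    "lunch", "weather", "canberra", "city", "home", "news", "photo", "great",
    "tired", "monday", "friday", "beach", "garden", "dinner", "music", "road",
)

_RELEVANT_EXTRA = (
    "arrived", "tonight", "everywhere", "swarm", "back", "spring", "heard",
    "first", "saw", "window", "porch", "light", "season",
)


@dataclass(frozen=True)
class DecoyChannel:
    """Inject ``tokens`` into a background post with probability ``probability``."""

    tokens: tuple[str, ...]
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("decoy probability must lie in [0, 1]")
        if not self.tokens:
            raise ValueError("decoy channel needs at least one token")


@dataclass(frozen=True)
class ConfounderBurst:
    """Out-of-season burst sharing vocabulary with the queries."""

    start: date
    duration_days: int
    rate: float  # posts/day
    vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.duration_days <= 0 or self.rate < 0:
            raise ValueError("burst needs positive duration and non-negative rate")


@dataclass(frozen=True)
class StreamConfig:
    """Study conditions for one synthetic stream.

    ``baseline_rate`` is irrelevant posts/day; the pulse peaks at
    ``pulse_peak`` relevant posts/day ``pulse_rise_days`` after each
    arrival and then decays with half-life ``pulse_half_life_days``.
    ``target_snr`` calibrates a decoy channel on ``signal_tokens`` so that
    the expected fraction of query hits that are relevant equals it.
    """

    period: CoveragePeriod
    arrival_dates: tuple[date, ...]
    baseline_rate: float = 20.0
    pulse_peak: float = 20.0
    pulse_rise_days: int = 7
    pulse_half_life_days: float = 10.0
    signal_tokens: tuple[str, ...] = ("bogong", "moth")
    relevant_extra_vocab: tuple[str, ...] = _RELEVANT_EXTRA
    decoys: tuple[DecoyChannel, ...] = ()
    target_snr: float | None = None
    confounders: tuple[ConfounderBurst, ...] = ()
    verifiable_prob: float = 0.25
    true_positive_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.pulse_peak < 0:
            raise ValueError("rates must be non-negative")
        for a in self.arrival_dates:
            if not self.period.contains(a):
                raise ValueError(f"arrival date {a} outside period")
        if self.target_snr is not None and not 0.0 < self.target_snr <= 1.0:
            raise ValueError("target_snr must lie in (0, 1]")


@dataclass(frozen=True)
class StreamManifest:
    """Exact bookkeeping of one realized stream."""

    n_background: int
    n_pulse: int
    n_confounder: int
    n_dropped_in_gaps: int
    n_records: int
    collision_probability: float
    arrival_dates: tuple[date, ...]


def _pulse_rate(day: date, cfg: StreamConfig) -> float:
    rate = 0.0
    for arrival in cfg.arrival_dates:
        t = (day - arrival).days
        if t < 0:
            continue
        rise = min(1.0, (t + 1) / cfg.pulse_rise_days)
        decay = (
            math.exp(-math.log(2.0) * (t - cfg.pulse_rise_days) / cfg.pulse_half_life_days)
            if t > cfg.pulse_rise_days
            else 1.0
        )
        rate += cfg.pulse_peak * rise * decay
    return rate


def _expected_pulse_total(cfg: StreamConfig) -> float:
    day = cfg.period.start
    total = 0.0
    while day < cfg.period.end:
        if not cfg.period.in_gap(day):
            total += _pulse_rate(day, cfg)
        day += timedelta(days=1)
    return total


def _calibrated_collision(cfg: StreamConfig) -> float:
    """Decoy probability on signal tokens implied by the target SNR.

    With expected relevant hits R and expected background posts B, a
    per-post collision probability q gives SNR = R / (R + qB); solve for q
    and clip to [0, 1].
    """
    if cfg.target_snr is None:
        return 0.0
    n_days = sum(
        1
        for i in range((cfg.period.end - cfg.period.start).days)
        if not cfg.period.in_gap(cfg.period.start + timedelta(days=i))
    )
    expected_bg = cfg.baseline_rate * n_days
    expected_rel = _expected_pulse_total(cfg)
    if expected_bg == 0.0:
        return 0.0
    q = expected_rel * (1.0 - cfg.target_snr) / (cfg.target_snr * expected_bg)
    return min(1.0, q)


def _timestamp(day: date, rng: np.random.Generator) -> datetime:
    sec = int(rng.integers(0, 86400))
    return datetime(day.year, day.month, day.day, tzinfo=timezone.utc) + timedelta(
        seconds=sec
    )


def _bag(rng: np.random.Generator, vocab: Sequence[str], lo: int, hi: int) -> list[str]:
    n = int(rng.integers(lo, hi + 1))
    return [vocab[i] for i in rng.integers(0, len(vocab), size=n)]


def generate_stream(
    config: StreamConfig, seed: int | None = None
) -> tuple[list[TweetRecord], StreamManifest]:
    """Draw one stream; returns timestamp-sorted records plus bookkeeping.

    Latent relevance is structural: a record is labelled relevant iff it
    was emitted by the pulse process.  Records whose day falls inside a
    coverage gap are dropped (the collector was down), and the manifest
    accounts for them exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    collision = _calibrated_collision(config)
    decoys = config.decoys
    if collision > 0.0:
        decoys = decoys + (DecoyChannel(config.signal_tokens, collision),)

    drafts: list[tuple[datetime, str, str]] = []  # (ts, text, process)
    n_bg = n_pulse = n_conf = n_dropped = 0
    day = config.period.start
    while day < config.period.end:
        in_gap = config.period.in_gap(day)
        k_bg = int(rng.poisson(config.baseline_rate))
        k_pulse = int(rng.poisson(_pulse_rate(day, config)))
        burst_draws = [
            (burst, int(rng.poisson(burst.rate)))
            for burst in config.confounders
            if burst.start <= day < burst.start + timedelta(days=burst.duration_days)
        ]
        k_conf = sum(k for _, k in burst_draws)
        n_bg += k_bg
        n_pulse += k_pulse
        n_conf += k_conf
        if in_gap:
            n_dropped += k_bg + k_pulse + k_conf
            day += timedelta(days=1)
            continue
        for _ in range(k_bg):
            words = _bag(rng, _FILLER, 4, 8)
            for ch in decoys:
                if rng.random() < ch.probability:
                    words.extend(ch.tokens)
            rng.shuffle(words)
            drafts.append((_timestamp(day, rng), " ".join(words), "background"))
        for _ in range(k_pulse):
            words = list(config.signal_tokens)
            words += _bag(rng, config.relevant_extra_vocab, 2, 4)
            words += _bag(rng, _FILLER, 1, 3)
            rng.shuffle(words)
            drafts.append((_timestamp(day, rng), " ".join(words), "pulse"))
        for burst, k in burst_draws:
            for _ in range(k):
                # every burst post carries the full shared vocabulary, so the
                # burst collides with the query at its nominal rate
                words = list(burst.vocabulary)
                words += _bag(rng, _FILLER, 2, 4)
                rng.shuffle(words)
                drafts.append((_timestamp(day, rng), " ".join(words), "confounder"))
        day += timedelta(days=1)

    drafts.sort(key=lambda d: d[0])
    records = []
    for i, (ts, text, process) in enumerate(drafts):
        relevance = "relevant" if process == "pulse" else "irrelevant"
        verifiability = None
        if relevance == "relevant":
            if rng.random() < config.verifiable_prob:
                verifiability = (
                    "verifiable_true_positive"
                    if rng.random() < config.true_positive_prob
                    else "verifiable_false_positive"
                )
            else:
                verifiability = "unverifiable"
        records.append(
            TweetRecord(
                id=f"syn-{i:08d}",
                timestamp=ts,
                text=text,
                relevance=relevance,
                verifiability=verifiability,
            )
        )
    manifest = StreamManifest(
        n_background=n_bg,
        n_pulse=n_pulse,
        n_confounder=n_conf,
        n_dropped_in_gaps=n_dropped,
        n_records=len(records),
        collision_probability=collision,
        arrival_dates=config.arrival_dates,
    )
    assert manifest.n_records == n_bg + n_pulse + n_conf - n_dropped
    return records, manifest


# --- canonical two-season study conditions -----------------------------
#
# A 23-month coverage window spanning two Southern-Hemisphere Springs, with
# the first arrival anchored to the documented 7 September 2013 first
# sighting.  Every relevant (pulse) post names the species AND describes
# its call, so one stream supports both query styles on identical relevant
# volume: the common-name query ("koel") sees only the calibrated decoy
# collisions (target SNR 0.9), while the symptomatic query ("bird AND
# call") additionally collects 90% of the generic background chatter plus
# a late-summer confounder burst that shares its vocabulary.

STUDY_PERIOD = (date(2013, 7, 1), date(2015, 6, 1))
STUDY_ARRIVALS = (date(2013, 9, 7), date(2014, 9, 20))
STUDY_COMMON_QUERY = "koel"
STUDY_SYMPTOMATIC_QUERY = "bird AND call"


def two_season_study(seed: int = 0, confounder: bool = True) -> StreamConfig:
    """Study conditions for the headline high- vs low-SNR contrast.

    Baseline 30 irrelevant posts/day; arrival pulses peaking at 20
    relevant posts/day (far above the common-name query's decoy background
    of well under 1 hit/day); a 3-week out-of-season burst in February
    2015 when ``confounder`` is set.
    """
    confounders = ()
    if confounder:
        confounders = (
            ConfounderBurst(
                start=date(2015, 2, 1),
                duration_days=21,
                rate=40.0,
                vocabulary=("bird", "call", "flappy", "game"),
            ),
        )
    return StreamConfig(
        period=CoveragePeriod(*STUDY_PERIOD),
        arrival_dates=STUDY_ARRIVALS,
        baseline_rate=30.0,
        pulse_peak=20.0,
        pulse_rise_days=7,
        pulse_half_life_days=10.0,
        signal_tokens=("koel", "bird", "call"),
        decoys=(DecoyChannel(("bird", "call"), 0.9),),
        target_snr=0.9,
        confounders=confounders,
        seed=seed,
    )


@dataclass(frozen=True)
class TruthConfig:
    """Survey schedule plus the latent occupancy curve that drives volumes.

    Occupancy is zero before arrival, rises logistically over roughly
    ``rise_scale_days``, plateaus, and declines around ``departure_date``.
    Patch counts are Poisson in occupancy; dimensions are log-normal in cm.
    """

    survey_dates: tuple[date, ...]
    arrival_date: date
    departure_date: date
    rise_scale_days: float = 10.0
    decline_scale_days: float = 14.0
    max_patches: int = 30
    dim_means_cm: tuple[float, float, float] = (20.0, 10.0, 4.0)
    dim_sigma: float = 0.3
    monthly_shape: tuple[float, ...] = (0, 0, 0, 0, 0, 0, 0, 1, 5, 10, 8, 3)
    monthly_years: int = 5
    monthly_scale: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arrival_date >= self.departure_date:
            raise ValueError("arrival must precede departure")
        if len(self.monthly_shape) != 12:
            raise ValueError("monthly_shape needs 12 entries")
        if all(d <= self.arrival_date for d in self.survey_dates):
            raise ValueError("survey schedule lies entirely before arrival")

    def occupancy(self, day: date) -> float:
        t = (day - self.arrival_date).days
        if t < 0:
            return 0.0
        rise = 1.0 / (1.0 + math.exp(-(t - self.rise_scale_days) / (self.rise_scale_days / 4.0)))
        u = (day - self.departure_date).days
        decline = 1.0 / (1.0 + math.exp(u / (self.decline_scale_days / 4.0)))
        return rise * decline


def generate_truth(
    config: TruthConfig, seed: int | None = None
) -> tuple[list[SurveyRecord], GroundTruthSeries, MonthlyProfile]:
    """Draw surveys and a monthly sighting profile consistent with arrival."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    surveys: list[SurveyRecord] = []
    for day in sorted(config.survey_dates):
        occ = config.occupancy(day)
        n_patches = int(rng.poisson(occ * config.max_patches))
        patches = tuple(
            tuple(
                float(m * math.exp(rng.normal(0.0, config.dim_sigma)))
                for m in config.dim_means_cm
            )
            for _ in range(n_patches)
        )
        surveys.append(SurveyRecord(day, "site-01", patches))
    truth = percent_volume(surveys, true_arrival_date=config.arrival_date)
    pairs = []
    for _ in range(config.monthly_years):
        for month in range(1, 13):
            lam = config.monthly_shape[month - 1] * config.monthly_scale
            pairs.append((month, int(rng.poisson(lam))))
    profile = monthly_profile(pairs)
    return surveys, truth, profile


def generate_ar(
    coefficients: Sequence[float],
    n: int,
    sigma: float = 1.0,
    seed: int = 0,
    intercept: float = 0.0,
) -> np.ndarray:
    """Simulate a stationary AR(p) series, discarding a burn-in of 10 p points."""
    phi = np.asarray(coefficients, float)
    p = len(phi)
    if p:
        roots = np.roots(np.r_[-phi[::-1], 1.0])
        if np.any(np.abs(roots) <= 1.0):
            raise ValueError("AR coefficients are not stationary")
    rng = np.random.default_rng(seed)
    burn = 10 * p
    e = rng.normal(0.0, sigma, size=n + burn)
    y = np.zeros(n + burn)
    for t in range(n + burn):
        lagged = sum(phi[i] * y[t - 1 - i] for i in range(min(p, t)))
        y[t] = intercept + lagged + e[t]
    return y[burn:]


def inject_shift(series: Sequence[float], t0: int, delta: float) -> np.ndarray:
    """Add ``delta`` to every point at index >= t0 (a sustained mean shift)."""
    x = np.asarray(series, float).copy()
    if not 0 <= t0 < len(x):
        raise IndexError(f"t0 = {t0} out of range for length {len(x)}")
    x[t0:] += delta
    return x
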