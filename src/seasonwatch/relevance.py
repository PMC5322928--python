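"""Signal-to-noise accounting for query hits.

The signal-to-noise ratio (SNR) of a query is the fraction of its hits that
a human judged relevant to the target species.  When a query returns more
hits than can be labelled by hand, a month-stratified random subsample is
labelled instead and the SNR is estimated from it; the summary is then
flagged approximate.  Relevant tweets are further split into verifiable
ones (a photo/video allows judging true vs false positive) and
unverifiable ones.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .tweetstore import TweetRecord

__all__ = [
    "RelevanceSummary",
    "SampleSpec",
    "VerifiabilitySummary",
    "UndefinedSNRError",
    "compute_snr",
    "stratified_sample",
    "estimate_snr",
    "verifiability_summary",
    "round_half_away",
]


class UndefinedSNRError(ZeroDivisionError):
    """SNR is undefined for a query with zero hits (reported as "-")."""


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (88/98 -> 90%)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class RelevanceSummary:
    n_hits: int
    n_relevant: int
    snr: float
    snr_percent: int
    approximate: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_relevant <= self.n_hits:
            raise ValueError("need 0 <= n_relevant <= n_hits")
        if not 0.0 <= self.snr <= 1.0:
            raise ValueError("snr must lie in [0, 1]")


@dataclass(frozen=True)
class SampleSpec:
    """Month-stratified sampling plan: per calendar month take a simple
    random sample of ``round(fraction * n_month)`` hits (at least one per
    non-empty month), reproducibly from ``seed``."""

    fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")


@dataclass(frozen=True)
class VerifiabilitySummary:
    n_relevant: int
    n_unverifiable: int
    n_verifiable_true_positive: int
    n_verifiable_false_positive: int

    def __post_init__(self) -> None:
        total = (
            self.n_unverifiable
            + self.n_verifiable_true_positive
            + self.n_verifiable_false_positive
        )
        if total != self.n_relevant:
            raise ValueError("verifiability categories must sum to n_relevant")


def compute_snr(n_relevant: int, n_hits: int, approximate: bool = False) -> RelevanceSummary:
    """Exact SNR = n_relevant / n_hits, with the rounded integer percent."""
    if n_hits == 0:
        raise UndefinedSNRError("SNR undefined for 0 hits")
    if n_relevant > n_hits:
        raise ValueError("n_relevant cannot exceed n_hits")
    snr = n_relevant / n_hits
    return RelevanceSummary(
        n_hits=n_hits,
        n_relevant=n_relevant,
        snr=snr,
        snr_percent=round_half_away(100.0 * snr),
        approximate=approximate,
    )


def _stratum(rec: TweetRecord) -> tuple[int, int]:
    return (rec.timestamp.year, rec.timestamp.month)


def stratum_sizes(hits: Sequence[TweetRecord]) -> dict[tuple[int, int], int]:
    """Hit count per calendar (year, month) stratum."""
    sizes: dict[tuple[int, int], int] = defaultdict(int)
    for rec in hits:
        sizes[_stratum(rec)] += 1
    return dict(sizes)


def stratified_sample(
    hits: Sequence[TweetRecord], spec: SampleSpec
) -> list[TweetRecord]:
    """Sample without replacement within each calendar month.

    Allocation is proportional: s_m = round(fraction * n_m), never below 1
    for a non-empty month.  The same seed always reproduces the same
    subsample; records never cross month boundaries.
    """
    if not hits:
        raise ValueError("hits must be non-empty")
    rng = np.random.default_rng(spec.seed)
    by_month: dict[tuple[int, int], list[int]] = defaultdict(list)
    for i, rec in enumerate(hits):
        by_month[_stratum(rec)].append(i)
    chosen: list[int] = []
    for month in sorted(by_month):
        idx = by_month[month]
        s_m = max(1, round_half_away(spec.fraction * len(idx)))
        s_m = min(s_m, len(idx))
        picked = rng.choice(len(idx), size=s_m, replace=False)
        chosen.extend(idx[j] for j in sorted(picked))
    chosen.sort()
    return [hits[i] for i in chosen]


def estimate_snr(
    labelled_subsample: Sequence[TweetRecord],
    strata_sizes: Mapping[tuple[int, int], int] | None = None,
    weighted: bool = False,
) -> RelevanceSummary:
    """Approximate SNR from a labelled subsample.

    Default estimator is the plain ratio relevant/sampled.  With
    ``weighted=True`` (requires ``strata_sizes``) each month is weighted by
    its share of total hits: sum_m (n_m/N) * (rel_m/s_m) — identical to the
    plain ratio under exactly proportional allocation.
    """
    unlabelled = [r.id for r in labelled_subsample if r.relevance is None]
    if unlabelled:
        raise ValueError(f"unlabelled records in subsample: {unlabelled}")
    n = len(labelled_subsample)
    if n == 0:
        raise UndefinedSNRError("cannot estimate SNR from an empty subsample")
    n_rel = sum(r.relevance == "relevant" for r in labelled_subsample)
    if not weighted:
        return compute_snr(n_rel, n, approximate=True)
    if strata_sizes is None:
        raise ValueError("weighted estimator needs strata_sizes")
    by_month: dict[tuple[int, int], list[TweetRecord]] = defaultdict(list)
    for rec in labelled_subsample:
        by_month[_stratum(rec)].append(rec)
    total = sum(strata_sizes.values())
    snr = 0.0
    for month, recs in by_month.items():
        n_m = strata_sizes[month]
        rel_m = sum(r.relevance == "relevant" for r in recs)
        snr += (n_m / total) * (rel_m / len(recs))
    return RelevanceSummary(
        n_hits=n,
        n_relevant=n_rel,
        snr=snr,
        snr_percent=round_half_away(100.0 * snr),
        approximate=True,
    )


def verifiability_summary(records: Sequence[TweetRecord]) -> VerifiabilitySummary:
    """Tally verifiability categories over relevant, fully labelled records."""
    counts = {v: 0 for v in ("unverifiable", "verifiable_true_positive", "verifiable_false_positive")}
    for rec in records:
        if rec.relevance != "relevant":
            raise ValueError(f"record {rec.id} is not labelled relevant")
        if rec.verifiability is None:
            raise ValueError(f"record {rec.id} has no verifiability label")
        counts[rec.verifiability] += 1
    return VerifiabilitySummary(
        n_relevant=len(records),
        n_unverifiable=counts["unverifiable"],
        n_verifiable_true_positive=counts["verifiable_true_positive"],
        n_verifiable_false_positive=counts["verifiable_false_positive"],
    )
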