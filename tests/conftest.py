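from datetime import date, datetime, timezone

import pytest

from seasonwatch.tweetstore import CoveragePeriod, TweetRecord


def make_record(
    i: int,
    when: datetime | date,
    text: str = "hello world",
    relevance: str | None = None,
    verifiability: str | None = None,
    geotag: tuple[float, float] | None = None,
) -> TweetRecord:
    if isinstance(when, date) and not isinstance(when, datetime):
        when = datetime(when.year, when.month, when.day, 12, 0, tzinfo=timezone.utc)
    return TweetRecord(
        id=f"t{i:06d}",
        timestamp=when,
        text=text,
        geotag=geotag,
        relevance=relevance,
        verifiability=verifiability,
    )


@pytest.fixture
def one_year_period() -> CoveragePeriod:
    return CoveragePeriod(date(2013, 7, 1), date(2014, 7, 2))


@pytest.fixture
def two_season_period() -> CoveragePeriod:
    return CoveragePeriod(date(2013, 7, 1), date(2015, 6, 1))
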