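import datetime as dt

import numpy as np
import pandas as pd
import pytest

from chronocollide.classify import (
    LR5_TO_LR3,
    annotate_records,
    assign_moon_day,
    classify_illumination,
    frequency_table,
    report_rate,
)
from chronocollide.ephemeris import NEW_MOON_ANCHOR, solar_events
from chronocollide.records import AccidentRecord


def _record(date, time):
    return AccidentRecord(date=date, time=time, species="roe deer")


# -- illumination -----------------------------------------------------------


def test_illumination_window_examples(config):
    date = dt.date(2004, 3, 20)
    solar = solar_events(date, config)
    dusk_plus_10 = (solar.sunset + dt.timedelta(minutes=10)).time()
    assert classify_illumination(_record(date, dusk_plus_10), solar, config) == ("DU", "TW")
    assert classify_illumination(_record(date, dt.time(12, 0)), solar, config) == ("DL", "DL")
    assert classify_illumination(_record(date, dt.time(23, 30)), solar, config) == ("NaD", "NI")


def test_boundaries_are_left_closed(config):
    date = dt.date(2004, 6, 10)
    solar = solar_events(date, config)
    at_sunrise = solar.sunrise.time().replace(second=0, microsecond=0)
    at_sunset = solar.sunset.time().replace(second=0, microsecond=0)
    # truncate to the minute grid, then step to the first minute inside
    sr = _record(date, at_sunrise)
    if dt.datetime.combine(date, at_sunrise, tzinfo=config.tzinfo) < solar.sunrise:
        sr = _record(date, (dt.datetime.combine(date, at_sunrise) + dt.timedelta(minutes=1)).time())
    assert classify_illumination(sr, solar, config)[0] == "DL"
    ss = _record(date, at_sunset)
    if dt.datetime.combine(date, at_sunset, tzinfo=config.tzinfo) < solar.sunset:
        ss = _record(date, (dt.datetime.combine(date, at_sunset) + dt.timedelta(minutes=1)).time())
    assert classify_illumination(ss, solar, config)[0] == "DU"


def test_missing_time_is_unclassifiable_not_an_error(config):
    date = dt.date(2004, 3, 20)
    solar = solar_events(date, config)
    assert classify_illumination(_record(date, None), solar, config) is None


def test_mismatched_solar_day_rejected(config):
    solar = solar_events(dt.date(2004, 3, 20), config)
    with pytest.raises(ValueError):
        classify_illumination(_record(dt.date(2004, 3, 21), dt.time(12, 0)), solar, config)


def test_lr3_collapse_is_consistent_on_synthetic_data(annotated):
    classified = annotated[annotated.lr5 != ""]
    assert (classified.lr5.map(LR5_TO_LR3) == classified.lr3).all()
    lr3_direct = classified.groupby("lr3").size()
    lr3_from_lr5 = classified.groupby(classified.lr5.map(LR5_TO_LR3)).size()
    assert lr3_direct.equals(lr3_from_lr5)


# -- moon day ---------------------------------------------------------------


def _at_age(age_days, config):
    t = (NEW_MOON_ANCHOR + dt.timedelta(days=age_days)).astimezone(config.tzinfo)
    # pick an anchor cycle inside the supported era and study window
    t = t + dt.timedelta(days=config.synodic_days * 50)
    return AccidentRecord(date=t.date(), time=t.time().replace(second=0, microsecond=0),
                          species="roe deer")


def test_moon_day_from_lunar_age(config):
    assert assign_moon_day(_at_age(14.9, config), config) == 15
    assert assign_moon_day(_at_age(0.1, config), config) == 1
    assert assign_moon_day(_at_age(29.2, config), config) is None  # day 30 dropped
    keep = config.replace(drop_moon_day_30=False)
    assert assign_moon_day(_at_age(29.2, keep), keep) == 30


def test_missing_time_defaults_to_local_noon_for_moon_day(config):
    rec = AccidentRecord(date=dt.date(2004, 5, 7), time=None, species="roe deer")
    noon = AccidentRecord(date=dt.date(2004, 5, 7), time=dt.time(12, 0), species="roe deer")
    assert assign_moon_day(rec, config) == assign_moon_day(noon, config)


# -- calendar labels --------------------------------------------------------


def test_day_of_year_merges_leap_day(config):
    recs = [
        _record(dt.date(2004, 2, 28), dt.time(1, 0)),
        _record(dt.date(2004, 2, 29), dt.time(1, 0)),
        _record(dt.date(2004, 3, 1), dt.time(1, 0)),
        _record(dt.date(2004, 12, 31), dt.time(1, 0)),
        _record(dt.date(2003, 12, 31), dt.time(1, 0)),
    ]
    ann = annotate_records(recs, config)
    assert ann.day_of_year.tolist() == [59, 59, 60, 365, 365]


def test_weekday_and_month_labels_follow_the_calendar(config):
    rec = _record(dt.date(2004, 5, 7), dt.time(21, 30))  # a Friday in May
    ann = annotate_records([rec], config)
    assert ann.weekday.iloc[0] == "Fri" and ann.month.iloc[0] == "May"


# -- frequency tables -------------------------------------------------------


def test_two_year_hand_computed_table():
    ann = pd.DataFrame(
        {
            "year": [1] * 4 + [2] * 4,
            "cat": ["A", "A", "A", "B", "A", "B", "B", "B"],
        }
    )
    table = frequency_table(ann, "cat")
    assert table.counts.loc["A"].tolist() == [3, 1]
    assert table.proportions.loc["A"].tolist() == [0.75, 0.25]
    assert table.mean.tolist() == [0.5, 0.5]
    assert table.sd.tolist() == pytest.approx([0.3535533906, 0.3535533906])


def test_equal_counts_give_zero_sd():
    ann = pd.DataFrame({"year": [1, 1, 2, 2], "cat": ["A", "B", "A", "B"]})
    table = frequency_table(ann, "cat")
    assert (table.mean == 0.5).all() and (table.sd == 0.0).all()


def test_proportions_sum_to_one_and_accounting_closes(annotated):
    for by in ("season", "month", "weekday", "lr3", "lr5", "moon_day"):
        table = frequency_table(annotated, by)
        np.testing.assert_allclose(table.proportions.sum(axis=0), 1.0, atol=1e-12)
        assert table.total + table.excluded == len(annotated)


def test_year_with_no_labelled_records_is_an_error():
    ann = pd.DataFrame({"year": [1, 1, 2], "cat": ["A", "B", ""]})
    with pytest.raises(ValueError, match="year"):
        frequency_table(ann, "cat")


# -- report rates -----------------------------------------------------------


def test_report_rate_arithmetic():
    rates = report_rate({2002: 2580}, {2002: 3173})
    assert rates.loc[0, "rate_pct"] == 81.31
    zero = report_rate({2002: 0}, {2002: 500})
    assert zero.loc[0, "rate_pct"] == 0.0
    with pytest.raises(ValueError):
        report_rate({2002: 10}, {2002: 0})


def test_pooled_rate_is_computed_from_summed_counts():
    rates = report_rate(
        {2002: 2580, 2003: 2574, 2004: 2354, 2005: 2040, 2006: 2223},
        {2002: 3173, 2003: 3238, 2004: 3185, 2005: 3029, 2006: 3190},
    )
    pooled = rates[rates.year == "total"].iloc[0]
    assert pooled.police == 11771 and pooled.hunting == 15815
    assert pooled.rate_pct == 74.43
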