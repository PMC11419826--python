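"""Lineage analytics against brute-force oracles and printed conventions."""

import random

import numpy as np
import pandas as pd
import pytest

from tmesim import (
    CellRecord,
    Fate,
    LineageDB,
    doubling_time_stats,
    event_totals,
    fate_patterns,
    lineage_summaries,
    md_reproductive_progeny,
    population_curve,
    summary_regression,
)

from conftest import small_random_db, toy_bd_db


def _alive_at(r: CellRecord, t: float, observation_end: float) -> bool:
    if r.fate is Fate.ALIVE_END:
        return r.birth_time <= t <= observation_end
    return r.birth_time <= t < r.fate_time


def _curve_oracle(db: LineageDB, times) -> np.ndarray:
    return np.array(
        [
            sum(_alive_at(r, t, db.observation_end) for r in db.records)
            for t in times
        ]
    )


def test_single_progenitor_constant_curve():
    db = LineageDB(
        [CellRecord(1, 0, (), 0.0, 1000.0, Fate.ALIVE_END)],
        observation_end=1000.0,
    )
    curve = population_curve(db)
    assert (curve.values == 1).all()


def test_curve_normalized_to_100_from_420_progenitors():
    records = [
        CellRecord(i, 0, (), 0.0, 500.0, Fate.ALIVE_END) for i in range(1, 421)
    ]
    db = LineageDB(records, observation_end=500.0)
    curve = population_curve(db, normalize_to=100)
    assert curve.iloc[0] == pytest.approx(100.0)
    # whole series scaled by 100/420
    assert np.allclose(curve.values, 420 * (100 / 420))


def test_empty_db_gives_zero_curve():
    db = LineageDB([], observation_end=100.0)
    assert (population_curve(db).values == 0).all()


@pytest.mark.parametrize("seed", range(6))
def test_curve_matches_interval_counting_oracle(seed):
    db = small_random_db(seed)
    curve = population_curve(db)
    assert (curve.values == _curve_oracle(db, curve.index.values)).all()


def test_event_totals_trivial_cases():
    db = LineageDB(
        [CellRecord(1, 0, (), 0.0, 300.0, Fate.CD)], observation_end=300.0
    )
    assert event_totals(db)[1] == {"MD": 0, "CD": 1, "CF": 0}

    tripolar = LineageDB(
        [
            CellRecord(1, 0, (), 0.0, 300.0, Fate.MD, md_poles=3),
            CellRecord(1, 1, (0,), 300.0, 600.0, Fate.ALIVE_END),
            CellRecord(1, 2, (0,), 300.0, 600.0, Fate.ALIVE_END),
            CellRecord(1, 3, (0,), 300.0, 600.0, Fate.ALIVE_END),
        ],
        observation_end=600.0,
    )
    assert event_totals(tripolar)[1]["MD"] == 1  # one event regardless of arity


@pytest.mark.parametrize("seed", range(6))
def test_event_totals_match_brute_force_tally(seed):
    db = small_random_db(seed)
    _, totals = event_totals(db)
    for fate in ("MD", "CD", "CF"):
        assert totals[fate] == sum(1 for r in db.records if r.fate.value == fate)


def test_fate_patterns_cf_then_bd():
    db = LineageDB(
        [
            CellRecord(1, 0, (), 0.0, 500.0, Fate.BD),
            CellRecord(1, 1, (0,), 500.0, 900.0, Fate.CF),
            CellRecord(1, 2, (0,), 500.0, 900.0, Fate.CF),
            CellRecord(1, 3, (1, 2), 900.0, 1400.0, Fate.BD),
            CellRecord(1, 4, (3,), 1400.0, 2000.0, Fate.ALIVE_END),
            CellRecord(1, 5, (3,), 1400.0, 2000.0, Fate.ALIVE_END),
        ],
        observation_end=2000.0,
    )
    patterns = fate_patterns(db)
    assert patterns["CF > BD"] == 1
    assert patterns.combined("BD") == 1


def test_fate_patterns_md_products_alive_end_uncounted():
    db = LineageDB(
        [
            CellRecord(1, 0, (), 0.0, 300.0, Fate.MD, md_poles=3),
            CellRecord(1, 1, (0,), 300.0, 800.0, Fate.BD),
            CellRecord(1, 2, (0,), 300.0, 700.0, Fate.CD),
            CellRecord(1, 3, (0,), 300.0, 900.0, Fate.ALIVE_END),
            CellRecord(1, 4, (1,), 800.0, 900.0, Fate.ALIVE_END),
            CellRecord(1, 5, (1,), 800.0, 900.0, Fate.ALIVE_END),
        ],
        observation_end=900.0,
    )
    patterns = fate_patterns(db)
    assert patterns["MD > BD"] == 1
    assert patterns["MD > CD"] == 1
    assert sum(patterns.counts[k] for k in patterns.counts if k.startswith("MD >")) == 2


@pytest.mark.parametrize("seed", range(6))
def test_fate_patterns_match_parent_child_scan(seed):
    db = small_random_db(seed)
    patterns = fate_patterns(db)
    oracle: dict[str, int] = {}
    for child in db.records:
        if child.fate not in (Fate.BD, Fate.MD, Fate.CD, Fate.CF):
            continue
        # one increment per product cell (a fusion product has two CF parents)
        parent_fates = {
            db.index[(child.lineage_id, pid)].fate for pid in child.parent_ids
        }
        for pf in parent_fates:
            if pf in (Fate.MD, Fate.CF):
                key = f"{pf.value} > {child.fate.value}"
                oracle[key] = oracle.get(key, 0) + 1
    for key, n in oracle.items():
        assert patterns[key] == n
    combined_total = sum(v for k, v in patterns.counts.items() if "+" not in k)
    assert sum(oracle.values()) == combined_total


def test_doubling_time_examples():
    db = LineageDB(
        [
            CellRecord(1, 0, (), 0.0, 100.0, Fate.BD),
            CellRecord(1, 1, (0,), 100.0, 1600.0, Fate.BD),
            CellRecord(1, 2, (0,), 100.0, 1900.0, Fate.ALIVE_END),
            CellRecord(1, 3, (1,), 1600.0, 1900.0, Fate.ALIVE_END),
            CellRecord(1, 4, (1,), 1600.0, 1900.0, Fate.ALIVE_END),
        ],
        observation_end=1900.0,
    )
    stats = doubling_time_stats(db)
    assert stats.n == 1
    assert stats.mean == 1500.0  # 25 h


def test_doubling_time_mean_min_max():
    db = LineageDB(
        [
            CellRecord(1, 0, (), 0.0, 100.0, Fate.BD),
            CellRecord(1, 1, (0,), 100.0, 1300.0, Fate.BD),
            CellRecord(1, 2, (0,), 100.0, 1900.0, Fate.BD),
            CellRecord(1, 3, (1,), 1300.0, 2000.0, Fate.ALIVE_END),
            CellRecord(1, 4, (1,), 1300.0, 2000.0, Fate.ALIVE_END),
            CellRecord(1, 5, (2,), 1900.0, 2000.0, Fate.ALIVE_END),
            CellRecord(1, 6, (2,), 1900.0, 2000.0, Fate.ALIVE_END),
        ],
        observation_end=2000.0,
    )
    stats = doubling_time_stats(db)
    assert (stats.mean, stats.min, stats.max) == (1500.0, 1200.0, 1800.0)


def test_doubling_time_empty_result():
    db = LineageDB(
        [CellRecord(1, 0, (), 0.0, 400.0, Fate.ALIVE_END)], observation_end=400.0
    )
    assert doubling_time_stats(db).empty


@pytest.mark.parametrize("seed", range(4))
def test_doubling_times_match_brute_force_collection(seed):
    db = small_random_db(seed)
    stats = doubling_time_stats(db)
    oracle = []
    for r in db.records:
        if r.fate is Fate.BD and len(r.parent_ids) == 1:
            if db.index[(r.lineage_id, r.parent_ids[0])].fate is Fate.BD:
                oracle.append(r.fate_time - r.birth_time)
    assert sorted(stats.intervals) == sorted(oracle)


def test_lineage_summary_absent_sna1_is_low():
    db = LineageDB(
        [CellRecord(1, 0, (), 0.0, 400.0, Fate.ALIVE_END)], observation_end=400.0
    )
    row = lineage_summaries(db).iloc[0]
    assert row.total_sna1 == 0.0
    assert row.sna1_category == "low"


@pytest.mark.parametrize(
    "total, category",
    [(1999.9, "low"), (2000.0, "mid"), (3999.0, "mid"), (4000.0, "high")],
)
def test_sna1_category_boundaries(total, category):
    db = LineageDB(
        [CellRecord(1, 0, (), 0.0, 400.0, Fate.ALIVE_END, sna1=total)],
        observation_end=400.0,
    )
    assert lineage_summaries(db).iloc[0].sna1_category == category


def test_regression_r2_of_collinear_summaries_is_one():
    df = pd.DataFrame({"n_cells": [1, 2, 3, 4], "total_sna1": [10.0, 20.0, 30.0, 40.0]})
    slope, intercept, r2 = summary_regression(df)
    assert slope == pytest.approx(10.0)
    assert intercept == pytest.approx(0.0)
    assert r2 == pytest.approx(1.0)


def test_md_progeny_trivial_cases():
    no_md = toy_bd_db()
    assert md_reproductive_progeny(no_md) == (0, 0.0)

    db = LineageDB(
        [
            CellRecord(1, 0, (), 0.0, 300.0, Fate.MD, md_poles=3),
            CellRecord(1, 1, (0,), 300.0, 800.0, Fate.BD),
            CellRecord(1, 2, (0,), 300.0, 900.0, Fate.ALIVE_END),
            CellRecord(1, 3, (0,), 300.0, 900.0, Fate.ALIVE_END),
            CellRecord(1, 4, (1,), 800.0, 900.0, Fate.ALIVE_END),
            CellRecord(1, 5, (1,), 800.0, 900.0, Fate.ALIVE_END),
        ],
        observation_end=900.0,
    )
    count, fraction = md_reproductive_progeny(db)
    assert count == 1  # the MD product that divided bipolarly
    assert fraction == pytest.approx(1 / 4)


@pytest.mark.parametrize("seed", range(4))
def test_md_progeny_matches_ancestor_scan_oracle(seed):
    db = small_random_db(seed)

    def descends_from_md_product(r) -> bool:
        frontier = [r]
        while frontier:
            cur = frontier.pop()
            for pid in cur.parent_ids:
                parent = db.index[(cur.lineage_id, pid)]
                if parent.fate is Fate.MD:
                    return True
                frontier.append(parent)
        return False

    oracle = sum(
        1
        for r in db.records
        if r.fate is Fate.BD and descends_from_md_product(r)
    )
    count, _ = md_reproductive_progeny(db)
    assert count == oracle


@pytest.mark.parametrize("seed", range(4))
def test_population_conservation(seed):
    """count(t) = progenitors + births - deaths - 2*fusions + fusion products."""
    db = small_random_db(seed)
    curve = population_curve(db)
    for t in curve.index[:: max(1, len(curve) // 20)]:
        progenitors = sum(
            1 for r in db.records if not r.parent_ids and r.birth_time <= t
        )
        entered = sum(
            1 for r in db.records if r.parent_ids and r.birth_time <= t
        )
        left = sum(
            1
            for r in db.records
            if r.fate is not Fate.ALIVE_END and r.fate_time <= t
        )
        assert curve.loc[t] == progenitors + entered - left


def test_statistics_invariant_under_shuffle_and_renumbering(fixture_db):
    db = fixture_db
    renumbered = db.with_records(
        CellRecord(
            r.lineage_id + 1000,
            r.cell_id,
            r.parent_ids,
            r.birth_time,
            r.fate_time,
            r.fate,
            r.md_poles,
            r.sna1,
        )
        for r in db.records
    )
    rng = random.Random(0)
    shuffled_records = list(renumbered.records)
    rng.shuffle(shuffled_records)
    shuffled = renumbered.with_records(shuffled_records)

    assert (population_curve(db).values == population_curve(shuffled).values).all()
    assert event_totals(db)[1] == event_totals(shuffled)[1]
    assert fate_patterns(db).counts == fate_patterns(shuffled).counts
    assert doubling_time_stats(db).mean == doubling_time_stats(shuffled).mean
    assert md_reproductive_progeny(db) == md_reproductive_progeny(shuffled)
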