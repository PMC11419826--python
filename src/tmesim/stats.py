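"""Lineage-level analytics: population curves, event tallies, fate patterns,
doubling times, per-lineage SNA1 summaries and MD-progeny counts.

All functions are pure over a :class:`~tmesim.lineage.LineageDB` and are
invariant under record shuffling and lineage renumbering.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lineage import Fate, LineageDB

__all__ = [
    "population_curve",
    "event_totals",
    "fate_patterns",
    "FatePatternCounts",
    "doubling_time_stats",
    "DoublingTimeStats",
    "lineage_summaries",
    "summary_regression",
    "md_reproductive_progeny",
    "sna1_category",
]

# SNA1 total bins used for per-lineage categorization (arbitrary fluorescence
# units): low < 2000, mid in [2000, 4000), high >= 4000.
SNA1_LOW_MAX = 2000.0
SNA1_HIGH_MIN = 4000.0


def interval_counts(
    births: np.ndarray,
    exits: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Number of intervals [birth, exit) covering each time point.

    ``exit = inf`` counts the cell at every queried time >= birth (used for
    cells alive through the observation end).
    """
    births = np.sort(np.asarray(births, dtype=float))
    exits = np.sort(np.asarray(exits, dtype=float))
    times = np.asarray(times, dtype=float)
    n_born = np.searchsorted(births, times, side="right")
    n_gone = np.searchsorted(exits, times, side="right")
    return n_born - n_gone


def _grid(db: LineageDB) -> np.ndarray:
    if db.observation_end <= 0:
        return np.array([0.0])
    n = int(round(db.observation_end / db.frame_interval))
    return np.arange(n + 1) * db.frame_interval


def population_curve(
    db: LineageDB,
    normalize_to: float | None = None,
    times: np.ndarray | None = None,
) -> pd.Series:
    """Cell count over time.

    A cell is counted at time ``t`` when ``birth_time <= t < fate_time``; cells
    alive at the observation end (fate ALIVE_END) are counted through
    ``observation_end`` inclusive.  With ``normalize_to``, the whole series is
    scaled so its first point equals ``normalize_to`` (the conventional
    "adjusted to 100 cells at time point 1" presentation).
    """
    if times is None:
        times = _grid(db)
    times = np.asarray(times, dtype=float)
    if not db.records:
        return pd.Series(np.zeros(len(times)), index=times, name="n_cells")
    births = np.array([r.birth_time for r in db.records])
    exits = np.array(
        [np.inf if r.fate is Fate.ALIVE_END else r.fate_time for r in db.records]
    )
    counts = interval_counts(births, exits, times).astype(float)
    if normalize_to is not None and counts[0] > 0:
        counts = counts * (normalize_to / counts[0])
    return pd.Series(counts, index=times, name="n_cells")


def event_totals(db: LineageDB) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-lineage and whole-population tallies of MD, CD and CF events.

    Returns ``(per_lineage, totals)`` where ``per_lineage`` is indexed by
    lineage_id with columns MD/CD/CF.
    """
    lineages = db.lineage_ids()
    table = pd.DataFrame(
        0, index=pd.Index(lineages, name="lineage_id"), columns=["MD", "CD", "CF"]
    )
    for r in db.records:
        if r.fate in (Fate.MD, Fate.CD, Fate.CF):
            table.loc[r.lineage_id, r.fate.value] += 1
    totals = {c: int(table[c].sum()) for c in table.columns}
    return table, totals


_PATTERN_PRIORS = (Fate.CF, Fate.MD)
_PATTERN_NEXTS = (Fate.BD, Fate.MD, Fate.CD, Fate.CF)


@dataclass(frozen=True)
class FatePatternCounts:
    """Counts of "what happened next" for CF products and MD progeny.

    Keys are e.g. ``"CF > BD"`` (a fusion product later divided bipolarly) and
    the combined ``"MD + CF > BD"`` totals.  Products still alive at the
    observation end enter no pattern.
    """

    counts: dict[str, int]

    def __getitem__(self, key: str) -> int:
        return self.counts[key]

    def combined(self, next_fate: str) -> int:
        return self.counts[f"MD + CF > {next_fate}"]


def fate_patterns(db: LineageDB) -> FatePatternCounts:
    counts = {
        f"{p.value} > {n.value}": 0 for p in _PATTERN_PRIORS for n in _PATTERN_NEXTS
    }
    # count per product cell: a fusion product increments "CF > X" once even
    # though it has two CF parents
    for r in db.records:
        if not r.parent_ids or r.fate not in _PATTERN_NEXTS:
            continue
        parent = db.index[(r.lineage_id, r.parent_ids[0])]
        if parent.fate in _PATTERN_PRIORS:
            counts[f"{parent.fate.value} > {r.fate.value}"] += 1
    for n in _PATTERN_NEXTS:
        counts[f"MD + CF > {n.value}"] = (
            counts[f"MD > {n.value}"] + counts[f"CF > {n.value}"]
        )
    return FatePatternCounts(counts)


@dataclass(frozen=True)
class DoublingTimeStats:
    """Summary of BD-to-BD intervals (minutes)."""

    n: int
    mean: float
    min: float
    max: float
    intervals: tuple[float, ...]

    @property
    def empty(self) -> bool:
        return self.n == 0


def doubling_intervals(db: LineageDB) -> list[float]:
    """BD->BD intervals: durations of cells born from a BD that divide by BD."""
    out = []
    for r in db.records:
        if r.fate is not Fate.BD or len(r.parent_ids) != 1:
            continue
        parent = db.index[(r.lineage_id, r.parent_ids[0])]
        if parent.fate is Fate.BD:
            out.append(r.duration)
    return out


def doubling_time_stats(db: LineageDB) -> DoublingTimeStats:
    iv = doubling_intervals(db)
    if not iv:
        return DoublingTimeStats(0, float("nan"), float("nan"), float("nan"), ())
    arr = np.asarray(iv)
    return DoublingTimeStats(
        len(iv), float(arr.mean()), float(arr.min()), float(arr.max()), tuple(iv)
    )


def sna1_category(total_sna1: float) -> str:
    if total_sna1 < SNA1_LOW_MAX:
        return "low"
    if total_sna1 < SNA1_HIGH_MIN:
        return "mid"
    return "high"


def lineage_summaries(db: LineageDB) -> pd.DataFrame:
    """One row per lineage: cell count, total SNA1 and event counts.

    ``total_sna1`` sums every present ``sna1`` value in the lineage (absent
    values contribute 0); back-propagated internal values are included when the
    database carries them.  The category bins are <2000 (low), 2000-3999 (mid)
    and >=4000 (high) total SNA1 units.
    """
    per_lineage, _ = event_totals(db)
    rows = []
    for lid in db.lineage_ids():
        cells = db.lineage(lid)
        total = float(sum(r.sna1 for r in cells if r.sna1 is not None))
        rows.append(
            {
                "lineage_id": lid,
                "n_cells": len(cells),
                "total_sna1": total,
                "md_count": int(per_lineage.loc[lid, "MD"]),
                "cd_count": int(per_lineage.loc[lid, "CD"]),
                "cf_count": int(per_lineage.loc[lid, "CF"]),
                "sna1_category": sna1_category(total),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lineage_id",
            "n_cells",
            "total_sna1",
            "md_count",
            "cd_count",
            "cf_count",
            "sna1_category",
        ],
    )


def summary_regression(summaries: pd.DataFrame) -> tuple[float, float, float]:
    """OLS of total SNA1 on lineage cell count: (slope, intercept, R^2)."""
    res = sps.linregress(summaries["n_cells"], summaries["total_sna1"])
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def md_reproductive_progeny(db: LineageDB) -> tuple[int, float]:
    """Count of reproductive MD-descended cells and their fraction of the final
    population.

    A cell qualifies when it is an MD product or descends from one, and it is
    reproductive, i.e. undergoes at least one bipolar division during the
    observation.  The fraction divides by the number of cells alive at the
    observation end (0 when none are).
    """
    # seed the descent scan with the direct products of every MD
    md_descended: set[tuple[int, int]] = set()
    queue: deque[tuple[int, int]] = deque()
    for r in db.records:
        if r.fate is Fate.MD:
            for child in db.children_of(r.lineage_id, r.cell_id):
                if child.key not in md_descended:
                    md_descended.add(child.key)
                    queue.append(child.key)
    while queue:
        lid, cid = queue.popleft()
        for child in db.children_of(lid, cid):
            if child.key not in md_descended:
                md_descended.add(child.key)
                queue.append(child.key)
    count = sum(1 for key in md_descended if db.index[key].fate is Fate.BD)
    final_pop = sum(1 for r in db.records if r.fate is Fate.ALIVE_END)
    fraction = count / final_pop if final_pop else 0.0
    return count, fraction
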