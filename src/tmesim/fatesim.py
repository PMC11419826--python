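"""Cell-fate simulation: fit an event-transition model from lineage data and
generate "deduced" cell populations with assigned, scalable α2-6Sia levels.

The model is empirical: for each prior event (progenitor start, BD, MD, CF)
it stores the multiset of observed ``(next_event, duration)`` pairs.  The
simulator resamples these pairs jointly, which preserves the observed joint
structure of event type and waiting time without parametric assumptions.
Cells still alive at the end of the source observation are censored; their
durations are recorded separately and never resampled — in a simulation,
censoring re-emerges naturally when an event falls beyond the horizon.

Expression assignment reproduces the reproductive-capacity coupling of
α2-6Sia–expressing cells: at each bipolar division the daughters receive an
expression value only when some expressing source cell had a doubling time
within a ±10% window of the daughters' sampled intervals; the first daughter
draws uniformly from the expression list and the second falls within ±15% of
the first.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .lineage import CellRecord, Fate, LineageDB
from .sialylation import ExpressionList

__all__ = [
    "PRIOR_START",
    "TransitionModel",
    "FateSimParams",
    "MissingTransitionError",
    "fit_transition_model",
    "simulate_population",
    "assign_expression",
    "scale_expression",
]

#: Prior-event label for progenitor cells (no preceding event observed).
PRIOR_START = "START"

_EVENT_FATES = (Fate.BD, Fate.MD, Fate.CD, Fate.CF)


class MissingTransitionError(ValueError):
    """The model has no observed transition for a required prior event."""


@dataclass
class TransitionModel:
    """Empirical (next event, duration) distribution conditioned on the prior
    event.

    ``pairs[prior]`` holds completed observations; ``censored[prior]`` holds
    durations of cells still alive at observation end.  ``md_arities`` is the
    multiset of observed multipolar-division pole counts.
    """

    pairs: dict[str, list[tuple[str, float]]]
    md_arities: list[int] = field(default_factory=list)
    censored: dict[str, list[float]] = field(default_factory=dict)

    def priors(self) -> list[str]:
        return sorted(self.pairs)

    def n_events(self) -> int:
        return sum(len(v) for v in self.pairs.values())

    def probabilities(self, prior: str) -> dict[str, float]:
        """P(next event | prior) as empirical frequencies over completed events."""
        obs = self.pairs.get(prior)
        if not obs:
            raise MissingTransitionError(f"no completed events after {prior!r}")
        n = len(obs)
        out: dict[str, float] = {}
        for ev, _ in obs:
            out[ev] = out.get(ev, 0.0) + 1.0
        return {ev: c / n for ev, c in sorted(out.items())}

    def durations(self, prior: str, next_event: str | None = None) -> list[float]:
        obs = self.pairs.get(prior, [])
        return [d for ev, d in obs if next_event is None or ev == next_event]

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema": "tmesim-transition-model",
            "version": 1,
            "pairs": {p: [[ev, d] for ev, d in obs] for p, obs in self.pairs.items()},
            "md_arities": self.md_arities,
            "censored": self.censored,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransitionModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema") != "tmesim-transition-model":
            raise ValueError(f"{path}: not a transition-model file")
        return cls(
            pairs={
                p: [(ev, float(d)) for ev, d in obs]
                for p, obs in payload["pairs"].items()
            },
            md_arities=[int(a) for a in payload["md_arities"]],
            censored={
                p: [float(d) for d in ds] for p, ds in payload["censored"].items()
            },
        )


def _prior_of(db: LineageDB, record: CellRecord) -> str:
    if not record.parent_ids:
        return PRIOR_START
    # for a fusion product both parents carry fate CF
    parent = db.index[(record.lineage_id, record.parent_ids[0])]
    return parent.fate.value


def fit_transition_model(db: LineageDB) -> TransitionModel:
    """Tally every observed (prior event, next event, duration) triple.

    Raises ValueError when the database holds no completed event at all.
    """
    pairs: dict[str, list[tuple[str, float]]] = {}
    censored: dict[str, list[float]] = {}
    arities: list[int] = []
    for r in db.records:
        prior = _prior_of(db, r)
        if r.fate is Fate.ALIVE_END:
            censored.setdefault(prior, []).append(r.duration)
        else:
            pairs.setdefault(prior, []).append((r.fate.value, r.duration))
            if r.fate is Fate.MD:
                arities.append(
                    r.md_poles
                    if r.md_poles is not None
                    else len(db.children_of(r.lineage_id, r.cell_id))
                )
    if not pairs:
        raise ValueError("no completed events in the database")
    return TransitionModel(pairs=pairs, md_arities=arities, censored=censored)


@dataclass
class FateSimParams:
    """Knobs of deduced-population generation.

    Defaults follow the simulation conditions used throughout: 500 progenitors
    started at random cell-cycle phases and grown for 170 h; the expression
    gate window is ±10% of the doubling time and siblings fall within ±15% of
    each other; the scale factor multiplies assigned α2-6Sia values (capped at
    the source population maximum).
    """

    n_progenitors: int = 500
    horizon: float = 10_200.0  # minutes (170 h)
    doubling_window: float = 0.10
    sibling_window: float = 0.15
    scale_factor: float = 1.0
    seed: int = 0
    random_phase: bool = True
    gate_mode: str = "any"  # "any" expressing cell, or the "average" variant

    def __post_init__(self) -> None:
        if not 0 < self.doubling_window < 1:
            raise ValueError("doubling_window must lie in (0, 1)")
        if not 0 < self.sibling_window < 1:
            raise ValueError("sibling_window must lie in (0, 1)")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.gate_mode not in ("any", "average"):
            raise ValueError("gate_mode must be 'any' or 'average'")


def _sample_pair(
    model: TransitionModel, prior: str, rng: np.random.Generator
) -> tuple[str, float]:
    obs = model.pairs.get(prior)
    if not obs:
        raise MissingTransitionError(f"no completed events after {prior!r}")
    return obs[int(rng.integers(len(obs)))]


def simulate_population(model: TransitionModel, params: FateSimParams) -> LineageDB:
    """Generate a deduced cell population of ``n_progenitors`` lineages.

    Each progenitor draws its first (event, duration) pair from the
    progenitor-start conditional, then starts at a uniform random phase of
    that first wait (so progenitors sit at different stages of the cell
    cycle).  Afterwards every cell draws its own pair conditioned on the event
    that created it.  BD spawns 2 daughters, MD an arity resampled from the
    observed pole counts, CF pairs the cell with a concurrently alive cell of
    the same lineage (the event is redrawn among non-CF options when no
    partner exists).  Cells whose event falls beyond the horizon are recorded
    ALIVE_END.  Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    horizon = params.horizon
    records: list[CellRecord] = []
    # per-prior CF share: used to weight fusion-partner recruitment so each
    # prior's realized CF rate matches its fitted rate in expectation
    cf_share = {
        prior: sum(1 for ev, _ in obs if ev == Fate.CF.value) / len(obs)
        for prior, obs in model.pairs.items()
        if obs
    }
    # fitted CF durations mix initiator clocks with truncated partner
    # lifetimes (a recruited partner fuses on the initiator's schedule), so
    # only the longer half — the initiator-like half — triggers a fusion
    cf_median = {
        prior: float(np.median([d for ev, d in obs if ev == Fate.CF.value]))
        for prior, obs in model.pairs.items()
        if any(ev == Fate.CF.value for ev, _ in obs)
    }

    for lineage_id in range(1, params.n_progenitors + 1):
        # cell bookkeeping: id -> [birth, scheduled_fate, event, parents, alive]
        cells: dict[int, dict] = {}
        heap: list[tuple[float, int]] = []
        cancelled: set[int] = set()
        next_id = 0

        def new_cell(birth: float, prior: str, parents: tuple[int, ...]) -> None:
            nonlocal next_id
            ev, dur = _sample_pair(model, prior, rng)
            if not parents and params.random_phase:
                # progenitor already partway through its first wait
                dur = dur - rng.uniform(0.0, dur)
            cid = next_id
            next_id += 1
            cells[cid] = {
                "birth": birth,
                "fate_time": birth + dur,
                "event": ev,
                "parents": parents,
                "done": False,
            }
            if birth + dur <= horizon:
                heapq.heappush(heap, (birth + dur, cid))

        new_cell(0.0, PRIOR_START, ())

        while heap:
            t, cid = heapq.heappop(heap)
            if cid in cancelled or cells[cid]["done"]:
                continue
            cell = cells[cid]
            ev = cell["event"]
            if ev == Fate.CF.value:
                # every fusion leaves TWO CF-fated records in a database (the
                # initiator and its recruited partner), so a cell that samples
                # CF initiates a fusion only half the time; the other half of
                # the observed per-cell CF rate is produced by partner
                # recruitment, which keeps realized event frequencies equal to
                # the fitted ones in expectation
                prior = _creation_prior(cells, cid)
                initiate = t - cell["birth"] >= cf_median.get(prior, math.inf)
                partners = sorted(
                    c
                    for c, info in cells.items()
                    if c != cid
                    and not info["done"]
                    and c not in cancelled
                    and info["birth"] < t
                    and info["fate_time"] > t
                ) if initiate else []
                if partners:
                    # recruit fusion-prone cells preferentially: weight each
                    # candidate by its own prior's CF share, which keeps
                    # P(CF | prior) of the output equal to the model's
                    weights = np.array(
                        [
                            cf_share.get(_creation_prior(cells, c), 0.0)
                            for c in partners
                        ]
                    )
                    partners = (
                        partners if weights.sum() > 0 else []
                    )
                if partners:
                    partner = int(
                        rng.choice(partners, p=weights / weights.sum())
                    )
                    cancelled.add(partner)
                    pinfo = cells[partner]
                    pinfo["done"] = True
                    pinfo["event"] = Fate.CF.value
                    pinfo["fate_time"] = t
                    cell["done"] = True
                    new_cell(t, Fate.CF.value, (cid, partner))
                    continue
                # partner half of the rate, or no co-resident partner:
                # redraw among the non-CF alternatives
                alts = [
                    p
                    for p in model.pairs.get(_creation_prior(cells, cid), [])
                    if p[0] != Fate.CF.value
                ]
                if alts:
                    ev = alts[int(rng.integers(len(alts)))][0]
                else:
                    ev = Fate.CD.value
                cell["event"] = ev
            cell["done"] = True
            if ev == Fate.BD.value:
                for _ in range(2):
                    new_cell(t, Fate.BD.value, (cid,))
            elif ev == Fate.MD.value:
                arity = (
                    int(rng.choice(model.md_arities)) if model.md_arities else 3
                )
                cell["md_poles"] = arity
                for _ in range(arity):
                    new_cell(t, Fate.MD.value, (cid,))
            # CD: nothing to spawn

        for cid in sorted(cells):
            info = cells[cid]
            if info["done"] or cid in cancelled:
                fate = Fate(info["event"])
                fate_time = info["fate_time"]
            else:
                fate = Fate.ALIVE_END
                fate_time = horizon
            records.append(
                CellRecord(
                    lineage_id=lineage_id,
                    cell_id=cid,
                    parent_ids=tuple(info["parents"]),
                    birth_time=info["birth"],
                    fate_time=fate_time,
                    fate=fate,
                    md_poles=info.get("md_poles"),
                )
            )

    return LineageDB(records=records, frame_interval=10.0, observation_end=horizon)


def _creation_prior(cells: dict[int, dict], cid: int) -> str:
    parents = cells[cid]["parents"]
    if not parents:
        return PRIOR_START
    return cells[parents[0]]["event"] if len(parents) == 1 else Fate.CF.value


def expressing_doubling_pool(source_db: LineageDB) -> list[float]:
    """BD->BD intervals of source cells with sna1 > 0 (post back-propagation)."""
    out = []
    for r in source_db.records:
        if r.fate is not Fate.BD or len(r.parent_ids) != 1:
            continue
        parent = source_db.index[(r.lineage_id, r.parent_ids[0])]
        if parent.fate is Fate.BD and r.sna1 is not None and r.sna1 > 0:
            out.append(r.duration)
    return out


def assign_expression(
    deduced: LineageDB,
    expr_list: ExpressionList,
    source_db: LineageDB,
    params: FateSimParams,
) -> LineageDB:
    """Assign α2-6Sia expression values to the daughters of bipolar divisions.

    The gate: daughters receive values only when at least one expressing
    source cell's doubling time lies within ``±doubling_window`` of either
    daughter's sampled inter-event interval (``gate_mode="average"`` compares
    against the mean expressing doubling time instead).  On a pass, the first
    daughter draws uniformly from the expression list and the second draws
    uniformly from ``[v1*(1-sibling_window), v1*(1+sibling_window)]``.
    Daughters of failed gates, and cells not born of BD, keep ``sna1`` absent.
    """
    if not expr_list.values:
        raise ValueError("expression list is empty")
    pool = np.asarray(expressing_doubling_pool(source_db), dtype=float)
    pool_mean = float(pool.mean()) if pool.size else float("nan")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xE5A1]))
    w = params.doubling_window
    sw = params.sibling_window
    values = np.asarray(expr_list.values, dtype=float)

    def gate(interval: float) -> bool:
        if pool.size == 0:
            return False
        if params.gate_mode == "average":
            return abs(interval - pool_mean) <= w * pool_mean
        return bool(np.any(np.abs(pool - interval) <= w * interval))

    new_sna1: dict[tuple[int, int], float] = {}
    for r in deduced.records:
        if r.fate is not Fate.BD:
            continue
        daughters = sorted(
            deduced.children_of(r.lineage_id, r.cell_id), key=lambda c: c.cell_id
        )
        if len(daughters) != 2:
            continue
        if gate(daughters[0].duration) or gate(daughters[1].duration):
            v1 = float(values[int(rng.integers(len(values)))])
            v2 = float(rng.uniform(v1 * (1 - sw), v1 * (1 + sw)))
            new_sna1[daughters[0].key] = v1
            new_sna1[daughters[1].key] = v2

    return deduced.with_records(
        replace(r, sna1=new_sna1[r.key]) if r.key in new_sna1 else r
        for r in deduced.records
    )


def scale_expression(db: LineageDB, factor: float, v_max: float) -> LineageDB:
    """Multiply every present sna1 by ``factor``, capping at ``v_max``.

    Models in-vivo variation of α2-6Sia levels (e.g. factors 1.5, 0.5, 0.25)
    while never exceeding the highest level observed in the source population.
    Absent values stay absent.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return db.with_records(
        r if r.sna1 is None else replace(r, sna1=min(factor * r.sna1, v_max))
        for r in db.records
    )
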