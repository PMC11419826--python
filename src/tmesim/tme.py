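"""3D tumor-microenvironment simulation engine.

Deduced cancer cells and microenvironment agents (suppressive, permissive,
lethal) are placed uniformly at random inside a solid sphere (default radius
50 px).  Every cancer cell searches a fixed radius (default 6 px) around its
anchor for the two nearest microenvironment agents and resolves the effect:

* nearest lethal — a resistance draw (probability ``1/r`` with ``r`` mapped
  linearly from the cell's α2-6Sia expression into ``[1, resistance_max]``)
  followed by a strength draw (``s_lethal``% chance); on success the cell dies
  and its whole subtree is removed;
* nearest suppressive, second not permissive — resistance draw, then the
  cell's remaining inter-event wait and all descendant waits are prolonged by
  ``s_sup``%;
* nearest permissive, second not suppressive — waits shortened by
  ``s_perm``% (no resistance draw), floored at the shortest doubling time of
  the deduced population;
* mixed nearest pair — the nearer effect applies with a distance-weighted
  offset strength ``max(0, s_near - s_far * d_near / d_far)``.

Anchor geometry is static (motility only jitters the display within
``motility_cap``), so a cell's nearest-agent set never changes during its
lifetime; each cell is therefore resolved once, at the first timestep after
its birth, and lethal triggering is once per (cell, agent) pair by
construction.  A cell receives at most one suppressive-or-permissive
modification; daughters are born eligible again but inherit the accumulated
duration scaling.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .landscape import CATEGORIES, agent_counts
from .lineage import CellRecord, Fate, LineageDB, subtree
from .stats import interval_counts

__all__ = [
    "TMEParams",
    "TMEWorld",
    "EffectRecord",
    "SimulationResult",
    "place_agents",
    "sample_in_ball",
    "neighbors_within",
    "adjusted_suppressive_strength",
    "effect_probability",
    "apply_suppressive",
    "apply_permissive",
    "apply_lethal",
    "run_simulation",
    "sweep_grid",
    "sweep",
    "SweepRun",
]


@dataclass
class TMEParams:
    """Spatial and interaction parameters of the 3D TME simulation.

    Distances are pixels, times minutes.  ``s_sup``/``s_perm`` are percent
    changes of doubling time, ``s_lethal`` a percent kill probability per
    triggering encounter, ``resistance_max`` the fold-resistance of a cell at
    the maximum α2-6Sia expression.
    """

    sphere_radius: float = 50.0
    search_radius: float = 6.0
    daughter_radius: float = 6.0
    motility_cap: float = 2.0
    s_sup: float = 10.0
    s_perm: float = 10.0
    s_lethal: float = 100.0
    resistance_max: float = 1.0
    timestep: float = 10.0
    horizon: float = 6000.0
    seed: int = 0
    v_max: float | None = None  # expression scale reference; None = deduced max

    def __post_init__(self) -> None:
        for name in ("sphere_radius", "search_radius", "daughter_radius", "timestep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("s_sup", "s_perm", "s_lethal", "motility_cap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.s_perm >= 100:
            raise ValueError("s_perm must be < 100")
        if self.resistance_max < 1:
            raise ValueError("resistance_max must be >= 1")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")


@dataclass
class TMEWorld:
    """Positioned agents: microenvironment anchors plus cancer progenitor anchors."""

    micro_xyz: np.ndarray  # (M, 3)
    micro_cat: np.ndarray  # (M,) of {"suppressive", "permissive", "lethal"}
    cancer_xyz: np.ndarray  # (n_progenitors, 3)
    sphere_radius: float

    @property
    def n_micro(self) -> int:
        return len(self.micro_xyz)

    def counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.micro_cat == c)) for c in CATEGORIES}


def sample_in_ball(
    rng: np.random.Generator, n: int, radius: float, center: np.ndarray | None = None
) -> np.ndarray:
    """n points i.i.d. uniform in the solid ball of ``radius`` around ``center``."""
    direction = rng.normal(size=(n, 3))
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    pts = direction / norms * r
    if center is not None:
        pts = pts + center
    return pts


def place_agents(
    n_by_category: Mapping[str, int],
    n_cancer: int,
    params: TMEParams,
    seed: int | None = None,
) -> TMEWorld:
    """Place microenvironment agents and cancer progenitors uniformly in the
    simulation sphere.  Reproducible from ``seed`` (default ``params.seed``)."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    cats: list[str] = []
    for c in CATEGORIES:
        n = int(n_by_category.get(c, 0))
        if n < 0:
            raise ValueError(f"negative count for {c!r}")
        cats.extend([c] * n)
    micro_xyz = sample_in_ball(rng, len(cats), params.sphere_radius)
    cancer_xyz = sample_in_ball(rng, n_cancer, params.sphere_radius)
    return TMEWorld(
        micro_xyz=micro_xyz,
        micro_cat=np.array(cats, dtype=object),
        cancer_xyz=cancer_xyz,
        sphere_radius=params.sphere_radius,
    )


def neighbors_within(
    point: np.ndarray,
    positions: np.ndarray,
    radius: float,
    k: int = 2,
) -> list[tuple[int, float]]:
    """The ``k`` nearest agents within ``radius`` of ``point``.

    Returns (agent index, distance) pairs sorted by Euclidean distance, ties
    broken by index ascending; fewer than ``k`` when the ball is sparse.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    positions = np.asarray(positions, dtype=float)
    if len(positions) == 0:
        return []
    d = np.linalg.norm(positions - np.asarray(point, dtype=float), axis=1)
    candidates = sorted((float(d[i]), int(i)) for i in np.flatnonzero(d <= radius))
    return [(i, dist) for dist, i in candidates[:k]]


def adjusted_suppressive_strength(
    s_sup: float, s_perm: float, d_sup: float, d_perm: float
) -> float:
    """Distance-weighted offset when a suppressive agent is nearest and a
    permissive one second (``d_sup <= d_perm``):

        adjusted = max(0, s_sup - s_perm * d_sup / d_perm)

    e.g. strengths (50, 50) at distances (3, 6) give 50 - 25 = 25.  The
    symmetric permissive-nearest case swaps the roles of the arguments.
    """
    if d_sup <= 0 or d_perm <= 0:
        raise ValueError("distances must be positive")
    return max(0.0, s_sup - s_perm * (d_sup / d_perm))


def effect_probability(
    expression: float | None, v_max: float | None, resistance_max: float
) -> float:
    """Chance that a suppressive or lethal encounter takes effect.

    Resistance ``r = 1 + (resistance_max - 1) * expression / v_max`` (linear
    in normalized α2-6Sia expression; absent expression gives ``r = 1``); the
    probability is ``1/r`` — e.g. 5-fold maximum resistance leaves a fully
    expressing cell a one-in-five chance of being affected.
    """
    if resistance_max < 1:
        raise ValueError("resistance_max must be >= 1")
    if expression is None or v_max is None or v_max <= 0:
        return 1.0
    ratio = min(max(expression, 0.0) / v_max, 1.0)
    return 1.0 / (1.0 + (resistance_max - 1.0) * ratio)


# ---------------------------------------------------------------------------
# database-level effect operations (pure; the engine applies the same
# arithmetic incrementally during a run)


def _rescale_subtree(
    db: LineageDB,
    lineage_id: int,
    cell_id: int,
    k: float,
    at_time: float | None,
    floor: float | None,
) -> LineageDB:
    ids = subtree(db, lineage_id, cell_id)
    root = db.index[(lineage_id, cell_id)]
    if at_time is None:
        at_time = root.birth_time
    if not root.birth_time <= at_time <= root.fate_time:
        raise ValueError("at_time must fall within the cell's lifetime")

    def scaled_total(orig_total: float, scaled: float) -> float:
        if floor is not None and k < 1:
            return min(orig_total, max(scaled, floor))
        return scaled

    new_birth: dict[int, float] = {}
    new_fate: dict[int, float] = {}
    members = sorted(
        (db.index[(lineage_id, i)] for i in ids),
        key=lambda r: (r.birth_time, r.cell_id),
    )
    for r in members:
        if r.cell_id == cell_id:
            nb = r.birth_time
            cand = (at_time - nb) + (r.fate_time - at_time) * k
            total = scaled_total(r.duration, cand)
        else:
            parent_fates = [
                new_fate.get(p, db.index[(lineage_id, p)].fate_time)
                for p in r.parent_ids
            ]
            nb = max(parent_fates)
            total = scaled_total(r.duration, r.duration * k)
        new_birth[r.cell_id] = nb
        new_fate[r.cell_id] = min(nb + total, db.observation_end) if (
            r.fate is Fate.ALIVE_END
        ) else nb + total

    def rebuild(r: CellRecord) -> CellRecord:
        if r.cell_id not in new_birth:
            return r
        return replace(
            r, birth_time=new_birth[r.cell_id], fate_time=new_fate[r.cell_id]
        )

    return db.with_records(rebuild(r) for r in db.records)


def apply_suppressive(
    db: LineageDB,
    lineage_id: int,
    cell_id: int,
    strength_percent: float,
    at_time: float | None = None,
) -> LineageDB:
    """Prolong the cell's remaining wait and every descendant wait by
    ``strength_percent``% (e.g. a 25 h doubling time at strength 10 becomes
    27.5 h).  ``at_time`` defaults to the cell's birth (whole wait affected)."""
    if strength_percent < 0:
        raise ValueError("strength must be >= 0")
    return _rescale_subtree(
        db, lineage_id, cell_id, 1.0 + strength_percent / 100.0, at_time, None
    )


def apply_permissive(
    db: LineageDB,
    lineage_id: int,
    cell_id: int,
    strength_percent: float,
    min_doubling: float,
    at_time: float | None = None,
) -> LineageDB:
    """Shorten waits by ``strength_percent``%, never below ``min_doubling``
    (the shortest doubling time observed in the deduced population); waits
    already below the floor are left unchanged."""
    if not 0 <= strength_percent < 100:
        raise ValueError("strength must lie in [0, 100)")
    return _rescale_subtree(
        db, lineage_id, cell_id, 1.0 - strength_percent / 100.0, at_time, min_doubling
    )


def apply_lethal(
    db: LineageDB,
    lineage_id: int,
    cell_id: int,
    at_time: float | None = None,
) -> LineageDB:
    """Kill the cell at ``at_time`` (default: its birth): its subtree is
    removed from the database and the cell itself is recorded as CD."""
    ids = subtree(db, lineage_id, cell_id)
    root = db.index[(lineage_id, cell_id)]
    if at_time is None:
        at_time = root.birth_time
    kill = replace(
        root,
        fate=Fate.CD,
        fate_time=max(at_time, root.birth_time),
        md_poles=None,
    )
    kept = [
        r
        for r in db.records
        if not (r.lineage_id == lineage_id and r.cell_id in ids)
    ]
    kept.append(kill)
    return db.with_records(kept)


# ---------------------------------------------------------------------------
# the simulation proper


@dataclass(frozen=True)
class EffectRecord:
    """One resolved encounter between a cancer cell and its nearest agents."""

    time: float
    lineage_id: int
    cell_id: int
    agent_id: int
    category: str
    strength: float
    probability: float
    applied: bool
    effect: str | None  # "suppressed" | "promoted" | "killed" | None


@dataclass
class SimulationResult:
    """Outcome of one 3D TME run."""

    times: np.ndarray
    population: np.ndarray
    final_population: int
    effect_log: list[EffectRecord]
    final_expression: np.ndarray
    md_progeny_count: int
    md_progeny_fraction: float
    db: LineageDB


def min_doubling_time(deduced: LineageDB) -> float:
    """Shortest doubling time (duration of a BD-fated cell) in the population."""
    durations = [r.duration for r in deduced.records if r.fate is Fate.BD]
    return min(durations) if durations else math.inf


def _grid_ceil(t: float, dt: float) -> float:
    return math.ceil(t / dt - 1e-9) * dt


def run_simulation(
    deduced: LineageDB, world: TMEWorld, params: TMEParams
) -> SimulationResult:
    """Simulate the fate of a deduced cell population inside a TME world.

    The deduced database is the growth schedule; encounters with
    microenvironment agents rescale waits or kill subtrees as described in the
    module docstring.  Fully deterministic given (deduced, world, params).
    """
    lineages = deduced.lineage_ids()
    if len(world.cancer_xyz) < len(lineages):
        raise ValueError(
            f"world has {len(world.cancer_xyz)} cancer anchors for "
            f"{len(lineages)} lineages"
        )
    dt = params.timestep
    horizon = params.horizon
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x73E5]))
    tree = cKDTree(world.micro_xyz) if world.n_micro else None
    floor = min_doubling_time(deduced)
    v_max = params.v_max
    if v_max is None:
        present = [r.sna1 for r in deduced.records if r.sna1 is not None]
        v_max = max(present) if present else None

    # per simulated cell state, keyed by deduced record key
    state: dict[tuple[int, int], dict] = {}
    pending_fusion: dict[tuple[int, int], int] = {}
    effect_log: list[EffectRecord] = []
    heap: list[tuple[float, int, int, tuple[int, int], int]] = []
    seq = itertools.count()

    def push(t: float, kind: int, key: tuple[int, int], version: int) -> None:
        heapq.heappush(heap, (t, kind, next(seq), key, version))

    def daughter_position(parent_pos: np.ndarray) -> np.ndarray:
        for _ in range(100):
            cand = sample_in_ball(rng, 1, params.daughter_radius, parent_pos)[0]
            if np.linalg.norm(cand) <= world.sphere_radius:
                return cand
        return cand * (world.sphere_radius / np.linalg.norm(cand))

    def spawn(key: tuple[int, int], birth: float, factor: float, pos: np.ndarray) -> None:
        rec = deduced.index[key]
        base = rec.duration
        eff = base * factor
        if factor < 1:
            eff = max(eff, min(floor, base))
        sched = math.inf if rec.fate is Fate.ALIVE_END else birth + eff
        st = {
            "birth": birth,
            "sched": sched,
            "factor": factor,
            "pos": pos,
            "version": 0,
            "killed": False,
            "done": False,
            "exit": None,  # actual fate time once resolved
            "fate": None,
        }
        state[key] = st
        t_eval = _grid_ceil(birth, dt)
        if t_eval <= horizon:
            push(t_eval, 0, key, 0)
        if sched <= horizon:
            push(sched, 1, key, 0)

    def resolve_encounter(t: float, key: tuple[int, int]) -> None:
        st = state[key]
        if tree is None:
            return
        idx = tree.query_ball_point(st["pos"], params.search_radius)
        if not idx:
            return
        pos = st["pos"]
        pairs = sorted(
            (float(np.linalg.norm(world.micro_xyz[i] - pos)), int(i)) for i in idx
        )
        d1, a1 = pairs[0]
        cat1 = str(world.micro_cat[a1])
        cat2 = str(world.micro_cat[pairs[1][1]]) if len(pairs) > 1 else None
        d2 = pairs[1][0] if len(pairs) > 1 else None
        expr = deduced.index[key].sna1

        if cat1 == "lethal":
            p = effect_probability(expr, v_max, params.resistance_max)
            hit = rng.uniform() < p and rng.uniform() < params.s_lethal / 100.0
            if hit:
                # death lands within the frame of the encounter; never record a
                # zero-duration life for a cell evaluated at its birth instant
                kill_t = t if t > st["birth"] else min(t + dt, st["sched"])
                st["killed"] = True
                st["done"] = True
                st["exit"] = kill_t
                st["fate"] = Fate.CD
                st["version"] += 1
            effect_log.append(
                EffectRecord(t, key[0], key[1], a1, "lethal", params.s_lethal,
                             p, hit, "killed" if hit else None)
            )
            return

        if cat1 == "suppressive":
            s = params.s_sup
            if cat2 == "permissive":
                s = adjusted_suppressive_strength(params.s_sup, params.s_perm, d1, d2)
            p = effect_probability(expr, v_max, params.resistance_max)
            hit = rng.uniform() < p
            applied = hit and s > 0
            if applied:
                st["sched"] = t + (st["sched"] - t) * (1 + s / 100.0)
                st["factor"] *= 1 + s / 100.0
                st["version"] += 1
                if st["sched"] <= horizon:
                    push(st["sched"], 1, key, st["version"])
            effect_log.append(
                EffectRecord(t, key[0], key[1], a1, "suppressive", s, p,
                             applied, "suppressed" if applied else None)
            )
            return

        # nearest permissive (no resistance draw)
        s = params.s_perm
        if cat2 == "suppressive":
            s = adjusted_suppressive_strength(params.s_perm, params.s_sup, d1, d2)
        applied = s > 0
        if applied:
            birth = st["birth"]
            cand = t + (st["sched"] - t) * (1 - s / 100.0)
            if math.isfinite(st["sched"]):
                new_total = max(cand - birth, min(floor, st["sched"] - birth))
                st["sched"] = birth + new_total
                st["version"] += 1
                if st["sched"] <= horizon:
                    push(st["sched"], 1, key, st["version"])
            st["factor"] *= 1 - s / 100.0
        effect_log.append(
            EffectRecord(t, key[0], key[1], a1, "permissive", s, 1.0,
                         applied, "promoted" if applied else None)
        )

    def fire_fate(t: float, key: tuple[int, int]) -> None:
        st = state[key]
        rec = deduced.index[key]
        if rec.fate is Fate.CF:
            # the fusion completes when the slower partner arrives
            product = next(
                (
                    c
                    for c in deduced.children_of(*key)
                    if len(c.parent_ids) == 2
                ),
                None,
            )
            st["done"] = True
            st["fate"] = Fate.CF
            if product is None:
                st["exit"] = t
                return
            pending_fusion[product.key] = pending_fusion.get(product.key, 0) + 1
            if pending_fusion[product.key] < len(product.parent_ids):
                return  # wait for the partner; exit set when fusion completes
            for pid in product.parent_ids:
                pst = state[(key[0], pid)]
                pst["exit"] = t
                pst["fate"] = Fate.CF
            spawn(product.key, t, st["factor"], daughter_position(st["pos"]))
            return
        st["done"] = True
        st["exit"] = t
        st["fate"] = rec.fate
        if rec.fate in (Fate.BD, Fate.MD):
            for child in sorted(
                deduced.children_of(*key), key=lambda c: c.cell_id
            ):
                if len(child.parent_ids) == 1:
                    spawn(child.key, t, st["factor"], daughter_position(st["pos"]))

    # progenitors take the pre-placed cancer anchors in lineage order
    for i, lid in enumerate(lineages):
        progenitors = [
            r for r in deduced.records if r.lineage_id == lid and not r.parent_ids
        ]
        for r in progenitors:
            spawn(r.key, 0.0, 1.0, world.cancer_xyz[i])

    while heap:
        t, kind, _, key, version = heapq.heappop(heap)
        st = state[key]
        if st["killed"] or st["done"]:
            continue
        if kind == 0:
            if st["sched"] > t:  # still alive at the evaluation instant
                resolve_encounter(t, key)
        else:
            if version == st["version"]:
                fire_fate(t, key)

    # assemble output records and the population trace
    out_records: list[CellRecord] = []
    births, exits = [], []
    for key, st in state.items():
        rec = deduced.index[key]
        if st["exit"] is None:
            fate, fate_time, exit_time = Fate.ALIVE_END, horizon, math.inf
        else:
            fate, fate_time, exit_time = st["fate"], st["exit"], st["exit"]
        out_records.append(
            CellRecord(
                lineage_id=rec.lineage_id,
                cell_id=rec.cell_id,
                parent_ids=rec.parent_ids,
                birth_time=st["birth"],
                fate_time=fate_time,
                fate=fate,
                md_poles=rec.md_poles if fate is Fate.MD else None,
                sna1=rec.sna1,
            )
        )
        births.append(st["birth"])
        exits.append(exit_time)

    out_records.sort(key=lambda r: (r.lineage_id, r.cell_id))
    out_db = LineageDB(
        records=out_records, frame_interval=dt, observation_end=horizon
    )
    n_steps = int(round(horizon / dt))
    times = np.arange(n_steps + 1) * dt
    population = interval_counts(np.array(births), np.array(exits), times)
    final_expression = np.array(
        [
            r.sna1
            for r in out_records
            if r.fate is Fate.ALIVE_END and r.sna1 is not None
        ]
    )
    from .stats import md_reproductive_progeny  # local to avoid cycle at import

    md_count, md_fraction = md_reproductive_progeny(out_db)
    return SimulationResult(
        times=times,
        population=population,
        final_population=int(population[-1]),
        effect_log=effect_log,
        final_expression=final_expression,
        md_progeny_count=md_count,
        md_progeny_fraction=md_fraction,
        db=out_db,
    )


# ---------------------------------------------------------------------------
# parameter sweeps


@dataclass
class SweepRun:
    """One grid point of a ratio sweep."""

    ratios: dict[str, float]
    counts: dict[str, int]
    seed: int
    result: SimulationResult | None


def sweep_grid(
    ranges: Mapping[str, tuple[float, float]], increment: float
) -> list[dict[str, float]]:
    """Cartesian ratio grid over the three categories.

    ``ranges[cat] = (lo, hi)`` inclusive with the given increment; a range
    0-1 at increment 0.1 for all three categories enumerates 11^3 = 1331
    configurations.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    axes = []
    for cat in CATEGORIES:
        lo, hi = ranges.get(cat, (0.0, 0.0))
        if lo > hi:
            raise ValueError(f"{cat}: lo > hi")
        n = int(round((hi - lo) / increment)) + 1 if hi > lo else 1
        axes.append([lo + i * increment for i in range(n)])
    return [
        dict(zip(CATEGORIES, combo)) for combo in itertools.product(*axes)
    ]


def sweep(
    deduced: LineageDB,
    ranges: Mapping[str, tuple[float, float]],
    increment: float,
    params: TMEParams,
    run: bool = True,
) -> list[SweepRun]:
    """Run (or enumerate, with ``run=False``) a full ratio sweep.

    Each grid point derives its own seed from ``(params.seed, grid index)``,
    so runs are independent of execution order and individually replayable.
    """
    n_cancer = len(deduced.progenitors())
    out = []
    for i, ratios in enumerate(sweep_grid(ranges, increment)):
        derived = int(
            np.random.SeedSequence([params.seed, i]).generate_state(1)[0] % (2**31)
        )
        counts = agent_counts(n_cancer, ratios=ratios)
        result = None
        if run:
            run_params = replace(params, seed=derived)
            world = place_agents(
                {c: counts[f"n_{c}"] for c in CATEGORIES},
                n_cancer,
                run_params,
                seed=derived,
            )
            result = run_simulation(deduced, world, run_params)
        out.append(SweepRun(ratios=ratios, counts=counts, seed=derived, result=result))
    return out
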