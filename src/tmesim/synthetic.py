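"""Synthetic inputs with the statistical structure the pipeline assumes.

The lineage generator emulates the empirical shape of tracked cancer-cell
populations: growth dominated by bipolar division with a doubling time around
26-27 h, rare multipolar division / death / fusion, a majority of post-MD and
post-CF progeny dying, and a subpopulation of α2-6Sia-expressing cells whose
doubling times cluster tightly (within ±10% of their mean at association
strength 1).  Terminal cells carry a measured SNA1 value: zero in
non-expressing lineages, a right-skewed positive value in expressing ones —
the half-zeros structure of a mixed tracked population.

Ground-truth parameters live in the :class:`FixtureSpec`, so model-recovery
tests can compare refitted probabilities against what generated the data.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lineage import CellRecord, Fate, LineageDB

__all__ = ["FixtureSpec", "make_synthetic_lineage_db", "make_synthetic_landscape"]


def _default_transitions() -> dict[str, dict[str, float]]:
    growth = {"BD": 0.90, "MD": 0.03, "CD": 0.05, "CF": 0.02}
    post_aberrant = {"BD": 0.30, "MD": 0.05, "CD": 0.55, "CF": 0.10}
    return {
        "START": dict(growth),
        "BD": dict(growth),
        "MD": dict(post_aberrant),
        "CF": dict(post_aberrant),
    }


def _default_durations() -> dict[str, tuple]:
    # log-normal waits, median = 1596 min (26.6 h doubling time)
    return {p: ("lognormal", 1596.0, 0.18) for p in ("START", "BD", "MD", "CF")}


@dataclass
class FixtureSpec:
    """Ground truth for a synthetic lineage database.

    ``transitions[prior][next]`` are probabilities (summing to 1 per prior);
    ``durations[prior]`` is ``("lognormal", median_minutes, sigma)`` or
    ``("fixed", minutes)``.  ``frac_expressing`` is the fraction of lineages
    founded by an α2-6Sia-expressing cell; ``association`` in [0, 1] controls
    how tightly expressing cells' division waits cluster around the typical
    doubling time (1 = all within ±10%).
    """

    n_lineages: int = 100
    horizon: float = 10_200.0
    transitions: dict[str, dict[str, float]] = field(
        default_factory=_default_transitions
    )
    durations: dict[str, tuple] = field(default_factory=_default_durations)
    md_arity_probs: dict[int, float] = field(
        default_factory=lambda: {3: 0.9, 4: 0.1}
    )
    frac_expressing: float = 0.5
    expr_median: float = 800.0
    expr_sigma: float = 0.5
    association: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lineages <= 0:
            raise ValueError("n_lineages must be positive")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        for prior, probs in self.transitions.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"transitions[{prior!r}] sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"negative probability under {prior!r}")
        if not 0 <= self.frac_expressing <= 1:
            raise ValueError("frac_expressing must lie in [0, 1]")
        if not 0 <= self.association <= 1:
            raise ValueError("association must lie in [0, 1]")


def _draw_duration(
    spec: FixtureSpec, prior: str, rng: np.random.Generator, expressing: bool
) -> float:
    kind, *args = spec.durations[prior]
    if kind == "fixed":
        return float(args[0])
    if kind != "lognormal":
        raise ValueError(f"unknown duration kind {kind!r}")
    median, sigma = args
    if expressing and rng.uniform() < spec.association:
        # expressing cells: tight doubling times, within ±10% of the typical
        return float(rng.uniform(0.9 * median, 1.1 * median))
    return float(median * np.exp(sigma * rng.normal()))


def make_synthetic_lineage_db(spec: FixtureSpec) -> LineageDB:
    """Generate a valid lineage database with terminal SNA1 measurements."""
    rng = np.random.default_rng(spec.seed)
    records: list[CellRecord] = []
    arities = sorted(spec.md_arity_probs)
    arity_p = np.array([spec.md_arity_probs[a] for a in arities], dtype=float)
    arity_p = arity_p / arity_p.sum()

    for lineage_id in range(1, spec.n_lineages + 1):
        expressing = rng.uniform() < spec.frac_expressing
        cells: dict[int, dict] = {}
        heap: list[tuple[float, int]] = []
        cancelled: set[int] = set()
        next_id = 0

        def sample_event(prior: str) -> str:
            probs = spec.transitions[prior]
            names = sorted(probs)
            return str(
                rng.choice(names, p=np.array([probs[n] for n in names]))
            )

        def new_cell(birth: float, prior: str, parents: tuple[int, ...]) -> None:
            nonlocal next_id
            ev = sample_event(prior)
            dur = _draw_duration(spec, prior, rng, expressing)
            cid = next_id
            next_id += 1
            cells[cid] = {
                "birth": birth,
                "fate_time": birth + dur,
                "event": ev,
                "parents": parents,
                "done": False,
            }
            if birth + dur <= spec.horizon:
                heapq.heappush(heap, (birth + dur, cid))

        new_cell(0.0, "START", ())

        while heap:
            t, cid = heapq.heappop(heap)
            if cid in cancelled or cells[cid]["done"]:
                continue
            cell = cells[cid]
            ev = cell["event"]
            if ev == "CF":
                # a fusion leaves two CF records (initiator + partner), so a
                # sampled CF initiates only half the time; this keeps the
                # realized per-cell CF rate equal to spec.transitions
                initiate = rng.uniform() < 0.5
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
                    # weight recruitment by the candidate prior's CF share so
                    # realized per-prior CF rates match spec.transitions
                    def _prior_of(c):
                        ps = cells[c]["parents"]
                        if not ps:
                            return "START"
                        return cells[ps[0]]["event"] if len(ps) == 1 else "CF"

                    weights = np.array(
                        [
                            spec.transitions[_prior_of(c)].get("CF", 0.0)
                            for c in partners
                        ]
                    )
                    partners = partners if weights.sum() > 0 else []
                if partners:
                    partner = int(rng.choice(partners, p=weights / weights.sum()))
                    cancelled.add(partner)
                    cells[partner].update(done=True, event="CF", fate_time=t)
                    cell["done"] = True
                    new_cell(t, "CF", (cid, partner))
                    continue
                # no partner alive: renormalize over the non-CF alternatives
                prior = (
                    "START"
                    if not cell["parents"]
                    else (
                        cells[cell["parents"][0]]["event"]
                        if len(cell["parents"]) == 1
                        else "CF"
                    )
                )
                probs = {
                    k: v for k, v in spec.transitions[prior].items() if k != "CF"
                }
                total = sum(probs.values())
                if total > 0:
                    names = sorted(probs)
                    ev = str(
                        rng.choice(
                            names, p=np.array([probs[n] / total for n in names])
                        )
                    )
                else:
                    ev = "CD"
                cell["event"] = ev
            cell["done"] = True
            if ev == "BD":
                for _ in range(2):
                    new_cell(t, "BD", (cid,))
            elif ev == "MD":
                arity = int(rng.choice(arities, p=arity_p))
                cell["md_poles"] = arity
                for _ in range(arity):
                    new_cell(t, "MD", (cid,))

        for cid in sorted(cells):
            info = cells[cid]
            if info["done"] or cid in cancelled:
                fate, fate_time, sna1 = Fate(info["event"]), info["fate_time"], None
            else:
                fate, fate_time = Fate.ALIVE_END, spec.horizon
                sna1 = (
                    float(
                        spec.expr_median * np.exp(spec.expr_sigma * rng.normal())
                    )
                    if expressing
                    else 0.0
                )
            records.append(
                CellRecord(
                    lineage_id=lineage_id,
                    cell_id=cid,
                    parent_ids=tuple(info["parents"]),
                    birth_time=info["birth"],
                    fate_time=fate_time,
                    fate=fate,
                    md_poles=info.get("md_poles"),
                    sna1=sna1,
                )
            )

    return LineageDB(
        records=records, frame_interval=10.0, observation_end=spec.horizon
    )


# canonical columns of a ConsensusTME-style export, including the two types
# the categorization deliberately excludes
_LANDSCAPE_COLUMNS = [
    "T_cells_CD4",
    "T_cells_CD8",
    "T_cells_gamma_delta",
    "B_cells",
    "Plasma_cells",
    "Monocytes",
    "Macrophages_M2",
    "T_regulatory_cells",
    "Mast_cells",
    "Endothelial_cells",
    "Fibroblasts",
    "Cytotoxic_cells",
    "NK_cells",
    "Macrophages_M1",
    "Neutrophils",
]


def make_synthetic_landscape(
    n_cases: int,
    seed: int = 0,
    case_prefix: str = "case",
    path: str | Path | None = None,
) -> pd.DataFrame:
    """A per-case cell-type percentage table in ConsensusTME layout.

    Each row's percentages come from a Dirichlet draw scaled to a random
    total immune/stromal content between 20% and 80% of the tumor.
    """
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    rng = np.random.default_rng(seed)
    alpha = np.full(len(_LANDSCAPE_COLUMNS), 0.8)
    shares = rng.dirichlet(alpha, size=n_cases)
    totals = rng.uniform(20.0, 80.0, size=(n_cases, 1))
    data = np.round(shares * totals, 4)
    df = pd.DataFrame(data, columns=_LANDSCAPE_COLUMNS)
    df.insert(0, "case_id", [f"{case_prefix}_{i+1:04d}" for i in range(n_cases)])
    if path is not None:
        df.to_csv(path, index=False)
    return df
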