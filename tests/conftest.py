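import logging

import pytest

from tmesim import (
    CellRecord,
    Fate,
    FixtureSpec,
    LineageDB,
    make_synthetic_lineage_db,
)

# extinct synthetic lineages legitimately carry no terminal SNA1 measurement;
# silence the (intended) warning noise in the test run
logging.getLogger("tmesim.sialylation").setLevel(logging.ERROR)


def toy_bd_db() -> LineageDB:
    """Progenitor dividing at t=600 into two daughters alive until t=1200."""
    return LineageDB(
        records=[
            CellRecord(1, 0, (), 0.0, 600.0, Fate.BD),
            CellRecord(1, 1, (0,), 600.0, 1200.0, Fate.ALIVE_END, sna1=2.0),
            CellRecord(1, 2, (0,), 600.0, 1200.0, Fate.ALIVE_END, sna1=4.0),
        ],
        frame_interval=10.0,
        observation_end=1200.0,
    )


def fusion_db() -> LineageDB:
    """Two progenitor daughters fuse; the product survives to the end."""
    return LineageDB(
        records=[
            CellRecord(1, 0, (), 0.0, 500.0, Fate.BD),
            CellRecord(1, 1, (0,), 500.0, 900.0, Fate.CF),
            CellRecord(1, 2, (0,), 500.0, 900.0, Fate.CF),
            CellRecord(1, 3, (1, 2), 900.0, 1500.0, Fate.ALIVE_END, sna1=5.0),
        ],
        frame_interval=10.0,
        observation_end=1500.0,
    )


def complete_bd_tree(generations: int, step: float = 500.0) -> LineageDB:
    """Complete binary tree: every cell divides after ``step`` minutes."""
    records = [
        CellRecord(1, 0, (), 0.0, step, Fate.BD if generations > 0 else Fate.ALIVE_END)
    ]
    frontier = [0]
    next_id = 1
    for g in range(1, generations + 1):
        born = g * step
        fate = Fate.BD if g < generations else Fate.ALIVE_END
        new_frontier = []
        for parent in frontier:
            for _ in range(2):
                records.append(
                    CellRecord(1, next_id, (parent,), born, born + step, fate)
                )
                new_frontier.append(next_id)
                next_id += 1
        frontier = new_frontier
    return LineageDB(
        records=records, frame_interval=10.0, observation_end=(generations + 1) * step
    )


def small_random_db(seed: int, n_lineages: int = 3, horizon: float = 5000.0) -> LineageDB:
    """Small but eventful synthetic database for fuzz/oracle comparisons."""
    spec = FixtureSpec(
        n_lineages=n_lineages,
        horizon=horizon,
        transitions={
            "START": {"BD": 0.80, "MD": 0.08, "CD": 0.07, "CF": 0.05},
            "BD": {"BD": 0.80, "MD": 0.08, "CD": 0.07, "CF": 0.05},
            "MD": {"BD": 0.35, "MD": 0.05, "CD": 0.50, "CF": 0.10},
            "CF": {"BD": 0.35, "MD": 0.05, "CD": 0.50, "CF": 0.10},
        },
        durations={p: ("lognormal", 900.0, 0.35) for p in ("START", "BD", "MD", "CF")},
        frac_expressing=0.6,
        seed=seed,
    )
    return make_synthetic_lineage_db(spec)


@pytest.fixture(scope="session")
def fixture_db() -> LineageDB:
    """Medium synthetic database shared across statistics tests."""
    return make_synthetic_lineage_db(FixtureSpec(n_lineages=60, horizon=8000.0, seed=11))
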