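"""3D TME engine: geometry, effect arithmetic, subtree removal, full runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmesim import (
    CellRecord,
    Fate,
    FateSimParams,
    FixtureSpec,
    LineageDB,
    TMEParams,
    TMEWorld,
    adjusted_suppressive_strength,
    apply_lethal,
    apply_permissive,
    apply_suppressive,
    effect_probability,
    fit_transition_model,
    make_synthetic_lineage_db,
    neighbors_within,
    place_agents,
    population_curve,
    run_simulation,
    simulate_population,
    subtree,
    sweep,
    sweep_grid,
)
from tmesim.tme import min_doubling_time, sample_in_ball

from conftest import complete_bd_tree


# ---------------------------------------------------------------------------
# strength / probability arithmetic


def test_adjusted_strength_worked_example():
    assert adjusted_suppressive_strength(50, 50, 3, 6) == 25.0


def test_adjusted_strength_full_cancellation_at_equal_distance():
    assert adjusted_suppressive_strength(40, 40, 5, 5) == 0.0


def test_adjusted_strength_without_permissive_influence():
    assert adjusted_suppressive_strength(30, 0, 2, 6) == 30.0


def test_adjusted_strength_clamped_at_zero():
    assert adjusted_suppressive_strength(10, 100, 5, 6) == 0.0


def test_adjusted_strength_rejects_nonpositive_distances():
    with pytest.raises(ValueError):
        adjusted_suppressive_strength(50, 50, 0, 6)


@settings(max_examples=50, derandomize=True)
@given(
    s1=st.floats(0, 100),
    s2=st.floats(0, 100),
    d1=st.floats(0.1, 6),
    d2=st.floats(0.1, 6),
)
def test_adjusted_strength_bounds(s1, s2, d1, d2):
    lo, hi = sorted((d1, d2))
    adj = adjusted_suppressive_strength(s1, s2, lo, hi)
    assert 0 <= adj <= s1


def test_effect_probability_five_fold_resistance():
    assert effect_probability(100.0, 100.0, 5.0) == pytest.approx(0.2)


def test_effect_probability_no_resistance():
    assert effect_probability(0.0, 100.0, 5.0) == 1.0
    assert effect_probability(50.0, 100.0, 1.0) == 1.0
    assert effect_probability(None, 100.0, 5.0) == 1.0


def test_effect_probability_linear_midpoint():
    assert effect_probability(50.0, 100.0, 5.0) == pytest.approx(1 / 3)


def test_effect_probability_rejects_resistance_below_one():
    with pytest.raises(ValueError):
        effect_probability(1.0, 1.0, 0.5)


# ---------------------------------------------------------------------------
# geometry


def test_neighbors_empty_when_none_in_radius():
    positions = np.array([[10.0, 0, 0]])
    assert neighbors_within(np.zeros(3), positions, radius=6.0) == []


def test_neighbors_picks_two_nearest():
    positions = np.array([[2.0, 0, 0], [4.0, 0, 0], [5.0, 0, 0]])
    result = neighbors_within(np.zeros(3), positions, radius=6.0)
    assert [i for i, _ in result] == [0, 1]
    assert [d for _, d in result] == pytest.approx([2.0, 4.0])


def test_neighbors_ties_broken_by_index():
    positions = np.array([[3.0, 0, 0], [0, 3.0, 0], [0, 0, 3.0]])
    result = neighbors_within(np.zeros(3), positions, radius=6.0)
    assert [i for i, _ in result] == [0, 1]


@pytest.mark.parametrize("seed", range(10))
def test_neighbors_match_exhaustive_sort_oracle(seed):
    rng = np.random.default_rng(seed)
    positions = rng.uniform(-8, 8, size=(40, 3))
    point = rng.uniform(-2, 2, size=3)
    result = neighbors_within(point, positions, radius=6.0)
    oracle = sorted(
        (float(np.linalg.norm(p - point)), i)
        for i, p in enumerate(positions)
        if np.linalg.norm(p - point) <= 6.0
    )[:2]
    assert [(i, pytest.approx(d)) for d, i in oracle] == result


def test_placement_stays_inside_sphere():
    params = TMEParams(seed=5)
    world = place_agents({"suppressive": 200, "lethal": 100}, 150, params)
    assert (np.linalg.norm(world.micro_xyz, axis=1) <= params.sphere_radius).all()
    assert (np.linalg.norm(world.cancer_xyz, axis=1) <= params.sphere_radius).all()
    assert world.counts() == {"suppressive": 200, "permissive": 0, "lethal": 100}


def test_placement_radial_cdf():
    """Uniform placement in a ball: P(r <= x) = (x/R)^3."""
    from scipy import stats as sps

    rng = np.random.default_rng(0)
    pts = sample_in_ball(rng, 5000, 50.0)
    radii = np.linalg.norm(pts, axis=1)
    res = sps.kstest(radii, lambda x: (x / 50.0) ** 3)
    assert res.pvalue > 0.01


def test_placement_reproducible_from_seed():
    params = TMEParams(seed=9)
    a = place_agents({"lethal": 50}, 20, params)
    b = place_agents({"lethal": 50}, 20, params)
    assert (a.micro_xyz == b.micro_xyz).all()
    assert (a.cancer_xyz == b.cancer_xyz).all()


# ---------------------------------------------------------------------------
# database-level effect operations


def _division_toy() -> LineageDB:
    c = CellRecord(1, 0, (), 0.0, 1500.0, Fate.BD)  # 25 h doubling
    d1 = CellRecord(1, 1, (0,), 1500.0, 1800.0, Fate.ALIVE_END)
    d2 = CellRecord(1, 2, (0,), 1500.0, 1800.0, Fate.ALIVE_END)
    return LineageDB([c, d1, d2], observation_end=1800.0)


def test_suppressive_prolongs_25h_to_27_5h():
    out = apply_suppressive(_division_toy(), 1, 0, 10.0)
    assert out.index[(1, 0)].fate_time == pytest.approx(1650.0)  # 27.5 h
    # daughters shift with the parent
    assert out.index[(1, 1)].birth_time == pytest.approx(1650.0)


def test_zero_strength_is_identity():
    db = _division_toy()
    assert apply_suppressive(db, 1, 0, 0.0) == db
    assert apply_permissive(db, 1, 0, 0.0, min_doubling=1200.0) == db


def test_permissive_shortens_with_floor():
    db = LineageDB(
        [CellRecord(1, 0, (), 0.0, 1500.0, Fate.CD)], observation_end=1500.0
    )
    out = apply_permissive(db, 1, 0, 10.0, min_doubling=1200.0)
    assert out.index[(1, 0)].fate_time == pytest.approx(1350.0)  # 22.5 h

    short = LineageDB(
        [CellRecord(1, 0, (), 0.0, 1260.0, Fate.CD)], observation_end=1260.0
    )
    floored = apply_permissive(short, 1, 0, 10.0, min_doubling=1200.0)
    assert floored.index[(1, 0)].fate_time == pytest.approx(1200.0)


def test_permissive_rejects_strength_100():
    with pytest.raises(ValueError):
        apply_permissive(_division_toy(), 1, 0, 100.0, min_doubling=10.0)


@pytest.mark.parametrize("strength, k", [(10.0, 1.1), (50.0, 1.5)])
def test_subtree_rescale_matches_per_record_multiplication(strength, k):
    db = complete_bd_tree(3, step=400.0)
    out = apply_suppressive(db, 1, 0, strength)
    for r in out.records:
        orig = db.index[r.key]
        if orig.fate is Fate.ALIVE_END:
            continue  # censored records are capped at the observation end
        assert r.duration == pytest.approx(orig.duration * k)


def test_kill_leaf_removes_only_that_cell():
    db = complete_bd_tree(1, step=500.0)  # 3 records: root + 2 leaves
    out = apply_lethal(db, 1, 2, at_time=700.0)
    assert len(out) == 3
    killed = out.index[(1, 2)]
    assert killed.fate is Fate.CD
    assert killed.fate_time == 700.0


def test_kill_root_of_8_leaf_tree_removes_15_records():
    db = complete_bd_tree(3, step=500.0)
    assert len(db) == 15
    assert len(subtree(db, 1, 0)) == 15
    out = apply_lethal(db, 1, 0, at_time=100.0)
    # the whole subtree is removed; only the CD record of the cell remains
    assert len(out) == 1
    assert out.records[0].fate is Fate.CD


@pytest.mark.parametrize("seed", range(5))
def test_random_kills_leave_complement_of_subtree(seed):
    from conftest import small_random_db

    db = small_random_db(seed)
    rng = np.random.default_rng(seed)
    target = db.records[int(rng.integers(len(db.records)))]
    out = apply_lethal(db, target.lineage_id, target.cell_id)
    removed = subtree(db, target.lineage_id, target.cell_id)
    surviving = {r.key for r in out.records}
    expected = {
        r.key
        for r in db.records
        if not (r.lineage_id == target.lineage_id and r.cell_id in removed)
    } | {target.key}
    assert surviving == expected


# ---------------------------------------------------------------------------
# full simulation runs


def _deduced(n=30, horizon=6000.0, seed=1) -> LineageDB:
    src = make_synthetic_lineage_db(
        FixtureSpec(n_lineages=40, horizon=8000.0, seed=17)
    )
    model = fit_transition_model(src)
    return simulate_population(
        model, FateSimParams(n_progenitors=n, horizon=horizon, seed=seed)
    )


@pytest.fixture(scope="module")
def deduced_db() -> LineageDB:
    return _deduced()


def test_empty_world_equals_unperturbed_population(deduced_db):
    params = TMEParams(seed=2, horizon=6000.0)
    world = place_agents({}, 30, params)
    result = run_simulation(deduced_db, world, params)
    control = population_curve(deduced_db, times=result.times)
    assert (result.population == control.values).all()


def test_zero_strengths_equal_control(deduced_db):
    base = TMEParams(seed=2, horizon=6000.0)
    world = place_agents(
        {"suppressive": 40, "permissive": 40, "lethal": 40}, 30, base
    )
    zeroed = TMEParams(seed=2, horizon=6000.0, s_sup=0, s_perm=0, s_lethal=0)
    result = run_simulation(deduced_db, world, zeroed)
    control = run_simulation(deduced_db, place_agents({}, 30, base), zeroed)
    assert (result.population == control.population).all()


def test_certain_death_extinguishes_population(deduced_db):
    params = TMEParams(seed=3, horizon=6000.0, s_lethal=100.0, resistance_max=1.0)
    n = len(deduced_db.progenitors())
    empty = place_agents({}, n, params)
    # one lethal agent coincident with every cancer progenitor anchor
    world = TMEWorld(
        micro_xyz=empty.cancer_xyz.copy(),
        micro_cat=np.array(["lethal"] * n, dtype=object),
        cancer_xyz=empty.cancer_xyz,
        sphere_radius=params.sphere_radius,
    )
    result = run_simulation(deduced_db, world, params)
    assert result.final_population == 0
    # every progenitor was killed on its first (and only) lethal encounter
    kills = [e for e in result.effect_log if e.effect == "killed"]
    assert len(kills) == n


def test_one_effect_rule_in_log(deduced_db):
    params = TMEParams(
        seed=5, horizon=6000.0, s_sup=50.0, s_perm=40.0, s_lethal=0.0
    )
    world = place_agents(
        {"suppressive": 150, "permissive": 150}, 30, params
    )
    result = run_simulation(deduced_db, world, params)
    applied = [e for e in result.effect_log
               if e.applied and e.category in ("suppressive", "permissive")]
    assert applied, "expected some applied effects at these densities"
    keys = [(e.lineage_id, e.cell_id) for e in applied]
    assert len(keys) == len(set(keys))


def test_run_is_seed_deterministic(deduced_db):
    params = TMEParams(seed=7, horizon=6000.0, s_lethal=50.0, resistance_max=2.0)
    world = place_agents({"suppressive": 60, "lethal": 60}, 30, params)
    a = run_simulation(deduced_db, world, params)
    b = run_simulation(deduced_db, world, params)
    assert (a.population == b.population).all()
    assert a.effect_log == b.effect_log
    assert a.db == b.db


def test_result_population_consistent_with_records(deduced_db):
    params = TMEParams(seed=11, horizon=6000.0, s_lethal=80.0)
    world = place_agents({"lethal": 80, "permissive": 40}, 30, params)
    result = run_simulation(deduced_db, world, params)
    result.db.validate()
    recounted = population_curve(result.db, times=result.times)
    assert (result.population == recounted.values).all()
    assert result.final_population == sum(
        1 for r in result.db.records if r.fate is Fate.ALIVE_END
    )


def test_suppressed_cells_divide_later_than_control(deduced_db):
    params = TMEParams(seed=13, horizon=6000.0, s_sup=80.0, s_lethal=0.0)
    world = place_agents({"suppressive": 250}, 30, params)
    result = run_simulation(deduced_db, world, params)
    control = run_simulation(deduced_db, place_agents({}, 30, params), params)
    assert result.final_population <= control.final_population
    suppressed = [e for e in result.effect_log if e.effect == "suppressed"]
    assert suppressed


def test_min_doubling_time_is_shortest_bd_duration(deduced_db):
    durations = [r.duration for r in deduced_db.records if r.fate is Fate.BD]
    assert min_doubling_time(deduced_db) == min(durations)


# ---------------------------------------------------------------------------
# sweeps


def test_sweep_grid_1331_configurations():
    ranges = {c: (0.0, 1.0) for c in ("suppressive", "permissive", "lethal")}
    assert len(sweep_grid(ranges, 0.1)) == 1331


def test_sweep_grid_27_configurations():
    ranges = {c: (0.0, 1.0) for c in ("suppressive", "permissive", "lethal")}
    assert len(sweep_grid(ranges, 0.5)) == 27


def test_sweep_grid_single_point():
    ranges = {c: (0.2, 0.2) for c in ("suppressive", "permissive", "lethal")}
    assert len(sweep_grid(ranges, 0.1)) == 1


def test_sweep_grid_rejects_bad_increment():
    with pytest.raises(ValueError):
        sweep_grid({"lethal": (0.0, 1.0)}, 0.0)


def test_sweep_runs_are_order_independent(deduced_db):
    params = TMEParams(seed=19, horizon=3000.0, s_lethal=100.0)
    ranges = {"lethal": (0.0, 0.5)}
    runs = sweep(deduced_db, ranges, 0.5, params)
    assert len(runs) == 2
    assert runs[0].counts["n_lethal"] == 0
    assert runs[1].counts["n_lethal"] == 15
    # replaying a single grid point reproduces its recorded result
    replay = sweep(deduced_db, ranges, 0.5, params)[1]
    assert (replay.result.population == runs[1].result.population).all()
    assert runs[0].seed != runs[1].seed
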