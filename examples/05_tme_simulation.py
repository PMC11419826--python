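"""A full 3D TME run: deduced cancer cells among microenvironment agents.

Places a deduced population and its suppressive/permissive/lethal neighbors
uniformly in a 50-px sphere and simulates 6000 min, logging every resolved
encounter.  A control without agents shows the unperturbed expansion.
"""

import numpy as np

from tmesim import (
    FateSimParams,
    FixtureSpec,
    TMEParams,
    assign_expression,
    backpropagate_expression,
    build_expression_list,
    fit_transition_model,
    make_synthetic_lineage_db,
    place_agents,
    run_simulation,
    simulate_population,
)

source = backpropagate_expression(
    make_synthetic_lineage_db(FixtureSpec(n_lineages=100, horizon=10_200.0, seed=6))
)
expr = build_expression_list(source, source="synthetic-100")
model = fit_transition_model(source)
params = FateSimParams(n_progenitors=200, horizon=6000.0, seed=7)
deduced = assign_expression(simulate_population(model, params), expr, source, params)

tme = TMEParams(
    seed=8, horizon=6000.0, s_sup=10.0, s_perm=10.0, s_lethal=100.0,
    resistance_max=5.0, v_max=expr.v_max,
)
n = len(deduced.progenitors())

control = run_simulation(deduced, place_agents({}, n, tme), tme)
print(f"control (no microenvironment): {control.final_population} cells at 6000 min")

world = place_agents(
    {"suppressive": 90, "permissive": 40, "lethal": 60}, n, tme
)
result = run_simulation(deduced, world, tme)
print(f"with TME ({world.counts()}): {result.final_population} cells")

by_effect = {}
for e in result.effect_log:
    if e.applied:
        by_effect[e.effect] = by_effect.get(e.effect, 0) + 1
print(f"applied effects: {by_effect} over {len(result.effect_log)} encounters")
print(f"reproductive MD-progeny in the surviving population: "
      f"{result.md_progeny_count} ({100 * result.md_progeny_fraction:.2f}%)")
if len(result.final_expression):
    print(f"mean α2-6Sia among survivors: {np.mean(result.final_expression):.0f} "
          f"(population max {expr.v_max:.0f})")
# fewer cells than control = the net suppressive + lethal burden of this world
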