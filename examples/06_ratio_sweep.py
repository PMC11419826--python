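"""Parameter sweep over microenvironment ratios.

Enumerates a cancer:lethal ratio grid (with fixed suppressive/permissive) and
runs one seeded simulation per grid point, showing how the final population
falls as the lethal burden rises.
"""

from tmesim import (
    FateSimParams,
    FixtureSpec,
    TMEParams,
    fit_transition_model,
    make_synthetic_lineage_db,
    simulate_population,
    sweep,
    sweep_grid,
)

source = make_synthetic_lineage_db(FixtureSpec(n_lineages=80, horizon=9000.0, seed=9))
model = fit_transition_model(source)
deduced = simulate_population(
    model, FateSimParams(n_progenitors=100, horizon=5000.0, seed=10)
)

# the full three-category grid of the worked example: 11^3 configurations
full = sweep_grid({c: (0.0, 1.0) for c in ("suppressive", "permissive", "lethal")}, 0.1)
print(f"0-1 by 0.1 over three categories enumerates {len(full)} configurations")

params = TMEParams(seed=11, horizon=5000.0, s_lethal=100.0)
runs = sweep(deduced, {"lethal": (0.0, 1.0)}, 0.25, params)
print("cancer:lethal ratio -> final population")
for r in runs:
    print(f"  1:{r.ratios['lethal']:.2f} ({r.counts['n_lethal']:3d} agents) "
          f"-> {r.result.final_population}")
# monotone decline with lethal burden; each grid point has its own derived seed
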