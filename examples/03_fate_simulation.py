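"""Deduced cell populations from the event-transition model.

Fits the empirical (next event, duration) model from a source population,
generates a 500-progenitor deduced population over 170 h, assigns α2-6Sia
expression through the ±10% doubling-time gate, and scales it by the in-vivo
variation factors.
"""

from tmesim import (
    Fate,
    FateSimParams,
    FixtureSpec,
    assign_expression,
    backpropagate_expression,
    build_expression_list,
    fit_transition_model,
    make_synthetic_lineage_db,
    scale_expression,
    simulate_population,
)

source = backpropagate_expression(
    make_synthetic_lineage_db(FixtureSpec(n_lineages=100, horizon=10_200.0, seed=3))
)
expr = build_expression_list(source, source="synthetic-100")
model = fit_transition_model(source)
print("fitted conditionals:")
for prior in model.priors():
    probs = {k: round(v, 3) for k, v in model.probabilities(prior).items()}
    print(f"  after {prior}: {probs}  ({len(model.pairs[prior])} events)")

params = FateSimParams(n_progenitors=500, horizon=10_200.0, seed=4)
deduced = simulate_population(model, params)
final = sum(1 for r in deduced.records if r.fate is Fate.ALIVE_END)
print(f"deduced population: {len(deduced)} cells from 500 progenitors, "
      f"{final} alive at 170 h")

deduced = assign_expression(deduced, expr, source, params)
assigned = [r.sna1 for r in deduced.records if r.sna1 is not None]
print(f"expression assigned to {len(assigned)} cells "
      f"(mean {sum(assigned) / len(assigned):.0f} SNA1 units)")

for factor in (1.5, 0.5, 0.25):
    scaled = scale_expression(deduced, factor, expr.v_max)
    vals = [r.sna1 for r in scaled.records if r.sna1 is not None]
    print(f"  x{factor}: mean {sum(vals) / len(vals):.0f} "
          f"(capped at {expr.v_max:.0f})")
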