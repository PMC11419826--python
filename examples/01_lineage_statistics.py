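"""Lineage analytics on a synthetic tracked population.

Generates a synthetic single-cell lineage database (the statistical stand-in
for a tracked cancer-cell population), then computes the population expansion
curve, event tallies, post-MD/CF fate patterns, doubling times and the
reproductive MD-progeny count.
"""

from tmesim import (
    FixtureSpec,
    doubling_time_stats,
    event_totals,
    fate_patterns,
    make_synthetic_lineage_db,
    md_reproductive_progeny,
    population_curve,
)

db = make_synthetic_lineage_db(FixtureSpec(n_lineages=100, horizon=10_200.0, seed=1))
print(f"{len(db)} cells in {len(db.lineage_ids())} lineages over 170 h")

curve = population_curve(db, normalize_to=100)
print(f"population curve (normalized to 100 at time 1): "
      f"start {curve.iloc[0]:.0f} -> end {curve.iloc[-1]:.1f}")
# the end value over 100 is the fold-expansion of the population

_, totals = event_totals(db)
print(f"event totals: {totals}  (multipolar divisions, deaths, fusions)")

patterns = fate_patterns(db)
print("fates following MD/CF:",
      {k: v for k, v in patterns.counts.items() if "+" not in k and v})

dts = doubling_time_stats(db)
print(f"doubling time: mean {dts.mean / 60:.1f} h "
      f"(range {dts.min / 60:.1f}-{dts.max / 60:.1f} h, n={dts.n})")

count, fraction = md_reproductive_progeny(db)
print(f"reproductive MD-progeny: {count} cells "
      f"({100 * fraction:.2f}% of the final population)")
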