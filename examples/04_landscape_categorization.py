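"""Per-case TME composition reduced to suppressive/permissive/lethal fractions.

Builds a synthetic ConsensusTME-style table (one cancer case per row, one
immune/stromal cell type per column, in percent), categorizes every case and
derives the microenvironment agent counts for a 500-cell simulation.
"""

from tmesim import agent_counts, categorize, make_synthetic_landscape

# a cervical-cohort-sized table: 193 cases
df = make_synthetic_landscape(193, seed=5)
print(f"{len(df)} cases, {len(df.columns) - 1} cell-type columns")

row = df.iloc[0]
composition = row.drop("case_id").to_dict()
fractions = categorize(composition)
print(f"case {row.case_id}: fractions {({k: round(v, 3) for k, v in fractions.items()})}")
counts = agent_counts(500, fractions=fractions)
print(f"agents to place beside 500 cancer cells: {counts}")

# the two dual-role types contribute to no category
print("M1 + neutrophil percentages (excluded from every category):",
      round(row.Macrophages_M1 + row.Neutrophils, 2))

# worked arithmetic: 45% suppressive of 500 cancer cells -> 225 agents
print("45% of 500 ->", agent_counts(500, fractions={"suppressive": 0.45}))
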