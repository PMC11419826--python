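"""Per-case tumor-microenvironment composition tables reduced to suppressive /
permissive / lethal fractions and agent counts.

The categorization follows the three-microenvironment abstraction applied to
ConsensusTME-style immune-deconvolution outputs (one row per cancer case, one
column per cell type, values in percent):

* suppressive — CD4+ T cells, CD8+ T cells, gamma-delta T cells, B cells,
  plasma cells, monocytes;
* permissive — M2 macrophages, regulatory T cells, mast cells, endothelial
  cells, cancer-associated fibroblasts;
* lethal — cytotoxic cells and natural killer cells.

M1 macrophages and neutrophils play context-dependent dual roles and are
deliberately excluded.  Column labels vary between exports, so the mapping is
an editable alias table; unknown columns are reported rather than silently
dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "CATEGORIES",
    "DEFAULT_ALIASES",
    "LandscapeCase",
    "categorize",
    "agent_counts",
    "read_landscape_table",
    "write_landscape_summary",
]

CATEGORIES = ("suppressive", "permissive", "lethal")

# canonical cell-type name -> category ("exclude" = recognized but never summed)
_TYPE_CATEGORY: dict[str, str] = {
    "t_cells_cd4": "suppressive",
    "t_cells_cd8": "suppressive",
    "t_cells_gamma_delta": "suppressive",
    "b_cells": "suppressive",
    "plasma_cells": "suppressive",
    "monocytes": "suppressive",
    "macrophages_m2": "permissive",
    "t_regulatory_cells": "permissive",
    "mast_cells": "permissive",
    "endothelial_cells": "permissive",
    "fibroblasts": "permissive",
    "cytotoxic_cells": "lethal",
    "nk_cells": "lethal",
    "macrophages_m1": "exclude",
    "neutrophils": "exclude",
}

# spelling variants seen in the wild -> canonical name
DEFAULT_ALIASES: dict[str, str] = {
    "t_cell_cd4": "t_cells_cd4",
    "t_cell_cd8": "t_cells_cd8",
    "t_cell_gamma_delta": "t_cells_gamma_delta",
    "gamma_delta_t_cells": "t_cells_gamma_delta",
    "b_cell": "b_cells",
    "plasma_cell": "plasma_cells",
    "monocyte": "monocytes",
    "macrophage_m2": "macrophages_m2",
    "m2_macrophages": "macrophages_m2",
    "tregs": "t_regulatory_cells",
    "regulatory_t_cells": "t_regulatory_cells",
    "mast_cell": "mast_cells",
    "endothelial": "endothelial_cells",
    "endothelial_cell": "endothelial_cells",
    "cancer_associated_fibroblasts": "fibroblasts",
    "caf": "fibroblasts",
    "fibroblast": "fibroblasts",
    "cytotoxic_cell": "cytotoxic_cells",
    "natural_killer_cells": "nk_cells",
    "nk_cell": "nk_cells",
    "macrophage_m1": "macrophages_m1",
    "m1_macrophages": "macrophages_m1",
    "neutrophil": "neutrophils",
}


def _normalize(name: str) -> str:
    return (
        name.strip()
        .lower()
        .replace(" ", "_")
        .replace(".", "_")
        .replace("-", "_")
        .replace("+", "")
    )


def _resolve(name: str, aliases: Mapping[str, str] | None) -> str | None:
    """Canonical type for a column name, "ignore", or None when unknown."""
    norm = _normalize(name)
    if aliases:
        mapped = {_normalize(k): v for k, v in aliases.items()}.get(norm)
        if mapped is not None:
            return mapped if mapped == "ignore" else _normalize(mapped)
    if norm in _TYPE_CATEGORY:
        return norm
    mapped = DEFAULT_ALIASES.get(norm)
    return mapped


@dataclass(frozen=True)
class LandscapeCase:
    """One cancer case: raw cell-type percentages and derived category fractions."""

    case_id: str
    composition: dict[str, float]
    fractions: dict[str, float]


def categorize(
    composition: Mapping[str, float],
    aliases: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Reduce a cell-type percentage map to the three category fractions.

    Each fraction is the sum of the member types' percentages divided by 100.
    Unmapped and excluded (M1/neutrophil) types contribute nothing; the
    fractions are independent ratios to cancer cells and may sum above 1.
    """
    fractions = {c: 0.0 for c in CATEGORIES}
    for name, pct in composition.items():
        if pct < 0:
            raise ValueError(f"negative percentage for {name!r}: {pct}")
        canonical = _resolve(name, aliases)
        if canonical is None or canonical == "ignore":
            continue
        cat = _TYPE_CATEGORY.get(canonical)
        if cat in fractions:
            fractions[cat] += pct / 100.0
    return fractions


def agent_counts(
    n_cancer: int,
    fractions: Mapping[str, float] | None = None,
    ratios: Mapping[str, float] | None = None,
) -> dict[str, int]:
    """Microenvironment agent counts for ``n_cancer`` cancer cells.

    Each count is ``round(n_cancer * fraction)`` (nearest integer, ties to
    even); ``ratios`` gives explicit cancer:category ratios instead (e.g.
    1:0.5 places 250 agents for 500 cancer cells).
    """
    if n_cancer <= 0:
        raise ValueError("n_cancer must be positive")
    src = ratios if ratios is not None else fractions
    if src is None:
        raise ValueError("provide fractions or ratios")
    out = {}
    for cat in CATEGORIES:
        f = float(src.get(cat, 0.0))
        if f < 0:
            raise ValueError(f"negative fraction for {cat!r}")
        out[f"n_{cat}"] = round(n_cancer * f)
    return out


def read_landscape_table(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
    id_column: str | None = None,
) -> list[LandscapeCase]:
    """Read a per-case composition CSV into categorized cases.

    The id column defaults to the first column.  Columns that resolve to no
    known cell type raise a warning naming them (map them to "ignore" in
    ``aliases`` to silence); excluded types are parsed but contribute nothing.
    """
    df = pd.read_csv(path)
    if id_column is None:
        id_column = df.columns[0]
    type_cols = [c for c in df.columns if c != id_column]
    unknown = [c for c in type_cols if _resolve(c, aliases) is None]
    if unknown:
        warnings.warn(
            f"unmapped cell-type columns {unknown} contribute to no category; "
            "alias them explicitly (or to 'ignore') to silence this warning",
            stacklevel=2,
        )
    cases = []
    for _, row in df.iterrows():
        comp = {c: float(row[c]) for c in type_cols}
        cases.append(
            LandscapeCase(
                case_id=str(row[id_column]),
                composition=comp,
                fractions=categorize(comp, aliases),
            )
        )
    return cases


def write_landscape_summary(
    cases: list[LandscapeCase], path: str | Path, n_cancer: int = 500
) -> pd.DataFrame:
    """Write case_id, category fractions and agent counts (for ``n_cancer``)."""
    rows = []
    for case in cases:
        counts = agent_counts(n_cancer, fractions=case.fractions)
        rows.append({"case_id": case.case_id, **case.fractions, **counts})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
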