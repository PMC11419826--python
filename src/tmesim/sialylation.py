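"""Back-propagation of terminal SNA1 (α2-6Sia) measurements and the expression
list consumed by the fate simulator.

SNA1 lectin staining happens once, at the end of live-cell imaging, so only
cells alive at the observation end carry a measured value.  Ancestral values
are reconstructed by walking each lineage tree bottom-up: every dividing cell
receives the arithmetic mean of its daughters' (post-propagation) values.
Dead branches (CD leaves) carry no measurement and are simply excluded from
the average — death is not evidence of zero expression.  A fusion product's
value propagates to both of its parents equally.

The resulting per-cell values across *all* generations form the expression
list: the pool the fate simulator draws from when assigning α2-6Sia levels to
deduced cells.  Measured zeros are kept (a zero is a real observation of a
non-expressing cell).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

from .lineage import LineageDB

__all__ = ["ExpressionList", "backpropagate_expression", "build_expression_list"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionList:
    """Immutable pool of SNA1 values with the observed population maximum."""

    values: tuple[float, ...]
    v_max: float | None
    source: str = ""

    def __post_init__(self) -> None:
        if self.values:
            expected = max(self.values)
            if self.v_max is None or self.v_max != expected:
                object.__setattr__(self, "v_max", expected)

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path: str | Path) -> None:
        lines = [
            f"#tmesim-expression v1 source={self.source or '-'} "
            f"v_max={'' if self.v_max is None else repr(float(self.v_max))}",
            "sna1",
        ]
        lines += [repr(float(v)) for v in self.values]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExpressionList":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("#tmesim-expression"):
            raise ValueError(f"{path}: missing expression-list header")
        meta = dict(tok.partition("=")[::2] for tok in lines[0].split()[2:])
        values = tuple(float(x) for x in lines[2:] if x.strip())
        return cls(values=values, v_max=None if not values else max(values),
                   source=meta.get("source", ""))


def backpropagate_expression(db: LineageDB) -> LineageDB:
    """Fill ancestral ``sna1`` values from measured terminal cells.

    Returns a new database in which every cell with descendants carries the
    mean of its children's (post-propagation) values, averaging only over
    branches that carry a measurement.  Leaves are unchanged.  A lineage with
    no measured cell at all is left untouched (with a log warning).  The
    operation is idempotent.
    """
    new_values: dict[tuple[int, int], float | None] = {}
    for lid in db.lineage_ids():
        cells = db.lineage(lid)
        if not any(r.sna1 is not None for r in cells):
            logger.warning(
                "lineage %d has no measured SNA1 value; left untouched", lid
            )
            for r in cells:
                new_values[r.key] = r.sna1
            continue
        # bottom-up: visit cells in decreasing fate_time order so every child
        # is resolved before its parent(s)
        for r in sorted(cells, key=lambda c: (-c.fate_time, -c.birth_time, c.cell_id)):
            kids = db.children_of(lid, r.cell_id)
            if not kids:
                new_values[r.key] = r.sna1
            else:
                vals = [
                    new_values[k.key] for k in kids if new_values[k.key] is not None
                ]
                new_values[r.key] = sum(vals) / len(vals) if vals else None
    return db.with_records(
        replace(r, sna1=new_values[r.key]) for r in db.records
    )


def build_expression_list(db: LineageDB, source: str = "") -> ExpressionList:
    """Collect every present ``sna1`` value (all generations, zeros included).

    Expected to run after :func:`backpropagate_expression` so internal
    generations contribute.  An empty database yields an empty list with
    ``v_max`` flagged as None.
    """
    values = tuple(r.sna1 for r in db.records if r.sna1 is not None)
    return ExpressionList(
        values=values, v_max=max(values) if values else None, source=source
    )
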