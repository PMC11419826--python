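"""Cell-lineage data model and serialization.

A :class:`LineageDB` is the genealogy of tracked or simulated cells.  Each
:class:`CellRecord` is one cell *generation*: the cell exists from its birth
until its fate event, which is one of

* ``BD`` – bipolar division (two daughters),
* ``MD`` – multipolar division (``md_poles`` >= 3 daughters),
* ``CD`` – cell death (no daughters),
* ``CF`` – cell fusion (two partner cells end in CF at the same instant and a
  single fusion product with two parents is born),
* ``ALIVE_END`` – the cell was still alive when observation (or simulation)
  ended.

Times are minutes.  Empirical data is frame based (default 10-min frames);
simulated data may carry real-valued times.  An optional ``sna1`` field holds
the SNA1 lectin fluorescence value of the cell (a proxy for membrane
α2-6-linked sialic acid), in arbitrary units.

Files come in two equivalent layouts, CSV (one row per cell, ``parent_ids``
semicolon-joined) and JSON, both carrying a versioned schema header plus the
database-level metadata (``frame_interval``, ``observation_end``).
"""

from __future__ import annotations

import csv
import io
import json
from collections import deque
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Fate",
    "CellRecord",
    "LineageDB",
    "LineageValidationError",
    "read_lineage_db",
    "write_lineage_db",
    "subtree",
]

SCHEMA_NAME = "tmesim-lineage"
SCHEMA_VERSION = 1


class Fate(str, Enum):
    """Terminal event of one cell generation."""

    BD = "BD"
    MD = "MD"
    CD = "CD"
    CF = "CF"
    ALIVE_END = "ALIVE_END"


#: Fates that leave descendants in the lineage tree.
DIVISION_FATES = (Fate.BD, Fate.MD)


class LineageValidationError(ValueError):
    """A lineage database violates a structural invariant.

    The message names the offending (lineage_id, cell_id) where applicable.
    """


@dataclass(frozen=True)
class CellRecord:
    """One cell generation in a lineage tree."""

    lineage_id: int
    cell_id: int
    parent_ids: tuple[int, ...]
    birth_time: float
    fate_time: float
    fate: Fate
    md_poles: int | None = None
    sna1: float | None = None

    @property
    def key(self) -> tuple[int, int]:
        return (self.lineage_id, self.cell_id)

    @property
    def duration(self) -> float:
        """Minutes from birth to the fate event (censoring time for ALIVE_END)."""
        return self.fate_time - self.birth_time


@dataclass
class LineageDB:
    """A collection of cell records plus observation metadata."""

    records: list[CellRecord]
    frame_interval: float = 10.0
    observation_end: float = 0.0

    def __post_init__(self) -> None:
        self._index: dict[tuple[int, int], CellRecord] | None = None
        self._children: dict[tuple[int, int], list[CellRecord]] | None = None

    # -- derived lookups ---------------------------------------------------

    @property
    def index(self) -> dict[tuple[int, int], CellRecord]:
        if self._index is None:
            self._index = {r.key: r for r in self.records}
        return self._index

    @property
    def children_map(self) -> dict[tuple[int, int], list[CellRecord]]:
        """Parent key -> child records (fusion products appear under both parents)."""
        if self._children is None:
            cm: dict[tuple[int, int], list[CellRecord]] = {}
            for r in self.records:
                for pid in r.parent_ids:
                    cm.setdefault((r.lineage_id, pid), []).append(r)
            self._children = cm
        return self._children

    def children_of(self, lineage_id: int, cell_id: int) -> list[CellRecord]:
        return self.children_map.get((lineage_id, cell_id), [])

    def lineage_ids(self) -> list[int]:
        return sorted({r.lineage_id for r in self.records})

    def lineage(self, lineage_id: int) -> list[CellRecord]:
        return [r for r in self.records if r.lineage_id == lineage_id]

    def progenitors(self) -> list[CellRecord]:
        return [r for r in self.records if not r.parent_ids]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CellRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LineageDB):
            return NotImplemented
        return (
            self.frame_interval == other.frame_interval
            and self.observation_end == other.observation_end
            and self.records == other.records
        )

    def with_records(self, records: Iterable[CellRecord]) -> "LineageDB":
        return LineageDB(
            records=list(records),
            frame_interval=self.frame_interval,
            observation_end=self.observation_end,
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> "LineageDB":
        """Check every structural invariant; raise LineageValidationError on the
        first violation, naming the offending record.  Returns self."""
        seen: set[tuple[int, int]] = set()
        for r in self.records:
            if r.key in seen:
                raise LineageValidationError(f"duplicate cell id {r.key}")
            seen.add(r.key)

        idx = {r.key: r for r in self.records}
        for r in self.records:
            if len(r.parent_ids) not in (0, 1, 2):
                raise LineageValidationError(
                    f"cell {r.key}: {len(r.parent_ids)} parents (must be 0, 1 or 2)"
                )
            if r.birth_time < 0:
                raise LineageValidationError(f"cell {r.key}: negative birth_time")
            if not r.parent_ids and r.birth_time != 0:
                raise LineageValidationError(
                    f"progenitor {r.key}: birth_time {r.birth_time} != 0"
                )
            if r.fate is Fate.ALIVE_END:
                # fate_time > birth_time, or equal to the observation end for a
                # cell born exactly at the final frame
                if r.fate_time < r.birth_time or (
                    r.fate_time == r.birth_time
                    and r.fate_time != self.observation_end
                ):
                    raise LineageValidationError(
                        f"cell {r.key}: ALIVE_END fate_time {r.fate_time} "
                        f"inconsistent with birth_time {r.birth_time}"
                    )
            elif r.fate_time <= r.birth_time:
                raise LineageValidationError(
                    f"cell {r.key}: fate_time {r.fate_time} <= birth_time "
                    f"{r.birth_time}"
                )
            if r.fate is Fate.MD:
                if r.md_poles is None or r.md_poles < 3:
                    raise LineageValidationError(
                        f"cell {r.key}: MD requires md_poles >= 3"
                    )
            elif r.md_poles is not None:
                raise LineageValidationError(
                    f"cell {r.key}: md_poles set for non-MD fate {r.fate.value}"
                )
            if r.sna1 is not None and r.sna1 < 0:
                raise LineageValidationError(f"cell {r.key}: negative sna1")
            for pid in r.parent_ids:
                parent = idx.get((r.lineage_id, pid))
                if parent is None:
                    raise LineageValidationError(
                        f"cell {r.key}: dangling parent reference {pid}"
                    )
                if parent.fate_time != r.birth_time:
                    raise LineageValidationError(
                        f"cell {r.key}: birth_time {r.birth_time} != parent "
                        f"{parent.key} fate_time {parent.fate_time}"
                    )
            if len(r.parent_ids) == 2:
                p0 = idx[(r.lineage_id, r.parent_ids[0])]
                p1 = idx[(r.lineage_id, r.parent_ids[1])]
                for p in (p0, p1):
                    if p.fate is not Fate.CF:
                        raise LineageValidationError(
                            f"cell {r.key}: fusion parent {p.key} has fate "
                            f"{p.fate.value}, expected CF"
                        )
                if p0.fate_time != p1.fate_time:
                    raise LineageValidationError(
                        f"cell {r.key}: fusion partners {p0.key}/{p1.key} have "
                        "different fate times"
                    )

        # fate arity: number of children must match the fate
        cm: dict[tuple[int, int], list[CellRecord]] = {}
        for r in self.records:
            for pid in r.parent_ids:
                cm.setdefault((r.lineage_id, pid), []).append(r)
        for r in self.records:
            kids = cm.get(r.key, [])
            if r.fate is Fate.BD and len(kids) != 2:
                raise LineageValidationError(
                    f"cell {r.key}: BD has {len(kids)} children, expected 2"
                )
            if r.fate is Fate.MD and len(kids) != r.md_poles:
                raise LineageValidationError(
                    f"cell {r.key}: MD has {len(kids)} children, expected "
                    f"{r.md_poles}"
                )
            if r.fate in (Fate.CD, Fate.ALIVE_END) and kids:
                raise LineageValidationError(
                    f"cell {r.key}: {r.fate.value} cell has children"
                )
            if r.fate is Fate.CF:
                products = [k for k in kids if len(k.parent_ids) == 2]
                if len(products) != 1 or len(kids) != 1:
                    raise LineageValidationError(
                        f"cell {r.key}: CF must have exactly one fusion product "
                        f"child, found {len(kids)}"
                    )
        # Acyclicity follows from the strict time ordering checked above:
        # every non-ALIVE_END parent has fate_time > birth_time and every
        # child's birth_time equals its parent's fate_time.
        return self


# ---------------------------------------------------------------------------
# subtree


def subtree(db: LineageDB, lineage_id: int, cell_id: int) -> set[int]:
    """The cell and all its descendants (cell ids within ``lineage_id``).

    The set is closed under the child relation; a fusion product belongs to the
    subtree as soon as *either* of its parents does.
    """
    if (lineage_id, cell_id) not in db.index:
        raise KeyError(f"unknown cell ({lineage_id}, {cell_id})")
    out: set[int] = {cell_id}
    queue: deque[int] = deque([cell_id])
    while queue:
        cid = queue.popleft()
        for child in db.children_of(lineage_id, cid):
            if child.cell_id not in out:
                out.add(child.cell_id)
                queue.append(child.cell_id)
    return out


# ---------------------------------------------------------------------------
# serialization

_CSV_FIELDS = [
    "lineage_id",
    "cell_id",
    "parent_ids",
    "birth_time",
    "fate_time",
    "fate",
    "md_poles",
    "sna1",
]


def _fmt_num(x: float) -> str:
    """Shortest exact decimal representation (round-trips bit-identically)."""
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


def write_lineage_db(db: LineageDB, path: str | Path, format: str | None = None) -> None:
    """Serialize ``db`` so that :func:`read_lineage_db` recovers equal content."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        buf = io.StringIO()
        buf.write(
            f"#{SCHEMA_NAME} v{SCHEMA_VERSION} "
            f"frame_interval={_fmt_num(db.frame_interval)} "
            f"observation_end={_fmt_num(db.observation_end)}\n"
        )
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(_CSV_FIELDS)
        for r in db.records:
            writer.writerow(
                [
                    r.lineage_id,
                    r.cell_id,
                    ";".join(str(p) for p in r.parent_ids),
                    _fmt_num(r.birth_time),
                    _fmt_num(r.fate_time),
                    r.fate.value,
                    "" if r.md_poles is None else r.md_poles,
                    "" if r.sna1 is None else _fmt_num(r.sna1),
                ]
            )
        path.write_text(buf.getvalue())
    elif fmt == "json":
        payload = {
            "schema": SCHEMA_NAME,
            "version": SCHEMA_VERSION,
            "frame_interval": db.frame_interval,
            "observation_end": db.observation_end,
            "records": [
                {
                    "lineage_id": r.lineage_id,
                    "cell_id": r.cell_id,
                    "parent_ids": list(r.parent_ids),
                    "birth_time": r.birth_time,
                    "fate_time": r.fate_time,
                    "fate": r.fate.value,
                    "md_poles": r.md_poles,
                    "sna1": r.sna1,
                }
                for r in db.records
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_lineage_db(
    path: str | Path, format: str | None = None, validate: bool = True
) -> LineageDB:
    """Read and (by default) validate a lineage database file."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        text = path.read_text()
        lines = text.splitlines()
        if not lines or not lines[0].startswith(f"#{SCHEMA_NAME}"):
            raise LineageValidationError(
                f"{path}: missing '{SCHEMA_NAME}' schema header"
            )
        meta: dict[str, float] = {}
        for tok in lines[0].split()[2:]:
            k, _, v = tok.partition("=")
            meta[k] = float(v)
        records = []
        reader = csv.DictReader(lines[1:])
        for row in reader:
            records.append(
                CellRecord(
                    lineage_id=int(row["lineage_id"]),
                    cell_id=int(row["cell_id"]),
                    parent_ids=tuple(
                        int(p) for p in row["parent_ids"].split(";") if p != ""
                    ),
                    birth_time=float(row["birth_time"]),
                    fate_time=float(row["fate_time"]),
                    fate=Fate(row["fate"]),
                    md_poles=int(row["md_poles"]) if row["md_poles"] else None,
                    sna1=float(row["sna1"]) if row["sna1"] else None,
                )
            )
        db = LineageDB(
            records=records,
            frame_interval=meta.get("frame_interval", 10.0),
            observation_end=meta.get("observation_end", 0.0),
        )
    elif fmt == "json":
        payload = json.loads(path.read_text())
        if payload.get("schema") != SCHEMA_NAME:
            raise LineageValidationError(f"{path}: unexpected schema")
        records = [
            CellRecord(
                lineage_id=int(rec["lineage_id"]),
                cell_id=int(rec["cell_id"]),
                parent_ids=tuple(int(p) for p in rec["parent_ids"]),
                birth_time=float(rec["birth_time"]),
                fate_time=float(rec["fate_time"]),
                fate=Fate(rec["fate"]),
                md_poles=rec.get("md_poles"),
                sna1=rec.get("sna1"),
            )
            for rec in payload["records"]
        ]
        db = LineageDB(
            records=records,
            frame_interval=float(payload["frame_interval"]),
            observation_end=float(payload["observation_end"]),
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if validate:
        db.validate()
    return db
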