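"""Typed containers and file I/O for pedigrees, behavioral logs and dyadic matrices.

All downstream matrix algebra assumes a shared, ordered individual index;
:class:`DyadicMatrix` carries that index explicitly and every reader/writer
in this module preserves it deterministically (id-sorted on disk).

File formats (CSV or TSV, chosen by extension):

* pedigree: columns ``id, mother, father, birth_date, sex`` — empty parent
  fields mark founders, dates are ISO-8601;
* event log: columns ``focal, partner, behavior, value, protocol``;
* conflict log: columns ``winner, loser``;
* focal time: columns ``id, hours``;
* dyadic matrix: first row and first column are ids.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Behaviors recognised in event logs.
BEHAVIOR_CATALOGUE = frozenset(
    {"proximity", "body_contact", "grooming", "agonistic-submission", "approach", "retreat"}
)

#: The three CSI component behaviors (affiliation rates).
AFFILIATIVE_BEHAVIORS = ("proximity", "body_contact", "grooming")

FEMALE = "female"
MALE = "male"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, bad refs)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    Parent ids of ``None`` mark founders (or unrecorded parentage, which is
    treated identically: the individual contributes no ancestral paths
    through that side).
    """

    id: str
    mother_id: str | None = None
    father_id: str | None = None
    birth_date: _dt.date | None = None
    sex: str | None = None
    alive_during_study: bool = True


@dataclass(frozen=True)
class BehaviorEvent:
    """A single focal-protocol record: focal interacted with partner.

    ``duration_or_count`` is seconds for state behaviors (grooming, body
    contact, proximity when sampled as a state) and a count for point events;
    the distinction never matters downstream because only behavior-wise rates
    are used and the CSI normalises each behavior by its own grand mean.
    """

    focal_id: str
    partner_id: str
    behavior: str
    duration_or_count: float
    protocol_id: str = ""

    def __post_init__(self) -> None:
        if self.focal_id == self.partner_id:
            raise ValueError(f"focal and partner are the same id: {self.focal_id!r}")
        if self.behavior not in BEHAVIOR_CATALOGUE:
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if not np.isfinite(self.duration_or_count) or self.duration_or_count < 0:
            raise ValueError(f"duration_or_count must be >= 0, got {self.duration_or_count}")


@dataclass(frozen=True)
class ConflictRecord:
    """Outcome of one decided agonistic conflict."""

    winner_id: str
    loser_id: str

    def __post_init__(self) -> None:
        if self.winner_id == self.loser_id:
            raise ValueError(f"winner and loser are the same id: {self.winner_id!r}")


class PedigreeTable:
    """Validated collection of :class:`Individual` records.

    Validation enforces unique ids, resolvable parent references, parent sex
    consistency (when sex is recorded) and acyclicity of the ancestry graph.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self._by_id: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._by_id:
                raise PedigreeError(f"duplicate individual id: {ind.id!r}")
            self._by_id[ind.id] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self._by_id.values():
            for parent_id, expected_sex, role in (
                (ind.mother_id, FEMALE, "mother"),
                (ind.father_id, MALE, "father"),
            ):
                if parent_id is None:
                    continue
                if parent_id not in self._by_id:
                    raise PedigreeError(
                        f"{ind.id!r} references unknown {role} {parent_id!r}"
                    )
                parent = self._by_id[parent_id]
                if parent.sex is not None and parent.sex != expected_sex:
                    raise PedigreeError(
                        f"{role} {parent_id!r} of {ind.id!r} has sex {parent.sex!r}"
                    )
        cycle = self._find_cycle()
        if cycle:
            raise PedigreeError("cyclic ancestry: " + " -> ".join(cycle))

    def _find_cycle(self) -> list[str] | None:
        # iterative DFS over parent links; returns one offending cycle
        WHITE, GREY, BLACK = 0, 1, 2
        color = {i: WHITE for i in self._by_id}
        for start in self._by_id:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            path: list[str] = []
            while stack:
                node, pi = stack[-1]
                if pi == 0:
                    color[node] = GREY
                    path.append(node)
                parents = [
                    p
                    for p in (self._by_id[node].mother_id, self._by_id[node].father_id)
                    if p is not None
                ]
                if pi < len(parents):
                    stack[-1] = (node, pi + 1)
                    parent = parents[pi]
                    if color[parent] == GREY:
                        return path[path.index(parent):] + [parent]
                    if color[parent] == WHITE:
                        stack.append((parent, 0))
                else:
                    color[node] = BLACK
                    path.pop()
                    stack.pop()
        return None

    # -- mapping-style access -------------------------------------------------

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __getitem__(self, individual_id: str) -> Individual:
        try:
            return self._by_id[individual_id]
        except KeyError:
            raise KeyError(f"id {individual_id!r} not in pedigree") from None

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PedigreeTable):
            return NotImplemented
        return self._by_id == other._by_id

    @property
    def ids(self) -> list[str]:
        return sorted(self._by_id)

    def females(self) -> list[str]:
        return sorted(i.id for i in self if i.sex == FEMALE)

    def parents(self, individual_id: str) -> tuple[str | None, str | None]:
        ind = self[individual_id]
        return ind.mother_id, ind.father_id

    def topological_order(self) -> list[str]:
        """Ids ordered parents-before-offspring (founders first)."""
        order: list[str] = []
        seen: set[str] = set()

        def visit(i: str) -> None:
            if i in seen:
                return
            seen.add(i)
            for p in self.parents(i):
                if p is not None:
                    visit(p)
            order.append(i)

        for i in self.ids:
            visit(i)
        return order

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": i.id,
                "mother": i.mother_id or "",
                "father": i.father_id or "",
                "birth_date": i.birth_date.isoformat() if i.birth_date else "",
                "sex": i.sex or "",
                "alive": int(i.alive_during_study),
            }
            for i in sorted(self, key=lambda x: x.id)
        ]
        return pd.DataFrame(
            rows, columns=["id", "mother", "father", "birth_date", "sex", "alive"]
        )


@dataclass
class DyadicMatrix:
    """Square individual-by-individual matrix with an aligned id index.

    When ``directed`` is False the matrix must be symmetric; when
    ``diagonal_defined`` is False the diagonal carries no information and is
    excluded from every statistic computed downstream.
    """

    ids: list[str]
    values: np.ndarray
    directed: bool = False
    diagonal_defined: bool = False
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in DyadicMatrix")
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} ids"
            )
        if not self.directed and self.values.dtype.kind in "fiu":
            if not np.allclose(self.values, self.values.T, equal_nan=True):
                raise ValueError("undirected DyadicMatrix must be symmetric")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        return self.values[self._index[a], self._index[b]]

    @property
    def n(self) -> int:
        return len(self.ids)

    def dyads(self) -> list[tuple[str, str]]:
        """Unordered dyads in index order (upper triangle)."""
        return [
            (self.ids[i], self.ids[j])
            for i in range(self.n)
            for j in range(i + 1, self.n)
        ]

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle values (undirected) or all off-diagonal (directed)."""
        if self.directed:
            mask = ~np.eye(self.n, dtype=bool)
            return self.values[mask]
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reindex(self, ids: Sequence[str]) -> "DyadicMatrix":
        """Return a copy aligned to a new id order (ids must be a subset)."""
        idx = [self._index[i] for i in ids]
        return DyadicMatrix(
            list(ids),
            self.values[np.ix_(idx, idx)].copy(),
            directed=self.directed,
            diagonal_defined=self.diagonal_defined,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_date(text: str) -> _dt.date | None:
    text = (text or "").strip()
    if not text:
        return None
    return _dt.date.fromisoformat(text)


def read_pedigree(path: str | Path) -> PedigreeTable:
    """Read and validate a pedigree table.

    Raises :class:`PedigreeError` on duplicate ids, unresolvable parent
    references or cyclic ancestry (an individual appearing among its own
    ancestors).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    required = {"id", "mother", "father", "birth_date", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree file missing columns: {sorted(missing)}")
    individuals = [
        Individual(
            id=row["id"].strip(),
            mother_id=row["mother"].strip() or None,
            father_id=row["father"].strip() or None,
            birth_date=_parse_date(row["birth_date"]),
            sex=row["sex"].strip() or None,
            alive_during_study=bool(int(row["alive"])) if "alive" in df.columns else True,
        )
        for _, row in df.iterrows()
    ]
    return PedigreeTable(individuals)


def write_pedigree(pedigree: PedigreeTable, path: str | Path) -> None:
    path = Path(path)
    pedigree.to_frame().to_csv(path, sep=_sep_for(path), index=False)


def read_events(path: str | Path) -> list[BehaviorEvent]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    return [
        BehaviorEvent(
            focal_id=row["focal"].strip(),
            partner_id=row["partner"].strip(),
            behavior=row["behavior"].strip(),
            duration_or_count=float(row["value"]),
            protocol_id=row.get("protocol", "").strip(),
        )
        for _, row in df.iterrows()
    ]


def write_events(events: Sequence[BehaviorEvent], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "focal": e.focal_id,
                "partner": e.partner_id,
                "behavior": e.behavior,
                "value": e.duration_or_count,
                "protocol": e.protocol_id,
            }
            for e in events
        ],
        columns=["focal", "partner", "behavior", "value", "protocol"],
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_conflicts(path: str | Path) -> list[ConflictRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    return [
        ConflictRecord(winner_id=row["winner"].strip(), loser_id=row["loser"].strip())
        for _, row in df.iterrows()
    ]


def write_conflicts(records: Sequence[ConflictRecord], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        [{"winner": r.winner_id, "loser": r.loser_id} for r in records],
        columns=["winner", "loser"],
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_focal_time(path: str | Path) -> dict[str, float]:
    """Read per-individual focal observation time (hours)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"id": str})
    return {str(row["id"]).strip(): float(row["hours"]) for _, row in df.iterrows()}


def write_focal_time(hours: Mapping[str, float], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        sorted(hours.items()), columns=["id", "hours"]
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_matrix(path: str | Path, directed: bool = False) -> DyadicMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise ValueError("matrix file row and column ids differ")
    return DyadicMatrix(ids, df.to_numpy(), directed=directed)


def write_matrix(matrix: DyadicMatrix, path: str | Path) -> None:
    """Write a dyadic matrix in id-sorted order (deterministic on disk)."""
    path = Path(path)
    order = sorted(matrix.ids)
    matrix.reindex(order).to_frame().to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# event aggregation
# ---------------------------------------------------------------------------


def events_to_rate_matrices(
    events: Sequence[BehaviorEvent],
    focal_time: Mapping[str, float],
    behaviors: Sequence[str] = AFFILIATIVE_BEHAVIORS,
    ids: Sequence[str] | None = None,
) -> dict[str, DyadicMatrix]:
    """Aggregate an event log into one undirected rate matrix per behavior.

    The dyadic rate is the total duration-or-count recorded for the dyad
    across both members' focal sessions, divided by the *sum* of the two
    members' focal observation time — the standard focal-sampling
    normalisation, which keeps rates comparable when observation effort
    varies across individuals.  Who happened to be focal is pooled, so
    matrices are symmetric with zero diagonal.

    Parameters
    ----------
    events
        Behavioral records; only those whose behavior is in ``behaviors``
        contribute.
    focal_time
        Observation hours per individual; must be positive for every id
        appearing in a retained event.
    behaviors
        Behaviors to build matrices for (default: the three CSI components).
    ids
        Optional explicit id universe; defaults to the sorted keys of
        ``focal_time``.
    """
    id_list = sorted(focal_time) if ids is None else list(ids)
    index = {i: k for k, i in enumerate(id_list)}
    n = len(id_list)
    totals = {b: np.zeros((n, n)) for b in behaviors}
    wanted = set(behaviors)
    for e in events:
        if e.behavior not in wanted:
            continue
        for who in (e.focal_id, e.partner_id):
            if who not in index:
                raise KeyError(f"event references id {who!r} with no focal time")
            if not focal_time.get(who, 0) > 0:
                raise ValueError(f"id {who!r} has non-positive focal time")
        i, j = index[e.focal_id], index[e.partner_id]
        totals[e.behavior][i, j] += e.duration_or_count
        totals[e.behavior][j, i] += e.duration_or_count
    hours = np.array([focal_time[i] for i in id_list], dtype=float)
    denom = hours[:, None] + hours[None, :]
    out: dict[str, DyadicMatrix] = {}
    for b in behaviors:
        rates = totals[b] / denom
        np.fill_diagonal(rates, 0.0)
        out[b] = DyadicMatrix(id_list, rates, directed=False, diagonal_defined=False)
    return out
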