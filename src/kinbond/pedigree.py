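"""Pedigree relatedness with a maternal/paternal path decomposition.

The coefficient of relatedness between two non-inbred individuals is the sum,
over all simple ancestral paths connecting them through a common ancestor, of
``0.5 ** L`` where ``L`` is the number of parent-offspring links on the path.
A path is *simple* when no individual appears on it twice; this is the
classical path-counting rule and, on non-inbred pedigrees, reproduces the
off-diagonal of the additive (numerator) relationship matrix computed by the
tabular recursion (:func:`additive_relationship_matrix`, kept here as an
independent cross-check and as a fallback for inbred input).

Each path is classified by the *first* parent link taken from each of the two
focal individuals: mother+mother paths are maternal, father+father paths are
paternal, and one-of-each paths are mixed.  When one focal individual is
itself the common ancestor (a descendant path, e.g. mother-daughter), the
single defined first link decides the class.  This is the only decomposition
under which maternal + paternal + mixed sums exactly to the total and under
which cousins through sister mothers count as maternal kin, matching how
behavioral studies of matrilineal primates tabulate kin classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from kinbond.core_io import PedigreeTable

MOTHER = "mother"
FATHER = "father"

#: Kin-category labels for female dyads.
KIN_LABELS = (
    "mother_daughter",
    "full_sisters",
    "maternal_half_sisters",
    "paternal_half_sisters",
    "distant_or_nonkin",
    "excluded",
)

#: Maternal relatedness at or above which a paternal-sister dyad is excluded
#: from kin-category contrasts (boundary inclusive).
PATERNAL_SISTER_MATERNAL_EXCLUSION = 0.0625

#: Total relatedness at or below which a dyad without a shared parent counts
#: as distant kin or non-kin (boundary inclusive).
DISTANT_KIN_THRESHOLD = 0.125


@dataclass(frozen=True)
class KinCategory:
    label: str

    def __post_init__(self) -> None:
        if self.label not in KIN_LABELS:
            raise ValueError(f"unknown kin category {self.label!r}")


@dataclass(frozen=True)
class RelatednessRecord:
    """Per-dyad relatedness and its maternal/paternal/mixed decomposition.

    ``paths`` lists (common-ancestor id, link count, contribution) for every
    counted path; components are NaN (with total from the tabular method)
    when the pedigree is inbred and the path decomposition does not apply.
    """

    id_a: str
    id_b: str
    r_maternal: float
    r_paternal: float
    r_mixed: float
    r_total: float
    paths: tuple[tuple[str, int, float], ...] = ()

    @property
    def decomposed(self) -> bool:
        return not np.isnan(self.r_maternal)


def _ancestral_paths(pedigree: PedigreeTable, start: str):
    """All simple upward paths from ``start``: (ancestor, nodes, links, first)."""
    out: list[tuple[str, frozenset[str], int, str | None]] = [
        (start, frozenset([start]), 0, None)
    ]
    stack: list[tuple[str, frozenset[str], int, str | None]] = [
        (start, frozenset([start]), 0, None)
    ]
    while stack:
        node, nodes, links, first = stack.pop()
        mother, father = pedigree.parents(node)
        for parent, link in ((mother, MOTHER), (father, FATHER)):
            if parent is None or parent in nodes:
                continue
            entry = (parent, nodes | {parent}, links + 1, first or link)
            out.append(entry)
            stack.append(entry)
    return out


def is_inbred(pedigree: PedigreeTable) -> bool:
    """True when any individual's parents are related (nonzero inbreeding)."""
    a, ids = _tabular(pedigree)
    pos = {i: k for k, i in enumerate(ids)}
    for ind in pedigree:
        if ind.mother_id is not None and ind.father_id is not None:
            if a[pos[ind.mother_id], pos[ind.father_id]] > 0:
                return True
    return False


def _tabular(pedigree: PedigreeTable) -> tuple[np.ndarray, list[str]]:
    ids = pedigree.topological_order()
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n))
    for k, i in enumerate(ids):
        mother, father = pedigree.parents(i)
        mi = pos[mother] if mother is not None else None
        fi = pos[father] if father is not None else None
        f_i = 0.5 * a[mi, fi] if (mi is not None and fi is not None) else 0.0
        a[k, k] = 1.0 + f_i
        for j in range(k):
            val = 0.0
            if mi is not None:
                val += 0.5 * a[j, mi]
            if fi is not None:
                val += 0.5 * a[j, fi]
            a[k, j] = a[j, k] = val
    return a, ids


def additive_relationship_matrix(pedigree: PedigreeTable) -> pd.DataFrame:
    """Wright's numerator relationship matrix via the tabular recursion.

    ``a[i, j] = 0.5 * (a[j, dam_i] + a[j, sire_i])`` with unknown parents
    contributing zero and ``a[i, i] = 1 + F_i``.  Off-diagonal entries equal
    the path-counting coefficient of relatedness on non-inbred pedigrees.
    """
    a, ids = _tabular(pedigree)
    order = sorted(ids)
    frame = pd.DataFrame(a, index=ids, columns=ids)
    return frame.loc[order, order]


def relatedness(
    pedigree: PedigreeTable, a: str, b: str, *, assume_non_inbred: bool = False
) -> RelatednessRecord:
    """Relatedness between ``a`` and ``b`` with path-class decomposition.

    Enumerates every simple path ``a -> common ancestor -> b`` (the two
    upward branches share no individual besides the common ancestor),
    contributes ``0.5 ** links`` per path, and accumulates contributions
    into maternal, paternal and mixed classes by the first links taken from
    ``a`` and from ``b``.

    On inbred pedigrees the simple-path sum is no longer the coefficient of
    relatedness, so the total falls back to the tabular additive relationship
    and the decomposition is reported as NaN (with a warning).  Callers that
    have already verified the pedigree may pass ``assume_non_inbred=True``
    to skip the (pedigree-wide) inbreeding check.
    """
    if a == b:
        raise ValueError("relatedness requires two distinct individuals")
    for x in (a, b):
        if x not in pedigree:
            raise KeyError(f"id {x!r} not in pedigree")
    if not assume_non_inbred and is_inbred(pedigree):
        warnings.warn(
            "pedigree is inbred: path decomposition unavailable, "
            "r_total taken from the tabular method",
            stacklevel=2,
        )
        amat = additive_relationship_matrix(pedigree)
        return RelatednessRecord(
            a, b, np.nan, np.nan, np.nan, float(amat.loc[a, b]), ()
        )

    paths_a = _ancestral_paths(pedigree, a)
    paths_b = _ancestral_paths(pedigree, b)
    by_anc_b: dict[str, list[tuple[frozenset[str], int, str | None]]] = {}
    for anc, nodes, links, first in paths_b:
        by_anc_b.setdefault(anc, []).append((nodes, links, first))

    totals = {MOTHER + MOTHER: 0.0, FATHER + FATHER: 0.0, "mixed": 0.0}
    paths: list[tuple[str, int, float]] = []
    for anc, nodes_a, links_a, first_a in paths_a:
        for nodes_b, links_b, first_b in by_anc_b.get(anc, ()):
            if nodes_a & nodes_b != {anc}:
                continue
            links = links_a + links_b
            contribution = 0.5 ** links
            firsts = {f for f in (first_a, first_b) if f is not None}
            if firsts == {MOTHER}:
                key = MOTHER + MOTHER
            elif firsts == {FATHER}:
                key = FATHER + FATHER
            else:
                key = "mixed"
            totals[key] += contribution
            paths.append((anc, links, contribution))

    r_mat = totals[MOTHER + MOTHER]
    r_pat = totals[FATHER + FATHER]
    r_mix = totals["mixed"]
    return RelatednessRecord(
        a, b, r_mat, r_pat, r_mix, r_mat + r_pat + r_mix, tuple(paths)
    )


def classify_kin(record: RelatednessRecord, pedigree: PedigreeTable) -> KinCategory:
    """Assign a dyad to a kin category.

    Categories (mutually exclusive, total over dyads):

    * ``mother_daughter`` — parent-offspring link in either direction;
    * ``full_sisters`` — same (known) mother and same (known) father;
    * ``maternal_half_sisters`` — same mother, fathers differ or unknown;
    * ``paternal_half_sisters`` — same father, mothers differ, and maternal
      relatedness below 0.0625;
    * ``excluded`` — same father but maternally related at >= 0.0625
      (confounded paternal/maternal contrast), or no shared parent yet total
      relatedness above 0.125 (close lateral kin such as aunt-niece, which
      fit no contrast category; retained for regression analyses);
    * ``distant_or_nonkin`` — no shared parent and total relatedness <= 0.125.

    Unknown parents never match: two individuals with unrecorded fathers are
    treated as having distinct founder fathers.
    """
    a, b = record.id_a, record.id_b
    mother_a, father_a = pedigree.parents(a)
    mother_b, father_b = pedigree.parents(b)
    if a in (mother_b, father_b) or b in (mother_a, father_a):
        return KinCategory("mother_daughter")
    same_mother = mother_a is not None and mother_a == mother_b
    same_father = father_a is not None and father_a == father_b
    if same_mother and same_father:
        return KinCategory("full_sisters")
    if same_mother:
        return KinCategory("maternal_half_sisters")
    if same_father:
        if record.r_maternal >= PATERNAL_SISTER_MATERNAL_EXCLUSION:
            return KinCategory("excluded")
        return KinCategory("paternal_half_sisters")
    if record.r_total <= DISTANT_KIN_THRESHOLD:
        return KinCategory("distant_or_nonkin")
    return KinCategory("excluded")


def relatedness_table(
    pedigree: PedigreeTable, ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Relatedness and kin category for every unordered dyad among ``ids``.

    Columns: id_a, id_b, r_maternal, r_paternal, r_mixed, r_total, category.
    """
    members = sorted(ids) if ids is not None else pedigree.females()
    non_inbred = not is_inbred(pedigree)  # checked once for the whole table
    rows = []
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            rec = relatedness(pedigree, a, b, assume_non_inbred=non_inbred)
            rows.append(
                {
                    "id_a": a,
                    "id_b": b,
                    "r_maternal": rec.r_maternal,
                    "r_paternal": rec.r_paternal,
                    "r_mixed": rec.r_mixed,
                    "r_total": rec.r_total,
                    "category": classify_kin(rec, pedigree).label,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "id_a",
            "id_b",
            "r_maternal",
            "r_paternal",
            "r_mixed",
            "r_total",
            "category",
        ],
    )


def paternal_sister_probability_by_age_gap(
    pedigree: PedigreeTable, females: Iterable[str]
) -> pd.DataFrame:
    """Proportion of female dyads sharing a father, per integer age gap.

    Age gap is the absolute difference in birth years.  Dyads with a missing
    birth date are skipped with a warning.  Returns columns
    ``age_gap, n_dyads, n_paternal_sisters, proportion``.
    """
    members = sorted(females)
    counts: dict[int, list[int]] = {}
    skipped = 0
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            ind_a, ind_b = pedigree[a], pedigree[b]
            if ind_a.birth_date is None or ind_b.birth_date is None:
                skipped += 1
                continue
            gap = abs(ind_a.birth_date.year - ind_b.birth_date.year)
            shared = (
                ind_a.father_id is not None and ind_a.father_id == ind_b.father_id
            )
            tally = counts.setdefault(gap, [0, 0])
            tally[0] += 1
            tally[1] += int(shared)
    if skipped:
        warnings.warn(f"skipped {skipped} dyads with missing birth dates", stacklevel=2)
    rows = [
        {
            "age_gap": gap,
            "n_dyads": n,
            "n_paternal_sisters": k,
            "proportion": k / n,
        }
        for gap, (n, k) in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["age_gap", "n_dyads", "n_paternal_sisters", "proportion"]
    )
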