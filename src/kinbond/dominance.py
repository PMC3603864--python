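"""Dominance-hierarchy construction and diagnostics.

The hierarchy is built from decided agonistic conflicts.  Each dyad's net
direction is the more frequent winner; dyads with equal non-zero counts are
tied and dyads with no conflicts are unknown.  Ranking uses the I&SI
criterion: minimise first the number of inconsistencies I (dyads whose net
direction contradicts the order), then their total strength SI (summed rank
distances of inconsistent dyads).  For small groups (n <= 8) the optimum is
found by exhaustive enumeration of all orders; otherwise a seeded
local-search with random restarts is used.

Linearity is measured by Landau's h and de Vries' h' (unknown and tied
relationships randomly filled and averaged), with a two-step randomization
p-value against random-preference null matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from kinbond.core_io import ConflictRecord


@dataclass
class ConflictMatrix:
    """Win-loss count matrix: ``wins[i][j]`` = times id i defeated id j."""

    ids: list[str]
    wins: np.ndarray

    def __post_init__(self) -> None:
        self.wins = np.asarray(self.wins, dtype=int)
        n = len(self.ids)
        if self.wins.shape != (n, n):
            raise ValueError("wins matrix shape does not match ids")
        if (self.wins < 0).any():
            raise ValueError("win counts must be non-negative")
        if np.diag(self.wins).any():
            raise ValueError("diagonal of a conflict matrix must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class RankOrder:
    """An ordering of ids (rank 1 = top) with its I&SI score."""

    order: tuple[str, ...]
    I: int
    SI: int


@dataclass
class HierarchyDiagnostics:
    h: float | None = None
    h_prime: float | None = None
    p_linearity: float | None = None
    dci: float | None = None
    pct_unknown: float | None = None
    pct_two_way: float | None = None
    pct_tied: float | None = None
    pct_inconsistent: float | None = None


def build_conflict_matrix(
    records: Sequence[ConflictRecord], ids: Sequence[str]
) -> ConflictMatrix:
    """Tally decided conflicts into a win-loss matrix over ``ids``."""
    index = {i: k for k, i in enumerate(ids)}
    wins = np.zeros((len(ids), len(ids)), dtype=int)
    for r in records:
        for who in (r.winner_id, r.loser_id):
            if who not in index:
                raise KeyError(f"conflict references unknown id {who!r}")
        wins[index[r.winner_id], index[r.loser_id]] += 1
    return ConflictMatrix(list(ids), wins)


def _net_edges(wins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Directed edges (u, v): u net-dominates v (strictly more wins)."""
    dominated = wins > wins.T
    u, v = np.nonzero(dominated)
    return u, v


def _score_order(ranks: np.ndarray, eu: np.ndarray, ev: np.ndarray) -> tuple[int, int]:
    """(I, SI) of an order given by ``ranks`` (position of each individual)."""
    diff = ranks[eu] - ranks[ev]
    bad = diff > 0
    return int(bad.sum()), int(diff[bad].sum())


def _exhaustive_isi(matrix: ConflictMatrix) -> RankOrder:
    n = matrix.n
    eu, ev = _net_edges(matrix.wins)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    ranks = np.argsort(perms, axis=1)  # ranks[m, ind] = position of ind in perm m
    if len(eu):
        diff = ranks[:, eu] - ranks[:, ev]
        bad = diff > 0
        I = bad.sum(axis=1)
        SI = np.where(bad, diff, 0).sum(axis=1)
    else:
        I = np.zeros(len(perms), dtype=int)
        SI = np.zeros(len(perms), dtype=int)
    score = I.astype(np.int64) * (n ** 3) + SI
    best = score == score.min()
    candidates = perms[best]
    # deterministic tie-break: lexicographically smallest id sequence
    sequences = [tuple(matrix.ids[i] for i in p) for p in candidates]
    order = min(sequences)
    k = sequences.index(order)
    return RankOrder(order, int(I[best][k]), int(SI[best][k]))


def _local_search(
    perm: np.ndarray, eu: np.ndarray, ev: np.ndarray, big: int
) -> tuple[np.ndarray, int]:
    """First-improvement search over pairwise swaps and insertion moves."""
    perm = perm.copy()
    ranks = np.argsort(perm)
    i_cur, si_cur = _score_order(ranks, eu, ev)
    cur = i_cur * big + si_cur
    n = len(perm)
    improved = True
    while improved:
        improved = False
        # pairwise position swaps
        for i in range(n - 1):
            for j in range(i + 1, n):
                perm[i], perm[j] = perm[j], perm[i]
                ranks[perm[i]], ranks[perm[j]] = i, j
                i_new, si_new = _score_order(ranks, eu, ev)
                new = i_new * big + si_new
                if new < cur:
                    cur = new
                    improved = True
                else:
                    perm[i], perm[j] = perm[j], perm[i]
                    ranks[perm[i]], ranks[perm[j]] = i, j
        # insertion moves: pull one individual out, reinsert elsewhere
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                candidate = np.delete(perm, i)
                candidate = np.insert(candidate, j, perm[i])
                cand_ranks = np.argsort(candidate)
                i_new, si_new = _score_order(cand_ranks, eu, ev)
                new = i_new * big + si_new
                if new < cur:
                    perm, ranks, cur = candidate, cand_ranks, new
                    improved = True
    return perm, cur


def isi_rank(
    matrix: ConflictMatrix,
    restarts: int = 100,
    seed: int = 0,
    method: str = "auto",
) -> RankOrder:
    """Order individuals by the I&SI criterion.

    Parameters
    ----------
    matrix
        Win-loss counts.
    restarts
        Number of random restarts for the local search (ignored when the
        exhaustive path is taken).
    seed
        Seed for the restart shuffles; the result is deterministic for a
        fixed seed.
    method
        ``"auto"`` (exhaustive for n <= 8, else heuristic), ``"exhaustive"``
        or ``"heuristic"``.

    The heuristic starts from individuals sorted by descending number of
    net-dominated opponents and repeatedly applies pairwise position swaps
    while (I, SI) lexicographically decreases, keeping the best order over
    all restarts.  Ties between equally scored orders break on the
    lexicographically smallest id sequence.
    """
    n = matrix.n
    if n < 2:
        raise ValueError("ranking requires at least two individuals")
    if method not in {"auto", "exhaustive", "heuristic"}:
        raise ValueError(f"unknown method {method!r}")
    if method == "exhaustive" or (method == "auto" and n <= 8):
        return _exhaustive_isi(matrix)

    eu, ev = _net_edges(matrix.wins)
    big = n ** 3
    rng = np.random.default_rng(seed)
    n_dominated = (matrix.wins > matrix.wins.T).sum(axis=1)
    # initial order: most dominating first, id as deterministic tie-break
    init = np.array(
        sorted(range(n), key=lambda i: (-n_dominated[i], matrix.ids[i])),
        dtype=np.int64,
    )
    best_perm, best_score = _local_search(init, eu, ev, big)
    best_seq = tuple(matrix.ids[i] for i in best_perm)
    for _ in range(max(0, restarts - 1)):
        start = rng.permutation(n).astype(np.int64)
        perm, score = _local_search(start, eu, ev, big)
        seq = tuple(matrix.ids[i] for i in perm)
        if score < best_score or (score == best_score and seq < best_seq):
            best_perm, best_score, best_seq = perm, score, seq
    ranks = np.argsort(best_perm)
    I, SI = _score_order(ranks, eu, ev)
    return RankOrder(best_seq, I, SI)


def _landau_h(V: np.ndarray, n: int) -> np.ndarray:
    """Landau's h from out-degrees V (vectorised over leading axes)."""
    return 12.0 / (n ** 3 - n) * ((V - (n - 1) / 2.0) ** 2).sum(axis=-1)


def linearity(
    matrix: ConflictMatrix, n_random: int = 10_000, seed: int = 0
) -> HierarchyDiagnostics:
    """Landau h, de Vries h' and a randomization p-value for linearity.

    ``h`` is computed on the net-outcome digraph with unknown and tied dyads
    contributing half a win to each member (their expected value).  ``h'``
    randomly assigns a direction to every unknown or tied dyad and averages
    Landau's h over ``n_random`` fills.  The p-value is the two-step
    randomization probability: in each iteration the filled h is compared
    with the h of a fully random tournament, and p is the proportion of
    iterations (observed comparison included) in which the null h is at
    least as large.
    """
    n = matrix.n
    if n < 3:
        raise ValueError("linearity requires at least three individuals")
    wins = matrix.wins
    known_u, known_v = _net_edges(wins)
    both_zero = (wins == 0) & (wins.T == 0)
    tied = (wins == wins.T) & (wins > 0)
    iu, ju = np.triu_indices(n, k=1)
    undecided = both_zero[iu, ju] | tied[iu, ju]
    und_i, und_j = iu[undecided], ju[undecided]
    n_und = len(und_i)

    V_known = np.bincount(known_u, minlength=n).astype(float)
    # h with undecided dyads at their expected half-win
    V_half = V_known + 0.5 * (
        np.bincount(und_i, minlength=n) + np.bincount(und_j, minlength=n)
    )
    h = float(_landau_h(V_half, n))

    rng = np.random.default_rng(seed)
    m = int(n_random)
    if n_und:
        draws = rng.integers(0, 2, size=(m, n_und))
        V_fill = np.tile(V_known, (m, 1))
        rows = np.arange(m)[:, None]
        np.add.at(V_fill, (rows, und_i[None, :].repeat(m, axis=0)), draws)
        np.add.at(V_fill, (rows, und_j[None, :].repeat(m, axis=0)), 1 - draws)
        h_fill = _landau_h(V_fill, n)
        h_prime = float(h_fill.mean())
    else:
        h_fill = np.full(m, h)
        h_prime = h

    null_draws = rng.integers(0, 2, size=(m, len(iu)))
    V_null = np.zeros((m, n))
    rows = np.arange(m)[:, None]
    np.add.at(V_null, (rows, iu[None, :].repeat(m, axis=0)), null_draws)
    np.add.at(V_null, (rows, ju[None, :].repeat(m, axis=0)), 1 - null_draws)
    h_null = _landau_h(V_null, n)
    p = (int((h_null >= h_fill).sum()) + 1) / (m + 1)
    return HierarchyDiagnostics(h=h, h_prime=h_prime, p_linearity=p)


def directional_consistency(matrix: ConflictMatrix) -> float:
    """Directional consistency index: sum(H - L) / sum(H + L) over dyads.

    H and L are the counts in the more and less frequent direction of each
    dyad.  Requires at least one conflict.
    """
    wins = matrix.wins
    if wins.sum() == 0:
        raise ValueError("directional consistency undefined for an empty matrix")
    iu, ju = np.triu_indices(matrix.n, k=1)
    a, b = wins[iu, ju], wins[ju, iu]
    H = np.maximum(a, b)
    L = np.minimum(a, b)
    return float((H - L).sum() / (H + L).sum())


def classify_dyad_relationships(
    matrix: ConflictMatrix, order: RankOrder
) -> HierarchyDiagnostics:
    """Percentages of unknown, two-way, tied and inconsistent dyads.

    Categories are assigned with precedence unknown > tied > two-way >
    inconsistent > one-way; percentages are over all n(n-1)/2 dyads.  A dyad
    is inconsistent when its net direction contradicts ``order``.
    """
    n = matrix.n
    rank = {ind: k for k, ind in enumerate(order.order)}
    missing = [i for i in matrix.ids if i not in rank]
    if missing:
        raise ValueError(f"order does not cover ids: {missing}")
    wins = matrix.wins
    counts = {"unknown": 0, "two_way": 0, "tied": 0, "inconsistent": 0}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = wins[i, j], wins[j, i]
            if a == 0 and b == 0:
                counts["unknown"] += 1
            elif a == b:
                counts["tied"] += 1
            elif a > 0 and b > 0:
                counts["two_way"] += 1
            else:
                winner, loser = (i, j) if a > b else (j, i)
                if rank[matrix.ids[winner]] > rank[matrix.ids[loser]]:
                    counts["inconsistent"] += 1
    total = n * (n - 1) / 2
    return HierarchyDiagnostics(
        pct_unknown=100.0 * counts["unknown"] / total,
        pct_two_way=100.0 * counts["two_way"] / total,
        pct_tied=100.0 * counts["tied"] / total,
        pct_inconsistent=100.0 * counts["inconsistent"] / total,
    )
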