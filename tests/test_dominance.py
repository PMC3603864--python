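"""Hierarchy ranking, linearity and consistency diagnostics."""

import itertools

import numpy as np
import pytest

from kinbond.core_io import ConflictRecord
from kinbond.dominance import (
    ConflictMatrix,
    build_conflict_matrix,
    classify_dyad_relationships,
    directional_consistency,
    isi_rank,
    linearity,
)
from kinbond.synthdata import SimConfig, simulate_conflicts


def brute_force_isi(matrix):
    """Independent oracle: lexicographic (I, SI) minimum over all n! orders."""
    n = matrix.n
    wins = matrix.wins
    best = None
    for perm in itertools.permutations(range(n)):
        rank = {ind: r for r, ind in enumerate(perm)}
        I = SI = 0
        for i in range(n):
            for j in range(n):
                if wins[i, j] > wins[j, i] and rank[i] > rank[j]:
                    I += 1
                    SI += rank[i] - rank[j]
        if best is None or (I, SI) < best:
            best = (I, SI)
    return best


def transitive_matrix(n, per_dyad=2):
    ids = [f"i{k}" for k in range(n)]
    wins = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            wins[i, j] = per_dyad
    return ConflictMatrix(ids, wins)


def test_build_conflict_matrix():
    records = [ConflictRecord("A", "B")] * 2 + [ConflictRecord("B", "A")]
    m = build_conflict_matrix(records, ["A", "B", "C"])
    assert m.wins[0, 1] == 2 and m.wins[1, 0] == 1
    assert build_conflict_matrix([], ["A", "B"]).wins.sum() == 0
    with pytest.raises(KeyError):
        build_conflict_matrix([ConflictRecord("A", "X")], ["A", "B"])


def test_conflict_counts_match_generator_tally():
    config = SimConfig(seed=5)
    ids = [f"f{k}" for k in range(10)]
    records, _ = simulate_conflicts(config, ids)
    m = build_conflict_matrix(records, ids)
    assert m.wins.sum() == len(records) == config.n_conflicts


def test_isi_recovers_transitive_order():
    """A perfectly transitive matrix yields I = SI = 0 from any start."""
    m = transitive_matrix(12)
    result = isi_rank(m, restarts=5, seed=1, method="heuristic")
    assert result.I == 0 and result.SI == 0
    assert list(result.order) == m.ids  # unique optimum is the true order


def test_rock_paper_scissors_has_one_inconsistency():
    """In a 3-cycle every order leaves one inconsistency; the back edge
    necessarily spans the full rank distance of 2."""
    wins = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
    m = ConflictMatrix(["a", "b", "c"], wins)
    assert brute_force_isi(m) == (1, 2)
    result = isi_rank(m)
    assert (result.I, result.SI) == (1, 2)


@pytest.mark.parametrize("n", [4, 5, 6, 7])
def test_heuristic_matches_exhaustive_oracle(n):
    """The restart local search attains the enumerated (I, SI) optimum."""
    rng = np.random.default_rng(n)
    for _ in range(5):
        wins = rng.integers(0, 3, size=(n, n))
        np.fill_diagonal(wins, 0)
        m = ConflictMatrix([f"i{k}" for k in range(n)], wins)
        expected = brute_force_isi(m)
        result = isi_rank(m, restarts=30, seed=0, method="heuristic")
        assert (result.I, result.SI) == expected
        exact = isi_rank(m, method="exhaustive")
        assert (exact.I, exact.SI) == expected


def test_isi_never_worse_than_initial_order():
    rng = np.random.default_rng(7)
    wins = rng.integers(0, 2, size=(15, 15))
    np.fill_diagonal(wins, 0)
    m = ConflictMatrix([f"i{k}" for k in range(15)], wins)
    # initial-order score: most net-dominated first
    n_dom = (wins > wins.T).sum(axis=1)
    init = sorted(range(15), key=lambda i: (-n_dom[i], m.ids[i]))
    rank = {ind: r for r, ind in enumerate(init)}
    I0 = sum(
        1
        for i in range(15)
        for j in range(15)
        if wins[i, j] > wins[j, i] and rank[i] > rank[j]
    )
    result = isi_rank(m, restarts=10, seed=0, method="heuristic")
    assert result.I <= I0


def test_linearity_perfect_transitive():
    diag = linearity(transitive_matrix(6), n_random=200, seed=0)
    assert diag.h == pytest.approx(1.0)
    assert diag.h_prime == pytest.approx(1.0)
    assert diag.p_linearity < 0.05


def test_linearity_all_unknown_is_null():
    """With every dyad unknown the filled h is itself a null draw: the
    p-value concentrates near 0.5."""
    m = ConflictMatrix([f"i{k}" for k in range(8)], np.zeros((8, 8), dtype=int))
    diag = linearity(m, n_random=4000, seed=0)
    assert 0.4 < diag.p_linearity < 0.6


def test_h_prime_single_unknown_dyad_matches_exhaustive_fills():
    """n = 5 with one unknown dyad: h' converges to the mean of the two
    possible fills of that dyad."""
    m = transitive_matrix(5)
    wins = m.wins.copy()
    wins[0, 1] = 0  # dyad (0,1) now unknown
    m = ConflictMatrix(m.ids, wins)

    def h_of(V):
        n = 5
        return 12 / (n**3 - n) * sum((v - (n - 1) / 2) ** 2 for v in V)

    # fills: 0 beats 1 -> V = (4,3,2,1,0); 1 beats 0 -> V = (3,4,2,1,0)
    exact = (h_of([4, 3, 2, 1, 0]) + h_of([3, 4, 2, 1, 0])) / 2
    diag = linearity(m, n_random=20_000, seed=0)
    assert diag.h_prime == pytest.approx(exact, abs=0.01)


def test_h_decreases_when_cycle_introduced():
    trans = transitive_matrix(4)
    h_trans = linearity(trans, n_random=10, seed=0).h
    wins = trans.wins.copy()
    wins[0, 3], wins[3, 0] = 0, 1  # bottom beats top: creates a cycle
    h_cyc = linearity(ConflictMatrix(trans.ids, wins), n_random=10, seed=0).h
    assert h_cyc < h_trans


def test_linearity_significant_for_steep_group():
    config = SimConfig(seed=9, hierarchy_steepness=3.0)
    ids = [f"f{k}" for k in range(20)]
    records, _ = simulate_conflicts(config, ids)
    m = build_conflict_matrix(records, ids)
    diag = linearity(m, n_random=2000, seed=0)
    assert diag.p_linearity < 0.01


def test_directional_consistency():
    assert directional_consistency(transitive_matrix(5)) == 1.0
    tied = np.array([[0, 2], [2, 0]])
    assert directional_consistency(ConflictMatrix(["a", "b"], tied)) == 0.0
    skew = np.array([[0, 3], [1, 0]])
    assert directional_consistency(ConflictMatrix(["a", "b"], skew)) == 0.5
    with pytest.raises(ValueError):
        directional_consistency(ConflictMatrix(["a", "b"], np.zeros((2, 2), int)))


def test_classify_dyad_relationships():
    n = 4
    ids = [f"i{k}" for k in range(n)]
    zero = ConflictMatrix(ids, np.zeros((n, n), dtype=int))
    order = isi_rank(zero)
    pct = classify_dyad_relationships(zero, order)
    assert pct.pct_unknown == 100.0

    trans = transitive_matrix(n)
    order = isi_rank(trans)
    pct = classify_dyad_relationships(trans, order)
    assert (pct.pct_unknown, pct.pct_two_way, pct.pct_tied, pct.pct_inconsistent) == (
        0.0, 0.0, 0.0, 0.0,
    )

    wins = trans.wins.copy()
    wins[2, 3], wins[3, 2] = 0, 2  # one reversed dyad against the clear order
    rev = ConflictMatrix(ids, wins)
    pct = classify_dyad_relationships(rev, order)
    assert pct.pct_inconsistent == pytest.approx(100 / 6)
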