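"""Pedigree relatedness: path counting, decomposition, kin classification."""

import numpy as np
import pytest

from kinbond.pedigree import (
    KIN_LABELS,
    additive_relationship_matrix,
    classify_kin,
    paternal_sister_probability_by_age_gap,
    relatedness,
    relatedness_table,
)
from tests.conftest import ind, pedigree, random_pedigree


def mother_daughter():
    return pedigree(ind("M"), ind("D", mother="M", year=2005)), "M", "D"


def full_sisters():
    return (
        pedigree(
            ind("M"), ind("F", sex="male"),
            ind("A", mother="M", father="F", year=2004),
            ind("B", mother="M", father="F", year=2005),
        ),
        "A", "B",
    )


def maternal_half_sisters():
    return (
        pedigree(
            ind("M"), ind("F1", sex="male"), ind("F2", sex="male"),
            ind("A", mother="M", father="F1", year=2004),
            ind("B", mother="M", father="F2", year=2005),
        ),
        "A", "B",
    )


def paternal_half_sisters():
    return (
        pedigree(
            ind("F", sex="male"), ind("M1"), ind("M2"),
            ind("A", mother="M1", father="F", year=2004),
            ind("B", mother="M2", father="F", year=2005),
        ),
        "A", "B",
    )


def cousins_full_sister_mothers():
    return (
        pedigree(
            ind("GM", year=1990), ind("GF", year=1990, sex="male"),
            ind("M1", mother="GM", father="GF", year=1996),
            ind("M2", mother="GM", father="GF", year=1997),
            ind("F1", year=1990, sex="male"), ind("F2", year=1990, sex="male"),
            ind("A", mother="M1", father="F1", year=2004),
            ind("B", mother="M2", father="F2", year=2005),
        ),
        "A", "B",
    )


def cousins_half_sister_mothers():
    return (
        pedigree(
            ind("GM", year=1990),
            ind("M1", mother="GM", year=1996),
            ind("M2", mother="GM", year=1997),
            ind("F1", year=1990, sex="male"), ind("F2", year=1990, sex="male"),
            ind("A", mother="M1", father="F1", year=2004),
            ind("B", mother="M2", father="F2", year=2005),
        ),
        "A", "B",
    )


def founders():
    return pedigree(ind("A"), ind("B")), "A", "B"


@pytest.mark.parametrize(
    "builder, r_mat, r_pat, r_total",
    [
        (mother_daughter, 0.5, 0.0, 0.5),
        (full_sisters, 0.25, 0.25, 0.5),
        (maternal_half_sisters, 0.25, 0.0, 0.25),
        (paternal_half_sisters, 0.0, 0.25, 0.25),
        (cousins_full_sister_mothers, 0.125, 0.0, 0.125),
        (cousins_half_sister_mothers, 0.0625, 0.0, 0.0625),
        (founders, 0.0, 0.0, 0.0),
    ],
    ids=lambda x: getattr(x, "__name__", str(x)),
)
def test_relatedness_components(builder, r_mat, r_pat, r_total):
    """Path counting reproduces the canonical kinship coefficients."""
    ped, a, b = builder()
    rec = relatedness(ped, a, b)
    assert rec.r_maternal == r_mat
    assert rec.r_paternal == r_pat
    assert rec.r_total == r_total
    assert rec.r_total == rec.r_maternal + rec.r_paternal + rec.r_mixed


def test_multi_path_summation():
    """Aunt-niece (0.125) plus a second-cousin-style path (0.015625) add to
    0.140625: relatedness through several routes is summed per path."""
    # maternal route: G -> (X1 = A, X2); B is X2's daughter => A-B at 0.125
    # paternal route: founder Z, grandsons F1 (A's father) and F2 (B's father)
    # via distinct daughters of Z => one 6-link path contributing 0.5**6
    ped = pedigree(
        ind("G", year=1985),
        ind("Z", year=1980),
        ind("W", mother="Z", year=1986),
        ind("V", mother="Z", year=1987),
        ind("F1", mother="W", year=1992, sex="male"),
        ind("F2", mother="V", year=1993, sex="male"),
        ind("A", mother="G", father="F1", year=1998),
        ind("X2", mother="G", year=1992),
        ind("B", mother="X2", father="F2", year=2000),
    )
    rec = relatedness(ped, "A", "B")
    assert rec.r_total == pytest.approx(0.125 + 0.015625, abs=0)
    contributions = sorted(c for _, _, c in rec.paths)
    assert contributions == [0.015625, 0.125]


def test_relatedness_errors():
    ped, a, b = founders()
    with pytest.raises(ValueError):
        relatedness(ped, a, a)
    with pytest.raises(KeyError):
        relatedness(ped, a, "nobody")


def test_path_counting_matches_tabular_oracle():
    """On 200 random non-inbred pedigrees the simple-path sum equals the
    additive-relationship (tabular) recursion for every pair."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        ped = random_pedigree(rng)
        amat = additive_relationship_matrix(ped)
        ids = ped.ids
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                rec = relatedness(ped, a, b, assume_non_inbred=True)
                assert rec.r_total == pytest.approx(amat.loc[a, b], abs=1e-12)


def test_relatedness_symmetric_and_bounded(rng):
    for _ in range(20):
        ped = random_pedigree(rng)
        ids = ped.ids
        a, b = ids[0], ids[-1]
        r_ab = relatedness(ped, a, b)
        r_ba = relatedness(ped, b, a)
        for attr in ("r_maternal", "r_paternal", "r_mixed", "r_total"):
            va, vb = getattr(r_ab, attr), getattr(r_ba, attr)
            assert va == pytest.approx(vb, abs=1e-12)
            assert 0.0 <= va <= 1.0


def test_inbred_pedigree_falls_back_to_tabular():
    """Father-daughter mating: decomposition unavailable, total from the
    tabular method (and matching it exactly)."""
    ped = pedigree(
        ind("M"), ind("F", sex="male"),
        ind("D", mother="M", father="F", year=1995),
        ind("X", mother="D", father="F", year=2000),
    )
    with pytest.warns(UserWarning, match="inbred"):
        rec = relatedness(ped, "X", "M")
    assert np.isnan(rec.r_maternal)
    amat = additive_relationship_matrix(ped)
    assert rec.r_total == pytest.approx(amat.loc["X", "M"])


# ---------------------------------------------------------------------------
# kin classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "builder, label",
    [
        (mother_daughter, "mother_daughter"),
        (full_sisters, "full_sisters"),
        (maternal_half_sisters, "maternal_half_sisters"),
        (paternal_half_sisters, "paternal_half_sisters"),
        (founders, "distant_or_nonkin"),
        (cousins_full_sister_mothers, "distant_or_nonkin"),
    ],
    ids=lambda x: getattr(x, "__name__", str(x)),
)
def test_classify_kin_categories(builder, label):
    ped, a, b = builder()
    rec = relatedness(ped, a, b)
    assert classify_kin(rec, ped).label == label


def test_paternal_sisters_excluded_at_maternal_boundary():
    """Same father plus maternal relatedness exactly 0.0625 is excluded
    (boundary inclusive): the paternal contrast would be confounded."""
    # mothers are maternal half-sisters => daughters' maternal relatedness
    # is 0.0625; both daughters share father F
    ped = pedigree(
        ind("GG", year=1980),
        ind("M1", mother="GG", year=1992),
        ind("M2", mother="GG", year=1993),
        ind("F", sex="male"),
        ind("A", mother="M1", father="F", year=2000),
        ind("B", mother="M2", father="F", year=2001),
    )
    rec = relatedness(ped, "A", "B")
    assert rec.r_maternal == 0.0625
    assert classify_kin(rec, ped).label == "excluded"


def test_close_lateral_kin_without_shared_parent_flagged():
    """Aunt-niece through a full-sister link (r = 0.25) fits no contrast
    category: no shared parent but total relatedness above 0.125."""
    ped = pedigree(
        ind("GM"), ind("GF", sex="male"),
        ind("A", mother="GM", father="GF", year=1995),
        ind("S", mother="GM", father="GF", year=1996),
        ind("B", mother="S", year=2002),
    )
    rec = relatedness(ped, "A", "B")
    assert rec.r_total == 0.25
    assert classify_kin(rec, ped).label == "excluded"


def test_classification_exhaustive_and_exclusive(default_sim):
    """Every synthetic female dyad receives exactly one known label."""
    table = relatedness_table(default_sim.pedigree, default_sim.study_females)
    n = len(default_sim.study_females)
    assert len(table) == n * (n - 1) // 2
    assert set(table["category"]).issubset(set(KIN_LABELS))


# ---------------------------------------------------------------------------
# paternal sistership by age gap
# ---------------------------------------------------------------------------


def test_age_gap_table_single_sire_cohorts():
    """When one sire covers adjacent cohorts, all same-cohort dyads share a
    father (proportion 1 at gap 0)."""
    members = []
    individuals = [ind("S1", sex="male", year=1990), ind("S2", sex="male", year=1990)]
    for c in range(4):
        sire = "S1" if c < 2 else "S2"
        for k in range(3):
            mid = f"mo{c}{k}"
            individuals.append(ind(mid, year=1992))
            fid = f"d{c}{k}"
            individuals.append(ind(fid, mother=mid, father=sire, year=2000 + c))
            members.append(fid)
    ped = pedigree(*individuals)
    table = paternal_sister_probability_by_age_gap(ped, members)
    by_gap = table.set_index("age_gap")["proportion"]
    assert by_gap[0] == 1.0
    # brute-force oracle: gap-g dyads share a father iff cohorts in same tenure
    for gap in by_gap.index:
        pairs = shared = 0
        for c1 in range(4):
            for c2 in range(c1, 4):
                if abs(c1 - c2) != gap:
                    continue
                n = 3 * 3 if c1 != c2 else 3
                pairs += n
                if (c1 < 2) == (c2 < 2):
                    shared += n
        assert by_gap[gap] == pytest.approx(shared / pairs)


def test_age_gap_table_empty_inputs():
    ped, *_ = founders()
    assert paternal_sister_probability_by_age_gap(ped, []).empty
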