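"""Mantel-like permutation test for category differences in a dyadic matrix.

Dyadic values are not independent — every dyad shares a member with many
others — so category contrasts (e.g. bond strength across kin classes) are
tested by permuting *individuals*, not dyads: a random permutation of the id
labels is applied simultaneously to the rows and columns of the value
matrix, which preserves each individual's marginal profile while breaking
the value-category association.

The overall statistic is the sum of squared deviations of the per-category
means from the unweighted mean of those means; pairwise contrasts use the
absolute difference of two category means.  Both are non-negative deviation
measures, so the test is one-tailed (>=), and the observed labelling counts
as one permutation, bounding p below by 1/n_perm.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from kinbond.core_io import DyadicMatrix

#: Category labels ignored by the test (dropped from all statistics).
DEFAULT_EXCLUDED_LABELS = frozenset({"excluded", ""})


@dataclass
class PermutationResult:
    observed_statistic: float
    p_value: float
    n_perm: int
    per_category_means: dict[str, float]
    pairwise: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)


def _category_positions(
    categories: DyadicMatrix, excluded: frozenset[str]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    n = categories.n
    iu, ju = np.triu_indices(n, k=1)
    labels = np.asarray(categories.values, dtype=object)[iu, ju]
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for label in sorted({str(x) for x in labels}):
        if label in excluded:
            continue
        mask = labels == label
        out[label] = (iu[mask], ju[mask])
    return out


def categorical_matrix_test(
    values: DyadicMatrix,
    categories: DyadicMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    excluded_labels: frozenset[str] = DEFAULT_EXCLUDED_LABELS,
    exhaustive: bool = False,
    bonferroni: bool = False,
) -> PermutationResult:
    """Test whether dyadic values differ across levels of a dyadic category.

    Parameters
    ----------
    values
        Symmetric matrix of the dyadic quantity (e.g. CSI).
    categories
        Symmetric matrix of category labels on the same id index; labels in
        ``excluded_labels`` are dropped from all statistics.
    n_perm
        Number of permutations, the observed labelling included.
    seed
        Seed for the permutation stream.
    exhaustive
        Enumerate all n! label permutations instead of sampling (exact p;
        only sensible for small n).  ``n_perm`` is then ignored.
    bonferroni
        Multiply pairwise p-values by the number of pairwise contrasts
        (capped at 1).  Off by default: raw permutation p-values are
        reported per contrast.

    Returns
    -------
    PermutationResult
        Overall statistic and p-value, per-category means, and for every
        category pair the absolute mean difference with its permutation p.
    """
    if values.ids != categories.ids:
        raise ValueError("value and category matrices must share the id index")
    n = values.n
    positions = _category_positions(categories, excluded_labels)
    labels = list(positions)
    if len(labels) < 2:
        raise ValueError("need at least two categories with dyads")
    if not exhaustive and n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is very small", stacklevel=2)

    V = np.asarray(values.values, dtype=float)

    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
        m = len(perms)
    else:
        rng = np.random.default_rng(seed)
        m = int(n_perm)
        perms = np.empty((m, n), dtype=np.int64)
        perms[0] = np.arange(n)  # the observed labelling is one permutation
        for k in range(1, m):
            perms[k] = rng.permutation(n)

    cat_means = np.empty((m, len(labels)))
    for c, label in enumerate(labels):
        ic, jc = positions[label]
        cat_means[:, c] = V[perms[:, ic], perms[:, jc]].mean(axis=1)

    overall = ((cat_means - cat_means.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    if exhaustive:
        observed_overall = float(
            sum(
                (V[positions[l]].mean() - _grand(V, positions, labels)) ** 2
                for l in labels
            )
        )
    else:
        observed_overall = float(overall[0])
    p_overall = float((overall >= observed_overall - 1e-12).mean())

    observed_means = {l: float(V[positions[l]].mean()) for l in labels}
    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    pairs = list(itertools.combinations(range(len(labels)), 2))
    for a, b in pairs:
        diffs = np.abs(cat_means[:, a] - cat_means[:, b])
        obs = abs(observed_means[labels[a]] - observed_means[labels[b]])
        p = float((diffs >= obs - 1e-12).mean())
        if bonferroni:
            p = min(1.0, p * len(pairs))
        pairwise[(labels[a], labels[b])] = (obs, p)

    return PermutationResult(
        observed_statistic=observed_overall,
        p_value=p_overall,
        n_perm=m,
        per_category_means=observed_means,
        pairwise=pairwise,
    )


def _grand(V, positions, labels):
    return float(np.mean([V[positions[l]].mean() for l in labels]))
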