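"""Composite Sociality Index and row-wise matrix correlations.

The CSI summarises dyadic bond strength from several affiliation-rate
matrices: each behavior's dyadic rate is divided by that behavior's grand
mean rate over all dyads, and the normalised components are averaged.  By
construction the CSI averages 1 over dyads, so values above 1 mark
above-average bonds.  The index is invariant to rescaling any behavior's
rates by a positive constant, which makes the choice of time unit
immaterial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

from kinbond.core_io import DyadicMatrix


@dataclass
class CsiMatrix:
    """CSI values with the per-behavior grand means used to normalise."""

    matrix: DyadicMatrix
    component_means: dict[str, float]

    @property
    def ids(self) -> list[str]:
        return self.matrix.ids

    def grand_mean(self) -> float:
        return float(self.matrix.offdiag_values().mean())


def csi(
    rates: Mapping[str, DyadicMatrix],
    valid_mask: np.ndarray | None = None,
) -> CsiMatrix:
    """Composite Sociality Index from per-behavior rate matrices.

    ``CSI(a, b) = mean over behaviors of rate(a, b) / grand-mean rate``,
    with grand means taken over all unordered dyads (or over ``valid_mask``
    dyads when some dyads were never jointly observable).

    Raises ``ValueError`` when a behavior's rates are all zero (its grand
    mean would be zero) — such a behavior carries no information and must be
    dropped by the caller.
    """
    if not rates:
        raise ValueError("csi requires at least one rate matrix")
    matrices = list(rates.values())
    ids = matrices[0].ids
    for m in matrices[1:]:
        if m.ids != ids:
            raise ValueError("rate matrices must share the same id index")
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    if valid_mask is None:
        valid = np.ones(len(iu[0]), dtype=bool)
    else:
        valid_mask = np.asarray(valid_mask, dtype=bool)
        if valid_mask.shape != (n, n):
            raise ValueError("valid_mask must be an n x n boolean matrix")
        valid = valid_mask[iu]
        if not valid.any():
            raise ValueError("valid_mask excludes every dyad")

    total = np.zeros((n, n))
    means: dict[str, float] = {}
    for name, m in rates.items():
        grand = float(m.values[iu][valid].mean())
        if grand == 0:
            raise ValueError(f"behavior {name!r} has all-zero rates")
        means[name] = grand
        total += m.values / grand
    values = total / len(rates)
    np.fill_diagonal(values, 0.0)
    return CsiMatrix(
        DyadicMatrix(list(ids), values, directed=False, diagonal_defined=False),
        means,
    )


def _row_gather_index(n: int) -> np.ndarray:
    """idx[i] = the n-1 column positions of row i excluding the diagonal."""
    idx = np.empty((n, n - 1), dtype=np.int64)
    for i in range(n):
        idx[i] = np.concatenate([np.arange(i), np.arange(i + 1, n)])
    return idx


def _mean_row_rho(
    A: np.ndarray, B: np.ndarray, idx: np.ndarray, warn: bool = False
) -> float:
    """Mean over rows of the Spearman correlation of paired off-diagonal rows."""
    n = A.shape[0]
    rows = np.arange(n)[:, None]
    a = A[rows, idx]
    b = B[rows, idx]
    ra = rankdata(a, axis=1)
    rb = rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    va = (ra ** 2).sum(axis=1)
    vb = (rb ** 2).sum(axis=1)
    ok = (va > 0) & (vb > 0)
    if not ok.any():
        raise ValueError("every row is constant; row-wise correlation undefined")
    if warn and not ok.all():
        warnings.warn(
            f"excluded {int((~ok).sum())} constant rows from the row-wise "
            "correlation",
            stacklevel=3,
        )
    rho = (ra[ok] * rb[ok]).sum(axis=1) / np.sqrt(va[ok] * vb[ok])
    return float(rho.mean())


def rowwise_matrix_correlation(
    a: DyadicMatrix, b: DyadicMatrix, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Row-wise Spearman matrix correlation with a permutation p-value.

    The statistic is the mean, over individuals, of the Spearman correlation
    between that individual's row of ``a`` and of ``b`` (diagonal cells
    excluded; constant rows excluded with a warning).  The null distribution
    permutes the id labels of ``b`` simultaneously over rows and columns,
    which preserves the dyadic dependence structure within each matrix.  The
    p-value is the proportion of permutations, the observed labelling
    included, with a statistic at least as large as observed.
    """
    if a.ids != b.ids:
        raise ValueError("matrices must share the same id index")
    n = a.n
    if n < 3:
        raise ValueError("row-wise correlation requires at least three ids")
    idx = _row_gather_index(n)
    A, B = np.asarray(a.values, dtype=float), np.asarray(b.values, dtype=float)
    observed = _mean_row_rho(A, B, idx, warn=True)
    rng = np.random.default_rng(seed)
    at_least = 1  # the observed labelling counts as one permutation
    for _ in range(n_perm - 1):
        pi = rng.permutation(n)
        if _mean_row_rho(A, B[np.ix_(pi, pi)], idx) >= observed - 1e-12:
            at_least += 1
    return observed, at_least / n_perm
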