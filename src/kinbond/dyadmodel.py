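"""Dyadic linear mixed models with crossed individual random effects.

The response (CSI) and the continuous predictors are square-root
transformed (to tame right skew) and z-standardised.  Each unordered dyad
contributes one row; the two members enter as two crossed random
intercepts, assigned by a fixed convention (lexicographically smaller id to
the first factor) so a fit is invariant to how dyads were ordered in the
input.  Models are fitted by maximum likelihood (statsmodels ``MixedLM``
with two variance components built from member-incidence matrices);
restricted maximum likelihood is used only when reporting variance
components.

Significance of the full model is a likelihood-ratio test against the null
model (intercept plus the two random effects); per-term p-values come from
drop-one likelihood-ratio tests, which replace posterior-simulation
p-values from older mixed-model tooling with an asymptotically equivalent
and fully reproducible procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

DEFAULT_TERMS = ("mat_rel", "pat_sister", "rank_diff")


@dataclass
class ModelFit:
    """Summary of one dyadic mixed-model fit."""

    estimates: dict[str, float]
    lrt_chisq: float
    lrt_df: int
    lrt_p: float
    term_p: dict[str, float] = field(default_factory=dict)
    vif: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    loglik_full: float = np.nan
    loglik_null: float = np.nan
    variance_components: dict[str, float] = field(default_factory=dict)
    n_rows: int = 0


def transform(values: Sequence[float], kind: str = "sqrt_z") -> np.ndarray:
    """Square-root (optional) then z-standardise a vector.

    ``sqrt_z`` requires non-negative input; ``z`` skips the square root.
    Standardisation uses the sample standard deviation (n - 1).  A constant
    vector has no z-transform and raises.
    """
    x = np.asarray(values, dtype=float)
    if kind == "sqrt_z":
        if (x < 0).any():
            raise ValueError("sqrt_z transform requires non-negative values")
        x = np.sqrt(x)
    elif kind != "z":
        raise ValueError(f"unknown transform kind {kind!r}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-transform a constant vector")
    return (x - x.mean()) / sd


def build_dyad_table(
    csi_values: Mapping[tuple[str, str], float],
    relatedness: pd.DataFrame,
    ranks: Mapping[str, int],
    ages: Mapping[str, float],
    standardize_pat_sister: bool = False,
) -> pd.DataFrame:
    """Assemble the per-dyad model table.

    Parameters
    ----------
    csi_values
        CSI per unordered dyad, keyed by (id_a, id_b) in any member order.
    relatedness
        Table from :func:`kinbond.pedigree.relatedness_table` (columns
        ``id_a, id_b, r_maternal, category``).
    ranks
        Ordinal rank (1 = top) per individual.
    ages
        Age (years) per individual.
    standardize_pat_sister
        If True, z-standardise the binary paternal-sister indicator like the
        continuous predictors; by default it stays on its natural 0/1 scale.

    Returns one row per dyad with raw columns (``csi, r_maternal,
    rank_gap, age_gap, pat_sister, category``) and transformed model columns
    (``csi_t, mat_rel, rank_diff, age_diff``).  Member columns ``id_1`` /
    ``id_2`` hold the lexicographically smaller / larger id.
    """
    lookup = {}
    for (a, b), v in csi_values.items():
        lookup[(min(a, b), max(a, b))] = v
    rows = []
    for _, r in relatedness.iterrows():
        a, b = sorted((r["id_a"], r["id_b"]))
        if (a, b) not in lookup:
            continue
        rows.append(
            {
                "id_1": a,
                "id_2": b,
                "csi": lookup[(a, b)],
                "r_maternal": r["r_maternal"],
                "pat_sister": float(
                    r["category"] in ("paternal_half_sisters", "full_sisters")
                    or r["r_paternal"] > 0
                ),
                "rank_gap": abs(ranks[a] - ranks[b]),
                "age_gap": abs(ages[a] - ages[b]),
                "category": r["category"],
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no dyads with both CSI and relatedness")
    df["csi_t"] = transform(df["csi"], "sqrt_z")
    df["mat_rel"] = transform(df["r_maternal"], "sqrt_z")
    df["rank_diff"] = transform(df["rank_gap"], "sqrt_z")
    if df["age_gap"].nunique() > 1:
        df["age_diff"] = transform(df["age_gap"], "sqrt_z")
    else:
        df["age_diff"] = 0.0
    if standardize_pat_sister:
        df["pat_sister"] = transform(df["pat_sister"], "z")
    return df


def _vcspec(df: pd.DataFrame) -> tuple[VCSpec, np.ndarray]:
    # each factor keeps only the ids that occur in that member slot: all-zero
    # incidence columns make the mixed-model solver singular
    n = len(df)
    names, colnames, mats = [], [], []
    for k, col in enumerate(("id_1", "id_2"), start=1):
        inds = sorted(set(df[col]))
        pos = {i: j for j, i in enumerate(inds)}
        Z = np.zeros((n, len(inds)))
        Z[np.arange(n), [pos[i] for i in df[col]]] = 1.0
        names.append(f"member_{k}")
        colnames.append([inds])
        mats.append([Z])
    return VCSpec(names, colnames, mats), np.zeros(n)


def _fit_ml(y: np.ndarray, X: np.ndarray, spec: VCSpec, groups: np.ndarray, reml=False):
    # L-BFGS is fast but can stop short of the optimum (or hit a singular
    # profile point); a Nelder-Mead polish from its solution is cheap and
    # reliably reaches the lme4-grade optimum
    model = MixedLM(y, X, groups=groups, exog_vc=spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        first = None
        try:
            first = model.fit(reml=reml, method="lbfgs", maxiter=1000)
        except np.linalg.LinAlgError:
            pass
        if first is None:
            return model.fit(reml=reml, method="nm", maxiter=2000)
        polished = model.fit(
            reml=reml, method="nm", maxiter=2000, start_params=first.params_object
        )
    return polished if polished.llf >= first.llf else first


def fit_dyadic_lmm(
    rows: pd.DataFrame,
    terms: Sequence[str] = DEFAULT_TERMS,
    response: str = "csi_t",
    diagnostics: bool = True,
) -> ModelFit:
    """Fit the dyadic mixed model and test it against the null model.

    ``rows`` is the table from :func:`build_dyad_table` (or any frame with
    the named term columns plus ``id_1``/``id_2``).  The model is

        response ~ 1 + terms + (1 | member_1) + (1 | member_2)

    fitted by ML.  ``lrt_chisq`` compares the full fit with the
    intercept-only null (same random structure), on ``len(terms)`` degrees
    of freedom; ``term_p`` holds drop-one LRT p-values; ``vif`` holds
    variance inflation factors from the fixed-effects-only regression;
    ``variance_components`` holds REML variance estimates.  Pass
    ``diagnostics=False`` to skip the drop-one/VIF/REML refits (useful in
    replicate simulations that only need estimates and the overall LRT).
    """
    terms = list(terms)
    df = rows.reset_index(drop=True)
    y = df[response].to_numpy(dtype=float)
    X_full = np.column_stack(
        [np.ones(len(df))] + [df[t].to_numpy(dtype=float) for t in terms]
    )
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("design matrix is rank deficient")
    spec, groups = _vcspec(df)

    full = _fit_ml(y, X_full, spec, groups)
    null = _fit_ml(y, np.ones((len(df), 1)), spec, groups)
    lrt = max(0.0, 2.0 * (full.llf - null.llf))
    lrt_df = len(terms)
    lrt_p = float(stats.chi2.sf(lrt, lrt_df)) if lrt_df else 1.0

    estimates = {"(Intercept)": float(full.fe_params[0])}
    for k, t in enumerate(terms):
        estimates[t] = float(full.fe_params[k + 1])

    term_p: dict[str, float] = {}
    vifs: dict[str, float] = {}
    vc: dict[str, float] = {}
    if diagnostics:
        for k, t in enumerate(terms):
            X_drop = np.delete(X_full, k + 1, axis=1)
            reduced = _fit_ml(y, X_drop, spec, groups)
            chisq = max(0.0, 2.0 * (full.llf - reduced.llf))
            term_p[t] = float(stats.chi2.sf(chisq, 1))
        if len(terms) >= 2:
            vifs = vif(df, terms)
        reml_fit = _fit_ml(y, X_full, spec, groups, reml=True)
        vc = {
            "member_1": float(reml_fit.vcomp[0]),
            "member_2": float(reml_fit.vcomp[1]),
            "residual": float(reml_fit.scale),
        }

    return ModelFit(
        estimates=estimates,
        lrt_chisq=float(lrt),
        lrt_df=lrt_df,
        lrt_p=lrt_p,
        term_p=term_p,
        vif=vifs,
        converged=bool(full.converged and null.converged),
        loglik_full=float(full.llf),
        loglik_null=float(null.llf),
        variance_components=vc,
        n_rows=len(df),
    )


def vif(design: pd.DataFrame, terms: Sequence[str]) -> dict[str, float]:
    """Variance inflation factors from the fixed-effects-only regression.

    ``VIF_k = 1 / (1 - R^2_k)`` where ``R^2_k`` is from regressing predictor
    k (with intercept) on the remaining predictors.  Perfect collinearity is
    reported as ``inf``.
    """
    terms = list(terms)
    if len(terms) < 2:
        raise ValueError("vif requires at least two terms")
    X = design[terms].to_numpy(dtype=float)
    out: dict[str, float] = {}
    for k, t in enumerate(terms):
        yk = X[:, k]
        Xk = np.column_stack([np.ones(len(X)), np.delete(X, k, axis=1)])
        beta, *_ = np.linalg.lstsq(Xk, yk, rcond=None)
        resid = yk - Xk @ beta
        ss_tot = ((yk - yk.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 1.0
        out[t] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def sister_bond_mother_presence_contrast(
    csi_present: Sequence[float], csi_absent: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sample t-test of sister-dyad CSI by mother presence.

    Returns (t, p) for mother-present versus mother-absent sister dyads.
    Each group needs at least two dyads.
    """
    a = np.asarray(csi_present, dtype=float)
    b = np.asarray(csi_absent, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two dyads")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
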