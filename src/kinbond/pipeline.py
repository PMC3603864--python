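"""End-to-end orchestration: inputs -> relatedness -> hierarchy -> CSI ->
permutation tests -> dyadic mixed models -> report.

``run_pipeline`` accepts a configuration mapping (or a YAML file path) with
either a ``simulate`` block (:class:`kinbond.synthdata.SimConfig` fields) or
an ``inputs`` block of file paths, plus analysis settings::

    simulate: {n_females: 30, seed: 7}
    # or
    inputs:
      pedigree: pedigree.tsv
      events: events.tsv
      conflicts: conflicts.tsv
      focal_time: times.tsv
    n_perm: 10000        # permutations (CSI category test, row-wise rho)
    n_random: 10000      # linearity randomizations
    restarts: 100        # I&SI restarts
    seed: 0              # analysis seed (permutations, ranking restarts)
    study_year: 2008     # ages = study_year - birth year
    output: out_dir      # optional; report.json + TSV tables are written

All numbers in the returned report are recomputable from the inputs and the
seeds; runs with identical configuration are byte-identical on disk.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from kinbond._version import __version__
from kinbond.core_io import (
    DyadicMatrix,
    events_to_rate_matrices,
    read_conflicts,
    read_events,
    read_focal_time,
    read_pedigree,
    write_matrix,
)
from kinbond.dominance import (
    build_conflict_matrix,
    classify_dyad_relationships,
    directional_consistency,
    isi_rank,
    linearity,
)
from kinbond.dyadmodel import (
    build_dyad_table,
    fit_dyadic_lmm,
    sister_bond_mother_presence_contrast,
)
from kinbond.pedigree import paternal_sister_probability_by_age_gap, relatedness_table
from kinbond.permtest import categorical_matrix_test
from kinbond.sociality import csi, rowwise_matrix_correlation
from kinbond.synthdata import SimConfig, simulate_group

log = logging.getLogger("kinbond")

#: Run report: a JSON-serialisable mapping, one key per pipeline stage.
RunReport = dict

_SISTER_CATEGORIES = ("full_sisters", "maternal_half_sisters")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return run

    return wrap


def _load_config(config: Mapping[str, Any] | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


@_stage("inputs")
def _gather_inputs(cfg: dict):
    if "simulate" in cfg:
        sim = simulate_group(SimConfig(**cfg["simulate"]))
        return sim.pedigree, sim.study_females, sim.events, sim.conflicts, sim.focal_time
    inputs = cfg["inputs"]
    pedigree = read_pedigree(inputs["pedigree"])
    events = read_events(inputs["events"])
    conflicts = read_conflicts(inputs["conflicts"])
    focal_time = read_focal_time(inputs["focal_time"])
    females = sorted(focal_time)
    return pedigree, females, events, conflicts, focal_time


def _category_matrix(rel: pd.DataFrame, ids: list[str]) -> DyadicMatrix:
    n = len(ids)
    pos = {i: k for k, i in enumerate(ids)}
    values = np.full((n, n), "", dtype=object)
    for _, r in rel.iterrows():
        i, j = pos[r["id_a"]], pos[r["id_b"]]
        values[i, j] = values[j, i] = r["category"]
    return DyadicMatrix(ids, values, directed=False, diagonal_defined=False)


def run_pipeline(
    config: Mapping[str, Any] | str | Path, output: str | Path | None = None
) -> RunReport:
    """Run every analysis stage and return (optionally write) the report.

    See the module docstring for the configuration schema.  When ``output``
    (or a config ``output`` key) is given, ``report.json`` plus TSV tables
    (CSI matrix, relatedness table, rank order) are written there.
    """
    cfg = _load_config(config)
    n_perm = int(cfg.get("n_perm", 10_000))
    n_random = int(cfg.get("n_random", 10_000))
    restarts = int(cfg.get("restarts", 100))
    seed = int(cfg.get("seed", 0))
    study_year = int(cfg.get("study_year", 2008))
    terms = list(cfg.get("terms", ["mat_rel", "pat_sister", "rank_diff"]))

    pedigree, females, events, conflicts, focal_time = _gather_inputs(cfg)

    rel = _stage("relatedness")(relatedness_table)(pedigree, females)

    hierarchy = _stage("hierarchy")(_hierarchy_stage)(
        conflicts, females, restarts, n_random, seed
    )
    order = hierarchy.pop("_order")

    soc = _stage("sociality")(_sociality_stage)(events, focal_time, females, n_perm, seed)
    csi_matrix = soc.pop("_csi")

    kin_table = _stage("kin_categories")(_kin_category_stage)(rel, csi_matrix)

    perm = _stage("permutation_test")(_permtest_stage)(rel, csi_matrix, n_perm, seed)

    models = _stage("models")(_model_stage)(
        rel, csi_matrix, order, pedigree, study_year, terms
    )

    summaries = _stage("summaries")(_summary_stage)(
        rel, csi_matrix, pedigree, females
    )

    report: RunReport = {
        "version": __version__,
        "seeds": {"analysis": seed, **(
            {"simulation": cfg["simulate"].get("seed", 0)} if "simulate" in cfg else {}
        )},
        "settings": {
            "n_perm": n_perm,
            "n_random": n_random,
            "restarts": restarts,
            "study_year": study_year,
            "terms": terms,
        },
        "n_females": len(females),
        "n_dyads": len(females) * (len(females) - 1) // 2,
        "hierarchy": hierarchy,
        "sociality": soc,
        "kin_categories": kin_table,
        "permutation_test": perm,
        "models": models,
        "summaries": summaries,
    }

    out_dir = output or cfg.get("output")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        rel.to_csv(out_dir / "relatedness.tsv", sep="\t", index=False)
        write_matrix(csi_matrix.matrix, out_dir / "csi.tsv")
        pd.DataFrame(
            {"rank": range(1, len(order.order) + 1), "id": list(order.order)}
        ).to_csv(out_dir / "rank_order.tsv", sep="\t", index=False)
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _hierarchy_stage(conflicts, females, restarts, n_random, seed):
    matrix = build_conflict_matrix(conflicts, females)
    order = isi_rank(matrix, restarts=restarts, seed=seed)
    lin = linearity(matrix, n_random=n_random, seed=seed)
    pct = classify_dyad_relationships(matrix, order)
    return {
        "_order": order,
        "order": list(order.order),
        "I": order.I,
        "SI": order.SI,
        "h": lin.h,
        "h_prime": lin.h_prime,
        "p_linearity": lin.p_linearity,
        "dci": directional_consistency(matrix),
        "pct_unknown": pct.pct_unknown,
        "pct_two_way": pct.pct_two_way,
        "pct_tied": pct.pct_tied,
        "pct_inconsistent": pct.pct_inconsistent,
        "n_conflicts": len(conflicts),
    }


def _sociality_stage(events, focal_time, females, n_perm, seed):
    rates = events_to_rate_matrices(events, focal_time, ids=females)
    csi_matrix = csi(rates)
    behaviors = list(rates)
    correlations = {}
    for i, a in enumerate(behaviors):
        for b in behaviors[i + 1 :]:
            rho, p = rowwise_matrix_correlation(
                rates[a], rates[b], n_perm=n_perm, seed=seed
            )
            correlations[f"{a}~{b}"] = {"mean_rho": rho, "p": p}
    return {
        "_csi": csi_matrix,
        "csi_grand_mean": csi_matrix.grand_mean(),
        "component_means": csi_matrix.component_means,
        "component_correlations": correlations,
    }


def _kin_category_stage(rel, csi_matrix):
    values = {
        cat: [] for cat in sorted(rel["category"].unique())
    }
    for _, r in rel.iterrows():
        values[r["category"]].append(csi_matrix.matrix.loc(r["id_a"], r["id_b"]))
    return {
        cat: {
            "n_dyads": len(v),
            "mean_csi": float(np.mean(v)) if v else None,
            "sd_csi": float(np.std(v, ddof=1)) if len(v) > 1 else None,
        }
        for cat, v in values.items()
    }


def _permtest_stage(rel, csi_matrix, n_perm, seed):
    ids = csi_matrix.ids
    categories = _category_matrix(rel, ids)
    result = categorical_matrix_test(
        csi_matrix.matrix, categories, n_perm=n_perm, seed=seed
    )
    return {
        "observed_statistic": result.observed_statistic,
        "p_value": result.p_value,
        "n_perm": result.n_perm,
        "per_category_means": result.per_category_means,
        "pairwise": {
            f"{a}|{b}": {"abs_mean_difference": d, "p": p}
            for (a, b), (d, p) in sorted(result.pairwise.items())
        },
    }


def _model_stage(rel, csi_matrix, order, pedigree, study_year, terms):
    ranks = {ind: r + 1 for r, ind in enumerate(order.order)}
    ages = {
        i: study_year - pedigree[i].birth_date.year
        for i in csi_matrix.ids
        if pedigree[i].birth_date is not None
    }
    csi_values = {
        (a, b): csi_matrix.matrix.loc(a, b) for a, b in csi_matrix.matrix.dyads()
    }
    table = build_dyad_table(csi_values, rel, ranks, ages)

    def summary(fit):
        return {
            "estimates": fit.estimates,
            "lrt_chisq": fit.lrt_chisq,
            "lrt_df": fit.lrt_df,
            "lrt_p": fit.lrt_p,
            "term_p": fit.term_p,
            "vif": fit.vif,
            "converged": fit.converged,
            "variance_components": fit.variance_components,
            "n_dyads": fit.n_rows,
        }

    out = {"full": summary(fit_dyadic_lmm(table, terms))}
    # age model: add age distance, drop parent-offspring dyads whose age gap
    # is structurally large
    no_md = table[table["category"] != "mother_daughter"]
    out["with_age"] = summary(fit_dyadic_lmm(no_md, list(terms) + ["age_diff"]))
    return out


def _summary_stage(rel, csi_matrix, pedigree, females):
    out: dict[str, Any] = {}
    gap_table = paternal_sister_probability_by_age_gap(pedigree, females)
    out["paternal_sister_by_age_gap"] = gap_table.to_dict(orient="records")

    # Spearman correlation of age gap vs CSI among paternal sisters
    pat = rel[rel["category"] == "paternal_half_sisters"]
    gaps, csis = [], []
    for _, r in pat.iterrows():
        a, b = r["id_a"], r["id_b"]
        ba, bb = pedigree[a].birth_date, pedigree[b].birth_date
        if ba is None or bb is None:
            continue
        gaps.append(abs(ba.year - bb.year))
        csis.append(csi_matrix.matrix.loc(a, b))
    if len(gaps) >= 3 and len(set(gaps)) > 1:
        rho, p = stats.spearmanr(gaps, csis)
        out["paternal_sister_age_vs_csi"] = {"rho": float(rho), "p": float(p)}
    else:
        out["paternal_sister_age_vs_csi"] = None

    # sister bonds by mother presence
    study = set(females)
    present, absent = [], []
    for _, r in rel.iterrows():
        if r["category"] not in _SISTER_CATEGORIES:
            continue
        mother = pedigree[r["id_a"]].mother_id
        value = csi_matrix.matrix.loc(r["id_a"], r["id_b"])
        (present if mother in study else absent).append(value)
    if len(present) >= 2 and len(absent) >= 2:
        t, p = sister_bond_mother_presence_contrast(present, absent)
        out["sister_bonds_by_mother_presence"] = {
            "mean_csi_mother_present": float(np.mean(present)),
            "mean_csi_mother_absent": float(np.mean(absent)),
            "n_present": len(present),
            "n_absent": len(absent),
            "t": t,
            "p": p,
        }
    else:
        out["sister_bonds_by_mother_presence"] = None
    return out
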