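"""Synthetic study-group generator.

Emulates a captive breeding group of the kind the pipeline analyses: a
handful of matrilines several generations deep, a strict one-sire-at-a-time
breeding regimen (every female born in the same cohort shares a father, and
sires rotate every few cohorts), a latent linear dominance hierarchy that
produces decided conflicts, and dyadic affiliation counts whose expected
rates rise with maternal relatedness, paternal sistership and rank
similarity.

Structure of the generated pedigree
-----------------------------------
* ``n_matrilines`` founder females, each extended by
  ``matriline_generations - 1`` matrilineal descendants with unrecorded
  sires (paternity records begin with the study cohorts, as in groups where
  breeding males are exchanged and earlier paternity was never assigned);
  these females form the breeding pool.
* ``n_cohorts`` birth cohorts of study daughters; the cohort's scheduled
  male sires every birth, so cohort peers are always paternal sisters.
  Because recorded sires are terminal founders and cohort daughters do not
  themselves reproduce within the simulated window, every ancestral path is
  purely maternal or purely paternal — mixed-class relatedness is zero by
  design, matching a study system whose only paternal kin relation is
  paternal half-sistership.
* Mothers are drawn from a persistent subset of breeding females, so full
  sisters (same mother within one sire tenure) and maternal half-sisters
  (same mother across tenures) both arise.

The affiliation generator works on the log-rate scale (counts are Poisson),
while the analysis models transformed CSI linearly; recovering effect signs
across that mismatch is deliberately part of what the end-to-end tests
check.  :func:`simulate_linear_dyadic` generates data from the analysis
model itself for exact parameter-recovery checks.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from kinbond.core_io import BehaviorEvent, ConflictRecord, Individual, PedigreeTable
from kinbond.dyadmodel import transform
from kinbond.pedigree import relatedness_table

STUDY_YEAR = 2008
FIRST_COHORT_YEAR = 2000


@dataclass
class SimConfig:
    """Parameters of the synthetic study group.

    Defaults mirror the study system the pipeline was built for: ~30
    females observed 3 h 40 min each, roughly 1100 decided conflicts, one
    breeding male at a time rotating every ``sire_rotation`` cohorts, and
    affiliation effects of maternal relatedness (+), paternal sistership
    (+) and rank distance (-) of the magnitude reported for matrilineal
    macaque groups.
    """

    n_females: int = 30
    n_matrilines: int = 6
    matriline_generations: int = 2
    n_cohorts: int = 6
    sire_rotation: int = 2  # cohorts per breeding tenure
    n_males: int = 2  # male pool; tenures cycle through it, so sires return
    n_breeders: int = 6
    n_absent_mothers: int = 2  # breeders removed from the group before the study
    focal_hours: float = 3.667  # 3 h 40 min per female
    n_conflicts: int = 1098
    hierarchy_steepness: float = 1.5  # logistic slope per rank unit
    beta_mat: float = 0.35
    beta_pat: float = 0.30
    beta_rank: float = -0.18
    beta_age: float = 0.0
    sigma_individual: float = 0.30
    base_rates: dict[str, float] = field(
        default_factory=lambda: {
            "proximity": 2.0,  # events per dyad-hour
            "body_contact": 1.0,
            "grooming": 0.6,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_matrilines < 1 or self.matriline_generations < 1:
            raise ValueError("need at least one matriline generation")
        pool = self.n_matrilines * self.matriline_generations
        if self.n_females <= pool - self.n_absent_mothers:
            raise ValueError(
                f"n_females = {self.n_females} leaves no study cohorts "
                f"(matriline pool is {pool})"
            )
        if self.sire_rotation < 1 or self.n_cohorts < 1 or self.n_males < 1:
            raise ValueError("invalid breeding schedule")
        if self.n_breeders > pool:
            raise ValueError("n_breeders exceeds the breeding pool")
        if not 0 <= self.n_absent_mothers <= self.n_breeders:
            raise ValueError("n_absent_mothers must be within the breeder count")
        if self.focal_hours <= 0:
            raise ValueError("focal_hours must be positive")
        if self.hierarchy_steepness < 0:
            raise ValueError("hierarchy_steepness must be non-negative")


@dataclass
class SimTruth:
    """Generator-side ground truth for the emitted logs."""

    true_rank_order: tuple[str, ...]
    true_coefficients: dict[str, float]
    expected_rates: pd.DataFrame  # id_a, id_b, behavior, rate (per dyad-hour)
    predictors: pd.DataFrame  # id_a, id_b, raw + transformed predictors
    individual_effects: dict[str, float]


@dataclass
class SimData:
    """One complete synthetic dataset."""

    config: SimConfig
    pedigree: PedigreeTable
    study_females: list[str]
    focal_time: dict[str, float]
    events: list[BehaviorEvent]
    conflicts: list[ConflictRecord]
    truth: SimTruth


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_pedigree(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[PedigreeTable, list[str]]:
    """Generate the pedigree; returns (pedigree, study female ids).

    Study females are the breeding-pool matriline females still present at
    study time plus the sired cohort daughters (``n_females`` in total).
    ``n_absent_mothers`` breeding females are marked as removed before the
    study (their daughters remain), which makes mother-present versus
    mother-absent sister contrasts possible.  Sires are in the pedigree but
    are not study subjects.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    individuals: dict[str, Individual] = {}
    pool: list[str] = []
    for m in range(config.n_matrilines):
        prev: str | None = None
        for g in range(config.matriline_generations):
            fid = f"F{m:02d}G{g}"
            birth = _dt.date(FIRST_COHORT_YEAR - 6 * (config.matriline_generations - g), 6, 15)
            individuals[fid] = Individual(
                fid, mother_id=prev, father_id=None, birth_date=birth, sex="female"
            )
            pool.append(fid)
            prev = fid

    n_tenures = -(-config.n_cohorts // config.sire_rotation)  # ceil
    n_sires = min(config.n_males, n_tenures)
    for s in range(n_sires):
        sid = f"M{s:02d}"
        individuals[sid] = Individual(
            sid, birth_date=_dt.date(FIRST_COHORT_YEAR - 10, 6, 15), sex="male"
        )

    breeders = sorted(rng.choice(pool, size=config.n_breeders, replace=False))
    absent = set(
        str(x) for x in rng.choice(breeders, size=config.n_absent_mothers, replace=False)
    )
    for fid in absent:
        old = individuals[fid]
        individuals[fid] = Individual(
            fid, old.mother_id, old.father_id, old.birth_date, old.sex,
            alive_during_study=False,
        )
    present_pool = [f for f in pool if f not in absent]

    n_daughters = config.n_females - len(present_pool)
    base, extra = divmod(n_daughters, config.n_cohorts)
    cohort_sizes = [base + (1 if c < extra else 0) for c in range(config.n_cohorts)]
    daughters: list[str] = []
    k = 0
    for c, size in enumerate(cohort_sizes):
        sire = f"M{(c // config.sire_rotation) % config.n_males:02d}"
        mothers = rng.choice(breeders, size=size, replace=False)
        for mother in mothers:
            did = f"D{k:02d}"
            individuals[did] = Individual(
                did,
                mother_id=str(mother),
                father_id=sire,
                birth_date=_dt.date(FIRST_COHORT_YEAR + c, 6, 15),
                sex="female",
            )
            daughters.append(did)
            k += 1
    pedigree = PedigreeTable(individuals.values())
    return pedigree, sorted(present_pool + daughters)


def simulate_conflicts(
    config: SimConfig,
    ids: Sequence[str],
    rng: np.random.Generator | None = None,
) -> tuple[list[ConflictRecord], tuple[str, ...]]:
    """Decided conflicts from a latent linear hierarchy.

    A latent rank order is drawn uniformly; for every sampled dyadic
    encounter the higher-ranked member wins with probability
    ``logistic(steepness * rank gap)``.  Returns the conflict log and the
    true order (rank 1 first).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ids = list(ids)
    n = len(ids)
    order = [ids[i] for i in rng.permutation(n)]
    rank = {ind: r for r, ind in enumerate(order)}  # 0 = top
    pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    records: list[ConflictRecord] = []
    choices = rng.integers(0, len(pairs), size=config.n_conflicts)
    u = rng.random(config.n_conflicts)
    for c, x in zip(choices, u):
        a, b = pairs[c]
        hi, lo = (a, b) if rank[a] < rank[b] else (b, a)
        gap = abs(rank[a] - rank[b])
        p_hi = 1.0 / (1.0 + np.exp(-config.hierarchy_steepness * gap))
        winner, loser = (hi, lo) if x < p_hi else (lo, hi)
        records.append(ConflictRecord(winner, loser))
    return records, tuple(order)


def _dyad_predictors(
    config: SimConfig,
    pedigree: PedigreeTable,
    females: Sequence[str],
    true_order: Sequence[str],
) -> pd.DataFrame:
    rel = relatedness_table(pedigree, females)
    rank = {ind: r + 1 for r, ind in enumerate(true_order)}
    rows = rel.copy()
    rows["pat_sister_raw"] = [
        float(
            pedigree[a].father_id is not None
            and pedigree[a].father_id == pedigree[b].father_id
        )
        for a, b in zip(rows["id_a"], rows["id_b"])
    ]
    rows["rank_gap"] = [abs(rank[a] - rank[b]) for a, b in zip(rows["id_a"], rows["id_b"])]
    rows["age_gap"] = [
        abs(pedigree[a].birth_date.year - pedigree[b].birth_date.year)
        for a, b in zip(rows["id_a"], rows["id_b"])
    ]
    rows["x_mat"] = transform(rows["r_maternal"], "sqrt_z")
    rows["x_rank"] = transform(rows["rank_gap"], "sqrt_z")
    rows["x_age"] = transform(rows["age_gap"], "sqrt_z")
    return rows


def simulate_affiliation(
    config: SimConfig,
    pedigree: PedigreeTable,
    females: Sequence[str],
    true_order: Sequence[str],
    rng: np.random.Generator | None = None,
) -> tuple[list[BehaviorEvent], SimTruth]:
    """Dyadic affiliation counts from a log-linear rate model.

    For each dyad and behavior the expected rate per joint observation hour
    is ``base_rate * exp(b_mat*x_mat + b_pat*pat + b_rank*x_rank +
    b_age*x_age + u_a + u_b)`` with individual effects
    ``u ~ Normal(0, sigma_individual^2)``; counts are Poisson over the
    dyad's joint focal time and reported as one aggregated event per
    dyad-behavior.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    females = list(females)
    pred = _dyad_predictors(config, pedigree, females, true_order)
    u = dict(zip(females, rng.normal(0.0, config.sigma_individual, len(females))))
    eta = (
        config.beta_mat * pred["x_mat"].to_numpy()
        + config.beta_pat * pred["pat_sister_raw"].to_numpy()
        + config.beta_rank * pred["x_rank"].to_numpy()
        + config.beta_age * pred["x_age"].to_numpy()
        + np.array([u[a] + u[b] for a, b in zip(pred["id_a"], pred["id_b"])])
    )
    events: list[BehaviorEvent] = []
    rate_rows = []
    joint_hours = 2.0 * config.focal_hours
    for behavior, base in config.base_rates.items():
        rates = base * np.exp(eta)
        counts = rng.poisson(rates * joint_hours)
        for (a, b, rate, count) in zip(pred["id_a"], pred["id_b"], rates, counts):
            rate_rows.append({"id_a": a, "id_b": b, "behavior": behavior, "rate": rate})
            if count > 0:
                events.append(
                    BehaviorEvent(
                        focal_id=a,
                        partner_id=b,
                        behavior=behavior,
                        duration_or_count=float(count),
                        protocol_id="sim",
                    )
                )
    truth = SimTruth(
        true_rank_order=tuple(true_order),
        true_coefficients={
            "mat_rel": config.beta_mat,
            "pat_sister": config.beta_pat,
            "rank_diff": config.beta_rank,
            "age_diff": config.beta_age,
        },
        expected_rates=pd.DataFrame(rate_rows),
        predictors=pred,
        individual_effects=u,
    )
    return events, truth


def simulate_group(config: SimConfig | None = None, seed: int | None = None) -> SimData:
    """Generate one complete synthetic dataset (pedigree, logs, truth)."""
    if config is None:
        config = SimConfig()
    if seed is not None:
        config = SimConfig(**{**config.__dict__, "seed": seed})
    rng_ped, rng_conf, rng_aff = _streams(config.seed, 3)
    pedigree, females = simulate_pedigree(config, rng_ped)
    conflicts, true_order = simulate_conflicts(config, females, rng_conf)
    events, truth = simulate_affiliation(config, pedigree, females, true_order, rng_aff)
    focal_time = {f: config.focal_hours for f in females}
    return SimData(
        config=config,
        pedigree=pedigree,
        study_females=females,
        focal_time=focal_time,
        events=events,
        conflicts=conflicts,
        truth=truth,
    )


def simulate_linear_dyadic(
    n_individuals: int = 30,
    beta: Mapping[str, float] | None = None,
    sigma_individual: float = 0.3,
    sigma_resid: float = 1.0,
    p_pat_sister: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Dyadic data generated from the analysis model itself.

    Every unordered pair of ``n_individuals`` contributes one row with
    standard-normal continuous predictors (``mat_rel``, ``rank_diff``), a
    Bernoulli ``pat_sister`` indicator, and response

        csi_t = b0 + b_mat*mat_rel + b_pat*pat_sister + b_rank*rank_diff
                + u_1 + u_2 + e

    with crossed individual effects ``u ~ N(0, sigma_individual^2)`` and
    residual ``e ~ N(0, sigma_resid^2)``.  Used for exact parameter-recovery
    and type-I-error checks of the mixed-model machinery.
    """
    if beta is None:
        beta = {}
    b0 = beta.get("(Intercept)", 0.0)
    b_mat = beta.get("mat_rel", 0.0)
    b_pat = beta.get("pat_sister", 0.0)
    b_rank = beta.get("rank_diff", 0.0)
    rng = np.random.default_rng(seed)
    ids = [f"I{i:02d}" for i in range(n_individuals)]
    u = dict(zip(ids, rng.normal(0.0, sigma_individual, n_individuals)))
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            x_mat = rng.normal()
            x_rank = rng.normal()
            x_pat = float(rng.random() < p_pat_sister)
            y = (
                b0
                + b_mat * x_mat
                + b_pat * x_pat
                + b_rank * x_rank
                + u[a]
                + u[b]
                + rng.normal(0.0, sigma_resid)
            )
            rows.append(
                {
                    "id_1": a,
                    "id_2": b,
                    "csi_t": y,
                    "mat_rel": x_mat,
                    "pat_sister": x_pat,
                    "rank_diff": x_rank,
                }
            )
    return pd.DataFrame(rows)
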