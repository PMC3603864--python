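# Methods

This note documents the models and procedures implemented in `kinbond`,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## Pedigree relatedness and its decomposition

The coefficient of relatedness between individuals a and b is computed by
path counting: every simple path a → common ancestor → b (the two upward
branches share no individual other than the common ancestor) contributes
0.5^L, with L the number of parent-offspring links on the path. On
non-inbred pedigrees this equals the off-diagonal of Wright's numerator
relationship matrix, which the package also computes independently via the
tabular recursion `a(i,j) = ½(a(j, dam_i) + a(j, sire_i))`; the test suite
asserts exact agreement on hundreds of random pedigrees. Path counting is
preferred as the primary route because it supports the decomposition the
analysis needs; the tabular method is the fallback for inbred input, where
simple-path summation is no longer valid (the decomposition is then
reported as NaN with a warning — the synthetic generator never mates
relatives, so this arises only with user-supplied pedigrees).

Each path is classed by the **first** parent link leaving each focal
individual: mother+mother → maternal, father+father → paternal, one of
each → mixed; a descendant path (one focal individual is the ancestor) is
classed by its single defined first link. This is the only rule under which
(i) maternal + paternal + mixed sums exactly to the total, (ii) a
mother–daughter dyad is purely maternal, and (iii) cousins through sister
mothers count as maternal kin — the way matrilineal-primate studies
tabulate kin classes. Unrecorded parents are treated as distinct founders.

Kin categories are assigned from shared parents plus thresholds: paternal
half-sisters whose maternal relatedness reaches 0.0625 are `excluded`
(the paternal contrast would be confounded; boundary inclusive), dyads
without a shared parent are `distant_or_nonkin` up to a total relatedness
of 0.125 (inclusive) and `excluded` above it (close lateral kin such as
aunt–niece fit no contrast category but stay in the regression data).

## Dominance hierarchy

The net outcome of a dyad is the direction with strictly more wins; equal
non-zero counts are tied, no conflicts means unknown. The I&SI criterion
orders individuals to minimise first the number of dyads whose net outcome
contradicts the order (I), then the summed rank distances of those dyads
(SI). For n ≤ 8 the optimum is found by enumerating all n! orders
(vectorised); above that a first-improvement local search over pairwise
swaps *and* single-individual reinsertions runs from a degree-sorted start
plus seeded random restarts (default 100). The swap neighbourhood alone can
stall in local optima that the insertion moves escape; with both
neighbourhoods the search matches the enumerated optimum on every random
matrix the suite throws at it. Ties between equally scored orders break on
the lexicographically smallest id sequence, making results reproducible.

Linearity: Landau's h = 12/(n³−n) Σ(Vᵢ−(n−1)/2)², with Vᵢ the number of
individuals i dominates. Unknown and tied dyads contribute ½ to each member
for the point estimate h; the improved h′ instead assigns each such dyad a
random direction and averages h over `n_random` fills (so h′ = h exactly
when every dyad is decided). The p-value is the two-step randomization
probability: each iteration compares the filled h with the h of a fully
random tournament, and p is the proportion of iterations (observed
comparison included) where the null value is at least as large. A property
worth knowing: when many dyads are tied or unknown, the refills inflate the
variance of the filled statistic and the p-value compresses towards 0.5 —
the test becomes conservative, which the suite demonstrates is absent on
densely decided matrices (null p uniform by KS) and which users should
expect on sparse ones.

The directional consistency index is Σ(H−L)/Σ(H+L) over dyads (H, L the
counts in the more/less frequent direction). Dyad-relationship percentages
are reported with precedence unknown > tied > two-way > inconsistent >
one-way, over all n(n−1)/2 dyads.

## Composite Sociality Index

Dyadic rates divide the total duration-or-count for the dyad (pooled over
both members' focal sessions) by the **sum of the two members' focal
observation hours** — the standard focal-sampling normalisation; the
source protocols do not pin down a denominator and this choice keeps rates
comparable when observation effort varies. Grooming given and received are
pooled (the index is symmetric). The CSI is the mean over behaviors of
rate/grand-mean-rate, so its grand mean is 1 by construction (asserted to
1e-12) and it is invariant to the time unit (asserted by a rescaling
test). A behavior with all-zero rates is an error, not a silent drop.
Dyads that were never jointly observable can be masked out of the grand
means via `valid_mask`; the simulator observes every dyad, so the default
uses all of them.

Component coherence is measured by row-wise Spearman matrix correlations:
the statistic is the mean over individuals of the correlation between
their two rows (diagonal excluded; constant rows dropped with a warning).
The null permutes the id labels of one matrix simultaneously over rows and
columns — the same node-permutation convention as the categorical test
below — rather than shuffling within rows, because within-row shuffles
destroy the dyadic dependence the test must respect.

## Categorical matrix permutation test

Dyadic values are not independent (each individual sits in n−1 dyads), so
category contrasts are tested by permuting individuals: a random
permutation of the id labels is applied to rows and columns of the value
matrix at once, categories stay fixed, and statistics are recomputed. The
overall statistic is Σ_c (m_c − m̄)² with m̄ the **unweighted** mean of the
category means (not the grand dyad mean); pairwise contrasts use |m_a −
m_b|. Both are non-negative deviation measures, so the test is one-tailed
(≥), the observed labelling counts as one permutation (p ≥ 1/n_perm), and
`excluded`-labelled dyads are dropped from every statistic. Pairwise
p-values are reported raw; a Bonferroni flag exists but is off by default.
An exhaustive mode enumerates all n! permutations and is tested against an
independent loop-based oracle; sampled mode is validated for type-I error
(within [0.03, 0.07] at α = 0.05 over 1,000 null replicates) and power
(> 0.9 for a 2-SD planted shift at n = 30).

## Dyadic mixed models

One row per unordered dyad; the response (CSI) and the continuous
predictors (maternal relatedness, rank distance, age distance) are
square-root transformed and z-standardised (sample sd, n−1); the
paternal-sister indicator stays 0/1 by default (a switch standardises it).
The two members enter as two crossed random intercepts. Membership is
assigned by a fixed convention — lexicographically smaller id to factor 1 —
and a regression test confirms the fit is insensitive to the opposite
convention. Fitting uses statsmodels `MixedLM` with two variance
components built from member-incidence matrices (columns restricted to ids
actually occurring in each slot; all-zero columns make the profiled solver
singular). Maximum likelihood is used for every model comparison, REML
only for the reported variance components. L-BFGS fits fast but can stop
short of the optimum, so every fit is polished by Nelder-Mead from the
L-BFGS solution; the result matches lme4 (`lmer(..., REML=FALSE)`) to
~1e-5 in fixed effects and log-likelihood on test data, with lme4 run via
Rscript as an independent oracle.

Model significance is the likelihood-ratio test of the full model against
the intercept-plus-random-effects null (χ² on `len(terms)` df). Per-term
p-values are drop-one LRTs — a deliberate replacement for
posterior-simulation p-values from older mixed-model tooling, chosen
because they are well-defined, reproducible, and asymptotically equivalent
at these sample sizes. VIFs come from the fixed-effects-only auxiliary
regression, per the usual practice of diagnosing collinearity without the
random terms. Two standard configurations run from one pipeline config:
the three-term model on all dyads, and the age model which adds age
distance and drops parent-offspring dyads (their age gap is structurally
large). The Welch two-sample t contrast of sister-dyad CSI by mother
presence is included as a pipeline summary.

## Synthetic study groups

The generator emulates the study design, not just its marginals:

* **Pedigree** — `n_matrilines` founder females extended matrilineally
  (`matriline_generations` deep, sires unrecorded, emulating groups where
  paternity records begin with the study cohorts); `n_cohorts` cohorts of
  daughters, each sired entirely by the scheduled male; sires cycle
  through a pool of `n_males` with `sire_rotation`-cohort tenures, so
  cohort peers are always paternal sisters and paternal sisterships span
  multiple age gaps. Mothers are drawn from a persistent breeder subset,
  producing full sisters (same mother within a tenure) and maternal
  half-sisters (same mother across tenures); a couple of breeding females
  (`n_absent_mothers`) are removed before the study so mother-present vs
  mother-absent sister contrasts exist. Because recorded sires are
  terminal founders and sired daughters do not reproduce within the
  simulated window, every ancestral path is purely maternal or purely
  paternal — mixed-class relatedness is structurally zero, matching a
  system whose only paternal kin relation is paternal half-sistership.
* **Conflicts** — a latent uniform-random rank order; in each of
  `n_conflicts` (default 1098) uniformly sampled dyadic encounters the
  higher-ranked member wins with probability logistic(steepness × rank
  gap). The default steepness of 1.5 yields strongly linear, highly
  one-sided hierarchies (DCI ≈ 0.96–0.97) of the kind stable captive
  groups show.
* **Affiliation** — per dyad and behavior, log expected rate = log base
  rate + β_mat·t(r_maternal) + β_pat·paternal-sister + β_rank·t(rank gap)
  + β_age·t(age gap) + u_a + u_b with u ~ N(0, σ²_ind); counts are Poisson
  over the dyad's joint focal time (default 2 × 3.667 h). Defaults:
  β = (0.35, 0.30, −0.18, 0), σ_ind = 0.3, base rates 2.0 / 1.0 / 0.6
  events per dyad-hour for proximity / body contact / grooming — effect
  magnitudes and data volume chosen once to match the emulated system's
  reported scale.

A single seed fans out through `SeedSequence.spawn` to per-component
streams, so pedigree, conflicts and affiliation are independently
reproducible. `SimTruth` carries the latent order, the generating
coefficients, every dyad's expected rate and the individual effects —
enough to recompute any expected quantity in tests.

Note the deliberate generative/analysis mismatch: effects are planted on
the log-rate (Poisson) scale while the analysis models transformed CSI
linearly. Recovery of effect *signs* and category ordering across that
mismatch is itself a robustness property and is what the end-to-end suite
asserts (signs recovered in ≥ 95% of replicate groups); numerical equality
of coefficients is asserted only for data generated from the linear model
itself (`simulate_linear_dyadic`), where mean estimates recover the truth
within 0.05.

## What passing tests do and do not show

The generator reproduces the design features the analysis leans on
(single-sire cohorts, matrilineal structure, rank-structured aggression,
kin-structured affiliation, crossed individual effects) but not demographic
realism: no mortality or migration during the study window, no male social
behavior, no observation-level biases (observer effects, visibility), and
affiliation counts are conditionally Poisson, i.e. less over-dispersed
than real behavior streams can be. Passing tests therefore establish that
the estimators and tests are correct and calibrated under the assumed
model, not that any particular field dataset satisfies those assumptions.

## Numerical and problem-size choices

* Replicate-based checks size their simulations to run on one CPU in a few
  minutes: type-I calibration uses 1,000 replicates (permutation test,
  12 ids, 200 permutations) and 500 replicates (mixed-model LRT, 15
  individuals); power and sign-recovery checks use 100 replicates at the
  full 30-female scale; exhaustive I&SI verification samples random
  matrices up to n = 8 (40,320 orders, vectorised).
* Permutation p-values always include the observed arrangement, so p ≥
  1/n_perm; comparisons use a 1e-12 tolerance so ties at the observed
  statistic count as at-least-as-extreme.
* Degenerate inputs fail loudly: all-zero behaviors, constant vectors
  under z-transform, empty conflict matrices for DCI, rank-deficient
  design matrices, cyclic pedigrees, negative values under sqrt.
* Matrices are written in id-sorted order and reports as sorted-key JSON,
  which is what makes same-seed runs byte-identical.
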