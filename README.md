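# kinbond

Dyadic social-bond analysis for group-living primates: who bonds with whom,
and how much of that is explained by maternal kinship, paternal kinship,
dominance rank and age?

`kinbond` implements, as a tested and reusable pipeline, the statistical
workflow used in behavioral-ecology studies of matrilineal primate groups
(the motivating system is a captive breeding group of ~30 rhesus macaque
females with complete pedigree records and a one-male-at-a-time breeding
regimen, so that every birth-cohort is a set of paternal half-sisters):

* **Pedigree relatedness** (`kinbond.pedigree`) — the coefficient of
  relatedness r between two females is the sum over all simple ancestral
  paths of 0.5^L (L = parent-offspring links on the path), decomposed into
  maternal, paternal and mixed components by the first link taken from each
  focal individual, and cross-checked against Wright's tabular
  additive-relationship recursion. Dyads are classified into kin categories
  (mother–daughter, full sisters, maternal half-sisters, paternal
  half-sisters, distant/non-kin), with paternal sisters excluded from
  category contrasts when they are also maternally related at r ≥ 0.0625.
* **Dominance hierarchy** (`kinbond.dominance`) — I&SI rank order from
  decided-conflict counts (minimise inconsistencies I, then their summed
  strength SI; exhaustive for n ≤ 8, seeded restart local search otherwise),
  Landau's h and de Vries' h′ linearity with a two-step randomization
  p-value, the directional consistency index, and unknown/two-way/tied/
  inconsistent dyad percentages.
* **Composite Sociality Index** (`kinbond.sociality`) — for each dyad, the
  mean over proximity, body-contact and grooming of the dyadic rate divided
  by that behavior's grand-mean rate; the CSI averages 1 by construction.
  Row-wise Spearman matrix correlations with node-label permutation nulls
  check that the components covary.
* **Matrix permutation test** (`kinbond.permtest`) — a Mantel-like test for
  category differences in a dyadic matrix: the id labels of the value
  matrix are permuted simultaneously over rows and columns, preserving the
  dyadic dependence structure; the overall statistic is the sum of squared
  deviations of category means from their unweighted mean.
* **Dyadic mixed models** (`kinbond.dyadmodel`) — transformed CSI regressed
  on maternal relatedness, paternal sistership, rank distance (and age
  distance) with crossed random intercepts for the two dyad members, fitted
  by maximum likelihood (statsmodels MixedLM; verified against lme4);
  full-vs-null likelihood-ratio tests, drop-one per-term tests, VIFs.
* **Synthetic study groups** (`kinbond.synthdata`) — a generator that
  reproduces the study design (matrilines, single-sire cohorts, latent
  linear hierarchy, kin- and rank-structured affiliation rates) so every
  stage can be validated end-to-end against known ground truth.
* **Pipeline + CLI** (`kinbond.pipeline`, `kinbond` command) — one
  deterministic run from config to a JSON report.

## Worked example

```python
from kinbond.pipeline import run_pipeline

report = run_pipeline({
    "simulate": {"seed": 42},        # 30-female synthetic group
    "n_perm": 10_000, "n_random": 10_000, "restarts": 20, "seed": 0,
})
```

On this dataset the hierarchy is strongly linear and one-sided —
`h' = 0.879, p = 0.0001, DCI = 0.973, I = 0, SI = 0` with
6.2% / 2.1% / 0.7% / 0.0% unknown / two-way / tied / inconsistent dyads —
and the CSI grand mean is 1.0 (definitional). Mean CSI by kin category:

| category               | dyads | mean CSI |
|------------------------|------:|---------:|
| mother_daughter        |    17 |     2.92 |
| full_sisters           |    15 |     1.93 |
| maternal_half_sisters  |    23 |     1.67 |
| paternal_half_sisters  |    82 |     0.93 |
| distant_or_nonkin      |   279 |     0.75 |

The dyadic mixed model recovers the planted effect directions:

```
estimates  mat_rel +0.615   pat_sister +0.476   rank_diff -0.288
LRT full vs null: chi2 = 592.25, df = 3, p < 1e-100
VIF: all < 1.01
```

i.e. bonds strengthen with maternal relatedness and paternal sistership and
weaken with rank distance, each term significant by drop-one LRT. The
categorical permutation test rejects overall (p = 0.0001); the single
pairwise paternal-sisters vs distant-kin contrast is weaker on this
realisation (mean difference 0.18, p = 0.21) — the regression, which
controls for maternal relatedness and rank, is the more sensitive
instrument, as expected.

The same pipeline runs from files
(`kinbond run --config run.yaml --out out/` with an `inputs:` block listing
pedigree, event-log, conflict-log and focal-time tables; see
`kinbond --help` for the per-stage commands).

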