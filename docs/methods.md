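# Methods

## Signature attribution and exposure phenotypes

Each patient's single-base substitutions are modelled as draws from a
multinomial mixture over a fixed signature catalog: with mixture weights
π_s and catalog columns P_s over the 96 trinucleotide channels, a mutation
in channel c has likelihood Σ_s π_s P_s(c). Weights are fit per patient by
EM; each mutation is assigned its maximum-posterior signature, and the
final assignment is the majority vote over 31 random Dirichlet
initialisations (ties break to the lower catalog index). The model
deliberately ignores sequential dependency between nearby mutations: cloud
and dispersed mutations are attributed with the same per-patient mixture.
Mutations are labelled *cloud* (C) when another same-sample mutation lies
within 1 kb on the same chromosome (configurable; the labelling is a
symmetric neighbour relation), else *dispersed* (D).

Exposures are integer counts per patient and signature-context label
("2C", "5D", ...). A label is kept as a phenotype only when its signature
holds strictly more than 10% of its group's (C or D separately) total
mutations. Phenotypes are z-scores of log10(count + 1), using the sample
(n−1) standard deviation; the log base and pseudocount are recorded on the
vector since any monotone transform leaves the Spearman-based expression
stage unchanged. Patients absent from the expression or alteration inputs
are dropped per-analysis, and phenotypes are re-standardized within each
analyzed sample set.

## Expression modules

Gene–phenotype association uses Spearman ρ (average ranks for ties, the
large-sample t approximation for p). BH adjustment is applied jointly over
all gene × signature pairs — the conservative scope, since a per-signature
adjustment would be anti-conservative when signatures are correlated.
Genes pass with |ρ| ≥ 0.3 and adjusted p ≤ 0.005 for at least one
signature; both thresholds are inclusive. Consensus clustering runs
K-means 100 times with fresh random starts, the cluster count cycling
round-robin over k = 5..50 (2..20 in restricted analyses) so the range is
covered evenly; the consensus matrix (co-clustering frequency) is
clustered by average linkage on 1 − consensus — the standard
consensus-clustering choice — and cut at a user-chosen final cluster
count; no automatic selection statistic is imposed. Enrichment is the
upper-tail hypergeometric test, reporting terms at nominal p < 0.05. In
restricted mode the background is the focus gene set, and a term is tested
only if it shares ≥ 2 genes with the focus set with an intersection
hypergeometric p < 0.05 against the full universe.

## Alteration matrices

A gene is altered in a patient when it has ≥ 1 non-silent mutation there
or the pair is annotated as biallelically inactivated. Per target
signature, mutations attributed to that signature are excluded in **both**
C and D contexts (the exclusion is defined on the underlying signature,
not the phenotype's context), and indels are dropped when the underlying
signature is 3 or 8 (overridable). Biallelic annotations are never subject
to either exclusion: they represent an independent inactivation mechanism.
Genes altered in less than 1% of the patient universe are removed; sample
subsetting re-applies the filter on the subset. Consequence classification
(silent vs non-silent) is taken from the input — annotation is upstream of
this method.

## Module search

The objective rewards covering high-phenotype patients and penalizes
redundant coverage: score(S) = Σ_{j covered} w_j − λ Σ_j max(0, c_j−1)|w_j|
with λ = 1 by default. Only the positive direction is searched; negating
the phenotype searches the other tail. The MILP uses binary gene variables
x (Σx = k exactly), binary coverage indicators z_j (z_j ≤ c_j, k·z_j ≥
c_j), continuous excess variables e_j ≥ c_j − 1 (pressed to max(0, c_j−1)
at the optimum because they only incur penalty), continuous edge variables
y_uv ≤ x_u, x_v with Σy ≥ 0.5·C(k,2) for the density floor, and
single-commodity flow from a selected root (k−1 units out, one consumed
per selected gene, arc capacity gated on both endpoints) for connectivity
— density 0.5 alone does not imply connectivity for k ≥ 4. The solver is
HiGHS via `scipy.optimize.milp` with a zero MIP gap and a 600 s default
time limit (incumbents are returned flagged non-optimal). Every solution
is re-validated independently of the solver: size, connectivity, density
and objective recomputation.

Ties among equal-objective optima break to the lexicographically smallest
gene set, found by iterative variable fixing (genes visited in sorted
order; a gene in the incumbent optimum needs no extra solve). The
exhaustive oracle enumerates connected k-subsets from their smallest
member with a seen-set to avoid duplicates, applies the same density floor
and tie-break, and bounds the enumeration at 10^6 subsets.

## Significance and size selection

Permutation p shuffles the phenotype across patients and re-runs the full
optimization per permutation, with the add-one correction
p = (1 + #{permuted ≥ observed}) / (1 + N); N defaults to 100 and the
attainable granularity 1/(N+1) is implied. The selected k is the largest k
such that, for every 2 ≤ k′ ≤ k, objective(k′) > 1.05 × objective(k′−1)
and p(k′) ≤ p(k′−1); k = 1 otherwise. Ties in p are allowed ("did not
increase"); an increase of exactly 5% does not qualify ("more than 5%").
The rule is invariant to positive scaling of the objectives. FDR is BH
across the signature-contexts tested in one run, with significance at
q < 0.1. Per-gene association is the same permutation scheme applied to
the single-gene objective; robustness is the fraction of attribution
reruns whose selected module contains the gene.

## Synthetic data

The generators emulate exactly the statistical structure the stages
assume, with ground truth always returned alongside the data:

* **Mutation catalogs** — per patient and signature, Poisson counts at the
  configured mean with channels drawn from the signature's multinomial.
  Clouds are runs of 2–10 mutations with uniform spacing below the cloud
  spacing (1 kb default); dispersed mutations and inter-run gaps are ≥ 10×
  that spacing, so a distance threshold separates the groups exactly. No
  real genome coordinates, replication timing or trinucleotide content are
  modelled, so passing tests validate the attribution and bookkeeping
  machinery, not genomic realism.
* **Networks** — Erdős–Rényi at a chosen edge density plus a random
  spanning tree over the planted module (connectivity is verified
  post-generation); all edge scores sit above the confidence threshold.
* **Alterations and phenotype** — each patient is covered by the planted
  module with probability `module_coverage` (default 0.3; the level is
  needed to plant an association of chosen strength and has no analogue in
  real preprocessing). A covered patient gets exactly one altered module
  gene with probability `exclusivity`, else two; background genes are
  independent Bernoulli. The phenotype is Gaussian on the log scale
  (matching the pipeline's log+z transform), shifted by `module_effect`
  for covered patients, then z-scored.
* **Expression** — module genes are ρ·(standardized exposure ranks) +
  √(1−ρ²)·noise, making the realized Spearman ≈ ρ; other genes are pure
  noise. Real expression covariance structure is not emulated.

All generators are byte-reproducible given their seed.

## Validation battery and problem sizes

The self-validation experiments (in `sigmodules.benchmarks`, re-run by
`scripts/acceptance.py`) use sizes chosen to exercise each property fully
while keeping the battery to minutes on one CPU: MILP-vs-enumeration on
100 random instances of ≤ 15 genes, ≤ 30 patients, k ≤ 4; planted-module
recovery at 200 patients, 50 genes, effect 2.0, exclusivity 0.9, 2%
background over 20 seeds; null calibration at 10 genes, 40 patients, k = 2
with 99 permutations × 50 replicates; consensus recovery of three 20-gene
modules at ρ = 0.6 over 10 seeds; EM recovery on a 70/30 mixture of ~1000
mutations. Under the null the permutation p is uniform on {1/(N+1), ...,
1}, so the expected P(p ≤ 0.05) is 0.05 with binomial Monte-Carlo spread
across 50 replicates.

## Known limitations

* The exact objective of the published connected-subnetwork ILP is defined
  in material not reproduced here; this package fixes the functional form
  stated above and treats parity with that implementation as out of scope.
* Sequential (HMM) dependency of clustered mutations is not modelled; a
  per-patient mixture with majority voting stands in for the published
  attribution engine.
* The ambiguous phrasing of the exposure filter ("above 10% within both
  groups") is read per-group: a signature may be retained in D but not C.
* No covariate adjustment (age, subtype) in the association tests; subtype
  analyses are supported as sample subsetting only.
* Weighted (non-binary) alteration scores and negative-direction-specific
  search are not implemented beyond phenotype negation.
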