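# Methods

## The problem

Two marker types carry complementary signal about population
connectivity. Otolith near-core chemistry records the environment of the
early (natal) life stage, so it separates groups of fish that began life
in chemically distinct water bodies regardless of gene flow; neutral
genetic markers record long-term effective migration. The pipeline
analyses each marker on its full dataset and joins the results per
individual, without any joint statistical model — integration is a
deliberate graphical/bookkeeping step, not a re-analysis.

## Infinite Gaussian mixture for otolith chemistry

### Model

With no baseline of candidate sources, the number of natal sources K is
unknown. Fish i contributes a p-vector x_i (log element:Ca ratios and δ
values, all z-scored). The model is a Dirichlet-process mixture of
multivariate Gaussians:

    partition ~ CRP(α),  α ~ Gamma(1, 1)
    (μ_k, Σ_k) ~ NIW(μ0, κ0, ν0, Ψ0)    for each occupied cluster
    x_i | cluster k ~ N(μ_k, Σ_k)

Component parameters are conjugate and are integrated out; the sampler
works directly on the partition (collapsed Gibbs). Each sweep reassigns
every fish with weights n_k · t_k(x_i) for existing clusters (t_k the
Student-t posterior predictive) and α · t_0(x_i) for a new cluster, then
attempts three split-merge Metropolis–Hastings moves, then resamples α by
the Escobar–West auxiliary-variable step.

The split-merge moves matter. Single-site Gibbs cannot move 30 fish
between clusters one at a time through low-probability intermediate
states, so chains initialized in one cluster essentially never split and
chains that merge never recover: the occupied-K statistic is metastable
in both directions. The added move proposes splitting a random pair's
cluster (allocation of the remaining members by sequential restricted
assignment) or merging two clusters, with the exact
marginal-likelihood/CRP ratio in the acceptance probability. The
allocation proposal uses a cheap per-axis (diagonal) Student-t predictive;
since its probability is used verbatim as the proposal density in the
Metropolis–Hastings ratio, the approximation affects only proposal
quality, never the stationary distribution. Chains are initialized with
every fish in its own cluster. Correctness is tested against the exact
partition posterior enumerated over all 5 partitions of a 3-point dataset
(with α marginalized by quadrature), at < 0.03 total-variation distance.

### Defaults and their rationale

* Standardization: element:Ca ratios are strictly positive and
  right-skewed, so they are natural-log transformed; δ13C/δ18O are
  interval-scale and stay linear; all columns are then z-scored (n−1 SD).
* Base measure on z-scored data: μ0 = 0, κ0 = 0.01 (diffuse cluster
  locations), ν0 = p + 2 (weakest ν with finite E[Σ] = Ψ0), Ψ0 = I.
* α ~ Gamma(1, 1); 2000 sweeps, thinning 1, burn-in the first 50 % of
  stored iterations (configurable; the sampler itself stores everything).
* K estimate: posterior mode of the occupied-cluster count, ties broken
  toward the smaller K (parsimony).
* Ordination: non-metric MDS (2-D, Euclidean distances on the
  standardized matrix, best of 20 random SMACOF starts, Kruskal stress-1).
  Exact duplicate rows are embedded once and share coordinates.
* Consensus view: average-linkage dendrogram on 1 − co-assignment,
  exported as newick.

### What the synthetic chemistry generator emulates

`simulate_otolith` draws each source from a multivariate Gaussian on the
analysis (log) scale. `separated_sources_spec` places adjacent source
means a given Euclidean distance apart in pooled within-source SD units,
loaded *equally on all p variables*. The isotropic orientation is a real
decision, not a convenience: per-variable z-scoring is not rotation
invariant, and concentrating the whole separation on a single variable is
the worst case for it — the exact split-vs-merge posterior gap (computed
by marginal-likelihood enumeration at 30+30 fish, separation 6) is then
negative for every Normal-inverse-Wishart base measure we scanned, i.e.
no sampler could recover K = 2 because the posterior itself prefers
K = 1. Spread across the six variables, the same separation gives a
clearly positive gap under the default prior. Real multi-element
signatures differ along several axes at once, so the isotropic layout is
also the more realistic emulation. The generator does not emulate
instrument noise structure, censoring, or between-cohort drift; passing
recovery tests therefore show sampler correctness and sensitivity at the
stated geometry, not field-data performance.

## Microsatellite statistics

* Ho: fraction of typed individuals heterozygous. He: Nei's unbiased
  estimator (2n/(2n−1))(1 − Σp²).
* F_IS: Weir–Cockerham f from the one-population variance components
  (b, c), per locus — not 1 − Ho/He.
* Pairwise F_ST: Weir–Cockerham θ, multilocus as Σa / Σ(a+b+c) over loci
  and alleles; p-values by permuting individuals between the pair
  (add-one rule (r+1)/(n+1)); the Bonferroni-adjusted threshold
  α/n_pairs is reported rather than adjusted p-values. Negative θ is
  reported as computed and truncated at zero only where a dissimilarity
  is required (PCoA, Mantel input).
* Allelic richness: Hurlbert rarefaction AR(g) = Σ_a [1 −
  C(2n−c_a, g)/C(2n, g)], with g defaulting per locus to the smallest
  typed gene-copy count across populations.
* Missing data: pairwise-complete per locus. Multilocus summaries are
  arithmetic means over loci with data; a published table that divides by
  the full locus count even when a locus is untyped will differ in
  exactly those populations.
* HWE: exact conditional test given allele counts. Complete enumeration
  of genotype tables (probability-ordered rejection region) for ≤ 3
  alleles and ≤ 30 individuals; otherwise a Markov chain that swaps two
  gene copies in the flat 2n arrangement per step and always accepts —
  the uniform law over labelled arrangements induces exactly the
  conditional table distribution, so no Hastings correction is needed
  (default 1000 dememorization, 100 000 steps).
* Null alleles: Brookfield estimator r = (He − Ho)/(1 + He), floored at 0
  with an excess-heterozygosity flag.
* Mantel: Pearson correlation of upper-triangle entries, simultaneous
  row/column permutations, add-one p. PCoA: Gower double-centering and
  eigendecomposition; axes only for positive eigenvalues; percentages
  relative to the positive-eigenvalue sum.

The F-model generator draws ancestral frequencies from a flat Dirichlet
and population frequencies from Dirichlet(p_anc (1−F)/F), which makes
E[θ] ≈ F and gives estimator-recovery tests a clean target; θ̂ from 12
loci has a seed-to-seed SD of roughly 0.03 at F = 0.08, so calibration
claims are made about the mean over seeds, not individual draws. With
`admixture_alpha` set, each individual draws a membership vector
Dirichlet(e_own + α/P) and every gene copy samples its source population
from it (α → 0: pure individuals; α → ∞: one pool). With `cline_slope`
set, the first allele's logit frequency is shifted linearly along the
1-D habitat positions, the remaining alleles rescaled proportionally.

## Admixture model and ΔK

Gibbs sampler over the standard admixture model with independent
Dirichlet(λ = 1) allele frequencies per cluster × locus, per-individual
membership q_i ~ Dirichlet(α, …, α), per-gene-copy cluster assignment,
and a Metropolis step on the single shared α (normal proposal SD 0.05,
uniform(0, 10) prior). Missing gene copies are skipped everywhere. Model
support is lnP(K) = mean(lnL) − var(lnL)/2 over post-burn-in sweeps.
Defaults mirror the study design: K = 1–7, 20 replicates (tests and the
acceptance script use K = 1–4 with 5 replicates, burn-in 2000 of 8000
total sweeps — sizes chosen so the full recovery experiment runs at desk
scale while keeping ΔK's replicate-SD denominator meaningful).

Replicate label switching is resolved by aligning each run's columns to
the first run with an exact linear-assignment solve (Hungarian), which
always attains the exhaustive-permutation optimum; aligned runs can be
averaged. Evanno's ΔK(K) = |L(K+1) − 2L(K) + L(K−1)| / SD(L(K)) uses
replicate means and SDs; it is undefined at the range endpoints (so it
can never select K = 1 — mean lnP(K) per K is reported alongside for
that reason), and interior K with zero replicate SD are flagged infinite
and excluded from the argmax. The inner sweep is compiled with numba;
everything above the sweep is plain numpy.

## Integration

An inner join on fish identity (optionally through an explicit ID map)
produces per-individual rows (mds1, mds2, q_cluster1). The genetic
coordinate is one column of the aligned K = 2 Q matrix; the two columns
are complementary, so choosing the other merely reflects the coordinate
as 1 − q. Individuals present in only one marker dataset are dropped
with a logged count; row order follows the chemistry dataset.

## Numerical notes and limitations

* All stochastic entry points take an explicit integer seed;
  `numpy.random.default_rng` streams are derived from it (the numba
  kernel seeds numba's own legacy-compatible state).
* Degenerate inputs are errors, not silent results: zero-variance
  chemistry columns, monomorphic loci in HWE, burn-in ≥ stored
  iterations, fewer than 3 populations for Mantel/PCoA, K ≠ 2 Q matrices
  at integration.
* The DPM's K estimate at moderate separation is honest posterior
  inference, not a point guarantee: at the test geometry
  (6 pooled SD, 30 fish/source) the split-vs-merge posterior gap ranges
  roughly +3 to +26 nats across datasets, so occasional modal K = 1
  draws are expected behaviour of the model, not sampler failure.
* No linkage-disequilibrium testing, no correlated-frequencies admixture
  model, no spatial priors, no coalescent simulation; the Genepop dialect
  supported is the 2/3-digit diploid core, not extensions.
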