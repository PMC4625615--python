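# Methods notes

## Data model

A pathway is a signed multigraph: node identifiers in a declared namespace,
edges carrying a direction flag, a sign (+1 activation, −1 inhibition, 0
neutral/unknown) and a free-text subtype. Directed and undirected edges
coexist and parallel edges between the same pair are kept — KEGG-style
topologies need all three. Everything that edits a pathway returns a new
value; nothing mutates in place, so permutation loops can share inputs
freely.

Where a method needs a simple graph, parallel edges collapse by sign
majority (ties → 0) and self-loops are dropped; where it needs a fully
directed graph, undirected edges are oriented either in both directions
(default) or in listing order (`orient_mode`). The orientation mode is
recorded in the run metadata because it changes SPIA/PRS propagation.

Gene-family/complex reduction (`reduce_graph`) accepts only groups that are
redundant by construction: a *family* has identical signed in/out
neighborhoods outside the group and no internal edges; a *complex* has
identical external neighborhoods and all-to-all undirected binding inside.
`estimate_cf` searches for maximal disjoint such groups greedily from the
lexicographically smallest seed node; ties and overlaps are resolved in
favor of the earlier seed. These two rules are this package's committed
definition of "mergeable" — the operation is only safe when the merged
nodes are exchangeable with respect to the rest of the graph, and the rules
are exactly that exchangeability.

## Graph machinery

Maximal cliques come from Bron–Kerbosch with a degeneracy-ordered outer
loop and pivoting — near-linear on the sparse, small-degeneracy graphs that
curated pathways are, and worst-case optimal otherwise. Output order is
canonical (sorted) so downstream junction trees are reproducible.

Junction trees are built as: orient → enforce a DAG by greedy minimal
feedback-edge removal (edges scanned in sorted order, kept only if they do
not close a directed cycle; removed edges are logged in the result notes) →
moralize (marry co-parents, drop directions) → triangulate with the
greedy min-fill heuristic, ties broken by node id → maximum-weight spanning
tree of the clique graph weighted by intersection size. The
running-intersection property is asserted on every construction. Min-fill
does not find a minimum triangulation; it is deterministic and empirically
close enough that clique sizes stay small on sparse pathways, which is all
the Gaussian machinery needs.

The "both directions" orientation of an undirected edge creates a 2-cycle;
feedback removal then keeps exactly one direction, so the moral graph still
contains the original undirected adjacency.

## Preprocessing

Counts are normalized between samples by TMM (reference column = upper
quartile of library-scaled counts closest to the mean upper quartile; trim
30 % of M and 5 % of A per tail by rank; factor = 2^(inverse-variance
weighted mean of surviving M); factors rescaled to geometric mean 1) or by
median-of-ratios size factors over genes positive in every sample.

The log transform is prior-count log-CPM: log2(count / S_j × 10⁶ + prior)
with effective library size S_j = library × factor and prior 0.5. Adding
the pseudo-count on the CPM scale (rather than the count scale) keeps zero
counts finite *and* makes the transform exactly invariant to a global
rescaling of counts and depths, which the count-scale placement is not. It
does not reproduce a negative-binomial regularized-log transform; it is a
simple variance-limiting transform whose output the moderated-t engine
treats like microarray data. The choice is recorded in run metadata.

Differential expression is a two-group moderated t: per-gene pooled
residual variances are shrunk toward a common prior fitted by moment
matching of log sample variances against a scaled-F distribution (closed
form via Newton trigamma inversion); the posterior variance
(d₀s₀² + d·s²)/(d₀+d) feeds a t statistic with d₀+d degrees of freedom.
`d0_override=0` recovers the ordinary t-test, `inf` a fully pooled z-like
test — both serve as oracles in the test suite. BH is the only
multiple-testing adjustment, applied per result set over the pathways that
produced a p-value.

DEG selection defaults to p < 0.05 and |logFC| > 2.

## The seven methods — committed details

Several of the original methods leave parts of their algorithm
unspecified; the commitments below are this package's definitions, flagged
in run metadata as such.

**SPIA.** Propagation matrix B[i,j] = sign(j→i)/N_ds(j), with N_ds(j) the
number of outgoing *nonzero-sign* edges of j (neutral edges carry no
perturbation, so they appear in neither numerator nor denominator).
ΔE holds the logFC of DE pathway genes; (I−B)·PF = ΔE is solved directly
and pathways with condition number above 10¹² are skipped as `singular`.
The perturbation null places N_DE values drawn with replacement from the
global DEG logFC pool on uniformly random pathway positions; p_PERT is
two-sided around the bootstrap median with the (1+k)/(n+1) estimator, so it
can never be 0. p_NDE is the upper-tail hypergeometric over the measured
universe; p_G = c − c·ln c.

**PRS.** v_i = |logFC_i| for DE pathway genes, w_i = 1 + |downstream DE
genes| with downstream = full directed reachability (not only direct
children), raw = Σ v_i w_i / max(1, N_DE on pathway). The null resamples
whole gene records (DE status, |logFC|) without replacement from the
measured genome onto the pathway's slots, recomputing the weights from the
permuted DE pattern. A null with zero variance is flagged and reported as
z = 0.

**PWEA.** TIF_i = mean over pathway partners at finite hop distance of
exp(ρ_ij/d_ij); isolated genes get TIF = 1. Genes are ranked by decreasing
moderated t; pathway genes add |t|·TIF (normalized by the pathway total),
others subtract 1/(N−n_path); ES is the signed maximal deviation of the
running sum. The null permutes sample labels and recomputes the full DE
profile (TIFs held fixed); each permutation's shuffle derives from an
independent child seed indexed by permutation number, so the loop
parallelizes without changing results, and the runner computes the permuted
t matrix once per dataset and shares it across pathways.

**TAPPA.** Pathway genes are z-scored with the population (ddof 0) standard
deviation. PCI_s = (1/|T|) Σ_{(i,j)∈T} sgn(z_i+z_j)·√(|z_i||z_j|) over the
undirected skeleton's edges plus self-loops; the sgn-of-sum form means a
self-loop contributes the signed magnitude z itself, which is what makes
the index sensitive to location shifts and not only to co-expression.
Groups are compared by a two-sided Mann–Whitney test: exact when
min(n₁,n₂) ≤ 8 and the PCIs are tie-free, otherwise the normal
approximation with tie and continuity corrections.

**DEGraph.** Per connected component (≥ 2 measured genes) of the skeleton:
eigenvectors of the (optionally signed) Laplacian for the k smallest
eigenvalues; samples are projected onto them and compared by Hotelling T²
with the exact F transform. The signed Laplacian uses D = diag(row sums of
|A|) so an inhibition edge contributes +1 off-diagonal; an anti-correlated
pattern across an inhibition edge is then "smooth". k defaults to
min(⌈p/4⌉, n−3, 5), clipped per component with a note. The pathway p is
the Bonferroni-corrected minimum component p. A singular projected
covariance gets a ridge of 10⁻⁸·trace/k, flagged.

**TopologyGSA.** On the junction tree, the decomposable Gaussian MLE
concentration is assembled as Σ_cliques padded inverse clique covariance −
Σ_separators padded inverse separator covariance. The mean statistic is the
Mahalanobis norm of the group-mean difference in the pooled concentration
scaled by n₁n₂/n; the covariance statistic is the deviance difference
between pooled and per-group fits. Both p-values come from sample-label
permutation (estimator (1+k)/(n+1)); an asymptotic χ² p for the covariance
statistic is reported alongside when computable (df = free parameters of
the decomposable model). The covariance test requires each group to exceed
the largest clique; otherwise it is skipped with status
`insufficient-samples` — the limitation that motivates clipper. Per-clique
mean/covariance tests are reported as well. All permutation statistics are
computed by batched (stacked) linear algebra across the permutation axis.

**clipper.** Step (i) repeats the junction-tree tests with Ledoit–Wolf
shrinkage per group toward (trace/p)·I (analytic intensity, matching the
standard formula; an explicit `shrinkage` value overrides it, 0 recovering
the unshrunk test exactly on the same permutation stream). Shrinkage keeps
every clique covariance invertible, so the tests remain defined for
n < p. Step (ii) scores each clique by −log10 of its smallest p, roots the
tree at the clique with the smallest selected-test p — ties at the
permutation floor 1/(nperm+1) broken by the larger observed statistic — and
reports the root-to-leaf path with the highest mean clique score by
exhaustive walk (clique trees are small).

## Uniform runner

`PathwayAnalysis(expression, groups, pathways)` routes by data kind:
counts → normalize (TMM default) → log-CPM → moderated t → DEG → method;
normalized input skips normalization; a precomputed DE table may drive
SPIA/PRS only. Per-pathway failures downgrade to status flags and never
abort a run. One master seed drives everything; per-pathway and
per-permutation streams derive from it by stable blake2 hashing of
(seed, context, index), so the thread count (`threads`, a thread pool over
pathways) cannot change any number.

## Synthetic data

`make_random_pathway` draws DAGs by sampling edges only from lower to
higher random rank; `make_collection` uses disjoint gene sets per pathway
(expected out-degree ~1.5 unless overridden). `simulate_expression`
supports NB counts (baseline means log-normal(log 500, 1), dispersion
φ = 0.1, affected group-2 means ×2^effect), unit-variance Gaussian data
(additive effect), and graph-Gaussian data whose precision is
I + 0.3·adjacency with an eigenvalue floor of 0.1 — giving the conditional
independence structure the multivariable tests assume. The `paper_like`
preset is the default study: 50 pathways of 10–40 genes, one planted with
effect 2 (log2) on 30 % of its genes, 4 + 4 samples, 200 background genes.

What the generators do *not* emulate: library-size and composition biases
beyond a global depth factor, gene-length effects, outlier samples,
correlated background genes, overlap between pathways, and real pathway
degree distributions. Passing the planted-recovery tests therefore shows
the methods rank a coordinated mean shift correctly under clean conditions;
it does not certify performance on real data.

## Calibration experiments and their limits

The null-calibration test runs each method on 200 pathway-level tests (40
independent datasets × 5 pathways of 35 genes at DAG edge probability 0.05,
Gaussian null, n = 4 + 4, nperm/nboot = 200) and requires the empirical
type-I error at α = 0.05 to stay within [0.03, 0.08]. Design notes:

- For SPIA/PRS the DEG rule is a p-only cut (p < 0.1): under a global null
  the two-threshold default selects essentially no genes and the
  competitive nulls would be degenerate (every p = 1).
- Many small datasets rather than few large ones keep the 200 tests nearly
  independent (pathways within a dataset share data and permutations).
- With n = 4 + 4 there are only 35 distinct two-sided label splits, so a
  permutation p ties with the observed split about nperm/35 times and has
  an effective floor near (1 + nperm/35)/(nperm+1) ≈ 0.033; all
  permutation-based methods are therefore mildly conservative at α = 0.05
  here. The exact Mann–Whitney test (TAPPA) has attainable two-sided levels
  2/70 ≈ 0.029 and 4/70 ≈ 0.057, so its true size at 0.05 is 0.029.
- SPIA's hypergeometric component is super-uniform (discrete upper-tail
  p-values), which makes its combined p conservative under a global null;
  at these conditions its type-I error sits around 0.02–0.03 and the
  calibration test documents this as a known failure rather than widening
  the band. The conservatism costs power but does not inflate false
  positives.

Problem sizes throughout the test suite (pathways of tens of genes,
genomes of hundreds, nperm/nboot = 200) are chosen as the smallest scales
at which the statistical properties under test are meaningfully resolved.

## Known limitations

- Two-level comparisons only; no paired designs, covariates, or
  multi-class extensions.
- The log transform approximates, but is not, an NB regularized-log; genes
  with very low counts keep some mean–variance relationship.
- DAG enforcement by greedy feedback removal is heuristic; strongly cyclic
  signaling loops lose edges (logged per pathway).
- KGML import covers gene entries, groups and standard relation subtypes;
  compounds and maps are skipped, and the subtype → (sign, direction)
  table is a fixed, documented dialect.
- TopologyGSA skips pathways whose triangulated cliques exceed what
  4-per-group samples can estimate; on dense pathways clipper is the
  intended fallback.
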