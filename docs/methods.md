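# Methods

## Model

Soft gene clustering is treated as a constrained labeling problem.
The state is a row-stochastic matrix **X** = (x_ik) over *I* genes and
*K* cluster labels. Two constraint sets are defined, one per
similarity source, and the solution is driven toward their
intersection (or, when the intersection is empty, toward a weighted
compromise) by simultaneous generalized projections:

    X_m = Σ_n w_n · P_n(X_{m−1}),   w_n ≥ 0,  Σ_n w_n = 1,

for m = 1..M. Each projector P_n is realized by relaxation labeling
(RL): J synchronous sweeps of the multiplicative (growth-transform)
update

    q_ik = Σ_{i'∈∂_i} exp(v_ii') · x_i'k
    x_ik ← x_ik · q_ik / Σ_k' x_ik' · q_ik'

where ∂_i is the n_neighbors highest-similarity neighbors of gene *i*
under constraint *n* and v_ii' the raw similarity value. The update
monotonically increases the gain G(X) = Σ_i Σ_k x_ik q_ik (checked to
1e-9 in the test suite on random instances), so each projection
locally maximizes agreement between neighboring genes' label
distributions under its constraint.

### Expression constraint

Pearson correlation of log-ratio profiles, computed with population
moments (the 1/L vs 1/(L−1) choice cancels). Conventions:

* log base 2 for the ratio transform (the microarray convention; the
  base cancels in the correlation anyway);
* anti-correlated pairs keep their negative value — opposite-phase
  genes are treated as most dissimilar;
* constant profiles have undefined correlation; those pairs are
  **masked** rather than zeroed, so projectors simply skip them (the
  same contract as unannotated genes on the GO side);
* missing values are row-mean imputed after dropping genes with more
  than `max_missing_fraction` (default 0.5) missing entries. This is
  a deliberately simple, deterministic imputation; fancier
  reconstruction is out of scope.

### GO constraint

Wang-style graph-based semantic similarity. For a term *c*, every
ancestor *t* receives S_c(t), the maximum over upward paths of the
product of per-edge semantic contribution factors, w_is-a = 0.8 and
w_part-of = 0.6 (configurable); S-values are computed by a memoized
pass in topological order and are verified against brute-force path
enumeration. SV(c) = Σ S_c(t). Term pairs score through shared
ancestors; gene pairs score by the best-match average over their term
sets within each aspect.

The three GO aspects are combined as the **unweighted mean over the
aspects where both genes carry at least one annotation**; pairs with
no shared annotated aspect are masked. This symmetric,
range-preserving combination rule is this package's design choice —
alternatives (e.g. weighting aspects by annotation counts) were not
pursued. Whether to mask or zero no-shared-aspect pairs is likewise a
design decision here: masking keeps "no evidence" distinct from
"evidence of dissimilarity" and lets the expression constraint carry
such genes, which is exactly the behavior the GO-deletion
cross-validation relies on.

Ontology parsing keeps is-a and part-of edges only (the two relations
with defined contribution factors), drops obsolete terms, resolves
alt_ids, and hard-errors on cycles. GAF parsing skips NOT-qualified
rows and keeps all evidence codes by default (an exclusion list, e.g.
`{"IEA"}`, is accepted).

## Numerical choices

* **Synchronous RL sweeps**: all genes update from the previous
  sweep's values. Sequential (in-place) updating would make results
  depend on gene order; synchronous updating is deterministic and
  order-independent, and empirically retains gain monotonicity.
* **exp(v) on raw similarities** for both constraints (expression
  maps to [e⁻¹, e], GO to [1, e]); no rescaling between constraints —
  cross-constraint balance is carried entirely by the projection
  weights w_n.
* **Degenerate rows** (empty neighborhood, zero support): identity
  projection, bitwise unchanged.
* **Neighborhood ties** broken by ascending gene index (stable sort on
  descending similarity).
* **Initialization**: rows drawn i.i.d. from the flat Dirichlet on the
  K-simplex with a seeded generator; all randomness in the package
  flows from explicit seeds and results are bitwise reproducible.
* **hard_assign ties** go to the lowest cluster index.
* **GLL**: p_wk ∝ Π_{i∈w} x_ik computed in log space with x floored at
  1e-12 (so a perfect one-hot solution scores 0 only up to ~1e-11
  residuals); natural logarithms throughout, reported as a total over
  (gene, membership) pairs, with a per-membership average available.
  The conditional-independence product is the primary estimator; the
  empirical mean p_wk = Σ_{i∈w} x_ik / n_w is available via
  `method="mean"` for sensitivity analysis.
* **NMI** with multi-membership references counts one contingency unit
  per (gene, membership) pair, reducing to standard NMI for
  single-membership genes; normalization is I/√(H_W·H_K) by default
  with 2I/(H_W+H_K) behind `normalization="sum"`. Exactly identical
  partitions return exactly 1 (detected structurally, avoiding
  floating-point shortfall).

## Defaults

| parameter | default | meaning |
|---|---|---|
| K (`k_clusters`) | 10 | predicted cluster count |
| M (`m_projections`) | 3 | simultaneous projection iterations |
| J (`j_iterations`) | 5 | RL sweeps per projection |
| `n_neighbors` | 10 | neighborhood size per constraint |
| (w_go, w_expr) | (0.8, 0.2) | projection weights, sum to 1 |
| w_is-a, w_part-of | 0.8, 0.6 | semantic contribution factors |

M, J, n_neighbors and the weights follow the settings reported to work
well for this projection scheme on yeast-scale data; all are
configurable.

## Synthetic data

The generators produce every input the pipeline reads (expression TSV,
OBO, GAF, reference TSV), deterministically from a seed. Defaults:
120 genes, 4 planted clusters, 20 time points, expression noise
SD 0.1 on amplitude-1 sinusoidal prototypes with cluster-specific
phases (so some cluster pairs are uncorrelated and some
anti-correlated, exercising the anti-correlation convention), 10%
annotation noise. A gene planted in two clusters averages its
clusters' prototypes and draws annotations from both subtrees.

What the generator does **not** emulate: real GO topology (tens of
thousands of terms, deep multi-parent hierarchies), realistic
annotation depth distributions, heteroscedastic microarray noise,
synchronization loss in time courses, and reference clusters that are
only partially correlated with annotations. Passing tests therefore
demonstrate correctness of the machinery and recovery of idealized
planted structure, not performance on real yeast data.

## Known limitations

* **Label collisions cap planted-partition recovery.** RL is a local
  consensus process: with block-structured similarities the
  neighborhoods lie entirely within a planted block, so each block
  converges to a label determined only by its own random
  initialization. Distinct blocks can land on the same label, which
  coarsens the hard partition. With K = W = 4 equal blocks the chance
  that no more than one pair of blocks collides is about 2/3, which
  bounds how often end-to-end NMI ≥ 0.8 can be observed under random
  initialization. Nothing in the projection step couples distant
  blocks repulsively (all supports are positive), so this is inherent
  to the projection scheme itself, not an implementation artifact.
* **Soft memberships sharpen toward one-hot.** The multiplicative
  update amplifies any persistent imbalance in neighbor support
  exponentially across sweeps, so a genuinely bifunctional gene
  retains a mixed distribution only when its support from the two
  clusters stays nearly balanced; frequently it commits to one label,
  or ends at exactly (w_go, w_expr) when the two projectors commit it
  to different labels. A damped RL variant would preserve mixtures
  but would no longer be the stated update rule.
* The GO gene-pair similarity is quadratic in gene count with cached
  term-pair similarities; it is comfortable at a few hundred genes
  but not tuned for genome-scale inputs.
* Cross-validation evaluates held-out genes by default; scoring all
  genes after deletion is available via `evaluate="all"` since both
  protocols appear in practice.
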