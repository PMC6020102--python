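# Methods

## Network model and propagation

The predictor operates on a three-layer heterogeneous network: small
molecules (SMs), miRNAs and diseases, joined by two binary bipartite
adjacencies — `A` (ns x nm, known SM-miRNA associations) and `B`
(nm x nd, known miRNA-disease associations) — and three within-layer
similarity matrices `S_S`, `S_M`, `S_D`, each symmetric with entries in
[0, 1] and unit diagonal.

Two score matrices are iterated jointly from `W_sm⁰ = Ã`, `W_md⁰ = B̃`
(the normalized adjacencies):

    W_sm(k+1) = α · W_sm(k) (S_M W_md(k) S_D W_md(k)ᵀ) + (1-α) Ã
    W_md(k+1) = α · (W_sm(k)ᵀ S_S W_sm(k) S_M) W_md(k) + (1-α) B̃

Both updates use the current iterates simultaneously (a Jacobi-style
update): the bracket in the first line is the miRNA-miRNA flux routed
through the disease layer, in the second the miRNA-miRNA flux routed
through the SM layer. The SM-disease score `W_sd = W_sm S_M W_md` is a
by-product of the same fixed point.

A consequence worth knowing: the `W_sm` update multiplies from the right
only, so an SM whose row of `Ã` is entirely zero keeps a zero score row
forever. The method cannot rank candidates for SMs (or, symmetrically
weaker, miRNAs) with no known association — a genuine limitation of the
model, visible in cross-validation whenever a held-out edge was its SM's
only one.

### Normalization

Every input matrix is degree-normalized once, before iterating — not per
iteration, which would change the fixed point. The default is symmetric
degree normalization: `W'(i,j) = W(i,j)/√(r(i)c(j))` for bipartite
matrices (r/c row and column sums) and `D^{-1/2} S D^{-1/2}` for
similarities. This bounds every factor's spectral norm by 1, which makes
the α-damped update a contraction in practice; zero rows/columns are left
zero. A row-stochastic scheme is exposed (`normalize="row"`) for
sensitivity checks, but it does not bound the column sums of the bipartite
iterates and the coupled update can then diverge (the implementation
detects the overflow and raises); this instability is itself the reason
the symmetric scheme is the default.

### Parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.4 | decay factor: weight of propagated mass vs the known-association anchor; < 0.5 keeps the anchor dominant |
| cutoff | 1e-6 | L1 convergence threshold on the per-iteration change of each score matrix |
| max_iter | 1000 | iteration cap; hitting it emits a warning and returns the last iterate |
| normalize | "symmetric" | normalization scheme (see above) |

Convergence is verified empirically rather than proved: on every synthetic
fixture the residual trace is monotonically decreasing after the first two
iterations and the iteration converges in well under 100 steps at α = 0.4.
The fixed point is initialization-independent (checked against random
nonnegative starting points) and, as α → 0, approaches (1-α)Ã, so the
α → 0 ranking degenerates to the known adjacency.

## Similarity models

**Jaccard similarity** over per-entity annotation sets
(`|N(i)∩N(j)| / |N(i)∪N(j)|`) serves for SM side-effect similarity,
SM/miRNA disease-phenotype similarity, and the target-gene stand-in below.
Empty unions (or empty intersections) give 0; the diagonal is fixed at 1,
avoiding 0/0 for unannotated entities.

**Disease semantic similarity** uses per-disease MeSH-style ancestor DAGs.
Model 1 scores each term of `DAG(D)` by a contribution decaying with
distance from D: the disease itself contributes 1, every ancestor Δ times
the best of its children within the DAG. Δ is not standardized; 0.5, the
convention of the disease-semantic-similarity literature, is the default
and it is exposed in the API. Model 2 weights a term by its specificity
across the corpus, `-log(n_DAGs containing t / n_diseases)`; the logarithm
base (natural by default) cancels between numerator and denominator, so
the similarity is base-invariant (asserted to 1e-12 in tests). Both models
score a disease pair by the shared-term contribution mass over the total
mass; both are provably ≤ 1, and the implementation asserts the [0, 1]
invariant rather than clamping. Diseases whose total model-2 weight is
zero (all terms ubiquitous) score 1 against an identical term set and 0
otherwise — the limit behavior.

**GIP kernel.** A disease's interaction profile is its *column* of `B`
(the matrix is miRNA x disease, so columns, not rows, are the per-disease
profiles). The kernel is `exp(-γ_d ||IP(u)-IP(v)||²)` with bandwidth
`γ_d = γ'/mean_u ||IP(u)||²`; γ' defaults to 1, the standard choice for
GIP kernels. An all-zero `B` leaves the bandwidth undefined and the caller
must supply γ explicitly.

**Integration.** Each layer's sources are combined as a weighted mean
(default weight 1 each: SM sources disease-phenotype, target-gene,
chemical-structure, side-effect; miRNA sources disease-phenotype,
target-gene). Real similarity sources rarely cover the full universe, so
integration renormalizes per cell: a source contributes at (i, j) only if
both entities are covered by it, and the divisor is the sum of weights of
the contributing sources there. Zero-filling uncovered cells would bias
similarity downward instead. Disease similarity takes the mean of the two
semantic models where both diseases have DAGs and falls back to the GIP
kernel elsewhere. Chemical-structure (SIMCOMP) and gene-functional
consistency similarities are consumed as precomputed labeled matrices;
computing them is out of scope, and a clearly-labeled Jaccard-over-target-
genes stand-in is available for pipelines lacking the matrices.

## NBI baseline

The comparison method is two-step resource allocation on the SM-miRNA
bipartite graph alone: a query SM puts one resource unit on each of its
miRNAs; each miRNA splits its resource equally among its SMs; each SM
splits its accumulated resource equally among its miRNAs. Degrees are
recomputed from the training matrix of each CV fold, so no information
about held-out edges leaks. Division by a zero degree contributes 0.
Total distributed resource always equals the query's degree (binary
matrices cannot strand resource on an isolated node mid-walk), which the
tests assert as a conservation law. The gene layer some NBI variants add
is out of scope — the comparison here uses associations only.

## Cross-validation protocol

Each known SM-miRNA association is held out in turn (LOOCV) or in random
near-equal groups (k-fold, sizes differing by at most 1), zeroed in the
training matrix, and the scorer re-run from scratch per fold. The held-out
pair's score is ranked against candidates — every pair unknown in the
*original* matrix (so other held-out pairs are never candidates). Global
ranking uses all candidates; local ranking restricts to candidates sharing
the pair's SM (or miRNA). Because CV only perturbs `A` while the GIP
kernel depends on `B`, the disease similarity is computed once, not per
fold.

The per-test percentile is the fraction of candidates scored strictly
below the test score plus half the ties (half-credit is unbiased under
exchangeability; with a shared candidate set the mean percentile equals
the pooled-ranking AUC, which the tests cross-check against
scikit-learn's `roc_auc_score`). The headline AUC is the mean percentile;
a pooled ROC curve over all (test, candidate) labels is exported
alongside. The randomization control draws uniformly random "known" pairs,
repeats the requested LOOCV protocol, and reports the AUC distribution
with a two-sided one-sample t test against 0.5.

## Synthetic data generator

The generator emulates the structure the method assumes, not any
particular database. Entities are assigned uniformly to `n_blocks` latent
clusters (default 4); similarities are `sim_within` (0.8) on same-block
pairs and `sim_between` (0.1) otherwise, plus symmetric Gaussian noise
(sd 0.05) truncated by clipping to [0, 1] to preserve the similarity
invariants. Associations are drawn one at a time: with probability
`coherence` from the same-block pairs of an *active* subset of entities,
otherwise uniformly from the whole grid. The active subsets (40% of SMs,
70% of miRNAs by default) reproduce the empirical regime of curated
SM-miRNA catalogues, where a small minority of compounds carries all known
associations at a high per-compound degree while most compounds have none;
drawing associations uniformly over all entities instead would spread the
signal one edge per entity and no propagation method could recover it.
Default sizes are desk-scale — 30 x 40 x 20 with 60 SM-miRNA and 120
miRNA-disease associations — chosen so a full LOOCV (one propagation run
per fold) completes in about a second. A `dense` regime flag restricts
every universe to associated entities; `structureless_spec()` produces the
no-signal variant (flat similarities, coherence 0, no active subsetting)
used by the randomization control.

What passing on synthetic data does *not* show: real similarity matrices
are not block-structured, identifier harmonization across databases is
assumed solved (ids are opaque strings), real association matrices have
heavier-tailed degree distributions than the two-regime generator, and
annotation noise is idealized. Synthetic recovery demonstrates that the
machinery extracts exactly the planted signal — at coherence 0 the LOOCV
AUC sits at 0.5, rising monotonically to > 0.9 at coherence 1 — not that
any particular real-data AUC is attainable.

## Numerical choices and degenerate inputs

- Similarity matrices are validated on construction: asymmetry beyond 1e-6
  rejects, smaller asymmetry is symmetrized as (M+Mᵀ)/2; entries outside
  [0, 1] by more than 1e-8 reject, smaller excursions are clipped; the
  diagonal is forced to 1.
- L1 norm means the sum of absolute entrywise differences throughout.
- All-zero `A` and `B` converge immediately to all-zero scores.
- Ties in ranking always receive half credit; sorting for output uses a
  stable sort so equal scores keep input order.
- Every stochastic routine takes an explicit seed; repeat streams are
  spawned from a single generator so per-repeat results are reproducible
  and independent.
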