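# Methods

`cemusa` scores a spatial-transcriptomics clustering result against
ground-truth tissue domains with a single discrepancy value d ∈ [0, 2].
Unlike purely external metrics (ARI, NMI, ...) it is sensitive to *where*
mislabels sit on the slide, and unlike purely internal spatial-continuity
indices (CHAOS, PAS) it is anchored to the ground truth; an edge-weighting
hook additionally encodes *how severe* each mislabel is.

## The model

**Label matching.** Clustering algorithms emit arbitrary cluster names. Each
cluster u and domain v are compared by the Jaccard coefficient of their spot
sets, J[u,v] = |C_u ∩ C_v| / |C_u ∪ C_v|, and the Hungarian algorithm selects
the assignment maximizing total similarity. When the cluster count K1 and
domain count K differ, J is padded with zero rows/columns; a cluster matched
to a dummy column takes its best row (many-to-one), and a domain matched to a
dummy row recruits its best-Jaccard cluster only if that cluster's spots lie
closer (mean Euclidean distance to the domain's spot centroid) to the new
domain than to the cluster's current one. "Closer" is not further specified
by the underlying method description; spot-centroid distance is the simplest
spatially meaningful reading, and the rule moves the whole cluster when the
aggregate condition holds.

A caveat this package makes explicit with the `match` flag of
`cemusa_score`: Jaccard/Hungarian alignment is the right preprocessing for
arbitrary cluster alphabets, but it is the *wrong* one for synthesized
results that already claim specific domain identities. A result that labels
86% of the slide "domain 1" wrongly is, after re-alignment, indistinguishable
from its own color swap (a nearly correct result), so mislabel simulations —
including every generator in `cemusa.scenarios` — are evaluated as claimed
(`match=False`). Real clustering output should keep the default
`match=True`.

**Graphs and severity weights.** Both labelings are laid over one spatial
adjacency (default: symmetrized k-nearest-neighbor graph with k = 6,
matching hexagonal Visium packing; Delaunay and fixed-radius graphs are
provided for sparse or irregular slides). Each adjacent pair gets a code:
k if both endpoints share label k, 0 if they disagree. Each pair also gets a
weight W:

* *expression scheme* — scaled cosine similarity (cos+1)/2 of the endpoint
  expression profiles for same-label pairs, its complement for disagreeing
  pairs: splitting similar spots or merging dissimilar ones is penalized
  most. Weights are computed per graph from that graph's own codes.
* *cost scheme* — each spot's (true class, predicted class) confusion status
  is looked up in a user cost table (e.g. missed-cancer FN = 2, over-called
  FP = 1) and a pair's weight is the mean of its endpoint costs. The truth
  graph is concordant with itself, so its weights are the concordant cost.
* *uniform* — all weights 1; d reduces to a purely topological comparison.

**Edge-attribute distributions.** Every adjacent pair contributes one row:
code k ↦ unit vector e_k in R^K scaled by its weight, code 0 ↦ the zero
vector. The row cloud is modeled by an isotropic Gaussian KDE with
bandwidth h (default 0.1). The KDE uses the standard K-dimensional
normalization 1/(m h^K (2π)^{K/2}) so it integrates to one; only samples
matter downstream, so this choice does not affect scores.

**Discrepancy.** n batches of b points are sampled from each side's KDE
(uniform support choice + Gaussian jitter of scale h). Every pair of batches
is compared by the squared sliced 2-Wasserstein distance — the average over
L random unit directions of the exact sorted-quantile 1-D transport cost —
mapped through the kernel k = exp(−γ · W2²) (default γ = 10), and aggregated
with the biased V-statistic MMD²:

    d = mean k(x_i, x_i′) + mean k(y_j, y_j′) − 2 · mean k(x_i, y_j)

with full double sums including diagonals. One shared direction set is used
per evaluation; with equal batch sizes the squared sliced distance is then a
squared Euclidean distance between the flattened sorted projections, so the
kernel Gram matrix is exactly a Gaussian RBF Gram — positive semi-definite
by construction. This yields the estimator's three structural guarantees,
each enforced as a test: d = 0 exactly on identical batch lists, d ∈ [0, 2]
(kernel range (0, 1]), and min-eigenvalue(Gram) ≥ −1e−8. It is also why the
kernel argument is the *squared* sliced distance: that choice makes the
positive-definiteness exact rather than approximate. A half-sum variant of
the within terms (excluding diagonals, which some presentations write) is
negative on identical inputs and breaks the [0, 2] range; it is deliberately
not implemented.

## Numerical and design choices

* **Direction sampling.** Directions are drawn as random orthonormal frames
  (QR of a Gaussian matrix, random column signs). Each direction is still
  marginally uniform on the sphere, so the sliced estimate is unbiased, but
  within-frame orthogonality removes most of the direction-set imbalance
  that i.i.d. draws leave at moderate L. Measured on the mislabel-location
  scenario, the seed-to-seed standard deviation of a score difference drops
  from 0.11 (i.i.d., L=50) to 0.03 (frames, L=50).
* **Sampling sizes.** Defaults are n = 50 batches of b = 1000 points and
  L = 50 projections. On identical distributions the V-statistic has a
  positive noise floor ≈ (2/n)(1 − k̄), where 1 − k̄ ≈ γ·E[W2²] is driven by
  batch-to-batch mixture-proportion noise ∝ 1/b. The defaults put the
  measured floor at ≤ 0.016 on the hardest (two-domain) grids — inside the
  documented ≤ 0.02 envelope for perfect clusterings — at ≈ 0.3 s per
  evaluation of a 400-spot dataset.
* **Reproducibility.** One user seed fans out through named substreams
  (truth sampling, clustering sampling, projections); repeated runs are
  bitwise identical.
* **Hungarian tie-break.** Among optimal assignments the lexicographically
  smallest is returned (greedy refinement with optimal-completion checks),
  so matching is deterministic under ties.
* **k-NN ties.** Equidistant neighbor candidates are ranked by (distance,
  index); the pair u–v is kept if either endpoint ranks the other within k.
* **PAS ties.** Neighbors tied at the k-th distance contribute
  fractionally ((k − closer)/ties each), which makes PAS exactly invariant
  under isometries of the layout — a property the severity scenario's parity
  contrast relies on. CHAOS uses only nearest-neighbor distances and is
  tie-insensitive.
* **Degenerate inputs.** Zero expression profiles, label code 0, negative
  weights, non-square assignment matrices, empty KDE supports, and h ≤ 0 or
  γ ≤ 0 are rejected with typed errors; isolated nodes under a radius graph
  are kept with a warning.

## What the synthetic scenarios emulate

The generators reproduce the structure of three published simulation
designs on regular grids with two-class Gaussian expression profiles
(documented spot and mislabel counts are fixed study conditions):

* *label agreement* — 342 spots (3 domain-1 at the margin, 339 domain-2);
  Result I flips the 47 domain-2 spots nearest the margin, Result II the
  complementary 292. External metrics favor I; internal topology metrics
  barely distinguish the color-swap pair.
* *mislabel location* — a 116-spot layer-6 band over a 174-spot WM band with
  a boundary-proximal expression gradient; both results flip exactly 29 WM
  spots (boundary row vs core row), so every external metric ties exactly,
  while the discrepancy score separates them.
* *error severity* — mirror-symmetric 24+24 normal/cancer blocks; 12 FP vs
  12 FN flips that are reflections of each other, so topology and all
  count-based metrics tie; only an FN-weighted cost table separates them.
* *sensitivity series* — 360 spots, 180 per class, with 9→95 random flips
  across ten datasets; the score's Spearman correlation with the error rate
  is ≥ 0.9 over h ∈ {0.001, 0.01, 0.1, 0.5} × γ ∈ {0.5, 1, 5, 10}.

What passing these tests does **not** show: the generators use regular grids
and clean two-class Gaussian profiles. Real slides have irregular spot
layouts, domain shapes and sizes, dropout-heavy counts, and graded
expression boundaries; the scenarios preserve each design's discriminating
structure, not the noise characteristics of real data.

## Known limitations

* Scores are Monte-Carlo estimates: two different seeds differ by O(0.01–
  0.05) depending on dataset size and K. Comparisons between results should
  share a seed (the pipeline draws truth- and clustering-side samples from
  per-side substreams, so paired comparisons are partially variance-
  reduced).
* The adjacency construction dominates sensitivity on sparse or irregular
  layouts; prefer Delaunay or radius graphs there and check robustness
  across settings.
* With `match=True`, a result whose clusters mostly swap two domain
  identities is scored after re-alignment, i.e. mildly; use `match=False`
  when claimed identities themselves are under evaluation.
* ASW, Calinski-Harabasz, and Davies-Bouldin indices are not included in
  the benchmark panel: their feature space for spatial use is not
  standardized; CHAOS and PAS cover the topology-only contrast.
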