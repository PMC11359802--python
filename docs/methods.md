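# Methods

## Model

`chai` treats each clustering algorithm's output as a vote on pairwise
cell relationships. A partition of *m* cells becomes a binary
co-membership matrix `M ∈ {0,1}^{m×m}` with `Mᵢⱼ = 1` iff cells *i* and
*j* share a cluster. The diagonal is fixed at 1: the rule only addresses
pairs, but downstream averaging and diffusion need a defined diagonal, and
a cell trivially co-clusters with itself. Cluster labels are opaque
categories — numeric labels carry no order — so the encoding is invariant
to any bijective relabelling, and reordering cells conjugates the matrix.

Consensus assumes the views err *independently*: where they disagree, the
majority signal dominates the fused matrix. Correlated errors (two
algorithms sharing the same embedding, say) weaken that assumption; the
package fuses whatever it is given and leaves view selection to the user.

## Fusion

**AvgSim** is the entry-wise mean of the n binary matrices: entry (i, j)
is the fraction of algorithms co-clustering that pair, in [0, 1], diagonal
1. It is monotone in every input entry and idempotent on identical views.

**SNF** follows the cross-diffusion scheme of similarity network fusion,
applied directly to the binary matrices as affinities (no distance kernel
is involved — the views are already similarities):

1. *Row normalisation*: `Pᵢⱼ = Wᵢⱼ / (2 Σ_{j≠i} Wᵢⱼ)` off-diagonal,
   `Pᵢᵢ = ½`; each row sums to 1 with half the mass held on the cell
   itself, which keeps the iteration numerically stable.
2. *Local kernel*: row i of `S` keeps only the K largest off-diagonal
   entries of row i (renormalised to sum to 1); all other entries — the
   weak edges — are zeroed.
3. *Cross-diffusion*: for t iterations, each view is updated as
   `P_v ← S_v · mean_{w≠v}(P_w) · S_vᵀ`, then re-normalised and
   symmetrised (`(P+Pᵀ)/2`).
4. *Output*: the mean of the final `P_v`, re-normalised, then
   `W ← (W + Wᵀ + I)/2` (the reference method's diagonal regularisation).

Defaults K=20, t=20 match the reference implementation's documented
defaults; K is clamped to m−1 on small inputs with a logged warning.

Degenerate rows (a cell sharing no cluster with any other cell in some
view) receive uniform off-diagonal mass instead of a division by zero, and
the event is logged. Ties at the top-K cutoff break toward the smallest
cell index. This makes the algorithm fully deterministic, at a price:
binary views are saturated with ties, so exact permutation equivariance
holds only on tie-free (continuous-valued) inputs; on binary inputs,
conjugation by a permutation can shift fused entries at the ~1e-2 level.
The tests check equivariance on tie-free views and determinism everywhere.

## Spectral readout and choosing k

The fused matrix is clustered with the normalised-Laplacian variant of
spectral clustering: self-affinities removed, symmetric normalisation
`D^{-1/2} A D^{-1/2}`, the k leading eigenvectors as an embedding, rows
normalised to unit length, and a k-means readout (fixed seed, 10
restarts). Labels are re-coded to 1..k by order of first appearance, so a
rerun is byte-identical.

Two degenerate regimes are handled explicitly:

* k = m returns the singleton partition directly (the embedding carries no
  geometry there).
* When the embedding has fewer distinct points than k — e.g. a perfect
  two-block matrix scanned at k = 3 — k-means returns fewer than k
  clusters; the largest cluster is then split deterministically (lowest
  cell indices first) until k are occupied. The forced singletons score
  silhouette 0, so an inflated k never wins the scan.

When k is unknown, the package scans k over a range (default 2–15, clamped
to m−1), clusters at each k, and scores the partition by mean silhouette
width on the distance `d = 1 − S/max(S)`. This distance choice is a design
decision — a similarity matrix admits several; it is recorded in the run's
provenance so alternatives remain comparable. Ties in the argmax go to the
smallest k (parsimony). For benchmarking against a known truth the scan
range can be set to 2..k_true+1 via `k_scan` / the CLI flags.

## Spatial integration

Spot coordinates become a binary KNN adjacency: Euclidean distances on the
raw coordinates (no rescaling — the graph is scale-invariant anyway),
K=3 neighbours by default, self excluded, diagonal set to 1, and the
directed KNN graph symmetrised by union (OR), which preserves minimum
degree K. Distance ties at the K-th neighbour break toward the smallest
index. Three variants consume it:

* `avgsim-st`: the adjacency joins the average as an (n+1)-th view.
* `snf-first-level`: one SNF pass over all n+1 views.
* `snf-second-level`: SNF over the n assignment views first, then a second
  two-view SNF of that result with the adjacency. As one view of two
  rather than one of n+1, the spatial modality carries more weight here.

All three reduce exactly to their non-spatial counterparts when the
spatial matrix is excluded.

## Agreement metrics

ARI is evaluated from the contingency table,
`(Σᵢⱼ C(nᵢⱼ,2) − E) / (½[ΣᵢC(aᵢ,2)+ΣⱼC(bⱼ,2)] − E)` with
`E = ΣᵢC(aᵢ,2)·ΣⱼC(bⱼ,2)/C(n,2)`; a zero denominator (both partitions
trivial, hence identical) returns 1. NMI is `2I/(H(C)+H(K))` with
natural-log entropies (the form is base-invariant); two constant labelings
return 1, by convention, and the event is logged. Per-sample silhouette is
`(b−a)/max(a,b)` with singleton clusters scored 0. The test suite
cross-checks all three against independent oracles (exhaustive pair
counting, direct entropy sums, and scikit-learn) including all 203
partitions of six items.

## Synthetic data

The generator emulates the conditions under which consensus is expected to
help, not realistic scRNA-seq:

* **Truth**: m cells over k clusters, sizes by largest-remainder rounding
  of the proportion weights (default equal), membership shuffled by seed.
* **Noisy views**: each simulated algorithm independently reassigns each
  cell with probability `flip_rate` to a uniformly chosen wrong cluster.
  Defaults: 5 views, flip rate 0.10 (a moderately hard regime: individual
  views score ARI ≈ 0.75 at k=4); the spatial fixtures use flip rate 0.20
  so label noise clearly exceeds spatial noise.
* **Expression**: negative-binomial counts (gamma–Poisson, shape 2) with
  lognormal baseline means and disjoint per-cluster marker blocks whose
  means are multiplied by `effect_size` (default 4; 8 is "strong signal",
  0 removes all structure). Feeds the built-in baseline clusterers only.
* **Coordinates**: one Gaussian blob per cluster, centres on a grid with
  spacing = `spatial_separation` × within-cluster s.d.; separation 10
  gives ≥95% same-cluster KNN edges, 0.1 is near chance.

Because view errors are independent and clusters are exchangeable, passing
tests demonstrate the machinery and its favourable regime; they do not
show robustness to the correlated errors, nested subpopulations or batch
structure of real data.

## Problem sizes and numerics

The test and acceptance fixtures use m ≤ 500 cells, 5 views and 5
replicate seeds — large enough that individual-view ARI is well away from
both 0 and 1, small enough to run the whole suite in well under a minute.
Symmetry of fused outputs is enforced to 1e-8 relative; SNF equivalence
with an independently coded loop-based reference is asserted entry-wise at
1e-8. All randomness flows from a single integer seed per run, recorded in
the result's provenance together with the method, k, silhouette trace,
fusion parameters and SHA-256 digests of the input files.

## Limitations

* Consensus inherits any bias shared by the input algorithms; averaging
  cannot undo errors all views agree on.
* The silhouette scan clusters the fused matrix itself under the
  `1 − S/max(S)` distance; scanning an embedding instead could choose
  differently on weakly separated data.
* SNF output depends on tie-breaking on heavily tied (binary) inputs; see
  the fusion section.
* The built-in clusterers are plumbing for end-to-end runs, not
  re-implementations of published scRNA-seq methods, and the expression
  simulator models no dropout or library-size variation.
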