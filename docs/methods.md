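# Methods

## Model

`plexus` represents a multi-omics dataset as a heterogeneous multilayer
network (HMLN): an ordered set of layers, each a weighted graph over its own
node type (TFs, accessibility peaks, genes, methylation regions), joined by
weighted bipartite inter-layer links. Node ids are namespaced internally as
`layer:node`, so a gene that is also a transcription factor appears as two
distinct nodes — one in the TF layer, one in the gene layer.

All analysis reduces to random walks with restart (RWR) on a single
column-stochastic **supra-transition operator** over the union of all
layers' nodes. For a node `v` with bipartite links into `k ≥ 1` adjacent
layers, the outgoing probability splits as: jump probability `λ` into each
adjacent linked layer (within a jump, mass proportional to bipartite edge
weight), and the remainder `1 − kλ` over intra-layer edges proportional to
weight. Defaults and degenerate cases:

- `λ = 0.5` per adjacent linked layer, renormalized equally to
  `min(λ, 1/k)` so the jump total never exceeds 1. A consequence worth
  knowing: a node adjacent to two linked layers (e.g. a peak with both a
  TF motif hit and a nearby gene) spends all its non-restart mass on
  inter-layer jumps. `λ` and the renormalization are configurable
  (`RWRConfig.lambda_jump`, `renormalize_jumps`); with renormalization off,
  an over-committed node raises a configuration error.
- A node with no bipartite links keeps all mass intra-layer; a node with
  bipartite links but no intra-layer edges splits all mass equally across
  its adjacent layers; a node with neither is a *dangling* column.
- Dangling mass is redirected to the **seed distribution**, not a uniform
  teleport, which keeps every score interpretable as proximity to the seeds
  and keeps unreachable nodes at exactly 0.
- Undirected layers are symmetrized at operator construction; the gene
  layer's directed regulator→target edges stay directed.

The walk solves `x = (1 − r)(P x + d·s) + r·s` (with `d` the dangling mass
and `s` the normalized seeds) by power iteration from `x₀ = s`. Restart
`r = 0.7` (standard in biological-network RWR), L1 tolerance `1e-10`,
`max_iter = 1000`; the tolerance is tight because downstream outputs are
*rankings*, which are sensitive near ties. Ties in rankings break
lexicographically so runs are byte-stable. `rwr_oracle` solves the same
fixed point densely — `x = r(I − (1 − r)P̃)⁻¹ s` on the BFS-reachable
subsystem — and exists purely as an independent cross-check.

## Layer inference

- **Gene layer** (directed): for each target gene, an
  extremely-randomized-trees regression of its profile on all other genes;
  per-regulator importances become candidate edges and the global top
  `keep_fraction` (default 0.1) is retained. `n_trees = 100` per target by
  default — desk scale, configurable upward. Zero-variance genes contribute
  no edges in either role. Expression is used as provided; a
  library-size + log1p helper exists but is off by default because
  preprocessing belongs upstream.
- **Peak layer** (undirected): candidate pairs are same-chromosome peaks
  whose interval midpoints lie within `window` (default 500 kb); the edge
  weight is the Pearson correlation of accessibility profiles, optionally
  after random pseudo-cell aggregation under a stated seed. Edges with
  weight ≤ τ (default 0) are dropped, and **negative correlations are
  dropped rather than absolute-valued**: the walk needs non-negative
  transition mass, and anti-correlation is not evidence of co-regulation.
- **Generic coordinate-bearing omic** (e.g. snmC regions): same windowed
  correlation construction.
- **TF layer**: isolated nodes by default; supplying a TF–TF edge list
  turns on the cooperation variant.

## Inter-layer links

- **TF→peak**: position-count-matrix scanning of peak sequences on both
  strands. A window scores `Σⱼ log2((c[bⱼ,j]+p) / (totⱼ+4p) / bg[bⱼ])` with
  pseudocount `p = 0.8` and uniform background; windows containing `N`
  score −∞; hits need ≥ `rel_threshold` (default 0.8) of the motif's
  maximum attainable score. Links are **binary by default** (weight 1 per
  TF–peak pair): log-odds scales grow with motif width and would distort
  cross-TF competition in the walk; max-score weighting is available.
  TFs without a motif model stay isolated and are logged.
- **peak→gene / region→gene / region→peak**: proximity within a window
  (default 100 kb) on the same chromosome, anchored at the TSS (`start` for
  `+`/`.`, `end − 1` for `−`) or at the feature body. Coordinates are
  BED-convention 0-based half-open everywhere; the distance between
  `[s, e)` and a point `t` is 0 if `s ≤ t < e`, else
  `min(|t − s|, |t − (e−1)|)`. The window is deliberately local: distal
  enhancers are reached through peak–peak co-accessibility edges at walk
  time, not by widening the bipartite.

## Outputs

Layer subsets per output: TF targets and the GRN walk the full network;
TF binding regions walk TF + peaks only; gene regulatory regions walk
genes + peaks only. Orientation is the scientific point: walks from a TF
make *genes* compete for that TF (target prediction), walks from a gene
make *TFs* compete for that gene (GRN reconstruction). The GRN keeps every
positive-score edge; sparsification is a separate, explicit step
(`filter_to_density`, default target density 0.05 — raw walk-based networks
are near-complete and incomparable across methods without equalizing
density; ties at the cutoff break by weight desc, then TF, then gene).
Communities come from Louvain modularity on the undirected weighted GRN
across a resolution grid in [0, 2] with a fixed partition seed
(byte-identical reruns); Leidenalg is deliberately not the default so the
procedure matches the classical Louvain baseline.

## Synthetic data

The generator emulates an unpaired scRNA/scATAC/snmC study with planted
ground truth. Each of `n_tfs` TFs drives a *cascade*: a ~80 kb genomic
locus holding the TSSs of the TF's gene set (its own gene included —
autoregulation — so every planted TF→gene pair has a TF→peak→gene path)
and a set of peaks carrying the TF's exact consensus motif (width 10;
an optional mutation rate adds difficulty). Loci are spaced 600 kb apart —
beyond the 500 kb co-accessibility window — across 4 chromosomes;
background peaks and methylation regions fill the gaps at least 120 kb
from any locus, outside the 100 kb proximity window of planted genes.

Correlation structure comes from a latent activity per cascade and cell:
`f = a[cascade, group]·0.7 + N(0, 1)`, with group programs
`a ~ N(0, 1)` shared across omics but cell sets drawn independently per
omic (unpaired by construction; 3 groups, 300/250/200 cells by default).
Counts: scRNA is negative binomial (dispersion 0.3) with mean
`base·max(1 + 0.8f, 0.02)`; scATAC is Bernoulli with rate
`sigmoid(−2 + 2f)` for cascade peaks and a constant per-peak rate for
background; snmC is a Beta-distributed methylation fraction
(concentration 20) anti-correlated with activity. Ground-truth files
(TF→gene, TF→peak, gene→peak, cascade gene sets as GMT) are derived from
the actual placement with the same distance rule the pipeline uses.

What the generator does **not** emulate: sequencing-depth variation,
doublets, batch effects, overlapping regulatory programs beyond the
optional non-disjoint-cascade mode, trans-chromosomal regulation, and
realistic motif degeneracy. Passing the planted-recovery tests therefore
shows the pipeline correctly propagates clean multi-omics signal through
every stage; it does not certify performance on real tissue data.

## Evaluation

- Mean overlap of per-TF rankings with the truth at cutoffs
  {3, 5, 10, 15, 20, 30, 40, 50, 75, 100}; TFs with empty truth are
  excluded from means.
- Fisher's exact test per TF on the 2×2 table of top-k vs truth over the
  universe of ranked genes, **one-sided for enrichment** — "a significant
  number of correct targets" is a one-directional claim; the count of TFs
  with p < 0.05 is reported.
- F1 of predicted vs true sets; genomic region sets match by ≥ 1 bp
  interval overlap (a reciprocal-overlap option would be stricter; the
  rule is configurable in spirit — exact-id matching is used whenever
  inputs are plain sets).
- Community enrichment: hypergeometric over-representation per
  (community, gene set), Benjamini–Hochberg corrected per collection,
  community enriched if any adjusted p < α; reported as percentage and
  count of enriched communities.
- GRN comparison: Spearman over the union of edges with weight 0 for an
  edge absent from one network, average ranks for ties.

### Null calibration of the Fisher screen

Fisher's exact test is discrete and therefore conservative: with a
200-gene universe, 10 true targets and k = 10, the smallest attainable
p-values jump from ≈0.089 (overlap 2) to ≈0.012 (overlap 3), so the
realized null rejection probability is `p₀ = P(overlap ≥ 3) ≈ 0.009`,
well below the nominal α = 0.05. The calibration check accordingly
asserts two things over 1000 permuted-ranking replicates: the
significant-TF count lies within 3σ of Binomial(n, p₀) with p₀ computed
exactly from the hypergeometric null, and it never exceeds the nominal
Binomial(n, α) 3σ upper bound. A two-sided band around α itself would
reject every correct implementation of a discrete test.

### Robustness to unbalanced cell groups

Halving one cell group in one omic and rebuilding mimics unbalanced
cell-type proportions in unpaired designs. On the default bundle, halving
an scATAC group leaves the GRN essentially unchanged (Spearman ≈ 0.9999
vs the unperturbed GRN) while the co-accessibility layer itself moves
substantially (≈ 0.75): the walk aggregates over many paths and
compensates for false/missing links in a single layer. Halving an scRNA
group is the harsher direction here: the gene layer is both the seed
layer and an intra layer of the walk, so its noise feeds straight into
the near-zero "competition" scores that 19 of 20 TFs receive for each
gene, and the GRN Spearman (≈ 0.72) lands close to, not above, the gene
layer's own (≈ 0.75). Both directions are computed and reported by the
acceptance script; the headline robustness claim is demonstrated on the
scATAC perturbation.

## Problem sizes and determinism

The standard benchmark bundle is 20 TFs, 500 peaks, 200 genes,
50 methylation regions, 3 cell groups, 300/250/200 cells, seed 0 — chosen
so a full pipeline pass (layer inference dominates, ~30 s for the
tree-ensemble layer) plus all walks completes in well under five minutes
on one CPU. Every random choice flows from explicit seeds
(`numpy.random.default_rng`, per-gene regressor seeds, Louvain partition
seed), writers order rows deterministically and format floats fixedly, so
two identically-seeded runs are byte-identical — which is itself one of
the acceptance checks.

## Known limitations

- The λ-split default treats all adjacent layers symmetrically; there is
  no per-layer-pair tuning out of the box (the config accepts only a
  scalar).
- The co-accessibility layer is plain windowed correlation; no
  graphical-lasso regularization or distance decay.
- Motif scanning uses a 0-order uniform background and exact PCM
  log-odds; no GC correction or motif clustering.
- The GRN weight is the raw walk probability; no per-gene normalization
  or significance filtering beyond `filter_to_density`.
- Evaluation consumes ground-truth files as given; building ground truths
  from ChIP-seq/perturbation compendia is out of scope.
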