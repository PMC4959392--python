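# Methods

## Model and procedure

A pathway is modeled as a discrete Bayesian network over its genes, each a
binary expressed/not-expressed variable.  For a pathway whose assembled
network has `E` edges, the candidate family holds `N = E + 1` structures:
index 0 is the normal network, and variant `k` removes the `k`-th edge in
lexicographic order.  Only single-edge silencing is enumerated; multi-edge
disturbance is out of scope.

Structures are scored with the BDeu log marginal likelihood: for node `i`
with `r_i = 2` states and `q_i = 2^{|parents|}` parent configurations, the
Dirichlet prior cells are `α_ijk = ess / (r_i q_i)` (`ess` = equivalent
sample size, default 1.0 — the common uninformative choice; the `--ess`
flag threads through).  All arithmetic is in log space via log-gamma: raw
BDeu values underflow double precision for realistic pathway sizes.  The
score is Markov-equivalence invariant (verified in the tests), so the edge
orientations chosen at assembly time are largely score-neutral.

Per-sample structure likelihoods are leave-one-out ratios
`BDeu(g|D) / BDeu(g|D−{s})`.  The implementation decrements the held-out
sample's count cell instead of re-accumulating, which collapses per node to
`ln((α_ijk + N_ijk − 1)/(α_ij + N_ij − 1))` — the node's posterior-predictive
term — and is tested to equal the naive difference of two full scores.
This makes scoring O(nodes) per sample, and within a family the variants
reuse the normal network's per-node terms (a variant differs only at the
silenced edge's child).

The `N` log ratios are normalized by log-sum-exp into the pathway activity
distribution.  Normalization is required because the downstream
Jensen–Shannon divergence takes probability vectors; it is the minimal
convention consistent with treating the likelihood collection as a
distribution over candidate structures.

PAVd sums, over pathways, the square root of the base-2 Jensen–Shannon
divergence between two samples' distributions.  Base 2 bounds each
pathway's contribution by 1; the base affects only scale, not the metric
axioms.  Identity of indiscernibles is tested at 1e-12 and the triangle
inequality at 1e-9 (floating-point slack on exact mathematical
properties).

## Network assembly conventions

Interaction catalogs (SIF) carry no guaranteed orientation and may contain
cycles, but Bayesian-network scoring needs a simple DAG.  The conventions,
chosen for determinism and reproducibility:

* relation labels in a fixed directed-relation list (the Pathway Commons
  `controls-*` / `catalysis-precedes` family) keep their catalog direction;
  all other relations are undirected and oriented lexicographically
  smaller → larger gene symbol;
* if both orientations of a pair survive, only the lexicographic one is
  kept;
* remaining cycles are broken by depth-first search from lexicographically
  sorted nodes, removing back edges in discovery order (removals are
  logged);
* genes absent from the expression matrix are dropped from the network —
  count tables would otherwise be undefined;
* pathways whose assembled network has fewer than `min_edges` (default 1)
  edges are skipped.

Gene sets larger than the configured cap (CLI default 50) are dropped
whole, not truncated — filtering excludes a set rather than redefining it.

## Discretization

The scoring engine needs binary calls.  Each gene is fit on the
log2(count+1) scale with a two-component Gaussian mixture (EM, fixed
seed); a sample is "expressed" when the posterior of the higher-mean
component exceeds 0.5, ties falling to 0.  Genes with no usable bimodal
structure — constant, component weight < 0.01, or mean separation < 0.1
log2 units — are labeled all-0 and flagged.  This is a deliberately simple
caller: users with a dedicated RNA-seq discretizer can supply a pre-binarized
matrix and skip this stage.  Calls are invariant to positive rescaling of
a well-separated gene (tested at ≥ 99% label agreement across scale
factors 1/10/100).

## Clustering, enrichment, ranking

Complete-linkage agglomerative clustering runs on the condensed PAVd
matrix; the dendrogram is exportable as Newick with merge heights as
branch lengths.  The number of clusters `k` is an explicit user choice
(no default): group identification on real cohorts is a judgment call,
and the dendrogram export exists to support it.  Cluster labels are
canonicalized by decreasing size, ties by smallest member index.

Enrichment of a category within a cluster is the one-sided hypergeometric
upper tail P(X ≥ k) with the full clustered cohort as background;
unannotated samples count toward cohort and cluster sizes but toward no
category.  Raw p-values are reported without multiplicity adjustment
(mirroring how such tables are conventionally presented); users needing
FDR control can apply Benjamini–Hochberg downstream.

Pathway ranking between two groups scores each pathway by √JS between the
groups' average activity distributions (the element-wise mean of member
distributions, itself a probability vector), descending, ties by pathway
id.

## Synthetic cohorts

The generator emulates the assumed structure of a disease cohort: binary
expression drawn by ancestral sampling from known pathway networks, with
designated sample groups drawn from variants in which one interaction is
silenced.  Roots are Bernoulli(0.5); a child copies a Boolean aggregate of
its parents (AND or OR, drawn per node from the seed) with probability
β ∈ (0.5, 1], flipping otherwise; a silenced edge makes the child ignore
that parent (falling back to Bernoulli(0.5) if no parent remains).
Background genes are independent Bernoulli(0.5) noise.  All randomness
flows from one seed through named generators; cohorts are byte-for-byte
reproducible.

The reference study design (`default_two_group_spec`) is ten 5-gene chain
pathways, β = 0.9, two groups of 50, group B silencing one seed-chosen
edge in five of the pathways, plus 20 background genes — a moderately
sized two-subtype cohort with strong but noisy coupling.

What the generator does *not* emulate: count-level RNA-seq noise (it
operates at the binary level where scoring happens), correlated pathway
membership, and — importantly — the constitutive expression shifts that
accompany real disturbed interactions (in real tumors a silenced
interaction typically manifests as its target gene being consistently
unexpressed across the disturbed group; the generator's silenced children
are free-running coin flips).  Passing tests therefore demonstrate
correctness of the scoring and distance machinery, not that per-sample
clustering succeeds on any real cohort.

## Known limitations: per-sample recovery in balanced cohorts

Two regimes must be distinguished.

*Group-level attribution works.*  Averaging activity distributions within
a (known or recovered) group reliably identifies the silenced interaction:
over 20 replicate reference cohorts, the disturbed group's average
distribution peaks at the truly silenced edge's variant in ~99% of cases.

*Per-sample subtype recovery in a balanced cohort does not.*  The
leave-one-out predictive for a silenced edge's child is trained on the
pooled cohort; when half the cohort is disturbed, the pooled conditional
P(child | parent) on that edge equals the marginal P(child), so the normal
and silenced candidates assign nearly identical predictive probabilities
to every sample and the per-sample signal is second-order (finite-cohort,
O(1/n)).  Independently, a decoupled child matches the intact signature
with probability 1/2, so the disturbed group's expected within-group PAVd
equals the between-group PAVd: the disturbed group is a diffuse shell
around the compact intact group, and no k=2 cut of a metric clustering can
recover it.  The acceptance suite includes the end-to-end recovery check
under the reference design and it fails by construction, not by
implementation error (spectral and k-means embeddings of the same
distances fail equally; attribution on the same cohorts succeeds).
Per-sample separation requires disturbed mechanisms that are both a
cohort minority and constitutively expressed-shifted — the regime real
cohorts appear to occupy.

## Numerical choices

* Probability-vector validation: distributions must sum to 1 within 1e-9
  internally (1e-6 for user-supplied JS inputs); serialization refuses
  vectors off by more than 1e-6 and round-trips to < 1e-12.
* JS computes 0·log 0 as 0 and clamps tiny negative rounding to 0.
* Ties in the discretizer posterior (exactly 0.5) fall to "not expressed".
* Merge ties in linkage follow scipy's deterministic ordering; the same
  matrix always yields the same assignment.
* Degenerate inputs: empty gene sets and self-loop interactions are
  construction errors; edgeless pathways raise `UnusablePathwayError` at
  enumeration and are filtered (with a logged count) by `build_families`;
  leave-one-out on a 1-sample cohort is an error.

## Problem sizes

The test suite and acceptance script run, per replicate, cohorts of 100
samples × 70 genes with 10 pathways (5 candidates each), 20 replicates per
study; oracle checks enumerate all 25 three-node DAGs × 50 random
8-sample datasets and all hypergeometric configurations up to cohort size
12.  These sizes make every check exact or tightly sampled while keeping
the full suite under a minute.
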