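# Methods

## Model and assumptions

`hetlink` treats lncRNA–protein interaction prediction as supervised link
prediction on a typed heterogeneous graph. The working assumptions are:

1. **Guilt by association.** Molecules with similar interaction partners
   (high Jaccard similarity of association sets) or similar sequences (low
   alignment e-value) tend to share interaction partners. Similarity edges
   therefore carry signal about unobserved interactions.
2. **Topology is learnable from walks.** Metapath-constrained random walks
   sample typed neighborhoods; skip-gram embeddings place nodes that occur
   in similar walk contexts close together, so a pair's concatenated
   embedding is informative about whether an edge exists.
3. **Negatives must be constructed.** Only positive interactions are
   observed. The three negative-sampling strategies encode different
   assumptions about which unobserved pairs are safely non-interacting:
   uniformly random pairs, compartment-disjoint pairs (molecules that never
   share a subcellular compartment cannot physically meet), and pairs far
   apart in the prior interaction network.

## Pipeline stages and key choices

**Dataset splitting.** Labelled pairs are split 9:1 into train/test,
independently re-drawn per repeat (3 repeats by default) and stratified by
class so both partitions stay balanced. Stratification is a design choice:
plain mixing would keep the balance only approximately, and an exactly
balanced test set makes the six confusion metrics comparable across repeats.

**Similarity graphs from training data only.** Association sets for the
Jaccard graphs are computed from the training interactions of the current
repeat. Using all interactions would let a held-out pair influence the
similarity structure it is later judged against; test information is kept
out of every training artifact (similarity graphs, walks, the feature
scaler). A `similarity.training_only=False` flag reproduces the full-data
variant for comparison. Edge rules are strict inequalities: Jaccard > 0.5
(lncRNA) and > 0 (protein); e-value < 1e-3 (lncRNA) and < 1e-2 (protein).
Asymmetric BLAST hits are resolved by the "either orientation passes" rule
(an undirected edge needs a symmetric criterion; the max-stringency
alternative is the `orientation="both"` flag). Alignment edge weights are
−log10(e-value) capped at 300 — walks are weight-agnostic, so weights are
informational only, and the cap keeps an e-value of exactly 0 finite.
The two Jaccard thresholds differ because protein association sets (many
lncRNA partners each) overlap almost surely, while lncRNA sets are sparse.

**Network assembly.** Interaction edges join L↔P only; similarity edges join
same-type nodes only, which makes edge-kind admissibility during walks a
pure consequence of node types. Isolated nodes (e.g. endpoints that appear
only in test pairs) are retained and later receive fallback embeddings;
dropping them would silently shrink the evaluated test set. The ablation
variants are reachable from configuration alone: `KNet` (interactions only),
`KJNet` (+Jaccard), `KBNet` (+alignment), `full` (KJNet and KBNet embedded
independently, vectors spliced).

**Walks.** Both schemes (`LPLPL`, `LLPPLL`) run on every network and their
corpora are concatenated per network before training; the two printed
schemes are not paired with specific networks, so symmetric treatment is the
neutral choice. Schemes cycle (position *i* uses type *i* mod (len−1)),
which requires the first and last types to match — both defaults satisfy
this. On `LLPPLL`, the L→L and P→P steps can only traverse similarity edges
and the L→P/P→L steps only interaction edges; on a network without
similarity edges the scheme dead-ends immediately and contributes nothing,
which is the intended degenerate behaviour for `KNet`. Dead-ended walks are
truncated and kept when at least 2 nodes long (skip-gram needs one context
pair), otherwise discarded and counted in the log. Defaults: 10 walks per
start node, length 80 — common practice for metapath walk corpora, exposed
as `walk.num_walks` / `walk.length`.

**Embeddings.** The skip-gram-with-negative-sampling trainer is implemented
in-package as a numba-compiled word2vec-style SGD kernel: unigram^0.75
negative-sampling distribution (5 negatives per update), stochastically
reduced context windows (a pair at offset *d* enters an epoch with
probability (window−d+1)/window), learning rate decaying linearly from 0.025
to 1e-4, input vectors initialized uniformly in ±0.5/dim, context vectors at
zero. It is single-threaded and fully seeded, so training is bit-for-bit
reproducible on one platform. Defaults: dimension 64 per network, window 5,
5 epochs. Nodes absent from every walk get the zero vector (logged); a node
missing from one of the two networks contributes a zero half to its spliced
128-dim vector. Pair features are [lncRNA ‖ protein], 256-dim at defaults.

**Classifier and evaluation.** An RBF-kernel SVM (C=1, gamma="scale" — no
hyperparameters are prescribed for this stage, and the library defaults are
robust at these feature scales; a grid-search helper exists but is off by
default) on features standardized with training statistics only. ROC uses
continuous decision scores, sweeping all thresholds with ties grouped; AUC
is the trapezoidal integral, identical to the normalized Mann–Whitney U
statistic (asserted against an exhaustive pairwise oracle in the tests).
Metrics with a zero denominator are reported as `None` and flagged rather
than zeroed, so degenerate predictors stay visible; MCC with a zero
denominator is 0 by convention, also flagged.

**Negative sampling.** All strategies return exactly `count` pairs (equal to
the positive count by default, keeping classes balanced), disjoint from the
positives, deterministically per seed. Distances are measured on the
training-positives-only bipartite graph — measuring on all positives would
leak test labels — and candidate sets additionally exclude *all* known
positives, because a held-out positive can sit at an eligible distance in
the training graph. In a bipartite graph every finite L–P distance is odd;
unreachable pairs qualify only under the explicit `distance_inf` strategy,
since the bounded variants imply finite distance. Negatives are re-sampled
per repeat by default (`negatives.resample_per_repeat=False` fixes one set),
so each repeat is a fully independent experiment.

## The synthetic benchmark

`synthetic_data.generate_planted_network` draws a planted-block bipartite
network: each molecule gets one of `k_blocks` latent blocks; an interaction
(l, p) is Bernoulli(`p_within`) when the blocks match and
Bernoulli(`p_between`) otherwise. Similarity tables are emitted as
alignment-style hits present within blocks with probability 1−`sim_noise`
and across blocks with probability `sim_noise`, with e-values log-uniform in
[1e-50, 1e-5] so present hits pass the pipeline's cutoffs. Each block is one
compartment in the localization table, giving the subcellular strategy a
consistent ground truth. Benchmark defaults are 150 lncRNAs × 30 proteins,
3 blocks, `p_within`=0.6, `p_between`=0.02, `sim_noise`=0.05 — dense enough
that Jaccard similarities are informative, sparse enough that cross-block
edges exist, and desk-scale so the full pipeline runs in seconds per repeat.
`generate_sequences` adds per-block ancestor sequences with point-mutated
copies, and `toy_alignment_hits` is a Hamming-identity scorer (synthetic, not
an aligner) mapping excess identity over the random baseline to a pseudo
e-value, so the alignment ingestion path can be exercised without shelling
out to BLAST.

What the generator does *not* emulate: the heavy-tailed degree distribution
of real interaction databases, hub proteins with thousands of partners,
correlated noise between sequence similarity and interaction status, or
multi-compartment localization. Passing tests therefore demonstrate that the
implementation recovers planted modular structure without leaking test
information — not that real-data accuracy will match.

## Numerical and procedural details

* All randomness flows through seeded `numpy` generators; stage seeds are
  derived from one base seed via `SeedSequence` spawn keys (kept < 2³¹), so
  a single `--seed` reproduces every artifact byte-for-byte.
* Iteration orders are sorted everywhere a set feeds a random draw or a
  serialization, making outputs independent of hash ordering.
* Ties in BLAST HSP collapse: the first minimum e-value line wins.
* Jaccard of two empty sets is defined as 0 (avoids 0/0; such nodes gain no
  edges, the conservative choice).
* Embedding tables serialize with 6 significant digits under a `dim=` header;
  round-trips are exact to that precision.

## Problem sizes used by the test suite and acceptance script

Unit tests run on fixtures of 10–50 molecules. The end-to-end recovery
checks use the benchmark defaults (150×30, ~950 positives): five seeds for
the structural-recovery experiment and three repeats elsewhere, sizes chosen
to keep the whole suite and the acceptance script in the minutes range on a
single CPU while leaving the planted-structure signal comfortably above the
recovery thresholds.

## Known limitations

* The skip-gram trainer is plain SGNS over node-id tokens; the type-aware
  heterogeneous-softmax variant is not implemented (a config flag is
  reserved).
* `cross_repeat_evaluate` re-embeds networks per repeat; on large networks
  this dominates runtime and could be parallelized across repeats.
* The alignment path consumes BLAST tabular output; the package never runs
  BLAST itself, and program choice/parameters for nucleotide vs protein
  searches are the caller's responsibility.
* Bit-for-bit reproducibility is per-platform; across BLAS/compiler
  versions, embedding floats may differ in the last units of precision.
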