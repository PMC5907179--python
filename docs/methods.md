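# Methods

## Model

The scorer operates on a tripartite graph G(D, T, R, E) with disease,
target and ncRNA node classes and edges only between adjacent layers,
held as two binary adjacency matrices `A_DT` (m×n) and `A_TR` (n×p).
Associations are scored by two-hop resource allocation within each
bipartite layer — entities that share a neighbour receive weight
inversely proportional to that neighbour's degree — with each layer's
weight matrix multiplied elementwise by a sequence-similarity kernel:

    W_T = K_target ∘ (A_DT^T diag(1/deg_D) A_DT)
    W_R = K_rna    ∘ (A_TR^T diag(1/deg'_T) A_TR)
    W_C = W_T (A_TR W_R),      P = A_DT W_C

`deg_D` are disease degrees in the disease–target layer. For the layer-2
denominator two readings are defensible (a target has a degree in each
layer); the default uses the target's degree *within the target–ncRNA
layer*, parallel to layer 1 where the denominator is also the degree
within the layer being projected. `layer2_degree="dt_network"` selects
the other reading. Terms with zero degree are skipped via masked
division — such neighbours have no incident edges, so their numerators
are zero anyway and no 0/0 arises.

No row normalization is applied to `W_C` or `P`; scores are an ordering
contract within a disease row only, and ranked outputs are produced per
disease.

## Features and kernels

Sequences are featurized as l-gram spectra: counts of all contiguous
length-l substrings, overlaps included. The vocabulary is the set of
*observed* l-mers (sorted lexicographically), not the full |Σ|^l
enumeration — the kernels are identical either way and memory stays
bounded for the 20-letter protein alphabet at l=4. Targets and ncRNAs
are featurized and standardized separately; their features never mix.
Records shorter than l yield all-zero rows rather than errors, since
real ncRNA/target length distributions are extremely heterogeneous.

Counts are standardized per column, x' = (x − x̄)/σ, using the
*population* standard deviation (the formula carries no Bessel
correction; `ddof=1` is available). Zero-variance columns are zeroed,
not dropped, keeping column indices stable. Standardization statistics
are computed once on the full sequence set: cross-validation holds out
*links*, never sequences, so no information about the held-out labels
flows through the feature scaling.

The similarity kernel is RBF, `exp(−‖x_i − x_j‖²/(2σ²))` with the
bandwidth constrained to 0 < σ < 1; σ1 parameterizes the target kernel
(layer 1) and σ2 the ncRNA kernel (layer 2) by default
(`sigma_assignment="formula"` swaps them; since both bandwidths are
tuned on the same symmetric grid, the assignment only relabels axes).
Linear and polynomial kernels are provided for comparison; the
polynomial kernel defaults to the inhomogeneous form (x·y + 1)², with
the offset exposed because only "degree 2" is specified by convention.
Linear/polynomial values may be negative on standardized features and
are consumed as-is, without clipping.

A numerical property worth knowing: on *unrelated* sequences the
expected squared distance between standardized feature rows is about
twice the vocabulary size, so for protein spectra at l≥2 (vocabulary
hundreds to thousands) every off-diagonal RBF entry underflows toward
zero for any σ < 1 and the layer-1 weights degenerate to their diagonal.
Informative off-diagonal similarity then comes only from genuinely
similar sequences. The synthetic studies therefore run at l=1, where
distances stay in exp-representable range for both alphabets; with real
data, where homologous sequences produce small distances, larger l
behaves sensibly (and l ∈ {1..4} is the supported sweep).

## Evaluation protocol

All m×p disease–ncRNA pairs are instances; a pair is positive iff it is
connected through at least one target, `(A_DT A_TR)[d,r] ≥ 1` (the
all-pairs reading is required — restricting to connected pairs would
leave no negatives for an ROC). Pairs are split into k=5 folds,
stratified by label so that sparse positives spread evenly (an
unstratified mode exists; with stratification off, small networks can
produce single-class folds, which are skipped with a warning rather
than failing the run). Fold assignment, and each repeat's
re-randomization, derive deterministically from one master seed.

Link cutting removes, for every positive test pair (d, r), the
target–ncRNA edge (t, r) of every target t adjacent to both. Cutting
the TR edge (rather than the DT edge) severs the disease–ncRNA path
while preserving disease–target evidence shared with training pairs;
`cut_mode="both"` also removes the DT edges for the stricter variant.
After cutting, a label oracle confirms every positive test pair has
zero remaining paths — this is asserted in the test suite.

AUC is computed as the Mann–Whitney statistic with midrank tie
handling; ROC points come from a threshold sweep and per-fold curves
are averaged on a fixed 101-point FPR grid. Folds are scored on their
own pairs only.

Bandwidth tuning evaluates all 81 points of {0.1,…,0.9}² with fold
partitions shared across points and per-axis kernel caching (squared
distances are σ-independent and computed once). Ties break toward the
lexicographically smaller (σ1, σ2). Note the selection criterion is
*test-fold* AUC — the protocol this package implements is optimistic
model selection by construction, and the grid-search AUC should be read
as a tuned optimum, not an unbiased generalization estimate.

## Synthetic data generator

The generator emulates the structural premise the method exploits:
ncRNAs fall into clusters (default ⌈p/10⌉) whose members (a) share a
preferred target subset — edge odds to preferred targets are multiplied
by exp(signal) — and (b) descend from a common ancestor sequence with
per-position substitution probability exp(−signal). At signal = 0 both
couplings vanish and edges/sequences are fully i.i.d. Sequence
similarity thus correlates with shared-target structure exactly when
signal > 0, which is what lets the kernel-weighted propagation recover
link-cut held-out associations. Defaults: sequence lengths uniform in
100–300, targets over the 20-letter amino-acid alphabet, ncRNAs over
ACGU, Bernoulli edge sampling at the configured densities, with an
exact-edge-count mode (uniform subset of cells) used for degree-
statistic fixtures where E must be fixed. signal = 4 is the "strongly
clustered" regime used in the demonstrations: ~2% within-cluster
divergence and preferred-edge probability ≈ 0.74 against a 5–6%
background.

What the generator does *not* emulate: heavy-tailed (power-law-like)
degree distributions, realistic disease co-morbidity structure,
biological sequence composition (codon bias, conserved motifs), or
length–degree correlations. Passing tests therefore show the pipeline
is correct and that it recovers the planted similarity-topology
coupling; they do not certify performance on curated interaction
databases.

## Numerical and design choices

- All matrices are dense float64; at the intended scales (hundreds of
  nodes, vocabulary ≤ ~10⁴) nothing requires sparsity.
- Kernel matrices are explicitly symmetrized ((K+K^T)/2) and the RBF
  diagonal pinned to exactly 1 to absorb floating-point asymmetry.
- Identifier order is order of first appearance in the supplied lists;
  every matrix is indexed consistently by those orders.
- Interaction files are TSV with an optional single header line,
  detected by its tokens not being known identifiers; an unknown
  identifier anywhere else is an error naming it, and a network entity
  without a sequence is rejected at load time (the method needs
  features for every node).
- RNG: a single master seed; per-repeat and per-purpose substreams are
  derived through `numpy.random.default_rng([seed, tag])`, so repeats
  are independent but the whole run reproduces bit-identically.

## Study sizes

The bundled demonstrations and the acceptance script use networks of
roughly 50–80 diseases, 25–40 targets and 30–40 ncRNAs (2 000–2 400
pairs), 100 random oracle instances with dimensions ≤ 7, 1 000 random
score/label vectors for the AUC estimator check, and 1–3 CV repeats.
These sizes give stable statistics (null AUC within ±0.01 of 0.5 across
seeds) while keeping every script in the seconds-to-minutes range.

## Known limitations

- The grid search replicates optimistic test-fold selection (see
  above); nested CV is the honest alternative and can be composed from
  the API but is not the built-in protocol.
- Scores are not calibrated probabilities and are not comparable across
  diseases with different degrees.
- Entities absent from both edge lists still receive kernel rows; they
  contribute nothing to propagation but do affect standardization
  statistics.
- The RBF underflow regime described above means that with many
  mutually unrelated sequences and large vocabularies the method
  degrades toward kernel-free resource allocation restricted to the
  diagonal; this is a property of the model, not a bug.
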