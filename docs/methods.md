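# Methods

## The encoding

A nucleotide sequence s of length l is re-alphabeted three times, once
per physicochemical axis: ring structure (A,G → R; C,T → Y), functional
group (A,C → M; G,T → K) and hydrogen bonding (C,G → S; A,T → W). Each
binary string drives a one-dimensional chaos game on the integer cells
1..2^k. The walker starts at the midpoint ind_0 = 2^(k-1) and, for each
symbol, moves halfway toward one endpoint with ceiling rounding:

    ind_j = ceil((ind_{j-1} + a) / 2),   a = 0 for the low symbol
                                         a = 2^k for the high symbol.

In shifted coordinates x = ind − 1 this is x' = (x >> 1) | (bit << (k−1)):
each step shifts the history down one bit and writes the new symbol into
the most significant position. After k steps the start value is fully
shifted out, so the cell is a bijective function of the last k symbols
and the count vector is a binary k-mer spectrum — each cell aggregating
the 2^k nucleotide k-mers that share one binary image. Three axes give
3·2^k features against the 4^k of the classical spectrum.

The endpoint pair {0, 2^k} is the only choice under which the recurrence
enumerates binary k-mers; with any smaller high endpoint the walk cannot
reach the upper cells, and the midpoint start only makes sense on the
interval [0, 2^k]. The implementation fixes the high endpoint at 2^k
accordingly.

Bit order: the most recent symbol is the most significant bit, so the
window character at 0-based offset p carries weight 2^p. This is checked
two independent ways in the tests — an exhaustive enumeration of all
walks at small k, and a sliding-window counter (`brute_force_binary_
kmer_counts`) that never touches the walk code.

The classical 4^k baseline (`encode_fcgr`) uses the identical recurrence
with 2-bit digits (A=0, C=1, G=2, T=3), so digit significance corresponds
to window position exactly as in the binary case. `group_collapse` maps
each quaternary cell to its three binary images digit-wise and sums; by
construction `group_collapse(encode_fcgr(s, k))` equals
`encode_pcmer(s, k)` in `kmer_only` mode, and that equality is enforced
as a test rather than assumed.

## Counting modes and degenerate input

- `all_positions` (default): a count is deposited at every position,
  including the first k−1 positions where the cell still carries bits of
  the midpoint start. This matches the published flowchart of the
  procedure and is what the classification pipeline uses. Each vector
  sums to the number of counted positions (= l on a clean sequence).
- `kmer_only`: counts start once a full k-window is in scope; vectors
  sum to l − k + 1. This mode has exact k-mer semantics and is required
  by the collapse relation and the counting oracle.

Characters outside A/C/G/T (IUPAC ambiguity codes, stray symbols) are
preserved at I/O time and handled at encoding time: the sequence is split
at each such character and the walk restarts from the midpoint, exactly
as a k-mer counter drops windows spanning an N. Skipping the character
without resetting would silently assign counts to corrupted k-mers and is
deliberately not offered. Empty sequences and k outside [1, 24] (PC-mer)
or [1, 12] (4-letter baseline) raise errors; the caps keep the dense
vectors within ordinary memory.

Profiles are raw counts by default; frequency normalization (divide by
positions counted) is available but off, since counts feed the
classifiers directly and the synthetic reads have uniform length. Mixed
normalization states are rejected at comparison time.

## Comparison pipeline

Dissimilarity between two profiles is the Manhattan distance over all
3·2^k cells. A labeled distance matrix is scored by leave-one-out
retrieval AUC: for each query, all other sequences are ranked by
ascending distance, same-label pairs are the positives, the ROC AUC of
that ranking is computed with midrank tie handling, and the unweighted
mean over queries is reported. Queries whose class has no other member
are excluded with a warning. This construction depends only on the
ordering of distances, so it is invariant under monotone transforms — a
property test. Agreement between two distance matrices is the Pearson
correlation over strict upper-triangle entries; a zero-variance triangle
is flagged as undefined rather than returned as NaN.

No alignment-based reference comparator is included: correlation tests
use the synthetic generator's known substitution rates as ground truth,
which avoids importing an arbitrary scoring-parameter choice.

## Classification pipeline

Features are the concatenated profiles in fixed block order (ring
structure, functional group, hydrogen bonding). Eight classifier
configurations are provided with these fixed settings: logistic
regression (L2, one-vs-rest, tol 1e-4, C=1), decision tree (Gini),
Gaussian naive Bayes, LDA, MLP (one 100-neuron ReLU layer, Adam, alpha
1e-4, learning rate 1e-3, 200 epochs), linear SVC (L2), and nearest
centroid with class means (euclidean) or class medians (manhattan).
Everything unnamed stays at the scikit-learn defaults, with one
exception: logistic regression's `max_iter` is raised to 1000 because
lbfgs on raw count features reliably needs more than the default 100
iterations to reach tol 1e-4; the fitted optimum is unchanged, only
actually reached.

Evaluation is stratified k-fold cross-validation (default 10 folds) with
a user-set seed controlling both fold assignment and any stochastic
fitting. Metrics — accuracy, precision, recall, F1 — are computed per
fold on held-out predictions and averaged arithmetically; macro averages
are primary (class sizes above the finest level are unbalanced in the
motivating application) with weighted averages recorded alongside. The
confusion matrix is summed over folds, so its row sums equal the class
counts. If the smallest class has fewer members than the requested
folds, the fold count is lowered to that size with a warning.

## Synthetic data: what it emulates and what it does not

Classes are order-1 Markov chains over A/C/G/T — the minimal model
giving class-distinct k-mer spectra at every k ≥ 2. Transition matrices
are drawn row-wise from Dirichlet(1,1,1,1) under a fixed seed and
optionally blended toward the uniform chain by a `divergence` knob in
[0, 1], so class separability can be dialed continuously from
well-separated (1.0, the default) to indistinguishable (0.0). Default
dataset shape is 100 sequences per class of length 500 — read-scale
sequences at a sample size where 10-fold CV keeps ≥ 2 test members per
class per fold.

Divergence series mutate a single ancestor at a ladder of substitution
rates (each substituted base drawn uniformly from the three
alternatives), with optional indels splitting an `indel_rate` evenly
between per-position deletion and insertion. Indels default to 0 so the
count-conservation identities stay exact; they are switched on only in
tests that specifically exercise length variation.

This generator emulates class-distinct composition and graded
divergence. It does not emulate sequencing-platform error profiles,
chimeras, conserved/variable region structure of real marker genes, or
taxonomic label noise — so passing tests demonstrate the correctness and
the discriminative mechanics of the encoding, not field accuracy on real
amplicon or shotgun data, which depends on those properties.

## Numerical and design choices

- Cells are 1-based in the recurrence (matching the index arithmetic)
  and serialized in cell order within each scheme block; internally the
  arrays are 0-based with cell = index + 1.
- All counts are int64; bincount over precomputed window values
  vectorizes the walk, with a short explicit loop only for the first
  k−1 positions where the midpoint start still matters.
- Ties in retrieval ranking are resolved by midrank (the ROC convention);
  an all-tied matrix scores exactly 0.5.
- Determinism: identical inputs give bit-identical profiles; fold
  assignment and generator output are pure functions of their seeds;
  stochastic learners (MLP) record their seed in the report and tests
  assert tolerance bands, not exact floats.
- The acceptance script runs the full study sizes (200 sequences × k up
  to 8 for the oracle sweep; 5 × 100 × 500 for classification; 7 rates ×
  20 replicates for divergence), chosen so the complete run finishes in
  well under a minute of compute per suite on one CPU.

## Known limitations

- The grouped encoding is not injective: sequences differing only within
  a physicochemical group at every axis position are indistinguishable
  (by design — that is the compression).
- Retrieval AUC on the 4^k baseline at read length ≪ 4^k compares sparse
  spectra; its value fluctuates more across seeds than the grouped
  profile's, which is visible in the acceptance output as a small
  PC-mer-vs-baseline AUC gap on some seeds.
- No reverse-complement canonicalization is performed; strand-mixed
  inputs should be oriented upstream.
- FASTQ quality values and compressed streams are out of scope at I/O.
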