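# Methods

## Overview

`dhlppi` couples two components: (i) a Siamese convolutional encoder
trained to hash protein sequences into N-bit binary codes such that
interacting pairs land within a small Hamming radius, and (ii) an exact
Hamming-radius search over those codes whose pre-screening stage is
built on the pigeonhole principle. The first component is a statistical
model fitted to labeled pair data; the second is deterministic
combinatorial machinery whose correctness does not depend on the model.

## The encoder

**Tokenization.** Each residue maps to a fixed integer (A→1, G→2, V→3,
I→4, L→5, F→6, P→7, Y→8, M→9, T→10, S→11, H→12, N→13, Q→14, W→15, R→16,
K→17, D→18, E→19, C→20); sequences are zero-padded to length L (default
5000) with trailing zeros and truncated head-anchored beyond L. The map
is pinned explicitly rather than derived from a corpus tokenizer so that
encoding is deterministic and framework-independent. Non-standard
residues (B, J, O, U, X, Z) map to the padding token with a warning by
default; a strict mode raises instead. Token 0 has an ordinary learned
embedding row: masking it is possible in principle but adds a special
case with no observed benefit at desk scale.

**Trunk.** An embedding layer (`embed_dim` per residue, default 128)
followed by four convolution blocks. Per block the order is
convolution → ReLU → batch normalization → pooling; batch normalization
after the activation is unconventional but is the order this
architecture specifies, and we keep it. Defaults: 64/128/256/512 kernels
of sizes 5/7/9/15, all stride 1 with "same" zero padding (keeps length
bookkeeping trivial); blocks 1–3 use non-overlapping average pooling
(window 2 by default — the window is a free parameter), block 4 uses
global average pooling. Batch statistics are exponential running
averages (momentum 0.9) frozen at inference, so encoding is
deterministic once training ends.

**Heads.** Two fully connected projections with N = 64 outputs each, no
bias, frozen at their initialization: one produces the *ontic* code
(database side), the other the *query* code (probe side). Weights are
drawn from symmetric uniform bounds ±1/√fan_in using two distinct seeds;
equal seeds are rejected at construction since they would collapse the
two roles. The trunk is literally shared storage between the two
branches (the Siamese property), so a gradient step through either
branch updates both.

**Range control and binarization.** A sigmoid maps each head output to
(0, 1); the hash code thresholds at 0.5 (inclusive: 0.5 → 1). Bit i of
the code is output neuron i, and the integer form is big-endian over
bits 0..N−1 — the convention the fragment index relies on.

## Losses

Three losses act on the *relaxed* (pre-binarization) codes; Manhattan
distance between relaxed codes converges to Hamming distance as the
components saturate.

* Discrimination: `label·max(dist − in_dist, 0) + (1 −
  label)·max(unin_dist − dist, 0)` with margins in_dist = 2,
  unin_dist = 12. This is the standard contrastive-hinge form: both
  hinges act on the same pair distance. (A literal transcription
  of the printed definition would make the non-interacting term the
  constant `max(12 − 12, 0) = 0` and the loss degenerate; the
  surrounding description — non-interacting pairs should sit at
  distance ≥ 12 — makes the hinge reading the only sensible one.)
* Hash constraint: per code `max(0.25·N − Σ(HC_i − 0.5)², 0)` — maximal
  (0.25·N) when every component sits at the threshold, zero exactly on
  binary codes.
* Bit balance: per code `(mean(HC) − 0.5)²`.

Weights λ_d = λ_h = 1, λ_b = 2/N. λ_b compensates the 1/N² scale of the
balance term; it is exposed as configurable since its derivation is not
otherwise specified. Batch reduction is the arithmetic mean over pairs.

## Training

Each labeled pair (A, B) is used twice — (query = B, ontic = A) then
roles reversed — doubling the sample count. Cross-validation splits at
the level of *undirected pairs before doubling* so a pair and its
reversal never straddle the train/test boundary (splitting after
doubling would leak: the reversed twin of a test pair could sit in
training). Ten folds realize the 9:1 ratio. The optimizer is Adam
(default lr 5·10⁻³, batch 64, 50 epochs — chosen for reliable
convergence of the scaled-down profile; the architecture source does not
specify an optimizer). All randomness flows through a single seeded
generator; training is bit-reproducible given the seed. The frozen
projections are verified unchanged by the test suite.

## Search

With threshold d, codes are split into 2d equal fragments (N must be
divisible by 2d). If hamming(a, b) ≤ d, at least d of the 2d fragments
agree exactly, so for each of the C(2d, d) d-subsets of fragment
positions a sorted table of concatenated fragment values supports
exact-match candidate retrieval with no false negatives; candidates are
then verified by exact Hamming distance. At d = 4, N = 64 this is 70
tables of 32-bit values. Design choices:

* Subsets are enumerated lexicographically. Any fixed complete
  enumeration preserves the guarantee; a fixed order makes index
  construction reproducible.
* Equal-range binary search (lower/upper bound) returns *all* ties, and
  candidates are deduplicated across tables before verification.
* Self-matches are excluded from all-against-all output by default
  (`include_self=True` restores them, e.g. for homodimer screens);
  output is directed (query, target) with an optional union
  symmetrization.
* For uniform balanced codes the expected spurious-candidate count per
  query is ≈ C(2d, d)·M/2^(N/2) — about 70·40 000/2³² ≈ 6.5·10⁻⁴ at
  M = 40 000 — which the occupancy check measures directly. Degenerate
  databases (many duplicated codes) make verification O(M) per query;
  no cap is imposed.

## Evaluation

Precision, recall (= sensitivity), F1, specificity, accuracy and MCC
from TP/FP/FN/TN over the labeled pairs only. Any statistic with a zero
denominator is reported as 0 (including MCC). Cross-validated figures
are averaged per fold; reports round to 3 decimals.

## Synthetic data

Two generators provide ground truth without external data.

* **Planted-neighbor code databases**: M uniform N-bit codes plus clones
  made by flipping exactly k distinct bits of a random base code, so
  every planted pair has a known exact distance. The brute-force linear
  scan over these codes is the oracle for the indexed search.
* **Motif-family interactomes**: proteins are split evenly across
  `n_motif_families` families; each carries its family's motif (a fixed
  random `motif_len`-mer) at a uniform position in an otherwise
  i.i.d.-background sequence. Within-family pairs interact with
  probability `p_interact_within_family`; cross-family pairs are
  negatives, subsampled to balance the classes.

Desk defaults (200 proteins, length 200, 4 families, p = 0.25, 300
pairs per class, motif length 20 in the generator default / 30 in the
end-to-end checks) emulate a small benchmark interactome in which the
interaction determinant is a shared sequence motif of roughly
binding-domain scale. Two properties matter and are deliberate:

* the positive-pair graph must be dense enough per family (here ~75
  edges over 50 members) to be connected — the contrastive loss only
  pulls *sampled* pairs together, and family-consistent codes emerge by
  transitivity through shared partners; with sparse positives the model
  memorizes disconnected pair clusters and held-out pairs fail;
* the motif must be long enough to dominate the background signal that
  survives global average pooling.

What this generator does **not** emulate: real amino-acid composition
(background is uniform unless `background_freqs` is given), domain
architecture, paralogy, promiscuous hubs, or interactions driven by
structure rather than a shared linear motif. Passing end-to-end tests
therefore show that the architecture, losses, training loop and search
stack work as designed on a recoverable signal — not that the model
attains any particular accuracy on real interactomes.

## Scaled-down profile

The full-scale profile (L = 5000, embed 128, widths 64/128/256/512)
is impractical for routine tests, so `EncoderConfig.desk_profile()`
provides L = 256, embed 16, widths 16/32/64/160, pool window 4, same
kernel sizes and N. The final width is chosen **above 2N**: the trunk
feature vector must satisfy sign/margin constraints through *both*
frozen projections (~2N half-spaces), which is generically infeasible
below 2N dimensions — at width 64 the desk model cannot fit its
training set at all, while at width 160 it does. The full-scale
profile's 512 channels already satisfy this.

End-to-end checks use the desk profile with embed 32 and 60 epochs on
the 200-protein interactome; these problem sizes keep a full
train/evaluate cycle to a few CPU-minutes.

## Numerical notes

* Sign convention at exact ties: `sign(0) = 0` in the discrimination
  gradient; binarization threshold is inclusive at 0.5.
* The hinge and hash-constraint maxima make losses piecewise smooth;
  gradients at the kinks take the inactive branch (zero).
* Batch-norm epsilon 10⁻⁵; Adam defaults β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸.
* Hash codes are stored as uint64; Hamming distance is popcount of XOR.
  Empty databases, empty query sets and zero-epoch training are all
  defined no-ops.

## Known limitations

* Hamming verification after pre-screening is exact, but the *learned*
  radius structure is only as good as training; there is no score
  beyond the integer distance (no ROC sweep is provided).
* The numpy training loop is CPU-bound and single-device; the
  full-scale profile trains slowly and is intended for offline use.
* Very long proteins are truncated at L; the paper-scale default
  L = 5000 covers almost all natural proteins but the truncation is
  silent apart from a warning.
* `cv_split` requires at least `cv_folds` pairs to make every fold
  non-trivial; degenerate inputs produce empty folds rather than errors.
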