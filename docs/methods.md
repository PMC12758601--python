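# Methods

This note records the scientific and numerical choices behind `scglang`:
what the pipeline computes, which knobs matter, what the synthetic data
does and does not emulate, and where the design was genuinely open.

## Segmentation

A chain is represented as an ordered list of residues, each carrying a
one-letter amino-acid code (`X` for nonstandard residues), one of the eight
DSSP secondary-structure classes, and the six numeric DSSP fields ACC, TCO,
KAPPA, ALPHA, PHI, PSI. DSSP's blank (coil) class is stored as `C`;
lower-case letters in the DSSP amino-acid column (half-cystines) map to
`C`ysteine. All intervals are 0-based half-open, so fragments of a chain
tile `[0, L)` with no ambiguity.

Chain-break rows (`!` in the DSSP table) emit no residue but are recorded
as break positions; every segmenter — including the random ablation
segmenters — starts a new fragment at a break, since a fragment is meant to
be a spatially contiguous unit. Singleton runs are kept as fragments of
length 1; no merging is performed.

The three ablation segmenters draw from one seeded generator per chain,
derived from `(global seed, CRC32(chain_id))`, so corpus-level results do
not depend on iteration order. The uniform-random segmenter draws one
length `L ~ U{3..60}` per chain and emits the remainder as a final shorter
fragment; the dynamic-random segmenter draws i.i.d. lengths until the chain
is exhausted; the length-shuffling segmenter permutes the SS-run lengths
within each break-delimited block (the permutation cannot cross a break
without splitting a length, which would change the length multiset).

## Fragment features (74-d)

* **Composition (20).** Fractions over the standard amino acids; `X`
  residues are excluded from numerator and denominator, and an all-`X`
  fragment yields the zero vector rather than an error.
* **Evolutionary conservation (40).** PSSM log-odds (the first 20-column
  block of a PSI-BLAST ascii PSSM) pass through a logistic sigmoid; HHM
  match-emission scores `s` become probabilities `2^(-s/1000)` with `*`
  mapped to 0. Column means over the fragment's rows give two 20-d vectors,
  PSSM first. Both matrices are reordered into a single canonical
  alphabetical amino-acid column order at read time. When profiles are
  unavailable the block is zero-imputed and flagged, so a structure-only
  vocabulary can still be trained.
* **Geometry (14).** An 8-d one-hot of the fragment's SS class (ablation
  fragments use the majority class, ties broken by the fixed alphabet order
  H,B,E,G,I,T,S,C), then fragment means of: relative accessibility
  (ACC divided by the residue's theoretical maximum ASA, Tien et al. 2013
  values, clipped to [0,1]; the mean of the twenty maxima is used for `X`),
  TCO unchanged, and KAPPA/ALPHA/PHI/PSI divided by 180°. The DSSP
  missing-angle sentinel 360.0 is kept verbatim at parse time and mapped to
  0 *before* averaging, centralizing imputation in one place.

The six DSSP fields were chosen as the only natural six-tuple of numeric
per-residue columns in classic DSSP output covering accessibility and
torsion-angle character. Feature vectors are z-scored per dimension before
vocabulary training; the fitted mean/scale are stored in the vocabulary
manifest and reapplied at tokenization, because the three blocks live on
heterogeneous scales and an unscaled Euclidean quantizer would be dominated
by whichever block happens to have the largest variance. Zero-variance
dimensions keep scale 1 to avoid division blow-ups.

## Vocabulary training

The VQ-VAE minimizes `L = L_recons + L_codebook + β·L_commit` with
β = 0.25 and K = 1024 by default (both configurable; desk-scale experiments
here use smaller K). Quantization is nearest-Euclidean-row with a
lowest-index tie-break for determinism. The codebook is updated by the
gradient of `||sg[z_e] − z_q||²` only, the encoder additionally by the
commitment term and (via the straight-through estimator) by the
reconstruction term; these routing contracts are asserted by tests against
the package's own reverse-mode autodiff engine and cross-checked by finite
differences.

Reconstruction loss: a KL divergence between distribution views of input
and reconstruction is provided (both vectors pass through a softmax over
the 74 standardized dimensions; the reconstruction enters as logits). A
74-d fragment descriptor is not intrinsically a probability distribution,
so the softmax view is one defensible reading rather than the only one; a
plain mean-squared-error option exists and is the default used in the
recovery experiments, where reconstruction fidelity in feature space is
what the test measures.

**Encoder.** The attention encoder linearly projects the 74-d input into
T = 3 slot tokens of width 64 (one slot per feature block conceptually),
applies 4-head self-attention over the slots with a residual connection,
mean-pools, and projects to the code dimension d = 64. The MLP ablation has
two hidden ReLU layers of width 64. The decoder is `d → 64 → 74` with one
ReLU. These sizes are deliberately small: all experiments run on one CPU
core in seconds to minutes.

**Initialization and collapse control.** Training begins with a short
reconstruction-only warmup (3 epochs by default) during which no
quantization happens; the codebook is then initialized by k-means over the
corpus latents (subsampled above 8192 points). Initializing codes from a
*randomly initialized* encoder's latents was tried first and rejected:
distinct feature-space clusters can land on top of each other in an
untrained latent space, and codes seeded there stay entangled for the rest
of training. During training (but not in the final 20% of epochs, so the
codebook can settle), codes assigned fewer than 10% of their expected share
of latents are re-seeded at latents sampled with probability proportional
to squared quantization error — the standard dead-code restart, targeted at
clusters currently sharing a code. Optimization uses Adam at 1e-3, batch
size 256; every source of randomness (parameter init, shuffling, k-means
restarts) derives from the single config seed, making retraining bitwise
reproducible.

The k-means vocabulary baseline clusters the standardized 74-d features
directly (no encoder) with 30 restarts; fewer restarts occasionally return
a split/merge local optimum even on well-separated data. Tokenization
against either vocabulary goes through the same nearest-row quantizer.

## Serialization

Tokenization freezes the trained encoder and codebook; the vocabulary
directory carries a manifest hash that is stamped into every sentence, and
corpus files record it, so corpus/vocabulary mismatches are detected on
read (token ids outside `[0, K)` likewise). Corpora are plain text with a
single header line; sentences longer than 512 tokens are truncated at
corpus-write time only, leaving in-memory sentences intact.

## Synthetic data

The chain generator emulates: PDB-like SS class frequencies under a
no-immediate-repeat Markov law; geometric run lengths with class-specific
means (helix ≈ 10 residues, bridge ≈ 1); class-conditional Gaussian DSSP
fields centred on textbook values (helix φ/ψ ≈ −63/−42°, strand
≈ −118/+134°); termini carrying the 360° sentinel; occasional chain breaks;
and profile matrices that favour the observed residue. All numeric fields
are quantized to on-disk print precision before being stored, so written
DSSP/PSSM/HHM files re-read through the package parsers reproduce the
in-memory objects exactly.

It does **not** emulate tertiary packing, hydrogen-bond structure, sequence
redundancy, profile-structure correlations beyond residue identity, or
real DSSP quirks beyond the classic dialect. Passing tests therefore show
that the pipeline's bookkeeping, numerics and learning dynamics are
correct under realistic marginal statistics — not that the learned
vocabulary is biologically meaningful on real proteins.

The mixture fixture for vocabulary-recovery tests draws component centres
that are themselves valid feature vectors (Dirichlet composition, uniform
conservation, a one-hot class, uniform geometry), adds isotropic noise with
per-coordinate sd equal to (minimum centre distance)/separation (default
separation 10), and projects samples back onto the feature invariants.
Before freezing the recovery thresholds, the geometry was verified
directly: nearest-true-centre assignment is error-free at this separation,
so recovery failures indicate optimizer problems, not ambiguous data.

## Problem sizes and runtime

Desk-scale defaults keep the full test suite under a minute and the
acceptance script under half a minute on one CPU core: recovery experiments
use 4000 fragments in 74-d with K = 16 (30 epochs) and K = 64 (15 epochs,
3 seeds per encoder), compression statistics use 200 generated chains, and
the end-to-end determinism check uses 6 chains with K = 12.

## Known limitations

* Only classic fixed-width DSSP output is parsed; the mmCIF dialect is not.
* Residues unresolved in the crystal simply never appear; no gap handling
  beyond chain breaks.
* The KL reconstruction view of non-distributional features is a modelling
  convention (see above); results quoted here use the MSE form.
* The attention encoder's slot-projection design is this package's own
  construction; other ways of feeding a single 74-d vector to attention are
  plausible.
* No EMA or Gumbel-softmax quantizers, no residual/multi-codebook VQ, and
  no language-model training on the token corpora.
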