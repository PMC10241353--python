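# Methods

This note records the modelling choices behind `bgclm`, the parameters that
matter, what the synthetic data does and does not emulate, and the numerical
conventions a maintainer should know.

## Representation and objective

A BGC is an ordered chain of Pfam accessions with a product-class token
prepended, drawn from one joint vocabulary (Pfam tokens, class tokens,
specials MASK/PAD/UNK occupying disjoint contiguous id ranges). The training
objective is masked-token reconstruction: per sequence, each non-pad position
is independently selected for supervision with probability 0.15
(Bernoulli per position, not exact-count sampling — the standard BERT
convention; the selection probability is configurable). Selected positions
are replaced by MASK with probability 0.8, by a uniformly drawn **Pfam**
token with probability 0.1 (never a class or special token), or left
unchanged with probability 0.1. The prepended class token is corrupted and
reconstructed like any other token through the single joint softmax — there
is no separate class head — which is what makes zero-shot class prediction a
side effect of pretraining. The loss is the mean cross entropy over
supervised positions.

## Architecture

Embedding lookup (dimension `E`) → linear projection to hidden width `H` →
`n` residual blocks → linear decoder to the vocabulary. Block `b` uses
dilation `2^(b mod (log2(d_max)+1))`, cycling 1, 2, 4, …, `d_max`; each block
is LayerNorm → GELU → 1×1 projection `H→H/2` → dilated kernel-3 convolution
(same-length zero padding) → GELU → 1×1 projection `H/2→H` → residual add.
Convolutions are unmasked (bidirectional): the objective is autoencoding.
With the published hyperparameters (`E=1280, H=256, n=32, d_max=128`, kernel
3) and a vocabulary of 19,550 Pfams + 55 classes + 3 specials the closed-form
count is 34,168,216 parameters, anchoring the block design (one
normalization per block, half-width bottleneck) at ≈34 M. The exact internal
ordering of the reference encoder is not fully specified anywhere we could
rely on; this parameter-count anchor is the design's external check.

PAD rows of the embedding are zeroed and hidden states at pad positions are
re-zeroed after the embedding and after every block, so a sequence's logits
are independent of how much padding its batch carries (tested). MASK, PAD,
class and UNK embedding rows are always trainable, even in the
frozen-embedding regime, because they have no pretrained counterpart; only
Pfam rows freeze.

The network is implemented in numpy with hand-written backward passes and an
Adam optimizer; gradients are pinned by central-finite-difference tests at
float64. This keeps the package dependency-light and fully deterministic on
CPU. The trade-off is scale: desk-scale models (hidden ≤ 128, ≤ 16 layers)
train in minutes, but the package makes no claim of GPU-scale training
parity.

## Embeddings

Three regimes: pretrained-finetuned, pretrained-frozen, random-finetuned.
Pretrained tables are mean-pooled per-residue protein-language-model vectors
supplied as a `token<TAB>v1..v_d` TSV; producing them is outside this
package. Random initialization is zero-mean Gaussian with σ = 0.02 (common
transformer practice; configurable — no authoritative value exists).

## Training loop

Adam with learning rate 1e-4 and batch 64 are the full-scale defaults. Epoch
shuffling and corruption draws are reseeded `seed+epoch`, and validation
corruption uses one fixed seed across epochs so per-epoch validation losses
are comparable; the epoch minimizing validation loss is returned. Desk-scale
runs (hidden 64, 8 layers, dilation cycle to 16, embedding 64) use learning
rate 1e-3, chosen a priori as standard for small models; 1e-4 merely
converges more slowly at this scale. Divergence (non-finite loss) aborts with
a diagnostic rather than silently continuing.

Supervised fine-tuning follows the shuffle-into-genome procedure: at each
epoch the positive (BGC) and negative chains are permuted (seed+epoch),
concatenated into one labelled track, cut into chunks of 256 domains
(configurable; no authoritative value), and a per-domain logistic head on the
final hidden states is trained with binary cross-entropy, jointly with the
encoder by default (a flag freezes it — whether the reference procedure did
is unknown). No class token is inserted into the concatenated genome, since
negatives have none. The epoch with the highest validation domain AUROC is
returned.

## Detection scoring

Windows are stride-1 spans of `w = 64` domains over the genome's domain
track, ignoring gene boundaries; a track shorter than `w` yields one
whole-track window. Start entropy is computed on the class-token slice of
the softmax, renormalized (a full-vocabulary variant is available behind
`start_entropy_slice="full"`; the slice is the default because the MASK
occupies the class-token slot). All entropies and NLLs are in nats.

The reduction of each domain's ≤ 64 × 3 values to one score is an unweighted
arithmetic mean of the raw nat-scale values, negated so higher = more
BGC-like. The value set is fixed by the method; the reduction itself is a
design choice (weights configurable) — the unweighted mean is the simplest
defensible default and is what the acceptance experiments validate. Edge
domains average over their available windows; positions where no window
begins (the trailing `w−1`) have no start score and are excluded from start
AUROC. AUROC is the Mann–Whitney probability with ties at 1/2 and average
precision the step-wise precision sum over ranked positives (both via
scikit-learn, cross-checked in tests against O(n²) pair counting and an
explicit curve walk).

## Corpus splitting

Because near-identical clusters recur across genomes, splits must not leak
substrings. Records are grouped into connected components of the undirected
strict-substring relation (contiguous domain-run containment, class tokens
excluded); components are shuffled by the split seed and greedily assigned
to the split with the largest remaining deficit. This guarantees the
cross-split property deterministically at the cost of split sizes only
approximating the fractions when components are large. Records overlapping a
holdout corpus in either containment direction are removed from train and
validation (not test). Record ids must be unique; duplicates are an error.

## Annotation pipeline

Genome → ORF prediction (prodigal) → per-gene profile-HMM search (hmmsearch)
→ domtblout parsing (accession version suffixes stripped, independent
E-value ≤ 1e-5 by default; no authoritative threshold exists) → per-gene
greedy overlap resolution → ordering by (gene rank, envelope start). The
greedy resolver keeps hits in descending bitscore (ties: smaller start, then
lexicographic accession) and drops any hit sharing ≥ 1 residue with a kept
hit; it is a documented, injectable stand-in for an external resolver and is
not claimed to replicate any specific one. Gene rank follows the ORF
caller's output order, not coordinates, to respect contig boundaries.
Coordinates are 1-based inclusive internally (HMMER convention); exported
interval tracks are 0-based half-open and say so in their headers. Missing
executables raise a capability error; a precomputed domtblout bypasses both
tools and is contract-tested to match the manual parse→resolve→order chain.

## Synthetic data

The generator emulates exactly one property of real corpora: product classes
differ in Pfam composition. Each class owns a disjoint signature set; all
classes share a background set; BGC domains are i.i.d. draws (signature with
probability `signature_purity`, else background). Genomes are uniform
background chains with non-overlapping implanted BGCs placed by a uniform
stars-and-bars gap split, labelled per domain and per start. Defaults — 200
Pfams, 5 classes, 20 signature + 60 background domains, BGC lengths 16–48
domains (a few dozen genes, typical of real clusters), genomes of 500
domains with 3 implants, purity 0.8 — are the package's study conditions and
are fixed once.

What this does **not** emulate: Markov or modular domain order within
clusters (an optional first-order Markov flag exists for richer tests, off
by default), realistic Pfam co-occurrence statistics, class imbalance (a
skew option exists), shared domains between classes, or annotation noise.
Passing the detection experiments therefore shows the windowed entropy
machinery and training loop are sound — not that real-genome AUROCs will
match; those depend on real corpora and full-scale training, which are out
of scope here.

## Desk-scale experiment sizes

The test suite's end-to-end run pretrains hidden-64 / 8-layer models on
2,000 synthetic records for 30 epochs and scores 20 genomes of 500 domains;
the examples use 600 records and 10–15 epochs. These sizes were chosen so
the full suite runs in a few minutes on one CPU core while leaving clear
margins on the acceptance thresholds (held-out class top-1 > 0.8, class ECE
< 2.5, domain AUROC > 0.8, start AUROC > 0.7).

## Numerical conventions and edge cases

* Log-softmax and entropies computed in float64 with max-subtraction;
  activations in float32.
* Entropy uses 0·ln 0 = 0 and validates its input simplex to 1e-6.
* A corruption plan with zero supervised positions yields loss 0 with a
  warning (and is skipped by the training loop).
* ECE with no supervised positions in the requested token group is an error,
  not a silent 0.
* AUROC/average precision on single-class labels raise
  `UndefinedMetricError` rather than returning a default.
* Out-of-vocabulary Pfams at inference map to UNK rather than erroring;
  training corpora under the strict vocab policy error instead.
* The vocabulary treats its size as data-derived everywhere; the reference
  sizes (19,550 Pfams, 55 classes) appear only in tests and the acceptance
  script as instantiation inputs.

## Known limitations

* numpy training is single-threaded-ish (BLAS aside) and impractical beyond
  ~10⁵ sequences or hidden widths ≫ 256.
* The fine-tuning path evaluates validation AUROC on whole tracks chunked at
  the training chunk length; domains near chunk edges see truncated context.
* Detection emits per-domain and per-start scores only; interval calling /
  merging into discrete cluster boundaries is deliberately out of scope.
* `OracleStub` (perfect predictor) uses a targets-peeking test-double
  protocol (`wants_targets`) that real models must not implement.
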