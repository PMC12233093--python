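# Methods

## Problem

Untargeted metabolomics measures tandem (MS/MS) spectra of unknown small
molecules.  Annotation assigns a structure to each spectrum by ranking a
candidate set — typically every database structure sharing the precursor's
molecular formula — and reporting where the true structure lands
(`rank@k`: the percentage of queries whose target ranks at position k or
better).

This package implements an *implicit* annotation approach: instead of
predicting a spectrum from each candidate or a fingerprint from the
spectrum, both molecules and spectra are embedded into one joint vector
space, and candidates are ranked by cosine similarity between their
embeddings and the query spectrum's embedding.

## Model

**Spectrum representation.** Peaks are normalized so the base peak has
intensity 999 (spectral-library convention), discretized into 1000 one-Da
bins (`[n, n+1)`; peaks at or above 1000 Da dropped), co-binned intensities
summed, and transformed elementwise.  The default transform is
`log10(1 + x)/3`, which maps empty bins to 0 and a lone base-peak bin to
exactly 1.  A strict variant `log10(x)/3` (empty and sub-unit bins clamped
to 0) is selectable; the default deviates from the strict form only in how
it regularizes the log at zero.  Normalization precedes binning; the order
matters because the log is taken of the summed bin.

**Spectral encoder.** A 3-layer MLP, 1000 → hidden → hidden → d, ReLU
activations.

**Molecular encoder.** The heavy-atom graph with per-atom features (atom
type one-hot over {C, N, O, S, P, F, Cl, Br, I, B, Se, Si} + other, atomic
mass, total valence, ring membership, formal charge, radical electrons,
chirality tag one-hot, degree, hydrogen count, aromaticity) and per-bond
features (bond type one-hot, ring membership, conjugation, stereo one-hot)
is processed by a stack of graph convolutions.  Each layer computes

    h_i' = ReLU(W_self h_i + (1/|N(i)|) Σ_{j∈N(i)} W_msg [h_j ; e_ij] + b)

i.e. degree-normalized neighbor aggregation with edge features concatenated
into messages, plus a residual connection from the second layer on.  Node
states are pooled by an elementwise max over atoms (max pooling, not
mean/sum), then a 2-layer MLP maps to the joint dimension d.  Embeddings
are *not* L2-normalized at the encoder output; normalization lives inside
the cosine computations so that dot-product scoring remains a meaningful
ablation.

**Discriminator and losses.** A spectrum-molecule pair is scored by
`h(z_spec, z_mol) = exp(cos(z_spec, z_mol)/τ)`.  The contrastive loss is
InfoNCE over a batch of k matched pairs, spectra as anchors:

    L_contrastive = (1/k) Σ_n −log[ h(z_spec^n, z_mol^n) / Σ_m h(z_spec^n, z_mol^m) ]

with natural logarithms.  A symmetric (molecules-as-anchors) term exists
behind a flag, default off.  The regularization loss is the mean cosine
between each spectrum and the `kaug` candidates of its target drawn that
epoch, not clamped below zero.  The total loss is
`α·L_contrastive + β·L_regularization` with (α, β) = (1.0, 0.0) for the
first 97% of epochs and (0.9, 0.1) for the final 3% (boundary at
`floor(0.97·epochs)`; for very short runs the final epoch alone is
regularized so the fine-tuning phase is never empty).  A cross-entropy-on-
dot-products variant (no cosine normalization, no temperature) is provided
for the loss ablation; it coincides with InfoNCE at τ = 1 on unit-norm
embeddings but is not invariant to rescaling individual embeddings.

**Candidates.** A local store indexes molecules by Hill formula and by
monoisotopic mass (ppm windows, default 10 ppm).  A target's candidate set
excludes the target, and is sorted by descending ECFP4 (Morgan radius 2,
2048 bits) Tanimoto similarity to the target, ties broken by id.  During
the fine-tuning phase a per-target cursor walks this sorted list `kaug`
entries per epoch, wrapping — hardest decoys first, the rest cycled in.

**Training.** Adam (lr 1e-3 default) with optional decoupled weight decay
and cosine learning-rate decay floored at 10% of the base rate, so the
late fine-tuning epochs can still move the weights.  Batches are re-shuffled
each epoch from a (seed, epoch)-derived stream; runs are deterministic
under a fixed seed and single-threaded BLAS.  Candidate embeddings are
computed with gradients on, by the same molecular encoder.  Splits are
structure-disjoint: molecules are grouped by the first (connectivity)
InChIKey block and whole groups travel to one side with all their spectra.

**Ranking.** At inference the target is injected into the scored pool, all
pool members are embedded and scored against the spectrum embedding
(cosine by default; raw dot product as ablation), and the target's rank is
pessimistic under ties: every competitor scoring ≥ the target outranks it,
so score collisions can never inflate rank@1.  `rank@k` aggregates per
query spectrum (one trial each); a per-molecule mode (best spectrum per
molecule) exists behind a flag.

## Synthetic benchmark

Real spectral libraries and database-scale candidate retrieval are outside
desk scale, so the package ships a seeded generator that reproduces the
*statistical shape* of that setting:

- **Universe.** Molecules are assembled by bonding 2–4 substructure blocks
  drawn from a grammar, under valence checks, deduplicated by InChIKey
  connectivity block.  Blocks come in isomeric groups (e.g. ethanol /
  dimethyl ether), and a family is built from one group multiset, so every
  family member shares one molecular formula while spanning both
  same-skeleton (high-Tanimoto, hard) and rearranged-skeleton
  (low-Tanimoto) decoys — matching the observation that most real
  formula-matched candidates are structurally dissimilar to the target.
  Defaults: 300 molecules, ≥10 families of ≥5 isomers.
- **Spectra.** An in-silico fragmenter cuts up to `cut_depth` (default 2)
  acyclic single bonds; every connected fragment yields a peak at its
  protonated monoisotopic mass (+1.00728 Da, positive-mode [M+H]+), with
  log-normal intensity noise (CV 0.25), per-fragment dropout (p = 0.1) and
  0–3 uniform noise peaks.  Each molecule gets 2 views (distinct condition
  seeds: same fragment masses, different noise/dropout).  Fragmentation is
  graph-combinatorial, not physical: no bond energies, rearrangements,
  ring opening, isotope envelopes or negative mode.  Ring-position isomers
  with identical fragment-mass multisets remain genuinely
  indistinguishable, which caps attainable rank@1 below 100%.
- **Candidates** are the target's formula family drawn from the universe
  itself — true formula isomers, no external database.

What passing tests on this generator demonstrate: the pipeline can learn a
structure-determined spectrum mapping from matched pairs and use it to
rank unseen structures.  What they do not demonstrate: robustness to real
fragmentation physics, instrument heterogeneity, adduct diversity, or
database-scale (10³-candidate) retrieval.

## Study sizes and defaults

The desk-scale study uses the default generator (300 molecules, 2 views,
~36 formula families, mean candidate-set size ≈ 7) and a reduced model:
joint dimension d = 64, hidden width 512, 3 GCN layers, τ = 0.04,
batch 32, kaug = 8, 50 epochs, weight decay 1e-2, cosine lr decay.  The
architecture skeleton (GCN → maxpool → MLP×2; MLP×3 spectral encoder;
cosine InfoNCE; 97%/3% schedule with β = 0.1) is fixed; width, depth,
temperature and optimizer settings were selected on the synthetic task and
are fully config-exposed.  General library defaults are hidden 256,
d = 256, dropout 0.1, τ = 0.07.

On this task the trained model reaches held-out rank@1 of roughly 36-50%
against a 10-12% random baseline (3.5-4× recovery, varying with the
dataset seed), with rank@5 above 90%; the residual rank@1 errors are
dominated by memorized training-set isomers narrowly outranking the
unseen target, a small-training-set effect (240 training molecules) that
shrinks with universe size.  A pairing-shuffled control collapses to the
random baseline, confirming the signal comes from the molecule-spectrum
correspondence and not from leakage through the generator.

Candidate regularization behaves as designed mechanically: branching the
final fine-tuning epochs with and without the candidate term (identical
first phase, continuous optimizer state) lowers the mean
spectrum-candidate cosine on every seed tested.  At this scale it costs a
few points of held-out rank@1 rather than gaining: because candidates are
drawn from the universe itself, held-out molecules appear among the
hardest candidates of training targets, and the push moves exactly those
unseen targets away from their family's spectral region.  The effect
shrinks as the candidate pool grows relative to the held-out set.

## Numerical and implementation choices

- The encoders, losses and training loop run on a compact reverse-mode
  autodiff core over float64 NumPy arrays written for this package
  (`jestr/_autodiff.py`), with gather/segment-sum/segment-max primitives
  for message passing and pooling; gradient correctness is tested against
  central finite differences.
- Cosine computations guard the norm with ε = 1e-12 inside training;
  public loss entry points reject exactly-zero embeddings.
- `log-sum-exp` is computed with a constant max shift for stability.
- Ties in candidate sorting and ranking have deterministic policies
  (ascending id; pessimistic rank).
- MGF I/O preserves peak order; MSP input is returned sorted by m/z by the
  underlying reader — immaterial downstream because binning is
  permutation-invariant.

## Known limitations

- Single-collision-energy, positive-mode, single-adduct emulation only.
- The molecular encoder's within-family resolution depends on training-set
  size; at 300 molecules it resolves families nearly perfectly (rank@5
  > 90%) but ranks the exact isomer first in only about half of held-out
  queries.
- No early stopping or validation-based model selection (fixed-epoch
  schedule by design).
- CPU-only; training the default synthetic study takes a few minutes on
  one core.
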