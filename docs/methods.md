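# Methods

This note records the scientific and numerical choices behind the package:
what the model and the synthetic data assume, which knobs matter, and where
the design was genuinely open.

## Task and model

The task is three-way classification of lung adenocarcinoma subtypes
(in-situ, minimally invasive, invasive) from three inputs per case: a 3D CT
volume in Hounsfield units, a per-lesion 3D bounding box, and a structured
clinical record. The architecture and objective are described in the
README; this note concentrates on the parts a maintainer would otherwise
have to reverse-engineer.

**Coordinate conventions.** Voxel indices are 0-based; boxes are
center+size. A crop-relative box divides both center and size by the crop
shape, treating the voxel grid as half-open, and is clamped to [0, 1];
boxes that overflow their crop are clamped rather than rejected. The crop
origin is `round(center) − shape//2`, which makes the relative center of a
lesion-centred crop exactly 0.5 up to the sub-voxel part of the center.
Out-of-volume crop regions are padded with the post-windowing floor 0
(−1000 HU), the natural value for air.

**Encoder details.** The bounding-box token occupies position 0 of the
token stack; since positions are learned, the slot choice is a convention
with no representational consequence. Token order for patches is
lexicographic over (x-block, y-block, z-block). Pooling is the mean over
the token axis of the final transformer layer, with no extra layer
normalization before the mean — so with all attention/MLP output
projections zeroed, the feature is exactly the mean of embedded-plus-
positional tokens, a property the tests pin to guard wiring regressions.
Transformer blocks are pre-norm with GELU MLPs of width 4D. Embeddings and
positional tables initialize truncated-normal (sd 0.02); linear maps use
fan-in-scaled uniform initialization.

The clinical encoder realizes "reshape ℝˡ → ℝ^{l×D}" as per-field learned
embedding rows scaled by the field values (plus a per-field bias row), and
the final reduction as flatten + linear rather than pooling, so each
clinical field keeps its identity up to the last projection.

The two CT scales use independent encoders by default; `share_cte=True`
shares the transformer stack and both projections while keeping
scale-specific positional tables (the token counts differ: 65 vs 1025 at
the reference crop sizes).

**Fusion details.** The Phase-1 output normalization is per-token layer
normalization without affine parameters; a config switch (`phase1_norm:
"l2"`) provides the plain L2 row normalization reading instead. Fusion
blocks include a feed-forward sub-block by default (`ffn: false` reproduces
the attention-only reading). Channel attention sums two sigmoid gates, so
multipliers live in (0, 2) and are exactly 1 at zero weights. Fusion
defaults are 2 layers and reduction ratio r = 1; with only three modality
channels, r = 1 is the only ratio that leaves an integer bottleneck wider
than one unit besides r = 3.

**Two pathways.** The contrastive pathway consumes L2-normalized features;
the classification pathway consumes the raw concatenated features. The
temperature is a learnable parameter initialized at log(1/0.07)
(`freeze_temperature` pins it).

**Contrastive targets.** The symmetric cross-entropy is taken against the
matching-pair diagonal (the standard CLIP reading), which is the only
shape-consistent interpretation of an N×N image–clinical similarity matrix.
A supervised variant with same-class positives (uniform target distribution
over them) is available via `contrastive_targets="class"` for
investigation; it is not the default.

**Dynamic weighting.** ω = Lc/(Lc+Lf) is recomputed every step from the
current detached loss values; no gradient flows through ω itself, which the
tests verify directly (the gradient of the total w.r.t. each term equals
its fixed mixing weight). When both terms are zero, ω falls back to 0.5 —
also the natural "initial weight" before any loss is observed. Focal loss
uses γ = 0.25 and inverse-frequency α_t normalized so a balanced cohort
gives all-ones; both are configuration values (canonical focal loss uses
γ = 2).

## Training and evaluation conventions

Adam with lr 1e-4, weight decay 1e-3 (classic L2-into-gradient form),
betas (0.9, 0.99); per-epoch exponential decay with factor 0.99; batch
size 24; 500 epochs at full scale, 30 by desk default. Flip augmentation
applies per axis with probability 0.5, training split only, and always
mirrors the box with the grid. EHR standardization statistics (population
convention, ddof = 0) and one-hot vocabularies are fitted per training fold
only, so no fold ever sees validation statistics; unseen categories at
encode time map to an all-zeros group with a logged warning.

Metrics are macro-averaged with undefined per-class values set to 0, and
AUC is one-vs-rest macro with constant scores scoring exactly 0.5. These
two conventions are forced by the degenerate all-majority baseline row the
package reproduces analytically (accuracy 71.01, macro precision
23.67 = 71.01/3, macro F1 27.68, AUC 50.00 on a 49-of-69 split). Model
selection within a fold keeps the epoch with the best validation accuracy.
Cross-validation asserts train/validation disjointness at runtime and
reports per-fold, mean ± sd and pooled-prediction metrics; published
headline numbers do not say which pooling they use, so both are emitted.

## Synthetic phantoms

The generator emulates the radiological narrative of the three subtypes
with the simplest closed-form shape family: a radially perturbed sphere,
r(θ, φ) = r₀·(1 + a·P(θ, φ)), with P a fixed low-order harmonic pattern
(random phases per case) and per-class defaults

| class | mean radius (mm) | interior intensity | spiculation a |
|---|---|---|---|
| in-situ | 4 | 0.35 (≈ −510 HU, ground-glass) | 0.00 |
| minimally invasive | 7 | 0.55 (≈ −230 HU) | 0.15 |
| invasive | 11 | 0.80 (≈ +120 HU, solid) | 0.35 |

Radii jitter uniformly ±15% around the class mean, which keeps the three
class ranges disjoint — so with zero noise a single threshold on measured
lesion size classifies perfectly, guaranteeing the learning-sanity
experiment is achievable by construction. Intensity maps to HU as
intensity·1400 − 1000, chosen so the [−1000, 400] window is exercised
across its full range; the background is uniform aerated lung at −900 HU;
Gaussian noise (default sd 0.05 in intensity units) is added everywhere.
The bounding box is the tight axis-aligned box of the lesion support;
lesions that cannot fit inside the volume with a margin are rejected with
an explicit error, never truncated.

Clinical records draw numeric fields from class-shifted normals and
categorical fields from per-class category probabilities. The default
schema — age, sex, smoking status, measured nodule diameter (correlated
with the true lesion radius), and a serum marker — exercises both encodings
and is fully overridable. No public field list exists for the reference
cohort, so this schema is an explicit stand-in, not a reconstruction.

What the phantoms deliberately do **not** model: real parenchymal texture,
vessels and airways, partial-volume effects at lesion margins, multi-lesion
cases, scanner/protocol variability, and realistic EHR missingness.
Passing tests on phantoms therefore demonstrates that the pipeline,
architecture, objective and evaluation machinery are wired correctly and
can learn separable structure — not that the model reaches any particular
accuracy on clinical data.

## Problem sizes and numerics

All tensors are float64; at the package's model sizes the precision is
worth more than float32 speed, and it keeps the oracle comparisons tight
(attention vs brute-force per-head loop agrees to 1e-5, finite-difference
gradient checks to 1e-3 relative). Softmax is computed with max-shift
stabilization; layer normalization uses eps 1e-5; Adam uses eps 1e-8.
Ties in the max-pooling gradient split evenly.

The desk-scale experiment uses the spec'd tiny architecture (embed 64,
depth 2, heads 4, one fusion layer) with reduced crops — 16³ and 32×32×16,
patch 8 — 120 phantoms, learning rate 1e-3 and 30 epochs per fold. The
reduced crops and the higher learning rate are the package's own
desk-scale choices: the small token counts (9 and 33) keep five folds of
the numpy trainer at roughly two minutes total, and 1e-3 compensates for
the short schedule (600 optimizer steps, vs hundreds of thousands at the
reference scale). The full-size configuration (embed 768, depth 12, crops
32³/128×128×32) runs through the identical code path and is exercised
shape-wise and finiteness-wise in the tests.

## Known limitations

- The numpy trainer is single-device and eager; it is sized for the
  desk-scale experiments, not for the full 768-dim/12-layer configuration
  at realistic cohort sizes.
- `cmmf predict` applies a fold's checkpointed EHR statistics; records with
  fields or categories outside the training schema encode to zeros for the
  unseen parts.
- The contrastive losses require batches with at least two cases to be
  informative (a single-pair batch scores zero by construction).
- DICOM reading supports plain axial series with uniform slice spacing;
  orientation metadata beyond slice position is not interpreted.
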