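# Methods

## Model

The package couples two components.

**Stain translation.** An unpaired image-to-image GAN maps H&E-style
patches (domain X) to EBER-style patches (domain Y). The generator is the
standard ResNet translator: 7×7 stem, two stride-2 downsampling
convolutions, residual bottleneck blocks (9 by default), two
upsample-and-convolve stages and a 7×7 tanh head. The adversarial term is a
least-squares loss on a patch-based discriminator; content is tied to the
input by contrastive PatchNCE losses that match two-layer-MLP projections
of encoder features at shared spatial locations against negatives drawn
from other locations of the same image, at five encoder depths (raw image,
stem, both downsampling outputs, bottleneck). The target-domain NCE term
uses the identity pass G(y). On top of this, a pathology-fidelity term

    L_PF = E_y | cls(pool(G_enc(y))) − l_y |

trains a one-layer sigmoid head on globally average-pooled bottleneck
features of *real* target patches against their {0,1} positivity labels.
Its gradient flows into the shared encoder at every generator update, so
the representation used for translation must also linearly separate
positive from negative pathology. All four loss weights default to 1;
with the fidelity weight at 0 the model, losses, and update order are
exactly contrastive unpaired translation (CUT), which is verified by a
trajectory-equality test against an independently composed reference loop.

**Rule cascade.** EBER chemistry makes classification nearly rule-based:
positive nuclei are dark blue (red channel < 100), negative tissue is pink
(red channel > 200). The cascade is: background removal (a pixel is glass
iff min(R,G,B) ≥ 230), per-pixel thresholding (positive iff foreground and
R < 100, strict), connected-component analysis (patch positive iff the
largest component strictly exceeds 100 px), and slide aggregation (NPC iff
at least one positive patch). The same first two levels label the GAN's
target-domain training patches (automatic annotation).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| pixel_positive_r_max | 100 | 8-bit intensity | separation valley between the positive (<100) and negative (>200) red-channel modes |
| component_min_area | 100 | pixels | safety margin below the ~125 px average footprint of the smallest tumor cell per patch |
| background_min_intensity | 230 | 8-bit intensity | near-white glass; the criterion itself (min-channel) is this package's choice |
| wsi_positive_count_min | 1 | patches | mirrors the clinical rule: any EBER-positive focus means NPC |
| connectivity | 8 | — | stained nuclei are blobs; diagonal contact should not split a cell (4 selectable, all oracles run under both) |
| lr / β₁ / β₂ | 2e-4 / 0.5 / 0.999 | — | translation-GAN convention |
| epochs / batch | 200 / 4 | — | full-scale schedule; decay is linear to zero from the midpoint |
| τ (NCE) | 0.07 | — | contrastive-translation convention |
| n_nce_patches | 256 | locations/image | contrastive-translation convention; reduced in desk-scale runs |

Thresholds are strict inequalities ("less than 100", "exceeds") and are
exposed on every API and CLI entry point.

## Synthetic data

The generator renders scenes of noisy discs on a tissue or glass canvas in
both stain styles with a shared geometry, so ground truth is exact: the
positivity mask equals the rendered tumor pixels by construction (non-tumor
cells are painted before tumor cells; per-pixel noise is uniform *within*
each palette interval, so palette compliance is exact, not statistical).
It emulates the features the method actually relies on: the red-channel
separation of EBER positives/negatives, near-saturated glass background,
the minimum tumor footprint (~125 px, validated at scene construction), and
distinct H&E appearances for tumor nuclei and small lymphocyte-like cells.
The H&E palettes are freely chosen and clearly separable — real H&E
tumor/lymphocyte discrimination is morphological and much harder, so
passing synthetic tests demonstrates the machinery (losses, cascade,
plumbing), not clinical performance. Not modelled: stain-vector physics,
slide-preparation artifacts (staining overflow, tissue squeezing), texture,
or nucleus shape variation.

## Numerical choices

- Images are normalised to [−1, 1] inside the GAN and encoded back to
  8 bits at the boundary; inference has no stochastic layers, so staining
  is deterministic.
- The decoder upsamples by nearest-neighbour interpolation followed by a
  3×3 convolution (avoids transposed-convolution checkerboard artifacts).
- All arithmetic is float64 on a hand-written NumPy autodiff engine scoped
  to these networks; gradients are verified against central finite
  differences.
- One Adam optimizer covers generator + projection heads + classifier, a
  second covers the discriminator; the classifier head participates in the
  same update as the generator (the fidelity gradient reaches the encoder).
- Projection-head linear layers use uniform bias initialisation so that
  feature vectors zeroed by ReLU at narrow widths still project to nonzero
  embeddings; convolution weights use the N(0, 0.02) GAN convention.
- During training the PatchNCE loss is computed in its pairwise-logit form
  (an S×S similarity matrix per image); a test pins its equality to the
  explicit-negatives definition.
- All randomness (init, data order, NCE sampling) derives from one seed
  via independent child streams; checkpoints restore bit-compatibly.
- RMSE is computed on [0,1]-scaled intensities jointly over RGB; PSNR uses
  MAX_I = 1 and reports infinity (flagged, not raised) for identical
  images; SSIM uses C1=(0.01L)², C2=(0.03L)², an 11-tap Gaussian window
  (σ = 1.5) on luminance, with the map cropped by the filter radius.
  Evaluation sets are scored per image and then averaged (mean-of-PSNR,
  not PSNR-of-mean-RMSE — the two differ in general).
- Degenerate inputs: empty verdict sequences raise ("no foreground"
  rather than a diagnosis); all-background patches contribute their overall
  mean to intensity histograms; an all-zero mask has component area 0.
- Tiling uses 0-based (row, col) half-open tiles; the last row/column of
  origins is clamped into bounds (extra overlap at edges) instead of
  padding. Overlapping image tiles are blended by unweighted mean,
  overlapping masks by logical OR; default inference stride 192 at tile
  256 (25 % overlap), with stride = tile used wherever exactness is
  asserted.

## Design choices where the design was open

- *Background criterion*: no published definition exists; min(R,G,B) ≥ 230
  is declared (not inferred) and configurable.
- *Classifier input*: global average pooling before the one-layer head —
  the simplest permutation-invariant reduction of encoder features.
- *Fidelity labels*: the L1 classification term is applied only to real
  target-domain patches (generated images have no labels), with labels from
  the automatic annotation.
- *Decay shape*: linear to zero from the midpoint, the standard
  translation-GAN schedule.
- *Discriminator*: 70×70-receptive-field patch discriminator; scaled-down
  runs shrink depth, not the design.
- *Per-pixel rule vs per-image means*: masks use the per-pixel red-channel
  rule; per-image mean-intensity histograms are provided separately to
  validate the threshold choice.

## Problem sizes

Unit and oracle tests run on 32–64 px patches and 3×3-tile pseudo-slides.
The training smoke study uses 160 patches per domain at 64×64, generator
width 8 with 3 residual blocks, a 2-layer discriminator, 64 NCE locations,
5 epochs, and evaluates staining agreement on 200 held-out source patches;
the reduction-to-CUT check uses 16 patches per domain at 32×32 for 2
epochs. The acceptance script re-runs these sizes from scratch.

## Known limitations

- Desk-scale GAN training (a few hundred updates) is only a functional
  smoke test. Across seeds the 5-epoch run usually reaches 63–75 %
  stained-patch agreement (binomial p ≤ 1e-4), but occasional seeds stay
  near chance — the translator's colour polarity is not yet locked in this
  regime, and the toy model over-stains toward positive much as unconstrained
  translators do at full scale. Clinical-scale behaviour (200 epochs,
  ~80 k patches, GPU) is out of reach of these runs.
- The fidelity head moves slowly at desk scale (L_PF decreases by ~1 %
  over 5 epochs); its architectural effect on the encoder, not its
  convergence, is what the smoke test exercises.
- The rule cascade is calibrated to the stated staining statistics; no
  threshold fitting on clinical data is included.
- The synthetic H&E domain reduces tumor/lymphocyte morphology to colour,
  so synthetic agreement rates say nothing about real H&E difficulty.
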