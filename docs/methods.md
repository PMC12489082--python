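# Methods

## What the package models

beltscan implements a complete sensing-to-decision chain for belt-based
microwave lung screening on synthetic data. The chain is the object of
interest; the electromagnetic forward model is a deliberately transparent
stand-in for full-wave simulation of voxel body models. It is built so
that every assumption the downstream processing relies on holds *exactly*,
which turns the processing chain into something that can be tested against
closed-form expectations rather than against another simulator.

## Forward model

A measurement is an 8×8 complex scattering matrix on a uniform frequency
grid (default 500 points, 0.5–3.5 GHz). The body sweep is the sum of three
terms; the empty-domain sweep contains only the first:

1. **Coupling clutter** C_ij(f): seeded random symmetric amplitudes
   (0.05–0.15 off-diagonal, 0.25–0.35 on the diagonal) with free-space
   propagation phase over the antenna separation. Deterministic in the
   scenario's clutter seed; identical in the body and empty sweeps, so
   empty-domain subtraction cancels it exactly.
2. **Skin reflection** K(f) = A·0.02·exp(−2jk(f)·0.01): identical in every
   channel (rank-1, equal weights) by construction, so per-frequency
   channel-mean subtraction removes it exactly. On measured data the skin
   term would have channel structure and mean subtraction would leave a
   residual; this is the single largest idealization in the package.
3. **Tumor term** (Born point scatterer)
   T_ij(f) = κ·V·Δχ(f)·exp(−(α+jk(f))(d_i+d_j))/(d_i·d_j). Response is
   proportional to tumor volume and dielectric contrast and decays with
   the antenna–tumor distances, which is all the structure the learning
   stages exploit: detectability grows with size, off-plane belt positions
   attenuate the signature, and the backprojection phase matches the model
   phase exactly at the scatterer.

Parameters with units and defaults:

| parameter | default | meaning |
|---|---|---|
| torso semi-axes | 0.15 × 0.10 m | belt ellipse (phantom A); 0.13 × 0.09 m for phantom C |
| background ε_r, σ | 35, 0.5 S/m | effective torso medium (ε_r 42, 0.6 for phantom C) |
| tumor ε_r, σ | 55, 1.5 S/m | malignant-tissue contrast, well above background |
| lung radius / centers | 0.05 m at (±0.06, 0) | circular lung regions holding the tumor |
| κ | 180 | overall scattering gain, fixed so a 20 mm tumor at zero offset sits ≈ 40 dB below the clutter — the calibration chain has to matter |
| α | σ·η₀/(2√ε_r) ≈ 15.9 Np/m | conductive attenuation; zero-σ backgrounds give the lossless case used by localization tests |

The dielectric values are qualitative placeholders that respect the
ordering tumor ≫ background > lung; frequency-resolved tissue curves are
out of scope. Tumor centers are jittered inside the requested lung (seeded)
so that left/right cases of equal size are not exact mirror copies.

Measurement noise (`add_noise`) multiplies each entry's magnitude by
(1+u) and shifts its phase by u′·|phase|, u, u′ ~ U(−p, p), independently
per frequency and channel pair with the upper triangle mirrored to
preserve reciprocity.

## Study design (synthetic data generator)

The generator's defaults are the study conditions, not tuning knobs:

- **Set A** — 140 on-plane cases: 70 diameters per lung, uniform over
  2–60 mm. This grid places 8 diameters ≤ 8 mm in each lung.
- **Set B** — 20 off-plane cases: 10 sizes per lung
  (4, 5, 6, 7, 8, 15, 25, 35, 45, 55 mm) at vertical offsets of ±20 to
  ±40 mm; 5 sizes per lung are ≤ 8 mm.
- Sets A+B together therefore contain 26 class-0 (≤ 8 mm) vs 134 class-1
  cases — the canonical imbalance the balancing stage must resolve
  (ADASYN at β = 1 synthesizes exactly 108 points, giving 134 vs 134).
- **Set C** — 10 cases (5 diameters per lung, 10–50 mm) on a second
  phantom with different semi-axes and background medium, used only for
  cross-phantom evaluation.

All randomness (clutter, placement jitter, ADASYN, splits, training)
derives from one root seed through named SHA-256 substreams, so any stage
is reproducible in isolation and the whole run is reproducible end to end.

## Processing chain

**Calibration** is body − empty (complex, per element). The subtraction
direction is sign-ambiguous in common usage; downstream magnitudes are
sign-invariant, so body − empty is used throughout. **Skin-artifact
removal** subtracts the per-frequency complex mean over all 64 channels;
it is idempotent and leaves a zero channel mean at every frequency.

**Features**: each channel's |S| and frequency-unwrapped phase are averaged
over the closed band [1.5, 3] GHz (inclusive endpoints), giving 64 + 64
values in row-major channel order, amplitudes first. Amplitudes are
averaged in linear units, not dB. Phase is unwrapped before averaging
because the mean of wrapped phase is meaningless near the branch cut. All
64 channels are kept, including reciprocal duplicates, preserving the
2 × 64 × 500 = 64 000-value raw record per case.

**Imaging** is plain coherent backprojection with uniform pair weights
over all 64 transmit–receive pairs (monostatic terms included; a flag
excludes them), magnitude output (a flag gives magnitude squared), and a
single effective background medium for the propagation speed. Per-geometry
phase factors are cached, which makes batch reconstruction of a study
cheap. Images are normalized to the maximum of a healthy-reference case.
Because the full preprocessing chain nulls a healthy synthetic case
*exactly*, the healthy reference is taken one step earlier in the chain —
the healthy case imaged after calibration but before skin-artifact
removal, i.e. the benign artifact level. Rendering clips normalized values
at the 99.5th percentile of the training images' values (a fixed color
scale with dynamic range for small tumors) and maps them through a fixed
perceptual colormap.

## Rebalancing, augmentation, splits

ADASYN follows the standard construction: per minority point, the majority
fraction among its k = 5 nearest neighbours in the combined set weights
the allocation of G = round(β·(M − m)) synthetic points;
largest-remainder rounding makes Σg_i = G exact (naive per-point rounding
does not reproduce the canonical count of 108); each synthetic point
interpolates between a minority point and one of its k nearest minority
neighbours. A uniform allocation is used when no minority point has
majority neighbours. For images, ADASYN runs on flattened raw pixels.

Augmentation produces exactly 4 instances per image (original, horizontal
flip, vertical flip, 180° rotation = both flips). Splits are by *case*:
all augmented/synthetic descendants follow their parent, descendants of
held-out cases are dropped entirely, and a descendant whose parents
straddle partitions is dropped rather than leaked.

## Models

- Gradient-boosted detector: 10 trees, depth 3, η 0.3, subsample 0.5,
  on the 128 features, threshold 0.5.
- Gradient-boosted size regressor: 1000 trees, depth 4, η 0.3,
  subsample 0.5; targets are tumor radii in mm, on-plane (set A) cases only.
- CNN detector and size regressor: four 3×3 conv blocks (8, 16, 32, 32
  filters, ReLU, 2×2 max-pool), global average pooling, dense 16, and a
  1-unit head (sigmoid via BCE-with-logits for detection, linear for
  size); ≈ 16k parameters. Adam (lr 10⁻³, batch 16); binary cross-entropy
  / mean-squared-error losses. The CNN engine is a self-contained NumPy
  implementation (im2col convolutions, analytic backprop verified against
  finite differences in the test suite). Global average pooling makes the
  topology resolution-independent, so reduced-size profiles reuse it
  unchanged.

## Noise fine-tuning

Half of the on-plane cases are sampled (seeded); each contributes one copy
per noise level (1%, 5%, 10%), where the perturbation multiplies every
value of the model-input record — the 128-feature vector, or the
normalized raster — by (1+u), u ~ U(−p, p). Perturbing the raw sweep
per-frequency instead is near-vacuous here: the 375-point band average
attenuates independent per-frequency noise ~19-fold, leaving the naive
model effectively noise-immune, so the protocol acts on the data record
fed to the model. Tree models continue boosting on the noisy set
(incremental learning); the CNN continues training (default 100 epochs at
full scale). The regressor's continuation uses 100 trees at learning rate
0.02: with only a few hundred noisy rows, continuation at the original
rate (0.3) drives the training error to ~0, memorizing individual noise
draws and *hurting* noisy-test performance; strong shrinkage is the
standard remedy for small continuation sets. Evaluation compares naive and
fine-tuned bundles on 20 unseen cases perturbed at the 10% level. On this
synthetic study the naive models are already fairly noise-tolerant (the
feature–size mapping is heavily redundant), so the fine-tuning gain is
real but modest — the inequality "fine-tuned not worse than naive" holds
in a majority of seeds rather than by a wide margin, unlike on complex
voxel-model data where naive models degrade much more.

## Decision fusion and staging

Multiple belt heights are fused by OR for detection and max for size (an
off-plane reading under-estimates, never over-estimates, in this model).
Stages follow the size bins IA ≤ 30 < IB ≤ 40 < IIA ≤ 50 < IIB (mm,
largest dimension; right-closed intervals so the partition is gapless;
anything above 50 mm is reported as IIB by this lookup). Reported "size"
is the diameter; models predict radii = size/2. The evaluation module
reports accuracy, mean squared error (in mm², squared radius error) and an
unpaired two-sample Student t-test with pooled variance and
df = n_a + n_b − 2 (Welch behind a flag); two constant samples with equal
means give t = 0, p = 1, with unequal means t = ∞, p = 0.

## Problem sizes and profiles

The default `RunConfig` is a smoke profile chosen so a complete study runs
in about a minute on one CPU: 48×48 pixel imaging grid, 32×32 CNN input
rasters, 40 CNN epochs (20 for fine-tuning). The full-scale settings —
634×496 rendering, 400×400 CNN input, 300/100 epochs — are ordinary config
fields; nothing in the code depends on the reduced sizes. Case counts and
the 500-point frequency grid are never reduced in the default profile.
The 12-case fixture bundle uses a 160-point grid so its on-disk Touchstone
files stay small.

## What passing tests do and do not show

The generator satisfies the chain's assumptions exactly: clutter cancels
exactly, the skin term is exactly common-mode, the point-scatterer phase
matches the imaging kernel exactly, and class separability is governed by
a clean monotone volume law. Passing tests therefore validate the
*implementation* of every stage and the *internal consistency* of the
protocol — they do not demonstrate clinical performance. Real data would
add channel-structured skin residuals, heterogeneous propagation,
antenna dispersion and correlated noise, all of which degrade the
idealized separations measured here; headline metrics (e.g. perfect
detection accuracy) are properties of the synthetic conditions.

## Known limitations

- Single effective medium; no heterogeneous ray paths or multiple
  scattering (first-order Born only).
- Skin modeled as exactly common-mode; mean subtraction is exactly right
  only on synthetic data.
- Spherical single tumors; no lesion shape, multiplicity, or tissue
  texture.
- Dielectric constants are qualitative placeholders, not dispersive
  tissue curves.
- The cross-phantom set varies geometry and background permittivity only;
  real inter-subject variation is far richer.
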