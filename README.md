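# hveegnet

Hierarchical variational autoencoders with a dynamic-time-warping loss for
high-fidelity reconstruction of multi-channel EEG, plus a
reconstruction-error anomaly detector that flags corrupted repetitions in
motor-imagery recordings.

## The problem and who this is for

Multi-channel EEG is hard to reconstruct with autoencoders: the signals are
noisy, broadband, and vary strongly across subjects. This package is for
neuroinformatics researchers who want (a) a compact convolutional VAE that
reconstructs 22-channel motor-imagery segments with high fidelity, and (b) a
principled way to spot corrupted trials (amplifier saturation, mains
contamination, muscle artifacts, blinks) without manual inspection: segments
the trained model reconstructs poorly are anomalies.

## Models and loss

Two EEGNet-style encoder/decoder pairs are provided:

* **vEEGNet-ver3** — a plain VAE. The encoder stacks a temporal convolution
  (kernel 1×128), a depthwise spatial convolution spanning all C electrodes,
  and a separable convolution (1×32 depthwise + 1×1 pointwise), with batch
  norm, ELU and average pooling (1,4)/(1,8). A 1×1 sampling head doubles the
  feature depth; the first half is the posterior mean μ, the second the
  log-variance log σ² of the single latent space z₀. The decoder mirrors
  the encoder with nearest-neighbour upsampling and transposed convolutions.

* **hvEEGNet** — the hierarchical variant with three latent spaces, tapped
  at the output of each encoder block: z₃ (temporal level, in electrode
  space), z₂ (spatial level), z₁ (deepest, after the separable block with
  (1,10) pooling and no pooling in the spatial block). Decoding starts from
  z₁; the sampled z₂ is temporally filtered and combined with the decoder
  features by a learned linear combination; the sampled z₃ is added before
  the final temporal stage. Partial-hierarchy decodes (z₁ only, z₁+z₂, full)
  expose what each level contributes.

For the benchmark geometry (C = 22, T = 1000) the models have exactly
**8,224** (hvEEGNet) and **4,992** (vEEGNet-ver3) trainable parameters.

Training minimizes `L = L_KL + L_R` where

* `L_KL = ½ Σᵢ (σᵢ² + μᵢ² − 1 − log σᵢ²)` is the closed-form KL divergence
  to a standard-normal prior, summed over hierarchy levels, and
* `L_R` is the channel-summed **soft dynamic time warping** between input and
  reconstruction: the DTW recurrence `W(i,j) = |a(i)−b(j)| +
  min(W(i−1,j−1), W(i,j−1), W(i−1,j))` with the hard minimum replaced by a
  temperature-γ soft minimum so the loss is differentiable.

Evaluation uses the exact, *normalized* DTW score (the mean of the
cumulative costs along the optimal warping path; the corner-cost/K variant
is available behind a mode switch).

Anomaly detection builds the R×C matrix `Ē` of normalized per-channel DTW
scores averaged over training runs, treats each repetition as a point in
C-dimensional error space, computes Euclidean k-th-nearest-neighbour
distances (k = 15 at benchmark size), thresholds the sorted distance curve
at its knee (Kneedle), and flags the repetitions above it.

Everything runs on a small self-contained numpy/numba stack — no GPU or
deep-learning framework needed; training at desk scale takes seconds to
minutes per run.

## Worked example

```python
import numpy as np
import hveegnet as hv

# clean two-second 4-channel EEG at 64 Hz, microvolt scale
ds = hv.generate_clean(n_subjects=1, n_trials=32, n_channels=4, T=128,
                       fs=64.0, seed=11)
# saturate one held-out repetition end to end (amplifier rail at 20x RMS)
ds = hv.inject_artifact(ds, hv.ArtifactSpec(
    kind="saturation", subject=0, repetition=25, channels=(0, 1, 2, 3),
    magnitude=20.0))
batch = ds.segments(0)                  # (32, 1, 4, 128)
train_pool, held_out = batch[:16], batch[16:]

arch = hv.ArchitectureConfig(n_channels=4, n_samples=128, temporal_kernel=32,
                             separable_kernel=16, z2_filter_kernel=17)
cfg = hv.TrainingConfig(batch_size=8, epochs=200, runs=1, checkpoint_every=0)
models, hists = hv.run_protocol(train_pool, "hveegnet", arch, cfg, base_seed=1)
h = hists[0]
print(f"train soft-DTW loss: {h.train_l_r[0]:.0f} (epoch 1) -> {h.train_l_r[-1]:.0f} (epoch 200)")
print(f"validation score:    {h.val_score[0]:.1f} -> {h.val_score[-1]:.1f}")

E = hv.compute_error_matrix(models[0], held_out)
report = hv.detect_outliers(E, k=3)
rep_means = E.values.mean(axis=1)
print(f"held-out mean scores: clean {np.delete(rep_means, 9).mean():.1f}, "
      f"saturated repetition {rep_means[9]:.1f}")
print(f"flagged repetitions (held-out indexing): {report.flagged}")
```

which prints (about a minute on one CPU core):

```
train soft-DTW loss: 7555 (epoch 1) -> 843 (epoch 200)
validation score:    862.6 -> 79.2
held-out mean scores: clean 78.1, saturated repetition 818.5
flagged repetitions (held-out indexing): [9]
```

The training loss falls by an order of magnitude, held-out clean segments
score ~78 while the saturated one scores ~818 (a 10× separation), and the
kNN + knee detector flags exactly the saturated repetition.

A command-line surface wraps the same pipeline
(`hveegnet simulate | train | reconstruct | detect-outliers | evaluate`);
every command takes `--seed` and re-running it reproduces outputs byte for
byte.

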