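# Methods

This note documents the models, the numerical choices behind them, what the
synthetic data generator does and does not emulate, and the limits of what
the tests demonstrate.

## Models

Both autoencoders use the EEGNet block structure on inputs shaped
`(batch, 1, C, T)`:

| block | layers | hvEEGNet | vEEGNet-ver3 |
|---|---|---|---|
| temporal | conv (1,128), 1→8 maps; batch norm | no pooling | no pooling |
| spatial | depthwise conv (C,1), 8→16 maps (depth multiplier 2); batch norm; ELU; dropout 0.5 | no pooling | avg pool (1,4) |
| separable | depthwise conv (1,32) + pointwise (1,1), 16→16; batch norm; ELU; dropout 0.5 | avg pool (1,10) | avg pool (1,8) |

Sampling heads are 1×1 convolutions that double the feature depth; the first
half of the doubled map is the posterior mean, the second half the
log-variance. vEEGNet-ver3 has one head after the separable block (z₀);
hvEEGNet has three, one per block output (z₃ temporal, z₂ spatial, z₁
separable/deepest). Latents are drawn with the reparameterization trick
`z = μ + exp(logvar/2)·ε`.

The decoder mirrors the encoder in reverse order. Transposed convolutions
at stride 1 are implemented as plain convolutions with the transpose
padding geometry (the spatial stage pads the collapsed electrode axis by
C−1 on both sides, expanding 1 row back to C). Upsampling is
nearest-neighbour repetition by the pooling factor followed by cropping or
edge-padding to the exact pre-pooling length recorded by the encoder, so
`forward(x).shape == x.shape` for every admissible T (pooling uses floor
division).

Hierarchical decoding: the z₁ sample enters the separable-transpose block;
the z₂ sample is passed through a depthwise temporal filter (kernel 125 =
half the benchmark sampling rate, odd so same-padding is symmetric) and
fused with the block output by a pointwise convolution over their
concatenation — a *learned linear combination* of decoder features and
sample, whose simplest special case is the plain sum; the z₃ sample is
added to the spatial-transpose output directly, since the final 128-tap
temporal stage immediately filters it anyway. Partial-hierarchy decoding
substitutes zeros for omitted levels.

**Bias convention.** Convolutions adjacent to a batch norm carry no bias
(the affine shift absorbs it — the standard EEGNet implementation choice);
every latent-path convolution (sampling heads, z₂ filter and fusion)
carries one. Batch norms use affine parameters, eps 1e-5, momentum 0.1.
The published description of this architecture family underdetermines the
sampling-path internals; the conventions above were resolved so that the
trainable-parameter totals reproduce the reference implementation's printed
counts exactly — 8,224 for hvEEGNet and 4,992 for vEEGNet-ver3 at C=22,
T=1000 — which the test suite pins. Under this resolution the decoder
(4,768) carries more parameters than the encoder (3,456) because the
sampling/injection machinery lives on the decoding path.

## Loss and training

* `L = kl_weight · L_KL + L_R`, with `kl_weight = 1` by default (no
  annealing).
* `L_KL` is the closed-form diagonal-Gaussian KL to a standard-normal
  prior, summed over hierarchy levels and averaged over the batch. The
  hierarchical formulation admits conditional priors `p(z_l | z_<l)`; this
  package adopts the standard-normal-per-level simplification and realizes
  deep-to-shallow conditioning structurally (the z₂/z₃ injection paths),
  not through the prior.
* `L_R` is the soft-DTW between reconstruction and input with local cost
  `|a−b|` (absolute difference — the same local cost the evaluation score
  uses, *not* the squared cost common in generic soft-DTW code), summed
  over channels, un-normalized, averaged over the batch. Temperature
  `gamma = 1.0` by default, which is small relative to microvolt-scale
  signals; the gradient flows through the expected-alignment matrix of the
  soft-min relaxation.
* Optimizer: Adam at learning rate 0.01 with an exponential per-epoch decay
  `lr_e = 0.01 · 0.999^e`, batch size 30, 80 epochs, 20 runs per subject —
  the reference protocol. Each run's seed drives the weight
  initialization, the train/validation shuffle (10% validation, floor),
  dropout masks and reparameterization noise; a fixed seed makes the whole
  run bit-reproducible on one CPU.
* Unsuccessful-run screening: a run is excluded when its loss becomes
  non-finite or its final training loss exceeds the initial one. The
  reference protocol excludes "unsuccessful" runs without stating a rule;
  this two-rule screen is the package's operationalization.

Because the local cost is L1, the reconstruction gradient is sign-based and
amplitude-invariant, while the KL gradient grows with latent magnitude.
The balance of the two therefore depends on the *physical scale* of the
data: at microvolt amplitudes (tens of µV) reconstruction dominates and
training converges; on unit-variance data the KL term wins and the
posteriors collapse. This is why the synthetic generator emits
microvolt-scale signals (nominal 20 µV RMS) rather than unit-RMS ones.

## Evaluation and anomaly detection

The evaluation score is the exact-DTW *normalized* score: the mean of the
cumulative cost values read along the optimal warping path (`Σ d(k) / K`).
A second convention, corner cost divided by path length, is available as
`mode="corner"`; both are reported with an explicit mode flag because the
two normalizations differ (K ≥ T) and the literature uses both. Path
tie-breaks prefer the diagonal predecessor, then the left, then the down —
deterministic.

Scoring uses the posterior-mean (zero-noise) decode so the error matrix is
deterministic given a checkpoint; a stochastic variant exists behind a
flag. Matrices from surviving runs are averaged elementwise into `Ē`.

Outlier identification treats each repetition (row of `Ē`) as a point in
C-dimensional space. Distances are Euclidean; the k-th-nearest-neighbour
distance *excludes the query point itself*. k = 15 at the benchmark size
(288 test repetitions); at fixture size (16 held-out repetitions) k = 3,
which still exceeds the planted-outlier multiplicity — the requirement
that keeps a cluster of mutual outliers from shielding itself. The sorted
ascending distance curve is thresholded at its Kneedle knee
(decreasing-sensitivity locator, sensitivity 1.0, implemented in-package);
rows strictly above the threshold are flagged. A degenerate (constant)
curve yields no knee, zero outliers and a warning.

The *transition point* of a training history is the checkpoint (5-epoch
cadence) where the mean-error curve elbows: among checkpoints whose
across-run standard deviation is at or below its median, the point
maximizing the distance below the chord of the normalized curve (the
Kneedle elbow statistic) is returned, ties toward the earlier epoch.
Linear curves fall back to the last checkpoint and constant curves to the
first, each with a warning.

## Synthetic data

The generator emulates the spectral shape of clean resting EEG: 1/f
colored noise (exponent 1.0) with Gaussian power bumps at 10 Hz (alpha, 3×
the local baseline) and 20 Hz (beta, 1.5×), a small broadband noise floor,
one shared slow oscillation (1.5 Hz) giving channels a common low-rank
component, per-subject lognormal gains (sd 0.2), and channels standardized
to a nominal 20 µV RMS. Phases are randomized per channel; everything is
seed-deterministic. Two stock shapes: *tiny* (2 subjects × 32 trials × 4
channels × 128 samples at 64 Hz — 2-second segments keep both peaks below
the 32 Hz Nyquist) and *benchmark* (1 × 576 × 22 × 1000 at 250 Hz).
By default 3% of repetitions (floor) carry a saturation artifact.

Injectable artifacts, with magnitudes in multiples of the nominal RMS:
hard amplifier saturation (constant rail), 50 Hz mains sinusoid, broadband
muscle noise (>30 Hz emphasis), and slow biphasic blink transients.
Ground truth for every injection is recorded.

What the generator does **not** emulate: volume conduction / realistic
channel covariance, non-stationarity within a segment, event-related
(de)synchronization, inter-trial structure, or real artifact morphology.
Passing tests on this data therefore demonstrate the correctness and the
qualitative behaviour of the pipeline (losses fall, hierarchy outperforms
the single latent space, strongly corrupted segments separate), not
reconstruction-quality numbers transferable to real recordings.

## Reduced-scale study conditions

Full-protocol sizes (22×1000, 80 epochs × 20 runs) are impractical for a
test suite on one CPU, so behavioural checks run on the tiny geometry with
a scaled architecture (temporal kernel 32, separable 16, z₂ filter 17 for
T=128 at 64 Hz): learning sanity uses 10-epoch runs across 10 seeds;
model comparison uses 5 paired 30-epoch runs; the planted-anomaly study
trains 2 runs of 250 epochs on the first-session half and scores the
held-out half, where three repetitions carry full-segment saturation at a
20×-RMS rail (0.4 mV — conservative relative to real amplifier limits).
That scenario yields a ≥10× separation between corrupted and clean mean
errors, the regime under which the detector is validated to achieve
precision = recall = 1.

## Numerical choices and degenerate inputs

* All arithmetic is float64, single-threaded; numba JIT-compiles the DTW
  recursions.
* Soft-DTW uses a max-shifted log-sum-exp; an optional Sakoe-Chiba band
  exists purely as a speed device and is off by default.
* Convolution weights are Glorot-uniform initialized from the model seed.
* Empty sequences, non-finite samples, shape mismatches, windows outside a
  trial, and fewer repetitions than k all raise `ValueError` with a
  description; a non-finite training loss flags the run instead of
  raising.
* Checkpoints are single `.npz` files with a JSON header (variant, seed,
  config) plus weights and batch-norm running statistics.

## Known limitations

* The standard-normal per-level prior is a simplification of the general
  hierarchical formulation; with learned conditional priors the KL term
  and the generative sampling path would change.
* The encoder/decoder split of the parameter total is a convention of this
  implementation; only the totals are externally pinned.
* Training at the full benchmark geometry works but is slow on one CPU
  (the DTW term is O(T²) per channel); the package is tuned for desk-scale
  experimentation.
* The anomaly detector flags poorly reconstructed repetitions; it does not
  classify artifact types — that remains expert judgment.
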