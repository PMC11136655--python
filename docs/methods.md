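# Methods

## The model

The network maps the male's recent visual experience — the 10 most recent
panorama frames (~300 ms at 30 Hz) — to his six behavioural outputs.

**Vision network.** Each frame passes through three stride-2, 3×3
convolution stages (32 filters by default; stages 2–3 depthwise-separable),
each followed by batch normalization and a rectifier, then a two-stage
factorized readout: a learned spatial pooling mask shared across channels,
followed by a linear channel mixing into 16 embedding variables. Weights are
shared across the 10 frames (a 1-D convolution in time). Inputs are raw
0–255 greyscale panoramas re-centred by subtracting 255 (background exactly
0) and scaled by 1/255 inside the network.

**Bottleneck.** The 10 concatenated embeddings (160 values) pass through a
64-unit dense layer and a dense layer with one unit per silenced cell type,
each with batchnorm and a rectifier, so bottleneck activities are
non-negative — each unit stands for the summed activity of one optic
glomerulus. The genotype→unit assignment is the identity permutation over a
declared genotype ordering, frozen at initialization.

**Decision network.** Three 128-unit dense layers (batchnorm + rectifier), a
linear head for the three velocities (fit in z-scored space; z-statistics
come from control training data only, falling back to unit scale if an
output is constant) and a sigmoid head for the three song probabilities.

**Knockout training.** Each sample carries a binary mask over the
bottleneck, applied multiplicatively after the rectifier, so a masked unit
outputs exactly 0 and receives no gradient for that sample. Modes:
`knockout` (the genotype's unit is masked), `dropout` (a uniformly random
unit masked for non-control samples), `no_knockout` (all ones), `untrained`
(initial weights returned untouched). Optimization is SGD with learning rate
1e-3 and momentum 0.7 (defaults); batches are balanced across genotype
classes (12 samples each — 288 for the full 24-class design) and, within
each genotype's quota, split as evenly as possible across song classes
(sine / pulse / none). Mirror augmentation flips images left-right and
negates lateral and angular velocities with probability 0.5 (training only).
Early stopping monitors validation forward-velocity R² once per epoch
(an epoch is a configurable number of batches — the capped dataset has no
natural epoch), tolerates `patience` non-improving evaluations, and restores
the best checkpoint. Batchnorm uses batch statistics during training and
running averages (momentum 0.9, initialized to the identity transform) at
inference; the untrained baseline therefore evaluates with identity
normalization.

Everything is implemented in NumPy with explicit forward/backward passes;
single-threaded runs with a fixed seed and data order are bit-deterministic.

## Stimulus rendering

The full panorama is 256 columns over 360° (64 rows); removing the 40°
blind wedge directly behind the male leaves round(256·320/360) = 228
columns. A normalized position p maps to an azimuth of 180p degrees
(rightward positive); size is the sphere-model subtense 2·arcsin(r/d)
normalized so 180° ↦ 1; rotation 0° means the female faces away.

The fictive female is drawn procedurally: ellipses for abdomen, thorax, head
and two eyes in a square patch, with the body axis projected onto the image
horizontal by sin(rotation) and occlusion ordered by depth (head hidden when
she faces away). The patch bank is defined at 1° rotation resolution and
rasterized analytically at the required pixel width (rather than scaling a
fixed 25×25 bitmap), which keeps the mirror identity
render(p, φ) = fliplr(render(−p, −φ)) exact. The patch's angular width at
size 1.0 is calibrated so the body artwork (its widest cross-section spans
55% of the patch) subtends 65° at rotation 0 — the calibration constant is
the contract; whether patch width scales with the artwork's native width or
the 180° normalization is absorbed into that constant. Patch placement
rounds to the nearest pixel with a mirror-symmetric rounding rule; pixels
falling outside the retained 320° are discarded (no wraparound). Vertical
placement is always the horizontal centre line.

Spot stimuli: translation (fixed 20° diameter, 2 s), loom
θ(t) = −2·atan(−(r/v)/t) with t the time remaining until maximum size
(start 80°, cap 180°), and linear expansion θ = 10 + v·t capped at 90°. The
2-s linear-expansion duration is inferred from the printed final diameters
(30° at 10°/s from a 10° start) and the ramp includes both endpoints.
Probe sweeps ramp one parameter up and back down per period; the model-probe
protocol uses periods of 150/100/50/10 frames (the printed 0.66-s fourth
period is 20 frames at 30 Hz; the printed frame count of 10 is taken as
canonical), the imaging protocol 150/100/50 frames (300 frames, 10 s) with
the protocol-fixed values position 0.25 / size 0.8 for the non-varied
parameters.

## Courtship criteria and splits

A frame is a courtship frame if any of four criteria holds over a centred
20-s window (truncated at session edges): mean thorax distance < 5 mm; song
fraction > 0.1; mean |female azimuth from the male's head| ≤ 45°; mean
approach (closure) speed ≥ 4.5 mm/s. Velocities are internally per-second
(the 4.5 mm/s criterion fixes that reading). Test sets are unions of
non-overlapping 3-s windows drawn from courtship regions (15 min = 27,000
frames per genotype at full scale; proportionally reduced with a warning
when a genotype has less); control also receives a validation set. Training
uses remaining courtship frames, excluding every frame within 9 frames
before a held-out window (so no test frame's 10-frame input window overlaps
training), capped at 600,000 per genotype. Samples whose pose frames are
missing are flagged NaN and excluded.

## Probing

Tuning tensors evaluate the bottleneck on a full-factorial 50³ grid (size
0.3–1.1, position −1–1, rotation −180–180°), each stimulus a 10-fold repeat
of one static image; the vision network runs once per image. Variance
decomposition is the functional ANOVA under the uniform grid measure: each
marginal component is the variance of the doubly-averaged response, the
interaction term is the remainder (non-negative by construction; asserted to
−1e−10). CLIP clamps units to their mean activity over the evaluation
frames, greedily removing the unit whose clamping maintains the best score
(R² for movement, 1 − normalized cross-entropy for song; a degenerate
constant prediction scores 0; ties break toward the lowest unit index);
per-unit normalized change is the drop at the unit's removal step divided by
the total drop, clipped to [0, 1]. The sufficiency construction takes the
longest CLIP-ordered prefix whose clamping keeps the output trace within a
trace-R² of 0.9 of the full model (the threshold is a package choice and is
configurable); the remaining units are tested for sufficiency and, by
clamping them instead, necessity. Summary-graph edges require strictly
R² > 0.30 (features) or normalized change > 0.30 (behaviours).

## Neural evaluation

Detrending z-scores each repeat over time, then applies one common affine
map so the output repeat-average has exactly the original average's mean and
standard deviation; the operation is idempotent and leaves identical repeats
unchanged. Responsiveness compares 50 split-half R² values against 50 null
values built from the all-stimulus repeat pool with independent time
reversal (p = 0.5) and sign flips (p = 0.5);
d′ = (μ_actual − μ_null)/√((σ²_actual + σ²_null)/2), responsive iff d′ > 1
(the standard sensitivity index; the pooled-variance form is a package
convention). The noise-corrected R² corrects both the squared covariance
and the repeat-average variance by unbiased noise-power estimates
(num = cov(x, ȳ)² − var(x)·σ̂²/(n(T−1)), den = var(x)·(var(ȳ) − σ̂²/n)); its
contract is the calibration: mean within ±0.05 of 1 for a true-mean model at
20 repeats, ≈0 for independent models, and exact affine/sign invariance.
The causal filter is a linear least-squares fit of 10 past/current taps plus
an intercept (the rectifier-offset role), with a ridge fallback for
ill-conditioned designs; the all-unit mapping is a 5-fold cross-validated
ridge regression scored on pooled out-of-fold predictions. Adaptation
decays the output toward baseline at rate 0.1 per frame wherever the raw
response repeats exactly, re-seeding to the raw value on any change (the
re-entry rule is a package convention).

## The synthetic ground truth

`simfly` simulates a sensorimotor system whose answer key is known: each of
n units has a non-negative Gaussian tuning bump over (size, position,
rotation) — centres stratified over size 0.5–0.95, position ±0.45, rotation
±120°, widths 0.12–0.25 / 0.18–0.35 / 50–110° — optionally plus sensitivity
to one-frame parameter changes, and a readout W (n × 6) in which every
output depends on at least two units (a population code). Female parameters
follow a mean-reverting random walk (time constant ~200 frames, stationary
spread covering the tuning ranges, reflected at bounds); velocities are
W'g plus Gaussian noise of σ = 0.5 (signal standard deviations are ~1–1.5,
a moderately noisy regime); songs are Bernoulli draws from a logistic link
with gain 3 and bias −2 (sparse baseline song). Male pose tracks are
integrated from the behaviour table and the female is placed by the inverse
egocentric geometry, so behaviour extraction and the renderer are exercised
on their native inputs and round-trip to machine precision.

What the simulator does **not** emulate: real fly kinematic statistics
beyond boundedness and smoothness, female behaviour, wing song structure
beyond per-frame binaries, occlusions or tracking noise, and — deliberately —
left-right mirror symmetry of the stimulus-to-behaviour map. Because the
synthetic map is not mirror-symmetric, the reference recovery runs disable
the mirror augmentation that is appropriate for real data; passing recovery
tests therefore demonstrates the alignment mechanism of knockout training,
not robustness to the augmentation or to real-data nuisance structure.

## Reference recovery configuration

Ground-truth recovery is scored at a deliberately small reference scale so
the full comparison runs on one CPU in minutes: 5 units, the reduced 16×57
panorama, one 300-s session per genotype (~54k frames), 16 convolution
filters, batches of 6 classes × 12 samples, learning rate 1e-2 (the default
1e-3 is tuned to full-scale training; the scaled-down task needs the larger
step to converge within its budget), 50 batches per epoch, up to 15 epochs
with patience 3, no augmentation. Recovery metrics: (a) mean absolute
Pearson correlation between each model unit's tuning tensor and the matched
ground-truth unit's tuning on a shared 16³ grid (sign/scale-normalized;
constant tensors score 0); (b) Spearman rank correlation between CLIP
normalized changes and |W|, pooled over all unit × output pairs — the pooled
form is used because per-output rank correlations over only 5 units are
dominated by sampling noise. CLIP here scores against noise-free
ground-truth output traces (velocities W'g and song probabilities) so the
curves are well-conditioned. The experiment also reports the correlation,
across genotypes, between observed and model-predicted genotype-mean forward
velocity (each genotype predicted with its knockout mask applied). All
training modes share initialization and data order. Across reference seeds the knockout network's advantage over
the no-knockout baseline is consistent in tuning recovery; the contribution
metric is noisier (5 units), which is why the pooled statistic is used.

## Numerical conventions

Rotation angles wrap to (−180°, 180°]; azimuth and turning are rightward
positive. R² is the squared Pearson correlation over finite frames (NaN for
degenerate series); song prediction quality is 1 minus cross-entropy
normalized by the base-rate predictor's cross-entropy. Permutation p-values
use the +1 convention (minimum 1/(runs+1) at the default 1,000 runs);
bootstrap intervals are percentile intervals. All randomness flows through
explicit `numpy.random.Generator` seeds.
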