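"""The bottlenecked vision-to-behaviour network and knockout training.

Architecture (three parts):

* **Vision network** — three strided 3x3 convolution stages (32 filters,
  stride 2; stages 2-3 are depthwise-separable), each followed by batchnorm
  and a rectifier, then a two-stage factorized readout (a learned spatial
  pooling mask shared across channels followed by a channel mixing) producing
  16 embedding variables per frame. Weights are shared across the 10 input
  frames.
* **Bottleneck** — the 10 concatenated embeddings pass through a 64-unit
  dense layer and a dense layer with one unit per silenced neuron type
  (batchnorm + rectifier each), so bottleneck activities are non-negative.
  Each bottleneck unit stands for the summed activity of one cell type.
* **Decision network** — three 128-unit dense layers (batchnorm + rectifier)
  with a linear head for the three velocities (fit in z-scored space) and a
  sigmoid head for the three song probabilities.

Knockout training: every training sample carries a binary mask over the
bottleneck; for data recorded from an animal with cell type *g* silenced the
corresponding unit is multiplied by zero (so its gradient vanishes for that
sample), for control data the mask is all ones. Alternative modes: "dropout"
(a uniformly random unit zeroed for non-control samples), "no_knockout"
(all-ones masks) and "untrained" (initial weights returned untouched).

Optimization is plain SGD (learning rate 1e-3, momentum 0.7) on batches
balanced across genotype classes (12 samples each; 288 for the 24-class
full design) and across song classes (sine / pulse / no song), with
left-right mirror augmentation. Velocities are z-scored with control
training statistics; losses are mean squared error (velocities) plus binary
cross-entropy (songs). Early stopping monitors validation forward-velocity
R-squared and restores the best checkpoint.

Everything is implemented in NumPy with explicit forward/backward passes;
with a fixed seed and data order the training trajectory is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "GenotypeMap",
    "OneToOneNetwork",
    "make_batch",
    "train",
    "evaluate",
    "genotype_mean_shifts",
    "r_squared",
    "song_score",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Param:
    __slots__ = ("value", "grad", "velocity", "name")

    def __init__(self, value: np.ndarray, name: str):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)
        self.name = name


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _same_pad(n, k, s):
    out = -(-n // s)  # ceil
    total = max((out - 1) * s + k - n, 0)
    return out, total // 2, total - total // 2


class Conv2D:
    """3x3 strided convolution, SAME padding, channels-last."""

    def __init__(self, rng, cin, cout, k=3, stride=2, name="conv"):
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout
        self.W = _Param(_glorot(rng, (k * k * cin, cout), k * k * cin, k * k * cout),
                        f"{name}/W")
        self.b = _Param(np.zeros(cout, dtype=np.float32), f"{name}/b")
        self.name = name

    def params(self):
        return [self.W, self.b]

    def _patches(self, xp, OH, OW):
        k, s = self.k, self.stride
        N = xp.shape[0]
        cols = np.empty((N, OH, OW, k * k, xp.shape[3]), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                cols[:, :, :, ki * k + kj, :] = \
                    xp[:, ki:ki + OH * s:s, kj:kj + OW * s:s, :]
        return cols

    def forward(self, x, training=False):
        N, H, W, C = x.shape
        OH, pt, pb = _same_pad(H, self.k, self.stride)
        OW, pl, pr = _same_pad(W, self.k, self.stride)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = self._patches(xp, OH, OW).reshape(N, OH, OW, -1)
        self._cache = (cols, xp.shape, (pt, pl), (H, W))
        return cols @ self.W.value + self.b.value

    def backward(self, dy):
        cols, xp_shape, (pt, pl), (H, W) = self._cache
        N, OH, OW, _ = dy.shape
        flat_cols = cols.reshape(-1, cols.shape[-1])
        flat_dy = dy.reshape(-1, self.cout)
        self.W.grad += flat_cols.T @ flat_dy
        self.b.grad += flat_dy.sum(axis=0)
        dcols = (flat_dy @ self.W.value.T).reshape(N, OH, OW, self.k * self.k, self.cin)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        k, s = self.k, self.stride
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki:ki + OH * s:s, kj:kj + OW * s:s, :] += \
                    dcols[:, :, :, ki * k + kj, :]
        return dxp[:, pt:pt + H, pl:pl + W, :]


class SeparableConv2D:
    """Depthwise 3x3 (stride 2) followed by a pointwise 1x1 convolution."""

    def __init__(self, rng, cin, cout, k=3, stride=2, name="sepconv"):
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout
        self.Wd = _Param(_glorot(rng, (k * k, cin), k * k, k * k), f"{name}/Wd")
        self.Wp = _Param(_glorot(rng, (cin, cout), cin, cout), f"{name}/Wp")
        self.b = _Param(np.zeros(cout, dtype=np.float32), f"{name}/b")
        self.name = name

    def params(self):
        return [self.Wd, self.Wp, self.b]

    def forward(self, x, training=False):
        N, H, W, C = x.shape
        k, s = self.k, self.stride
        OH, pt, pb = _same_pad(H, k, s)
        OW, pl, pr = _same_pad(W, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        # depthwise stage accumulated over kernel offsets (no im2col buffer)
        depth = np.zeros((N, OH, OW, C), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                depth += xp[:, ki:ki + OH * s:s, kj:kj + OW * s:s, :] \
                    * self.Wd.value[ki * k + kj]
        out = depth @ self.Wp.value + self.b.value
        self._cache = (xp, depth, (OH, OW), (pt, pl), (H, W))
        return out

    def backward(self, dy):
        xp, depth, (OH, OW), (pt, pl), (H, W) = self._cache
        N = dy.shape[0]
        flat_depth = depth.reshape(-1, self.cin)
        flat_dy = dy.reshape(-1, self.cout)
        self.Wp.grad += flat_depth.T @ flat_dy
        self.b.grad += flat_dy.sum(axis=0)
        ddepth = (flat_dy @ self.Wp.value.T).reshape(N, OH, OW, self.cin)
        dxp = np.zeros(xp.shape, dtype=np.float32)
        k, s = self.k, self.stride
        for ki in range(k):
            for kj in range(k):
                sl = xp[:, ki:ki + OH * s:s, kj:kj + OW * s:s, :]
                self.Wd.grad[ki * k + kj] += (sl * ddepth).sum(axis=(0, 1, 2))
                dxp[:, ki:ki + OH * s:s, kj:kj + OW * s:s, :] += \
                    ddepth * self.Wd.value[ki * k + kj]
        return dxp[:, pt:pt + H, pl:pl + W, :]


class BatchNorm:
    """Batch normalization over all axes but the last; running statistics
    (initialized to identity) are used at inference."""

    def __init__(self, c, momentum=0.9, eps=1e-5, name="bn"):
        self.gamma = _Param(np.ones(c, dtype=np.float32), f"{name}/gamma")
        self.beta = _Param(np.zeros(c, dtype=np.float32), f"{name}/beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps, self.name = momentum, eps, name

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, training)
        return (self.gamma.value * xhat + self.beta.value).astype(np.float32, copy=False)

    def backward(self, dy):
        xhat, inv, axes, training = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value * inv
        if not training:
            return (dy * g).astype(np.float32, copy=False)
        m = np.prod([dy.shape[a] for a in axes])
        mean_dy = dy.mean(axis=axes)
        mean_dyx = (dy * xhat).mean(axis=axes)
        return (g * (dy - mean_dy - xhat * mean_dyx)).astype(np.float32, copy=False)


class ReLU:
    def params(self):
        return []

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dy):
        return np.where(self._mask, dy, np.float32(0.0))


class Dense:
    def __init__(self, rng, cin, cout, name="dense"):
        self.W = _Param(_glorot(rng, (cin, cout), cin, cout), f"{name}/W")
        self.b = _Param(np.zeros(cout, dtype=np.float32), f"{name}/b")
        self.name = name

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class FactorizedReadout:
    """Two-stage linear map: a learned spatial pooling mask shared across
    channels, then a channel mixing into ``n_embed`` variables. No batchnorm
    or rectifier follows."""

    def __init__(self, rng, spatial, cin, n_embed, name="readout"):
        self.mask = _Param(np.full(spatial, 1.0 / spatial, dtype=np.float32),
                           f"{name}/mask")
        self.W = _Param(_glorot(rng, (cin, n_embed), cin, n_embed), f"{name}/W")
        self.b = _Param(np.zeros(n_embed, dtype=np.float32), f"{name}/b")
        self.spatial, self.cin, self.n_embed = spatial, cin, n_embed
        self.name = name

    def params(self):
        return [self.mask, self.W, self.b]

    def forward(self, x, training=False):
        N = x.shape[0]
        xs = x.reshape(N, self.spatial, self.cin)
        pooled = np.einsum("nsc,s->nc", xs, self.mask.value)
        self._cache = (xs, pooled, x.shape)
        return pooled @ self.W.value + self.b.value

    def backward(self, dy):
        xs, pooled, xshape = self._cache
        self.W.grad += pooled.T @ dy
        self.b.grad += dy.sum(axis=0)
        dpooled = dy @ self.W.value.T
        self.mask.grad += np.einsum("nsc,nc->s", xs, dpooled)
        dxs = self.mask.value[None, :, None] * dpooled[:, None, :]
        return dxs.reshape(xshape)


# ---------------------------------------------------------------------------
# configuration and genotype -> unit assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkConfig:
    n_bottleneck: int = 23
    rows: int = 64
    cols: int = 228
    n_history: int = 10
    conv_filters: int = 32
    n_embed: int = 16
    bottleneck_hidden: int = 64
    decision_width: int = 128
    n_velocity: int = 3
    n_song: int = 3


@dataclass
class TrainConfig:
    mode: str = "knockout"           # knockout | dropout | no_knockout | untrained
    learning_rate: float = 1e-3
    momentum: float = 0.7
    n_per_class: int = 12
    batches_per_epoch: int = 50
    max_epochs: int = 40
    patience: int = 1
    augment: bool = True
    seed: int = 0


class GenotypeMap:
    """Fixed genotype-to-bottleneck-unit assignment (identity permutation
    over the declared genotype ordering, frozen at initialization)."""

    def __init__(self, genotypes, n_units: int, control_label: str = "control"):
        self.control_label = control_label
        self.silenced = [g for g in genotypes if g != control_label]
        if len(self.silenced) > n_units:
            raise ValueError("more silenced genotypes than bottleneck units")
        self.n_units = n_units
        self.unit_of = {g: i for i, g in enumerate(self.silenced)}

    def mask_for(self, genotype: str) -> np.ndarray:
        mask = np.ones(self.n_units, dtype=np.float32)
        if genotype != self.control_label:
            mask[self.unit_of[genotype]] = 0.0
        return mask


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)),
                    np.exp(z) / (1.0 + np.exp(z)))


class OneToOneNetwork:
    """Vision + bottleneck + decision network with per-sample knockout masks."""

    def __init__(self, config: NetworkConfig = NetworkConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        f = c.conv_filters
        self.conv1 = Conv2D(rng, 1, f, name="vision/conv1")
        self.bn1 = BatchNorm(f, name="vision/bn1")
        self.sep2 = SeparableConv2D(rng, f, f, name="vision/sep2")
        self.bn2 = BatchNorm(f, name="vision/bn2")
        self.sep3 = SeparableConv2D(rng, f, f, name="vision/sep3")
        self.bn3 = BatchNorm(f, name="vision/bn3")
        h, w = c.rows, c.cols
        for _ in range(3):
            h = -(-h // 2)
            w = -(-w // 2)
        self._spatial = h * w
        self.readout = FactorizedReadout(rng, self._spatial, f, c.n_embed,
                                         name="vision/readout")
        self.fc1 = Dense(rng, c.n_embed * c.n_history, c.bottleneck_hidden,
                         name="bottleneck/fc1")
        self.bnf1 = BatchNorm(c.bottleneck_hidden, name="bottleneck/bn1")
        self.fc2 = Dense(rng, c.bottleneck_hidden, c.n_bottleneck,
                         name="bottleneck/fc2")
        self.bnf2 = BatchNorm(c.n_bottleneck, name="bottleneck/bn2")
        self.dec = []
        cin = c.n_bottleneck
        for i in range(3):
            self.dec.append(Dense(rng, cin, c.decision_width, name=f"decision/fc{i+1}"))
            self.dec.append(BatchNorm(c.decision_width, name=f"decision/bn{i+1}"))
            cin = c.decision_width
        self.head_vel = Dense(rng, cin, c.n_velocity, name="head/velocity")
        self.head_song = Dense(rng, cin, c.n_song, name="head/song")
        self._relus = {}  # rectifiers instantiated per site (cache backprop masks)
        # z-scoring statistics for the velocity outputs (control training data)
        self.vel_mean = np.zeros(c.n_velocity, dtype=np.float32)
        self.vel_std = np.ones(c.n_velocity, dtype=np.float32)

    # -- parameter plumbing -------------------------------------------------

    def _layers(self):
        layers = [self.conv1, self.bn1, self.sep2, self.bn2, self.sep3,
                  self.bn3, self.readout, self.fc1, self.bnf1, self.fc2,
                  self.bnf2, *self.dec, self.head_vel, self.head_song]
        return layers

    def parameters(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def get_weights(self):
        state = [p.value.copy() for p in self.parameters()]
        bn_state = []
        for layer in self._layers():
            if isinstance(layer, BatchNorm):
                bn_state.append((layer.running_mean.copy(), layer.running_var.copy()))
        return state, bn_state, (self.vel_mean.copy(), self.vel_std.copy())

    def set_weights(self, snapshot):
        state, bn_state, (vm, vs) = snapshot
        for p, v in zip(self.parameters(), state):
            p.value[...] = v
        i = 0
        for layer in self._layers():
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = bn_state[i][0]
                layer.running_var[...] = bn_state[i][1]
                i += 1
        self.vel_mean[...] = vm
        self.vel_std[...] = vs

    def parameter_counts(self) -> dict:
        counts = {}
        for layer in self._layers():
            n = sum(int(np.prod(p.value.shape)) for p in layer.params())
            if n:
                counts[layer.name] = n
        return counts

    def set_output_scaling(self, mean, std):
        self.vel_mean = np.asarray(mean, dtype=np.float32)
        self.vel_std = np.asarray(std, dtype=np.float32)

    # -- forward / backward -------------------------------------------------

    def _relu_for(self, key):
        if key not in self._relus:
            self._relus[key] = ReLU()
        return self._relus[key]

    def embed_frames(self, frames: np.ndarray, training: bool = False) -> np.ndarray:
        """Vision network on a stack of single frames (M, rows, cols) ->
        (M, n_embed). Input must already be re-centred (background 0)."""
        x = frames[..., None].astype(np.float32) / 255.0
        x = self.conv1.forward(x, training)
        x = self.bn1.forward(x, training)
        x = self._relu_for("v1").forward(x, training)
        x = self.sep2.forward(x, training)
        x = self.bn2.forward(x, training)
        x = self._relu_for("v2").forward(x, training)
        x = self.sep3.forward(x, training)
        x = self.bn3.forward(x, training)
        x = self._relu_for("v3").forward(x, training)
        return self.readout.forward(x, training)

    def _embed_backward(self, dembed):
        dx = self.readout.backward(dembed)
        dx = self._relu_for("v3").backward(dx)
        dx = self.bn3.backward(dx)
        dx = self.sep3.backward(dx)
        dx = self._relu_for("v2").backward(dx)
        dx = self.bn2.backward(dx)
        dx = self.sep2.backward(dx)
        dx = self._relu_for("v1").backward(dx)
        dx = self.bn1.backward(dx)
        self.conv1.backward(dx)

    def bottleneck_from_embedding(self, emb_seq: np.ndarray,
                                  training: bool = False) -> np.ndarray:
        """(N, n_history * n_embed) concatenated embeddings -> non-negative
        bottleneck activities (N, n_bottleneck)."""
        x = self.fc1.forward(emb_seq, training)
        x = self.bnf1.forward(x, training)
        x = self._relu_for("b1").forward(x, training)
        x = self.fc2.forward(x, training)
        x = self.bnf2.forward(x, training)
        return self._relu_for("b2").forward(x, training)

    def decision_from_bottleneck(self, activities: np.ndarray,
                                 training: bool = False):
        """Masked bottleneck activities -> (velocities z-space, song probs,
        song logits)."""
        x = activities
        for i in range(3):
            x = self.dec[2 * i].forward(x, training)
            x = self.dec[2 * i + 1].forward(x, training)
            x = self._relu_for(f"d{i}").forward(x, training)
        vel = self.head_vel.forward(x, training)
        logits = self.head_song.forward(x, training)
        return vel, _sigmoid(logits), logits

    def forward(self, images: np.ndarray, mask: np.ndarray | None = None,
                training: bool = False):
        """Full forward pass.

        ``images``: (N, n_history, rows, cols), re-centred.
        ``mask``: (N, n_bottleneck) knockout masks (all ones if None).
        Returns (bottleneck activities before masking, velocities in z-space,
        song probabilities).
        """
        N, T, H, W = images.shape
        c = self.config
        if (T, H, W) != (c.n_history, c.rows, c.cols):
            raise ValueError(
                f"expected (N, {c.n_history}, {c.rows}, {c.cols}) input, got {images.shape}")
        emb = self.embed_frames(images.reshape(N * T, H, W), training)
        emb_seq = emb.reshape(N, T * c.n_embed)
        acts = self.bottleneck_from_embedding(emb_seq, training)
        if mask is None:
            mask = np.ones((N, c.n_bottleneck), dtype=np.float32)
        self._mask = mask
        self._acts = acts
        vel, song_p, logits = self.decision_from_bottleneck(acts * mask, training)
        self._song_p = song_p
        return acts, vel, song_p

    def backward(self, dvel: np.ndarray, dlogits: np.ndarray):
        """Backward pass for gradients w.r.t. velocity outputs and song
        logits; accumulates parameter gradients."""
        dx = self.head_vel.backward(dvel) + self.head_song.backward(dlogits)
        for i in range(2, -1, -1):
            dx = self._relu_for(f"d{i}").backward(dx)
            dx = self.dec[2 * i + 1].backward(dx)
            dx = self.dec[2 * i].backward(dx)
        dacts = dx * self._mask  # masked units receive zero gradient
        dx = self._relu_for("b2").backward(dacts)
        dx = self.bnf2.backward(dx)
        dx = self.fc2.backward(dx)
        dx = self._relu_for("b1").backward(dx)
        dx = self.bnf1.backward(dx)
        demb_seq = self.fc1.backward(dx)
        c = self.config
        N = demb_seq.shape[0]
        self._embed_backward(demb_seq.reshape(N * c.n_history, c.n_embed))

    def predict(self, images: np.ndarray, mask: np.ndarray | None = None,
                batch_size: int = 256):
        """Inference in chunks; velocities are de-standardized to native
        units. Returns (activities, velocities, song probabilities)."""
        acts, vels, songs = [], [], []
        for i in range(0, images.shape[0], batch_size):
            a, v, s = self.forward(images[i:i + batch_size],
                                   None if mask is None else mask[i:i + batch_size],
                                   training=False)
            acts.append(a)
            vels.append(v * self.vel_std + self.vel_mean)
            songs.append(s)
        return (np.concatenate(acts), np.concatenate(vels), np.concatenate(songs))


# ---------------------------------------------------------------------------
# batching, training, evaluation
# ---------------------------------------------------------------------------

SONG_CLASSES = ("sine", "pulse", "none")


def _song_class_quota(n: int):
    base = n // 3
    quota = [base, base, base]
    for i in range(n - 3 * base):
        quota[i] += 1
    return dict(zip(SONG_CLASSES, quota))


def make_batch(dataset, genotype_map: GenotypeMap, rng, mode: str = "knockout",
               n_per_class: int = 12, augment: bool = True):
    """Assemble one balanced training batch.

    ``dataset`` must expose ``genotypes`` (list including the control label),
    ``sample_ids(genotype, song_class)`` -> index array (song classes "sine",
    "pulse", "none") and ``get_samples(genotype, ids)`` -> (images, targets).
    Each genotype contributes ``n_per_class`` samples, split as evenly as
    possible across song classes (falling back to whatever classes exist,
    sampling with replacement when a pool is exhausted).
    """
    images, targets, masks = [], [], []
    n_units = genotype_map.n_units
    for genotype in dataset.genotypes:
        quota = _song_class_quota(n_per_class)
        chosen = []
        pools = {sc: dataset.sample_ids(genotype, sc) for sc in SONG_CLASSES}
        nonempty = [sc for sc in SONG_CLASSES if len(pools[sc]) > 0]
        if not nonempty:
            raise ValueError(f"no samples for genotype {genotype!r}")
        for sc in SONG_CLASSES:
            want = quota[sc]
            pool = pools[sc]
            if len(pool) == 0:
                pool = pools[nonempty[int(rng.integers(len(nonempty)))]]
            chosen.extend(rng.choice(pool, size=want, replace=len(pool) < want))
        imgs, tgts = dataset.get_samples(genotype, np.asarray(chosen))
        if augment:
            flip = rng.random(len(chosen)) < 0.5
            imgs = imgs.copy()
            tgts = tgts.copy()
            imgs[flip] = imgs[flip][..., ::-1]
            tgts[flip, 1] *= -1
            tgts[flip, 2] *= -1
        for j in range(len(chosen)):
            if mode == "knockout":
                m = genotype_map.mask_for(genotype)
            elif mode == "dropout":
                m = np.ones(n_units, dtype=np.float32)
                if genotype != genotype_map.control_label:
                    m[int(rng.integers(n_units))] = 0.0
            elif mode in ("no_knockout", "untrained"):
                m = np.ones(n_units, dtype=np.float32)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            masks.append(m)
        images.append(imgs)
        targets.append(tgts)
    return (np.concatenate(images), np.concatenate(targets),
            np.stack(masks).astype(np.float32))


def r_squared(pred, target):
    """Squared Pearson correlation over finite frames; NaN if degenerate."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    ok = np.isfinite(pred) & np.isfinite(target)
    if ok.sum() < 2:
        return float("nan")
    p, t = pred[ok], target[ok]
    if np.std(p) == 0 or np.std(t) == 0:
        return float("nan")
    return float(np.corrcoef(p, t)[0, 1] ** 2)


def _bce(p, y, eps=1e-7):
    p = np.clip(p, eps, 1 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def song_score(pred_p, target):
    """1 minus cross-entropy normalized by the base-rate predictor's
    cross-entropy (1 = perfect, 0 = no better than the mean rate)."""
    rate = float(np.mean(target))
    if rate in (0.0, 1.0):
        return float("nan")
    return 1.0 - _bce(pred_p, target) / _bce(np.full_like(pred_p, rate), target)


def _loss_and_grads(model, images, targets_z, masks):
    acts, vel, song_p = model.forward(images, masks, training=True)
    N = images.shape[0]
    vt = targets_z[:, :3]
    st = targets_z[:, 3:]
    mse = float(np.mean((vel - vt) ** 2))
    bce = _bce(song_p, st)
    dvel = (2.0 / (N * 3)) * (vel - vt).astype(np.float32)
    dlogits = ((song_p - st) / (N * 3)).astype(np.float32)
    model.zero_grad()
    model.backward(dvel, dlogits)
    return mse, bce


def _sgd_step(model, lr, momentum):
    for p in model.parameters():
        p.velocity = momentum * p.velocity - lr * p.grad
        p.value += p.velocity


def train(model: OneToOneNetwork, dataset, genotype_map: GenotypeMap,
          cfg: TrainConfig):
    """Train with early stopping on validation forward-velocity R-squared.

    ``dataset`` additionally provides ``control_velocity_stats()`` ->
    (mean, std) over control training frames and ``validation_set()`` ->
    (images, targets) from held-out control data. Returns (model, log), the
    model carrying the best-validation weights. ``mode='untrained'`` returns
    the initial weights untouched.
    """
    log = []
    if cfg.mode == "untrained":
        return model, log
    rng = np.random.default_rng(cfg.seed)
    mean, std = dataset.control_velocity_stats()
    std = np.where(np.asarray(std) > 0, std, 1.0)  # constant outputs: unit scale
    model.set_output_scaling(mean, std)
    val_images, val_targets = dataset.validation_set()

    def val_r2():
        _, vel, _ = model.predict(val_images)
        return r_squared(vel[:, 0], val_targets[:, 0])

    best = (-np.inf, model.get_weights())
    bad = 0
    for epoch in range(cfg.max_epochs):
        mse_sum = bce_sum = 0.0
        for _ in range(cfg.batches_per_epoch):
            images, targets, masks = make_batch(
                dataset, genotype_map, rng, mode=cfg.mode,
                n_per_class=cfg.n_per_class, augment=cfg.augment)
            tz = targets.copy().astype(np.float32)
            tz[:, :3] = (tz[:, :3] - model.vel_mean) / model.vel_std
            mse, bce = _loss_and_grads(model, images, tz, masks)
            if not np.isfinite(mse) or not np.isfinite(bce):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (mse={mse}, bce={bce})")
            _sgd_step(model, cfg.learning_rate, cfg.momentum)
            mse_sum += mse
            bce_sum += bce
        r2 = val_r2()
        log.append({"epoch": epoch, "mse": mse_sum / cfg.batches_per_epoch,
                    "bce": bce_sum / cfg.batches_per_epoch,
                    "val_forward_r2": r2})
        if np.isfinite(r2) and r2 > best[0]:
            best = (r2, model.get_weights())
            bad = 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    model.set_weights(best[1])
    return model, log


def genotype_mean_shifts(model: OneToOneNetwork, dataset,
                         genotype_map: GenotypeMap) -> "object":
    """Predicted vs observed genotype-mean behaviour.

    For every genotype, the model predicts its held-out test frames with the
    genotype's knockout mask applied (control unmasked); returns a DataFrame
    indexed by genotype with observed and predicted means per output —
    the population-level comparison of silencing effects.
    """
    import pandas as pd

    rows = {}
    for genotype in dataset.genotypes:
        images, targets = dataset.test_set(genotype)
        m = np.tile(genotype_map.mask_for(genotype), (images.shape[0], 1))
        _, vel, song = model.predict(images, m)
        pred = np.concatenate([vel.mean(axis=0), song.mean(axis=0)])
        obs = np.nanmean(targets, axis=0)
        rows[genotype] = np.concatenate([obs, pred])
    names = ("forward", "lateral", "angular", "sine", "pfast", "pslow")
    cols = [f"observed_{n}" for n in names] + [f"predicted_{n}" for n in names]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def evaluate(model: OneToOneNetwork, images: np.ndarray, targets: np.ndarray,
             mask: np.ndarray | None = None) -> dict:
    """Held-out scores: squared Pearson R^2 for the three velocities and
    1 - normalized cross-entropy for the three songs."""
    _, vel, song = model.predict(images, mask)
    out = {}
    names = ("forward", "lateral", "angular")
    for i, name in enumerate(names):
        out[name] = r_squared(vel[:, i], targets[:, i])
    for i, name in enumerate(("sine", "pfast", "pslow")):
        out[name] = song_score(song[:, i], targets[:, 3 + i])
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: OneToOneNetwork, path) -> None:
    import h5py
    from dataclasses import asdict

    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(asdict(model.config))
        for p in model.parameters():
            f.create_dataset(f"weights/{p.name}", data=p.value)
        for layer in model._layers():
            if isinstance(layer, BatchNorm):
                f.create_dataset(f"running/{layer.name}/mean", data=layer.running_mean)
                f.create_dataset(f"running/{layer.name}/var", data=layer.running_var)
        f.create_dataset("scaling/vel_mean", data=model.vel_mean)
        f.create_dataset("scaling/vel_std", data=model.vel_std)


def load_checkpoint(path) -> OneToOneNetwork:
    import h5py

    with h5py.File(path, "r") as f:
        config = NetworkConfig(**json.loads(f.attrs["config"]))
        model = OneToOneNetwork(config)
        for p in model.parameters():
            p.value[...] = f[f"weights/{p.name}"][()]
        for layer in model._layers():
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = f[f"running/{layer.name}/mean"][()]
                layer.running_var[...] = f[f"running/{layer.name}/var"][()]
        model.vel_mean = f["scaling/vel_mean"][()]
        model.vel_std = f["scaling/vel_std"][()]
    return model
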