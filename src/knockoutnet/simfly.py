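"""Synthetic ground-truth sensorimotor system.

A simulated fly with ``n_units`` visual units of known tuning (non-negative
Gaussian bumps over female size, position and rotation, with optional
sensitivity to the one-frame change in size and position) and a known linear
readout W (n_units x 6) onto the six behavioural outputs. Sessions consist
of a smooth bounded random walk of the female parameters, the rendered
panorama frames, and a behaviour table

    velocities = g(params) @ W[:, :3] + Gaussian noise
    P(song)    = sigmoid(gain * g(params) @ W[:, 3:] + bias), sampled Bernoulli

with the genotype's unit forced to zero before the readout — exactly the
experimental design knockout training assumes. A pose-level synthesis path
turns prescribed velocities into two-fly joint tracks so the behaviour
extraction code is exercised on its native input.

Everything is seeded and reproducible; the simulator feeds every downstream
consumer (behaviour extraction, network training, probing, neural
evaluation) without any external data. The reference recovery configuration
is deliberately small: 5 units, the reduced 16 x 57 panorama, a few minutes
of data per genotype.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import render as rnd
from .behaviour import (BEHAVIOUR_COLUMNS, PoseTrack, courtship_features,
                        courtship_mask, make_splits)
from .render import REDUCED_RES, RenderConfig, place_female, render_params_array

__all__ = [
    "GroundTruth",
    "make_ground_truth",
    "SyntheticSession",
    "simulate_session",
    "synthesize_pose",
    "SyntheticDataset",
    "build_reference_dataset",
    "recovery_score",
    "reference_recovery_experiment",
]

FPS = 30.0


@dataclass
class GroundTruth:
    """Known unit tuning and unit-to-behaviour readout."""

    n_units: int
    centres: np.ndarray          # (n, 3) over (size, position, rotation)
    widths: np.ndarray           # (n, 3)
    amplitudes: np.ndarray       # (n,)
    deriv_gain: np.ndarray       # (n, 2) sensitivity to |dsize|, |dposition|
    W: np.ndarray                # (n, 6) readout
    velocity_noise: float = 0.5  # mm/s-scale Gaussian noise on velocities
    song_gain: float = 3.0
    # negative bias keeps baseline song sparse; units drive song bouts
    song_bias: np.ndarray = field(default_factory=lambda: np.full(3, -2.0))
    seed: int = 0

    def tuning(self, params: np.ndarray, dparams: np.ndarray | None = None) -> np.ndarray:
        """Evaluate non-negative unit tuning g on (T, 3) parameter rows.

        ``dparams`` (T, 2): one-frame changes of size and position; omit (or
        pass zeros) for static stimuli. Rotation distance is wrapped.
        """
        p = np.asarray(params, dtype=float)
        d2 = np.zeros((p.shape[0], self.n_units))
        for k in range(3):
            diff = p[:, k, None] - self.centres[None, :, k]
            if k == 2:
                diff = (diff + 180.0) % 360.0 - 180.0
            d2 += (diff / self.widths[None, :, k]) ** 2
        g = self.amplitudes[None, :] * np.exp(-0.5 * d2)
        if dparams is not None:
            dp = np.abs(np.asarray(dparams, dtype=float))
            g = g + dp @ self.deriv_gain.T
        return g

    def to_json(self) -> str:
        return json.dumps({
            "n_units": self.n_units,
            "centres": self.centres.tolist(),
            "widths": self.widths.tolist(),
            "amplitudes": self.amplitudes.tolist(),
            "deriv_gain": self.deriv_gain.tolist(),
            "W": self.W.tolist(),
            "velocity_noise": self.velocity_noise,
            "song_gain": self.song_gain,
            "song_bias": self.song_bias.tolist(),
            "seed": self.seed,
        })

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            d["n_units"], np.array(d["centres"]), np.array(d["widths"]),
            np.array(d["amplitudes"]), np.array(d["deriv_gain"]),
            np.array(d["W"]), d["velocity_noise"], d["song_gain"],
            np.array(d["song_bias"]), d["seed"],
        )


def make_ground_truth(n_units: int, seed: int = 0,
                      derivative_fraction: float = 0.0) -> GroundTruth:
    """Draw a ground truth with tuning centres spread over the parameter
    ranges the trajectory visits and a readout in which every behavioural
    output depends on at least two units."""
    if n_units < 2:
        raise ValueError("need at least 2 units")
    rng = np.random.default_rng(seed)
    # stratified centres: shuffle a regular grid per axis so units tile the space
    centres = np.column_stack([
        rng.permuted(np.linspace(0.5, 0.95, n_units)),
        rng.permuted(np.linspace(-0.45, 0.45, n_units)),
        rng.permuted(np.linspace(-120.0, 120.0, n_units)),
    ])
    widths = np.column_stack([
        rng.uniform(0.12, 0.25, n_units),
        rng.uniform(0.18, 0.35, n_units),
        rng.uniform(50.0, 110.0, n_units),
    ])
    amplitudes = rng.uniform(0.8, 1.2, n_units)
    deriv_gain = np.zeros((n_units, 2))
    n_deriv = int(round(derivative_fraction * n_units))
    if n_deriv:
        idx = rng.choice(n_units, size=n_deriv, replace=False)
        deriv_gain[idx] = rng.uniform(0.5, 2.0, size=(n_deriv, 2))
    # readout: each output driven by >= 2 units (population-code regime)
    W = np.zeros((n_units, 6))
    for b in range(6):
        k = int(rng.integers(2, n_units + 1))
        units = rng.choice(n_units, size=k, replace=False)
        W[units, b] = rng.normal(0.0, 2.5, size=k)
        # ensure two entries are meaningfully nonzero
        while np.sum(np.abs(W[:, b]) > 0.25) < 2:
            W[units, b] = rng.normal(0.0, 2.5, size=k)
    return GroundTruth(n_units, centres, widths, amplitudes, deriv_gain, W,
                       seed=seed)


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSession:
    params: np.ndarray            # (T, 3) female parameters
    g_true: np.ndarray            # (T, n_units) ground-truth unit activity
    behaviour: pd.DataFrame       # six output columns
    pose: PoseTrack
    genotype: str
    seed: int
    frames: np.ndarray | None = None
    courtship: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


def _parameter_walk(T: int, rng) -> np.ndarray:
    """Smooth bounded random walk of (size, position, rotation):
    mean-reverting steps with reflection at the bounds."""
    # mean-reversion time constant ~200 frames; stationary spread covers the
    # tuning ranges (std ~ sigma / sqrt(2 theta))
    bounds = np.array([[0.4, 1.0], [-0.55, 0.55], [-170.0, 170.0]])
    mu = np.array([0.7, 0.0, 0.0])
    theta = 0.005
    sigma = np.array([0.015, 0.03, 9.0])
    x = np.empty((T, 3))
    x[0] = mu + rng.normal(0, sigma * 4)
    for t in range(1, T):
        step = theta * (mu - x[t - 1]) + sigma * rng.normal(size=3)
        x[t] = x[t - 1] + step
        for k in range(3):
            lo, hi = bounds[k]
            if x[t, k] < lo:
                x[t, k] = lo + (lo - x[t, k])
            elif x[t, k] > hi:
                x[t, k] = hi - (x[t, k] - hi)
    return np.clip(x, bounds[:, 0], bounds[:, 1])


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def synthesize_pose(forward: np.ndarray, lateral: np.ndarray,
                    angular: np.ndarray, params: np.ndarray,
                    song: np.ndarray, genotype: str = "control",
                    session_id: str = "synthetic", fps: float = FPS,
                    body_length_mm: float = 1.0) -> PoseTrack:
    """Two-fly pose tracks realizing prescribed male velocities and female
    egocentric parameters exactly (round-trips through the behaviour
    extraction and egocentric-geometry code)."""
    T = forward.shape[0]
    psi = np.zeros(T)
    pos = np.zeros((T, 2))
    for t in range(1, T):
        psi[t] = psi[t - 1] - math.radians(angular[t]) / fps
        h = np.array([math.cos(psi[t]), math.sin(psi[t])])
        r = np.array([h[1], -h[0]])
        pos[t] = pos[t - 1] + (forward[t] * h + lateral[t] * r) / fps
    headings = np.column_stack([np.cos(psi), np.sin(psi)])
    male_thorax = pos
    male_head = pos + body_length_mm * headings
    female_thorax = np.empty((T, 2))
    female_head = np.empty((T, 2))
    for t in range(T):
        fp = rnd.FemaleParams(*params[t])
        body, fh = place_female(male_head[t], headings[t], fp)
        female_thorax[t] = body
        female_head[t] = body + 0.5 * body_length_mm * fh
    return PoseTrack(male_head, male_thorax, female_head, female_thorax,
                     song, genotype, session_id, fps)


def simulate_session(gt: GroundTruth, genotype: str, duration_s: float,
                     seed: int = 0,
                     render_config: RenderConfig | None = REDUCED_RES,
                     fps: float = FPS,
                     control_label: str = "control") -> SyntheticSession:
    """Simulate one courtship session for a control or unit-silenced fly.

    ``genotype`` is ``control`` or ``"unit<k>"`` (unit index k silenced).
    Frames are rendered unless ``render_config`` is None.
    """
    if duration_s < 20.0:
        raise ValueError("session must cover at least one 20-s courtship window")
    rng = np.random.default_rng(seed)
    T = int(round(duration_s * fps))
    params = _parameter_walk(T, rng)
    dparams = np.zeros((T, 2))
    dparams[1:] = np.diff(params[:, :2], axis=0)
    g = gt.tuning(params, dparams)
    if genotype != control_label:
        unit = int(genotype.removeprefix("unit"))
        g = g.copy()
        g[:, unit] = 0.0
    vel = g @ gt.W[:, :3] + rng.normal(0, gt.velocity_noise, size=(T, 3))
    song_p = _sigmoid(gt.song_gain * (g @ gt.W[:, 3:]) + gt.song_bias)
    song = (rng.random((T, 3)) < song_p).astype(float)
    behaviour = pd.DataFrame(
        np.column_stack([vel, song]), columns=list(BEHAVIOUR_COLUMNS))
    pose = synthesize_pose(vel[:, 0], vel[:, 1], vel[:, 2], params, song,
                           genotype, f"{genotype}-{seed}", fps)
    frames = None
    if render_config is not None:
        frames = render_params_array(params, render_config)
    feats = courtship_features(pose)
    mask = courtship_mask(feats, fps=fps)
    return SyntheticSession(params, g, behaviour, pose, genotype, seed,
                            frames, mask)


# ---------------------------------------------------------------------------
# dataset protocol for network training
# ---------------------------------------------------------------------------

class SyntheticDataset:
    """Adapts simulated sessions + splits to the training batch protocol."""

    def __init__(self, sessions, splits, n_history: int = 10,
                 control_label: str = "control"):
        self.sessions = list(sessions)
        self.splits = splits
        self.n_history = n_history
        self.control_label = control_label
        self.genotypes = sorted(splits.train.keys(),
                                key=lambda g: (g != control_label, g))
        # index samples: only frames with a full input history
        self._samples = {}     # genotype -> (n, 2) [session, frame]
        self._by_song = {}     # (genotype, song_class) -> sample row indices
        for g in self.genotypes:
            pairs = splits.train[g]
            pairs = pairs[pairs[:, 1] >= n_history - 1]
            self._samples[g] = pairs
            beh = [self.sessions[s].behaviour for s in range(len(self.sessions))]
            sine = np.array([beh[s].iat[f, 3] > 0 for s, f in pairs])
            pulse = np.array([(beh[s].iat[f, 4] > 0 or beh[s].iat[f, 5] > 0)
                              for s, f in pairs]) & ~sine
            none = ~sine & ~pulse
            self._by_song[(g, "sine")] = np.flatnonzero(sine)
            self._by_song[(g, "pulse")] = np.flatnonzero(pulse)
            self._by_song[(g, "none")] = np.flatnonzero(none)

    def sample_ids(self, genotype, song_class):
        return self._by_song[(genotype, song_class)]

    def _windows(self, pairs):
        out_imgs = []
        out_tgts = []
        offs = np.arange(self.n_history - 1, -1, -1)
        for s, f in pairs:
            sess = self.sessions[s]
            idx = np.maximum(f - offs, 0)
            out_imgs.append(sess.frames[idx])
            out_tgts.append(sess.behaviour.iloc[f].to_numpy(dtype=np.float32))
        return np.stack(out_imgs), np.stack(out_tgts)

    def get_samples(self, genotype, ids):
        pairs = self._samples[genotype][np.asarray(ids, dtype=int)]
        return self._windows(pairs)

    def control_velocity_stats(self):
        pairs = self._samples[self.control_label]
        beh = np.stack([
            self.sessions[s].behaviour.iloc[f, :3].to_numpy() for s, f in pairs
        ])
        return beh.mean(axis=0), beh.std(axis=0)

    def _held_out(self, table, genotype):
        pairs = table[genotype]
        pairs = pairs[pairs[:, 1] >= self.n_history - 1]
        return self._windows(pairs)

    def validation_set(self):
        return self._held_out(self.splits.validation, self.control_label)

    def test_set(self, genotype=None):
        return self._held_out(self.splits.test, genotype or self.control_label)


def build_reference_dataset(gt: GroundTruth, seed: int = 0,
                            duration_s: float = 300.0,
                            render_config: RenderConfig = REDUCED_RES,
                            test_frames: int = 900,
                            train_cap: int = 600000):
    """Simulate one session per genotype (control + each silenced unit),
    build splits at the reduced reference budgets, and wrap everything as a
    training dataset. Returns (dataset, sessions)."""
    genotypes = ["control"] + [f"unit{i}" for i in range(gt.n_units)]
    sessions = [
        simulate_session(gt, g, duration_s, seed=seed * 1009 + i,
                         render_config=render_config)
        for i, g in enumerate(genotypes)
    ]
    splits = make_splits(
        [{"genotype": s.genotype, "courtship": s.courtship} for s in sessions],
        seed=seed, test_frames=test_frames, val_frames=test_frames,
        train_cap=train_cap,
    )
    return SyntheticDataset(sessions, splits), sessions


# ---------------------------------------------------------------------------
# ground-truth recovery scoring
# ---------------------------------------------------------------------------

def _pearson(a, b):
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def recovery_score(model, gt: GroundTruth,
                   render_config: RenderConfig = REDUCED_RES,
                   grid_size: int = 20,
                   eval_images: np.ndarray | None = None,
                   eval_targets: np.ndarray | None = None,
                   model_tensors: np.ndarray | None = None) -> dict:
    """Score how well a trained model recovers the ground truth, unit by unit.

    Tuning recovery: sign- and scale-normalized Pearson correlation (the
    absolute correlation) between each model unit's tuning tensor and the
    matched ground-truth unit's tuning evaluated on the same grid; a constant
    tensor recovers nothing and scores 0. Contribution recovery (if held-out
    control data are given):
    Spearman rank correlation between the CLIP normalized changes and the
    ground-truth |W| magnitudes — pooled over all unit x output pairs (the
    stable headline statistic) and per behavioural output (noisier, n_units
    points each). ``eval_targets`` should be the noise-free ground-truth
    output traces (velocities W'g and song probabilities), so every output is
    scored as a continuous trace by R^2 and the CLIP curves are
    well-conditioned.
    """
    from scipy.stats import spearmanr

    from .probe import clip, tuning_grid_params, tuning_maps

    grid = tuning_grid_params(grid_size)
    if model_tensors is None:
        model_tensors = tuning_maps(model, render_config, grid_size)
    model_t = model_tensors
    gt_t = gt.tuning(grid).T.reshape(gt.n_units, grid_size, grid_size, grid_size)
    n = min(model_t.shape[0], gt.n_units)
    tuning_corr = np.array([abs(_pearson(model_t[i], gt_t[i])) for i in range(n)])
    tuning_corr = np.nan_to_num(tuning_corr)
    out = {
        "tuning_correlations": tuning_corr,
        "mean_tuning_correlation": float(np.mean(tuning_corr)),
    }
    if eval_images is not None:
        acts, _, _ = model.predict(eval_images)
        rank_corrs = []
        clip_table = np.zeros((n, 6))
        for b in range(6):

            def decision_fn(A, b=b):
                vel, song_p, _ = model.decision_from_bottleneck(
                    A.astype(np.float32), training=False)
                return vel[:, b] if b < 3 else song_p[:, b - 3]

            res = clip(decision_fn, acts, eval_targets[:, b], kind="velocity")
            clip_table[:, b] = res.normalized_change[:n]
            changes = res.normalized_change[:n]
            if np.ptp(changes) == 0:  # no measurable contributions: no recovery
                rank_corrs.append(0.0)
            else:
                rank_corrs.append(
                    spearmanr(changes, np.abs(gt.W[:n, b])).statistic)
        out["clip_rank_correlations"] = np.array(rank_corrs)
        out["mean_clip_rank_correlation"] = float(np.nanmean(rank_corrs))
        pooled = spearmanr(clip_table.ravel(), np.abs(gt.W[:n]).ravel()).statistic
        out["clip_rank_correlation_pooled"] = float(np.nan_to_num(pooled))
        out["clip_table"] = clip_table
    return out


def clean_targets(gt: GroundTruth, sessions, pairs) -> np.ndarray:
    """Noise-free ground-truth output traces for (session, frame) pairs:
    velocities W'g and song probabilities (continuous, not sampled)."""
    g = np.stack([sessions[s].g_true[f] for s, f in pairs])
    vel = g @ gt.W[:, :3]
    song_p = _sigmoid(gt.song_gain * (g @ gt.W[:, 3:]) + gt.song_bias)
    return np.column_stack([vel, song_p])


def reference_recovery_experiment(seed: int = 1, n_units: int = 5,
                                  duration_s: float = 300.0,
                                  max_epochs: int = 12,
                                  grid_size: int = 16,
                                  modes=("knockout", "no_knockout", "untrained"),
                                  verbose: bool = False) -> dict:
    """Ground-truth recovery comparison across training procedures.

    The reference configuration: ``n_units`` ground-truth units, the reduced
    16 x 57 panorama, one ~``duration_s`` session per genotype (~54k frames
    total at the default), 16-filter vision network, learning rate 1e-2, and
    no mirror augmentation (the synthetic ground truth is not
    mirror-symmetric). All modes share the same weight initialization and
    data order. Returns per-mode recovery scores plus the shared dataset
    sizes.
    """
    from .network import (GenotypeMap, NetworkConfig, OneToOneNetwork,
                          TrainConfig)
    from .network import train as train_fn

    gt = make_ground_truth(n_units, seed)
    dataset, sessions = build_reference_dataset(gt, seed, duration_s=duration_s)
    cfg = NetworkConfig(n_bottleneck=n_units, rows=REDUCED_RES.rows,
                        cols=REDUCED_RES.retained_columns, conv_filters=16)
    gmap = GenotypeMap(dataset.genotypes, n_units)
    eval_images, _ = dataset.test_set("control")
    test_pairs = dataset.splits.test["control"]
    test_pairs = test_pairs[test_pairs[:, 1] >= dataset.n_history - 1]
    eval_targets = clean_targets(gt, sessions, test_pairs)
    results = {"seed": seed, "n_units": n_units,
               "n_train_frames": int(sum(len(v) for v in dataset.splits.train.values()))}
    for mode in modes:
        model = OneToOneNetwork(cfg, seed=seed)
        tc = TrainConfig(mode=mode, learning_rate=1e-2, batches_per_epoch=50,
                         max_epochs=max_epochs, patience=3, augment=False,
                         seed=seed)
        model, log = train_fn(model, dataset, gmap, tc)
        score = recovery_score(model, gt, REDUCED_RES, grid_size,
                               eval_images, eval_targets)
        if verbose:
            print(mode, "val:", [round(r["val_forward_r2"], 3) for r in log])
        from .network import genotype_mean_shifts

        shifts = genotype_mean_shifts(model, dataset, gmap)
        shift_corr = _pearson(
            shifts["observed_forward"].to_numpy(),
            shifts["predicted_forward"].to_numpy())
        results[mode] = {
            "genotype_shift_correlation": float(np.nan_to_num(shift_corr)),
            "mean_tuning_correlation": score["mean_tuning_correlation"],
            "mean_clip_rank_correlation": score["mean_clip_rank_correlation"],
            "clip_rank_correlation_pooled": score["clip_rank_correlation_pooled"],
            "tuning_correlations": score["tuning_correlations"],
            "clip_rank_correlations": score["clip_rank_correlations"],
            "log": log,
        }
    return results
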