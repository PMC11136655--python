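"""Behavioural variables, courtship-frame classification and data splits.

Six per-frame output variables describe the male: forward velocity (one-frame
displacement projected on his thorax-to-head heading, mm/s), lateral velocity
(orthogonal projection, rightward positive), angular velocity (heading change
per frame scaled to deg/s, rightward turns positive), and three binary song
indicators (sine, Pfast, Pslow).

"Courtship frames" are frames passing any of four criteria evaluated over a
centred 20-s window (truncated at session edges): mean male-female thorax
distance < 5 mm; song fraction > 0.1; mean absolute female azimuth from the
male's head <= 45 degrees; mean approach speed >= 4.5 mm/s. Training and
evaluation are restricted to courtship frames.

Splits follow the window protocol: per genotype, non-overlapping 3-s test
windows up to a 15-min budget (27,000 frames at 30 Hz); control additionally
receives an equally sized validation set; remaining courtship frames are
capped at 600,000 per genotype for training, and no test frame's 10-frame
input window overlaps any training frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PoseTrack",
    "BEHAVIOUR_COLUMNS",
    "extract_behaviour",
    "courtship_features",
    "courtship_mask",
    "SplitSpec",
    "make_splits",
    "augment_flip",
]

FPS = 30.0
BEHAVIOUR_COLUMNS = ("forward", "lateral", "angular", "sine", "pfast", "pslow")

#: pairs recorded per silenced-line condition in the courtship dataset
PAIRS_PER_CONDITION = {
    "LC4": 17, "LC6": 19, "LC9": 18, "LC10a": 13, "LC10ad": 15, "LC10bc": 16,
    "LC10d": 16, "LC11": 14, "LC12": 14, "LC13": 17, "LC15": 16, "LC16": 19,
    "LC17": 14, "LC18": 14, "LC20": 16, "LC21": 15, "LC22": 22, "LC24": 18,
    "LC25": 16, "LC26": 18, "LC31": 24, "LPLC1": 16, "LPLC2": 17,
    "control": 75,
}


@dataclass
class PoseTrack:
    """Per-frame joint coordinates (mm) for one male-female session."""

    male_head: np.ndarray      # (T, 2)
    male_thorax: np.ndarray    # (T, 2)
    female_head: np.ndarray    # (T, 2)
    female_thorax: np.ndarray  # (T, 2)
    song: np.ndarray           # (T, 3) binary: sine, pfast, pslow
    genotype: str = "control"
    session_id: str = "session0"
    fps: float = FPS

    def __post_init__(self):
        T = self.male_head.shape[0]
        for name in ("male_thorax", "female_head", "female_thorax"):
            if getattr(self, name).shape[0] != T:
                raise ValueError("all joint arrays must share the frame axis")
        if self.song.shape != (T, 3):
            raise ValueError("song must be (T, 3)")

    @property
    def n_frames(self) -> int:
        return self.male_head.shape[0]

    def missing(self) -> np.ndarray:
        """Boolean mask of frames with any non-finite joint coordinate."""
        joints = np.concatenate(
            [self.male_head, self.male_thorax, self.female_head, self.female_thorax],
            axis=1,
        )
        return ~np.isfinite(joints).all(axis=1)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, genotype: str = "control",
                       session_id: str = "session0", fps: float = FPS,
                       song: np.ndarray | None = None) -> "PoseTrack":
        """Build from a long table with columns frame, fly, joint, x_mm, y_mm."""
        wide = df.pivot_table(index="frame", columns=["fly", "joint"],
                              values=["x_mm", "y_mm"])
        T = wide.shape[0]

        def joint(fly, j):
            return np.column_stack([wide[("x_mm", fly, j)].to_numpy(),
                                    wide[("y_mm", fly, j)].to_numpy()])

        if song is None:
            song = np.zeros((T, 3))
        return cls(joint("male", "head"), joint("male", "thorax"),
                   joint("female", "head"), joint("female", "thorax"),
                   np.asarray(song), genotype, session_id, fps)


def _heading(track: PoseTrack) -> np.ndarray:
    h = track.male_head - track.male_thorax
    norm = np.linalg.norm(h, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return h / norm


def extract_behaviour(track: PoseTrack, fps: float | None = None) -> pd.DataFrame:
    """Per-frame behavioural variables of the male.

    Velocities are computed from one-frame differences and scaled to
    per-second units; the first frame (and frames with missing joints) are
    NaN. Columns follow :data:`BEHAVIOUR_COLUMNS`.
    """
    if track.n_frames < 2:
        raise ValueError("need at least 2 frames")
    fps = fps or track.fps
    pos = track.male_thorax
    h = _heading(track)
    right = np.column_stack([h[:, 1], -h[:, 0]])  # heading rotated 90 deg clockwise

    disp = np.full_like(pos, np.nan)
    disp[1:] = pos[1:] - pos[:-1]
    forward = np.einsum("ij,ij->i", disp, h) * fps
    lateral = np.einsum("ij,ij->i", disp, right) * fps

    cross = h[:-1, 0] * h[1:, 1] - h[:-1, 1] * h[1:, 0]
    dot = np.einsum("ij,ij->i", h[:-1], h[1:])
    angular = np.full(track.n_frames, np.nan)
    angular[1:] = -np.degrees(np.arctan2(cross, dot)) * fps  # rightward positive

    bad = track.missing()
    bad_vel = bad.copy()
    bad_vel[1:] |= bad[:-1]
    for arr in (forward, lateral, angular):
        arr[bad_vel] = np.nan

    df = pd.DataFrame({
        "forward": forward,
        "lateral": lateral,
        "angular": angular,
        "sine": track.song[:, 0].astype(float),
        "pfast": track.song[:, 1].astype(float),
        "pslow": track.song[:, 2].astype(float),
    })
    return df


def courtship_features(track: PoseTrack) -> pd.DataFrame:
    """Per-frame features feeding the courtship criteria: thorax distance,
    any-song indicator, female azimuth from the male's head (deg), and
    approach speed (closure rate, mm/s)."""
    from .render import _signed_angle  # shared sign convention

    dist = np.linalg.norm(track.female_thorax - track.male_thorax, axis=1)
    song_any = (track.song.sum(axis=1) > 0).astype(float)
    h = _heading(track)
    v = track.female_thorax - track.male_head
    azimuth = np.array([
        _signed_angle(h[t], v[t]) if np.isfinite(h[t]).all() and np.isfinite(v[t]).all()
        and np.linalg.norm(v[t]) > 0 else np.nan
        for t in range(track.n_frames)
    ])
    approach = np.full(track.n_frames, np.nan)
    approach[1:] = -(dist[1:] - dist[:-1]) * track.fps
    return pd.DataFrame({
        "distance": dist,
        "song_any": song_any,
        "azimuth": azimuth,
        "approach": approach,
    })


def _windowed_mean(x: np.ndarray, half: int) -> np.ndarray:
    """Centred moving average with edge truncation, NaN-aware."""
    T = x.size
    valid = np.isfinite(x).astype(float)
    xv = np.where(np.isfinite(x), x, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(xv)])
    ccnt = np.concatenate([[0.0], np.cumsum(valid)])
    lo = np.maximum(np.arange(T) - half, 0)
    hi = np.minimum(np.arange(T) + half + 1, T)
    total = csum[hi] - csum[lo]
    count = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(count > 0, total / count, np.nan)


def courtship_mask(features: pd.DataFrame, window_s: float = 20.0,
                   fps: float = FPS) -> np.ndarray:
    """Boolean courtship mask; a frame qualifies if ANY criterion holds over
    the centred window (truncated at session edges)."""
    half = int(round(window_s * fps / 2))
    mean_dist = _windowed_mean(features["distance"].to_numpy(), half)
    song_frac = _windowed_mean(features["song_any"].to_numpy(), half)
    mean_abs_az = _windowed_mean(np.abs(features["azimuth"].to_numpy()), half)
    mean_appr = _windowed_mean(features["approach"].to_numpy(), half)
    with np.errstate(invalid="ignore"):
        mask = (
            (mean_dist < 5.0)
            | (song_frac > 0.1)
            | (mean_abs_az <= 45.0)
            | (mean_appr >= 4.5)
        )
    return np.where(np.isnan(mean_dist), False, mask)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Frame-index splits per genotype. Each entry is an (n, 2) int array of
    (session_index, frame) pairs."""

    train: dict = field(default_factory=dict)
    test: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    window_frames: int = 90
    n_history: int = 10

    def to_json_dict(self) -> dict:
        def conv(d):
            return {g: np.asarray(v).tolist() for g, v in d.items()}
        return {
            "train": conv(self.train),
            "test": conv(self.test),
            "validation": conv(self.validation),
            "window_frames": self.window_frames,
            "n_history": self.n_history,
        }


def make_splits(
    sessions,
    seed: int = 0,
    test_frames: int = 27000,
    val_frames: int | None = None,
    train_cap: int = 600000,
    window_s: float = 3.0,
    fps: float = FPS,
    n_history: int = 10,
    control_label: str = "control",
) -> SplitSpec:
    """Build train/validation/test splits from courtship-masked sessions.

    ``sessions`` is a sequence of objects with attributes (or dict keys)
    ``genotype`` and ``courtship`` (boolean per-frame mask). Test sets are
    unions of non-overlapping ``window_s`` windows fully inside courtship
    regions, drawn per genotype up to ``test_frames``; the control genotype
    additionally receives a validation set of the same size (``val_frames``
    defaults to ``test_frames``). Remaining courtship frames, excluding every
    frame within ``n_history - 1`` frames before a held-out window, form the
    training pool, capped at ``train_cap`` per genotype.
    """
    rng = np.random.default_rng(seed)
    if val_frames is None:
        val_frames = test_frames
    win = int(round(window_s * fps))

    def get(s, key):
        return s[key] if isinstance(s, dict) else getattr(s, key)

    by_genotype: dict[str, list[tuple[int, np.ndarray]]] = {}
    for i, s in enumerate(sessions):
        by_genotype.setdefault(get(s, "genotype"), []).append(
            (i, np.asarray(get(s, "courtship"), dtype=bool))
        )

    spec = SplitSpec(window_frames=win, n_history=n_history)
    for genotype in sorted(by_genotype):
        entries = by_genotype[genotype]
        # candidate window starts: windows fully inside courtship regions
        candidates = []
        for sess_idx, mask in entries:
            ok = np.ones(max(mask.size - win + 1, 0), dtype=bool)
            csum = np.concatenate([[0], np.cumsum(mask)])
            full = (csum[win:] - csum[:-win]) == win
            ok &= full
            for start in np.flatnonzero(ok):
                candidates.append((sess_idx, start))
        rng.shuffle(candidates)

        held: dict[str, list] = {"test": [], "validation": []}
        taken = {sess_idx: np.zeros(mask.size, dtype=bool)
                 for sess_idx, mask in entries}
        budgets = [("test", test_frames)]
        if genotype == control_label:
            budgets.append(("validation", val_frames))
        ci = 0
        for name, budget in budgets:
            got = 0
            while got < budget and ci < len(candidates):
                sess_idx, start = candidates[ci]
                ci += 1
                if taken[sess_idx][start:start + win].any():
                    continue
                taken[sess_idx][start:start + win] = True
                held[name].extend((sess_idx, f) for f in range(start, start + win))
                got += win
            if got < budget:
                warnings.warn(
                    f"genotype {genotype!r}: only {got} of {budget} "
                    f"{name} frames available", stacklevel=2)

        # training pool: courtship frames not inside a held-out window nor in
        # the n_history-1 frames preceding one (input-window overlap rule)
        train_pairs = []
        for sess_idx, mask in entries:
            excluded = taken[sess_idx].copy()
            idx = np.flatnonzero(taken[sess_idx])
            for off in range(1, n_history):
                prev = idx - off
                prev = prev[prev >= 0]
                excluded[prev] = True
            avail = mask & ~excluded
            train_pairs.extend((sess_idx, f) for f in np.flatnonzero(avail))
        if len(train_pairs) > train_cap:
            sel = rng.choice(len(train_pairs), size=train_cap, replace=False)
            train_pairs = [train_pairs[i] for i in sorted(sel)]

        spec.test[genotype] = np.array(held["test"], dtype=int).reshape(-1, 2)
        if genotype == control_label:
            spec.validation[genotype] = np.array(
                held["validation"], dtype=int).reshape(-1, 2)
        spec.train[genotype] = np.array(train_pairs, dtype=int).reshape(-1, 2)
    return spec


def augment_flip(images: np.ndarray, behaviour: np.ndarray, p: float = 0.5,
                 rng=None):
    """Left-right mirror augmentation for a single training sample.

    With probability ``p`` the image stack is mirrored along its column axis
    and the lateral and angular velocities change sign; forward velocity and
    song labels are untouched. Returns (images, behaviour, flipped).
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if gen.random() >= p:
        return images, behaviour, False
    flipped = images[..., ::-1].copy()
    b = np.asarray(behaviour, dtype=float).copy()
    b[1] = -b[1]
    b[2] = -b[2]
    return flipped, b, True
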