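"""Egocentric panorama renderer and stimulus generation.

Reconstructs the visual input of a male fly as a greyscale panorama in which
a procedurally drawn fictive female (ellipses for head, eyes, thorax and
abdomen; no wings) is placed according to three normalized parameters:

* ``size``   - dimensionless in [0, 1]; 1.0 corresponds to a 180-degree
  angular subtense of a 4-mm sphere standing in for the female's body.
* ``position`` - dimensionless in [-1, 1]; 0 is straight ahead, +/-0.5 is
  90 degrees to the right/left, +/-1 is directly behind.
* ``rotation`` - degrees in (-180, 180]; 0 means the female faces away from
  the male, +/-180 toward him, +90 faces to his right.

The full panorama covers 360 degrees with 256 columns (64 rows at full
resolution); the 40-degree blind wedge directly behind the male is removed,
leaving round(256 * 320/360) = 228 columns. Raw pixel values are 0..255 on a
white (255) background; before use as network input the image is re-centred
by subtracting 255 so the background is exactly 0 and female pixels are
negative.

The module also generates the artificial probe stimuli: translating spots,
looming discs theta(t) = -2 atan(-(r/v)/t), linearly expanding discs
theta = 10 + v t, single-parameter sweep sequences (model-probe and imaging
variants) and greedily optimized parameter sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "FemaleParams",
    "RenderConfig",
    "FULL_RES",
    "REDUCED_RES",
    "BODY_DIAMETER_MM",
    "angular_size",
    "distance_for_size",
    "position_to_azimuth",
    "azimuth_to_position",
    "egocentric_params",
    "place_female",
    "render_frame",
    "render_params_array",
    "frames_to_sequences",
    "SpotTrajectory",
    "spot_trajectory",
    "loom_angle",
    "probe_sequence",
    "greedy_optimized_sequence",
    "write_sequence_h5",
    "read_sequence_h5",
]

BODY_DIAMETER_MM = 4.0
#: body subtense (visual degrees) of the female at size 1.0, rotation 0
BODY_SUBTENSE_DEG = 65.0
FRAME_RATE = 30.0


def _wrap_rotation(rotation: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    r = (float(rotation) + 180.0) % 360.0 - 180.0
    return 180.0 if r == -180.0 else r


@dataclass(frozen=True)
class FemaleParams:
    """Normalized egocentric parameters of the fictive female."""

    size: float
    position: float
    rotation: float

    def __post_init__(self):
        if self.size < 0:
            raise ValueError("size must be >= 0")
        if abs(self.position) > 1:
            raise ValueError("position must lie in [-1, 1]")
        object.__setattr__(self, "rotation", _wrap_rotation(self.rotation))

    def as_array(self) -> np.ndarray:
        return np.array([self.size, self.position, self.rotation], dtype=float)


@dataclass(frozen=True)
class RenderConfig:
    """Panorama resolution. The full panorama spans 360 degrees over
    ``full_columns``; the retained image drops the 40-degree rear wedge."""

    rows: int = 64
    full_columns: int = 256

    @property
    def retained_columns(self) -> int:
        return round(self.full_columns * 320.0 / 360.0)

    @property
    def deg_per_column_full(self) -> float:
        return 360.0 / self.full_columns

    @property
    def degrees_per_column(self) -> float:
        """Nominal degrees per retained column (320 degrees over the image)."""
        return 320.0 / self.retained_columns

    @property
    def wedge_margin(self) -> int:
        """Columns removed on each side of the full panorama."""
        return (self.full_columns - self.retained_columns) // 2


FULL_RES = RenderConfig(rows=64, full_columns=256)
#: reduced resolution used by the small-scale simulation pipeline (16 x 57)
REDUCED_RES = RenderConfig(rows=16, full_columns=64)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def angular_size(distance_mm: float, body_diameter_mm: float = BODY_DIAMETER_MM) -> float:
    """Normalized angular size of a sphere of given diameter at a distance.

    The subtended angle between the two silhouette tangent points of a sphere
    of radius ``body_diameter/2`` seen from ``distance`` is
    ``2 arcsin(r / d)``; it is normalized so that 180 degrees maps to 1.0.
    """
    if distance_mm <= 0:
        raise ValueError("distance must be positive")
    if body_diameter_mm <= 0:
        raise ValueError("body diameter must be positive")
    ratio = min(1.0, (body_diameter_mm / 2.0) / distance_mm)
    return 2.0 * math.degrees(math.asin(ratio)) / 180.0


def distance_for_size(size: float, body_diameter_mm: float = BODY_DIAMETER_MM) -> float:
    """Inverse of :func:`angular_size` (size in (0, 1])."""
    if not 0 < size <= 1:
        raise ValueError("size must lie in (0, 1] to invert")
    return (body_diameter_mm / 2.0) / math.sin(math.radians(size * 90.0))


def position_to_azimuth(position: float) -> float:
    """Azimuth in visual degrees (rightward positive) for a normalized position."""
    return float(position) * 180.0


def azimuth_to_position(azimuth_deg: float) -> float:
    return float(azimuth_deg) / 180.0


def _signed_angle(v_from: np.ndarray, v_to: np.ndarray) -> float:
    """Angle in degrees from v_from to v_to, rightward (clockwise) positive."""
    cross = v_from[0] * v_to[1] - v_from[1] * v_to[0]
    dot = float(np.dot(v_from, v_to))
    return -math.degrees(math.atan2(cross, dot))


def _rotate_right(v: np.ndarray, deg: float) -> np.ndarray:
    """Rotate a 2-vector by ``deg`` degrees clockwise (rightward positive)."""
    a = math.radians(-deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def egocentric_params(male_head, male_heading, female_body, female_heading) -> FemaleParams:
    """Egocentric female parameters from world-frame positions and headings.

    ``position`` is the signed azimuth of the female body from the male
    heading, divided by 180 (rightward positive). ``rotation`` is the signed
    angle between the male-to-female direction and the female heading
    (0 = facing away). ``size`` comes from the head-to-body distance via the
    sphere model.
    """
    male_head = np.asarray(male_head, dtype=float)
    male_heading = np.asarray(male_heading, dtype=float)
    female_body = np.asarray(female_body, dtype=float)
    female_heading = np.asarray(female_heading, dtype=float)
    if np.linalg.norm(male_heading) == 0 or np.linalg.norm(female_heading) == 0:
        raise ValueError("headings must be non-zero vectors")
    v = female_body - male_head
    dist = float(np.linalg.norm(v))
    if dist == 0:
        raise ValueError("male and female coordinates coincide")
    azimuth = _signed_angle(male_heading, v)
    rotation = _signed_angle(v, female_heading)
    return FemaleParams(
        size=angular_size(dist),
        position=azimuth_to_position(azimuth),
        rotation=rotation,
    )


def place_female(male_head, male_heading, params: FemaleParams):
    """Inverse placement: world-frame female body position and heading that
    realize ``params`` for the given male pose. Returns (body_xy, heading)."""
    male_head = np.asarray(male_head, dtype=float)
    h = np.asarray(male_heading, dtype=float)
    h = h / np.linalg.norm(h)
    dist = distance_for_size(params.size)
    direction = _rotate_right(h, position_to_azimuth(params.position))
    body = male_head + dist * direction
    heading = _rotate_right(direction, params.rotation)
    return body, heading


# ---------------------------------------------------------------------------
# fictive-female patch bank
# ---------------------------------------------------------------------------

# Artwork in continuous patch coordinates u (horizontal), w (vertical), both
# in [-1, 1]. Each element: (axial_center, lateral_offset, r_along, r_cross,
# r_height, grey value). The female's body axis projects onto the horizontal
# with factor sin(rotation); lateral offsets project with cos(rotation).
_BODY_ELEMENTS = (
    # name        t      lat   r_along r_cross r_h   shade
    ("abdomen", -0.45,  0.00,  0.50,  0.55,  0.50,  70.0),
    ("thorax",   0.10,  0.00,  0.40,  0.45,  0.42, 110.0),
    ("head",     0.60,  0.00,  0.25,  0.32,  0.30, 110.0),
    ("eye_l",    0.60, -0.20,  0.12,  0.12,  0.12,  40.0),
    ("eye_r",    0.60,  0.20,  0.12,  0.12,  0.12,  40.0),
)

#: widest cross-section of the artwork (abdomen) as a fraction of the patch
#: half-width; fixes the patch-width calibration below.
_BODY_FRACTION = 0.55

#: angular width of the square patch at size 1.0, chosen so that the body
#: artwork at rotation 0 subtends exactly BODY_SUBTENSE_DEG at size 1.0.
PATCH_DEG_AT_SIZE_1 = BODY_SUBTENSE_DEG / _BODY_FRACTION


@lru_cache(maxsize=4096)
def _patch(rotation_deg: int, width_px: int) -> np.ndarray:
    """Rasterize the fictive female at an integer rotation into a square
    ``width_px`` patch. Returns raw grey values with NaN marking background.

    The bank is defined at 1-degree rotation resolution (360 entries per
    pixel width) and rasterized analytically at the target width, which keeps
    the mirror identity patch(-rot) == fliplr(patch(rot)) exact.
    """
    P = int(width_px)
    phi = math.radians(rotation_deg)
    s, c = math.sin(phi), math.cos(phi)
    # pixel centres, symmetric about 0
    coords = (np.arange(P) - (P - 1) / 2.0) * (2.0 / P)
    U, W = np.meshgrid(coords, coords)  # W: rows (vertical), U: columns
    patch = np.full((P, P), np.nan)
    # depth along the line of sight is t*cos(phi); draw far elements first so
    # near ones paint over them (head occluded when the female faces away)
    depth = np.array([e[1] * c for e in _BODY_ELEMENTS])
    draw_order = np.argsort(-depth, kind="stable")
    for idx in draw_order:
        _, t, lat, r_along, r_cross, r_height, shade = _BODY_ELEMENTS[idx]
        u0 = t * s + lat * c
        ru = r_along * abs(s) + r_cross * abs(c)
        inside = ((U - u0) / ru) ** 2 + (W / r_height) ** 2 <= 1.0
        patch[inside] = shade
    return patch


def render_frame(
    params: FemaleParams,
    config: RenderConfig = FULL_RES,
    recentre: bool = True,
) -> np.ndarray:
    """Render one panorama frame for the given female parameters.

    Returns a float32 array of shape ``(rows, retained_columns)``. With
    ``recentre`` (default) the background is exactly 0 and female pixels are
    negative (raw value minus 255); otherwise raw 0..255 values are returned.
    """
    rows, retained = config.rows, config.retained_columns
    full = config.full_columns
    canvas = np.full((rows, full), 255.0, dtype=np.float64)
    if params.size > 0:
        width_deg = params.size * PATCH_DEG_AT_SIZE_1
        P = int(round(width_deg / config.deg_per_column_full))
        if P >= 1:
            rot = int(round(params.rotation)) % 360
            patch = _patch(rot, P)
            centre_col = (full - 1) / 2.0 + position_to_azimuth(params.position) / config.deg_per_column_full
            centre_row = (rows - 1) / 2.0
            # nearest-integer placement; this rounding is mirror-symmetric
            # (left(p) + left(-p) == full - P away from exact half-pixel ties)
            left = int(math.floor(centre_col - (P - 1) / 2.0 + 0.5))
            top = int(math.floor(centre_row - (P - 1) / 2.0 + 0.5))
            # clip to canvas; no wraparound across the rear
            c0, c1 = max(left, 0), min(left + P, full)
            r0, r1 = max(top, 0), min(top + P, rows)
            if c0 < c1 and r0 < r1:
                sub = patch[r0 - top:r1 - top, c0 - left:c1 - left]
                target = canvas[r0:r1, c0:c1]
                mask = ~np.isnan(sub)
                target[mask] = sub[mask]
    m = config.wedge_margin
    image = canvas[:, m:m + retained]
    if recentre:
        image = image - 255.0
    return image.astype(np.float32)


def render_params_array(
    params: np.ndarray,
    config: RenderConfig = FULL_RES,
    recentre: bool = True,
) -> np.ndarray:
    """Render a (T, 3) array of (size, position, rotation) rows into a
    (T, rows, retained_columns) stack."""
    params = np.asarray(params, dtype=float)
    out = np.empty((params.shape[0], config.rows, config.retained_columns), dtype=np.float32)
    for i, (s, p, r) in enumerate(params):
        out[i] = render_frame(FemaleParams(s, p, r), config, recentre=recentre)
    return out


def frames_to_sequences(frames: np.ndarray, n_history: int = 10) -> np.ndarray:
    """Stack rendered frames into sliding windows of the ``n_history`` most
    recent frames (most recent last). Windows before frame ``n_history - 1``
    are padded by repeating the first frame."""
    T = frames.shape[0]
    idx = np.arange(T)[:, None] - np.arange(n_history - 1, -1, -1)[None, :]
    idx = np.maximum(idx, 0)
    return frames[idx]


# ---------------------------------------------------------------------------
# artificial spot stimuli
# ---------------------------------------------------------------------------

@dataclass
class SpotTrajectory:
    """Diameter (and, for translation, azimuth) series of a spot stimulus."""

    kind: str
    diameter_series: np.ndarray        # visual degrees per frame
    azimuth_series: np.ndarray | None  # visual degrees, translation only
    r_over_v: float | None = None      # ms, loom only
    velocity: float | None = None      # deg/s, translate & linear_expand
    frame_rate: float = FRAME_RATE


def spot_trajectory(kind: str, *, r_over_v: float | None = None,
                    velocity: float | None = None,
                    duration_s: float | None = None,
                    frame_rate: float = FRAME_RATE) -> SpotTrajectory:
    """Generate a spot stimulus trajectory.

    * ``translate``: fixed 20-degree spot moving left to right at
      ``velocity`` deg/s for 2 s (default).
    * ``loom``: expanding disc theta(t) = -2 atan(-(r/v)/t) with t the time
      remaining (ms) until maximum size; starts at 80 degrees, capped at 180.
    * ``linear_expand``: theta = 10 + v t, capped at 90 degrees; default
      duration 2 s.
    """
    if kind == "translate":
        if velocity is None:
            raise ValueError("translate requires velocity (deg/s)")
        dur = 2.0 if duration_s is None else duration_s
        n = int(round(dur * frame_rate))
        t = np.arange(n) / frame_rate
        azimuth = velocity * (t - dur / 2.0)
        diam = np.full(n, 20.0)
        return SpotTrajectory(kind, diam, azimuth, velocity=velocity,
                              frame_rate=frame_rate)
    if kind == "loom":
        if r_over_v is None or r_over_v <= 0:
            raise ValueError("loom requires positive r_over_v (ms)")
        # time remaining at the 80-degree starting diameter
        t_start_ms = r_over_v / math.tan(math.radians(40.0))
        if duration_s is None:
            duration_s = t_start_ms / 1000.0 + 0.5
        n = int(round(duration_s * frame_rate))
        t_ms = t_start_ms - np.arange(n) * (1000.0 / frame_rate)
        diam = np.where(
            t_ms > 0,
            2.0 * np.degrees(np.arctan(np.divide(r_over_v, t_ms,
                                                 out=np.full(n, np.inf),
                                                 where=t_ms > 0))),
            180.0,
        )
        diam = np.minimum(diam, 180.0)
        return SpotTrajectory(kind, diam, None, r_over_v=r_over_v,
                              frame_rate=frame_rate)
    if kind == "linear_expand":
        if velocity is None or velocity <= 0:
            raise ValueError("linear_expand requires positive velocity (deg/s)")
        dur = 2.0 if duration_s is None else duration_s
        # inclusive of both endpoints: a 2-s ramp at 10 deg/s ends at 30 deg
        n = int(round(dur * frame_rate)) + 1
        t = np.arange(n) / frame_rate
        diam = np.minimum(10.0 + velocity * t, 90.0)
        return SpotTrajectory(kind, diam, None, velocity=velocity,
                              frame_rate=frame_rate)
    raise ValueError(f"unknown spot kind {kind!r}")


def loom_angle(t_remaining_ms: float, r_over_v_ms: float) -> float:
    """Loom angular diameter theta(t) = -2 atan(-(r/v)/t) in degrees."""
    if t_remaining_ms <= 0:
        raise ValueError("time remaining must be positive")
    return -2.0 * math.degrees(math.atan(-r_over_v_ms / t_remaining_ms))


# ---------------------------------------------------------------------------
# single-parameter probe sequences
# ---------------------------------------------------------------------------

#: (varied range, fixed values) per parameter for the two probe protocols.
_MODEL_PROBE = {
    "size": ((0.5, 0.9), {"position": 0.0, "rotation": 0.0}),
    "position": ((-0.25, 0.25), {"size": 0.8, "rotation": 0.0}),
    "rotation": ((-45.0, 45.0), {"size": 0.8, "position": 0.0}),
}
_MODEL_PROBE_PERIODS = (150, 100, 50, 10)

_IMAGING_PROBE = {
    "size": ((0.4, 0.9), {"position": 0.25, "rotation": 0.0}),
    "position": ((-0.1, 0.5), {"size": 0.8, "rotation": 0.0}),
    "rotation": ((-180.0, 180.0), {"size": 0.8, "position": 0.25}),
}
_IMAGING_PROBE_PERIODS = (150, 100, 50)


def probe_sequence(parameter: str, mode: str = "model_probe") -> np.ndarray:
    """Deterministic single-parameter sweep of the fictive female.

    Returns a (T, 3) array of (size, position, rotation). Each period ramps
    the varied parameter linearly from its minimum to its maximum over the
    first half and plays the ramp time-reversed over the second half;
    non-varied parameters stay at their protocol-fixed values. The
    ``model_probe`` protocol uses periods of 150/100/50/10 frames (310
    total); the ``imaging`` protocol uses 150/100/50 (300 frames, 10 s).
    """
    if mode == "model_probe":
        spec, periods = _MODEL_PROBE, _MODEL_PROBE_PERIODS
    elif mode == "imaging":
        spec, periods = _IMAGING_PROBE, _IMAGING_PROBE_PERIODS
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if parameter not in spec:
        raise ValueError(f"unknown parameter {parameter!r}")
    (lo, hi), fixed = spec[parameter]
    varied = []
    for n in periods:
        half = n // 2
        up = np.linspace(lo, hi, half)
        varied.append(up)
        varied.append(up[::-1])
    varied = np.concatenate(varied)
    T = varied.size
    out = np.empty((T, 3))
    cols = {"size": 0, "position": 1, "rotation": 2}
    for name, idx in cols.items():
        out[:, idx] = varied if name == parameter else fixed[name]
    return out


# ---------------------------------------------------------------------------
# greedy model-driven stimulus optimization
# ---------------------------------------------------------------------------

def greedy_optimized_sequence(
    objective_fn,
    start: FemaleParams,
    n_frames: int = 300,
    switch_frames=None,
    step: float = 0.05,
    size_floor: float = 0.3,
    size_cap: float = 1.0,
    position_range=(-0.1, 0.5),
    rng=None,
) -> np.ndarray:
    """Greedy stimulus-parameter sequence maximizing a signed model objective.

    ``objective_fn(params_history)`` receives the (t+1, 3) parameter history
    up to and including the candidate frame and returns a scalar; the sign of
    the objective flips at each entry of ``switch_frames`` (default: a single
    switch at the midpoint, i.e. maximize then minimize). Candidates at each
    frame are the neighbouring lattice points within ``+-step`` per
    normalized parameter (rotation normalized by 360); the current point
    itself is excluded so consecutive frames always differ. Constraint
    violations (size <= ``size_floor``, position outside ``position_range``)
    are discarded; an empty candidate set raises.
    """
    if switch_frames is None:
        switch_frames = [n_frames // 2]
    deltas = np.array([-step, -step / 2, 0.0, step / 2, step])
    history = [start.as_array()]
    for t in range(1, n_frames):
        sign = 1.0
        for sf in switch_frames:
            if t >= sf:
                sign *= -1.0
        cur = history[-1]
        best, best_val = None, -np.inf
        for ds in deltas:
            for dp in deltas:
                for dr in deltas * 360.0:
                    if ds == 0 and dp == 0 and dr == 0:
                        continue
                    s = cur[0] + ds
                    p = cur[1] + dp
                    r = _wrap_rotation(cur[2] + dr)
                    eps = 1e-9
                    if not (size_floor + eps < s <= size_cap + eps):
                        continue
                    if not (position_range[0] - eps <= p <= position_range[1] + eps):
                        continue
                    cand = np.array([s, p, r])
                    val = sign * objective_fn(np.vstack(history + [cand]))
                    if val > best_val:
                        best_val, best = val, cand
        if best is None:
            raise ValueError("empty candidate set under constraints")
        history.append(best)
    return np.vstack(history)


# ---------------------------------------------------------------------------
# HDF5 I/O
# ---------------------------------------------------------------------------

def write_sequence_h5(path, frames: np.ndarray, params: np.ndarray,
                      frame_rate: float = FRAME_RATE) -> None:
    """Write a rendered stimulus sequence (frames [T, H, W], params [T, 3])."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=np.asarray(frames, dtype=np.float32))
        f.create_dataset("params", data=np.asarray(params, dtype=np.float64))
        f.attrs["frame_rate"] = frame_rate


def read_sequence_h5(path):
    import h5py

    with h5py.File(path, "r") as f:
        return f["frames"][()], f["params"][()], float(f.attrs["frame_rate"])
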