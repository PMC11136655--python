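"""Characterization of trained bottleneck units.

Tuning maps enumerate the model's bottleneck responses on a full-factorial
grid over female size ([0.3, 1.1]), position ([-1, 1]) and rotation
([-180, 180] degrees), 50 values per axis by default (125,000 static
stimulus sequences: each 10-frame input repeats one image).

The response variance of each unit over this grid is decomposed into the
three marginal components (variance of the doubly-averaged response along
each axis) plus an interaction remainder — a functional-ANOVA decomposition
under the uniform grid measure, so every component is non-negative and they
sum exactly to the total.

The cumulative inactivation procedure (CLIP) greedily clamps bottleneck
units to their mean activity, at each step removing the unit whose clamping
maintains the best prediction, producing an importance ordering and a
normalized change in performance per unit. Necessity/sufficiency analyses
clamp a candidate set (or its complement) and compare output traces to the
full model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import r_squared, song_score
from .render import FemaleParams, RenderConfig, FULL_RES, render_frame

__all__ = [
    "tuning_axes",
    "tuning_grid_params",
    "tuning_maps",
    "VarianceComponents",
    "variance_decomposition",
    "parameter_r2",
    "all_unit_parameter_r2",
    "ClipResult",
    "clip",
    "necessity_sufficiency",
    "summary_graph",
]

TUNING_RANGES = {"size": (0.3, 1.1), "position": (-1.0, 1.0),
                 "rotation": (-180.0, 180.0)}


def tuning_axes(grid_size: int = 50):
    """Linearly spaced grid axes (size, position, rotation)."""
    return tuple(np.linspace(lo, hi, grid_size)
                 for lo, hi in TUNING_RANGES.values())


def tuning_grid_params(grid_size: int = 50) -> np.ndarray:
    """All (size, position, rotation) combinations, shape (grid_size**3, 3);
    the default grid enumerates 125,000 stimuli."""
    s, p, r = tuning_axes(grid_size)
    S, P, R = np.meshgrid(s, p, r, indexing="ij")
    return np.column_stack([S.ravel(), P.ravel(), R.ravel()])


def tuning_maps(model, render_config: RenderConfig = FULL_RES,
                grid_size: int = 50, batch_size: int = 4096) -> np.ndarray:
    """Bottleneck tuning tensors, shape (n_units, g, g, g).

    Each grid point is rendered once; because every stimulus repeats the same
    image for all 10 input frames, the vision network runs once per image and
    its embedding is tiled across the history axis.
    """
    params = tuning_grid_params(grid_size)
    n = model.config.n_bottleneck
    T = model.config.n_history
    out = np.empty((params.shape[0], n), dtype=np.float32)
    for i0 in range(0, params.shape[0], batch_size):
        chunk = params[i0:i0 + batch_size]
        frames = np.stack([
            render_frame(FemaleParams(s, p, r), render_config)
            for s, p, r in chunk
        ])
        emb = model.embed_frames(frames, training=False)
        emb_seq = np.tile(emb, (1, T))
        out[i0:i0 + len(chunk)] = model.bottleneck_from_embedding(
            emb_seq, training=False)
    return out.T.reshape(n, grid_size, grid_size, grid_size)


@dataclass
class VarianceComponents:
    total: float
    size: float
    position: float
    rotation: float
    interactions: float

    def as_dict(self):
        return {"total": self.total, "size": self.size,
                "position": self.position, "rotation": self.rotation,
                "interactions": self.interactions}


def variance_decomposition(tensor: np.ndarray) -> VarianceComponents:
    """Functional-ANOVA decomposition of a full-factorial tuning tensor.

    The marginal component for an axis is the variance (over its grid
    values) of the response averaged over the other two axes; interactions
    are the remainder. The grid is deterministic, so there is no
    repeat-to-repeat noise term.
    """
    t = np.asarray(tensor, dtype=float)
    if t.ndim != 3:
        raise ValueError("tuning tensor must be 3-dimensional")
    total = float(np.var(t))
    comp = {}
    for axis, name in enumerate(("size", "position", "rotation")):
        others = tuple(a for a in range(3) if a != axis)
        comp[name] = float(np.var(t.mean(axis=others)))
    interactions = total - sum(comp.values())
    if interactions < -1e-10 * max(total, 1.0):
        raise AssertionError("negative interaction variance beyond tolerance")
    return VarianceComponents(total, comp["size"], comp["position"],
                              comp["rotation"], max(interactions, 0.0))


def parameter_r2(responses: np.ndarray, parameter: np.ndarray,
                 circular: bool = False) -> float:
    """Squared Pearson correlation between a unit trace and a stimulus
    parameter; circular parameters (position, rotation) are scored as the
    maximum over their cos and sin channels (full circle = 360 degrees for
    rotation, positions -1..1)."""
    if not circular:
        return r_squared(responses, parameter)
    angle = np.asarray(parameter, dtype=float) * np.pi \
        if np.nanmax(np.abs(parameter)) <= 1.0 + 1e-9 \
        else np.radians(parameter)
    scores = [r_squared(responses, np.cos(angle)),
              r_squared(responses, np.sin(angle))]
    scores = [s for s in scores if np.isfinite(s)]
    return max(scores) if scores else float("nan")


def all_unit_parameter_r2(unit_traces: np.ndarray, target: np.ndarray,
                          circular: bool = False, folds: int = 5,
                          alphas=(0.01, 0.1, 1.0, 10.0, 100.0),
                          seed: int = 0) -> float:
    """Cross-validated ridge-regression R^2 from all units to one parameter.

    Out-of-fold predictions are pooled and scored by squared Pearson
    correlation; the ridge penalty is chosen on inner folds. Circular targets
    are scored as the max over cos/sin channels.
    """
    from sklearn.linear_model import RidgeCV
    from sklearn.model_selection import KFold

    X = np.asarray(unit_traces, dtype=float)
    if circular:
        angle = np.asarray(target, dtype=float) * np.pi \
            if np.nanmax(np.abs(target)) <= 1.0 + 1e-9 else np.radians(target)
        return max(
            all_unit_parameter_r2(X, np.cos(angle), False, folds, alphas, seed),
            all_unit_parameter_r2(X, np.sin(angle), False, folds, alphas, seed),
        )
    y = np.asarray(target, dtype=float)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    X, y = X[ok], y[ok]
    pred = np.empty_like(y)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in kf.split(X):
        reg = RidgeCV(alphas=alphas).fit(X[tr], y[tr])
        pred[te] = reg.predict(X[te])
    return r_squared(pred, y)


# ---------------------------------------------------------------------------
# cumulative inactivation (CLIP)
# ---------------------------------------------------------------------------

@dataclass
class ClipResult:
    """Greedy inactivation ordering (weakest contributor first), the
    performance curve from no clamping to all units clamped (n_units + 1
    entries), and the normalized per-unit change in [0, 1]."""

    order: np.ndarray
    curve: np.ndarray
    normalized_change: np.ndarray
    clamp_values: np.ndarray
    kind: str


def _score(pred, target, kind):
    """Prediction score for CLIP; a degenerate (constant) prediction scores
    0, the performance of a constant predictor."""
    s = song_score(pred, target) if kind == "song" else r_squared(pred, target)
    return 0.0 if not np.isfinite(s) else s


def clip(decision_fn, activities: np.ndarray, target: np.ndarray,
         kind: str = "velocity") -> ClipResult:
    """Cumulative inactivation of bottleneck units.

    ``decision_fn(activities)`` maps an (T, n_units) activity matrix to a
    predicted output trace; units are clamped to their mean activity over the
    evaluation frames. At each step the unit whose clamping maintains the
    best score is inactivated (ties broken toward the lowest unit index).
    ``kind`` is "velocity" (R^2) or "song" (1 - normalized cross-entropy).
    """
    A = np.asarray(activities, dtype=np.float32)
    T, n = A.shape
    clamp = A.mean(axis=0)
    remaining = list(range(n))
    clamped: list[int] = []
    curve = [_score(decision_fn(A), target, kind)]
    current = A.copy()
    step_drop = np.zeros(n)
    for _ in range(n):
        best_j, best_perf = None, -np.inf
        for j in remaining:
            trial = current.copy()
            trial[:, j] = clamp[j]
            perf = _score(decision_fn(trial), target, kind)
            if np.isnan(perf):
                perf = -np.inf
            if perf > best_perf:  # strict: ties keep the lowest index
                best_perf, best_j = perf, j
        if best_j is None:  # every candidate scored NaN
            best_j = remaining[0]
        current[:, best_j] = clamp[best_j]
        remaining.remove(best_j)
        clamped.append(best_j)
        prev = curve[-1]
        curve.append(best_perf if best_perf > -np.inf else float("nan"))
        step_drop[best_j] = (prev if np.isfinite(prev) else 0.0) - \
            (curve[-1] if np.isfinite(curve[-1]) else 0.0)
    curve = np.asarray(curve)
    total_drop = curve[0] - curve[-1]
    if np.isfinite(total_drop) and total_drop > 0:
        normalized = np.clip(step_drop / total_drop, 0.0, 1.0)
    else:
        normalized = np.zeros(n)
    return ClipResult(np.asarray(clamped), curve, normalized, clamp, kind)


@dataclass
class NecessitySufficiency:
    sufficient_set: np.ndarray
    weak_set: np.ndarray
    full_trace: np.ndarray
    sufficiency_trace: np.ndarray
    necessity_trace: np.ndarray
    sufficiency_r2: float
    necessity_r2: float
    sufficient: bool
    necessary: bool


def necessity_sufficiency(decision_fn, activities: np.ndarray,
                          clip_result: ClipResult,
                          trace_r2_threshold: float = 0.9) -> NecessitySufficiency:
    """Test a candidate unit group for sufficiency and necessity.

    The weak set is the longest prefix of the CLIP ordering whose clamping
    keeps the output trace within ``trace_r2_threshold`` R^2 of the full
    model; the remaining units form the sufficient set. Sufficiency: clamping
    the weak set leaves the trace matching the full model. Necessity:
    clamping the sufficient set instead degrades it below threshold.
    """
    A = np.asarray(activities, dtype=np.float32)
    clamp = clip_result.clamp_values
    full = decision_fn(A)

    def clamped_trace(units):
        trial = A.copy()
        for j in units:
            trial[:, j] = clamp[j]
        return decision_fn(trial)

    weak: list[int] = []
    for j in clip_result.order:
        trial_trace = clamped_trace(weak + [int(j)])
        if r_squared(trial_trace, full) >= trace_r2_threshold:
            weak.append(int(j))
        else:
            break
    weak_set = np.asarray(weak, dtype=int)
    sufficient_set = np.asarray(
        [u for u in range(A.shape[1]) if u not in weak], dtype=int)
    suff_trace = clamped_trace(list(weak_set))
    nec_trace = clamped_trace(list(sufficient_set))
    suff_r2 = r_squared(suff_trace, full)
    nec_r2 = r_squared(nec_trace, full)
    return NecessitySufficiency(
        sufficient_set, weak_set, full, suff_trace, nec_trace,
        suff_r2, nec_r2,
        bool(np.isfinite(suff_r2) and suff_r2 >= trace_r2_threshold),
        bool(not np.isfinite(nec_r2) or nec_r2 < trace_r2_threshold),
    )


def summary_graph(r2_table: pd.DataFrame, clip_table: pd.DataFrame,
                  threshold: float = 0.30) -> pd.DataFrame:
    """Bipartite edge list linking units to visual features and behaviours.

    An edge unit -> feature exists iff its R^2 strictly exceeds ``threshold``;
    an edge unit -> behaviour iff its normalized change in performance
    strictly exceeds ``threshold``.
    """
    edges = []
    for table, kind in ((r2_table, "feature"), (clip_table, "behaviour")):
        if table is None or table.empty:
            continue
        for unit in table.index:
            for col in table.columns:
                val = table.loc[unit, col]
                if np.isfinite(val) and val > threshold:
                    edges.append({"unit": unit, "target": col,
                                  "kind": kind, "weight": float(val)})
    return pd.DataFrame(edges, columns=["unit", "target", "kind", "weight"])
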