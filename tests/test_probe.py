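"""Tuning grids, variance decomposition, CLIP and the summary graph."""

import itertools

import numpy as np
import pandas as pd
import pytest

from knockoutnet.network import r_squared
from knockoutnet.probe import (ClipResult, clip, necessity_sufficiency,
                               parameter_r2, all_unit_parameter_r2,
                               summary_graph, tuning_axes, tuning_grid_params,
                               variance_decomposition)


class TestTuningGrid:
    def test_default_grid_enumerates_125000_stimuli(self):
        params = tuning_grid_params(50)
        assert params.shape == (125000, 3)
        s, p, r = tuning_axes(50)
        assert len(s) == len(p) == len(r) == 50
        assert (s[0], s[-1]) == (0.3, 1.1)
        assert (p[0], p[-1]) == (-1.0, 1.0)
        assert (r[0], r[-1]) == (-180.0, 180.0)

    def test_axes_linearly_spaced(self):
        s, p, r = tuning_axes(50)
        for ax in (s, p, r):
            assert np.allclose(np.diff(ax), ax[1] - ax[0])


def _bruteforce_components(t):
    """Direct functional-ANOVA over the grid (independent uniform factors)."""
    total = t.var()
    comps = []
    for axis in range(3):
        others = tuple(a for a in range(3) if a != axis)
        comps.append(t.mean(axis=others).var())
    return total, comps, total - sum(comps)


class TestVarianceDecomposition:
    def test_single_axis_function_has_no_other_components(self):
        g = 12
        size_idx = np.arange(g, dtype=float)
        t = np.broadcast_to(size_idx[:, None, None] ** 2, (g, g, g)).copy()
        vc = variance_decomposition(t)
        tol = 1e-12 * vc.total
        assert vc.position == pytest.approx(0.0, abs=tol)
        assert vc.rotation == pytest.approx(0.0, abs=tol)
        assert vc.interactions == pytest.approx(0.0, abs=tol)
        assert vc.size == pytest.approx(vc.total)

    def test_additive_function_has_no_interactions(self):
        g = 10
        i = np.arange(g, dtype=float)
        t = 2.0 * i[:, None, None] + 3.0 * i[None, :, None] \
            + np.zeros((g, g, g))
        vc = variance_decomposition(t)
        assert vc.interactions == pytest.approx(0.0, abs=1e-10)
        assert vc.size + vc.position == pytest.approx(vc.total)

    def test_multiplicative_function_matches_bruteforce_residual(self):
        g = 8
        i = np.arange(g, dtype=float) - (g - 1) / 2  # centred
        t = i[:, None, None] * i[None, :, None] + np.zeros((g, g, g))
        vc = variance_decomposition(t)
        total, comps, resid = _bruteforce_components(t)
        assert vc.interactions == pytest.approx(resid)
        assert vc.interactions > 0

    def test_random_tensors_match_bruteforce_and_are_nonnegative(self, rng):
        """Components from random 50-cube tensors equal the brute-force
        oracle, are non-negative, and sum exactly to the total."""
        for _ in range(5):
            t = rng.normal(size=(50, 50, 50)) ** 2
            vc = variance_decomposition(t)
            total, comps, resid = _bruteforce_components(t)
            assert vc.total == pytest.approx(total)
            assert [vc.size, vc.position, vc.rotation] == pytest.approx(comps)
            assert vc.interactions == pytest.approx(resid, abs=1e-10)
            for c in (vc.size, vc.position, vc.rotation, vc.interactions):
                assert c >= 0
            assert vc.size + vc.position + vc.rotation + vc.interactions \
                == pytest.approx(vc.total)

    def test_degenerate_tensor_all_zero(self):
        vc = variance_decomposition(np.full((5, 5, 5), 3.14))
        for c in (vc.total, vc.size, vc.position, vc.rotation, vc.interactions):
            assert c == pytest.approx(0.0, abs=1e-20)


class TestParameterR2:
    def test_identity_response(self, rng):
        x = rng.normal(size=200)
        assert parameter_r2(x, x) == pytest.approx(1.0)

    def test_circular_cosine_channel(self):
        rot = np.linspace(-180, 180, 300)
        resp = np.cos(np.radians(rot))
        assert parameter_r2(resp, rot, circular=True) == pytest.approx(1.0)

    def test_circular_sine_channel(self):
        pos = np.linspace(-1, 1, 300)
        resp = np.sin(pos * np.pi)
        assert parameter_r2(resp, pos, circular=True) == pytest.approx(1.0)

    def test_constant_series_is_missing(self):
        assert np.isnan(parameter_r2(np.ones(50), np.arange(50.0)))

    def test_all_unit_ridge_recovers_spanned_target(self, rng):
        X = rng.normal(size=(400, 6))
        y = X @ rng.normal(size=6)
        assert all_unit_parameter_r2(X, y) > 0.98

    def test_all_unit_ridge_near_zero_for_noise(self, rng):
        X = rng.normal(size=(400, 6))
        y = rng.normal(size=400)
        assert all_unit_parameter_r2(X, y) < 0.05


def _exhaustive_best_curve(predict, A, target, clamp):
    """Oracle: the greedy CLIP path recomputed by explicit enumeration of the
    candidate unit at each step (same tie-break: lowest index)."""
    n = A.shape[1]
    current = A.copy()
    order, curve = [], [r_squared(predict(current), target)]
    remaining = list(range(n))
    while remaining:
        scores = []
        for j in remaining:
            trial = current.copy()
            trial[:, j] = clamp[j]
            s = r_squared(predict(trial), target)
            scores.append(0.0 if np.isnan(s) else s)
        best = int(np.argmax(scores))
        j = remaining.pop(best)
        order.append(j)
        current[:, j] = clamp[j]
        curve.append(scores[best])
    return order, curve


class TestClip:
    def _toy(self, rng, weights=(2.0, 0.0, 1.0)):
        A = rng.normal(size=(300, len(weights))).astype(np.float32) + 2.0
        w = np.asarray(weights)
        target = A @ w + rng.normal(0, 0.1, size=300)
        return A, w, target, (lambda M: M @ w)

    def test_linear_toy_ordering_and_normalized_changes(self, rng):
        """On y = 2 u1 + 0 u2 + u3 the greedy order ends with u1 and the
        normalized changes rank u1 > u3 > u2."""
        A, w, target, predict = self._toy(rng)
        res = clip(predict, A, target)
        assert res.order[-1] == 0
        nc = res.normalized_change
        assert nc[0] > nc[2] > nc[1]

    def test_matches_exhaustive_search_on_toy_models(self, rng):
        """Greedy CLIP reproduces the enumeration oracle on 5-unit models."""
        for trial in range(4):
            w = rng.normal(size=5)
            A = rng.normal(size=(200, 5)).astype(np.float32)
            target = A @ w + rng.normal(0, 0.05, size=200)
            predict = lambda M, w=w: M @ w
            res = clip(predict, A, target)
            order, curve = _exhaustive_best_curve(
                predict, A, target, A.mean(axis=0))
            assert list(res.order) == order
            assert res.curve == pytest.approx(np.asarray(curve), abs=1e-9)

    def test_dead_unit_clamped_first_with_zero_change(self, rng):
        A = rng.normal(size=(200, 3)).astype(np.float32)
        A[:, 1] = 5.0  # constant unit
        w = np.array([1.0, 1.0, 1.0])
        target = A @ w
        res = clip(lambda M: M @ w, A, target)
        assert res.order[0] == 1
        assert res.normalized_change[1] == pytest.approx(0.0, abs=1e-6)
        assert res.curve[1] == pytest.approx(res.curve[0])

    def test_curve_has_n_plus_one_entries_and_order_is_permutation(self, rng):
        A, w, target, predict = self._toy(rng)
        res = clip(predict, A, target)
        assert len(res.curve) == A.shape[1] + 1
        assert sorted(res.order) == list(range(A.shape[1]))

    def test_normalized_changes_clipped_to_unit_interval(self, rng):
        A, w, target, predict = self._toy(rng)
        res = clip(predict, A, target)
        assert np.all(res.normalized_change >= 0)
        assert np.all(res.normalized_change <= 1)


class TestNecessitySufficiency:
    def test_single_driving_unit(self, rng):
        A = rng.normal(size=(300, 4)).astype(np.float32)
        w = np.array([0.0, 0.0, 3.0, 0.0])
        target = A @ w
        predict = lambda M: M @ w
        res_clip = clip(predict, A, target)
        verdict = necessity_sufficiency(predict, A, res_clip)
        assert 2 in verdict.sufficient_set
        assert verdict.sufficient
        assert verdict.necessary
        # clamping the only driving unit leaves a constant (or degraded) trace
        nec = r_squared(verdict.necessity_trace, verdict.full_trace)
        assert np.isnan(nec) or nec < 0.9

    def test_all_units_trivially_sufficient(self, rng):
        A = rng.normal(size=(200, 3)).astype(np.float32)
        w = np.ones(3)
        predict = lambda M: M @ w
        res_clip = ClipResult(np.arange(3), np.zeros(4), np.zeros(3),
                              A.mean(axis=0), "velocity")
        verdict = necessity_sufficiency(predict, A, res_clip,
                                        trace_r2_threshold=1.1)
        # impossible threshold: weak set stays empty, all units sufficient
        assert len(verdict.weak_set) == 0
        assert set(verdict.sufficient_set) == {0, 1, 2}
        assert np.allclose(verdict.sufficiency_trace, verdict.full_trace)


class TestSummaryGraph:
    def test_empty_tables_empty_graph(self):
        edges = summary_graph(pd.DataFrame(), pd.DataFrame())
        assert edges.empty

    def test_threshold_is_strict(self):
        r2 = pd.DataFrame({"size": [0.30, 0.31]}, index=["u0", "u1"])
        nc = pd.DataFrame({"forward": [0.30, 0.0]}, index=["u0", "u1"])
        edges = summary_graph(r2, nc, threshold=0.30)
        assert len(edges) == 1
        assert edges.iloc[0]["unit"] == "u1" and edges.iloc[0]["kind"] == "feature"

    def test_single_super_threshold_entry(self):
        r2 = pd.DataFrame({"size": [0.9]}, index=["u0"])
        edges = summary_graph(r2, pd.DataFrame(), threshold=0.30)
        assert len(edges) == 1
        assert edges.iloc[0]["weight"] == 0.9
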