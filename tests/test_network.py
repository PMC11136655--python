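"""Network architecture, masking, batching, training and checkpoints."""

import numpy as np
import pytest
from scipy.stats import chisquare

from knockoutnet.network import (GenotypeMap, NetworkConfig, OneToOneNetwork,
                                 TrainConfig, evaluate, load_checkpoint,
                                 make_batch, r_squared, save_checkpoint,
                                 song_score, train)

TINY = NetworkConfig(n_bottleneck=2, rows=8, cols=12, conv_filters=4,
                     n_embed=4, bottleneck_hidden=8, decision_width=16)


class StubDataset:
    """Random-image dataset satisfying the training batch protocol."""

    def __init__(self, seed=0, n=400, config=TINY, genotypes=("control", "g0", "g1"),
                 targets=None):
        rng = np.random.default_rng(seed)
        self.genotypes = list(genotypes)
        c = config
        self.images = {
            g: rng.normal(-50, 30, size=(n, c.n_history, c.rows, c.cols)
                          ).astype(np.float32)
            for g in self.genotypes
        }
        if targets is None:
            self.targets = {
                g: np.column_stack([
                    rng.normal(0, 1, size=(n, 3)),
                    (rng.random((n, 3)) < 0.3).astype(float)])
                for g in self.genotypes
            }
        else:
            self.targets = {g: np.tile(targets, (n, 1)) for g in self.genotypes}
        self._song_class = {}
        for g in self.genotypes:
            t = self.targets[g]
            sine = t[:, 3] > 0
            pulse = ((t[:, 4] > 0) | (t[:, 5] > 0)) & ~sine
            self._song_class[(g, "sine")] = np.flatnonzero(sine)
            self._song_class[(g, "pulse")] = np.flatnonzero(pulse)
            self._song_class[(g, "none")] = np.flatnonzero(~sine & ~pulse)

    def sample_ids(self, genotype, song_class):
        return self._song_class[(genotype, song_class)]

    def get_samples(self, genotype, ids):
        return self.images[genotype][ids], self.targets[genotype][ids]

    def control_velocity_stats(self):
        t = self.targets["control"][:, :3]
        return t.mean(axis=0), t.std(axis=0)

    def validation_set(self):
        return self.images["control"][:100], self.targets["control"][:100]


@pytest.fixture(scope="module")
def tiny_model():
    return OneToOneNetwork(TINY, seed=0)


class TestArchitecture:
    def test_parameter_counts_closed_form(self):
        """Every stage's parameter count matches the closed form implied by
        the architecture (default 64 x 228 input, 32 filters, 23 units)."""
        model = OneToOneNetwork(NetworkConfig(), seed=0)
        counts = model.parameter_counts()
        f = 32
        assert counts["vision/conv1"] == 9 * 1 * f + f
        assert counts["vision/sep2"] == 9 * f + f * f + f
        assert counts["vision/sep3"] == 9 * f + f * f + f
        # three stride-2 SAME stages: 64x228 -> 32x114 -> 16x57 -> 8x29
        spatial = 8 * 29
        assert counts["vision/readout"] == spatial + f * 16 + 16
        assert counts["bottleneck/fc1"] == 160 * 64 + 64
        assert counts["bottleneck/fc2"] == 64 * 23 + 23
        for i in (1, 2, 3):
            expected_in = 23 if i == 1 else 128
            assert counts[f"decision/fc{i}"] == expected_in * 128 + 128
        assert counts["head/velocity"] == 128 * 3 + 3
        assert counts["head/song"] == 128 * 3 + 3
        for name, c in counts.items():
            if "bn" in name:
                assert c in (2 * f, 128, 2 * 64, 2 * 23, 2 * 128)

    def test_bottleneck_nonnegative_and_song_in_unit_interval(self, tiny_model, rng):
        imgs = rng.normal(-60, 40, size=(5, 10, 8, 12)).astype(np.float32)
        acts, vel, song = tiny_model.forward(imgs, training=False)
        assert acts.min() >= 0
        assert np.all((song > 0) & (song < 1))

    def test_shape_mismatch_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError):
            tiny_model.forward(rng.normal(size=(2, 10, 8, 13)).astype(np.float32))


class TestMasking:
    def test_all_ones_mask_identical_to_unmasked(self, tiny_model, rng):
        imgs = rng.normal(-60, 40, size=(4, 10, 8, 12)).astype(np.float32)
        a1 = tiny_model.forward(imgs, training=False)
        a2 = tiny_model.forward(imgs, np.ones((4, 2), dtype=np.float32),
                                training=False)
        for x, y in zip(a1, a2):
            assert np.array_equal(x, y)

    def test_masked_unit_contributes_nothing(self, rng):
        """The decision network's output must be identical whether the masked
        unit's activity is its computed value or anything else."""
        model = OneToOneNetwork(TINY, seed=1)
        imgs = rng.normal(-60, 40, size=(6, 10, 8, 12)).astype(np.float32)
        mask = np.ones((6, 2), dtype=np.float32)
        mask[:, 1] = 0.0
        _, vel_a, _ = model.forward(imgs, mask, training=False)
        acts, _, _ = model.forward(imgs, training=False)
        perturbed = acts.copy()
        perturbed[:, 1] += 100.0
        vel_b, _, _ = model.decision_from_bottleneck(perturbed * mask)
        assert np.allclose(vel_a, vel_b, atol=1e-5)

    def test_all_zero_mask_gives_constant_predictions(self, tiny_model, rng):
        imgs = rng.normal(-60, 40, size=(8, 10, 8, 12)).astype(np.float32)
        mask = np.zeros((8, 2), dtype=np.float32)
        _, vel, song = tiny_model.forward(imgs, mask, training=False)
        assert np.ptp(vel, axis=0) == pytest.approx(0.0, abs=1e-6)
        assert np.ptp(song, axis=0) == pytest.approx(0.0, abs=1e-6)

    def test_genotype_map_masks(self):
        gmap = GenotypeMap(["control", "g0", "g1"], 4)
        assert gmap.mask_for("control").tolist() == [1, 1, 1, 1]
        m = gmap.mask_for("g1")
        assert m.sum() == 3 and m[1] == 0


class TestMakeBatch:
    def test_batch_is_12_per_class_and_288_for_24_classes(self, rng):
        genotypes = ["control"] + [f"g{i}" for i in range(23)]
        ds = StubDataset(n=40, genotypes=genotypes)
        gmap = GenotypeMap(ds.genotypes, 23)
        imgs, tgts, masks = make_batch(ds, gmap, rng)
        assert imgs.shape[0] == 288
        assert tgts.shape == (288, 6)
        assert masks.shape == (288, 23)

    def test_knockout_masks_match_genotypes(self, rng):
        ds = StubDataset()
        gmap = GenotypeMap(ds.genotypes, 2)
        _, _, masks = make_batch(ds, gmap, rng, mode="knockout")
        assert np.all(masks[:12] == 1)          # control block
        assert np.all(masks[12:24, 0] == 0)     # g0 block
        assert np.all(masks[24:36, 1] == 0)     # g1 block

    def test_dropout_mode_unit_choice_is_uniform(self):
        """Chi-square test: over many batches the dropped unit index for
        non-control samples is uniform over units."""
        gen = np.random.default_rng(3)
        ds = StubDataset(genotypes=("control", "g0"))
        gmap = GenotypeMap(ds.genotypes, 6)
        zeroed = []
        for _ in range(850):
            _, _, masks = make_batch(ds, gmap, gen, mode="dropout",
                                     augment=False)
            dropped = np.argmin(masks[12:], axis=1)
            zeroed.extend(dropped)
        counts = np.bincount(zeroed, minlength=6)
        assert counts.sum() == 850 * 12
        assert chisquare(counts).pvalue > 0.001

    def test_no_knockout_mode_all_ones(self, rng):
        ds = StubDataset()
        gmap = GenotypeMap(ds.genotypes, 2)
        _, _, masks = make_batch(ds, gmap, rng, mode="no_knockout")
        assert np.all(masks == 1)


class TestTraining:
    def test_untrained_mode_leaves_weights_bit_identical(self):
        model = OneToOneNetwork(TINY, seed=5)
        before = [p.value.copy() for p in model.parameters()]
        ds = StubDataset()
        gmap = GenotypeMap(ds.genotypes, 2)
        model, log = train(model, ds, gmap, TrainConfig(mode="untrained"))
        assert log == []
        for p, b in zip(model.parameters(), before):
            assert np.array_equal(p.value, b)

    def test_training_is_deterministic_given_seed(self):
        ds = StubDataset()
        gmap = GenotypeMap(ds.genotypes, 2)
        cfg = TrainConfig(mode="knockout", batches_per_epoch=3, max_epochs=2,
                          patience=10, seed=11)
        m1, _ = train(OneToOneNetwork(TINY, seed=2), ds, gmap, cfg)
        m2, _ = train(OneToOneNetwork(TINY, seed=2), ds, gmap, cfg)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(p1.value, p2.value)

    def test_constant_velocity_recovered_after_destandardization(self):
        """Closed-form z-scoring check: fitting constant velocities recovers
        the constant through the control mean."""
        const = np.array([2.5, -1.0, 10.0, 0.0, 1.0, 0.0])
        ds = StubDataset(targets=const)
        gmap = GenotypeMap(ds.genotypes, 2)
        model = OneToOneNetwork(TINY, seed=3)
        cfg = TrainConfig(mode="knockout", batches_per_epoch=8, max_epochs=6,
                          patience=100, seed=0, augment=False)
        model, _ = train(model, ds, gmap, cfg)
        imgs = ds.images["control"][:50]
        _, vel, _ = model.predict(imgs)
        # std is 0 -> unit scale; the z-space optimum is the constant itself
        assert np.allclose(vel.mean(axis=0), const[:3], atol=0.3)

    def test_divergence_raises(self):
        ds = StubDataset()
        gmap = GenotypeMap(ds.genotypes, 2)
        model = OneToOneNetwork(TINY, seed=4)
        cfg = TrainConfig(mode="knockout", learning_rate=1e6,
                          batches_per_epoch=5, max_epochs=3, seed=0)
        with pytest.raises(FloatingPointError):
            train(model, ds, gmap, cfg)


class TestEvaluate:
    def test_perfect_and_shuffled_predictions(self, rng):
        x = rng.normal(size=500)
        assert r_squared(x, x) == pytest.approx(1.0)
        assert r_squared(rng.permutation(x), x) < 0.05
        assert np.isnan(r_squared(np.ones(500), x))

    def test_song_score_bounds(self, rng):
        y = (rng.random(500) < 0.3).astype(float)
        assert song_score(np.where(y > 0, 0.999, 0.001), y) > 0.9
        assert abs(song_score(np.full(500, y.mean()), y)) < 1e-9

    def test_evaluate_returns_all_outputs(self, tiny_model, rng):
        imgs = rng.normal(-60, 40, size=(60, 10, 8, 12)).astype(np.float32)
        targets = np.column_stack([rng.normal(size=(60, 3)),
                                   (rng.random((60, 3)) < 0.4).astype(float)])
        out = evaluate(tiny_model, imgs, targets)
        assert set(out) == {"forward", "lateral", "angular",
                            "sine", "pfast", "pslow"}


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        model = OneToOneNetwork(TINY, seed=9)
        model.set_output_scaling([1, 2, 3], [4, 5, 6])
        path = tmp_path / "ckpt.h5"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        imgs = rng.normal(-60, 40, size=(3, 10, 8, 12)).astype(np.float32)
        a1 = model.predict(imgs)
        a2 = loaded.predict(imgs)
        for x, y in zip(a1, a2):
            assert np.array_equal(x, y)
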