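"""Schedule, preprocessing, augmentation, splitting and the training loop."""
import math

import numpy as np
import pytest
from scipy import ndimage

from mm3dunet.blocks import TensorShape
from mm3dunet.io_synth import PhantomSpec, VolumeSample, generate_phantom_volume
from mm3dunet.network import NetworkConfig, build_network
from mm3dunet.train import (AugmentParams, TrainConfig, augment, cosine_lr,
                            evaluate_model, sample_slab, split_dataset,
                            train_model, zscore_normalize)


class TestCosineLR:
    def test_endpoints_and_midpoint(self):
        assert cosine_lr(0, 130, 1e-4) == pytest.approx(1e-4)
        assert cosine_lr(130, 130, 1e-4) == pytest.approx(0.0, abs=1e-20)
        assert cosine_lr(65, 130, 1e-4) == pytest.approx(5e-5)

    def test_matches_closed_form_everywhere(self):
        for t in range(0, 131):
            expected = 1e-4 / 2 * (1 + math.cos(t * math.pi / 130))
            assert abs(cosine_lr(t, 130, 1e-4) - expected) < 1e-12

    def test_step_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            cosine_lr(131, 130, 1e-4)


class TestZScore:
    def test_mean_zero_sd_one(self, rng):
        v = zscore_normalize(rng.random((8, 8, 8)) * 50 + 7)
        assert abs(v.mean()) < 1e-5 and abs(v.std() - 1) < 1e-5

    def test_idempotent(self, rng):
        v = zscore_normalize(rng.random((6, 6, 6)))
        np.testing.assert_allclose(zscore_normalize(v), v, atol=1e-5)

    def test_affine_invariance(self, rng):
        x = rng.random((6, 6, 6)).astype(np.float64)
        np.testing.assert_allclose(zscore_normalize(3.5 * x + 11.0),
                                   zscore_normalize(x), atol=1e-4)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_normalize(np.full((4, 4, 4), 3.0))


def _sample(rng, shape=(16, 24, 24)):
    spec = PhantomSpec(lesion_probability=1.0, slices_per_volume=shape[0],
                       in_plane_extent=shape[1], lesion_radius_range=(3.0, 5.0))
    return generate_phantom_volume(spec, rng)


class TestAugment:
    def test_identity_draw_leaves_sample_unchanged(self, rng):
        s = _sample(rng)
        params = AugmentParams(max_rotation_deg=0.0, flip_probability=0.0,
                               intensity_scale_range=0.0)
        out = augment(s, params, np.random.default_rng(0))
        np.testing.assert_allclose(out.volume, s.volume, atol=1e-6)
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_flip_is_an_involution(self, rng):
        s = _sample(rng)
        params = AugmentParams(max_rotation_deg=0.0, flip_probability=1.0,
                               intensity_scale_range=0.0)
        once = augment(s, params, np.random.default_rng(3))
        twice = augment(once, params, np.random.default_rng(3))
        np.testing.assert_allclose(twice.volume, s.volume, atol=1e-6)
        np.testing.assert_array_equal(twice.mask, s.mask)

    def test_rotation_keeps_mask_and_volume_aligned(self, rng):
        """Lesion centroid moves identically in mask and bright region."""
        s = _sample(rng)
        params = AugmentParams(max_rotation_deg=15.0, flip_probability=0.0,
                               intensity_scale_range=0.0)
        out = augment(s, params, np.random.default_rng(11))
        assert out.mask.any()
        cen_mask = np.array(ndimage.center_of_mass(out.mask))
        bright = out.volume > np.percentile(out.volume, 97)
        cen_bright = np.array(ndimage.center_of_mass(bright))
        assert np.linalg.norm(cen_mask - cen_bright) < 4.0

    def test_rotation_roughly_preserves_mask_volume(self, rng):
        s = _sample(rng)
        params = AugmentParams(max_rotation_deg=15.0, flip_probability=0.0,
                               intensity_scale_range=0.0)
        out = augment(s, params, np.random.default_rng(5))
        assert out.mask.sum() == pytest.approx(s.mask.sum(), rel=0.05)

    def test_intensity_scaling_touches_volume_only(self, rng):
        s = _sample(rng)
        params = AugmentParams(max_rotation_deg=0.0, flip_probability=0.0,
                               intensity_scale_range=0.2)
        arng = np.random.default_rng(8)
        out = augment(s, params, arng)
        np.testing.assert_array_equal(out.mask, s.mask)
        ratio = out.volume / s.volume
        assert ratio.std() < 1e-5  # single global factor


class TestSlabSampling:
    def test_every_start_position_reachable(self, rng):
        s = _sample(rng, shape=(24, 16, 16))
        starts = set()
        srng = np.random.default_rng(0)
        for _ in range(500):
            slab = sample_slab(s, 16, srng)
            # recover the start by matching the first slice
            for st in range(9):
                if np.array_equal(s.volume[st], slab.volume[0]):
                    starts.add(st)
                    break
        assert starts == set(range(9))

    def test_full_depth_slab_is_whole_volume(self, rng):
        s = _sample(rng)
        slab = sample_slab(s, 16, np.random.default_rng(0))
        np.testing.assert_array_equal(slab.volume, s.volume)

    def test_mask_window_matches_volume_window(self, rng):
        s = _sample(rng, shape=(32, 16, 16))
        srng = np.random.default_rng(2)
        slab = sample_slab(s, 16, srng)
        # find the window and check alignment
        for st in range(17):
            if np.array_equal(s.volume[st:st + 16], slab.volume):
                np.testing.assert_array_equal(s.mask[st:st + 16], slab.mask)
                return
        pytest.fail("slab not found in source volume")

    def test_too_thin_volume_rejected(self, rng):
        s = _sample(rng, shape=(16, 16, 16))
        with pytest.raises(ValueError):
            sample_slab(s, 32, np.random.default_rng(0))


class TestSplit:
    def test_paper_scale_counts(self):
        train, test = split_dataset([f"s{i}" for i in range(219)], 0.8, seed=0)
        assert len(train) == 175 and len(test) == 44

    def test_two_samples_half_ratio(self):
        train, test = split_dataset(["a", "b"], 0.5, seed=1)
        assert len(train) == 1 and len(test) == 1

    def test_deterministic_disjoint_exhaustive(self):
        ids = [f"s{i}" for i in range(37)]
        a = split_dataset(ids, 0.8, seed=5)
        b = split_dataset(ids, 0.8, seed=5)
        assert a == b
        assert set(a[0]) | set(a[1]) == set(ids)
        assert not set(a[0]) & set(a[1])


@pytest.fixture(scope="module")
def small_run():
    """A short but real optimisation run shared across training tests."""
    spec = PhantomSpec(n_volumes=6, slices_per_volume=16, in_plane_extent=24,
                       lesion_probability=1.0, lesion_radius_range=(3.0, 5.0),
                       seed=13)
    rng = np.random.default_rng(spec.seed)
    data = [generate_phantom_volume(spec, rng, f"p{i}") for i in range(6)]
    cfg = NetworkConfig(variant="mm_3dunet", base_channels=4, num_levels=2,
                        expansion_factor=2,
                        input_shape=TensorShape(1, 16, 24, 24), seed=13)
    tc = TrainConfig(epochs=3, batch_size=2, lr0=1e-2, slab_depth=16, seed=13)
    net = build_network(cfg)
    history = train_model(net, data, tc)
    return data, cfg, tc, net, history


class TestTrainingLoop:
    def test_history_schema_and_schedule(self, small_run):
        _, _, tc, _, history = small_run
        assert list(history.columns) == ["epoch", "lr", "dice", "ce",
                                         "combined", "val_iou", "val_dsc"]
        assert len(history) == tc.epochs
        for _, row in history.iterrows():
            assert abs(row.lr - cosine_lr(int(row.epoch), tc.epochs, tc.lr0)) < 1e-12

    def test_pure_segmentation_has_zero_ce(self, small_run):
        *_, history = small_run
        assert (history.ce == 0).all()

    def test_seeded_rerun_is_bitwise_identical(self, small_run):
        data, cfg, tc, net, history = small_run
        net2 = build_network(cfg)
        history2 = train_model(net2, data, tc)
        assert history.equals(history2)
        for (k, p), (k2, p2) in zip(sorted(net.parameters().items()),
                                    sorted(net2.parameters().items())):
            assert k == k2
            np.testing.assert_array_equal(p.value, p2.value)

    def test_loss_decreases_from_start_to_end(self, small_run):
        *_, history = small_run
        assert history.combined.iloc[-1] < history.combined.iloc[0]

    def test_empty_dataset_rejected(self, small_run):
        _, cfg, tc, _, _ = small_run
        with pytest.raises(ValueError):
            train_model(build_network(cfg), [], tc)


class TestEvaluation:
    def test_oracle_network_scores_one(self, rng):
        """Evaluating against a predictor that replays ground truth."""
        s = _sample(rng)

        class Oracle:
            config = type("C", (), {"use_act": False})()

            def forward(self, x):
                from mm3dunet.network import NetworkOutput
                return NetworkOutput(seg_probs=s.mask[None].astype(np.float32))

        table = evaluate_model(Oracle(), [s], 0.5)
        mean = table[table.sample_id == "mean"]
        assert float(mean.iou.iloc[0]) == 1.0
        assert float(mean.dsc.iloc[0]) == 1.0

    def test_all_zero_predictor_scores_zero_on_lesioned(self, rng):
        s = _sample(rng)

        class Zero:
            def forward(self, x):
                from mm3dunet.network import NetworkOutput
                return NetworkOutput(seg_probs=np.zeros_like(x, dtype=np.float32))

        table = evaluate_model(Zero(), [s], 0.5)
        assert float(table[table.sample_id == "mean"].iou.iloc[0]) == 0.0

    def test_metrics_match_independent_oracles(self, small_run, rng):
        from mm3dunet.losses_metrics import confusion_counts, dsc, iou
        from mm3dunet.network import predict_mask

        data, _, _, net, _ = small_run
        table = evaluate_model(net, data[:2], 0.5)
        for k, s in enumerate(data[:2]):
            x = zscore_normalize(s.volume)[None]
            pred = predict_mask(net.forward(x), 0.5)[0]
            c = confusion_counts(pred, s.mask)
            assert float(table.iloc[k].iou) == pytest.approx(iou(c))
            assert float(table.iloc[k].dsc) == pytest.approx(dsc(c))
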