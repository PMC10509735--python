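"""Contrastive pretraining: augmentation menu, InfoNCE objective, training
behaviour and frozen feature extraction."""

import dataclasses

import numpy as np
import pytest

from stackmil import nn
from stackmil.contrastive import (AugmentationConfig, EncoderSpec, SslConfig,
                                  augment_view, build_encoder, extract_features,
                                  info_nce_loss, load_encoder, save_encoder,
                                  slices_from_bags, train_ssl)
from stackmil.errors import (ConfigurationError, DataError, ValidationError)
from stackmil.simulate import SynthConfig, generate_specimen
from stackmil.utils import derive_rng


def brute_force_info_nce(z: np.ndarray, tau: float) -> float:
    """Independent oracle: explicit double loop over anchors and candidates."""
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    n = z.shape[0]
    total = 0.0
    for a in range(n):
        pos = a ^ 1
        num = np.exp(np.dot(z[a], z[pos]) / tau)
        den = sum(np.exp(np.dot(z[a], z[o]) / tau) for o in range(n) if o != a)
        total += -np.log(num / den)
    return total / n


class TestInfoNCE:
    def test_single_pair_loss_is_zero(self):
        z = np.random.default_rng(0).normal(size=(2, 6))
        assert info_nce_loss(z, 0.5).item() == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_pairs_closed_form(self):
        """Two identical-positive pairs with orthogonal cross similarities:
        loss = ln(1 + 2 e^{-2}) at temperature 0.5."""
        z = np.array([[1.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 1.0, 0]])
        expected = np.log(1 + 2 * np.exp(-2.0))
        assert info_nce_loss(z, 0.5).item() == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.23954, abs=5e-6)

    @pytest.mark.parametrize("b,p", [(2, 4), (4, 8), (3, 5)])
    def test_matches_brute_force(self, b, p):
        rng = np.random.default_rng(b * 10 + p)
        z = rng.normal(size=(2 * b, p))
        assert info_nce_loss(z, 0.7).item() == pytest.approx(
            brute_force_info_nce(z, 0.7), abs=1e-10)

    def test_invariant_to_global_rotation(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(6, 5))
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        assert info_nce_loss(z @ q, 0.5).item() == pytest.approx(
            info_nce_loss(z, 0.5).item(), rel=1e-9)

    def test_decreases_when_positive_similarity_increases(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(8, 5))
        base = info_nce_loss(z, 0.5).item()
        z2 = z.copy()
        z2[1] = 0.8 * z2[1] + 0.2 * z2[0] * np.linalg.norm(z2[1]) / np.linalg.norm(z2[0])
        assert info_nce_loss(z2, 0.5).item() < base

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        z0 = rng.normal(size=(4, 3))
        t = nn.Tensor(z0.copy(), requires_grad=True)
        info_nce_loss(t, 0.5).backward()
        eps = 1e-6
        num = np.zeros_like(z0)
        for i in range(z0.size):
            zp, zm = z0.copy().ravel(), z0.copy().ravel()
            zp[i] += eps
            zm[i] -= eps
            num.ravel()[i] = (brute_force_info_nce(zp.reshape(4, 3), 0.5)
                              - brute_force_info_nce(zm.reshape(4, 3), 0.5)) / (2 * eps)
        np.testing.assert_allclose(t.grad, num, rtol=1e-4, atol=1e-7)

    def test_errors(self):
        z = np.eye(4)
        with pytest.raises(ConfigurationError):
            info_nce_loss(z, 0.0)
        with pytest.raises(ValidationError):
            info_nce_loss(z[:3], 0.5)


class TestAugmentation:
    def test_identity_configuration_reproduces_input(self):
        cfg = AugmentationConfig(crop_scale_range=(1.0, 1.0), rotation_set=(0,),
                                 horizontal_flip_prob=0.0, color_jitter_prob=0.0,
                                 grayscale_prob=0.0, gaussian_blur_prob=0.0,
                                 solarize_prob=0.0, output_size=24)
        img = np.random.default_rng(0).integers(0, 255, size=(24, 24, 3)
                                                ).astype(np.uint8)
        out = augment_view(img, cfg, derive_rng(0, "aug"))
        np.testing.assert_array_equal(out, img)

    def test_crop_areas_within_configured_scale(self):
        cfg = AugmentationConfig(output_size=16)
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        rng = derive_rng(1, "crop")
        lo, hi = cfg.crop_scale_range
        for _ in range(2000):
            scale = rng.uniform(lo, hi)  # the exact draw augment_view makes
            side = max(1, int(round(np.sqrt(scale) * 32)))
            area_frac = side * side / (32 * 32)
            assert lo * 0.9 <= area_frac <= hi * 1.05

    def test_rotations_drawn_from_right_angle_set(self):
        cfg = AugmentationConfig(output_size=8)
        rng = derive_rng(2, "rot")
        seen = {int(rng.choice(list(cfg.rotation_set))) for _ in range(2000)}
        assert seen == {0, 90, 180, 270}

    def test_same_rng_state_reproduces_view(self):
        cfg = AugmentationConfig(output_size=16)
        img = np.random.default_rng(3).integers(0, 255, size=(32, 32, 3)
                                                ).astype(np.uint8)
        v1 = augment_view(img, cfg, derive_rng(7, "view"))
        v2 = augment_view(img, cfg, derive_rng(7, "view"))
        np.testing.assert_array_equal(v1, v2)
        assert v1.shape == (16, 16, 3)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ConfigurationError):
            AugmentationConfig(horizontal_flip_prob=1.5)
        with pytest.raises(ConfigurationError):
            AugmentationConfig(crop_scale_range=(0.0, 1.0))


SMALL_SYNTH = SynthConfig(tile_size=32, n_slices=3, nuclei_density=8.0,
                          nucleus_radius_px=3.0, nucleus_radius_sd=0.6,
                          tiles_per_specimen_range=(4, 4), seed=1)
SMALL_SPEC = EncoderSpec(input_size=32, feature_dim=16, conv_widths=(4, 8))
SMALL_SSL = SslConfig(batch_size=16, epochs=5, learning_rate=0.01,
                      projection_dim=8, feature_dim=16, seed=2)
SMALL_AUG = AugmentationConfig(output_size=32)


def _corpus(n_specimens=4, label_split=True):
    slices = []
    for s in range(n_specimens):
        label = s % 2 if label_split else 0
        bag = generate_specimen(SMALL_SYNTH, label, specimen_seed=s)
        slices.extend(slices_from_bags([bag]))
    return slices


class TestTrainSsl:
    def test_loss_decreases_and_audit_records_consumption(self):
        corpus = _corpus(6)
        encoder, trace, consumed = train_ssl(corpus, SMALL_SPEC, SMALL_SSL,
                                             SMALL_AUG)
        assert len(trace) == SMALL_SSL.epochs
        assert trace[-1] < trace[0]
        assert consumed == {s.specimen_id for s in corpus}

    def test_same_seed_reproduces_loss_trace(self):
        corpus = _corpus(2)
        _, t1, _ = train_ssl(corpus, SMALL_SPEC, SMALL_SSL, SMALL_AUG)
        _, t2, _ = train_ssl(corpus, SMALL_SPEC, SMALL_SSL, SMALL_AUG)
        assert t1 == t2

    def test_empty_corpus_raises(self):
        with pytest.raises(DataError):
            train_ssl([], SMALL_SPEC, SMALL_SSL, SMALL_AUG)

    def test_small_corpus_warns_about_truncated_batches(self):
        corpus = _corpus(1)[:4]
        cfg = dataclasses.replace(SMALL_SSL, batch_size=64, epochs=1)
        with pytest.warns(UserWarning, match="smaller than batch size"):
            train_ssl(corpus, SMALL_SPEC, cfg, SMALL_AUG)

    def test_pretrained_features_beat_random_for_linear_probe(self):
        """Frozen contrastive features separate the two synthetic classes
        better than a frozen randomly initialized encoder under the same
        linear probe protocol."""
        from sklearn.linear_model import LogisticRegression

        from stackmil.config import desk_scale

        bags = [generate_specimen(
            dataclasses.replace(SMALL_SYNTH, morphology_effect=2.5), s % 2,
            specimen_seed=s) for s in range(24)]
        corpus = slices_from_bags(bags[:16])
        probe_spec = EncoderSpec(input_size=32, feature_dim=16,
                                 conv_widths=(8, 16))
        ssl_cfg = dataclasses.replace(SMALL_SSL, epochs=15, batch_size=32,
                                      learning_rate=0.003)
        mild_aug = desk_scale(seed=0).augment
        encoder, _, _ = train_ssl(corpus, probe_spec, ssl_cfg, mild_aug)
        random_enc = build_encoder(probe_spec, seed=123)
        random_enc.eval()

        def probe_accuracy(enc):
            def feats(bag_list):
                x, y = [], []
                for b in bag_list:
                    for t in b.tiles:
                        f = extract_features(enc, t).values.mean(axis=1)
                        x.append(f)
                        y.append(b.labels["ER"])
                return np.array(x), np.array(y)
            xtr, ytr = feats(bags[:16])
            xte, yte = feats(bags[16:])
            clf = LogisticRegression(max_iter=2000).fit(xtr, ytr)
            return clf.score(xte, yte)

        assert probe_accuracy(encoder) >= probe_accuracy(random_enc)


class TestExtraction:
    def test_feature_stack_shape_and_determinism(self):
        bag = generate_specimen(SMALL_SYNTH, 0, specimen_seed=3)
        enc = build_encoder(SMALL_SPEC, seed=1)
        enc.eval()
        f1 = extract_features(enc, bag.tiles[0])
        f2 = extract_features(enc, bag.tiles[0])
        assert f1.values.shape == (16, 3)
        np.testing.assert_array_equal(f1.values, f2.values)
        assert np.all(np.isfinite(f1.values))

    def test_full_scale_dimension_contract(self):
        """A 256x256x3x17 tile maps to a 1024x17 feature stack under the
        full-scale configuration."""
        spec = EncoderSpec(input_size=256, feature_dim=1024, conv_widths=(4, 4))
        enc = build_encoder(spec, seed=0)
        enc.eval()
        pixels = np.zeros((256, 256, 3, 17), dtype=np.uint8)
        out = extract_features(enc, pixels)
        assert out.values.shape == (1024, 17)

    def test_slice_permutation_permutes_columns(self):
        bag = generate_specimen(SMALL_SYNTH, 1, specimen_seed=4)
        enc = build_encoder(SMALL_SPEC, seed=1)
        enc.eval()
        tile = bag.tiles[0]
        perm = [2, 0, 1]
        permuted = tile.pixels[:, :, :, perm]
        f_orig = extract_features(enc, tile).values
        f_perm = extract_features(enc, permuted).values
        np.testing.assert_allclose(f_perm, f_orig[:, perm], rtol=1e-12)

    def test_substack_equals_column_subset(self):
        bag = generate_specimen(SMALL_SYNTH, 1, specimen_seed=5)
        enc = build_encoder(SMALL_SPEC, seed=1)
        enc.eval()
        tile = bag.tiles[0]
        full = extract_features(enc, tile).values
        sub = extract_features(enc, tile.pixels[:, :, :, :2]).values
        np.testing.assert_allclose(sub, full[:, :2], rtol=1e-12)

    def test_incompatible_slice_size_raises(self):
        enc = build_encoder(SMALL_SPEC, seed=1)
        with pytest.raises(ValidationError, match="incompatible"):
            extract_features(enc, np.zeros((16, 16, 3, 2), dtype=np.uint8))

    def test_checkpoint_roundtrip(self, tmp_path):
        enc = build_encoder(SMALL_SPEC, seed=9)
        enc.eval()
        path = save_encoder(enc, tmp_path / "enc.npz", ssl_config=SMALL_SSL,
                            fold=0)
        loaded = load_encoder(path)
        x = np.random.default_rng(0).integers(0, 255, size=(32, 32, 3, 2)
                                              ).astype(np.uint8)
        np.testing.assert_array_equal(extract_features(enc, x).values,
                                      extract_features(loaded, x).values)


class TestFoldHygiene:
    def test_ssl_consumption_restricted_to_training_specimens(self):
        bags = [generate_specimen(SMALL_SYNTH, s % 2, specimen_seed=s)
                for s in range(6)]
        train_bags, held_out = bags[:4], bags[4:]
        _, _, consumed = train_ssl(slices_from_bags(train_bags), SMALL_SPEC,
                                   SMALL_SSL, SMALL_AUG)
        held_ids = {b.specimen_id for b in held_out}
        assert consumed.isdisjoint(held_ids)
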