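"""MIL head: z-integration arithmetic, attention algebra, aggregation,
classification, oversampling, and end-to-end training behaviour."""

import dataclasses

import numpy as np
import pytest

from stackmil import nn
from stackmil.errors import ConfigurationError, DataError, ValidationError
from stackmil.mil import (AttentionScores, AttentionPool, ClassifierConfig,
                          MilModel, ZIntegrator, ZIntegratorSpec, aggregate,
                          attention_scores, classify, integrate_z,
                          oversample_minority, predict_bag, train_classifier)
from stackmil.utils import derive_rng


def _plain_spec(**kw):
    base = dict(n_blocks=2, channels=(4, 4), z_decompose=False)
    base.update(kw)
    return ZIntegratorSpec(**base)


class TestIntegrateZ:
    def test_identity_configuration_passes_input_through(self):
        """Z=1, identity kernels, zero bias, nonnegative input -> unchanged."""
        spec = _plain_spec(n_blocks=2, channels=(3, 3), kernel_size=1)
        integ = ZIntegrator(3, spec, derive_rng(0, "z"))
        eye = np.eye(3)[:, :, None]  # (out, in, k=1)
        for block in integ.blocks:
            block.weight.data = eye.copy()
            block.bias.data = np.zeros(3)
        x = np.array([[1.0], [2.0], [0.5]])  # (D=3, Z=1), nonnegative
        np.testing.assert_allclose(integrate_z(x, integ), x[:, 0], rtol=1e-12)

    def test_hand_convolution_oracle(self):
        """One block, kernel (1,1,1) with same padding on rows [1,2,3] and
        [0,1,0]: convolution sums each row's 3-neighbourhoods, mean collapse
        averages over z."""
        spec = _plain_spec(n_blocks=1, channels=(2,), kernel_size=3)
        integ = ZIntegrator(2, spec, derive_rng(1, "z"))
        w = np.zeros((2, 2, 3))
        w[0, 0] = [1, 1, 1]
        w[1, 1] = [1, 1, 1]
        integ.blocks[0].weight.data = w
        integ.blocks[0].bias.data = np.zeros(2)
        x = np.array([[1.0, 2.0, 3.0], [0.0, 1.0, 0.0]])
        # same-padded window sums: row0 -> [3, 6, 5]; row1 -> [1, 1, 1]
        expected = np.array([np.mean([3, 6, 5]), np.mean([1, 1, 1])])
        np.testing.assert_allclose(integrate_z(x, integ), expected, rtol=1e-12)

    def test_all_zero_input_zero_bias_gives_zero(self):
        spec = _plain_spec(channels=(4, 4))
        integ = ZIntegrator(2, spec, derive_rng(2, "z"))
        for block in integ.blocks:
            block.bias.data = np.zeros_like(block.bias.data)
        out = integrate_z(np.zeros((2, 5)), integ)
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_z_decompose_preserves_information_shape(self):
        spec = ZIntegratorSpec(channels=(4, 4), z_decompose=True)
        integ = ZIntegrator(3, spec, derive_rng(3, "z"))
        out = integrate_z(np.random.default_rng(0).normal(size=(3, 7)), integ)
        assert out.shape == (4,)

    def test_spec_validation(self):
        with pytest.raises(ConfigurationError):
            ZIntegratorSpec(n_blocks=2, channels=(4,))
        with pytest.raises(ConfigurationError):
            ZIntegratorSpec(z_collapse="select")


class TestAttention:
    def test_singleton_bag_gets_weight_one(self):
        pool = AttentionPool(3, 4, derive_rng(0, "a"))
        scores = attention_scores(np.random.default_rng(0).normal(size=(1, 3)), pool)
        np.testing.assert_allclose(scores.weights, [1.0])

    def test_identical_representations_get_uniform_weights(self):
        pool = AttentionPool(3, 4, derive_rng(1, "a"))
        reprs = np.tile(np.array([0.3, -1.0, 2.0]), (5, 1))
        scores = attention_scores(reprs, pool)
        np.testing.assert_allclose(scores.weights, 0.2, rtol=1e-12)

    def test_hand_set_parameters_softmax_closed_form(self):
        """Pre-softmax scores (2, 0) -> weights (e^2/(e^2+1), 1/(e^2+1))."""
        pool = AttentionPool(1, 1, derive_rng(2, "a"))
        pool.v.weight.data = np.array([[10.0]])  # saturate tanh to sign(x)
        pool.v.bias.data = np.zeros(1)
        pool.w.weight.data = np.array([[1.0]])
        pool.w.bias.data = np.array([1.0])
        # inputs (+big, -big) -> tanh -> (1, -1) -> scores (2, 0)
        scores = attention_scores(np.array([[5.0], [-5.0]]), pool)
        e2 = np.exp(2.0)
        np.testing.assert_allclose(scores.weights,
                                   [e2 / (e2 + 1), 1 / (e2 + 1)], rtol=1e-6)
        np.testing.assert_allclose(scores.weights, [0.8808, 0.1192], atol=1e-4)

    def test_permutation_equivariance(self):
        pool = AttentionPool(4, 8, derive_rng(3, "a"))
        reprs = np.random.default_rng(3).normal(size=(6, 4))
        perm = np.random.default_rng(4).permutation(6)
        w1 = attention_scores(reprs, pool).weights
        w2 = attention_scores(reprs[perm], pool).weights
        np.testing.assert_allclose(w2, w1[perm], rtol=1e-12)

    def test_scores_validation(self):
        with pytest.raises(ValidationError):
            AttentionScores(weights=np.array([0.7, 0.7]))  # does not sum to 1
        with pytest.raises(ValidationError):
            AttentionScores(weights=np.array([1.5, -0.5]))  # negative


class TestAggregate:
    def test_single_tile_all_modes_coincide(self):
        r = np.array([[1.0, -2.0, 3.0]])
        s = AttentionScores(weights=np.array([1.0]))
        for mode in ("meanpool", "maxpool", "attention"):
            np.testing.assert_allclose(
                aggregate(r, mode, s if mode == "attention" else None), r[0])

    def test_mean_and_max_arithmetic(self):
        r = np.array([[0.0, 2.0], [2.0, 0.0]])
        np.testing.assert_allclose(aggregate(r, "meanpool"), [1.0, 1.0])
        np.testing.assert_allclose(aggregate(r, "maxpool"), [2.0, 2.0])

    def test_attention_weighted_sum(self):
        r = np.array([[0.0, 2.0], [2.0, 0.0]])
        s = AttentionScores(weights=np.array([0.25, 0.75]))
        np.testing.assert_allclose(aggregate(r, "attention", s), [1.5, 0.5])

    def test_uniform_attention_equals_meanpool(self):
        rng = np.random.default_rng(5)
        r = rng.normal(size=(7, 5))
        s = AttentionScores(weights=np.full(7, 1 / 7))
        np.testing.assert_allclose(aggregate(r, "attention", s),
                                   aggregate(r, "meanpool"), rtol=1e-12)

    def test_attention_without_scores_rejected(self):
        with pytest.raises(ValidationError):
            aggregate(np.ones((2, 2)), "attention")


class TestClassify:
    def test_zero_parameters_give_even_odds(self):
        clf = nn.Linear(4, 2, derive_rng(0, "c"))
        clf.weight.data = np.zeros((4, 2))
        clf.bias.data = np.zeros(2)
        np.testing.assert_allclose(classify(np.ones(4), clf), [0.5, 0.5])

    def test_log3_logit_gives_three_to_one(self):
        clf = nn.Linear(1, 2, derive_rng(1, "c"))
        clf.weight.data = np.array([[np.log(3.0), 0.0]])
        clf.bias.data = np.zeros(2)
        np.testing.assert_allclose(classify(np.array([1.0]), clf), [0.75, 0.25],
                                   rtol=1e-12)

    def test_probabilities_sum_to_one_over_parameter_sweep(self):
        rng = np.random.default_rng(2)
        clf = nn.Linear(3, 2, rng)
        for _ in range(1000):
            clf.weight.data = rng.normal(scale=3.0, size=(3, 2))
            clf.bias.data = rng.normal(scale=3.0, size=2)
            p = classify(rng.normal(size=3), clf)
            assert abs(p.sum() - 1.0) < 1e-6
            # strictly positive; the upper bound may saturate to 1.0 in
            # float64 for extreme logits
            assert p.min() > 0 and p.max() <= 1.0

    def test_non_finite_bag_repr_rejected(self):
        clf = nn.Linear(2, 2, derive_rng(3, "c"))
        with pytest.raises(ValidationError):
            classify(np.array([np.nan, 1.0]), clf)


class TestOversampling:
    def test_three_vs_nine_yields_eighteen_items(self):
        ids = [f"p{i}" for i in range(3)] + [f"n{i}" for i in range(9)]
        labels = {i: 1 if i.startswith("p") else 0 for i in ids}
        out = oversample_minority(ids, labels, seed=0)
        assert len(out) == 18
        assert sum(labels[i] for i in out) == 9                 # 9 positive draws
        assert sorted(i for i in out if labels[i] == 0) == sorted(
            i for i in ids if labels[i] == 0)                   # majority once

    def test_balanced_input_unchanged(self):
        ids = [f"s{i}" for i in range(10)]
        labels = {i: int(i[1:]) % 2 for i in ids}
        assert oversample_minority(ids, labels, seed=1) == ids

    def test_seeded_determinism(self):
        ids = [f"s{i}" for i in range(12)]
        labels = {i: 1 if int(i[1:]) < 4 else 0 for i in ids}
        assert oversample_minority(ids, labels, 7) == oversample_minority(ids, labels, 7)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            oversample_minority(["a", "b"], {"a": 1, "b": 1}, seed=0)


def _toy_features(n_bags=50, n_tiles=6, d=16, z=5, shift=4.0, seed=0):
    """Linearly separable bag features: positives shifted in 8 coordinates."""
    rng = derive_rng(seed, "toy-features")
    feats, labels = {}, {}
    for i in range(n_bags):
        lab = i % 2
        sid = f"S{i:03d}"
        x = rng.normal(size=(n_tiles, d, z))
        if lab:
            x[:, :8, :] += shift / np.sqrt(z)
        feats[sid] = x
        labels[sid] = lab
    return feats, labels


TRAIN_CFG = ClassifierConfig(aggregation_mode="attention", learning_rate=0.003,
                             epochs=30, seed=1)
TRAIN_SPEC = ZIntegratorSpec(channels=(16, 16))


class TestTraining:
    def test_separable_features_reach_perfect_training_accuracy(self):
        feats, labels = _toy_features()
        model, trace, consumed = train_classifier(feats, labels, TRAIN_CFG,
                                                  TRAIN_SPEC)
        assert trace[-1] < trace[0]
        acc = np.mean([(predict_bag(model, feats[s])[0][1] > 0.5) == labels[s]
                       for s in feats])
        assert acc == 1.0
        assert consumed == set(feats)

    def test_same_seed_identical_loss_trace(self):
        feats, labels = _toy_features(n_bags=12)
        _, t1, _ = train_classifier(feats, labels, TRAIN_CFG, TRAIN_SPEC)
        _, t2, _ = train_classifier(feats, labels, TRAIN_CFG, TRAIN_SPEC)
        assert t1 == t2

    def test_attention_concentrates_on_signal_tiles(self):
        """Bags where exactly one tile carries the class signal: the mean
        attention weight on signal tiles exceeds uniform 1/N on positive
        bags."""
        rng = derive_rng(3, "signal-tiles")
        n_tiles, d, z = 6, 16, 3
        feats, labels, signal_idx = {}, {}, {}
        for i in range(40):
            lab = i % 2
            sid = f"S{i:03d}"
            x = rng.normal(size=(n_tiles, d, z))
            j = int(rng.integers(n_tiles))
            if lab:
                x[j, :8, :] += 3.0
            feats[sid], labels[sid], signal_idx[sid] = x, lab, j
        cfg = dataclasses.replace(TRAIN_CFG, epochs=40)
        model, _, _ = train_classifier(feats, labels, cfg, TRAIN_SPEC)
        weights = []
        for sid in feats:
            if labels[sid] != 1:
                continue
            _, scores = predict_bag(model, feats[sid])
            weights.append(scores.weights[signal_idx[sid]])
        assert np.mean(weights) > 1.0 / n_tiles

    def test_one_step_updates_all_three_submodules(self):
        feats, labels = _toy_features(n_bags=4)
        cfg = dataclasses.replace(TRAIN_CFG, epochs=1)
        model = MilModel(16, TRAIN_SPEC, cfg)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        opt = nn.Adam(model.parameters(), lr=0.01)
        logits = model.forward_logits(nn.Tensor(feats["S001"]))
        loss = nn.cross_entropy(logits, 1)
        opt.zero_grad()
        loss.backward()
        opt.step()
        after = model.state_dict()
        changed = {k for k in before if not np.array_equal(before[k], after[k])}
        assert any(k.startswith("integrator") for k in changed)
        assert any(k.startswith("attention") for k in changed)
        assert any(k.startswith("classifier") for k in changed)

    def test_insufficient_class_counts_rejected(self):
        feats, labels = _toy_features(n_bags=4)
        labels = {k: 0 for k in labels}
        with pytest.raises(DataError):
            train_classifier(feats, labels, TRAIN_CFG, TRAIN_SPEC)
        with pytest.raises(DataError):
            train_classifier({}, {}, TRAIN_CFG, TRAIN_SPEC)


@pytest.fixture(scope="module")
def trained():
    feats, labels = _toy_features(n_bags=20)
    model, _, _ = train_classifier(feats, labels, TRAIN_CFG, TRAIN_SPEC)
    return model, feats


class TestPrediction:

    def test_tile_order_invariance(self, trained):
        model, feats = trained
        x = feats["S003"]
        perm = np.random.default_rng(0).permutation(x.shape[0])
        p1, s1 = predict_bag(model, x)
        p2, s2 = predict_bag(model, x[perm])
        assert abs(p1[1] - p2[1]) < 1e-9
        np.testing.assert_allclose(s2.weights, s1.weights[perm], rtol=1e-9)

    def test_single_tile_bag_mode_coincidence(self, trained):
        """All three aggregators coincide on a single-tile bag."""
        model, feats = trained
        x = feats["S000"][:1]  # one tile
        probs = {}
        for mode in ("meanpool", "maxpool", "attention"):
            model.config = dataclasses.replace(model.config,
                                               aggregation_mode=mode)
            probs[mode] = predict_bag(model, x)[0][1]
        model.config = dataclasses.replace(model.config,
                                           aggregation_mode="attention")
        assert probs["meanpool"] == pytest.approx(probs["attention"], abs=1e-12)
        assert probs["maxpool"] == pytest.approx(probs["attention"], abs=1e-12)

    def test_duplicated_tiles_invariant_under_meanpool(self):
        feats, labels = _toy_features(n_bags=20)
        cfg = dataclasses.replace(TRAIN_CFG, aggregation_mode="meanpool")
        model, _, _ = train_classifier(feats, labels, cfg, TRAIN_SPEC)
        x = feats["S005"]
        doubled = np.concatenate([x, x], axis=0)
        p1, _ = predict_bag(model, x)
        p2, _ = predict_bag(model, doubled)
        assert abs(p1[1] - p2[1]) < 1e-9

    def test_attention_weights_normalized_every_pass(self, trained):
        model, feats = trained
        for sid in list(feats)[:10]:
            _, scores = predict_bag(model, feats[sid])
            assert abs(scores.weights.sum() - 1.0) < 1e-6
            assert np.all(scores.weights >= 0)

    def test_restart_selection_keeps_lowest_loss_run(self):
        feats, labels = _toy_features(n_bags=12)
        cfg = dataclasses.replace(TRAIN_CFG, epochs=5, restarts=3)
        _, trace_multi, _ = train_classifier(feats, labels, cfg, TRAIN_SPEC)
        singles = []
        from stackmil.utils import derive_seed
        for r in range(3):
            cfg_r = dataclasses.replace(cfg, restarts=1,
                                        seed=derive_seed(cfg.seed, "restart", r))
            _, tr, _ = train_classifier(feats, labels, cfg_r, TRAIN_SPEC)
            singles.append(tr[-1])
        assert trace_multi[-1] == pytest.approx(min(singles))
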