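import numpy as np
import pytest

from incepspect.nets import (
    CbamSpec,
    InceptionSpec,
    NetConfig,
    Tensor,
    build_network,
    cbam,
    channel_attention,
    fit_net,
    mish,
    predict_net,
    regularized_loss,
    spatial_attention,
    train,
)
from incepspect.nets.models import Cbam

from conftest import make_set


class TestMish:
    def test_zero(self):
        assert mish(0.0) == 0.0

    def test_large_positive_approaches_identity(self):
        assert abs(mish(50.0) - 50.0) < 1e-9

    def test_known_value(self):
        # 1 * tanh(ln(1 + e)) evaluated independently to high precision
        assert mish(1.0) == pytest.approx(0.8650983882673103, abs=1e-12)

    def test_closed_form_on_grid(self):
        x = np.linspace(-20.0, 20.0, 1000)
        expected = x * np.tanh(np.log1p(np.exp(np.minimum(x, 30.0))))
        np.testing.assert_allclose(mish(x), expected, atol=1e-9)

    def test_extreme_inputs_stable(self):
        out = mish(np.array([-50.0, -500.0, 500.0]))
        assert np.all(np.isfinite(out))
        assert out[2] == pytest.approx(500.0)

    def test_tensor_path_matches_array_path(self, rng):
        x = rng.normal(size=(4, 5))
        np.testing.assert_allclose(Tensor(x).mish().data, mish(x), atol=1e-6)


class TestChannelAttention:
    def test_spatial_permutation_invariance(self, rng):
        F = rng.normal(size=(2, 8, 16))
        spec = CbamSpec(reduction_ratio=4)
        base = channel_attention(F, spec, rng=np.random.default_rng(0))
        perm = F[:, :, rng.permutation(16)]
        permuted = channel_attention(perm, spec, rng=np.random.default_rng(0))
        np.testing.assert_allclose(base, permuted, atol=1e-6)

    def test_zero_init_gives_half(self, rng):
        F = rng.normal(size=(3, 8, 10))
        out = channel_attention(F, CbamSpec(), zero_init=True)
        np.testing.assert_allclose(out, 0.5, atol=1e-12)

    def test_bounded_open_interval(self, rng):
        out = channel_attention(rng.normal(size=(2, 6, 12)), CbamSpec())
        assert np.all(out > 0) and np.all(out < 1)

    def test_output_shape(self, rng):
        out = channel_attention(rng.normal(size=(4, 16, 9)), CbamSpec())
        assert out.shape == (4, 16)


class TestSpatialAttention:
    def test_channel_permutation_invariance(self, rng):
        F = rng.normal(size=(2, 8, 16))
        spec = CbamSpec(spatial_kernel=7)
        base = spatial_attention(F, spec, rng=np.random.default_rng(0))
        perm = F[:, rng.permutation(8), :]
        permuted = spatial_attention(perm, spec, rng=np.random.default_rng(0))
        np.testing.assert_allclose(base, permuted, atol=1e-6)

    def test_zero_init_gives_half(self, rng):
        out = spatial_attention(rng.normal(size=(2, 4, 11)), CbamSpec(),
                                zero_init=True)
        np.testing.assert_allclose(out, 0.5, atol=1e-12)

    @pytest.mark.parametrize("kernel", [3, 5, 7, 9])
    def test_length_preserved(self, kernel, rng):
        F = rng.normal(size=(2, 4, 13))
        out = spatial_attention(F, CbamSpec(spatial_kernel=kernel))
        assert out.shape == (2, 1, 13)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            CbamSpec(spatial_kernel=4)


class TestCbam:
    def test_zero_init_quarter(self, rng):
        F = rng.normal(size=(2, 8, 10))
        out = cbam(F, CbamSpec(), zero_init=True)
        np.testing.assert_allclose(out, 0.25 * F, atol=1e-6)

    def test_bounded_by_input(self, rng):
        F = rng.normal(size=(3, 8, 12))
        out = cbam(F, CbamSpec())
        assert np.all(np.abs(out) <= np.abs(F) + 1e-12)

    def test_shape_preserved(self, rng):
        F = rng.normal(size=(5, 16, 21))
        assert cbam(F, CbamSpec()).shape == F.shape


class TestBuildNetwork:
    def test_forward_shape_batch32(self):
        net = build_network(NetConfig(seed=0), 213)
        x = np.random.default_rng(0).normal(size=(32, 1, 213))
        net.eval()
        assert net(Tensor(x)).shape == (32, 1)

    @pytest.mark.parametrize("arch", ["deepspectra", "cnn1d"])
    def test_baseline_forward_shapes(self, arch):
        net = build_network(NetConfig(architecture=arch, seed=0), 213)
        net.eval()
        x = np.random.default_rng(0).normal(size=(4, 1, 213))
        assert net(Tensor(x)).shape == (4, 1)

    def test_no_cbam_has_fewer_parameters(self):
        full = build_network(NetConfig(seed=0), 213)
        nocbam = build_network(NetConfig(variant="no_cbam", seed=0), 213)
        assert nocbam.n_parameters() < full.n_parameters()

    @pytest.mark.parametrize("variant", ["no_cbam", "no_inception", "no_residual"])
    def test_variants_forward(self, variant):
        net = build_network(NetConfig(variant=variant, seed=0), 213)
        net.eval()
        x = np.random.default_rng(0).normal(size=(3, 1, 213))
        assert net(Tensor(x)).shape == (3, 1)

    def test_same_seed_identical_init(self):
        a = build_network(NetConfig(seed=42), 213)
        b = build_network(NetConfig(seed=42), 213)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_different_seed_differs(self):
        a = build_network(NetConfig(seed=1), 213)
        b = build_network(NetConfig(seed=2), 213)
        assert any(not np.array_equal(pa.data, pb.data)
                   for pa, pb in zip(a.parameters(), b.parameters()))

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="stem"):
            build_network(NetConfig(seed=0), 3)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetConfig(architecture="transformer")
        with pytest.raises(ValueError):
            NetConfig(variant="bogus")
        with pytest.raises(ValueError):
            NetConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            InceptionSpec(0, 1, 1, 1)


class TestLoss:
    def _tiny_net(self):
        return build_network(NetConfig(
            seed=0, stem_filters=2, inception1=InceptionSpec(1, 1, 1, 1),
            inception2=InceptionSpec(1, 1, 1, 1), fc_units=3), 21)

    def test_perfect_predictions_zero(self):
        net = self._tiny_net()
        pred = Tensor(np.array([0.3, 0.7]))
        assert regularized_loss(pred, np.array([0.3, 0.7]), net, 0.0).data == 0.0

    def test_lambda_zero_is_mse(self):
        net = self._tiny_net()
        pred = Tensor(np.array([0.0, 0.0]))
        loss = regularized_loss(pred, np.array([1.0, 3.0]), net, 0.0)
        assert float(loss.data) == pytest.approx(5.0)

    def test_l2_term_counts_weights_only(self):
        net = self._tiny_net()
        pred = Tensor(np.zeros(2))
        lam = 0.01
        loss = regularized_loss(pred, np.zeros(2), net, lam)
        expected = lam * sum(float((w.data**2).sum())
                             for w in net.weight_parameters())
        assert float(loss.data) == pytest.approx(expected, rel=1e-5)

    def test_empty_batch_errors(self):
        net = self._tiny_net()
        with pytest.raises(ValueError, match="empty"):
            regularized_loss(Tensor(np.zeros((0,))), np.zeros(0), net, 0.0)


def _small_training_setup(n=48, p=21):
    rng = np.random.default_rng(5)
    y = rng.uniform(size=n)
    X = np.outer(y, rng.normal(size=p)) + 0.05 * rng.normal(size=(n, p))
    X = (X - X.min(0)) / np.maximum(X.max(0) - X.min(0), 1e-9)
    data = make_set(X, y)
    cfg = NetConfig(seed=3, stem_filters=4, inception1=InceptionSpec(2, 2, 2, 2),
                    inception2=InceptionSpec(2, 2, 2, 2), fc_units=8,
                    max_epochs=8, patience=8, batch_size=16)
    return data, cfg


class TestTraining:
    def test_loss_decreases(self):
        data, cfg = _small_training_setup()
        model = fit_net(data, cfg)
        assert model.history[0]["train_loss"] > min(h["train_loss"]
                                                    for h in model.history)

    def test_identical_seed_identical_history(self):
        data, cfg = _small_training_setup()
        a = fit_net(data, cfg)
        b = fit_net(data, cfg)
        assert a.history == b.history
        for pa, pb in zip(a.network.parameters(), b.network.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_predict_deterministic_and_shaped(self):
        data, cfg = _small_training_setup()
        model = fit_net(data, cfg)
        p1 = predict_net(model, data)
        p2 = predict_net(model, data)
        np.testing.assert_array_equal(p1, p2)
        assert p1.shape == (data.n_samples,)

    def test_predict_single_row(self):
        data, cfg = _small_training_setup()
        model = fit_net(data, cfg)
        assert predict_net(model, data.subset([0])).shape == (1,)

    def test_length_mismatch_rejected(self):
        data, cfg = _small_training_setup()
        model = fit_net(data, cfg)
        other = make_set(np.zeros((2, 10)), [0.1, 0.2])
        with pytest.raises(ValueError, match="wavelengths"):
            predict_net(model, other)

    def test_history_nonempty_and_finite(self):
        data, cfg = _small_training_setup()
        model = fit_net(data, cfg)
        assert len(model.history) > 0
        assert all(np.isfinite(h["train_loss"]) for h in model.history)


class TestCbamModuleInNetwork:
    def test_gates_in_unit_interval_random_net(self, rng):
        spec = CbamSpec(reduction_ratio=4)
        mod = Cbam(8, spec, rng=np.random.default_rng(7))
        mod.eval()
        F = rng.normal(size=(2, 8, 15))
        mc = mod.channel(Tensor(F)).data
        ms = mod.spatial(Tensor(F)).data
        assert np.all((mc > 0) & (mc < 1))
        assert np.all((ms > 0) & (ms < 1))
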