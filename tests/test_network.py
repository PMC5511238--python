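"""Network construction, training sanity and seeded determinism."""

import numpy as np
import pytest

from dlradiomics import NetworkSpec, SgdConfig, build_network, train_network
from dlradiomics.network import Conv, ConvNet, NetworkSpecError
from dlradiomics.preprocessing import PatchSet


def _weights(net):
    return [lay.W for lay in net.layers if isinstance(lay, Conv)]


def _toy_patchset(n=200, seed=0, n_channels=1):
    """Linearly separable bright-vs-dark patches."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n)
    patches = rng.normal(size=(n, n_channels, 33, 33)) * 0.5 + labels[:, None, None, None] * 1.5
    return PatchSet(patches=patches, labels=labels, centers=[("toy", 0, 0, 0)] * n)


class TestBuildNetwork:
    def test_default_spec_has_128_deep_filters(self):
        spec = NetworkSpec()
        assert spec.n_conv_layers == 6
        assert spec.fc_neurons == 4096
        assert spec.n_filters == 128
        net = build_network(spec, seed=0)
        assert net.n_parameters > 0
        assert net.receptive_field <= 33

    def test_shallow_ablation_builds(self):
        spec = NetworkSpec(
            n_conv_layers=1, conv_filters=(64,), fc_neurons=256, n_input_channels=1
        )
        net = build_network(spec, seed=0)
        p = net.forward_patches(np.random.default_rng(0).normal(size=(3, 1, 33, 33)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_forward_probabilities_sum_to_one(self, tiny_net):
        p = tiny_net.forward_patches(np.random.default_rng(1).normal(size=(5, 2, 33, 33)))
        assert p.shape == (5, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_depth_incompatible_with_patch_rejected(self):
        with pytest.raises(NetworkSpecError):
            build_network(
                NetworkSpec(
                    n_conv_layers=6,
                    conv_filters=(4,) * 6,
                    fc_neurons=8,
                    patch_size=13,
                )
            )

    def test_mismatched_filter_list_rejected(self):
        with pytest.raises(NetworkSpecError):
            NetworkSpec(n_conv_layers=3, conv_filters=(4, 8))


class TestTrainNetwork:
    def test_learns_separable_toy_problem(self):
        spec = NetworkSpec(
            n_conv_layers=1, conv_filters=(4,), fc_neurons=16, n_input_channels=1
        )
        net = build_network(spec, seed=0)
        train_network(net, _toy_patchset(), SgdConfig(n_epochs=15, batch_size=64), seed=0)
        assert net.training_log[-1]["accuracy"] >= 0.95

    def test_seeded_determinism(self):
        spec = NetworkSpec(
            n_conv_layers=1, conv_filters=(4,), fc_neurons=8, n_input_channels=1
        )
        ps = _toy_patchset(n=64)
        nets = []
        for _ in range(2):
            net = build_network(spec, seed=3)
            train_network(net, ps, SgdConfig(n_epochs=2, batch_size=32), seed=3)
            nets.append(net)
        for wa, wb in zip(_weights(nets[0]), _weights(nets[1])):
            assert np.array_equal(wa, wb)

    def test_empty_patch_set_rejected(self, tiny_net):
        ps = PatchSet(
            patches=np.empty((0, 2, 33, 33)), labels=np.empty(0, dtype=int), centers=[]
        )
        with pytest.raises(ValueError):
            train_network(tiny_net, ps)

    def test_single_class_rejected(self, tiny_net):
        ps = _toy_patchset(n=20, n_channels=2)
        ps.labels[:] = 1
        with pytest.raises(ValueError):
            train_network(tiny_net, ps)


class TestCheckpoint:
    def test_roundtrip(self, tiny_net, tmp_path):
        path = tmp_path / "net.npz"
        tiny_net.save(path)
        loaded = ConvNet.load(path)
        assert loaded.spec == tiny_net.spec
        for wa, wb in zip(_weights(tiny_net), _weights(loaded)):
            assert np.array_equal(wa, wb)
        x = np.random.default_rng(2).normal(size=(2, 2, 33, 33))
        np.testing.assert_array_equal(
            tiny_net.forward_patches(x), loaded.forward_patches(x)
        )
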