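import numpy as np
import pytest

from hemocloud.autodiff import Tensor
from hemocloud.pointnet import (
    CHANNEL_PRESETS,
    ExtractorConfig,
    PointNetExtractor,
    extract_features,
    feature_dimension,
    orthogonality_penalty,
    sample_input_points,
    standardize_points,
    train_extractor,
)
from hemocloud.types import ValidationError
from conftest import random_cloud


def perturb_tnets(net, rng, scale=0.3):
    """Move the T-Net output layers off the identity to exercise alignment."""
    for tnet in (net.input_tnet, net.feature_tnet):
        tnet.fc2.W.data = rng.normal(0, scale / tnet.d, tnet.fc2.W.data.shape).astype(
            tnet.fc2.W.data.dtype
        )
    return net


class TestConfig:
    @pytest.mark.parametrize("dim,channels", sorted(CHANNEL_PRESETS.items()))
    def test_feature_dimension_presets(self, dim, channels):
        assert feature_dimension(ExtractorConfig(channels=channels)) == dim

    def test_channel_ordering_enforced(self):
        with pytest.raises(ValidationError):
            ExtractorConfig(channels=(16, 8, 16, 16))
        with pytest.raises(ValidationError):
            ExtractorConfig(channels=(8, 8, 32, 16))

    def test_attribute_count_fixed(self):
        with pytest.raises(ValidationError):
            ExtractorConfig(n_attributes=6)


class TestSampling:
    def test_large_cloud_subsample_without_replacement(self, rng):
        cloud = random_cloud(rng, n=3000)
        pts = sample_input_points(cloud, 1024, np.random.default_rng(0))
        assert pts.shape == (1024, 7)
        # every sampled row exists in the source cloud
        src = {tuple(row) for row in cloud.matrix}
        assert all(tuple(row) in src for row in pts)
        # without replacement: all rows distinct
        assert len({tuple(row) for row in pts}) == 1024

    def test_exact_size_cloud_is_permutation(self, rng):
        cloud = random_cloud(rng, n=1024)
        pts = sample_input_points(cloud, 1024, np.random.default_rng(1))
        assert sorted(map(tuple, pts)) == sorted(map(tuple, cloud.matrix))

    def test_small_cloud_sampled_with_replacement(self, rng):
        cloud = random_cloud(rng, n=10)
        pts = sample_input_points(cloud, 64, np.random.default_rng(2))
        assert pts.shape == (64, 7)

    def test_seeded_determinism(self, rng):
        cloud = random_cloud(rng, n=3000)
        a = sample_input_points(cloud, 1024, np.random.default_rng(7))
        b = sample_input_points(cloud, 1024, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestForwardContracts:
    @pytest.mark.parametrize("dim,channels", sorted(CHANNEL_PRESETS.items()))
    def test_global_feature_length(self, dim, channels, rng):
        cloud = random_cloud(rng, n=3000)
        net = PointNetExtractor(ExtractorConfig(channels=channels, seed=1))
        vec = extract_features(cloud, net, rng=np.random.default_rng(0))
        assert vec.values.shape == (dim,)
        assert np.isfinite(vec.values).all()

    def test_identity_tnets_at_initialisation(self, rng):
        """Zero-initialised final T-Net layers start as exact identity transforms."""
        net = PointNetExtractor(ExtractorConfig(seed=0))
        x = standardize_points(random_cloud(rng, n=64).matrix)[None]
        out = net.forward(x, training=False)
        np.testing.assert_array_equal(out["input_transform"].data[0], np.eye(3))
        np.testing.assert_array_equal(out["feature_transform"].data[0], np.eye(8))

    def test_input_transform_leaves_attributes_untouched(self, rng):
        net = perturb_tnets(PointNetExtractor(ExtractorConfig(seed=0)), rng)
        x = standardize_points(random_cloud(rng, n=32).matrix)[None]
        aligned, t = net.input_transform(Tensor(x), training=False)
        np.testing.assert_array_equal(aligned.data[:, :, 3:], x[:, :, 3:])
        # coordinates equal explicit multiplication by the emitted matrix
        np.testing.assert_allclose(
            aligned.data[:, :, :3], x[:, :, :3] @ t.data, rtol=1e-6
        )

    def test_shared_mlp_weight_sharing(self, rng):
        net = PointNetExtractor(ExtractorConfig(seed=3))
        x = standardize_points(random_cloud(rng, n=16).matrix).astype(np.float32)
        batch = net.mlp1(Tensor(x[None]), training=False).data[0]
        single = net.mlp1(Tensor(x[4:5][None]), training=False).data[0, 0]
        np.testing.assert_allclose(batch[4], single, rtol=1e-6)

    def test_permutation_invariance_bit_identical(self, rng):
        cloud = random_cloud(rng, n=2000)
        net = perturb_tnets(PointNetExtractor(ExtractorConfig(seed=5)), rng)
        pts = sample_input_points(cloud, 1024, np.random.default_rng(3))
        base = extract_features(cloud, net, points=pts).values
        for _ in range(100):
            perm = rng.permutation(len(pts))
            out = extract_features(cloud, net, points=pts[perm]).values
            assert (out == base).all()


class TestOrthogonalityPenalty:
    def test_orthogonal_matrix_zero(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        assert float(orthogonality_penalty(Tensor(q)).data) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("k", [3, 8])
    def test_scaled_identity_closed_form(self, k):
        # ||2I (2I)^T - I||_F^2 = ||3I||_F^2 = 9k
        val = float(orthogonality_penalty(Tensor(2.0 * np.eye(k))).data)
        assert val == pytest.approx(9.0 * k, rel=1e-12)


class TestOracleEquivalence:
    def test_forward_matches_straight_loop(self, rng):
        """Full network on a 5-point toy cloud vs an independent per-point loop."""
        net = perturb_tnets(PointNetExtractor(ExtractorConfig(seed=11)), rng)
        x = standardize_points(random_cloud(rng, n=5).matrix)  # (5, 7)
        got = net.forward(x[None].astype(np.float32), training=False)["global"].data[0]

        def lin(v, layer):
            return layer.W.data.astype(float).T @ v + layer.b.data.astype(float)

        def bn(v, layer):
            rm = layer.running_mean.astype(float)
            rv = layer.running_var.astype(float)
            g = layer.gamma.data.astype(float)
            b = layer.beta.data.astype(float)
            return (v - rm) / np.sqrt(rv + layer.eps) * g + b

        def mlp(v, block):
            for l, bnorm in zip(block.linears, block.bns):
                v = np.maximum(bn(lin(v, l), bnorm), 0.0)
            return v

        def tnet(points, t):
            per = [mlp(p, t.mlp) for p in points]
            pooled = np.max(per, axis=0)
            h = np.maximum(bn(lin(pooled, t.fc1), t.bn1), 0.0)
            return lin(h, t.fc2).reshape(t.d, t.d)

        pts = [row.astype(float) for row in x]
        t_in = tnet([p[:3] for p in pts], net.input_tnet)
        aligned = [np.r_[p[:3] @ t_in, p[3:]] for p in pts]
        local = [mlp(p, net.mlp1) for p in aligned]
        t_feat = tnet(local, net.feature_tnet)
        lifted = [mlp(f @ t_feat, net.mlp2) for f in local]
        expected = np.max(lifted, axis=0)
        np.testing.assert_allclose(got, expected, rtol=1e-4, atol=1e-5)


class TestTraining:
    def make_clouds(self, rng, n_cases=8, n_points=128):
        clouds, labels = [], []
        for i in range(n_cases):
            label = i % 2
            cloud = random_cloud(rng, n=n_points, case_id=f"c{i}")
            # inject a crude label signal into wss
            cloud.data["wss"] *= 1.0 + 2.0 * label
            clouds.append(cloud)
            labels.append(label)
        return clouds, np.array(labels)

    def cfg(self, **kw):
        base = dict(channels=(4, 4, 8, 8), n_input_points=64, epochs=4,
                    batch_size=4, seed=2)
        base.update(kw)
        return ExtractorConfig(**base)

    def test_zero_epochs_returns_initialisation(self, rng):
        clouds, labels = self.make_clouds(rng)
        net = train_extractor(clouds, labels, self.cfg(epochs=0))
        fresh = PointNetExtractor(self.cfg(epochs=0))
        for a, b in zip(net.params(), fresh.params()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_loss_decreases(self, rng):
        clouds, labels = self.make_clouds(rng)
        net = train_extractor(clouds, labels, self.cfg(epochs=6))
        assert net.history[-1] <= net.history[0]

    def test_seeded_determinism(self, rng):
        clouds, labels = self.make_clouds(rng)
        n1 = train_extractor(clouds, labels, self.cfg())
        n2 = train_extractor(clouds, labels, self.cfg())
        for a, b in zip(n1.params(), n2.params()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_single_class_rejected(self, rng):
        clouds, _ = self.make_clouds(rng, n_cases=4)
        with pytest.raises(ValidationError):
            train_extractor(clouds, np.zeros(4, dtype=int), self.cfg())

    def test_save_load_roundtrip(self, rng, tmp_path):
        clouds, labels = self.make_clouds(rng)
        net = train_extractor(clouds, labels, self.cfg())
        path = tmp_path / "weights.npz"
        net.save(path)
        loaded = PointNetExtractor.load(path)
        pts = sample_input_points(clouds[0], 64, np.random.default_rng(0))
        a = extract_features(clouds[0], net, points=pts).values
        b = extract_features(clouds[0], loaded, points=pts).values
        np.testing.assert_array_equal(a, b)
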