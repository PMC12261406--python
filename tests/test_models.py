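"""Architecture contracts for every model family in the zoo."""

import math

import numpy as np
import pytest

from ppibench.autograd import Tensor
from ppibench.estimators import (
    MapCapabilityError,
    RandomForestPairClassifier,
    make_model,
    registry_names,
)
from ppibench.models import (
    DScriptNet,
    InteractionModule,
    RFEGPHead,
    RichouxNet,
    TunaNet,
    TwoDNet,
    dscript_pair_features,
    pairwise_outer_product,
)

D_EMB = 32


def random_pair(rng, l1=12, l2=15, d=D_EMB):
    return rng.standard_normal((l1, d)), rng.standard_normal((l2, d))


class TestPairwiseOuterProduct:
    def test_small_example(self):
        t = pairwise_outer_product(np.array([[1.0, 2.0]]),
                                   np.array([[3.0, 4.0], [5.0, 6.0]])).data
        np.testing.assert_array_equal(t[0, 0], [3.0, 8.0])
        np.testing.assert_array_equal(t[0, 1], [5.0, 12.0])

    def test_swap_transposes_first_axes(self, rng):
        a, b = rng.standard_normal((4, 6)), rng.standard_normal((7, 6))
        t1 = pairwise_outer_product(a, b).data
        t2 = pairwise_outer_product(b, a).data
        np.testing.assert_array_equal(t1, t2.transpose(1, 0, 2))

    def test_matches_triple_loop_oracle(self, rng):
        a, b = rng.standard_normal((4, 3)), rng.standard_normal((5, 3))
        t = pairwise_outer_product(a, b).data
        for i in range(4):
            for j in range(5):
                for c in range(3):
                    assert t[i, j, c] == a[i, c] * b[j, c]

    def test_mismatched_features_rejected(self, rng):
        with pytest.raises(ValueError):
            pairwise_outer_product(rng.standard_normal((3, 4)),
                                   rng.standard_normal((3, 5)))


class TestDScriptPairFeatures:
    def test_small_example(self):
        f = dscript_pair_features(np.array([[1.0, 4.0]]),
                                  np.array([[3.0, 1.0]])).data
        np.testing.assert_array_equal(f[0, 0], [2.0, 3.0, 3.0, 4.0])

    def test_symmetry(self, rng):
        a, b = rng.standard_normal((4, 6)), rng.standard_normal((7, 6))
        fab = dscript_pair_features(a, b).data
        fba = dscript_pair_features(b, a).data
        np.testing.assert_array_equal(fab, fba.transpose(1, 0, 2))

    def test_matches_triple_loop_oracle(self, rng):
        a, b = rng.standard_normal((3, 4)), rng.standard_normal((5, 4))
        f = dscript_pair_features(a, b).data
        for i in range(3):
            for j in range(5):
                expect = np.concatenate([np.abs(a[i] - b[j]), a[i] * b[j]])
                np.testing.assert_allclose(f[i, j], expect, atol=1e-14)


class TestInteractionModule:
    def test_monotone_under_positive_shift(self, rng):
        mod = InteractionModule(pool_kernel=2)
        mod.log_weight.data[...] = rng.standard_normal() * 0.3
        mod.log_gain.data[...] = rng.standard_normal() * 0.3
        for _ in range(20):
            m = np.abs(rng.standard_normal((rng.integers(3, 9), rng.integers(3, 9))))
            assert mod(m + 1.0).item() >= mod(m).item()

    def test_score_strictly_inside_unit_interval(self, rng):
        mod = InteractionModule()
        for _ in range(5):
            s = mod(np.abs(rng.standard_normal((6, 6)))).item()
            assert 0.0 < s < 1.0

    def test_uniform_map_size_invariance(self):
        mod = InteractionModule(pool_kernel=2)
        s1 = mod(np.full((4, 4), 0.7)).item()
        s2 = mod(np.full((10, 8), 0.7)).item()
        assert abs(s1 - s2) < 1e-6

    def test_all_zero_map_scores_sigmoid_offset(self):
        mod = InteractionModule()
        mod.offset.data[...] = 0.3
        expect = 1.0 / (1.0 + math.exp(-0.3))
        assert abs(mod(np.zeros((5, 5))).item() - expect) < 1e-12


class TestRFEGPHead:
    def test_variance_nonnegative_and_seeded(self, rng):
        h1 = RFEGPHead(6, 64, np.random.default_rng(3))
        h2 = RFEGPHead(6, 64, np.random.default_rng(3))
        v = rng.standard_normal(6)
        h1.eval(), h2.eval()
        (l1, var1), (l2, var2) = h1(v), h2(v)
        assert var1 >= 0.0
        assert l1.item() == l2.item() and var1 == var2

    def test_kernel_approximation_approaches_rbf(self, rng):
        head = RFEGPHead(5, 8192, np.random.default_rng(0))
        for _ in range(10):
            u, v = rng.standard_normal(5), rng.standard_normal(5)
            approx = float(head.features(u).data @ head.features(v).data)
            exact = math.exp(-np.sum((u - v) ** 2) / 2.0)
            assert abs(approx - exact) < 0.05

    def test_feature_count_validated(self):
        with pytest.raises(ValueError):
            RFEGPHead(4, 0)


class TestTwoDNet:
    def test_score_in_unit_interval_and_map_shape(self, rng):
        net = TwoDNet(D_EMB, kernel_size=3, seed=1)
        net.eval()
        a, b = random_pair(rng)
        score, pair_map = net(a, b)
        assert 0.0 < score.item() < 1.0
        assert pair_map.shape == (12 - 3 + 1, 15 - 3 + 1)

    def test_eval_mode_deterministic(self, rng):
        net = TwoDNet(D_EMB, attention="self", encoder_position="post_reduction",
                      dropout=0.3, seed=1)
        net.eval()
        a, b = random_pair(rng)
        s1 = net(a, b)[0].item()
        s2 = net(a, b)[0].item()
        assert s1 == s2

    def test_reduce_layers_shared_between_proteins(self, rng):
        net = TwoDNet(D_EMB, seed=0)
        x = rng.standard_normal((6, D_EMB))
        ra = net._reduce(Tensor(x)).data
        rb = net._reduce(Tensor(x)).data
        np.testing.assert_array_equal(ra, rb)

    def test_reduction_matches_affine_oracle(self, rng):
        net = TwoDNet(8, reduction_sizes=(5,), seed=0)
        x = rng.standard_normal((3, 8))
        out = net._reduce(Tensor(x)).data
        layer = net.reduce_layers[0]
        expect = np.maximum(x @ layer.W.data + layer.b.data, 0.0)
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_inconsistent_encoder_config_rejected(self):
        with pytest.raises(ValueError):
            TwoDNet(D_EMB, attention="self", encoder_position="none")
        with pytest.raises(ValueError):
            TwoDNet(D_EMB, attention="none", encoder_position="pre_reduction")


class TestRichouxNet:
    def test_rejects_per_token_input(self, rng):
        net = RichouxNet(D_EMB, seed=0)
        with pytest.raises(TypeError):
            net(rng.standard_normal((3, 5, D_EMB)), rng.standard_normal((3, 5, D_EMB)))

    def test_asymmetry_allowed(self, rng):
        net = RichouxNet(D_EMB, seed=0)
        net.eval()
        a, b = rng.standard_normal(D_EMB), rng.standard_normal(D_EMB)
        # unshared reduction weights: swapping inputs may change the score
        s_ab = net.score_pair(a, b).item()
        s_ba = net.score_pair(b, a).item()
        assert 0.0 < s_ab < 1.0 and 0.0 < s_ba < 1.0
        assert not math.isclose(s_ab, s_ba, abs_tol=1e-12)

    def test_parameter_count_closed_form(self):
        h = D_EMB  # default hidden width
        net = RichouxNet(D_EMB, seed=0)
        per_protein = (D_EMB * h + h) + (h * h + h) + 4 * h  # 2 linears + 2 BN
        joint = (2 * h) * h + h + 2 * h  # joint linear + BN
        out = h * 1 + 1
        assert net.n_parameters() == 2 * per_protein + joint + out


class TestDScriptNet:
    def test_map_nonnegative_and_score_in_interval(self, rng):
        net = DScriptNet(D_EMB, d=16, h=8, seed=3)
        net.eval()
        a, b = random_pair(rng)
        score, pair_map = net(a, b)
        assert (pair_map.data >= 0.0).all()
        assert 0.0 < score.item() < 1.0

    def test_short_protein_rejected(self, rng):
        net = DScriptNet(D_EMB, d=16, h=8, kernel_size=3, seed=3)
        with pytest.raises(ValueError):
            net(rng.standard_normal((4, D_EMB)), rng.standard_normal((12, D_EMB)))

    def test_swap_transposes_map_with_symmetric_weights(self, rng):
        net = DScriptNet(D_EMB, d=8, h=4, kernel_size=3, dropout=0.0, seed=3)
        net.eval()
        # constant positive conv weights make the stack symmetric, so the
        # pair-feature symmetry F(A,B)[i,j] == F(B,A)[j,i] must propagate
        net.conv1.W.data[...] = 0.05
        net.conv1.b.data[...] = 0.0
        net.conv2.W.data[...] = 0.05
        net.conv2.b.data[...] = 0.0
        a, b = random_pair(rng, 10, 13)
        m_ab = net(a, b)[1].data
        m_ba = net(b, a)[1].data
        np.testing.assert_allclose(m_ab, m_ba.T, atol=1e-8)


class TestTunaNet:
    def test_swap_symmetry_exact(self, rng):
        for variant in ({}, {"attention": "cross"}, {"spectral_norm": False}):
            net = TunaNet(D_EMB, d_att=16, n_rff=32, padded=False, seed=4, **variant)
            net.eval()
            a, b = random_pair(rng, 9, 14)
            assert net(a, b)[0].item() == net(b, a)[0].item()

    def test_padded_and_unpadded_agree(self, rng):
        padded = TunaNet(D_EMB, d_att=16, n_rff=32, padded=True, pad_len=40, seed=4)
        unpadded = TunaNet(D_EMB, d_att=16, n_rff=32, padded=False, seed=4)
        unpadded.load_state_dict(padded.state_dict())
        padded.eval(), unpadded.eval()
        a, b = random_pair(rng, 9, 14)
        assert abs(padded(a, b)[0].item() - unpadded(a, b)[0].item()) < 1e-5

    def test_uncertainty_nonnegative(self, rng):
        net = TunaNet(D_EMB, d_att=16, n_rff=32, padded=False, seed=4)
        net.eval()
        a, b = random_pair(rng)
        assert net(a, b)[1] >= 0.0

    def test_overlong_protein_rejected(self, rng):
        net = TunaNet(D_EMB, d_att=16, pad_len=10, padded=True, seed=4)
        with pytest.raises(ValueError, match="pad_len"):
            net(rng.standard_normal((12, D_EMB)), rng.standard_normal((5, D_EMB)))


class TestRandomForestBaseline:
    def test_deterministic_given_seed(self, rng):
        X = [(rng.standard_normal(8), rng.standard_normal(8)) for _ in range(40)]
        y = rng.integers(0, 2, size=40)
        p1 = RandomForestPairClassifier(seed=5).fit(X, y).score_pairs(X)
        p2 = RandomForestPairClassifier(seed=5).fit(X, y).score_pairs(X)
        np.testing.assert_array_equal(p1, p2)

    def test_separable_pairs_perfect_training_accuracy(self, rng):
        z = rng.standard_normal((30, 8))
        X, y = [], []
        for _ in range(120):
            i, j = rng.integers(0, 30, size=2)
            X.append((z[i], z[j]))
            y.append(int(z[i] @ z[j] > 0))
        clf = RandomForestPairClassifier(seed=0).fit(X, y)
        assert (clf.predict(X) == np.array(y)).mean() == 1.0

    def test_inconsistent_feature_lengths_rejected(self, rng):
        X = [(rng.standard_normal(8), rng.standard_normal(8)),
             (rng.standard_normal(8), rng.standard_normal(9))]
        with pytest.raises(ValueError, match="inconsistent"):
            RandomForestPairClassifier().fit(X, [0, 1])

    def test_pca_reduced_width_is_forty(self, rng):
        # RFC-40: 20 PCA components per protein -> 40 concatenated features
        from ppibench.experiments import prepare_synthetic_samples
        from ppibench.synthetic import SyntheticConfig

        cfg = SyntheticConfig(n_proteins=36, pairs_per_protein=4, seed=6)
        splits, _ = prepare_synthetic_samples(cfg, "protein", pca_components=20)
        a, b = splits["train"][0][0]
        assert len(a) == len(b) == 20
        feats = RandomForestPairClassifier._features(splits["train"][0])
        assert feats.shape[1] == 40

    def test_predict_map_unsupported(self, rng):
        clf = RandomForestPairClassifier()
        with pytest.raises(MapCapabilityError):
            clf.predict_map([])


class TestRegistry:
    def test_unknown_name_lists_valid_ones(self):
        with pytest.raises(KeyError, match="2d-baseline"):
            make_model("no-such-model")

    def test_every_registry_model_instantiates(self):
        for name in registry_names():
            model = make_model(name)
            assert hasattr(model, "fit")

    @pytest.mark.parametrize("name", [n for n in registry_names() if "RFC" not in n])
    def test_parameter_counts_match_closed_form(self, name):
        """Closed-form parameter arithmetic guards against silent drift."""
        model = make_model(name)
        net = model._build_net(D_EMB)
        assert net.n_parameters() == expected_parameter_count(name, D_EMB)


def linear_params(i, o):
    return i * o + o


def encoder_params(k, ff):
    mha = 4 * linear_params(k, k)
    norms = 4 * k
    ffn = linear_params(k, ff) + linear_params(ff, k)
    return mha + norms + ffn


def expected_parameter_count(name: str, d_emb: int) -> int:
    from ppibench.estimators import REGISTRY

    params = REGISTRY[name]["params"]
    if name.startswith("2d"):
        s1, s2, s3 = d_emb // 2, d_emb // 4, 64
        total = linear_params(d_emb, s1) + linear_params(s1, s2) + linear_params(s2, s3)
        total += 9 * s3 * 1 + 1  # 3x3 conv, one output channel
        pos = params.get("encoder_position", "none")
        if pos == "pre_reduction":
            total += encoder_params(d_emb, 4 * d_emb)
        elif pos == "post_reduction":
            total += encoder_params(s3, 4 * s3)
        return total
    if name.startswith("Richoux"):
        h = d_emb
        per_protein = linear_params(d_emb, h) + linear_params(h, h) + 4 * h
        total = 2 * per_protein + linear_params(2 * h, h) + 2 * h + linear_params(h, 1)
        if params.get("attention") == "self":
            total += encoder_params(d_emb, 4 * d_emb)
        return total
    if name.startswith("D-SCRIPT"):
        d = min(100, d_emb)
        h = d // 2
        total = linear_params(d_emb, d)
        total += 9 * (2 * d) * h + h + 2 * h  # conv1 + BN
        total += 9 * h * 1 + 1 + 2  # conv2 + BN(1)
        total += 3  # interaction module scalars
        pos = params.get("encoder_position", "none")
        if pos == "pre_reduction":
            total += encoder_params(d_emb, 4 * d_emb)
        elif pos == "post_reduction":
            total += encoder_params(d, 4 * d)
        return total
    if name.startswith("TUnA"):
        d_att, n_rff = 64, 256
        total = linear_params(d_emb, d_att)
        total += 2 * encoder_params(d_att, 4 * d_att)
        total += linear_params(n_rff, 1)
        return total
    raise AssertionError(f"unhandled family for {name}")
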