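import itertools
import math

import numpy as np
import pytest

from evscore import fusion
from evscore.errors import DataError, ParseError, ValidationError
from evscore.fusion import (SUBSETS, FeatureVector, LabeledScorePair,
                            build_network, evaluate_accuracy, forward,
                            load_network, read_dataset_tsv, save_network,
                            train, write_dataset_tsv)
from evscore.synth import make_calibrated_teacher, make_labeled_dataset


def forward_oracle(net, p):
    """Straight-line re-implementation of the three-layer forward pass."""
    subsets = [c for k in range(1, 7)
               for c in itertools.combinations(range(1, 7), k)]
    alphas = []
    for row, subset in enumerate(subsets):
        z = sum(net.w1[row, j - 1] * p[j - 1] for j in subset) - net.theta1[row]
        alphas.append(1.0 / (1.0 + math.exp(-z)))
    betas = []
    for i in range(1, 7):
        z = sum(net.w2[i - 1, col] * alphas[col]
                for col, s in enumerate(subsets) if len(s) == i) - net.theta2[i - 1]
        betas.append(1.0 / (1.0 + math.exp(-z)))
    return sum(net.lam[k] * betas[k] for k in range(6)) - net.theta_out


class TestArchitecture:
    def test_subset_layer_has_63_nodes(self):
        net = build_network(1)
        assert len(SUBSETS) == 63
        assert net.w1.shape[0] == 63

    def test_threshold_census_is_70(self):
        for seed in (0, 1, 99):
            assert build_network(seed).n_thresholds == 70

    def test_canonical_subset_order(self):
        assert SUBSETS[0] == (1,)
        assert SUBSETS[5] == (6,)
        assert SUBSETS[6] == (1, 2)
        assert SUBSETS[-1] == (1, 2, 3, 4, 5, 6)
        sizes = [len(s) for s in SUBSETS]
        assert sizes == sorted(sizes)

    def test_same_seed_identical_networks(self):
        a, b = build_network(7), build_network(7)
        np.testing.assert_array_equal(a.w1, b.w1)
        np.testing.assert_array_equal(a.lam, b.lam)

    def test_connectivity_masks_enforced(self):
        net = build_network(3)
        for row, subset in enumerate(SUBSETS):
            absent = set(range(1, 7)) - set(subset)
            assert all(net.w1[row, j - 1] == 0.0 for j in absent)
        for i in range(6):
            for col, s in enumerate(SUBSETS):
                if len(s) != i + 1:
                    assert net.w2[i, col] == 0.0


class TestForward:
    def test_all_zero_parameters_give_zero_output(self):
        net = fusion.FusionNetwork(np.zeros((63, 6)), np.zeros(63),
                                   np.zeros((6, 63)), np.zeros(6),
                                   np.zeros(6), 0.0)
        fv = FeatureVector(0.3, 0.9, 0.1, 0.5, 0.0, 1.0)
        assert forward(net, fv) == pytest.approx(0.0)

    def test_propagated_constant_half(self):
        # lambda = (1,0,...,0), all weights/thresholds 0: beta_1 = sigmoid(0)
        net = fusion.FusionNetwork(np.zeros((63, 6)), np.zeros(63),
                                   np.zeros((6, 63)), np.zeros(6),
                                   np.array([1, 0, 0, 0, 0, 0.0]), 0.0)
        assert forward(net, FeatureVector(*([0.5] * 6))) == pytest.approx(0.5)

    def test_matches_independent_oracle(self):
        net = build_network(0)
        for p in ([0.5] * 6, [0, 0.2, 0.4, 0.6, 0.8, 1.0], [1.0] * 6):
            assert forward(net, FeatureVector(*p)) == pytest.approx(
                forward_oracle(net, p), abs=1e-12)

    def test_feature_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            forward(build_network(0), FeatureVector(1.5, 0, 0, 0, 0, 0))

    def test_subset_node_insensitive_to_excluded_input(self):
        """Perturbing feature j never changes an H1 node excluding j."""
        net = build_network(5)
        base = np.full(6, 0.4)
        a1_base = fusion._forward_batch(net, base[None, :])[0][0]
        for j in range(6):
            bumped = base.copy()
            bumped[j] = 0.9
            a1 = fusion._forward_batch(net, bumped[None, :])[0][0]
            for row, subset in enumerate(SUBSETS):
                if (j + 1) not in subset:
                    assert a1[row] == a1_base[row]


class TestGradients:
    def test_backprop_matches_central_differences(self, rng):
        """Analytic gradients vs finite differences, 1e-5 relative."""
        net = build_network(0)
        P = rng.random((16, 6))
        y = rng.random(16)
        grads = fusion.gradients(net, P, y)
        eps = 1e-6

        def loss(n):
            return fusion.mse(n, (P, y))

        def check(get, set_, analytic):
            base = get()
            set_(base + eps)
            up = loss(net)
            set_(base - eps)
            dn = loss(net)
            set_(base)
            numeric = (up - dn) / (2 * eps)
            denom = max(1e-8, abs(analytic) + abs(numeric))
            assert abs(analytic - numeric) / denom < 1e-5

        for row, subset in enumerate(SUBSETS):
            for j in subset:
                check(lambda: net.w1[row, j - 1],
                      lambda v, r=row, jj=j: net.w1.__setitem__((r, jj - 1), v),
                      grads[0][row, j - 1])
            check(lambda: net.theta1[row],
                  lambda v, r=row: net.theta1.__setitem__(r, v),
                  grads[1][row])
        for i in range(6):
            cols = [c for c, s in enumerate(SUBSETS) if len(s) == i + 1]
            for c in cols[:4]:
                check(lambda: net.w2[i, c],
                      lambda v, ii=i, cc=c: net.w2.__setitem__((ii, cc), v),
                      grads[2][i, c])
            check(lambda: net.theta2[i],
                  lambda v, ii=i: net.theta2.__setitem__(ii, v),
                  grads[3][i])
            check(lambda: net.lam[i],
                  lambda v, ii=i: net.lam.__setitem__(ii, v),
                  grads[4][i])

        base = net.theta_out
        net.theta_out = base + eps
        up = loss(net)
        net.theta_out = base - eps
        dn = loss(net)
        net.theta_out = base
        numeric = (up - dn) / (2 * eps)
        assert abs(grads[5] - numeric) / max(1e-8, abs(grads[5]) + abs(numeric)) < 1e-5

    def test_absent_edges_have_zero_gradient(self, rng):
        net = build_network(2)
        grads = fusion.gradients(net, rng.random((8, 6)), rng.random(8))
        assert np.all(grads[0][fusion.H1_MASK == 0] == 0.0)
        assert np.all(grads[2][fusion.H2_MASK == 0] == 0.0)


class TestTrain:
    def test_zero_epochs_leaves_network_unchanged(self, rng):
        net = build_network(1)
        data = (rng.random((10, 6)), rng.random(10))
        out = train(net, data, epochs=0)
        np.testing.assert_array_equal(out.w1, net.w1)
        assert out.theta_out == net.theta_out

    def test_constant_label_dataset_reduces_mse(self, rng):
        net = build_network(1)
        data = (rng.random((50, 6)), np.full(50, 0.7))
        before = fusion.mse(net, data)
        after = fusion.mse(train(net, data, lr=0.1, epochs=200), data)
        assert after < before

    def test_full_batch_loss_strictly_non_increasing(self):
        teacher = make_calibrated_teacher(3)
        (P, y), _ = make_labeled_dataset(teacher, n_train=500, n_test=0, seed=3)
        net = build_network(4)
        losses = []
        cur = net
        for _ in range(40):
            losses.append(fusion.mse(cur, (P, y)))
            cur = train(cur, (P, y), lr=0.01, epochs=1)
        losses.append(fusion.mse(cur, (P, y)))
        assert all(b <= a + 1e-15 for a, b in zip(losses, losses[1:]))

    def test_training_respects_connectivity_mask(self, rng):
        data = (rng.random((30, 6)), rng.random(30))
        out = train(build_network(0), data, lr=0.5, epochs=50)
        assert np.all(out.w1[fusion.H1_MASK == 0] == 0.0)
        assert np.all(out.w2[fusion.H2_MASK == 0] == 0.0)

    def test_empty_data_is_error(self):
        with pytest.raises(DataError):
            train(build_network(0), (np.zeros((0, 6)), np.zeros(0)))

    def test_deterministic_given_seed(self, rng):
        data = (rng.random((64, 6)), rng.random(64))
        a = train(build_network(0), data, lr=0.3, epochs=5, seed=9, batch_size=16)
        b = train(build_network(0), data, lr=0.3, epochs=5, seed=9, batch_size=16)
        np.testing.assert_array_equal(a.w1, b.w1)
        np.testing.assert_array_equal(a.lam, b.lam)


class TestEvaluateAccuracy:
    def test_perfect_predictor(self):
        teacher = make_calibrated_teacher(5)
        (P, y), _ = make_labeled_dataset(teacher, n_train=200, n_test=0,
                                         noise_sd=0.0, seed=5)
        assert evaluate_accuracy(teacher, (P, y), 0.1) == 1.0

    def test_tolerance_one_accepts_everything(self, rng):
        net = make_calibrated_teacher(6)
        data = (rng.random((50, 6)), rng.random(50))
        assert evaluate_accuracy(net, data, tolerance=1.0) == 1.0


class TestSerialisation:
    def test_roundtrip(self, tmp_path):
        net = train(build_network(3),
                    (np.random.default_rng(0).random((20, 6)),
                     np.random.default_rng(1).random(20)), epochs=10)
        path = tmp_path / "net.txt"
        save_network(net, path)
        back = load_network(path)
        np.testing.assert_array_equal(back.w1, net.w1)
        np.testing.assert_array_equal(back.w2, net.w2)
        np.testing.assert_array_equal(back.theta1, net.theta1)
        np.testing.assert_array_equal(back.lam, net.lam)
        assert back.theta_out == net.theta_out

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("not a network\n", encoding="utf-8")
        with pytest.raises(ParseError):
            load_network(path)

    def test_dataset_tsv_roundtrip(self, tmp_path, rng):
        P, y = rng.random((15, 6)), rng.random(15)
        path = tmp_path / "data.tsv"
        write_dataset_tsv((P, y), path)
        P2, y2 = read_dataset_tsv(path)
        np.testing.assert_allclose(P2, P)
        np.testing.assert_allclose(y2, y)


class TestDomainTypes:
    def test_label_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            LabeledScorePair(FeatureVector(*[0.5] * 6), 1.2)

    def test_feature_vector_array_roundtrip(self):
        fv = FeatureVector(0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
        assert FeatureVector.from_array(fv.as_array()) == fv
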