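"""Contrastive hinge, pair bookkeeping, and the combined objective."""

import numpy as np
import pytest

from mclswt import (
    ContrastiveConfig,
    assign_pair_sign,
    cross_entropy,
    hinge_pair_loss,
    make_pairset,
    mirror_set_loss,
    original_set_loss,
    total_loss,
)
from mclswt.autodiff import Tensor

CFG = ContrastiveConfig()  # alpha 0.2, beta 1.2


class TestSignAndHinge:
    @pytest.mark.parametrize("li,lj,g", [(0, 0, 1), (1, 1, 1), (0, 1, -1), (1, 0, -1)])
    def test_sign_assignment(self, li, lj, g):
        assert assign_pair_sign(li, lj) == g

    def test_original_and_its_mirror_always_negative(self):
        # mirror trials carry the swapped label, so the pair sign is -1
        for label in (0, 1):
            assert assign_pair_sign(label, 1 - label) == -1

    @pytest.mark.parametrize(
        "g,D,expected",
        [
            (+1, 1.0, 0.0),  # boundary of the positive margin: 0.2 + (1.0-1.2)
            (+1, 1.5, 0.5),
            (-1, 1.0, 0.4),  # 0.2 - (1.0-1.2)
            (-1, 1.6, 0.0),  # clipped at zero
            (-1, 0.0, 1.4),  # a mirror collapsed onto its original
        ],
    )
    def test_hinge_hand_cases(self, g, D, expected):
        assert hinge_pair_loss(D, g, 0.2, 1.2) == pytest.approx(expected, abs=1e-12)

    def test_hinge_vectorized(self):
        out = hinge_pair_loss(np.array([1.0, 1.5]), np.array([1, 1]), 0.2, 1.2)
        np.testing.assert_allclose(out, [0.0, 0.5], atol=1e-12)


def brute_force_lo(emb, labels, cfg):
    vals = []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            D = np.linalg.norm(emb[i] - emb[j])
            g = 1 if labels[i] == labels[j] else -1
            vals.append(max(cfg.alpha + g * (D - cfg.beta), 0.0))
    if not vals:
        return 0.0
    return float(np.mean(vals) if cfg.aggregation == "mean" else np.sum(vals))


def brute_force_lm(emb_m, lab_m, emb_o, lab_o, cfg):
    vals = []
    for i in range(len(lab_m)):
        for j in range(len(lab_o)):
            D = np.linalg.norm(emb_m[i] - emb_o[j])
            g = 1 if lab_m[i] == lab_o[j] else -1
            vals.append(max(cfg.alpha + g * (D - cfg.beta), 0.0))
    if not vals:
        return 0.0
    return float(np.mean(vals) if cfg.aggregation == "mean" else np.sum(vals))


class TestPairLosses:
    def test_lo_zero_for_coincident_same_label(self):
        emb = np.zeros((2, 4))
        assert original_set_loss(emb, [0, 0], CFG) == 0.0

    def test_single_trial_no_pairs(self):
        assert original_set_loss(np.zeros((1, 4)), [0], CFG) == 0.0

    @pytest.mark.parametrize("aggregation", ["mean", "sum"])
    @pytest.mark.parametrize("n", [3, 4, 6])
    def test_lo_matches_brute_force_enumeration(self, n, aggregation):
        rng = np.random.default_rng(n)
        cfg = ContrastiveConfig(aggregation=aggregation)
        emb = rng.standard_normal((n, 5))
        labels = rng.integers(0, 2, size=n)
        assert original_set_loss(emb, labels, cfg) == pytest.approx(
            brute_force_lo(emb, labels, cfg), abs=1e-12
        )

    @pytest.mark.parametrize("aggregation", ["mean", "sum"])
    def test_lm_matches_brute_force_enumeration(self, aggregation):
        rng = np.random.default_rng(5)
        cfg = ContrastiveConfig(aggregation=aggregation)
        emb_o = rng.standard_normal((4, 5))
        emb_m = rng.standard_normal((3, 5))
        lab_o = np.array([0, 1, 0, 1])
        lab_m = np.array([1, 0, 1])
        assert mirror_set_loss(emb_m, lab_m, emb_o, lab_o, cfg) == pytest.approx(
            brute_force_lm(emb_m, lab_m, emb_o, lab_o, cfg), abs=1e-12
        )

    def test_mirror_identical_to_original_costs_1p4(self):
        emb = np.ones((1, 4))
        assert mirror_set_loss(emb, [1], emb, [0], CFG) == pytest.approx(1.4, abs=1e-12)

    def test_empty_mirror_set(self):
        assert mirror_set_loss(np.zeros((0, 4)), [], np.zeros((2, 4)), [0, 1], CFG) == 0.0

    def test_sum_equals_mean_times_pair_count(self):
        rng = np.random.default_rng(9)
        emb = rng.standard_normal((5, 3))
        labels = [0, 1, 0, 1, 0]
        mean = original_set_loss(emb, labels, ContrastiveConfig(aggregation="mean"))
        total = original_set_loss(emb, labels, ContrastiveConfig(aggregation="sum"))
        assert total == pytest.approx(mean * 10, rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        emb = rng.standard_normal((6, 4))
        labels = np.array([0, 1, 1, 0, 1, 0])
        perm = rng.permutation(6)
        assert original_set_loss(emb, labels, CFG) == pytest.approx(
            original_set_loss(emb[perm], labels[perm], CFG), rel=1e-9
        )


class TestPairSet:
    def test_structure(self):
        ps = make_pairset(np.array([0, 1, 0]), np.array([1, 0, 1]))
        assert (ps.origin == "oo").sum() == 3  # C(3,2)
        assert (ps.origin == "mo").sum() == 9  # 3 x 3
        assert np.all(ps.i != ps.j)
        # each original vs its own mirror is a negative pair
        own = (ps.i == ps.j + 3) & (ps.origin == "mo")
        assert np.all(ps.g[own] == -1)


class TestTotalLoss:
    def test_perfect_predictions_zero_ce(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy(probs, [0, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_predictions_ln2(self):
        probs = np.full((4, 2), 0.5)
        assert cross_entropy(probs, [0, 1, 0, 1]) == pytest.approx(np.log(2), rel=1e-12)

    def test_zero_weights_reduce_to_cross_entropy(self):
        rng = np.random.default_rng(2)
        probs = rng.dirichlet([1, 1], size=6)
        emb = rng.standard_normal((6, 4))
        labels = np.array([0, 1, 0, 1, 0, 1])
        ps = make_pairset(labels[:3], labels[3:])
        cfg = ContrastiveConfig(w_o=0.0, w_m=0.0)
        L, L_c, _, _ = total_loss(probs, labels, emb, ps, cfg)
        assert L == pytest.approx(L_c, rel=1e-12)
        assert L_c == pytest.approx(cross_entropy(probs, labels), rel=1e-12)

    def test_ablation_flags_zero_terms(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet([1, 1], size=4)
        emb = rng.standard_normal((4, 4)) * 3
        labels = np.array([0, 1, 1, 0])
        ps = make_pairset(labels[:2], labels[2:])
        cfg = ContrastiveConfig(enable_Lo=False, enable_Lm=False)
        L, L_c, L_o, L_m = total_loss(probs, labels, emb, ps, cfg)
        assert L_o == 0.0 and L_m == 0.0 and L == pytest.approx(L_c)

    def test_combination_weights(self):
        rng = np.random.default_rng(4)
        probs = rng.dirichlet([1, 1], size=4)
        emb = rng.standard_normal((4, 4))
        labels = np.array([0, 1, 1, 0])
        ps = make_pairset(labels[:2], labels[2:])
        cfg = ContrastiveConfig(w_o=0.2, w_m=0.3)
        L, L_c, L_o, L_m = total_loss(probs, labels, emb, ps, cfg)
        assert L == pytest.approx(L_c + 0.2 * L_o + 0.3 * L_m, rel=1e-12)
        lo_direct = original_set_loss(emb[:2], labels[:2], cfg)
        lm_direct = mirror_set_loss(emb[2:], labels[2:], emb[:2], labels[:2], cfg)
        assert L_o == pytest.approx(lo_direct, rel=1e-12)
        assert L_m == pytest.approx(lm_direct, rel=1e-12)

    def test_all_terms_nonnegative(self):
        rng = np.random.default_rng(5)
        probs = rng.dirichlet([1, 1], size=8)
        emb = rng.standard_normal((8, 6))
        labels = rng.integers(0, 2, size=8)
        ps = make_pairset(labels[:4], labels[4:])
        for v in total_loss(probs, labels, emb, ps, CFG):
            assert v >= 0.0


class TestGradientDirection:
    """Hinge gradients pull positives together and push negatives apart."""

    def _distance_grad(self, d0, g):
        e1 = Tensor(np.array([[0.0, 0.0]]), requires_grad=True)
        e2 = Tensor(np.array([[d0, 0.0]]), requires_grad=True)
        diff = e1.take([0]) - e2.take([0])
        D = diff.square().sum(axis=1).sqrt()
        hinge_pair_loss(D, np.array([g]), 0.2, 1.2).sum().backward()
        return e2.grad[0, 0]  # d loss / d x-coordinate of the far point

    def test_positive_pair_outside_margin_pulls_together(self):
        assert self._distance_grad(1.5, +1) > 0  # moving e2 closer reduces loss

    def test_negative_pair_inside_margin_pushes_apart(self):
        assert self._distance_grad(1.0, -1) < 0

    def test_satisfied_pairs_have_zero_gradient(self):
        assert self._distance_grad(0.5, +1) == 0.0
        assert self._distance_grad(2.0, -1) == 0.0
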