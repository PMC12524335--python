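"""Classification and box losses: scalar oracles, algebraic identities,
stationarity, gradient checks, and Hungarian matching vs brute force."""

import itertools
import math

import numpy as np
import pytest

from flockdetr.engine.tensor import Tensor
from flockdetr.losses import (LossWeights, box_cxcywh_to_corners, giou,
                              giou_corners, hungarian_match, iou_corners,
                              mal_loss, total_loss, vfl_loss)

from conftest import finite_diff_grad


class TestVarifocal:
    def test_perfect_predictions_have_vanishing_loss(self):
        assert vfl_loss(1 - 1e-9, 1.0).item() < 1e-5
        assert vfl_loss(1e-9, 0.0).item() < 1e-5

    def test_negative_branch_scalar_oracle(self):
        # 0.75 * 0.9^2 * (-ln 0.1) = 1.39875
        expected = 0.75 * 0.81 * -math.log(0.1)
        assert abs(vfl_loss(0.9, 0.0, alpha=0.75, gamma=2.0).item() - expected) < 1e-4

    def test_positive_branch_formula(self):
        p, q = 0.7, 0.6
        expected = -q * (q * math.log(p) + (1 - q) * math.log(1 - p))
        assert abs(vfl_loss(p, q).item() - expected) < 1e-5


class TestMatchability:
    def test_perfect_positive_is_log_loss(self):
        # y=1, q=1: target q^gamma = 1, loss = -log p
        p = 0.8
        assert abs(mal_loss(p, 1.0, 1.0).item() + math.log(p)) < 1e-5
        assert mal_loss(1 - 1e-9, 1.0, 1.0).item() < 1e-5

    @pytest.mark.parametrize("q,gamma", [(0.1, 2.0), (0.5, 2.0), (0.9, 1.5)])
    def test_half_probability_symmetry(self, q, gamma):
        # at p = 0.5 the two log terms coincide: loss = -log 0.5
        assert abs(mal_loss(0.5, q, 1.0, gamma).item() - math.log(2.0)) < 1e-5

    def test_positive_branch_scalar_oracle(self):
        # -(0.64 ln 0.9 + 0.36 ln 0.1) = 0.89636
        expected = -(0.64 * math.log(0.9) + 0.36 * math.log(0.1))
        assert abs(mal_loss(0.9, 0.8, 1.0, 2.0).item() - expected) < 1e-4

    def test_negative_branch_monotone_in_p(self):
        ps = np.linspace(0.01, 0.99, 50)
        losses = mal_loss(ps, np.zeros(50), np.zeros(50)).data
        assert (np.diff(losses) > 0).all()

    def test_positive_branch_minimized_at_q_pow_gamma(self):
        """Soft-label cross-entropy stationarity by grid search."""
        gamma = 2.0
        for q in (0.3, 0.6, 0.9):
            ps = np.linspace(0.001, 0.999, 2001)
            losses = mal_loss(ps, np.full(ps.shape, q), np.ones(ps.shape), gamma).data
            assert abs(ps[np.argmin(losses)] - q ** gamma) < 2e-3

    def test_agrees_with_vfl_at_unit_quality(self):
        # both reduce to -log p at q = 1 (vfl up to its leading q factor)
        for p in (0.3, 0.7, 0.95):
            assert abs(mal_loss(p, 1.0, 1.0).item() - vfl_loss(p, 1.0).item()) < 1e-6
            assert abs(mal_loss(p, 1.0, 1.0).item() + math.log(p)) < 1e-6

    def test_gradient_matches_finite_differences(self):
        """Float64 finite differences agree with the hand-derived
        derivative to 1e-5; the engine's float32 backward follows it."""
        gamma = 2.0

        def f64_loss(p, q, y):
            if y == 1.0:
                qg = q ** gamma
                return -(qg * np.log(p) + (1 - qg) * np.log1p(-p))
            return -(p ** gamma) * np.log1p(-p)

        def analytic(p, q, y):
            if y == 1.0:
                qg = q ** gamma
                return -(qg / p) + (1 - qg) / (1 - p)
            return -(gamma * p ** (gamma - 1) * np.log1p(-p)) + p ** gamma / (1 - p)

        for q, y in [(0.7, 1.0), (0.0, 0.0), (0.3, 1.0)]:
            ps = np.linspace(0.05, 0.95, 19)
            num = finite_diff_grad(
                lambda a: float(sum(f64_loss(pi, q, y) for pi in a)), ps.copy(), eps=1e-6)
            ana = np.array([analytic(p, q, y) for p in ps])
            assert np.allclose(num, ana, rtol=1e-5, atol=1e-5)
            t = Tensor(ps.astype(np.float32), requires_grad=True)
            mal_loss(t, np.full(19, q), np.full(19, y), gamma).sum().backward()
            assert np.allclose(t.grad, ana, rtol=5e-3, atol=1e-3)


class TestGIoU:
    def test_identical_boxes(self):
        assert abs(giou([0, 0, 2, 2], [0, 0, 2, 2]).item() - 1.0) < 1e-6

    def test_hand_geometry_oracle(self):
        # IoU 1/7, union 7, enclosure 9 -> 1/7 - 2/9
        expected = 1.0 / 7.0 - 2.0 / 9.0
        assert abs(giou([0, 0, 2, 2], [1, 1, 3, 3]).item() - expected) < 1e-5

    def test_far_separation_approaches_minus_one(self):
        v = giou([0, 0, 1, 1], [1e4, 1e4, 1e4 + 1, 1e4 + 1]).item()
        assert -1.0 <= v < -0.99

    def test_degenerate_zero_area_box(self):
        v = giou([0, 0, 0, 0], [1, 1, 2, 2]).item()
        assert -1.0 <= v <= 0.0

    def test_range_over_random_boxes(self, rng):
        for _ in range(100):
            a = np.sort(rng.random(4)).astype(np.float32)[[0, 1, 2, 3]]
            b = np.sort(rng.random(4)).astype(np.float32)[[0, 1, 2, 3]]
            a = [a[0], a[1], a[2] + 0.01, a[3] + 0.01]
            b = [b[0], b[1], b[2] + 0.01, b[3] + 0.01]
            v = giou(a, b).item()
            assert -1.0 - 1e-6 <= v <= 1.0 + 1e-6


def _brute_force_assignment(cost: np.ndarray):
    nq, ng = cost.shape
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(nq), ng):
        c = sum(cost[perm[j], j] for j in range(ng))
        if c < best_cost:
            best_cost, best = c, perm
    return best_cost


class TestHungarian:
    def test_single_pair(self):
        m = hungarian_match(np.array([[0.9]]), np.array([[[0.5, 0.5, 0.2, 0.2]]]),
                            [np.array([[0.5, 0.5, 0.2, 0.2]])])
        assert m.pairs[0].tolist() == [[0, 0]]
        assert m.labels[0].tolist() == [1.0]
        assert m.quality[0][0] > 0.99

    def test_three_by_two_hand_cost(self):
        """Cost [[1,9],[9,1],[5,5]] -> assignment {(0,0),(1,1)}, total 2."""
        from scipy.optimize import linear_sum_assignment
        cost = np.array([[1.0, 9.0], [9.0, 1.0], [5.0, 5.0]])
        qi, gi = linear_sum_assignment(cost)
        assert cost[qi, gi].sum() == _brute_force_assignment(cost) == 2.0
        assert set(zip(qi, gi)) == {(0, 0), (1, 1)}

    def test_matcher_cost_equals_brute_force_over_many_seeds(self):
        """Full pipeline cost (cls + L1 + GIoU) vs exhaustive enumeration."""
        w = LossWeights()
        for seed in range(200):
            r = np.random.default_rng(seed)
            nq = int(r.integers(1, 7))
            ng = int(r.integers(1, nq + 1))
            scores = r.random((1, nq)).astype(np.float32)
            boxes = np.clip(r.random((1, nq, 4)).astype(np.float32), 0.05, 0.95)
            gts = [np.clip(r.random((ng, 4)).astype(np.float32), 0.05, 0.95)]
            m = hungarian_match(scores, boxes, gts, w)
            # recompute this match's cost and compare with brute force
            pb = box_cxcywh_to_corners(boxes[0])
            gb = box_cxcywh_to_corners(gts[0])
            cost = (w.cost_cls * (1 - scores[0])[:, None]
                    + w.cost_l1 * np.abs(boxes[0][:, None] - gts[0][None]).sum(-1)
                    + w.cost_giou * (1 - giou_corners(
                        np.repeat(pb[:, None], ng, 1), np.repeat(gb[None], nq, 0)).data))
            got = cost[m.pairs[0][:, 0], m.pairs[0][:, 1]].sum()
            assert abs(got - _brute_force_assignment(cost)) < 1e-4

    def test_target_permutation_invariance(self, rng):
        scores = rng.random((1, 5)).astype(np.float32)
        boxes = np.clip(rng.random((1, 5, 4)), 0.1, 0.9).astype(np.float32)
        gts = np.clip(rng.random((3, 4)), 0.1, 0.9).astype(np.float32)
        m1 = hungarian_match(scores, boxes, [gts])
        m2 = hungarian_match(scores, boxes, [gts[::-1].copy()])
        assert set(m1.pairs[0][:, 0]) == set(m2.pairs[0][:, 0])

    def test_no_targets_yields_all_negative(self):
        m = hungarian_match(np.array([[0.5, 0.5]]),
                            np.full((1, 2, 4), 0.5, np.float32), [np.zeros((0, 4))])
        assert len(m.pairs[0]) == 0 and m.labels[0].sum() == 0


class TestTotalLoss:
    def test_perfect_predictions_vanish(self):
        gt = np.array([[0.5, 0.5, 0.2, 0.2]], np.float32)
        scores = Tensor(np.array([[1 - 1e-9]], np.float32))
        boxes = Tensor(gt[None])
        total, comps = total_loss(scores, boxes, [gt])
        assert total.item() < 1e-5

    def test_single_matched_pair_at_half_probability(self):
        gt = np.array([[0.5, 0.5, 0.2, 0.2]], np.float32)
        total, comps = total_loss(Tensor(np.array([[0.5]], np.float32)),
                                  Tensor(gt[None]), [gt])
        assert abs(total.item() - math.log(2.0)) < 1e-5
        assert comps["l1"] < 1e-7 and comps["giou"] < 1e-7

    def test_components_sum_to_total(self, rng):
        w = LossWeights()
        scores = Tensor(rng.random((2, 4)).astype(np.float32))
        boxes = Tensor(np.clip(rng.random((2, 4, 4)), 0.1, 0.9).astype(np.float32))
        gts = [np.clip(rng.random((2, 4)), 0.1, 0.9).astype(np.float32),
               np.zeros((0, 4), np.float32)]
        total, comps = total_loss(scores, boxes, gts, w)
        assert abs(total.item() - (comps["cls"] + comps["l1"] + comps["giou"])) < 1e-6

    def test_empty_batch_targets_give_classification_only(self, rng):
        scores = Tensor(rng.random((1, 5)).astype(np.float32))
        boxes = Tensor(np.full((1, 5, 4), 0.5, np.float32))
        total, comps = total_loss(scores, boxes, [np.zeros((0, 4))])
        assert comps["l1"] == 0.0 and comps["giou"] == 0.0
        assert total.item() > 0


from hypothesis import given, settings, strategies as st

_coord = st.floats(0.0, 100.0, allow_nan=False)


def _box(x0, y0, w, h):
    return [x0, y0, x0 + w, y0 + h]


@settings(max_examples=100, derandomize=True, deadline=None)
@given(x0=_coord, y0=_coord, u0=_coord, v0=_coord,
       w1=st.floats(0.1, 50), h1=st.floats(0.1, 50),
       w2=st.floats(0.1, 50), h2=st.floats(0.1, 50))
def test_giou_symmetric_bounded_and_caps_iou(x0, y0, u0, v0, w1, h1, w2, h2):
    """GIoU lies in (-1, 1], is symmetric, and never exceeds the IoU."""
    a, b = _box(x0, y0, w1, h1), _box(u0, v0, w2, h2)
    g_ab, g_ba = giou(a, b).item(), giou(b, a).item()
    assert abs(g_ab - g_ba) < 1e-5
    assert -1.0 - 1e-6 < g_ab <= 1.0 + 1e-6
    iou = iou_corners(np.array([a]), np.array([b]))[0, 0]
    assert g_ab <= iou + 1e-5


@settings(max_examples=60, derandomize=True, deadline=None)
@given(p=st.floats(0.01, 0.99), q=st.floats(0.0, 1.0))
def test_mal_nonnegative_and_zero_only_at_target(p, q):
    pos = mal_loss(p, q, 1.0).item()
    neg = mal_loss(p, q, 0.0).item()
    assert pos >= -1e-6 and neg >= -1e-6


def test_loss_config_validation():
    with pytest.raises(NotImplementedError):
        LossWeights(loss_type="slide")
    with pytest.raises(NotImplementedError):
        LossWeights(loss_type="emaslide")
    with pytest.raises(ValueError):
        LossWeights(loss_type="nonsense")
    with pytest.raises(ValueError):
        LossWeights(lambda_cls=-1.0)
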