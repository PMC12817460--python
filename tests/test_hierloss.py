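"""Hierarchical loss: projection, per-level loss, weighted total, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicomanno import hierloss
from dicomanno.hierloss import (
    LossWeights,
    hierarchical_loss,
    hierarchical_loss_grad,
    level_loss,
    level_membership,
    project_to_level,
)


def _onehot(codes, code):
    v = np.zeros(len(codes))
    v[codes.index(code)] = 1.0
    return v


def brute_force_hierarchical_loss(y, p, hier, codes, weights=(0.4, 0.3, 0.3), eps=1e-7):
    """Independent oracle: plain python loops over explicit label groups."""
    total = 0.0
    for level, w in zip((1, 2, 3), weights):
        groups = {}
        for i, code in enumerate(codes):
            groups.setdefault(hier.path_of(code)[level - 1], []).append(i)
        lloss = 0.0
        for members in groups.values():
            y_g = 1.0 if any(y[i] > 0 for i in members) else 0.0
            p_g = min(1.0, sum(p[i] for i in members))
            lloss += -y_g * np.log(max(p_g, eps))
        total += w * lloss
    return total


class TestProjection:
    def test_single_label_projects_to_its_region(self, hier, vocab):
        codes = vocab.codes
        p = _onehot(codes, 7569003)  # Finger
        labels, _ = level_membership(hier, codes, 1)
        proj = project_to_level(p, hier, codes, 1)
        assert proj[labels.index("Upper extremity")] == pytest.approx(1.0)
        assert proj.sum() == pytest.approx(1.0)

    def test_group_probabilities_sum(self, hier, vocab):
        codes = vocab.codes
        p = 0.4 * _onehot(codes, 85562004) + 0.3 * _onehot(codes, 8205005)  # Hand + Wrist
        labels, _ = level_membership(hier, codes, 2)
        proj = project_to_level(p, hier, codes, 2)
        assert proj[labels.index("Hand")] == pytest.approx(0.7)

    def test_identity_groups_pass_through(self, hier):
        codes = [818983003, 51282000]  # Abdomen, Spine: singleton level-1 groups here
        p = np.array([0.25, 0.6])
        proj = project_to_level(p, hier, codes, 1)
        assert proj == pytest.approx([0.25, 0.6])

    def test_targets_project_by_or(self, hier, vocab):
        codes = vocab.codes
        y = _onehot(codes, 85562004) + _onehot(codes, 7569003)  # Hand and Finger visible
        labels, _ = level_membership(hier, codes, 2)
        proj = project_to_level(y, hier, codes, 2, kind="target")
        assert proj[labels.index("Hand")] == 1.0
        assert proj.sum() == 1.0

    def test_invalid_level_rejected(self, hier, vocab):
        with pytest.raises(ValueError):
            project_to_level(np.zeros(len(vocab.codes)), hier, vocab.codes, 4)


class TestLevelLoss:
    def test_perfect_prediction_is_exactly_zero(self):
        assert level_loss(np.array([0, 1, 0]), np.array([0, 1.0, 0])) == 0.0

    def test_half_confidence_is_ln2(self):
        assert level_loss(np.array([1, 0]), np.array([0.5, 0.5])) == pytest.approx(np.log(2))

    def test_two_positives_sum(self):
        y = np.array([1, 1, 0])
        p = np.array([0.5, 0.5, 0.0])
        assert level_loss(y, p) == pytest.approx(2 * np.log(2))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            level_loss(np.zeros(3), np.zeros(4))


class TestHierarchicalLoss:
    def test_perfect_leaf_prediction_gives_zero(self, hier, vocab):
        codes = vocab.codes
        y = _onehot(codes, 85562004)
        assert hierarchical_loss(y, y, hier, codes) == 0.0

    def test_equal_level_losses_collapse_to_single_value(self, hier, vocab):
        # Abdomen is alone at every level, so each lloss_n = -log q and the
        # weights (summing to 1) leave J = -log q.
        codes = vocab.codes
        y = _onehot(codes, 818983003)
        p = 0.7 * y
        assert hierarchical_loss(y, p, hier, codes) == pytest.approx(-np.log(0.7))

    def test_within_region_error_cheaper_than_cross_region(self, hier, vocab):
        codes = vocab.codes
        y = _onehot(codes, 85562004)  # true: Hand
        within = 0.9 * _onehot(codes, 7569003)  # predicted Finger (same hand group)
        cross = 0.9 * _onehot(codes, 818983003)  # predicted Abdomen
        J_within = hierarchical_loss(y, within, hier, codes)
        J_cross = hierarchical_loss(y, cross, hier, codes)
        assert J_within < J_cross

    def test_monotone_penalty_across_all_error_targets(self, hier, vocab):
        codes = vocab.codes
        y = _onehot(codes, 85562004)  # Hand
        region = {c: hier.path_of(c)[0] for c in codes}
        J = {c: hierarchical_loss(y, 0.9 * _onehot(codes, c), hier, codes) for c in codes}
        worst_within = max(J[c] for c in codes if region[c] == "Upper extremity")
        best_cross = min(J[c] for c in codes if region[c] != "Upper extremity")
        assert worst_within < best_cross

    def test_matches_brute_force_oracle_on_random_instances(self, hier, vocab):
        rng = np.random.default_rng(7)
        all_codes = vocab.codes
        for _ in range(50):
            codes = list(rng.choice(all_codes, size=rng.integers(2, 11), replace=False))
            codes = [int(c) for c in codes]
            y = (rng.random(len(codes)) < 0.3).astype(float)
            if y.sum() == 0:
                y[rng.integers(len(codes))] = 1.0
            p = rng.random(len(codes))
            got = hierarchical_loss(y, p, hier, codes)
            want = brute_force_hierarchical_loss(y, p, hier, codes)
            assert got == pytest.approx(want, abs=1e-9)

    def test_batch_reduction_is_mean(self, hier, vocab):
        codes = vocab.codes
        y = np.stack([_onehot(codes, 85562004), _onehot(codes, 818983003)])
        p = np.stack([0.5 * y[0], 0.25 * y[1]])
        per_obs = hierarchical_loss(y, p, hier, codes, reduction="none")
        assert hierarchical_loss(y, p, hier, codes) == pytest.approx(per_obs.mean())

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-0.1, 0.5, 0.6)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_loss_is_nonnegative(self, seed):
        hier = _HIER
        codes = _CODES
        rng = np.random.default_rng(seed)
        y = (rng.random(len(codes)) < 0.4).astype(float)
        p = rng.random(len(codes))
        assert hierarchical_loss(y, p, hier, codes) >= 0.0

    def test_gradient_matches_finite_differences(self, hier, vocab):
        # probabilities kept small enough that no group sum reaches the
        # [0, 1] clip, where the analytic gradient is defined
        codes = vocab.codes[:12]
        rng = np.random.default_rng(3)
        y = _onehot(codes, codes[4])
        p = rng.uniform(0.01, 0.07, len(codes))
        grad = hierarchical_loss_grad(y, p, hier, codes)[0]
        eps = 1e-6
        for i in range(len(codes)):
            pp, pm = p.copy(), p.copy()
            pp[i] += eps
            pm[i] -= eps
            num = (
                hierarchical_loss(y, pp, hier, codes) - hierarchical_loss(y, pm, hier, codes)
            ) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-5)


# module-level tables for the hypothesis test (fixtures are not available there)
from dicomanno.vocab import load_hierarchy as _lh, load_vocabulary as _lv  # noqa: E402

_HIER = _lh()
_CODES = _lv().codes
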