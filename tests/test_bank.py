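"""Unit tests for the knowledge-bank formulas and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ckbank import (
    ClassKnowledgeBank,
    ckb_logits,
    class_similarity,
    combined_loss,
    contrastive_loss,
    cosine_similarity,
    init_bank,
    load_bank,
    predict_class,
    save_bank,
    softmax_probabilities,
)
from ckbank.bank import loss_and_grads
from ckbank.errors import (
    ConfigurationError,
    DegenerateInputError,
    LabelError,
    ShapeError,
)

from conftest import oracle_combined, oracle_contrastive, oracle_logits


class TestCosineSimilarity:
    @pytest.mark.parametrize("u, r, expected", [
        ((1, 0), (1, 0), 1.0),
        ((1, 0), (0, 1), 0.0),
        ((1, 2, 3), (4, 5, 6), 32 / math.sqrt(14 * 77)),
    ])
    def test_hand_values(self, u, r, expected):
        assert cosine_similarity(u, r) == pytest.approx(expected, abs=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(DegenerateInputError):
            cosine_similarity((0, 0), (1, 0))
        with pytest.raises(DegenerateInputError):
            cosine_similarity((1, 0), (0, 0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            cosine_similarity((1, 0), (1, 0, 0))

    @given(
        u=arrays(np.float64, 4, elements=st.floats(-5, 5)),
        r=arrays(np.float64, 4, elements=st.floats(-5, 5)),
        a=st.floats(0.01, 100), b=st.floats(0.01, 100),
    )
    def test_bounded_and_scale_invariant(self, u, r, a, b):
        if np.linalg.norm(u) < 1e-6 or np.linalg.norm(r) < 1e-6:
            return
        c = cosine_similarity(u, r)
        assert -1.0 <= c <= 1.0
        assert cosine_similarity(a * u, b * r) == pytest.approx(c, abs=1e-9)


class TestClassSimilarity:
    @pytest.mark.parametrize("units, r, expected", [
        ([(1, 0)], (5, 0), 1.0),                 # scale invariance, single unit
        ([(1, 0), (-1, 0)], (1, 0), 0.0),        # symmetric cancellation
        ([(1, 0), (0, 1)], (1, 0), 0.5),         # direct summation
    ])
    def test_hand_values(self, units, r, expected):
        assert class_similarity(np.array(units, float), r) == pytest.approx(expected)

    def test_permutation_invariant(self, rng):
        units = rng.standard_normal((6, 5))
        r = rng.standard_normal(5)
        base = class_similarity(units, r)
        for _ in range(5):
            perm = rng.permutation(6)
            assert class_similarity(units[perm], r) == pytest.approx(base, abs=1e-12)


class TestLogits:
    def test_axis_aligned(self):
        bank = ClassKnowledgeBank(np.array([[[1.0, 0.0]], [[0.0, 1.0]]]))
        np.testing.assert_allclose(ckb_logits(bank, [1.0, 0.0]), [1.0, 0.0], atol=1e-12)

    def test_self_similarity(self, rng):
        units = rng.standard_normal((3, 1, 6))
        bank = ClassKnowledgeBank(units)
        s = ckb_logits(bank, units[2, 0])
        assert s[2] == pytest.approx(1.0, abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        units = rng.standard_normal((3, 4, 8))
        bank = ClassKnowledgeBank(units)
        r = rng.standard_normal(8)
        np.testing.assert_allclose(ckb_logits(bank, r), oracle_logits(units, r),
                                   atol=1e-6)

    def test_batch_rows_independent(self, rng):
        bank = init_bank(4, 3, 6, seed=0)
        R = rng.standard_normal((5, 6))
        S = ckb_logits(bank, R)
        assert S.shape == (5, 4)
        for b in range(5):
            np.testing.assert_allclose(S[b], ckb_logits(bank, R[b]), atol=1e-12)

    def test_dim_mismatch(self):
        bank = init_bank(2, 2, 4, seed=0)
        with pytest.raises(ShapeError):
            ckb_logits(bank, np.ones(5))


class TestSoftmax:
    def test_symmetry_and_closed_form(self):
        np.testing.assert_allclose(softmax_probabilities([0.0, 0.0]), [0.5, 0.5])
        e2 = math.exp(2)
        np.testing.assert_allclose(
            softmax_probabilities([1.0, -1.0]),
            [e2 / (e2 + 1), 1 / (e2 + 1)], atol=1e-12,
        )

    @given(s=arrays(np.float64, 5, elements=st.floats(-1, 1)))
    def test_normalized_and_shift_invariant(self, s):
        p = softmax_probabilities(s)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p, softmax_probabilities(s - s.max()), atol=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(DegenerateInputError):
            softmax_probabilities([np.inf, 0.0])


class TestContrastiveLoss:
    def test_perfect_separation_and_orthogonal(self):
        bank = ClassKnowledgeBank(np.array([[[1.0, 0.0]], [[-1.0, 0.0]]]))
        assert contrastive_loss(bank, [1.0, 0.0], 0) == pytest.approx(-2.0)
        assert contrastive_loss(bank, [0.0, 1.0], 0) == pytest.approx(0.0)

    def test_matches_double_sum_oracle(self, rng):
        units = rng.standard_normal((4, 3, 6))
        bank = ClassKnowledgeBank(units)
        r = rng.standard_normal(6)
        for y in range(4):
            assert contrastive_loss(bank, r, y) == pytest.approx(
                oracle_contrastive(units, r, y), abs=1e-6)

    def test_decomposition_via_logits(self, rng):
        """L_con = -s_y + mean over other classes of s_i, exactly."""
        bank = init_bank(5, 3, 7, seed=3)
        r = rng.standard_normal(7)
        s = ckb_logits(bank, r)
        for y in range(5):
            expected = -s[y] + (s.sum() - s[y]) / 4
            assert contrastive_loss(bank, r, y) == pytest.approx(expected, abs=1e-12)

    def test_label_out_of_range(self):
        bank = init_bank(2, 2, 4, seed=0)
        with pytest.raises(LabelError):
            contrastive_loss(bank, np.ones(4), 2)


class TestCombinedLoss:
    def test_perfect_separation_closed_form(self):
        bank = ClassKnowledgeBank(np.array([[[1.0, 0.0]], [[-1.0, 0.0]]]))
        lv = combined_loss(bank, [1.0, 0.0], 0)
        assert lv.contrastive == pytest.approx(-2.0)
        assert lv.total == pytest.approx(-2.0 + math.log(1 + math.exp(-2)), abs=1e-12)
        assert lv.total == pytest.approx(lv.contrastive + lv.cross_entropy, abs=1e-9)

    def test_uniform_bank_symmetry(self, rng):
        """Identical class slices: contrastive term vanishes, CE is ln N."""
        slice_ = rng.standard_normal((3, 6))
        bank = ClassKnowledgeBank(np.stack([slice_] * 4))
        r = rng.standard_normal(6)
        lv = combined_loss(bank, r, 2)
        assert lv.contrastive == pytest.approx(0.0, abs=1e-12)
        assert lv.cross_entropy == pytest.approx(math.log(4), abs=1e-12)

    def test_matches_independent_oracle(self, rng):
        units = rng.standard_normal((4, 3, 6))
        bank = ClassKnowledgeBank(units)
        r = rng.standard_normal(6)
        con, cel, total = oracle_combined(units, r, 1)
        lv = combined_loss(bank, r, 1)
        assert lv.contrastive == pytest.approx(con, abs=1e-6)
        assert lv.cross_entropy == pytest.approx(cel, abs=1e-6)
        assert lv.total == pytest.approx(total, abs=1e-6)


class TestInitBank:
    def test_deterministic_and_unit_norm(self):
        b1 = init_bank(3, 4, 16, seed=7)
        b2 = init_bank(3, 4, 16, seed=7)
        np.testing.assert_array_equal(b1.units, b2.units)
        np.testing.assert_allclose(np.linalg.norm(b1.units, axis=-1), 1.0, atol=1e-6)

    def test_near_orthogonal_in_high_dimension(self):
        """64 random units in D=512 are nearly pairwise orthogonal."""
        bank = init_bank(2, 32, 512, seed=0)
        units = bank.units.reshape(64, 512)
        cosines = units @ units.T
        off_diag = cosines[~np.eye(64, dtype=bool)]
        assert abs(off_diag.mean()) < 0.1

    @pytest.mark.parametrize("n, m, d", [(1, 4, 8), (2, 0, 8), (2, 4, 0)])
    def test_invalid_sizes(self, n, m, d):
        with pytest.raises(ConfigurationError):
            init_bank(n, m, d, seed=0)


class TestPredict:
    def test_axis_aligned_and_tie_rule(self):
        bank = ClassKnowledgeBank(np.array([[[1.0, 0.0]], [[0.0, 1.0]]]))
        assert predict_class(bank, [1.0, 0.0]) == 0
        # exact tie: symmetric bank, equidistant representation -> class 0
        assert predict_class(bank, [1.0, 1.0]) == 0

    def test_agrees_with_softmax_argmax(self, rng):
        bank = init_bank(4, 3, 8, seed=5)
        agree = 0
        for _ in range(100):
            r = rng.standard_normal(8)
            p = softmax_probabilities(ckb_logits(bank, r))
            agree += predict_class(bank, r) == int(np.argmax(p))
        assert agree == 100


class TestBatchGradients:
    def test_matches_single_sample_mean(self, rng):
        """Batch-mean loss and grads equal the average of per-sample ones."""
        bank = init_bank(3, 2, 5, seed=2)
        R = rng.standard_normal((4, 5))
        y = np.array([0, 2, 1, 0])
        loss_b, gU_b, gR_b = loss_and_grads(bank, R, y)
        singles = [loss_and_grads(bank, R[k], [y[k]]) for k in range(4)]
        assert loss_b.total == pytest.approx(np.mean([s[0].total for s in singles]))
        np.testing.assert_allclose(gU_b, np.mean([s[1] for s in singles], axis=0),
                                   atol=1e-12)
        for k in range(4):
            np.testing.assert_allclose(gR_b[k], singles[k][2][0] / 4, atol=1e-12)


class TestSymmetries:
    def test_unit_permutation_and_rescaling_invariance(self, rng):
        units = rng.standard_normal((3, 4, 6))
        r = rng.standard_normal(6)
        base = ckb_logits(ClassKnowledgeBank(units), r)
        permuted = units[:, rng.permutation(4), :]
        np.testing.assert_allclose(
            ckb_logits(ClassKnowledgeBank(permuted), r), base, atol=1e-12)
        scales = rng.uniform(0.1, 10, size=(3, 4, 1))
        np.testing.assert_allclose(
            ckb_logits(ClassKnowledgeBank(units * scales), r), base, atol=1e-9)
        np.testing.assert_allclose(
            ckb_logits(ClassKnowledgeBank(units), 3.7 * r), base, atol=1e-9)

    def test_class_relabeling_permutes_outputs(self, rng):
        units = rng.standard_normal((4, 3, 5))
        r = rng.standard_normal(5)
        perm = np.array([2, 0, 3, 1])
        s = ckb_logits(ClassKnowledgeBank(units), r)
        s_perm = ckb_logits(ClassKnowledgeBank(units[perm]), r)
        np.testing.assert_allclose(s_perm, s[perm], atol=1e-12)
        p = softmax_probabilities(s)
        np.testing.assert_allclose(softmax_probabilities(s_perm), p[perm], atol=1e-12)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path):
        bank = init_bank(3, 5, 12, seed=42)
        path = tmp_path / "bank.npz"
        save_bank(bank, path)
        loaded = load_bank(path)
        np.testing.assert_array_equal(loaded.units, bank.units)
        assert loaded.seed == 42
        assert (loaded.n_classes, loaded.units_per_class, loaded.dim) == (3, 5, 12)
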