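"""Bit-packing, XNOR-popcount arithmetic and batch-norm folding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sbcnn.binary_core import (
    BinaryTensor,
    NeuronThreshold,
    binarize_sign,
    binary_neuron,
    fold_batchnorm,
    popcount,
    ste_grad,
    xnor,
)


class TestBinaryTensor:
    @pytest.mark.parametrize("length", list(range(1, 131)))
    def test_pack_roundtrip_exact(self, length):
        """Round trip across word boundaries (1..130 covers 64-bit edges)."""
        rng = np.random.default_rng(length)
        v = rng.choice([-1, 1], size=length).astype(np.int8)
        assert np.array_equal(BinaryTensor.from_signs(v).to_signs(), v)

    def test_live_bits_equal_shape_product(self):
        rng = np.random.default_rng(0)
        v = rng.choice([-1, 1], size=(3, 5, 7))
        t = BinaryTensor.from_signs(v)
        assert t.nbits == 105
        assert t.to_signs().shape == (3, 5, 7)

    def test_padding_bits_never_counted(self):
        t = BinaryTensor.from_signs(np.ones(67))
        assert popcount(t) == 67

    def test_rejects_nonbinary_values(self):
        with pytest.raises(ValueError):
            BinaryTensor.from_signs(np.array([1, 0, -1]))

    def test_rejects_dirty_padding(self):
        words = np.array([0xFFFFFFFFFFFFFFFF], dtype=np.uint64)
        with pytest.raises(ValueError, match="padding"):
            BinaryTensor((10,), words)


class TestBinarizeSign:
    def test_zero_maps_to_plus_one(self):
        out = binarize_sign(np.array([-0.3, 0.0, 2.1])).to_signs()
        assert np.array_equal(out, [-1, 1, 1])

    def test_all_negative(self):
        assert np.all(binarize_sign(-np.arange(1, 9.0)).to_signs() == -1)

    def test_matches_elementwise_comparison_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=500)
        expected = np.where(x >= 0, 1, -1)
        assert np.array_equal(binarize_sign(x).to_signs(), expected)

    def test_nan_error_names_index(self):
        x = np.zeros((2, 3))
        x[1, 2] = np.nan
        with pytest.raises(ValueError, match=r"\(1, 2\)"):
            binarize_sign(x)


class TestXnorPopcount:
    def test_truth_table(self):
        a = BinaryTensor.from_signs(np.array([1, -1]))
        b = BinaryTensor.from_signs(np.array([1, 1]))
        assert np.array_equal(xnor(a, b).to_signs(), [1, -1])

    def test_self_xnor_all_ones(self):
        rng = np.random.default_rng(1)
        a = BinaryTensor.from_signs(rng.choice([-1, 1], 100))
        assert np.all(xnor(a, a).to_signs() == 1)

    def test_xnor_equals_product_oracle(self):
        rng = np.random.default_rng(2)
        va = rng.choice([-1, 1], 300)
        vb = rng.choice([-1, 1], 300)
        out = xnor(BinaryTensor.from_signs(va), BinaryTensor.from_signs(vb)).to_signs()
        assert np.array_equal(out, va * vb)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            xnor(BinaryTensor.from_signs(np.ones(4)), BinaryTensor.from_signs(np.ones(5)))

    def test_popcount_examples(self):
        assert popcount(BinaryTensor.from_signs(np.ones(8))) == 8
        assert popcount(BinaryTensor.from_signs(-np.ones(30))) == 0

    def test_popcount_loop_oracle_across_word_boundary(self):
        rng = np.random.default_rng(3)
        v = rng.choice([-1, 1], 67)
        naive = sum(1 for e in v if e == 1)
        assert popcount(BinaryTensor.from_signs(v)) == naive

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=200),
           st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=200))
    def test_popcount_xnor_is_dot_product(self, wa, xa):
        """2*popcount(XNOR(w,x)) - n == w . x, exactly, for all lengths."""
        n = min(len(wa), len(xa))
        w = np.array(wa[:n])
        x = np.array(xa[:n])
        p = popcount(xnor(BinaryTensor.from_signs(w), BinaryTensor.from_signs(x)))
        assert 2 * p - n == int(w @ x)


class TestBinaryNeuron:
    def test_agreement_fires(self):
        w = BinaryTensor.from_signs(np.ones(16))
        assert binary_neuron(w, w, NeuronThreshold(b=10, n=16)) == 1

    def test_disagreement_suppresses(self):
        w = BinaryTensor.from_signs(np.ones(16))
        x = BinaryTensor.from_signs(-np.ones(16))
        assert binary_neuron(w, x, NeuronThreshold(b=1, n=16)) == -1

    def test_dot_product_oracle_random(self):
        """Output equals sign(w.x - (2b - n)) in integer arithmetic."""
        rng = np.random.default_rng(11)
        for _ in range(2000):
            n = int(rng.integers(1, 120))
            w = rng.choice([-1, 1], n)
            x = rng.choice([-1, 1], n)
            b = int(rng.integers(-2, n + 3))
            y = binary_neuron(
                BinaryTensor.from_signs(w), BinaryTensor.from_signs(x), NeuronThreshold(b=b, n=n)
            )
            expected = 1 if int(w @ x) - (2 * b - n) >= 0 else -1
            assert y == expected

    def test_invariant_under_joint_negation(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(1, 80))
            w = rng.choice([-1, 1], n)
            x = rng.choice([-1, 1], n)
            t = NeuronThreshold(b=int(rng.integers(0, n + 1)), n=n)
            # joint negation leaves every XNOR bit unchanged
            y1 = binary_neuron(BinaryTensor.from_signs(w), BinaryTensor.from_signs(x), t)
            y2 = binary_neuron(BinaryTensor.from_signs(-w), BinaryTensor.from_signs(-x), t)
            assert y1 == y2

    def test_fan_in_mismatch(self):
        w = BinaryTensor.from_signs(np.ones(8))
        with pytest.raises(ValueError, match="fan-in"):
            binary_neuron(w, w, NeuronThreshold(b=1, n=9))


class TestSteGrad:
    def test_passes_inside_window(self):
        assert ste_grad(np.array([3.0]), np.array([0.5]))[0] == 3.0

    def test_clips_outside_window(self):
        assert ste_grad(np.array([3.0]), np.array([1.5]))[0] == 0.0

    def test_matches_mask_oracle(self):
        rng = np.random.default_rng(5)
        g = rng.normal(size=200)
        pre = rng.normal(scale=2.0, size=200)
        assert np.array_equal(ste_grad(g, pre), g * (np.abs(pre) <= 1))


class TestFoldBatchnorm:
    def test_identity_bn_threshold(self):
        """scale 1, shift 0, mean 0, var 1 (eps 0): threshold is ceil(n/2)."""
        b, flip = fold_batchnorm(1.0, 0.0, 0.0, 1.0, n=16, eps=0.0)
        assert b[0] == 8 and not flip[0]

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            fold_batchnorm(0.0, 0.0, 0.0, 1.0, n=4)

    @pytest.mark.parametrize("gamma_sign", [1.0, -1.0])
    def test_folded_matches_float_path(self, gamma_sign):
        """Integer thresholded inference == float bn+sign, bit for bit."""
        rng = np.random.default_rng(int(gamma_sign) + 10)
        n = 27
        gamma = gamma_sign * rng.uniform(0.1, 2.0, 8)
        beta = rng.normal(0, 1, 8)
        mean = rng.normal(0, 3, 8)
        var = rng.uniform(0.05, 4.0, 8)
        b, flip = fold_batchnorm(gamma, beta, mean, var, n)
        W = rng.choice([-1.0, 1.0], (8, n))
        x = rng.choice([-1.0, 1.0], (1000, n))
        d = x @ W.T
        z = gamma * (d - mean) / np.sqrt(var + 1e-5) + beta
        y_float = np.where(z >= 0, 1, -1)
        d_int = np.where(flip, -d, d)
        y_int = np.where(d_int >= 2 * b - n, 1, -1)
        assert np.array_equal(y_float, y_int)
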