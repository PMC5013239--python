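"""Unit and property tests for the bitstring operators."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from geneswarm.binary_core import (
    ParticleLayout,
    as_bits,
    bits_to_string,
    get_local_attractor,
    get_mbest,
    hamming,
    jump_from_mu,
    jump_length,
    mutate_toward,
    _one_point_crossover,
)


class TestHamming:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("1011001010", "1011001010", 0),
            ("1111", "0000", 4),
            ("1011001010", "0010010110", 5),  # position-by-position count
            ("0", "1", 1),
        ],
    )
    def test_examples(self, a, b, expected):
        assert hamming(a, b) == expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="unequal length"):
            hamming("101", "10")

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            hamming("102", "101")

    @pytest.mark.parametrize("length", range(1, 7))
    def test_metric_axioms_exhaustive(self, length):
        """Symmetry, identity of indiscernibles and the triangle inequality
        over every string pair/triple of the given length."""
        strings = np.array(list(itertools.product([0, 1], repeat=length)), dtype=np.uint8)
        m = strings.shape[0]
        d = (strings[:, None, :] != strings[None, :, :]).sum(axis=2)
        assert (d == d.T).all()
        assert (np.diag(d) == 0).all()
        assert ((d == 0) == np.eye(m, dtype=bool)).all()
        # d[i,k] <= d[i,j] + d[j,k] for every triple
        assert (d[:, None, :] <= d[:, :, None] + d[None, :, :]).all()
        # spot-agree with the public function
        idx = np.random.default_rng(length).integers(0, m, size=(20, 2))
        for i, j in idx:
            assert hamming(strings[i], strings[j]) == d[i, j]


class TestMbest:
    def test_strict_majority(self, rng):
        assert bits_to_string(get_mbest(["111", "111", "000"], rng)) == "111"

    def test_singleton(self, rng):
        assert bits_to_string(get_mbest(["1010"], rng)) == "1010"

    def test_empty_raises(self, rng):
        with pytest.raises(ValueError):
            get_mbest([], rng)

    def test_odd_count_no_ties_is_order_independent(self, rng):
        pbests = ["1100", "1010", "1001", "0110", "0111"]
        ref = bits_to_string(get_mbest(pbests, rng))
        for _ in range(20):
            perm = list(rng.permutation(pbests))
            assert bits_to_string(get_mbest(perm, rng)) == ref

    def test_tie_probability_is_half(self):
        """On an exact per-bit tie the bit is 1 with probability 0.5; Monte
        Carlo frequency over 10,000 fresh calls within +/- 0.02."""
        rng = np.random.default_rng(2024)
        counts = np.zeros(2)
        for _ in range(10_000):
            counts += get_mbest(["10", "01"], rng)
        freq = counts / 10_000
        assert np.all(np.abs(freq - 0.5) <= 0.02)


class TestLocalAttractor:
    def test_identical_parents(self, rng):
        for _ in range(10):
            assert bits_to_string(get_local_attractor("0110", "0110", rng)) == "0110"

    def test_one_point_offspring_construction(self):
        head_from_a, head_from_b = _one_point_crossover(
            as_bits("1111"), as_bits("0000"), 2
        )
        assert bits_to_string(head_from_a) == "1100"
        assert bits_to_string(head_from_b) == "0011"

    @pytest.mark.parametrize("mode", ["one-point", "multipoint"])
    def test_betweenness_identity(self, mode):
        """d(P, pbest) + d(P, gbest) = d(pbest, gbest): every offspring bit
        comes from one of the parents."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            a = rng.integers(0, 2, size=50, dtype=np.uint8)
            b = rng.integers(0, 2, size=50, dtype=np.uint8)
            p = get_local_attractor(a, b, rng, mode=mode)
            assert hamming(p, a) + hamming(p, b) == hamming(a, b)

    def test_length_one(self, rng):
        kids = {bits_to_string(get_local_attractor("1", "0", rng)) for _ in range(50)}
        assert kids == {"0", "1"}

    def test_unknown_mode_raises(self, rng):
        with pytest.raises(ValueError, match="crossover mode"):
            get_local_attractor("11", "00", rng, mode="uniform")


class TestJump:
    def test_zero_distance_gives_zero_jump(self, rng):
        draw = jump_length("1010", "1010", 1.0, rng)
        assert draw.b == 0 and draw.pr == 0.0

    @pytest.mark.parametrize(
        "h, ce, mu, expected_b",
        [
            (10, 1.0, math.exp(-1.0), 10),  # ln(1/mu) = 1 exactly
            (3, 1.0, 0.9, 1),  # ceil(0.3161)
            (0, 1.0, 0.5, 0),
            (5, 2.0, math.exp(-1.0), 10),
        ],
    )
    def test_jump_arithmetic(self, h, ce, mu, expected_b):
        draw = jump_from_mu(h, ce, mu, 10)
        assert draw.b == expected_b
        assert draw.pr == min(expected_b / 10, 1.0)

    def test_pr_non_decreasing_in_b(self):
        prs = [jump_from_mu(h, 1.0, math.exp(-1.0), 10).pr for h in range(0, 15)]
        assert all(p2 >= p1 for p1, p2 in zip(prs, prs[1:]))
        assert prs[-1] == 1.0  # capped

    def test_b_positive_iff_distance_positive(self, rng):
        for _ in range(200):
            x = rng.integers(0, 2, size=12, dtype=np.uint8)
            m = rng.integers(0, 2, size=12, dtype=np.uint8)
            draw = jump_length(x, m, 1.0, rng)
            assert (draw.b == 0) == (hamming(x, m) == 0)

    def test_invalid_mu_raises(self):
        with pytest.raises(ValueError):
            jump_from_mu(3, 1.0, 0.0, 10)
        with pytest.raises(ValueError):
            jump_from_mu(3, 1.0, 1.0, 10)


class TestMutateToward:
    def test_pr_zero_is_identity(self, rng):
        from geneswarm.binary_core import JumpDraw

        p = rng.integers(0, 2, size=30, dtype=np.uint8)
        out = mutate_toward(p, JumpDraw(mu=0.5, b=0, pr=0.0), rng)
        assert np.array_equal(out, p)

    def test_pr_one_is_complement(self, rng):
        from geneswarm.binary_core import JumpDraw

        p = rng.integers(0, 2, size=30, dtype=np.uint8)
        out = mutate_toward(p, JumpDraw(mu=0.5, b=99, pr=1.0), rng)
        assert np.array_equal(out, 1 - p)

    def test_displacement_is_binomial(self):
        """Hamming displacement over 10,000 draws at l=50, Pr=0.1: mean within
        5.0 +/- 0.3 and a two-sample KS test against Binomial(50, 0.1)."""
        from geneswarm.binary_core import JumpDraw

        rng = np.random.default_rng(7)
        p = rng.integers(0, 2, size=50, dtype=np.uint8)
        draw = JumpDraw(mu=0.5, b=5, pr=0.1)
        disp = np.array(
            [hamming(mutate_toward(p, draw, rng), p) for _ in range(10_000)]
        )
        assert abs(disp.mean() - 5.0) <= 0.3
        ref = stats.binom.rvs(50, 0.1, size=10_000, random_state=11)
        assert stats.ks_2samp(disp, ref).pvalue > 0.01


class TestLayout:
    def test_totals(self):
        layout = ParticleLayout((30, 20))
        assert layout.total_length == 50 and layout.num_variables == 2
        assert ParticleLayout.single(50).substring_lengths == (50,)

    def test_invalid(self):
        with pytest.raises(ValueError):
            ParticleLayout((0,))
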