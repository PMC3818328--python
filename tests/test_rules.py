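"""Rule genomes: encoding, lookup, promotion, mutation, conservatism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vegadct as v
from vegadct.rules import _index

from conftest import aligned_promoted_network


class TestEncoding:
    def test_majority_k3_is_rule_232(self):
        assert v.rule_decimal(v.make_majority_rule(3)) == 232

    def test_majority_k1_copies_own_state(self):
        assert v.make_majority_rule(1).table.tolist() == [0, 1]

    @pytest.mark.parametrize("k,size", [(3, 8), (5, 32), (7, 128), (11, 2048)])
    def test_table_length_is_2_to_k(self, k, size):
        assert v.make_majority_rule(k).table.size == size

    def test_decimal_matches_bitweight_oracle(self, rng):
        # independent oracle: accumulate bit weights one by one
        for _ in range(20):
            rule = v.random_rule(5, rng)
            expected = sum(int(b) * 2**i for i, b in enumerate(rule.table))
            assert v.rule_decimal(rule) == expected

    def test_roundtrip_exhaustive_k3(self):
        for d in range(256):
            assert v.rule_decimal(v.rule_from_decimal(3, d)) == d

    @given(d=st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_k5(self, d):
        assert v.rule_decimal(v.rule_from_decimal(5, d)) == d

    def test_from_decimal_232_is_majority(self):
        assert v.rule_from_decimal(3, 232) == v.make_majority_rule(3)

    def test_from_decimal_zero_is_constant_zero(self):
        assert v.rule_from_decimal(3, 0).table.sum() == 0

    def test_arbitrary_precision_k11(self):
        d = 2**2047 + 1
        assert v.rule_decimal(v.rule_from_decimal(11, d)) == d

    @pytest.mark.parametrize("k", [0, 2, 4, -3])
    def test_even_or_nonpositive_k_rejected(self, k):
        with pytest.raises(ValueError):
            v.make_majority_rule(k)

    def test_out_of_range_decimal_rejected(self):
        with pytest.raises(ValueError):
            v.rule_from_decimal(3, 256)

    def test_table_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            v.RuleGenome(3, np.zeros(7, dtype=np.uint8))


class TestLookup:
    def test_majority_examples(self):
        maj = v.make_majority_rule(3)
        assert v.lookup(maj, 1, (1, 0)) == 1
        assert v.lookup(maj, 0, (0, 1)) == 0

    def test_index_matches_string_concat_oracle(self, rng):
        rule = v.random_rule(5, rng)
        for _ in range(50):
            own = int(rng.integers(2))
            nbrs = rng.integers(0, 2, size=4).tolist()
            idx = int("".join(str(b) for b in [own] + nbrs), 2)
            assert v.lookup(rule, own, nbrs) == rule.table[idx]

    def test_wrong_neighbor_count_rejected(self):
        with pytest.raises(ValueError):
            v.lookup(v.make_majority_rule(3), 1, (1, 0, 1))


class TestPromotion:
    def test_constant_zero_promotes_to_constant_zero(self):
        promoted = v.promote(v.rule_from_decimal(3, 0))
        assert promoted.k == 5 and promoted.table.sum() == 0

    def test_all_rules_all_inputs_preserve_output(self):
        # exhaustive over the whole k=3 rule space and every new-bit combo
        for d in range(256):
            base = v.rule_from_decimal(3, d)
            promoted = v.promote(base)
            tiled = promoted.table.reshape(-1, 4)
            assert np.all(tiled == base.table[:, None])

    def test_majority_promoted_examples(self):
        promoted = v.promote(v.make_majority_rule(3))
        for new in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            assert v.lookup(promoted, 1, (1, 0) + new) == 1

    def test_trajectory_equivalence_at_zero_noise(self, rng):
        # silent inputs: base rule on its ring == promoted rule on a ring
        # whose first two slots carry the same neighbors
        net = v.build_ring(31, 2)
        net4 = aligned_promoted_network(net)
        for _ in range(5):
            base = v.random_rule(3, rng)
            promoted = v.promote(base)
            s1 = rng.integers(0, 2, size=31).astype(np.uint8)
            s2 = s1.copy()
            for _ in range(50):
                s1 = v.step(s1, net, base, 0.0)
                s2 = v.step(s2, net4, promoted, 0.0)
            assert np.array_equal(s1, s2)


class TestMutation:
    def test_rate_zero_is_identity(self, rng):
        rule = v.random_rule(5, rng)
        assert v.mutate(rule, 0.0, rng) == rule

    def test_rate_one_is_complement(self, rng):
        rule = v.random_rule(5, rng)
        assert np.array_equal(v.mutate(rule, 1.0, rng).table, 1 - rule.table)

    def test_input_not_modified(self, rng):
        rule = v.random_rule(3, rng)
        before = rule.table.copy()
        v.mutate(rule, 0.5, rng)
        assert np.array_equal(rule.table, before)

    def test_flip_count_matches_binomial_expectation(self, rng):
        rule = v.random_rule(5, rng)
        trials = 10_000
        flips = [
            int((v.mutate(rule, 0.5, rng).table != rule.table).sum())
            for _ in range(trials)
        ]
        se = math.sqrt(32 * 0.25) / math.sqrt(trials)
        assert abs(np.mean(flips) - 16.0) < 3 * se

    def test_bad_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            v.mutate(v.make_majority_rule(3), 1.5, rng)


def _profile_oracle(rule, eta):
    """Brute-force expectation: enumerate every true neighbor pattern and
    every flip mask with its probability."""
    m = rule.k - 1
    p = np.zeros((2, rule.k))
    for s in (0, 1):
        for c in range(rule.k):
            acc, npat = 0.0, 0
            for pat in range(2**m):
                if bin(pat).count("1") != c:
                    continue
                npat += 1
                for mask in range(2**m):
                    nflip = bin(mask).count("1")
                    w = eta**nflip * (1 - eta) ** (m - nflip)
                    acc += w * rule.table[(s << m) | (pat ^ mask)]
            p[s, c] = acc / npat
    return p


class TestConservativeProfile:
    def test_majority_k3_noiseless(self):
        prof = v.conservative_profile(v.make_majority_rule(3))
        assert prof.p_one[1].tolist() == [0.0, 1.0, 1.0]
        assert prof.p_one[0].tolist() == [0.0, 0.0, 1.0]

    def test_majority_k3_half_noise_closed_form(self):
        # own=1: output 1 iff >=1 of 2 perceived ones; perception is
        # Bernoulli(1/2) regardless of the true pattern => 1 - 1/4
        prof = v.conservative_profile(v.make_majority_rule(3), eta=0.5)
        assert np.allclose(prof.p_one[1], 0.75)

    @pytest.mark.parametrize("k", [3, 5, 7])
    def test_majority_profile_is_step_function(self, k):
        prof = v.conservative_profile(v.make_majority_rule(k))
        for s in (0, 1):
            jump = (k + 1) // 2 - s
            expected = (np.arange(k) >= jump).astype(float)
            assert np.array_equal(prof.p_one[s], expected)

    @pytest.mark.parametrize("eta", [0.0, 0.2])
    def test_matches_bruteforce_oracle(self, rng, eta):
        rule = v.random_rule(5, rng)
        prof = v.conservative_profile(rule, eta)
        assert np.allclose(prof.p_one, _profile_oracle(rule, eta), atol=1e-12)

    @pytest.mark.parametrize("eta", [0.0, 0.3])
    def test_class_weighted_mean_equals_table_mean(self, rng, eta):
        # uniform inputs stay uniform under iid flips, so the weighted
        # profile must average back to the table's fraction of 1-outputs
        rule = v.random_rule(5, rng)
        prof = v.conservative_profile(rule, eta)
        w = np.array([math.comb(4, c) for c in range(5)]) / 2**5
        assert np.isclose((prof.p_one * w).sum(), rule.table.mean(), atol=1e-12)

    def test_majority_flip_thresholds(self):
        prof = v.conservative_profile(v.make_majority_rule(7))
        assert v.flip_thresholds(prof) == {0: 4, 1: 4}

    def test_bad_eta_rejected(self):
        with pytest.raises(ValueError):
            v.conservative_profile(v.make_majority_rule(3), eta=1.5)


class TestRuleFiles:
    def test_roundtrip(self, rng, tmp_path):
        rule = v.random_rule(5, rng)
        path = tmp_path / "rule.txt"
        v.write_rule(rule, path)
        assert v.read_rule(path) == rule

    def test_majority_k3_file_format(self, tmp_path):
        path = tmp_path / "maj.txt"
        v.write_rule(v.make_majority_rule(3), path)
        assert path.read_text().splitlines() == ["k=3", "11101000"]

    def test_length_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("k=3\n1110100\n")
        with pytest.raises(ValueError):
            v.read_rule(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("n=3\n11101000\n")
        with pytest.raises(ValueError):
            v.read_rule(path)


def test_index_convention_own_state_most_significant():
    # own state carries weight 2**(k-1); slot j carries 2**(k-2-j)
    assert _index(5, 1, (0, 0, 0, 0)) == 16
    assert _index(5, 0, (1, 0, 0, 0)) == 8
    assert _index(5, 0, (0, 0, 0, 1)) == 1
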