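"""Markov pattern generator: exact chain statistics and generator validity."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from seqcap.markov import (
    MarkovSpec,
    empirical_stats,
    generate_associations,
    load_sequence,
    pair_probabilities,
    save_sequence,
    transition_probabilities,
)


class TestTransitionProbabilities:
    @pytest.mark.parametrize(
        "f, c, expected",
        [
            (0.5, 0.0, (0.5, 0.5)),        # c=0: i.i.d. states
            (0.3, 1.0, (1.0, 0.0)),        # c=1: the chain never changes state
            (0.2, 0.5, (0.6, 0.1)),
        ],
    )
    def test_values(self, f, c, expected):
        assert transition_probabilities(MarkovSpec(f, c)) == pytest.approx(expected)

    @given(f=st.floats(0.05, 0.95), c=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_stationarity_and_correlation(self, f, c):
        """Exact enumeration: stationary mean f and lag-1 Pearson correlation c."""
        p11, p01 = transition_probabilities(MarkovSpec(f, c))
        # stationarity of (1-f, f) under the 2x2 transition matrix
        assert f * p11 + (1 - f) * p01 == pytest.approx(f, abs=1e-12)
        # lag-1 correlation from the exact pair distribution
        e_xy = f * p11
        corr_num = e_xy - f * f
        assert corr_num == pytest.approx(c * f * (1 - f), abs=1e-12)

    @pytest.mark.parametrize("f, c", [(0.0, 0.5), (1.0, 0.5), (0.5, -0.1), (0.5, 1.2)])
    def test_domain_errors(self, f, c):
        with pytest.raises(ValueError):
            MarkovSpec(f, c)


class TestPairProbabilities:
    @pytest.mark.parametrize(
        "f, c, expected",
        [
            (0.5, 0.0, (0.25, 0.25, 0.25, 0.25)),
            (0.3, 1.0, (0.7, 0.0, 0.0, 0.3)),
            (0.2, 0.5, (0.72, 0.08, 0.08, 0.12)),
        ],
    )
    def test_values(self, f, c, expected):
        pp = pair_probabilities(MarkovSpec(f, c))
        assert (pp.p00, pp.p01, pp.p10, pp.p11) == pytest.approx(expected)

    @pytest.mark.parametrize("f", [0.1, 0.3, 0.5, 0.7, 0.9])
    @pytest.mark.parametrize("c", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_marginals_and_normalization(self, f, c):
        pp = pair_probabilities(MarkovSpec(f, c))
        assert pp.p00 + pp.p01 + pp.p10 + pp.p11 == pytest.approx(1.0)
        assert pp.p11 + pp.p10 == pytest.approx(f)
        assert pp.p11 + pp.p01 == pytest.approx(f)
        assert pp.p01 == pytest.approx(pp.p10)


class TestGenerateAssociations:
    def test_shapes_binary_and_determinism(self):
        a = generate_associations(MarkovSpec(0.3, 0.2), MarkovSpec(0.6, 0.5), N=7, P=40, seed=3)
        b = generate_associations(MarkovSpec(0.3, 0.2), MarkovSpec(0.6, 0.5), N=7, P=40, seed=3)
        assert a.inputs.shape == (40, 7) and a.targets.shape == (40,)
        assert set(np.unique(a.inputs)) <= {0, 1}
        np.testing.assert_array_equal(a.inputs, b.inputs)
        np.testing.assert_array_equal(a.targets, b.targets)

    def test_columns_stable_under_growth(self):
        """Enlarging N or P must not change existing cells (child streams)."""
        small = generate_associations(MarkovSpec(0.5, 0.3), MarkovSpec(0.5, 0.0), N=4, P=30, seed=9)
        big = generate_associations(MarkovSpec(0.5, 0.3), MarkovSpec(0.5, 0.0), N=8, P=50, seed=9)
        np.testing.assert_array_equal(small.inputs, big.inputs[:30, :4])
        np.testing.assert_array_equal(small.targets, big.targets[:30])
        np.testing.assert_array_equal(small.inputs, big.prefix(30).inputs[:, :4])

    def test_frozen_chains_at_c_one(self):
        seq = generate_associations(MarkovSpec(0.5, 1.0), MarkovSpec(0.5, 1.0), N=5, P=20, seed=11)
        assert np.all(seq.inputs == seq.inputs[0])
        assert np.all(seq.targets == seq.targets[0])

    def test_single_pattern_activity(self):
        hits = [
            generate_associations(MarkovSpec(0.2, 0.9), MarkovSpec(0.5, 0.0), N=3, P=1, seed=s).inputs.mean()
            for s in range(500)
        ]
        se = np.sqrt(0.2 * 0.8 / (3 * 500))
        assert np.mean(hits) == pytest.approx(0.2, abs=3 * se)

    def test_long_stream_recovers_f_and_c(self):
        f, c, P = 0.5, 0.8, 2000
        seq = generate_associations(MarkovSpec(f, c), MarkovSpec(f, c), N=200, P=P, seed=5)
        means = seq.inputs.mean(axis=0)
        # Markov-chain CLT: var of the mean inflated by (1+c)/(1-c)
        se_mean = np.sqrt(f * (1 - f) * (1 + c) / (1 - c) / P)
        assert means.mean() == pytest.approx(f, abs=3 * se_mean / np.sqrt(200))
        corr = empirical_stats(seq.inputs[:, 0]).lag1_corr
        assert corr == pytest.approx(c, abs=3 * np.sqrt((1 - c**2) / P))

    def test_c_zero_patterns_are_iid_bernoulli(self):
        """Chi-square on joint pattern frequencies over many seeds at c=0."""
        f, N, P = 0.4, 3, 4
        counts = np.zeros(2**N)
        for seed in range(400):
            seq = generate_associations(MarkovSpec(f, 0.0), MarkovSpec(0.5, 0.0), N=N, P=P, seed=seed)
            idx = seq.inputs @ (2 ** np.arange(N))
            for i in idx:
                counts[i] += 1
        k = np.arange(2**N)
        ones = np.array([bin(v).count("1") for v in k])
        probs = f**ones * (1 - f) ** (N - ones)
        res = stats.chisquare(counts, probs * counts.sum())
        assert res.pvalue > 1e-3

    def test_pair_frequencies_converge_to_theory(self):
        f, c, P = 0.3, 0.6, 10_000
        seq = generate_associations(MarkovSpec(0.5, 0), MarkovSpec(f, c), N=1, P=P, seed=2)
        t = seq.targets
        pairs = list(zip(t[:-1], t[1:]))
        pp = pair_probabilities(MarkovSpec(f, c))
        for (a, b), p in zip([(0, 0), (0, 1), (1, 0), (1, 1)], [pp.p00, pp.p01, pp.p10, pp.p11]):
            freq = np.mean([x == (a, b) for x in pairs])
            se = np.sqrt(p * (1 - p) / P) * 2  # pairs overlap; inflate the SE
            assert freq == pytest.approx(p, abs=3 * se + 0.01)

    @pytest.mark.parametrize("N, P", [(0, 5), (5, 0), (-1, 3)])
    def test_domain_errors(self, N, P):
        with pytest.raises(ValueError):
            generate_associations(MarkovSpec(0.5, 0.0), MarkovSpec(0.5, 0.0), N=N, P=P, seed=0)


class TestEmpiricalStats:
    def test_alternating_stream(self):
        s = empirical_stats(np.array([0, 1, 0, 1, 0, 1]))
        assert s.mean == pytest.approx(0.5)
        assert s.lag1_corr == pytest.approx(-1.0)
        assert s.correlation_defined

    def test_constant_stream_flagged(self):
        s = empirical_stats(np.ones(4))
        assert s.mean == 1.0
        assert not s.correlation_defined
        assert np.isnan(s.lag1_corr)

    def test_recovers_chain_parameters(self):
        f, c, P = 0.3, 0.6, 20_000
        seq = generate_associations(MarkovSpec(0.5, 0), MarkovSpec(f, c), N=1, P=P, seed=8)
        s = empirical_stats(seq.targets)
        assert s.mean == pytest.approx(f, abs=3 * np.sqrt(f * (1 - f) * (1 + c) / (1 - c) / P))
        assert s.lag1_corr == pytest.approx(c, abs=3 * np.sqrt((1 - c**2) / P))

    def test_too_short(self):
        with pytest.raises(ValueError):
            empirical_stats(np.array([1]))


def test_serialization_roundtrip(tmp_path):
    seq = generate_associations(MarkovSpec(0.3, 0.2), MarkovSpec(0.6, 0.5), N=6, P=15, seed=4)
    path = tmp_path / "seq.txt"
    save_sequence(seq, path)
    meta = json.loads((tmp_path / "seq.txt.json").read_text())
    assert meta["seed"] == 4 and meta["input_spec"]["f"] == 0.3
    loaded = load_sequence(path)
    np.testing.assert_array_equal(loaded.inputs, seq.inputs)
    np.testing.assert_array_equal(loaded.targets, seq.targets)
    assert loaded.output_spec == seq.output_spec
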