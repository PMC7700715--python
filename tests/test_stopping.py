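"""Unit and property tests for the hypergeometric stopping test."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import screenstop as ss
from screenstop.stopping import SamplingState, StoppingConfig


def hyper_pmf(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact hypergeometric point mass by direct counting."""
    if k < 0 or k > min(K, n) or n - k > N - K:
        return Fraction(0)
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def hyper_cdf(k: int, N: int, K: int, n: int) -> float:
    return float(sum(hyper_pmf(j, N, K, n) for j in range(k + 1)))


def brute_k_tar(rho_seen: int, rho_al: int, tau: float) -> int:
    """Smallest K such that rho_seen / (rho_al + K) < tau, by linear scan."""
    K = 0
    while True:
        K += 1
        if rho_al + K > 0 and Fraction(rho_seen) < Fraction(tau) * (rho_al + K):
            return K


class TestComputeKTar:
    @pytest.mark.parametrize(
        "rho_seen, rho_al, tau, expected",
        [
            (45, 45, 0.95, 3),
            (228, 228, 0.95, 13),
            (0, 0, 0.95, 1),
            (19, 10, 0.9, 12),
        ],
    )
    def test_worked_examples(self, rho_seen, rho_al, tau, expected):
        assert ss.compute_k_tar(rho_seen, rho_al, tau) == expected

    @given(
        rho_seen=st.integers(0, 400),
        extra=st.integers(0, 400),
        tau=st.floats(0.01, 0.999),
    )
    def test_matches_strict_inequality_characterisation(self, rho_seen, extra, tau):
        """The floor formula equals the smallest K leaving recall below target."""
        rho_al = max(0, rho_seen - extra)
        assert ss.compute_k_tar(rho_seen, rho_al, tau) == brute_k_tar(
            rho_seen, rho_al, tau
        )

    def test_exact_recall_boundary_counts_as_achieved(self):
        # 228/240 is exactly 95%: one fewer remaining relevant than K_tar
        # leaves recall at the target, so the null needs K_tar = 13.
        assert ss.compute_k_tar(228, 228, 0.95) == 13
        assert 228 / (228 + 12) == pytest.approx(0.95)

    @pytest.mark.parametrize("tau", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_tau_rejected(self, tau):
        with pytest.raises(ValueError):
            ss.compute_k_tar(10, 5, tau)

    def test_rho_al_above_rho_seen_rejected(self):
        with pytest.raises(ValueError):
            ss.compute_k_tar(5, 6, 0.9)


class TestStoppingPValue:
    def test_small_instance_fraction(self):
        assert ss.stopping_p_value(10, 3, 5, 0) == pytest.approx(21 / 252)

    def test_degenerate_nulls_are_zero(self):
        assert ss.stopping_p_value(100, 0, 10, 0) == 0.0
        assert ss.stopping_p_value(100, -2, 10, 0) == 0.0
        assert ss.stopping_p_value(100, 101, 10, 0) == 0.0

    def test_exhaustive_sample_below_null_count(self):
        # all 50 drawn, only 4 relevant seen: impossible if 5 existed
        assert ss.stopping_p_value(50, 5, 50, 4) == 0.0

    def test_matches_enumeration_small(self):
        for N in range(1, 13):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for k in range(0, n + 1):
                        expected = 0.0 if K == 0 or K > N else hyper_cdf(k, N, K, n)
                        if K == 0:
                            expected = 0.0  # degenerate-null convention
                        assert ss.stopping_p_value(N, K, n, k) == pytest.approx(
                            expected, abs=1e-12
                        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ss.stopping_p_value(10, 2, 5, 6)
        with pytest.raises(ValueError):
            ss.stopping_p_value(10, 2, 11, 1)

    def test_monotone_in_sample_size(self):
        N, K, k = 40, 6, 2
        ps = [ss.stopping_p_value(N, K, n, k) for n in range(k, N + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_monotone_in_null_count(self):
        N, n, k = 40, 15, 3
        ps = [ss.stopping_p_value(N, K, n, k) for K in range(k, N + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestRandomSamplingCriterion:
    def test_start_of_sampling_worked_example(self):
        # 45 of 47 relevant seen, 5029 unseen, no draws yet: K_tar = 3 and
        # the test cannot reject without evidence.
        state = SamplingState(N_total=5999, N_AL=970, rho_AL=45, n=0, k=0)
        res = ss.evaluate_random_sampling_criterion(state, StoppingConfig())
        assert res.k_tar == 3
        assert res.p_value == pytest.approx(1.0)
        assert not res.reject

    def test_everything_screened_rejects(self):
        state = SamplingState(N_total=20, N_AL=0, rho_AL=0, n=20, k=20)
        res = ss.evaluate_random_sampling_criterion(state, StoppingConfig())
        assert res.p_value == 0.0
        assert res.reject

    def test_against_enumeration(self):
        state = SamplingState(N_total=400, N_AL=200, rho_AL=20, n=60, k=0)
        cfg = StoppingConfig()
        res = ss.evaluate_random_sampling_criterion(state, cfg)
        assert res.k_tar == 2
        expected = hyper_cdf(0, 200, 2, 60)
        assert res.p_value == pytest.approx(expected, abs=1e-12)
        assert res.reject == (expected < 0.05)

    def test_state_invariants_enforced(self):
        with pytest.raises(ValueError):
            SamplingState(N_total=10, N_AL=5, rho_AL=6, n=0, k=0)
        with pytest.raises(ValueError):
            SamplingState(N_total=10, N_AL=5, rho_AL=2, n=6, k=0)


class TestQuasiSampling:
    def naive(self, labels, N_total, tau):
        out = []
        t = len(labels)
        for i in range(1, t):
            rho_al = int(sum(labels[:i]))
            k = int(sum(labels[i:]))
            state = SamplingState(
                N_total=N_total, N_AL=i, rho_AL=rho_al, n=t - i, k=k
            )
            cfg = StoppingConfig(tau_tar=tau)
            out.append(ss.evaluate_random_sampling_criterion(state, cfg).p_value)
        return np.array(out)

    def test_all_relevant_never_contradicts_null(self):
        assert np.all(ss.quasi_sampling_p_sequence([1, 1, 1], 10, 0.95) == 1.0)
        assert ss.p_min([1, 1, 1], 10, 0.95) == 1.0

    def test_hand_sized_example_matches_loop(self):
        seq = ss.quasi_sampling_p_sequence([1, 0, 0, 0], 10, 0.95)
        np.testing.assert_allclose(seq, self.naive([1, 0, 0, 0], 10, 0.95), atol=1e-12)

    @given(data=st.data())
    def test_vectorised_equals_naive_loop(self, data):
        labels = data.draw(st.lists(st.integers(0, 1), min_size=2, max_size=50))
        N_total = len(labels) + data.draw(st.integers(0, 40))
        tau = data.draw(st.sampled_from([0.5, 0.8, 0.9, 0.95, 0.99]))
        got = ss.quasi_sampling_p_sequence(labels, N_total, tau)
        np.testing.assert_allclose(got, self.naive(labels, N_total, tau), atol=1e-12)

    @given(data=st.data())
    def test_appending_irrelevant_never_raises_p_min(self, data):
        labels = data.draw(st.lists(st.integers(0, 1), min_size=2, max_size=40))
        N_total = len(labels) + data.draw(st.integers(1, 30))
        before = ss.p_min(labels, N_total, 0.95)
        after = ss.p_min(labels + [0], N_total, 0.95)
        assert after <= before + 1e-12

    def test_empty_and_singleton_sequences(self):
        assert ss.quasi_sampling_p_sequence([], 10, 0.95).size == 0
        assert ss.quasi_sampling_p_sequence([1], 10, 0.95).size == 0
        assert ss.p_min([], 10, 0.95) == 1.0

    def test_too_many_labels_rejected(self):
        with pytest.raises(ValueError):
            ss.quasi_sampling_p_sequence([0, 1, 0], 2, 0.95)


class TestDecisions:
    def test_switch_threshold_is_half_alpha(self):
        cfg = StoppingConfig()
        assert cfg.switch_threshold == pytest.approx(0.525)
        assert ss.switch_decision(0.5, cfg)
        assert not ss.switch_decision(0.6, cfg)
        assert ss.switch_decision(0.05, cfg)

    def test_stop_threshold_strict(self):
        cfg = StoppingConfig()
        assert ss.quasi_sampling_stop_decision(0.04, cfg)
        assert not ss.quasi_sampling_stop_decision(0.05, cfg)
        assert not ss.quasi_sampling_stop_decision(1.0, cfg)

    def test_config_invariants(self):
        cfg = StoppingConfig(tau_tar=0.9, alpha=0.9)
        assert cfg.stop_threshold == pytest.approx(0.1)
        assert cfg.switch_threshold == pytest.approx(0.55)
        assert cfg.switch_threshold > cfg.stop_threshold
        for bad in (
            dict(tau_tar=0.0),
            dict(alpha=1.0),
            dict(heuristic_window=0),
            dict(batch_size=0),
            dict(seed_sample_size=0),
        ):
            with pytest.raises(ValueError):
                StoppingConfig(**bad)
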