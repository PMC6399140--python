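"""Markovianity / stationarity / symmetry G-tests and autoinformation."""
import numpy as np
import pytest

import msdyn as m
from msdyn.datatypes import UndefinedResultError

A, B, C, D = 0, 1, 2, 3


def _seq(labels, fs=250.0, names=("A", "B", "C", "D")):
    return m.LabelSequence(np.asarray(labels, dtype=np.int64), fs, list(names))


def _cycle(n, k=4):
    return _seq(np.arange(n) % k, names=tuple("ABCD")[:k])


class TestGStatisticIdentities:
    def test_order0_zero_when_counts_factorize(self):
        # [A,A,B,B] repeated (closed on A): all four pair counts equal,
        # so n_ij = n_i. * n_.j / n exactly
        seq = _seq([A, A, B, B] * 50 + [A], names=("A", "B"))
        r = m.markov_order0_test(seq)
        assert r.g_statistic == pytest.approx(0.0, abs=1e-9)

    def test_order1_zero_for_deterministic_cycle(self):
        r = m.markov_order1_test(_cycle(400))
        assert r.g_statistic == pytest.approx(0.0, abs=1e-9)

    def test_order2_zero_for_deterministic_cycle(self):
        r = m.markov_order2_test(_cycle(400))
        assert r.g_statistic == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_zero_for_balanced_counts(self):
        seq = _seq([A, B, A, C, A, B, A, C, A], names=("A", "B", "C"))
        r = m.symmetry_test(seq)
        assert r.g_statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_degenerate_single_state_rejected(self):
        with pytest.raises(UndefinedResultError):
            m.markov_order0_test(_seq([A] * 50))

    def test_expected_degrees_of_freedom(self):
        seq = _seq(np.random.default_rng(0).integers(0, 4, 2000))
        assert m.markov_order0_test(seq).df == 9
        assert m.markov_order1_test(seq).df == 36
        assert m.markov_order2_test(seq).df == 144
        assert m.symmetry_test(seq).df == 3
        assert m.stationarity_test(seq, 1.0).df == (8 - 1) * 4 * 3

    def test_symmetry_invariant_under_time_reversal(self, diag_chain):
        seq = m.sample_markov_sequence(diag_chain, 5000, seed=3)
        fwd = m.symmetry_test(seq)
        rev = m.symmetry_test(m.LabelSequence(seq.labels[::-1].copy(), 1.0,
                                              list(seq.state_names)))
        assert fwd.g_statistic == pytest.approx(rev.g_statistic, abs=1e-9)


class TestCalibrationAndPower:
    """Reduced-size Monte Carlo; the full-size runs live in acceptance."""

    def test_type_one_error_order1(self, diag_chain):
        rej = sum(m.markov_order1_test(
            m.sample_markov_sequence(diag_chain, 5000, seed=s)).significant
            for s in range(200))
        assert rej / 200 < 0.04  # 99% band around 0.01 at n=200

    def test_symmetry_null_calibrated(self, diag_chain):
        ps = [m.symmetry_test(
            m.sample_markov_sequence(diag_chain, 5000, seed=600 + s)).p_value
            for s in range(200)]
        # chi-squared calibration: mean p near 0.5, not piled at 1
        assert 0.4 < np.mean(ps) < 0.6

    def test_gamma_dwell_rejects_all_low_orders(self):
        cfg = m.SimulationConfig(duration=480.0, dwell_dist="gamma",
                                 dwell_mean=80.0, seed=1)
        seq = m.sample_state_sequence(cfg)
        assert m.markov_order0_test(seq).significant
        assert m.markov_order1_test(seq).significant
        assert m.markov_order2_test(seq).significant

    def test_cyclic_chain_fails_symmetry(self):
        cycle = np.array([[0, .9, .05, .05], [.05, 0, .9, .05],
                          [.05, .05, 0, .9], [.9, .05, .05, 0]])
        cfg = m.SimulationConfig(transition_matrix=cycle, duration=480.0,
                                 seed=2)
        seq = m.sample_state_sequence(cfg)
        assert m.symmetry_test(seq).significant

    def test_stationarity_detects_changepoint(self):
        t1 = np.full((4, 4), 1 / 3)
        np.fill_diagonal(t1, 0)
        t2 = m.perturb_jump_matrix(t1, {(0, 1): 0.3, (1, 2): 0.3,
                                        (2, 3): 0.3, (3, 0): 0.3})
        hits = 0
        for s in range(10):
            c1 = m.SimulationConfig(transition_matrix=t1, duration=240.0,
                                    seed=s)
            c2 = m.SimulationConfig(transition_matrix=t2, duration=240.0,
                                    seed=1000 + s)
            lab = np.concatenate([m.sample_state_sequence(c1).labels,
                                  m.sample_state_sequence(c2).labels])
            seq = m.LabelSequence(lab, 250.0, ["A", "B", "C", "D"])
            hits += m.stationarity_test(seq, 20.0, alpha=0.05).significant
        assert hits >= 9

    def test_homogeneous_chain_rarely_flagged(self, diag_chain):
        rej = sum(m.stationarity_test(
            m.sample_markov_sequence(diag_chain, 5000, seed=s), 1000.0
        ).significant for s in range(100))
        assert rej <= 5


class TestAIF:
    def test_lag_zero_is_marginal_entropy(self):
        seq = _cycle(4000)
        curve = m.aif(seq, max_lag_ms=40.0)
        assert curve.values[0] == pytest.approx(2.0, abs=1e-6)

    def test_strict_alternation_one_bit_everywhere(self):
        seq = _seq([A, B] * 2000, names=("A", "B"))
        curve = m.aif(seq, max_lag_ms=100.0)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-6)

    def test_plugin_matches_closed_form(self):
        t = np.array([[0.9, 0.1], [0.1, 0.9]])
        seq = m.sample_markov_sequence(t, 200_000, seed=5)
        seq = m.LabelSequence(seq.labels, 1000.0, list(seq.state_names))
        curve = m.aif(seq, max_lag_ms=50.0)
        oracle = np.array([m.markov_aif_closed_form(t, int(lag))
                           for lag in curve.lags])
        assert oracle[1] == pytest.approx(0.531, abs=0.001)
        assert np.max(np.abs(curve.values - oracle)) < 0.01

    def test_relabeling_invariance(self, diag_chain):
        seq = m.sample_markov_sequence(diag_chain, 20_000, seed=8)
        perm = np.array([2, 0, 3, 1])
        relabeled = m.LabelSequence(perm[seq.labels], 1.0,
                                    ["A", "B", "C", "D"])
        a = m.aif(m.LabelSequence(seq.labels, 1.0, list(seq.state_names)),
                  max_lag_ms=20_000.0)
        b = m.aif(relabeled, max_lag_ms=20_000.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_truncated_grid_warns(self):
        seq = _cycle(100)
        with pytest.warns(UserWarning):
            curve = m.aif(seq, max_lag_ms=4000.0)
        assert curve.lags[-1] == 99


class TestPartialAIF:
    def test_indicator_of_alternation(self):
        seq = _seq([A, B] * 1000, names=("A", "B"))
        curve = m.partial_aif(seq, "A", max_lag_ms=40.0)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-6)

    def test_lag_zero_is_binary_coverage_entropy(self, diag_chain):
        seq = m.sample_markov_sequence(diag_chain, 10_000, seed=9)
        seq = m.LabelSequence(seq.labels, 250.0, list(seq.state_names))
        cov = m.coverage(seq)
        for name in "ABCD":
            p = cov[name]
            h = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
            curve = m.partial_aif(seq, name, max_lag_ms=8.0)
            assert curve.values[0] == pytest.approx(h, abs=1e-9)

    def test_iid_indicator_decays_to_plugin_bias(self):
        rng = np.random.default_rng(10)
        n = 100_000
        seq = _seq(rng.integers(0, 4, n))
        curve = m.partial_aif(seq, "B", max_lag_ms=40.0)
        bias_bound = 2.0 / (2 * n * np.log(2))  # plug-in MI bias ~ df/(2n ln2)
        assert np.all(curve.values[1:] < 20 * bias_bound)

    def test_absent_state_rejected(self):
        with pytest.raises(UndefinedResultError):
            m.partial_aif(_seq([A, B, A, B]), "D")


class TestClosedFormAIF:
    def test_lag_zero_is_stationary_entropy(self):
        t = np.array([[0.9, 0.1], [0.1, 0.9]])
        pi = m.stationary_distribution(t)
        h = -(pi * np.log2(pi)).sum()
        assert m.markov_aif_closed_form(t, 0) == pytest.approx(h)

    def test_uniform_rows_independent(self):
        t = np.full((4, 4), 0.25)
        for lag in (1, 2, 5):
            assert m.markov_aif_closed_form(t, lag) == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_hand_value_at_lag_one(self):
        val = m.markov_aif_closed_form(np.array([[0.9, 0.1], [0.1, 0.9]]), 1)
        assert val == pytest.approx(0.5310, abs=5e-4)


class TestCohortSummary:
    def test_counting(self):
        def res(flag):
            return m.MarkovTestResult("markov0", 1.0, 9, 0.5, 0.01, flag)
        assert m.cohort_summary([res(True), res(False), res(True),
                                 res(True)]) == pytest.approx(0.75)
        assert m.cohort_summary([res(False)] * 4) == 0.0
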