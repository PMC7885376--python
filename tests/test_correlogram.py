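"""Cross-correlogram estimators against brute-force and hand-computed oracles."""

import numpy as np
import pytest

from dona.correlogram import (
    Scope,
    compute_ccg,
    compute_dccg,
    compute_eccg,
    lag_indices,
    session_windowed_ccgs,
    windowed_ccgs,
)
from dona.edlds import SNAEstimate
from dona.io import EpochSchedule, SpikeTrainSet

from conftest import random_session


def brute_force_ccg(spikes: SpikeTrainSet, tau: float, n_lags: int) -> np.ndarray:
    """Independent double loop over (reference spike, target spike) pairs."""
    N = spikes.n_neurons
    lags = lag_indices(n_lags)
    M = spikes.n_trials
    terms = np.zeros((M, N, N, len(lags)))
    for m in range(M):
        for j in range(N):
            refs = spikes.spikes[m][j]
            if len(refs) == 0:
                continue
            for i in range(N):
                if i == j:
                    continue
                for kk, k in enumerate(lags):
                    total = 0
                    for tr in refs:
                        lo = tr + (k - 1) * tau if k > 0 else tr + k * tau
                        hi = tr + k * tau if k > 0 else tr + (k + 1) * tau
                        for tt in spikes.spikes[m][i]:
                            if lo <= tt < hi:
                                total += 1
                    terms[m, j, i, kk] = total / len(refs)
    return terms.sum(axis=0) / M / tau


def constant_sna(spikes: SpikeTrainSet, rate: float | np.ndarray) -> SNAEstimate:
    sched = spikes.schedule
    rates = np.broadcast_to(
        np.asarray(rate, dtype=float),
        (spikes.n_trials, spikes.n_neurons, sched.n_bins),
    ).copy()
    return SNAEstimate(rates=rates, schedule=sched)


class TestCCG:
    def test_single_pair_hand_count(self):
        sched = EpochSchedule()
        s = SpikeTrainSet(
            spikes=[[np.array([0.100]), np.array([0.110])]], schedule=sched
        )
        ccg = compute_ccg(s, tau=0.025, n_lags=2)
        lags = list(ccg.lags)
        assert ccg.values[0, 1, lags.index(1)] == pytest.approx(40.0)
        others = [k for k in range(len(lags)) if lags[k] != 1]
        assert np.all(ccg.values[0, 1, others] == 0)
        # reverse direction: target precedes reference by one lag
        assert ccg.values[1, 0, lags.index(-1)] == pytest.approx(40.0)

    def test_silent_target_gives_zero_everywhere(self):
        sched = EpochSchedule()
        s = SpikeTrainSet(spikes=[[np.array([0.1, 0.2]), np.empty(0)]], schedule=sched)
        ccg = compute_ccg(s, tau=0.025, n_lags=3)
        assert np.all(ccg.values[0, 1] == 0)
        assert ccg.undefined[1, 0]  # silent neuron cannot serve as reference

    def test_duplicated_trial_leaves_average_unchanged(self):
        sched = EpochSchedule()
        trial = [np.array([0.1, 1.0, 2.0]), np.array([0.11, 1.02])]
        one = SpikeTrainSet(spikes=[trial], schedule=sched)
        two = SpikeTrainSet(spikes=[trial, trial], schedule=sched)
        np.testing.assert_allclose(
            compute_ccg(one, 0.025, 4).values, compute_ccg(two, 0.025, 4).values
        )

    def test_spike_at_reference_time_counts_at_lag_plus_one(self):
        sched = EpochSchedule()
        s = SpikeTrainSet(spikes=[[np.array([0.5]), np.array([0.5])]], schedule=sched)
        ccg = compute_ccg(s, tau=0.025, n_lags=1)
        lags = list(ccg.lags)
        assert ccg.values[0, 1, lags.index(1)] == pytest.approx(40.0)
        assert ccg.values[0, 1, lags.index(-1)] == 0

    def test_matches_brute_force_on_random_sessions(self, rng):
        for _ in range(10):
            s = random_session(
                rng,
                n_neurons=int(rng.integers(2, 5)),
                n_trials=int(rng.integers(1, 6)),
                max_spikes=25,
            )
            got = compute_ccg(s, tau=0.025, n_lags=3).values
            want = brute_force_ccg(s, tau=0.025, n_lags=3)
            off = ~np.eye(s.n_neurons, dtype=bool)
            np.testing.assert_array_equal(got[off], want[off])


class TestECCG:
    def test_constant_rate_recovers_rate_at_all_lags(self, rng):
        s = random_session(rng, n_neurons=3, n_trials=4, max_spikes=30)
        sna = constant_sna(s, 7.5)
        # keep reference spikes one full lag away from the trial edges so no
        # window is truncated
        scope = Scope(time_range=(0.1, s.schedule.trial_duration - 0.1))
        eccg = compute_eccg(sna, s, tau=0.025, n_lags=3, scope=scope)
        off = ~np.eye(3, dtype=bool) & ~eccg.undefined
        np.testing.assert_allclose(eccg.values[off], 7.5, atol=1e-9)

    def test_length_weighted_average_across_bin_edge(self):
        sched = EpochSchedule()
        # reference spike 15 ms before a bin edge; target rate 10 in that bin
        # and 20 afterwards -> lag +1 window mean is (15*10 + 10*20)/25
        edge = 10 * sched.s_bin
        t_ref = edge - 0.015
        s = SpikeTrainSet(spikes=[[np.array([t_ref]), np.array([0.05])]], schedule=sched)
        rates = np.full((1, 2, sched.n_bins), 10.0)
        rates[0, 1, 10:] = 20.0
        sna = SNAEstimate(rates=rates, schedule=sched)
        eccg = compute_eccg(sna, s, tau=0.025, n_lags=1)
        lags = list(eccg.lags)
        assert eccg.values[0, 1, lags.index(1)] == pytest.approx(14.0)

    def test_single_reference_spike_degeneracy(self):
        sched = EpochSchedule()
        s = SpikeTrainSet(spikes=[[np.array([1.0]), np.array([0.3])]], schedule=sched)
        rng = np.random.default_rng(0)
        rates = rng.uniform(2, 20, size=(1, 2, sched.n_bins))
        sna = SNAEstimate(rates=rates, schedule=sched)
        eccg = compute_eccg(sna, s, tau=0.025, n_lags=1)
        # window [1.0, 1.025) spans bins 14/15 of width 0.0674
        lo, hi = 1.0, 1.025
        edge = 15 * sched.s_bin
        want = (rates[0, 1, 14] * (edge - lo) + rates[0, 1, 15] * (hi - edge)) / 0.025
        lags = list(eccg.lags)
        assert eccg.values[0, 1, lags.index(1)] == pytest.approx(want)

    def test_window_truncated_at_trial_end(self):
        sched = EpochSchedule()
        t_ref = sched.trial_duration - 0.010  # forward window extends past end
        s = SpikeTrainSet(spikes=[[np.array([t_ref]), np.array([0.3])]], schedule=sched)
        sna = constant_sna(s, 5.0)
        eccg = compute_eccg(sna, s, tau=0.025, n_lags=1)
        lags = list(eccg.lags)
        # truncated window still averages the constant rate
        assert eccg.values[0, 1, lags.index(1)] == pytest.approx(5.0)


class TestDCCG:
    def test_equal_inputs_give_zero(self, rng, small_session, small_sna):
        session, _ = small_session
        ccg = compute_ccg(session, 0.025, 2)
        eccg = compute_eccg(small_sna, session, 0.025, 2)
        d = compute_dccg(ccg, eccg)
        np.testing.assert_allclose(d.values, ccg.values - eccg.values)
        same = compute_dccg(ccg, ccg)
        assert np.all(same.values == 0)

    def test_scope_mismatch_rejected(self, small_session, small_sna):
        session, _ = small_session
        ccg = compute_ccg(session, 0.025, 2)
        other = compute_ccg(session, 0.025, 2, scope=Scope(trials=(0, 1)))
        with pytest.raises(ValueError, match="scope"):
            compute_dccg(ccg, other)

    def test_injected_coupling_gives_transient_positive_lag_peak(self):
        """A 25-ms multiplicative coupling elevates the DCCG at lag +1 and
        decays toward zero within a few lags."""
        from dona.edlds import FitConfig, estimate_sna, fit_edlds
        from dona.io import bin_spikes
        from dona.synthetic import Coupling, SessionConfig, generate_session

        cfg = SessionConfig(
            n_neurons=5,
            n_trials=80,
            n_latent=2,
            couplings=(Coupling(ref=0, target=2, gain=2.0),),
        )
        session, truth = generate_session(cfg, seed=8)
        counts = bin_spikes(session)
        params = fit_edlds(counts, n_latent=2, config=FitConfig(max_iter=40))
        sna = estimate_sna(params, counts)
        ccg = compute_ccg(session, 0.025, 5)
        eccg = compute_eccg(sna, session, 0.025, 5)
        d = compute_dccg(ccg, eccg)
        lags = list(d.lags)
        peak = d.values[0, 2, lags.index(1)]
        base_rate = truth.rates[:, 2, :].mean()
        # the doubled post-spike rate should appear nearly in full at lag +1
        assert peak > 0.5 * base_rate
        far = [d.values[0, 2, lags.index(k)] for k in (3, 4, 5, -3, -4, -5)]
        assert np.max(np.abs(far)) < 0.3 * peak

    def test_trial_average_linearity(self, rng):
        """Weighted average of disjoint trial-set results equals the union."""
        s = random_session(rng, n_neurons=3, n_trials=6, max_spikes=30)
        tau, K = 0.025, 2
        a = compute_ccg(s, tau, K, scope=Scope(trials=(0, 1))).values
        b = compute_ccg(s, tau, K, scope=Scope(trials=(2, 3, 4, 5))).values
        union = compute_ccg(s, tau, K, scope=Scope(trials=tuple(range(6)))).values
        np.testing.assert_allclose((2 * a + 4 * b) / 6, union, atol=1e-12)


class TestWindowed:
    def test_whole_session_window_equals_global(self, small_session, small_sna):
        session, _ = small_session
        sna = small_sna
        cw, ew = windowed_ccgs(
            session, sna, 0.025, T=30, m=2,
            window_bins=session.schedule.n_bins, window_trials=session.n_trials,
        )
        cg = compute_ccg(session, 0.025, 1)
        eg = compute_eccg(sna, session, 0.025, 1)
        np.testing.assert_allclose(cw.values, cg.values)
        np.testing.assert_allclose(ew.values, eg.values)

    def test_vectorized_centers_match_single_center_path(
        self, small_session, small_sna
    ):
        session, _ = small_session
        sna = small_sna
        W = session_windowed_ccgs(session, sna, 0.025, window_bins=10, window_trials=4)
        for T, m in [(0, 0), (30, 3), (59, 7), (12, 5)]:
            cw, ew = windowed_ccgs(
                session, sna, 0.025, T=T, m=m, window_bins=10, window_trials=4
            )
            np.testing.assert_allclose(W["ccg"][0, m, :, :, T], cw.values[:, :, 1])
            np.testing.assert_allclose(W["ccg"][1, m, :, :, T], cw.values[:, :, 0])
            np.testing.assert_allclose(W["eccg"][0, m, :, :, T], ew.values[:, :, 1])
            np.testing.assert_allclose(W["eccg"][1, m, :, :, T], ew.values[:, :, 0])

    def test_edge_window_uses_available_trials(self, small_session, small_sna):
        session, _ = small_session
        cw, _ = windowed_ccgs(
            session, small_sna, 0.025, T=30, m=0, window_bins=20, window_trials=20
        )
        # only 8 trials exist; the scope must not exceed them
        assert len(cw.scope.trials) == session.n_trials

    def test_window_shrinks_estimator_variance(self, rng):
        """On stationary data, growing the window shrinks the spread of
        windowed estimates around the global value."""
        s = random_session(rng, n_neurons=3, n_trials=12, max_spikes=120)
        sna = constant_sna(s, 10.0)
        spreads = []
        for wb in (6, 60):
            W = session_windowed_ccgs(s, sna, 0.025, window_bins=wb, window_trials=12)
            vals = W["ccg"][0, 0, 0, 1, :]  # one pair, all bin centers
            spreads.append(np.std(vals))
        assert spreads[1] < spreads[0]
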