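"""DONA/PDONA: closed-form values, enumeration oracles, KL properties."""

import numpy as np
import pytest

from dona.divergence import (
    EXCL_FEW_SPIKES,
    EXCL_NONE,
    EXCL_SELF,
    EXCL_SHORT,
    all_patterns,
    compute_dona,
    compute_divergences,
    dona,
    pattern_probability,
    pdona,
    select_reference_window,
)
from dona.ona import compute_ona

DT = 0.0674 / 60


class TestDONA:
    def test_identical_traces_give_zero(self):
        r = 7.0
        assert dona(np.full(60, r), r, DT) == 0.0

    def test_two_level_trace_matches_direct_sum(self):
        """30 steps at doubled probability, 30 near zero (clipped)."""
        p_s = 0.01
        r = p_s / DT
        trace = np.zeros(60)
        trace[:30] = 2 * p_s / DT
        got = dona(trace, r, DT)
        eps = 1e-6
        want = 30 * (0.02 * np.log(0.02 / 0.01)) + 30 * (eps * np.log(eps / 0.01))
        assert got == pytest.approx(want, rel=1e-9)

    def test_nonnegative_on_mean_preserving_bins(self, rng):
        for _ in range(50):
            r = rng.uniform(0.5, 30)
            trace = rng.gamma(1.0, r, size=60)
            trace *= r / trace.mean()
            assert dona(trace, r, DT) >= 0

    def test_invariant_to_step_relabeling(self, rng):
        r = 5.0
        trace = rng.gamma(1.0, r, size=60)
        trace *= r / trace.mean()
        a = dona(trace, r, DT)
        b = dona(trace[rng.permutation(60)], r, DT)
        assert a == pytest.approx(b, rel=1e-12)

    def test_vectorized_matches_scalar(self, small_session, small_sna):
        session, _ = small_session
        ona = compute_ona(session, small_sna)
        d = compute_dona(ona)
        rng = np.random.default_rng(0)
        for _ in range(10):
            m, i, T = (
                int(rng.integers(session.n_trials)),
                int(rng.integers(session.n_neurons)),
                int(rng.integers(session.schedule.n_bins)),
            )
            want = dona(ona.ona[m, i, T], ona.sna_rates[m, i, T], ona.dt)
            assert d[m, i, T] == pytest.approx(want, rel=1e-12, abs=1e-15)

    def test_forcing_pure_sna_zeroes_dona(self, small_session, small_sna):
        """With alpha forced to 0, ONA collapses onto SNA and DONA vanishes."""
        session, _ = small_session
        ona = compute_ona(session, small_sna)
        ona.ona[:] = ona.sna_rates[:, :, :, None]
        assert np.allclose(compute_dona(ona), 0.0)


class TestPatternProbability:
    def test_iid_two_spike_case(self):
        p = 0.2
        pats, probs = pattern_probability(np.full(2, p / DT), DT)
        lookup = {tuple(int(x) for x in pat): pr for pat, pr in zip(pats, probs)}
        assert lookup[(1, 1)] == pytest.approx(p * p)
        assert lookup[(1, 0)] == pytest.approx(p * (1 - p))
        assert lookup[(0, 1)] == pytest.approx(p * (1 - p))
        assert lookup[(0, 0)] == pytest.approx((1 - p) * (1 - p))

    @pytest.mark.parametrize("n", range(1, 9))
    def test_normalization_over_all_patterns(self, rng, n):
        rates = rng.uniform(0.5, 50, size=n)
        _, probs = pattern_probability(rates, DT)
        assert abs(probs.sum() - 1.0) < 1e-12

    def test_matches_enumeration_oracle_n6(self, rng):
        rates = rng.uniform(1, 40, size=6)
        p = np.clip(rates * DT, 1e-6, 1 - 1e-6)
        pats, probs = pattern_probability(rates, DT)
        for pat, pr in zip(pats, probs):
            want = np.prod(np.where(pat > 0, p, 1 - p))
            assert pr == pytest.approx(want, rel=1e-12)


class TestPDONA:
    def test_zero_when_rates_agree(self, rng):
        rates = rng.uniform(1, 30, size=6)
        assert pdona(rates, rates, DT) == 0.0

    def test_single_spike_closed_form(self):
        got = pdona(np.array([0.2 / DT]), np.array([0.1 / DT]), DT)
        want = 0.2 * np.log(2.0) + 0.8 * np.log(0.8 / 0.9)
        assert got == pytest.approx(want, rel=1e-12)
        assert got == pytest.approx(0.0444, abs=5e-4)

    def test_factorized_form_equals_pattern_enumeration(self, rng):
        """The pipeline's per-spike Bernoulli sum equals the literal 2^n
        pattern KL."""
        from dona.divergence import _bernoulli_kl

        for _ in range(20):
            o = rng.uniform(0.5, 40, size=6)
            s = rng.uniform(0.5, 40, size=6)
            enum = pdona(o, s, DT)
            p_o = np.clip(o * DT, 1e-6, 1 - 1e-6)
            p_s = np.clip(s * DT, 1e-6, 1 - 1e-6)
            fact = _bernoulli_kl(p_o, p_s).sum()
            assert enum == pytest.approx(fact, rel=1e-10, abs=1e-14)

    def test_nonnegative_and_zero_iff_equal(self, rng):
        for _ in range(20):
            o = rng.uniform(0.5, 40, size=6)
            s = rng.uniform(0.5, 40, size=6)
            v = pdona(o, s, DT)
            assert v >= 0
            if np.max(np.abs(o - s)) * DT > 1e-9:
                assert v > 0


class TestReferenceWindow:
    def test_selects_consecutive_spikes_nearest_center(self):
        times = np.array([0.1, 0.2, 0.3, 2.0, 2.1, 2.2])
        sl = select_reference_window(times, 3, bin_center=2.05)
        np.testing.assert_allclose(times[sl], [2.0, 2.1, 2.2])
        sl = select_reference_window(times, 3, bin_center=0.0)
        np.testing.assert_allclose(times[sl], [0.1, 0.2, 0.3])

    def test_tie_breaks_toward_earlier_spikes(self):
        times = np.array([0.0, 1.0, 2.0, 3.0])
        # windows [0,1] (mean 0.5) and [1,2] (mean 1.5) tie for center 1.0
        sl = select_reference_window(times, 2, bin_center=1.0)
        np.testing.assert_allclose(times[sl], [0.0, 1.0])

    def test_too_few_spikes_returns_none(self):
        assert select_reference_window(np.array([0.1, 0.2]), 3, 1.0) is None


class TestSessionDivergences:
    def test_exclusion_reasons(self, small_session, small_sna):
        session, _ = small_session
        ona = compute_ona(session, small_sna)
        series = compute_divergences(session, ona, n=6, min_ref_spikes=10)
        N = session.n_neurons
        diag = series.excluded[:, np.arange(N), np.arange(N)]
        assert np.all(diag == EXCL_SELF)
        # exclusions match the reference spike counts
        counts = session.spike_counts()
        for m in range(session.n_trials):
            for j in range(N):
                mask = np.arange(N) != j
                if counts[m, j] < 6:
                    assert np.all(series.excluded[m, j, mask] == EXCL_SHORT)
                elif counts[m, j] < 10:
                    assert np.all(series.excluded[m, j, mask] == EXCL_FEW_SPIKES)
                else:
                    assert np.all(series.excluded[m, j, mask] == EXCL_NONE)
                    assert np.all(series.pdona[m, j, mask] >= 0)

    def test_pdona_matches_manual_reconstruction(self, small_session, small_sna):
        """Session PDONA equals the literal pattern-enumeration computation
        with the same spike-window selection and read-off rule."""
        session, _ = small_session
        ona = compute_ona(session, small_sna)
        series = compute_divergences(session, ona, n=6, min_ref_spikes=10)
        sched = session.schedule
        S = 60
        rng = np.random.default_rng(1)
        checked = 0
        for _ in range(200):
            m = int(rng.integers(session.n_trials))
            j = int(rng.integers(session.n_neurons))
            i = int(rng.integers(session.n_neurons))
            T = int(rng.integers(sched.n_bins))
            if i == j or series.excluded[m, j, i] != EXCL_NONE:
                continue
            refs = session.spikes[m][j]
            sl = select_reference_window(refs, 6, (T + 0.5) * sched.s_bin)
            sel = refs[sl]
            steps = (sel / ona.dt).astype(int) + 1
            n_steps = sched.n_bins * S
            ok = steps < n_steps
            flat = ona.ona[m, i].reshape(-1)
            r_o = np.where(ok, flat[np.minimum(steps, n_steps - 1)],
                           ona.sna_rates[m, i, np.minimum((sel / sched.s_bin).astype(int), sched.n_bins - 1)])
            r_s = np.where(ok, ona.sna_rates[m, i, np.minimum(steps, n_steps - 1) // S],
                           ona.sna_rates[m, i, np.minimum((sel / sched.s_bin).astype(int), sched.n_bins - 1)])
            want = pdona(r_o, r_s, ona.dt)
            assert series.pdona[m, j, i, T] == pytest.approx(want, rel=1e-5, abs=1e-9)
            checked += 1
        assert checked > 20

    def test_ground_truth_coupling_elevates_coupled_epoch(self):
        """An epoch-gated coupled pair shows higher PDONA in its active epoch
        than the same pair in inactive epochs."""
        from dona.edlds import FitConfig, estimate_sna, fit_edlds
        from dona.io import bin_spikes
        from dona.synthetic import Coupling, SessionConfig, generate_session

        cfg = SessionConfig(
            n_neurons=6,
            n_trials=60,
            n_latent=2,
            couplings=(Coupling(ref=0, target=3, gain=3.0, epochs=("response",)),),
        )
        session, _ = generate_session(cfg, seed=42)
        counts = bin_spikes(session)
        params = fit_edlds(counts, n_latent=2, config=FitConfig(max_iter=40))
        sna = estimate_sna(params, counts)
        ona = compute_ona(session, sna)
        series = compute_divergences(session, ona)
        pm = series.pdona_trial_mean()
        sched = session.schedule
        resp = np.nanmedian(pm[0, 3, sched.epoch_slice("response")])
        samp = np.nanmedian(pm[0, 3, sched.epoch_slice("sample")])
        delay = np.nanmedian(pm[0, 3, sched.epoch_slice("delay")])
        assert resp > samp
        assert resp > delay
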