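"""Transient correction of the latent-model rate estimate and its
likelihood-optimal mixing (TSNA / ONA).

Within each latent bin ``T`` the shared rate estimate ``r_i^T`` is modulated
on the fine ``dt`` grid by the spikes of every other neuron: a step that
falls within one correlogram lag ``tau`` after (ahead of) a reference
spike of neuron ``j`` receives that reference's windowed forward (backward)
CCG value, normalized by the population's summed windowed ECCG.  Rescaling the corrected trace so its bin
mean equals ``r_i^T`` gives the transient SNA (TSNA); the optimized neural
activity (ONA) is the convex mixture ``alpha* TSNA + (1-alpha*) SNA`` whose
weight maximizes the per-bin spike-train objective, with
``alpha = 1/(1+exp(-Q))`` searched over ``Q`` in [-10, 10].

The per-bin objective scores the target's observed spikes against the
per-step firing probability ``P(t) = (alpha TSNA(t) + (1-alpha) r_i^T) dt``
(clipped away from 0 and 1).  The default is the log-Bernoulli likelihood
``sum_t [delta_t log P(t) + (1-delta_t) log(1-P(t))]``, which is concave in
``alpha`` and yields interior evidence-weighted mixtures; the additive
score ``sum_t [delta_t P(t) + (1-delta_t)(1-P(t))]`` is available as
``objective="sum"``.  Because the TSNA normalization fixes the bin mean,
the additive score is exactly linear in ``alpha`` (clipping supplies the
only breakpoints): its optimum is always an interval endpoint, every bin
without a target spike is exactly flat, and the maximizer therefore
enumerates breakpoints and endpoints exactly instead of relying on a
smooth optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlogram import session_windowed_ccgs
from .edlds import SNAEstimate
from .io import STEPS_PER_BIN, SpikeTrainSet

EPS_P = 1e-6
Q_BOUNDS = (-10.0, 10.0)
DEFAULT_OBJECTIVE = "bernoulli"

# flag bits
FLAG_NO_REFERENCE = 1  # zero ECCG denominator: TSNA fell back to SNA
FLAG_ZERO_MEAN = 2  # corrected trace averaged to zero: TSNA fell back to SNA
FLAG_FLAT = 4  # flat objective: tie-broken at Q = 0
FLAG_CLIPPED = 8  # probability clipping active at the optimum


def _sigmoid(q: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(q, dtype=float)))


def _logit(a: float) -> float:
    return float(np.log(a / (1.0 - a)))


@dataclass
class ONAResult:
    """Fine-resolution TSNA/ONA traces and per-bin mixture summaries."""

    tsna: np.ndarray  # (n_trials, n_neurons, n_bins, steps)
    ona: np.ndarray  # (n_trials, n_neurons, n_bins, steps)
    sna_rates: np.ndarray  # (n_trials, n_neurons, n_bins)
    alpha: np.ndarray  # (n_trials, n_neurons, n_bins)
    q: np.ndarray
    loglik: np.ndarray
    flags: np.ndarray  # uint8 bitmask per (trial, neuron, bin)
    dt: float
    objective: str = DEFAULT_OBJECTIVE

    @property
    def n_trials(self) -> int:
        return self.tsna.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.tsna.shape[1]

    @property
    def n_bins(self) -> int:
        return self.tsna.shape[2]

    def trace(self, which: str, m: int, i: int) -> np.ndarray:
        """Full-trial fine-grid trace (n_bins * steps,) for one neuron."""
        arr = {"tsna": self.tsna, "ona": self.ona}[which]
        return arr[m, i].reshape(-1)


def corrected_rate(
    r_bin: float,
    ccg_plus: np.ndarray,
    ccg_minus: np.ndarray,
    eccg_plus: np.ndarray,
    eccg_minus: np.ndarray,
    delta_plus: np.ndarray,
    delta_minus: np.ndarray,
) -> float:
    """Corrected rate at one fine step for one target neuron.

    ``ccg_plus[j]``/``eccg_plus[j]`` are the windowed correlogram values of
    reference ``j`` at lag ``+tau`` (``*_minus`` at ``-tau``); ``delta_plus[j]``
    is 1 when the step lies inside the forward lag window of a reference
    spike (reference fired within ``(t-tau, t]``), ``delta_minus[j]`` when it
    lies inside the backward window (reference fires within ``(t, t+tau]``),
    so each lag's CCG weight acts on the steps that lag actually describes.
    Uses the normalized form in which each reference's contribution is its
    CCG weighted by the population ECCG sum.
    """
    d_plus = float(np.sum(eccg_plus))
    d_minus = float(np.sum(eccg_minus))
    total = 0.0
    if d_plus > 0:
        total += float(np.sum(np.asarray(delta_plus, float) * ccg_plus)) / d_plus
    if d_minus > 0:
        total += float(np.sum(np.asarray(delta_minus, float) * ccg_minus)) / d_minus
    return total * r_bin


def tsna(corrected_trace: np.ndarray, r_bin: float) -> tuple[np.ndarray, int]:
    """Rescale a corrected-rate trace so its bin mean equals ``r_bin``.

    Returns ``(trace, flag)``; a zero-mean corrected trace falls back to the
    constant SNA value with :data:`FLAG_ZERO_MEAN` set.
    """
    corrected_trace = np.asarray(corrected_trace, dtype=float)
    mean_c = corrected_trace.mean()
    if mean_c <= 0.0:
        return np.full_like(corrected_trace, r_bin), FLAG_ZERO_MEAN
    return corrected_trace * (r_bin / mean_c), 0


def _probabilities(
    tsna_trace: np.ndarray, r_bin: float, alpha: float, dt: float, eps_p: float
) -> np.ndarray:
    rate = alpha * tsna_trace + (1.0 - alpha) * r_bin
    return np.clip(rate * dt, eps_p, 1.0 - eps_p)


def spike_loglik(
    tsna_trace: np.ndarray,
    r_bin: float,
    spike_mask: np.ndarray,
    alpha: float,
    dt: float,
    objective: str = DEFAULT_OBJECTIVE,
    eps_p: float = EPS_P,
) -> float:
    """Per-bin objective of the SNA/TSNA mixture at weight ``alpha``.

    ``objective="bernoulli"`` (the default) scores the log product of
    per-step Bernoulli terms; ``objective="sum"`` scores the additive form
    ``sum_t [delta P + (1-delta)(1-P)]``.
    """
    spike_mask = np.asarray(spike_mask, dtype=bool)
    P = _probabilities(np.asarray(tsna_trace, float), r_bin, alpha, dt, eps_p)
    if objective == "sum":
        return float(np.where(spike_mask, P, 1.0 - P).sum())
    if objective == "bernoulli":
        return float(np.where(spike_mask, np.log(P), np.log1p(-P)).sum())
    raise ValueError(f"unknown objective {objective!r}")


def _objective_batch(
    tsna_bins: np.ndarray,
    r_bins: np.ndarray,
    spike_bins: np.ndarray,
    alphas: np.ndarray,
    dt: float,
    objective: str,
    eps_p: float,
) -> np.ndarray:
    """Objective value per bin at per-bin mixture weights (all vectorized)."""
    rate = alphas[:, None] * tsna_bins + (1.0 - alphas)[:, None] * r_bins[:, None]
    P = np.clip(rate * dt, eps_p, 1.0 - eps_p)
    if objective == "sum":
        return np.where(spike_bins, P, 1.0 - P).sum(axis=1)
    return np.where(spike_bins, np.log(P), np.log1p(-P)).sum(axis=1)


def _candidate_alphas(
    tsna_trace: np.ndarray, r_bin: float, dt: float, eps_p: float
) -> np.ndarray:
    """Interval endpoints plus every clipping breakpoint inside the interval
    (the additive objective is piecewise linear, so its maximum sits there)."""
    a_lo, a_hi = _sigmoid(Q_BOUNDS[0]), _sigmoid(Q_BOUNDS[1])
    u = tsna_trace - r_bin
    cands = [a_lo, a_hi, 0.5]
    nz = u[np.abs(u) > 0]
    for thresh in (eps_p, 1.0 - eps_p):
        a = (thresh / dt - r_bin) / nz
        a = a[(a > a_lo) & (a < a_hi)]
        cands.extend(a.tolist())
    return np.unique(np.asarray(cands))


def _optimize_sum_exact(
    tsna_trace: np.ndarray,
    r_bin: float,
    spike_mask: np.ndarray,
    dt: float,
    eps_p: float,
) -> tuple[float, float]:
    """Exact maximizer of the piecewise-linear additive objective."""
    cands = _candidate_alphas(tsna_trace, r_bin, dt, eps_p)
    vals = np.array(
        [
            spike_loglik(tsna_trace, r_bin, spike_mask, a, dt, "sum", eps_p)
            for a in cands
        ]
    )
    k = int(np.argmax(vals))
    ties = np.where(vals >= vals[k] - 1e-12)[0]
    k = ties[np.argmin(np.abs(cands[ties] - 0.5))]
    return float(cands[k]), float(vals[k])


def _optimize_batch(
    tsna_bins: np.ndarray,
    r_bins: np.ndarray,
    spike_bins: np.ndarray,
    dt: float,
    objective: str,
    eps_p: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized mixture optimization for a batch of bins.

    Additive objective: exactly linear in alpha wherever clipping is
    inactive, so the fast path selects the endpoint by the sign of the
    slope and only clipping-prone bins take the exact piecewise-linear
    route.  Log-Bernoulli objective: concave and smooth away from rare
    clipping kinks; maximized by a coarse grid on the logit scale followed
    by a vectorized ternary refinement of the bracketing interval.
    """
    B, S = tsna_bins.shape
    a_lo, a_hi = _sigmoid(Q_BOUNDS[0]), _sigmoid(Q_BOUNDS[1])
    alpha = np.full(B, 0.5)
    q = np.zeros(B)
    loglik = np.empty(B)
    flags = np.zeros(B, dtype=np.uint8)

    if objective == "sum":
        u = tsna_bins - r_bins[:, None]
        slope = ((2.0 * spike_bins - 1.0) * u).sum(axis=1) * dt
        p_lo = (r_bins[:, None] + a_lo * u) * dt
        p_hi = (r_bins[:, None] + a_hi * u) * dt
        slow = (
            (p_lo < eps_p) | (p_hi < eps_p) | (p_lo > 1 - eps_p) | (p_hi > 1 - eps_p)
        ).any(axis=1)
        fast = ~slow
        if np.any(fast):
            base = np.where(
                spike_bins[fast], r_bins[fast, None] * dt, 1.0 - r_bins[fast, None] * dt
            ).sum(axis=1)
            g = slope[fast]
            flat = np.abs(g) < 1e-12
            a_star = np.where(g > 0, a_hi, a_lo)
            a_star[flat] = 0.5
            alpha[fast] = a_star
            q[fast] = np.where(flat, 0.0, np.where(g > 0, Q_BOUNDS[1], Q_BOUNDS[0]))
            loglik[fast] = base + a_star * g
            f = flags[fast]
            f[flat] |= FLAG_FLAT
            flags[fast] = f
        for b in np.where(slow)[0]:
            a_s, l_s = _optimize_sum_exact(
                tsna_bins[b], r_bins[b], spike_bins[b], dt, eps_p
            )
            alpha[b], loglik[b] = a_s, l_s
            if abs(a_s - 0.5) < 1e-12:
                flags[b] |= FLAG_FLAT
                q[b] = 0.0
            else:
                q[b] = float(np.clip(_logit(a_s), *Q_BOUNDS))
        return alpha, q, loglik, flags

    # log-Bernoulli: hierarchical search on the logit lattice.  Q is
    # resolved to 0.01 (finer differences change the objective by far less
    # than any quantity downstream consumes); the objective is concave in
    # alpha, so a coarse pass plus a fine pass around the bracketing
    # interval finds the lattice maximum.
    q_grid = np.linspace(Q_BOUNDS[0], Q_BOUNDS[1], 41)  # step 0.5
    grid_vals = np.stack(
        [
            _objective_batch(
                tsna_bins, r_bins, spike_bins, np.full(B, _sigmoid(qv)), dt,
                objective, eps_p,
            )
            for qv in q_grid
        ]
    )  # (41, B)
    best = np.argmax(grid_vals, axis=0)
    spread = grid_vals.max(axis=0) - grid_vals.min(axis=0)
    flat = spread < 1e-12

    lo = q_grid[np.maximum(best - 1, 0)]
    fine_offsets = np.arange(0, 101) * 0.01  # covers [lo, lo + 1.0]
    best_q = q_grid[best].copy()
    best_v = grid_vals[best, np.arange(B)]
    for off in fine_offsets:
        qv = np.minimum(lo + off, Q_BOUNDS[1])
        v = _objective_batch(
            tsna_bins, r_bins, spike_bins, np.asarray(_sigmoid(qv)), dt,
            objective, eps_p,
        )
        better = v > best_v
        best_q = np.where(better, qv, best_q)
        best_v = np.where(better, v, best_v)
    q = best_q
    loglik = best_v
    alpha = np.asarray(_sigmoid(q))
    alpha[flat] = 0.5
    q[flat] = 0.0
    if np.any(flat):
        loglik[flat] = _objective_batch(
            tsna_bins[flat], r_bins[flat], spike_bins[flat],
            np.full(int(flat.sum()), 0.5), dt, objective, eps_p,
        )
    flags[flat] |= FLAG_FLAT
    return alpha, q, loglik, flags


def optimize_ona(
    tsna_trace: np.ndarray,
    r_bin: float,
    spike_mask: np.ndarray,
    dt: float,
    objective: str = DEFAULT_OBJECTIVE,
    eps_p: float = EPS_P,
) -> dict:
    """Maximize the per-bin objective over the mixture weight.

    Returns a dict with ``alpha``, ``q``, ``loglik``, ``flags`` and the
    ``ona`` trace.  Uses the same machinery as the session-level batch path:
    exact breakpoint enumeration for the piecewise-linear additive
    objective, logit-scale grid plus ternary refinement for the concave
    log-Bernoulli likelihood.  A flat objective is tie-broken at ``Q = 0``
    (equal mixture) and flagged.
    """
    tsna_trace = np.asarray(tsna_trace, dtype=float)
    spike_mask = np.asarray(spike_mask, dtype=bool)
    a, qv, lv, fl = _optimize_batch(
        tsna_trace[None, :],
        np.asarray([r_bin], dtype=float),
        spike_mask[None, :],
        dt,
        objective,
        eps_p,
    )
    alpha_star, q_star, l_star, flags = float(a[0]), float(qv[0]), float(lv[0]), int(fl[0])
    rate = alpha_star * tsna_trace + (1.0 - alpha_star) * r_bin
    P_raw = rate * dt
    if np.any(P_raw < eps_p) or np.any(P_raw > 1.0 - eps_p):
        flags |= FLAG_CLIPPED
    return {
        "alpha": alpha_star,
        "q": q_star,
        "loglik": l_star,
        "flags": flags,
        "ona": rate,
    }


def _reference_presence(
    spikes: SpikeTrainSet, m: int, tau: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (n_neurons, n_steps) arrays for every fine step start ``t``:
    ``after[j, u]`` — step lies in the forward lag window of a spike of ``j``
    (``j`` fired in ``(t-tau, t]``); ``before[j, u]`` — step lies in the
    backward window (``j`` fires in ``(t, t+tau]``)."""
    sched = spikes.schedule
    n_steps = sched.n_bins * STEPS_PER_BIN
    t = np.arange(n_steps) * sched.dt
    after = np.zeros((spikes.n_neurons, n_steps), dtype=bool)
    before = np.zeros((spikes.n_neurons, n_steps), dtype=bool)
    for j, s in enumerate(spikes.spikes[m]):
        if s.size == 0:
            continue
        after[j] = (
            np.searchsorted(s, t, side="right")
            - np.searchsorted(s, t - tau, side="right")
        ) > 0
        before[j] = (
            np.searchsorted(s, t + tau, side="right")
            - np.searchsorted(s, t, side="right")
        ) > 0
    return after, before


def _spike_step_mask(spikes: SpikeTrainSet, m: int) -> np.ndarray:
    """Boolean (n_neurons, n_steps): target fires within the step."""
    sched = spikes.schedule
    n_steps = sched.n_bins * STEPS_PER_BIN
    edges = np.arange(n_steps + 1) * sched.dt
    out = np.zeros((spikes.n_neurons, n_steps), dtype=bool)
    for i, s in enumerate(spikes.spikes[m]):
        if s.size:
            out[i] = np.diff(np.searchsorted(s, edges)) > 0
    return out


def compute_ona(
    spikes: SpikeTrainSet,
    sna: SNAEstimate,
    tau: float = 0.025,
    window_bins: int = 20,
    window_trials: int = 20,
    objective: str = DEFAULT_OBJECTIVE,
    eps_p: float = EPS_P,
    windowed: dict | None = None,
) -> ONAResult:
    """TSNA/ONA for every (trial, neuron, bin) of a session.

    ``windowed`` may pass a precomputed :func:`session_windowed_ccgs` result
    to avoid recomputation across pipeline stages.
    """
    sched = spikes.schedule
    M, N, n_bins = spikes.n_trials, spikes.n_neurons, sched.n_bins
    S = STEPS_PER_BIN
    dt = sched.dt
    if sna.rates.shape != (M, N, n_bins):
        raise ValueError("SNA shape does not match the session")

    W = windowed or session_windowed_ccgs(
        spikes, sna, tau=tau, window_bins=window_bins, window_trials=window_trials
    )
    ccg_w, eccg_w = W["ccg"], W["eccg"]  # (2, M, ref, target, n_bins)

    tsna_all = np.empty((M, N, n_bins, S))
    ona_all = np.empty((M, N, n_bins, S))
    alpha = np.empty((M, N, n_bins))
    qarr = np.empty((M, N, n_bins))
    lik = np.empty((M, N, n_bins))
    flags = np.zeros((M, N, n_bins), dtype=np.uint8)

    for m in range(M):
        after, before = _reference_presence(spikes, m, tau)
        spike_mask = _spike_step_mask(spikes, m)
        r_m = sna.rates[m]  # (N, n_bins)
        for T in range(n_bins):
            sl = slice(T * S, (T + 1) * S)
            cp = ccg_w[0, m, :, :, T]
            cm = ccg_w[1, m, :, :, T]
            ep = eccg_w[0, m, :, :, T]
            em = eccg_w[1, m, :, :, T]
            d_plus = ep.sum(axis=0)  # per target
            d_minus = em.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                wp = np.where(d_plus[None, :] > 0, cp / d_plus[None, :], 0.0)
                wm = np.where(d_minus[None, :] > 0, cm / d_minus[None, :], 0.0)
            # corrected trace: (target, step); forward weights act after a
            # reference spike, backward weights ahead of one
            corr = (after[:, sl].T @ wp + before[:, sl].T @ wm).T
            corr *= r_m[:, T][:, None]
            no_ref = (d_plus + d_minus) <= 0.0
            mean_c = corr.mean(axis=1)
            zero_mean = (mean_c <= 0.0) & ~no_ref
            ok = ~(no_ref | zero_mean)
            ts = np.empty_like(corr)
            ts[ok] = corr[ok] * (r_m[ok, T] / mean_c[ok])[:, None]
            ts[~ok] = r_m[~ok, T][:, None]
            flags[m, no_ref, T] |= FLAG_NO_REFERENCE
            flags[m, zero_mean, T] |= FLAG_ZERO_MEAN
            tsna_all[m, :, T, :] = ts

        # optimize all bins of this trial in one batch
        ts_flat = tsna_all[m].reshape(N * n_bins, S)
        r_flat = r_m.reshape(-1)
        sp_flat = spike_mask.reshape(N, n_bins, S).reshape(N * n_bins, S)
        a, qv, lv, fl = _optimize_batch(ts_flat, r_flat, sp_flat, dt, objective, eps_p)
        alpha[m] = a.reshape(N, n_bins)
        qarr[m] = qv.reshape(N, n_bins)
        lik[m] = lv.reshape(N, n_bins)
        flags[m] |= fl.reshape(N, n_bins)
        ona_all[m] = (
            alpha[m][:, :, None] * tsna_all[m]
            + (1.0 - alpha[m][:, :, None]) * r_m[:, :, None]
        )

    return ONAResult(
        tsna=tsna_all,
        ona=ona_all,
        sna_rates=sna.rates.copy(),
        alpha=alpha,
        q=qarr,
        loglik=lik,
        flags=flags,
        dt=dt,
        objective=objective,
    )
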