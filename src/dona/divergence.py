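"""Kullback-Leibler interaction measures.

DONA (ensemble): within one latent bin, compare the per-step firing
probabilities implied by the optimized rate (ONA) against the constant
shared-rate (SNA) probability, ``sum_t P_ona(t) log(P_ona(t)/P_sna)`` in
nats.  It vanishes when the optimization leaves the shared estimate
untouched and grows with the transient influence of the rest of the
population on the target neuron.

PDONA (directed pairwise): for a reference neuron ``j`` and target ``i``,
take the ``n`` consecutive reference spikes closest to the bin, form the
distribution over the ``2^n`` patterns of the target firing / not firing in
the step right after each reference spike under ONA-derived and SNA-derived
rates, and take the KL divergence between the two pattern distributions.
Because the per-spike Bernoulli terms are independent, the pattern KL
equals the sum of per-spike Bernoulli KLs; the session-level pipeline uses
that factorized form while :func:`pdona` evaluates the literal pattern
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .io import STEPS_PER_BIN, SpikeTrainSet
from .ona import EPS_P, ONAResult

# exclusion reason codes
EXCL_NONE = 0
EXCL_SELF = 1  # autointeraction (i == j), never evaluated
EXCL_FEW_SPIKES = 2  # reference fired < min_ref_spikes in the trial
EXCL_SHORT = 3  # fewer than n reference spikes in the trial


@dataclass
class DivergenceSeries:
    """DONA per (trial, neuron, bin) and PDONA per ordered pair, in nats."""

    dona: np.ndarray  # (n_trials, n_neurons, n_bins)
    pdona: np.ndarray  # (n_trials, n_ref, n_target, n_bins), float32
    excluded: np.ndarray  # (n_trials, n_ref, n_target) uint8 reason codes
    n: int
    min_ref_spikes: int

    def pdona_trial_mean(self) -> np.ndarray:
        """Trial-averaged PDONA per (ref, target, bin), NaN where every trial
        of a pair is excluded."""
        vals = self.pdona.astype(float).copy()
        vals[np.broadcast_to(self.excluded[:, :, :, None] != EXCL_NONE, vals.shape)] = np.nan
        import warnings

        with warnings.catch_warnings():
            # the diagonal (self-pairs) is all-NaN by construction
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(vals, axis=0)


def dona(
    ona_trace: np.ndarray, r_bin: float, dt: float, eps_p: float = EPS_P
) -> float:
    """Per-bin KL divergence (nats) between ONA- and SNA-implied per-step
    firing probabilities."""
    p_ona = np.clip(np.asarray(ona_trace, float) * dt, eps_p, 1.0 - eps_p)
    p_sna = float(np.clip(r_bin * dt, eps_p, 1.0 - eps_p))
    return float(np.sum(p_ona * (np.log(p_ona) - np.log(p_sna))))


def compute_dona(ona: ONAResult, eps_p: float = EPS_P) -> np.ndarray:
    """Vectorized :func:`dona` over every (trial, neuron, bin)."""
    out = np.empty(ona.alpha.shape)
    for m in range(ona.n_trials):
        p_o = np.clip(ona.ona[m] * ona.dt, eps_p, 1.0 - eps_p)
        p_s = np.clip(ona.sna_rates[m] * ona.dt, eps_p, 1.0 - eps_p)
        out[m] = np.sum(p_o * (np.log(p_o) - np.log(p_s[:, :, None])), axis=-1)
    return out


def all_patterns(n: int) -> np.ndarray:
    """All 2^n binary firing patterns, shape (2^n, n)."""
    return np.array(list(product((0, 1), repeat=n)), dtype=float)


def pattern_probability(
    rates: np.ndarray, dt: float, eps_p: float = EPS_P
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized distribution over firing patterns after ``n`` reference spikes.

    ``rates[k]`` is the target's rate at the step following the k-th
    reference spike; the per-spike firing probability is ``rates[k] * dt``
    (clipped).  Returns ``(patterns, probs)`` with ``probs`` summing to 1.
    """
    p = np.clip(np.asarray(rates, float) * dt, eps_p, 1.0 - eps_p)
    pats = all_patterns(len(p))
    terms = np.prod(pats * p + (1.0 - pats) * (1.0 - p), axis=1)
    return pats, terms / terms.sum()


def _bernoulli_kl(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return p * (np.log(p) - np.log(q)) + (1.0 - p) * (np.log1p(-p) - np.log1p(-q))


def pdona(
    ona_rates: np.ndarray,
    sna_rates: np.ndarray,
    dt: float,
    eps_p: float = EPS_P,
) -> float:
    """Pairwise KL divergence (nats) between the ONA- and SNA-implied pattern
    distributions at the same reference spike times.

    ``ona_rates``/``sna_rates`` hold the target's rate at the step after each
    of the ``n`` selected reference spikes.  Evaluated by explicit
    enumeration of all ``2^n`` patterns.
    """
    pats, p_ona = pattern_probability(ona_rates, dt, eps_p)
    _, p_sna = pattern_probability(sna_rates, dt, eps_p)
    return float(np.sum(p_ona * (np.log(p_ona) - np.log(p_sna))))


def select_reference_window(
    ref_times: np.ndarray, n: int, bin_center: float
) -> slice | None:
    """The ``n`` consecutive reference spikes whose mean time is nearest to
    the bin center; ties break toward earlier spikes."""
    nj = len(ref_times)
    if nj < n:
        return None
    means = np.convolve(ref_times, np.ones(n) / n, mode="valid")  # sorted
    idx = int(np.searchsorted(means, bin_center))
    best, best_d = None, np.inf
    for cand in (idx - 1, idx):
        if 0 <= cand < len(means):
            d = abs(means[cand] - bin_center)
            if d < best_d:  # strict: ties keep the earlier window
                best, best_d = cand, d
    return slice(best, best + n)


def compute_pdona(
    spikes: SpikeTrainSet,
    ona: ONAResult,
    n: int = 6,
    min_ref_spikes: int = 10,
    eps_p: float = EPS_P,
) -> tuple[np.ndarray, np.ndarray]:
    """PDONA for every ordered pair and (trial, bin).

    Uses the factorized per-spike Bernoulli form (identical to the pattern
    enumeration for probabilities in (0, 1)).  Returns ``(values, excluded)``
    with values float32 of shape (n_trials, n_ref, n_target, n_bins) and
    exclusion reason codes of shape (n_trials, n_ref, n_target).
    """
    sched = spikes.schedule
    M, N, n_bins = spikes.n_trials, spikes.n_neurons, sched.n_bins
    S = STEPS_PER_BIN
    dt = sched.dt
    n_steps = n_bins * S
    centers = (np.arange(n_bins) + 0.5) * sched.s_bin

    values = np.zeros((M, N, N, n_bins), dtype=np.float32)
    excluded = np.zeros((M, N, N), dtype=np.uint8)
    excluded[:, np.arange(N), np.arange(N)] = EXCL_SELF

    for m in range(M):
        ona_flat = ona.ona[m].reshape(N, n_steps)
        sna_bins = ona.sna_rates[m]  # (N, n_bins)
        for j in range(N):
            t_ref = spikes.spikes[m][j]
            nj = t_ref.size
            mask = np.arange(N) != j
            if nj < min_ref_spikes:
                excluded[m, j, mask] = np.maximum(
                    excluded[m, j, mask], EXCL_FEW_SPIKES
                )
            if nj < n:
                excluded[m, j, mask] = np.maximum(excluded[m, j, mask], EXCL_SHORT)
            if nj < max(n, min_ref_spikes):
                continue
            # per-bin selected windows of n consecutive reference spikes
            means = np.convolve(t_ref, np.ones(n) / n, mode="valid")
            idx = np.searchsorted(means, centers)
            lo = np.clip(idx - 1, 0, len(means) - 1)
            hi = np.clip(idx, 0, len(means) - 1)
            starts = np.where(
                np.abs(means[hi] - centers) < np.abs(means[lo] - centers), hi, lo
            )
            sel_times = t_ref[starts[:, None] + np.arange(n)[None, :]]  # (n_bins, n)
            step_after = (sel_times / dt).astype(int) + 1
            in_range = step_after < n_steps
            step_clamped = np.minimum(step_after, n_steps - 1)
            bin_of_spike = np.minimum(
                (sel_times / sched.s_bin).astype(int), n_bins - 1
            )
            bin_of_step = step_clamped // S
            for i in range(N):
                if i == j:
                    continue
                r_ona = ona_flat[i, step_clamped]
                r_sna = sna_bins[i, bin_of_step]
                # out-of-support read-off: fall back to the containing bin's SNA
                fallback = sna_bins[i, bin_of_spike]
                r_ona = np.where(in_range, r_ona, fallback)
                r_sna = np.where(in_range, r_sna, fallback)
                p_o = np.clip(r_ona * dt, eps_p, 1.0 - eps_p)
                p_s = np.clip(r_sna * dt, eps_p, 1.0 - eps_p)
                values[m, j, i] = _bernoulli_kl(p_o, p_s).sum(axis=1)
    return values, excluded


def compute_divergences(
    spikes: SpikeTrainSet,
    ona: ONAResult,
    n: int = 6,
    min_ref_spikes: int = 10,
    eps_p: float = EPS_P,
) -> DivergenceSeries:
    """DONA and PDONA for a whole session."""
    d = compute_dona(ona, eps_p=eps_p)
    p, excl = compute_pdona(
        spikes, ona, n=n, min_ref_spikes=min_ref_spikes, eps_p=eps_p
    )
    return DivergenceSeries(
        dona=d, pdona=p, excluded=excl, n=n, min_ref_spikes=min_ref_spikes
    )
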