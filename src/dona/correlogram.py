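"""Spike-train and rate-estimate cross-correlograms.

For an ordered pair (reference ``j``, target ``i``) the spike-based
cross-correlogram (CCG) at signed lag ``k`` is the trial average of the
per-reference-spike rate of target spikes inside the k-th lag window of
width ``tau``; the expected CCG (ECCG) replaces the target spike count by
the time average of the target's model rate estimate over the same window;
their difference (DCCG) isolates transient pairwise effects from the slow
shared dynamics that both constructions contain.

Lag conventions (stated once, used everywhere):

* positive lag ``k``: window ``[t_ref + (k-1) tau, t_ref + k tau)`` — a
  target spike exactly at the reference time belongs to ``k = +1``;
* negative lag ``k``: mirrored window ``[t_ref + k tau, t_ref + (k+1) tau)``;
* autocorrelations (``i == j``) are excluded;
* per-trial terms average per-reference-spike contributions; the trial
  average runs over every trial in scope, a trial without reference spikes
  contributing zero; a pair with no reference spikes anywhere in scope is
  flagged undefined rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edlds import SNAEstimate
from .io import SpikeTrainSet


def lag_indices(n_lags: int) -> np.ndarray:
    """Signed lag indices ``[-K..-1, +1..+K]`` (no zero lag)."""
    return np.concatenate([np.arange(-n_lags, 0), np.arange(1, n_lags + 1)])


@dataclass(frozen=True)
class Scope:
    """Estimation scope: which trials, and (optionally) which time range the
    *reference* spikes must fall in.  ``None`` means unrestricted."""

    trials: tuple[int, ...] | None = None
    time_range: tuple[float, float] | None = None
    description: str = "global"

    def trial_list(self, n_trials: int) -> list[int]:
        if self.trials is None:
            return list(range(n_trials))
        return list(self.trials)


@dataclass
class CCGSet:
    """Correlogram values for all ordered pairs at all signed lags.

    ``values[j, i, k]`` in spikes/s (CCG/DCCG) or spikes/s (ECCG, a rate),
    with lags ordered as :func:`lag_indices`.  ``undefined[j, i]`` marks
    pairs with no usable reference spikes in scope.
    """

    values: np.ndarray  # (n_ref, n_target, 2*n_lags)
    lags: np.ndarray  # signed lag indices
    tau: float
    kind: str  # "ccg" | "eccg" | "dccg"
    scope: Scope = field(default_factory=Scope)
    undefined: np.ndarray | None = None
    ref_spike_counts: np.ndarray | None = None  # reference spikes in scope, per ref

    def __post_init__(self) -> None:
        if self.undefined is None:
            self.undefined = np.zeros(self.values.shape[:2], dtype=bool)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    def lag_seconds(self) -> np.ndarray:
        return self.lags * self.tau

    def to_table(self) -> pd.DataFrame:
        j, i, k = np.meshgrid(
            np.arange(self.values.shape[0]),
            np.arange(self.values.shape[1]),
            np.arange(len(self.lags)),
            indexing="ij",
        )
        df = pd.DataFrame(
            {
                "ref": j.ravel(),
                "target": i.ravel(),
                "lag_index": self.lags[k.ravel()],
                "lag_s": self.lags[k.ravel()] * self.tau,
                "value": self.values.ravel(),
                "undefined": np.broadcast_to(
                    self.undefined[:, :, None], self.values.shape
                ).ravel(),
            }
        )
        df["kind"] = self.kind
        df["scope"] = self.scope.description
        return df[df["ref"] != df["target"]].reset_index(drop=True)


def _lag_edges(t_ref: np.ndarray, k: int, tau: float) -> tuple[np.ndarray, np.ndarray]:
    if k > 0:
        return t_ref + (k - 1) * tau, t_ref + k * tau
    return t_ref + k * tau, t_ref + (k + 1) * tau


def compute_ccg(
    spikes: SpikeTrainSet,
    tau: float = 0.025,
    n_lags: int = 10,
    scope: Scope | None = None,
) -> CCGSet:
    """Spike-based cross-correlogram for all ordered pairs.

    Only within-trial spike pairs are counted.  Reference spikes are those in
    the scope's trial set and time range; target spikes anywhere in the trial
    enter the lag windows.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    scope = scope or Scope()
    lags = lag_indices(n_lags)
    trials = scope.trial_list(spikes.n_trials)
    if not trials:
        raise ValueError("scope selects no trials")
    N = spikes.n_neurons
    M = len(trials)
    terms = np.zeros((M, N, N, len(lags)))
    ref_counts = np.zeros(N, dtype=int)

    for mi, m in enumerate(trials):
        trial = spikes.spikes[m]
        for j in range(N):
            t_ref = trial[j]
            if scope.time_range is not None:
                lo, hi = scope.time_range
                t_ref = t_ref[(t_ref >= lo) & (t_ref < hi)]
            nj = t_ref.size
            ref_counts[j] += nj
            if nj == 0:
                continue
            for i in range(N):
                if i == j:
                    continue
                tgt = trial[i]
                if tgt.size == 0:
                    continue
                for kk, k in enumerate(lags):
                    a, b = _lag_edges(t_ref, int(k), tau)
                    cnt = np.searchsorted(tgt, b, side="left") - np.searchsorted(
                        tgt, a, side="left"
                    )
                    terms[mi, j, i, kk] = cnt.sum() / nj
    values = terms.sum(axis=0) / M / tau
    undefined = np.broadcast_to((ref_counts == 0)[:, None], (N, N)).copy()
    return CCGSet(
        values=values,
        lags=lags,
        tau=tau,
        kind="ccg",
        scope=scope,
        undefined=undefined,
        ref_spike_counts=ref_counts,
    )


def _rate_integral_edges(sna: SNAEstimate, m: int, i: int) -> np.ndarray:
    """Cumulative integral of the piecewise-constant rate at bin edges."""
    r = sna.rates[m, i]
    return np.concatenate([[0.0], np.cumsum(r * sna.schedule.s_bin)])


def compute_eccg(
    sna: SNAEstimate,
    spikes: SpikeTrainSet,
    tau: float = 0.025,
    n_lags: int = 10,
    scope: Scope | None = None,
) -> CCGSet:
    """Rate-estimate cross-correlogram (ECCG).

    The per-reference-spike contribution is the time average of the target's
    piecewise-constant rate over the lag window, length-weighted across bin
    edges; windows are truncated at the trial boundaries and reference spikes
    whose window lies fully outside the trial are excluded from that lag's
    per-trial average.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    scope = scope or Scope()
    lags = lag_indices(n_lags)
    trials = scope.trial_list(spikes.n_trials)
    if not trials:
        raise ValueError("scope selects no trials")
    N = spikes.n_neurons
    if sna.n_neurons != N or sna.n_trials != spikes.n_trials:
        raise ValueError("SNA does not cover the session")
    M = len(trials)
    duration = spikes.schedule.trial_duration
    edges = spikes.schedule.bin_edges()
    terms = np.zeros((M, N, N, len(lags)))
    ref_counts = np.zeros(N, dtype=int)

    for mi, m in enumerate(trials):
        trial = spikes.spikes[m]
        cum_by_target: dict[int, np.ndarray] = {}
        for j in range(N):
            t_ref = trial[j]
            if scope.time_range is not None:
                lo, hi = scope.time_range
                t_ref = t_ref[(t_ref >= lo) & (t_ref < hi)]
            nj = t_ref.size
            ref_counts[j] += nj
            if nj == 0:
                continue
            for i in range(N):
                if i == j:
                    continue
                if i not in cum_by_target:
                    cum_by_target[i] = _rate_integral_edges(sna, m, i)
                cum = cum_by_target[i]
                for kk, k in enumerate(lags):
                    a, b = _lag_edges(t_ref, int(k), tau)
                    a = np.clip(a, 0.0, duration)
                    b = np.clip(b, 0.0, duration)
                    covered = b > a
                    if not np.any(covered):
                        continue
                    Ia = np.interp(a[covered], edges, cum)
                    Ib = np.interp(b[covered], edges, cum)
                    mean_r = (Ib - Ia) / (b[covered] - a[covered])
                    terms[mi, j, i, kk] = mean_r.sum() / covered.sum()
    values = terms.sum(axis=0) / M
    undefined = np.broadcast_to((ref_counts == 0)[:, None], (N, N)).copy()
    return CCGSet(
        values=values,
        lags=lags,
        tau=tau,
        kind="eccg",
        scope=scope,
        undefined=undefined,
        ref_spike_counts=ref_counts,
    )


def compute_dccg(ccg: CCGSet, eccg: CCGSet) -> CCGSet:
    """Elementwise CCG - ECCG; undefined flags propagate by union."""
    if ccg.tau != eccg.tau or not np.array_equal(ccg.lags, eccg.lags):
        raise ValueError("lag structures differ")
    if ccg.scope != eccg.scope:
        raise ValueError("estimation scopes differ")
    if ccg.values.shape != eccg.values.shape:
        raise ValueError("pair sets differ")
    return CCGSet(
        values=ccg.values - eccg.values,
        lags=ccg.lags.copy(),
        tau=ccg.tau,
        kind="dccg",
        scope=ccg.scope,
        undefined=ccg.undefined | eccg.undefined,
        ref_spike_counts=ccg.ref_spike_counts,
    )


def _centered_window(center: int, width: int, total: int) -> tuple[int, int]:
    """Half-open [lo, hi) of length min(width, total), shifted inward at edges."""
    width = min(width, total)
    lo = center - width // 2
    lo = max(0, min(lo, total - width))
    return lo, lo + width


def windowed_ccgs(
    spikes: SpikeTrainSet,
    sna: SNAEstimate,
    tau: float,
    T: int,
    m: int,
    window_bins: int = 20,
    window_trials: int = 20,
    n_lags: int = 1,
) -> tuple[CCGSet, CCGSet]:
    """CCG and ECCG localized to a centered window of bins around ``T`` and
    trials around ``m`` (truncated at session edges)."""
    if window_bins < 1 or window_trials < 1:
        raise ValueError("window sizes must be >= 1")
    sched = spikes.schedule
    t_lo, t_hi = _centered_window(T, window_bins, sched.n_bins)
    m_lo, m_hi = _centered_window(m, window_trials, spikes.n_trials)
    scope = Scope(
        trials=tuple(range(m_lo, m_hi)),
        time_range=(t_lo * sched.s_bin, t_hi * sched.s_bin),
        description=f"window(T={T},m={m},bins={window_bins},trials={window_trials})",
    )
    return (
        compute_ccg(spikes, tau, n_lags, scope),
        compute_eccg(sna, spikes, tau, n_lags, scope),
    )


def session_windowed_ccgs(
    spikes: SpikeTrainSet,
    sna: SNAEstimate,
    tau: float = 0.025,
    window_bins: int = 20,
    window_trials: int = 20,
) -> dict[str, np.ndarray]:
    """Windowed lag ±1 CCG/ECCG for *every* center (trial, bin) at once.

    Returns a dict with arrays of shape (2, n_trials, n_ref, n_target, n_bins)
    for keys ``"ccg"`` and ``"eccg"`` (lag axis ordered [+1, -1]) and an
    ``"undefined"`` mask of shape (n_trials, n_ref, n_bins).  Equivalent to
    calling :func:`windowed_ccgs` at every center, but computed with
    cumulative sums over bins and trials.
    """
    sched = spikes.schedule
    M, N, n_bins = spikes.n_trials, spikes.n_neurons, sched.n_bins
    duration = sched.trial_duration
    edges = sched.bin_edges()

    # per-(trial, ref, bin) sufficient statistics
    n_ref = np.zeros((M, N, n_bins), dtype=np.int64)
    n_cov = np.zeros((2, M, N, n_bins), dtype=np.int64)  # ECCG coverage per lag
    s_cnt = np.zeros((2, M, N, N, n_bins))
    s_rate = np.zeros((2, M, N, N, n_bins))

    for m in range(M):
        trial = spikes.spikes[m]
        cums = [_rate_integral_edges(sna, m, i) for i in range(N)]
        for j in range(N):
            t_ref = trial[j]
            if t_ref.size == 0:
                continue
            bins_of = np.minimum(
                (t_ref / sched.s_bin).astype(int), n_bins - 1
            )
            np.add.at(n_ref[m, j], bins_of, 1)
            for li, k in enumerate((1, -1)):
                a, b = _lag_edges(t_ref, k, tau)
                ac = np.clip(a, 0.0, duration)
                bc = np.clip(b, 0.0, duration)
                covered = bc > ac
                np.add.at(n_cov[li, m, j], bins_of[covered], 1)
                for i in range(N):
                    if i == j:
                        continue
                    tgt = trial[i]
                    if tgt.size:
                        cnt = np.searchsorted(tgt, b, side="left") - np.searchsorted(
                            tgt, a, side="left"
                        )
                        np.add.at(s_cnt[li, m, j, i], bins_of, cnt)
                    if np.any(covered):
                        Ia = np.interp(ac[covered], edges, cums[i])
                        Ib = np.interp(bc[covered], edges, cums[i])
                        mean_r = (Ib - Ia) / (bc[covered] - ac[covered])
                        np.add.at(s_rate[li, m, j, i], bins_of[covered], mean_r)

    # bin-window sums via padded cumulative sums
    def win_bins(arr: np.ndarray) -> np.ndarray:
        cs = np.concatenate(
            [np.zeros(arr.shape[:-1] + (1,), dtype=arr.dtype), np.cumsum(arr, axis=-1)],
            axis=-1,
        )
        lohi = np.array([_centered_window(T, window_bins, n_bins) for T in range(n_bins)])
        return cs[..., lohi[:, 1]] - cs[..., lohi[:, 0]]

    Wn = win_bins(n_ref)  # (M, N, n_bins)
    Wc = win_bins(n_cov)  # (2, M, N, n_bins)
    Ws = win_bins(s_cnt)  # (2, M, N, N, n_bins)
    Wr = win_bins(s_rate)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_c = np.where(Wn[None, :, :, None, :] > 0, Ws / Wn[None, :, :, None, :], 0.0)
        ratio_r = np.where(Wc[:, :, :, None, :] > 0, Wr / Wc[:, :, :, None, :], 0.0)

    # trial-window averages via cumulative sums over the trial axis
    def win_trials(arr: np.ndarray, axis: int) -> np.ndarray:
        cs = np.cumsum(arr, axis=axis)
        pad_shape = list(arr.shape)
        pad_shape[axis] = 1
        cs = np.concatenate([np.zeros(pad_shape, dtype=cs.dtype), cs], axis=axis)
        lohi = np.array([_centered_window(m, window_trials, M) for m in range(M)])
        hi = np.take(cs, lohi[:, 1], axis=axis)
        lo = np.take(cs, lohi[:, 0], axis=axis)
        return hi - lo, lohi[:, 1] - lohi[:, 0]

    sum_c, m_width = win_trials(ratio_c, axis=1)
    sum_r, _ = win_trials(ratio_r, axis=1)
    sum_n, _ = win_trials(Wn.astype(float), axis=0)

    width = m_width[None, :, None, None, None].astype(float)
    ccg = sum_c / width / tau
    eccg = sum_r / width
    undefined = sum_n[:, :, :] == 0  # (M(center), N(ref), n_bins)
    return {"ccg": ccg, "eccg": eccg, "undefined": undefined, "tau": tau}
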