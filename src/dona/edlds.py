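"""Epoch-switched linear dynamical systems model of shared population activity.

The model is a discrete-time linear-Gaussian state space on the latent-model
bin grid whose transition and projection matrices switch at the cued epoch
boundaries while the latent state itself stays continuous across switches::

    x_T = A(s_T) x_{T-1} + w_T,        w_T ~ N(0, Q)
    y_T = C(s_T) x_T + d   + v_T,      v_T ~ N(0, diag(R))

with ``s_T`` the epoch (sample/delay/response) of bin ``T``.  Spike counts
enter as per-bin rates ``y = counts / S_bin`` (additive-Gaussian on the
natural rate scale, so the smoothed rate estimate is unbiased even at the
sub-spike-per-bin counts typical of cortical data; a variance-stabilizing
square-root alternative is available).  The shared-neural-activity (SNA)
rate estimate is the smoothed projection rectified at a small positive
floor so downstream probability models stay well defined.

Fitting is plain EM: an exact Kalman filter/smoother E-step (covariance
recursions are shared across trials because all trials share the schedule,
so only the means are per-trial) and closed-form M-step updates, giving a
non-decreasing marginal log-likelihood.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from sklearn.decomposition import FactorAnalysis

from .io import BinnedCounts, EpochSchedule

#: rate floor applied to SNA estimates, spikes/s
RATE_FLOOR = 0.1


@dataclass
class FitConfig:
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    ridge: float = 1e-9
    r_floor: float = 1e-8
    rate_floor: float = RATE_FLOOR


@dataclass
class LatentParams:
    """Fitted parameters of the epoch-switched state-space model."""

    A: np.ndarray  # (3, n_latent, n_latent)
    C: np.ndarray  # (3, n_neurons, n_latent)
    d: np.ndarray  # (n_neurons,)
    Q: np.ndarray  # (n_latent, n_latent)
    R: np.ndarray  # (n_neurons,) diagonal observation variances
    mu0: np.ndarray  # (n_latent,)
    P0: np.ndarray  # (n_latent, n_latent)
    schedule: EpochSchedule
    transform: str = "rate"
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    warnings: list[str] = field(default_factory=list)
    rate_floor: float = RATE_FLOOR

    @property
    def n_latent(self) -> int:
        return self.A.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.C.shape[1]

    @property
    def r0(self) -> np.ndarray:
        """Baseline rate vector in spikes/s (back-transformed offset)."""
        if self.transform == "sqrt-rate":
            return np.clip(self.d, 0.0, None) ** 2
        return self.d.copy()

    def continuous_dynamics(self) -> np.ndarray:
        """Per-epoch continuous-time generator, ``logm(A)/S_bin`` (display only)."""
        return np.stack(
            [np.real(sla.logm(self.A[e])) / self.schedule.s_bin for e in range(3)]
        )

    def params_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.A, self.C, self.d, self.Q, self.R, self.mu0, self.P0):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]

    def save(self, path) -> None:
        """Serialize all parameter arrays to one HDF5 container."""
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("A", "C", "d", "Q", "R", "mu0", "P0", "loglik_trace"):
                f.create_dataset(name, data=np.asarray(getattr(self, name)))
            f.attrs["transform"] = self.transform
            f.attrs["converged"] = self.converged
            f.attrs["rate_floor"] = self.rate_floor
            f.attrs["s_bin"] = self.schedule.s_bin
            f.attrs["bins_per_epoch"] = list(self.schedule.bins_per_epoch)
            f.attrs["warnings"] = "\n".join(self.warnings)


def load_params(path) -> LatentParams:
    """Read a parameter container written by :meth:`LatentParams.save`."""
    import h5py

    with h5py.File(path, "r") as f:
        sched = EpochSchedule(
            s_bin=float(f.attrs["s_bin"]),
            bins_per_epoch=tuple(int(b) for b in f.attrs["bins_per_epoch"]),
        )
        return LatentParams(
            A=f["A"][()],
            C=f["C"][()],
            d=f["d"][()],
            Q=f["Q"][()],
            R=f["R"][()],
            mu0=f["mu0"][()],
            P0=f["P0"][()],
            schedule=sched,
            transform=str(f.attrs["transform"]),
            loglik_trace=f["loglik_trace"][()],
            converged=bool(f.attrs["converged"]),
            warnings=[w for w in str(f.attrs["warnings"]).split("\n") if w],
            rate_floor=float(f.attrs["rate_floor"]),
        )


@dataclass
class SNAEstimate:
    """Per-trial shared-neural-activity rates, piecewise constant per bin."""

    rates: np.ndarray  # (n_trials, n_neurons, n_bins), spikes/s
    schedule: EpochSchedule
    provenance: str = ""
    rate_floor: float = RATE_FLOOR

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[1]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[2]


def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def _psd_clip(M: np.ndarray, warnings: list[str], what: str) -> np.ndarray:
    """Clip negative eigenvalues only when they occur, so the exact M-step
    (and hence EM monotonicity) is untouched in the regular case."""
    w = np.linalg.eigvalsh(M)
    if w.min() >= 0.0:
        return M
    warnings.append(f"{what} clipped to positive semi-definite (min eig {w.min():.2e})")
    vals, vecs = np.linalg.eigh(M)
    return _sym((vecs * np.clip(vals, 1e-12, None)) @ vecs.T)


def _transform(counts: BinnedCounts, transform: str) -> np.ndarray:
    """Map binned counts to the observation scale of the linear model."""
    rates = counts.counts / counts.schedule.s_bin
    if transform == "rate":
        return rates
    if transform == "sqrt-rate":
        return np.sqrt(rates)
    raise ValueError(f"unknown transform {transform!r}")


class _Moments:
    """E-step output: smoothed means per trial and shared covariances."""

    __slots__ = ("xs", "Ps", "Pcross", "loglik")

    def __init__(self, xs, Ps, Pcross, loglik):
        self.xs = xs  # (M, n_bins, nl) smoothed means
        self.Ps = Ps  # (n_bins, nl, nl) smoothed covariances (shared)
        self.Pcross = Pcross  # (n_bins, nl, nl); Pcross[T] = Cov(x_T, x_{T-1}), T>=1
        self.loglik = loglik


def _estep(y: np.ndarray, p: LatentParams) -> _Moments:
    """Kalman filter + RTS smoother, vectorized over trials.

    Because every trial shares the schedule and noise model, all covariance
    recursions (and Kalman gains) are trial-independent; only the means are
    propagated per trial.
    """
    M, N, Tn = y.shape
    nl = p.n_latent
    epoch = p.schedule.epoch_of_bins(np.arange(Tn))
    A, C, d, Q, R = p.A, p.C, p.d, p.Q, np.diag(p.R)

    x_pred = np.empty((Tn, M, nl))
    P_pred = np.empty((Tn, nl, nl))
    x_filt = np.empty((Tn, M, nl))
    P_filt = np.empty((Tn, nl, nl))
    loglik = 0.0
    const = N * np.log(2.0 * np.pi)

    for T in range(Tn):
        e = int(epoch[T])
        if T == 0:
            x_pred[T] = p.mu0[None, :]
            P_pred[T] = p.P0
        else:
            x_pred[T] = x_filt[T - 1] @ A[e].T
            P_pred[T] = _sym(A[e] @ P_filt[T - 1] @ A[e].T + Q)
        Ce = C[e]
        S = _sym(Ce @ P_pred[T] @ Ce.T + R)
        cho = sla.cho_factor(S, lower=True)
        innov = y[:, :, T] - x_pred[T] @ Ce.T - d[None, :]
        solved = sla.cho_solve(cho, innov.T)  # (N, M)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        loglik += -0.5 * (M * (const + logdet) + np.sum(innov.T * solved))
        K = P_pred[T] @ Ce.T @ sla.cho_solve(cho, np.eye(N))  # (nl, N)
        x_filt[T] = x_pred[T] + innov @ K.T
        P_filt[T] = _sym(P_pred[T] - K @ Ce @ P_pred[T])

    xs = np.empty((Tn, M, nl))
    Ps = np.empty((Tn, nl, nl))
    Pcross = np.zeros((Tn, nl, nl))
    xs[-1] = x_filt[-1]
    Ps[-1] = P_filt[-1]
    for T in range(Tn - 2, -1, -1):
        e_next = int(epoch[T + 1])
        J = P_filt[T] @ A[e_next].T @ np.linalg.pinv(P_pred[T + 1])
        xs[T] = x_filt[T] + (xs[T + 1] - x_pred[T + 1]) @ J.T
        Ps[T] = _sym(P_filt[T] + J @ (Ps[T + 1] - P_pred[T + 1]) @ J.T)
        Pcross[T + 1] = Ps[T + 1] @ J.T
    return _Moments(np.swapaxes(xs, 0, 1), Ps, Pcross, loglik)


def _mstep(y: np.ndarray, mom: _Moments, p: LatentParams, cfg: FitConfig) -> LatentParams:
    M, N, Tn = y.shape
    nl = p.n_latent
    epoch = p.schedule.epoch_of_bins(np.arange(Tn))
    xs, Ps, Pcross = mom.xs, mom.Ps, mom.Pcross

    # second moments per bin, summed over trials
    Exx = M * Ps + np.einsum("mTa,mTb->Tab", xs, xs)
    Exx1 = np.zeros((Tn, nl, nl))
    Exx1[1:] = M * Pcross[1:] + np.einsum("mTa,mTb->Tab", xs[:, 1:], xs[:, :-1])

    ridge = cfg.ridge * np.eye(nl)
    warnings = list(p.warnings)

    # transitions, grouped by the epoch of the *target* bin
    A_new = np.empty_like(p.A)
    Qsum = np.zeros((nl, nl))
    for e in range(3):
        Tsel = np.where((epoch == e) & (np.arange(Tn) >= 1))[0]
        if Tsel.size == 0:
            A_new[e] = p.A[e]
            continue
        S10 = Exx1[Tsel].sum(axis=0)
        S00 = Exx[Tsel - 1].sum(axis=0)
        S11 = Exx[Tsel].sum(axis=0)
        try:
            A_new[e] = np.linalg.solve(S00.T, S10.T).T
        except np.linalg.LinAlgError:
            warnings.append(f"singular transition moments in epoch {e}; ridge applied")
            A_new[e] = np.linalg.solve((S00 + M * Tn * ridge).T, S10.T).T
        Ae = A_new[e]
        Qsum += S11 - Ae @ S10.T - S10 @ Ae.T + Ae @ S00 @ Ae.T
    Q_new = _psd_clip(_sym(Qsum / (M * (Tn - 1))), warnings, "innovation covariance")

    # joint solve for per-epoch projections and the shared offset
    dim = 3 * nl + 1
    G = np.zeros((dim, dim))
    B = np.zeros((N, dim))
    for e in range(3):
        Tsel = np.where(epoch == e)[0]
        sl = slice(e * nl, (e + 1) * nl)
        G[sl, sl] = Exx[Tsel].sum(axis=0)
        sx = xs[:, Tsel].sum(axis=(0, 1))  # (nl,)
        G[sl, -1] = sx
        G[-1, sl] = sx
        B[:, sl] = np.einsum("miT,mTa->ia", y[:, :, Tsel], xs[:, Tsel])
    G[-1, -1] = M * Tn
    B[:, -1] = y.sum(axis=(0, 2))
    try:
        Theta = np.linalg.solve(G, B.T).T  # (N, dim)
    except np.linalg.LinAlgError:
        warnings.append("singular projection moments; ridge applied")
        Theta = np.linalg.solve(G + cfg.ridge * M * Tn * np.eye(dim), B.T).T
    C_new = np.stack([Theta[:, e * nl : (e + 1) * nl] for e in range(3)])
    d_new = Theta[:, -1].copy()

    yy = np.einsum("miT,miT->i", y, y)
    R_new = (yy - 2 * np.einsum("ik,ik->i", Theta, B) + np.einsum(
        "ik,kl,il->i", Theta, G, Theta
    )) / (M * Tn)
    if np.any(R_new < cfg.r_floor):
        warnings.append("observation variance floored")
    R_new = np.maximum(R_new, cfg.r_floor)

    mu0 = xs[:, 0].mean(axis=0)
    dev = xs[:, 0] - mu0
    P0 = _psd_clip(_sym(Ps[0] + dev.T @ dev / M), warnings, "initial covariance")

    return LatentParams(
        A=A_new,
        C=C_new,
        d=d_new,
        Q=Q_new,
        R=R_new,
        mu0=mu0,
        P0=P0,
        schedule=p.schedule,
        transform=p.transform,
        loglik_trace=p.loglik_trace,
        converged=p.converged,
        warnings=warnings,
        rate_floor=p.rate_floor,
    )


def _init_params(
    y: np.ndarray,
    schedule: EpochSchedule,
    n_latent: int,
    cfg: FitConfig,
    transform: str,
) -> LatentParams:
    """Factor-analysis initialization of the projections, shrunk-identity
    dynamics, fixed seed for reproducibility."""
    M, N, Tn = y.shape
    epoch = schedule.epoch_of_bins(np.arange(Tn))
    d0 = y.mean(axis=(0, 2))
    C0 = np.empty((3, N, n_latent))
    Rs = []
    rng = np.random.default_rng(cfg.seed)
    for e in range(3):
        Ye = y[:, :, epoch == e].transpose(0, 2, 1).reshape(-1, N)
        if Ye.std(axis=0).max() < 1e-12:
            C0[e] = rng.normal(scale=1e-3, size=(N, n_latent))
            Rs.append(np.full(N, max(np.var(Ye), cfg.r_floor)))
            continue
        fa = FactorAnalysis(n_components=n_latent, random_state=cfg.seed, max_iter=200)
        try:
            fa.fit(Ye)
            C0[e] = fa.components_.T
            Rs.append(np.maximum(fa.noise_variance_, cfg.r_floor))
        except Exception:
            C0[e] = rng.normal(scale=1e-2, size=(N, n_latent))
            Rs.append(np.maximum(Ye.var(axis=0), cfg.r_floor))
    A0 = np.stack([0.9 * np.eye(n_latent)] * 3)
    Q0 = (1.0 - 0.81) * np.eye(n_latent)
    return LatentParams(
        A=A0,
        C=C0,
        d=d0,
        Q=Q0,
        R=np.maximum(np.mean(Rs, axis=0), cfg.r_floor),
        mu0=np.zeros(n_latent),
        P0=np.eye(n_latent),
        schedule=schedule,
        transform=transform,
        rate_floor=cfg.rate_floor,
    )


def fit_observations(
    y: np.ndarray,
    schedule: EpochSchedule,
    n_latent: int,
    config: FitConfig | None = None,
    transform: str = "identity",
) -> LatentParams:
    """EM fit of the epoch-switched state-space model to Gaussian observations
    ``y`` of shape (n_trials, n_neurons, n_bins)."""
    cfg = config or FitConfig()
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("observations must have shape (trials, neurons, bins)")
    M, N, Tn = y.shape
    if M < 2:
        raise ValueError("need at least 2 trials to fit the model")
    if n_latent >= N:
        raise ValueError("n_latent must be smaller than the number of neurons")
    if Tn != schedule.n_bins:
        raise ValueError("observation bins do not match the schedule")

    params = _init_params(y, schedule, n_latent, cfg, transform)
    trace: list[float] = []
    converged = False
    for _ in range(cfg.max_iter):
        mom = _estep(y, params)
        trace.append(mom.loglik)
        if len(trace) > 1:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) <= cfg.tol * max(1.0, abs(prev)):
                converged = True
                break
        params = _mstep(y, mom, params, cfg)
    if not converged:
        params.warnings.append(
            f"EM did not converge within {cfg.max_iter} iterations; best-so-far returned"
        )
    params.loglik_trace = np.asarray(trace)
    params.converged = converged
    return params


def fit_edlds(
    counts: BinnedCounts,
    schedule: EpochSchedule | None = None,
    n_latent: int = 8,
    config: FitConfig | None = None,
    transform: str = "rate",
) -> LatentParams:
    """Fit the latent model to binned spike counts.

    Counts are mapped to per-bin rates (``counts/S_bin``, the default) or
    square-root rates before the linear-Gaussian fit; the per-iteration
    marginal log-likelihood is recorded in ``loglik_trace`` and is
    non-decreasing up to numerical tolerance.
    """
    schedule = schedule or counts.schedule
    return fit_observations(
        _transform(counts, transform), schedule, n_latent, config, transform=transform
    )


def smooth_latents(params: LatentParams, y: np.ndarray) -> np.ndarray:
    """Posterior (smoothed) latent means, shape (n_trials, n_bins, n_latent)."""
    return _estep(np.asarray(y, dtype=float), params).xs


def estimate_sna(params: LatentParams, counts: BinnedCounts) -> SNAEstimate:
    """Map the smoothed latent trajectory through the projection to per-trial
    rate estimates (SNA), back-transformed and rectified at the rate floor."""
    y = _transform(counts, params.transform)
    if y.shape[1] != params.n_neurons:
        raise ValueError("neuron count does not match the fitted parameters")
    if y.shape[2] != params.schedule.n_bins:
        raise ValueError("bin count does not match the fitted schedule")
    xs = smooth_latents(params, y)  # (M, Tn, nl)
    Tn = params.schedule.n_bins
    epoch = params.schedule.epoch_of_bins(np.arange(Tn))
    yhat = np.empty_like(y)
    for e in range(3):
        idx = np.where(epoch == e)[0]
        yhat[:, :, idx] = np.einsum("il,mTl->miT", params.C[e], xs[:, idx])
    yhat += params.d[None, :, None]
    if params.transform == "sqrt-rate":
        rates = np.clip(yhat, 0.0, None) ** 2
    else:
        rates = yhat
    rates = np.maximum(rates, params.rate_floor)
    return SNAEstimate(
        rates=rates,
        schedule=params.schedule,
        provenance=f"params={params.params_hash()} smoother=rts",
        rate_floor=params.rate_floor,
    )


def model_loglik(params: LatentParams, counts: BinnedCounts) -> float:
    """Marginal log-likelihood (nats) of binned data under fitted parameters.

    Deterministic given inputs; useful for held-out selection of the latent
    dimension."""
    y = _transform(counts, params.transform)
    if y.shape[1] != params.n_neurons or y.shape[2] != params.schedule.n_bins:
        raise ValueError("data shape does not match the fitted parameters")
    return float(_estep(y, params).loglik)
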