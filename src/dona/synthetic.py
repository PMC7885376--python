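"""Ground-truth session generator.

Sessions are generated from the same modeling assumptions the analysis makes:
a low-dimensional latent state evolves by epoch-switched linear dynamics on
the latent-model bin grid, neurons receive the projected latent signal on top
of a baseline rate, and spikes are drawn as an inhomogeneous point process by
per-step Bernoulli thinning on the fine ``dt`` grid.  Transient pairwise
interactions are injected as epoch-gated multiplicative gains on the target's
rate for a short kernel (default one correlogram lag, 25 ms) after each
reference spike, which is the simplest mechanism that produces a transient
cross-correlogram excess on the tens-of-milliseconds timescale while leaving
the slow shared dynamics untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import EPOCH_LABELS, STEPS_PER_BIN, EpochSchedule, SpikeTrainSet, save_session


@dataclass(frozen=True)
class Coupling:
    """Directed transient coupling: after each spike of ``ref``, the rate of
    ``target`` is multiplied by ``gain`` for ``duration`` seconds whenever the
    current epoch is in ``epochs`` (empty tuple = always active)."""

    ref: int
    target: int
    gain: float = 2.0
    duration: float = 0.025
    epochs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        for e in self.epochs:
            if e not in EPOCH_LABELS:
                raise ValueError(f"unknown epoch {e!r}")


@dataclass
class SessionConfig:
    """Generative settings for one synthetic session."""

    n_neurons: int = 20
    n_trials: int = 100
    schedule: EpochSchedule = field(default_factory=EpochSchedule)
    n_latent: int = 2
    #: uniform range of per-neuron baseline rates, spikes/s
    base_rate_range: tuple[float, float] = (4.0, 12.0)
    #: std of latent-driven rate fluctuations relative to baseline
    latent_strength: float = 0.35
    #: per-epoch leak of the latent dynamics (eigenvalue magnitude)
    latent_decay: tuple[float, float, float] = (0.88, 0.94, 0.85)
    #: per-epoch rotation angle of the 2-D latent flow, radians/bin
    latent_rotation: tuple[float, float, float] = (0.10, 0.03, 0.20)
    couplings: tuple[Coupling, ...] = ()
    rate_floor: float = 0.5
    #: lick model: labels ~ Bernoulli(sigmoid(c0 + c_sp * z(log population count)))
    lick_c0: float = 0.0
    lick_c_sp: float = 0.0

    def __post_init__(self) -> None:
        if self.n_neurons < 2 or self.n_trials < 1:
            raise ValueError("need n_neurons >= 2 and n_trials >= 1")
        for c in self.couplings:
            if not (0 <= c.ref < self.n_neurons and 0 <= c.target < self.n_neurons):
                raise ValueError("coupling indices outside the population")
            if c.ref == c.target:
                raise ValueError("self-coupling is not supported")


@dataclass
class GroundTruth:
    """Everything needed to score a pipeline run against the generator."""

    config: SessionConfig
    seed: int
    A: np.ndarray  # (3, n_latent, n_latent) per-epoch transition
    V: np.ndarray  # (3, n_neurons, n_latent) per-epoch projection (rate units)
    r0: np.ndarray  # (n_neurons,) baseline rates, spikes/s
    Q: np.ndarray  # latent innovation covariance
    rates: np.ndarray  # (n_trials, n_neurons, n_bins) base rates before coupling
    latents: np.ndarray  # (n_trials, n_latent, n_bins)
    couplings: tuple[Coupling, ...] = ()
    clipped_steps: int = 0

    def coupling_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ref": c.ref,
                    "target": c.target,
                    "gain": c.gain,
                    "duration_s": c.duration,
                    "epochs": "|".join(c.epochs) or "all",
                }
                for c in self.couplings
            ],
            columns=["ref", "target", "gain", "duration_s", "epochs"],
        )


def _rotation_block(decay: float, angle: float, n: int) -> np.ndarray:
    """Stable transition matrix: 2-D rotations scaled by ``decay``."""
    A = np.eye(n) * decay
    c, s = np.cos(angle), np.sin(angle)
    for k in range(0, n - 1, 2):
        A[k : k + 2, k : k + 2] = decay * np.array([[c, -s], [s, c]])
    return A


def _draw_params(cfg: SessionConfig, rng: np.random.Generator):
    nl, npop = cfg.n_latent, cfg.n_neurons
    A = np.stack(
        [
            _rotation_block(cfg.latent_decay[e], cfg.latent_rotation[e], nl)
            for e in range(3)
        ]
    )
    r0 = rng.uniform(*cfg.base_rate_range, size=npop)
    # innovation keeps the stationary latent variance near 1 per coordinate
    Q = np.stack([np.eye(nl) * (1.0 - cfg.latent_decay[e] ** 2) for e in range(3)])
    # unit-norm projection rows scaled so latent-driven sd ~ latent_strength*r0
    V = np.empty((3, npop, nl))
    for e in range(3):
        dirs = rng.normal(size=(npop, nl))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        V[e] = dirs * (cfg.latent_strength * r0)[:, None]
    return A, V, r0, Q


def _simulate_latents(
    cfg: SessionConfig, A: np.ndarray, Q: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    sched = cfg.schedule
    n_bins = sched.n_bins
    epoch_of = sched.epoch_of_bins(np.arange(n_bins))
    x = np.zeros((cfg.n_trials, cfg.n_latent, n_bins))
    chol = [np.linalg.cholesky(Q[e]) for e in range(3)]
    state = rng.normal(size=(cfg.n_trials, cfg.n_latent))  # x_0 ~ N(0, I)
    for T in range(n_bins):
        e = int(epoch_of[T])
        noise = rng.normal(size=(cfg.n_trials, cfg.n_latent)) @ chol[e].T
        state = state @ A[e].T + noise
        x[:, :, T] = state
    return x


def generate_session(
    config: SessionConfig, seed: int
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Simulate one session with known latent dynamics and couplings.

    Deterministic given ``(config, seed)``: identical inputs yield
    bit-identical spike sets.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    sched = cfg.schedule
    dt = sched.dt
    n_bins = sched.n_bins
    n_steps = n_bins * STEPS_PER_BIN
    epoch_of_bin_arr = sched.epoch_of_bins(np.arange(n_bins))

    A, V, r0, Q = _draw_params(cfg, rng)
    x = _simulate_latents(cfg, A, Q, rng)

    # base rates, piecewise constant per bin, rectified at the floor
    rates = np.empty((cfg.n_trials, cfg.n_neurons, n_bins))
    for e in range(3):
        idx = np.where(epoch_of_bin_arr == e)[0]
        rates[:, :, idx] = np.einsum("il,mlT->miT", V[e], x[:, :, idx])
    rates += r0[None, :, None]
    np.maximum(rates, cfg.rate_floor, out=rates)

    kernel_steps = [max(1, int(round(c.duration / dt))) for c in cfg.couplings]
    gate = [
        np.ones(3, bool)
        if not c.epochs
        else np.isin(np.array(EPOCH_LABELS), np.array(c.epochs))
        for c in cfg.couplings
    ]
    remaining = np.zeros((len(cfg.couplings), cfg.n_trials), dtype=int)

    spike_steps: list[list[list[int]]] = [
        [[] for _ in range(cfg.n_neurons)] for _ in range(cfg.n_trials)
    ]
    clipped = 0
    uniforms = rng.random((n_steps, cfg.n_trials, cfg.n_neurons))
    for u in range(n_steps):
        T = u // STEPS_PER_BIN
        e = int(epoch_of_bin_arr[T])
        p = rates[:, :, T] * dt
        if cfg.couplings:
            mult = np.ones((cfg.n_trials, cfg.n_neurons))
            for ci, c in enumerate(cfg.couplings):
                if gate[ci][e]:
                    mult[:, c.target] *= np.where(remaining[ci] > 0, c.gain, 1.0)
            p = p * mult
        over = p > 1.0
        if np.any(over):
            clipped += int(over.sum())
            p = np.minimum(p, 1.0)
        fired = uniforms[u] < p
        if cfg.couplings:
            remaining = np.maximum(remaining - 1, 0)
            for ci, c in enumerate(cfg.couplings):
                remaining[ci, fired[:, c.ref]] = kernel_steps[ci]
        for m, i in zip(*np.nonzero(fired)):
            spike_steps[m][i].append(u)

    # spike times at step centers: strictly increasing, never on a bin edge
    spikes = [
        [(np.asarray(s, dtype=float) + 0.5) * dt for s in trial]
        for trial in spike_steps
    ]

    counts = np.array([[len(s) for s in trial] for trial in spikes])
    z = np.log1p(counts.sum(axis=1).astype(float))
    z = (z - z.mean()) / (z.std() + 1e-12)
    p_ipsi = 1.0 / (1.0 + np.exp(-(cfg.lick_c0 + cfg.lick_c_sp * z)))
    licks = np.where(rng.random(cfg.n_trials) < p_ipsi, "ipsi", "contra")

    session = SpikeTrainSet(
        spikes=spikes, schedule=sched, lick_labels=licks, session_id=f"synthetic-{seed}"
    )
    truth = GroundTruth(
        config=cfg,
        seed=seed,
        A=A,
        V=V,
        r0=r0,
        Q=Q,
        rates=rates,
        latents=x,
        couplings=cfg.couplings,
        clipped_steps=clipped,
    )
    return session, truth


def simulate_latent_observations(
    n_trials: int,
    n_neurons: int,
    n_latent: int,
    schedule: EpochSchedule | None = None,
    obs_noise: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Draw Gaussian observations directly from an epoch-switched linear
    dynamical system (no spiking), for validating the model fit itself.

    Returns ``(y, params)`` with ``y`` of shape (n_trials, n_neurons, n_bins)
    and ``params`` holding the generative A, V (per epoch), offset d and
    noise scales.
    """
    sched = schedule or EpochSchedule()
    rng = np.random.default_rng(seed)
    cfg = SessionConfig(
        n_neurons=n_neurons,
        n_trials=n_trials,
        schedule=sched,
        n_latent=n_latent,
    )
    A, _, _, Q = _draw_params(cfg, rng)
    V = np.empty((3, n_neurons, n_latent))
    for e in range(3):
        dirs = rng.normal(size=(n_neurons, n_latent))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        V[e] = dirs
    d = rng.uniform(1.0, 3.0, size=n_neurons)
    x = _simulate_latents(cfg, A, Q, rng)
    epoch_of = sched.epoch_of_bins(np.arange(sched.n_bins))
    y = np.empty((n_trials, n_neurons, sched.n_bins))
    for e in range(3):
        idx = np.where(epoch_of == e)[0]
        y[:, :, idx] = np.einsum("il,mlT->miT", V[e], x[:, :, idx])
    y += d[None, :, None]
    y += rng.normal(scale=obs_noise, size=y.shape)
    return y, {"A": A, "V": V, "d": d, "Q": Q, "obs_noise": obs_noise}


def simulate_decoder_data(
    n_trials: int,
    c0: float,
    c_sp: float,
    c_dona: float,
    seed: int = 0,
    mean_nsp: float = 15.0,
    dona_scale: float = 0.05,
    dona_sd: float = 0.7,
) -> pd.DataFrame:
    """Simulate per-trial spike counts, interaction summaries and lick labels
    from the logistic decoding model (log-odds linear in log counts and log
    interaction strength)."""
    rng = np.random.default_rng(seed)
    n_sp = rng.poisson(mean_nsp, size=n_trials).astype(float)
    dona_val = np.exp(rng.normal(np.log(dona_scale), dona_sd, size=n_trials))
    eps = 1e-6
    logit = c0 + c_sp * np.log(n_sp + eps) + c_dona * np.log(dona_val + eps)
    p = 1.0 / (1.0 + np.exp(-logit))
    label = np.where(rng.random(n_trials) < p, "ipsi", "contra")
    return pd.DataFrame({"n_sp": n_sp, "dona": dona_val, "label": label})


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset_config(name: str) -> SessionConfig:
    """Named study conditions used by the test-bed fixtures.

    * ``tiny``      — 3 neurons, 5 trials, no coupling (round-trip/smoke runs)
    * ``null``      — 20 neurons, 100 trials, latent-driven but uncoupled
    * ``recovery``  — 20 neurons, 100 trials, 10 directed couplings with
      gain 2 and a 25-ms kernel, active only in the response epoch
    """
    if name == "tiny":
        return SessionConfig(n_neurons=3, n_trials=5, n_latent=2)
    if name == "null":
        return SessionConfig(n_neurons=20, n_trials=100, n_latent=2)
    if name == "recovery":
        couplings = tuple(
            Coupling(ref=j, target=j + 10, gain=2.0, duration=0.025, epochs=("response",))
            for j in range(10)
        )
        return SessionConfig(
            n_neurons=20, n_trials=100, n_latent=2, couplings=couplings
        )
    raise ValueError(f"unknown preset {name!r}; expected tiny, null or recovery")


def make_fixture_suite(
    preset: str, out_dir: str | Path, seed: int = 0
) -> dict[str, Path]:
    """Write a preset session plus its ground-truth tables to ``out_dir``.

    Emits the native tabular session format, a coupling table, the baseline
    rates, and a YAML record of the generative configuration and seed.
    """
    cfg = preset_config(preset)
    session, truth = generate_session(cfg, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = out / preset
    written = {"session": save_session(session, base)[0]}

    coupling_path = base.with_suffix(".couplings.csv")
    truth.coupling_table().to_csv(coupling_path, index=False)
    written["couplings"] = coupling_path

    r0_path = base.with_suffix(".baseline_rates.csv")
    pd.DataFrame({"neuron": np.arange(cfg.n_neurons), "rate_hz": truth.r0}).to_csv(
        r0_path, index=False, float_format="%.6f"
    )
    written["baseline_rates"] = r0_path

    meta = {
        "preset": preset,
        "seed": int(seed),
        "n_neurons": cfg.n_neurons,
        "n_trials": cfg.n_trials,
        "n_latent": cfg.n_latent,
        "s_bin": cfg.schedule.s_bin,
        "bins_per_epoch": list(cfg.schedule.bins_per_epoch),
        "clipped_steps": int(truth.clipped_steps),
    }
    meta_path = base.with_suffix(".meta.yaml")
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    written["meta"] = meta_path
    return written
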