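"""Shared fixtures: small synthetic sessions and fitted pipeline stages.

Session-scoped fixtures hold the expensive preset runs (null/recovery) so the
whole-pipeline acceptance tests reuse one fit per preset.
"""

from __future__ import annotations

import numpy as np
import pytest

from dona.edlds import FitConfig, estimate_sna, fit_edlds
from dona.io import EpochSchedule, SpikeTrainSet, bin_spikes
from dona.ona import compute_ona
from dona.divergence import compute_divergences
from dona.synthetic import SessionConfig, generate_session, preset_config

#: latent dimension used when analyzing generated sessions (the generator's
#: own dimensionality, which is part of the simulation's ground truth)
ANALYSIS_N_LATENT = 2


@pytest.fixture(scope="session")
def tiny_session():
    session, truth = generate_session(preset_config("tiny"), seed=11)
    return session, truth


@pytest.fixture(scope="session")
def small_session():
    """5 neurons, 8 trials — big enough to fit, small enough for unit tests."""
    cfg = SessionConfig(n_neurons=5, n_trials=8, n_latent=2)
    session, truth = generate_session(cfg, seed=7)
    return session, truth


@pytest.fixture(scope="session")
def small_sna(small_session):
    session, _ = small_session
    counts = bin_spikes(session)
    params = fit_edlds(
        counts, n_latent=ANALYSIS_N_LATENT, config=FitConfig(max_iter=30)
    )
    return estimate_sna(params, counts)


def run_preset_pipeline(preset: str, seed: int):
    """Fit -> SNA -> ONA -> divergences for a preset; shared by acceptance
    tests and examples."""
    session, truth = generate_session(preset_config(preset), seed=seed)
    counts = bin_spikes(session)
    params = fit_edlds(
        counts, n_latent=ANALYSIS_N_LATENT, config=FitConfig(max_iter=60)
    )
    sna = estimate_sna(params, counts)
    ona = compute_ona(session, sna)
    series = compute_divergences(session, ona)
    return {
        "session": session,
        "truth": truth,
        "counts": counts,
        "params": params,
        "sna": sna,
        "ona": ona,
        "divergence": series,
    }


@pytest.fixture(scope="session")
def null_run():
    return run_preset_pipeline("null", seed=2024)


@pytest.fixture(scope="session")
def recovery_run():
    return run_preset_pipeline("recovery", seed=2024)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_session(rng: np.random.Generator, n_neurons=4, n_trials=5, max_spikes=40):
    """Unstructured random session for oracle comparisons."""
    sched = EpochSchedule()
    dur = sched.trial_duration
    spikes = []
    for _ in range(n_trials):
        trial = []
        for _ in range(n_neurons):
            n = int(rng.integers(0, max_spikes + 1))
            t = np.sort(rng.uniform(0, dur, size=n))
            t = np.unique(t)
            trial.append(t)
        spikes.append(trial)
    return SpikeTrainSet(spikes=spikes, schedule=sched)
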