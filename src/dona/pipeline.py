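"""End-to-end orchestration: fit -> SNA -> correlograms -> ONA -> divergences
-> statistics, with a serialized run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import json
import platform
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .correlogram import compute_ccg, compute_dccg, compute_eccg, session_windowed_ccgs
from .divergence import EXCL_NONE, compute_divergences
from .edlds import FitConfig, estimate_sna, fit_edlds
from .io import EpochSchedule, SpikeTrainSet, bin_spikes, load_session
from .ona import compute_ona
from .stats import (
    classify_epoch_preference,
    decoder_population_summary,
    fit_decoder,
    ncc_series,
    proportion_tests,
)
from .synthetic import generate_session, preset_config


@dataclass
class RunConfig:
    """Every numeric choice of a pipeline run, serialized into the manifest."""

    input_path: str | None = None  # native-format basename; or use preset
    preset: str | None = None  # tiny | null | recovery (generated on the fly)
    out_dir: str = "dona_out"
    seed: int = 0
    # schedule
    s_bin: float = 0.0674
    bins_per_epoch: tuple[int, int, int] = (20, 20, 20)
    # latent model
    n_latent: int = 8
    em_max_iter: int = 100
    em_tol: float = 1e-6
    # correlograms
    tau: float = 0.025
    n_lags: int = 10
    window_bins: int = 20
    window_trials: int = 20
    # optimization / divergence
    objective: str = "bernoulli"
    eps_p: float = 1e-6
    n_pattern: int = 6
    min_ref_spikes: int = 10
    # statistics
    alpha_level: float = 0.05
    decode_epoch: str = "delay"
    # session inclusion: analyze only sessions with more neurons than this
    min_neurons: int = 15
    write_full_pdona: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bins_per_epoch" in data:
            data["bins_per_epoch"] = tuple(data["bins_per_epoch"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bins_per_epoch"] = list(self.bins_per_epoch)
        return d

    def schedule(self) -> EpochSchedule:
        return EpochSchedule(s_bin=self.s_bin, bins_per_epoch=self.bins_per_epoch)


STAGES = ("load", "fit", "sna", "ccg", "ona", "divergence", "classify", "decode", "ncc")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_input(config: RunConfig) -> SpikeTrainSet:
    if config.preset is not None:
        cfg = preset_config(config.preset)
        session, _ = generate_session(cfg, seed=config.seed)
        return session
    if config.input_path is None:
        raise ValueError("config must set input_path or preset")
    return load_session(config.input_path, schedule=config.schedule())


def trial_shuffled_dona(
    spikes: SpikeTrainSet,
    sna,
    config: RunConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Interaction null: permute each neuron's trials independently (keeping
    its own spikes aligned with its own SNA) so cross-neuron transients are
    destroyed, then recompute windowed correlograms, ONA and DONA."""
    M = spikes.n_trials
    perms = [rng.permutation(M) for _ in range(spikes.n_neurons)]
    shuffled = [
        [spikes.spikes[perms[i][m]][i] for i in range(spikes.n_neurons)]
        for m in range(M)
    ]
    sh_spikes = SpikeTrainSet(
        spikes=shuffled,
        schedule=spikes.schedule,
        session_id=spikes.session_id + "-shuffled",
    )
    sh_rates = np.stack(
        [
            np.stack([sna.rates[perms[i][m], i] for i in range(spikes.n_neurons)])
            for m in range(M)
        ]
    )
    sh_sna = dataclasses.replace(sna, rates=sh_rates)
    ona = compute_ona(
        sh_spikes,
        sh_sna,
        tau=config.tau,
        window_bins=config.window_bins,
        window_trials=config.window_trials,
        objective=config.objective,
        eps_p=config.eps_p,
    )
    from .divergence import compute_dona

    return compute_dona(ona, eps_p=config.eps_p)


def run_pipeline(config: RunConfig, until: str | None = None) -> dict:
    """Execute the analysis stages in order and write all tables.

    ``until`` stops after the named stage (inclusive).  Any stage failure
    raises :class:`StageError`; the manifest written so far marks the run as
    incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    from . import __version__ as _pkg_version

    manifest: dict = {
        "version": _pkg_version,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "config": config.to_dict(),
        "stages": [],
        "complete": False,
        "flags": {},
    }
    stop_after = until or STAGES[-1]
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")

    def _write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        for stage in STAGES:
            try:
                _run_stage(stage, config, results, manifest, out)
            except Exception as exc:  # noqa: BLE001 - stage-named reraise
                _write_manifest()
                raise StageError(stage, exc) from exc
            manifest["stages"].append(stage)
            if stage == stop_after:
                break
        manifest["complete"] = True
    finally:
        _write_manifest()
    return results


def _run_stage(
    stage: str, config: RunConfig, results: dict, manifest: dict, out: Path
) -> None:
    if stage == "load":
        session = _load_input(config)
        if session.n_neurons <= config.min_neurons:
            manifest["flags"]["session_excluded"] = (
                f"{session.n_neurons} neurons <= threshold {config.min_neurons}"
            )
            raise ValueError(
                f"session excluded: {session.n_neurons} neurons (threshold "
                f"> {config.min_neurons}); lower min_neurons to analyze it"
            )
        results["session"] = session
        results["counts"] = bin_spikes(session)

    elif stage == "fit":
        fitcfg = FitConfig(
            max_iter=config.em_max_iter, tol=config.em_tol, seed=config.seed
        )
        params = fit_edlds(
            results["counts"],
            n_latent=min(config.n_latent, results["session"].n_neurons - 1),
            config=fitcfg,
        )
        results["params"] = params
        manifest["flags"]["em_converged"] = bool(params.converged)
        pd.DataFrame(
            {"iteration": np.arange(len(params.loglik_trace)),
             "loglik": params.loglik_trace}
        ).to_csv(out / "fit_log.csv", index=False)

    elif stage == "sna":
        sna = estimate_sna(results["params"], results["counts"])
        results["sna"] = sna
        _long3(sna.rates, "rate_hz").to_csv(out / "sna.csv", index=False)

    elif stage == "ccg":
        session, sna = results["session"], results["sna"]
        ccg = compute_ccg(session, tau=config.tau, n_lags=config.n_lags)
        eccg = compute_eccg(sna, session, tau=config.tau, n_lags=config.n_lags)
        dccg = compute_dccg(ccg, eccg)
        results.update(ccg=ccg, eccg=eccg, dccg=dccg)
        pd.concat(
            [c.to_table() for c in (ccg, eccg, dccg)], ignore_index=True
        ).to_csv(out / "correlograms.csv", index=False)

    elif stage == "ona":
        session, sna = results["session"], results["sna"]
        windowed = session_windowed_ccgs(
            session,
            sna,
            tau=config.tau,
            window_bins=config.window_bins,
            window_trials=config.window_trials,
        )
        ona = compute_ona(
            session,
            sna,
            tau=config.tau,
            window_bins=config.window_bins,
            window_trials=config.window_trials,
            objective=config.objective,
            eps_p=config.eps_p,
            windowed=windowed,
        )
        results["ona"] = ona
        summary = _long3(ona.alpha, "alpha")
        summary["q"] = ona.q.ravel()
        summary["loglik"] = ona.loglik.ravel()
        summary["flags"] = ona.flags.ravel()
        summary.to_csv(out / "ona_summary.csv", index=False)
        manifest["flags"]["ona_fallback_bins"] = int((ona.flags & 3 > 0).sum())

    elif stage == "divergence":
        series = compute_divergences(
            results["session"],
            results["ona"],
            n=config.n_pattern,
            min_ref_spikes=config.min_ref_spikes,
            eps_p=config.eps_p,
        )
        results["divergence"] = series
        _long3(series.dona, "dona").to_csv(out / "dona.csv", index=False)
        pmean = series.pdona_trial_mean()
        _pair_table(pmean).to_csv(out / "pdona_trial_mean.csv", index=False)
        if config.write_full_pdona:
            _pdona_full_table(series).to_csv(out / "pdona.csv", index=False)
        manifest["flags"]["pdona_excluded_pairs"] = int(
            (series.excluded != EXCL_NONE).sum()
        )

    elif stage == "classify":
        series = results["divergence"]
        sched = results["session"].schedule
        pref = classify_epoch_preference(
            series.dona, sched, alpha_level=config.alpha_level
        )
        results["epoch_preference"] = pref
        pref.table.to_csv(out / "epoch_preference.csv", index=False)
        # pairwise preference on trial-averaged PDONA
        pmean = series.pdona_trial_mean()
        N = pmean.shape[0]
        mask = ~np.eye(N, dtype=bool)
        pairs = np.argwhere(mask)
        pair_vals = pmean[mask]
        pair_pref = classify_epoch_preference(
            pair_vals, sched, alpha_level=config.alpha_level
        )
        pair_pref.table.insert(1, "ref", pairs[:, 0])
        pair_pref.table.insert(2, "target", pairs[:, 1])
        results["pair_preference"] = pair_pref
        pair_pref.table.to_csv(out / "pair_preference.csv", index=False)
        tests = [proportion_tests(pref.labels, alpha_level=config.alpha_level)]
        session = results["session"]
        if session.group_labels is not None:
            same = (
                session.group_labels[pairs[:, 0]] == session.group_labels[pairs[:, 1]]
            )
            tests.append(
                proportion_tests(
                    pair_pref.labels, same_group=same, alpha_level=config.alpha_level
                )
            )
        results["proportion_tests"] = pd.concat(tests, ignore_index=True)
        results["proportion_tests"].to_csv(out / "proportion_tests.csv", index=False)

    elif stage == "decode":
        session = results["session"]
        if session.lick_labels is None:
            manifest["flags"]["decode"] = "skipped: no lick labels"
            return
        sched = session.schedule
        sl = sched.epoch_slice(config.decode_epoch)
        counts = results["counts"].counts[:, :, sl].sum(axis=2)  # (M, N)
        dona_sum = results["divergence"].dona[:, :, sl].mean(axis=2)
        fits = []
        for i in range(session.n_neurons):
            try:
                fits.append(
                    fit_decoder(
                        counts[:, i],
                        dona_sum[:, i],
                        session.lick_labels,
                        epoch=config.decode_epoch,
                    )
                )
            except ValueError as exc:
                manifest["flags"][f"decode_neuron_{i}"] = str(exc)
        results["decoder_fits"] = fits
        if fits:
            pd.DataFrame(
                [
                    {
                        "neuron": i,
                        **f.coef,
                        **{f"p_{k}": v for k, v in f.pvalues.items()},
                        "aic_full": f.aic_full,
                        "aic_reduced": f.aic_reduced,
                        "preferred": f.preferred,
                        "flags": ";".join(f.flags),
                    }
                    for i, f in enumerate(fits)
                ]
            ).to_csv(out / "decoder.csv", index=False)
            results["decoder_summary"] = decoder_population_summary(
                fits, alpha_level=config.alpha_level
            )
            results["decoder_summary"].to_csv(out / "decoder_summary.csv", index=False)

    elif stage == "ncc":
        rho = ncc_series(results["counts"])
        results["ncc"] = rho
        df = pd.DataFrame(rho)
        df.insert(0, "neuron", np.arange(rho.shape[0]))
        df.to_csv(out / "ncc.csv", index=False)

    else:  # pragma: no cover
        raise ValueError(stage)


def _long3(arr: np.ndarray, value_name: str) -> pd.DataFrame:
    m, i, t = np.meshgrid(
        np.arange(arr.shape[0]),
        np.arange(arr.shape[1]),
        np.arange(arr.shape[2]),
        indexing="ij",
    )
    return pd.DataFrame(
        {
            "trial": m.ravel(),
            "neuron": i.ravel(),
            "bin": t.ravel(),
            value_name: arr.ravel(),
        }
    )


def _pair_table(pmean: np.ndarray) -> pd.DataFrame:
    j, i, t = np.meshgrid(
        np.arange(pmean.shape[0]),
        np.arange(pmean.shape[1]),
        np.arange(pmean.shape[2]),
        indexing="ij",
    )
    df = pd.DataFrame(
        {
            "ref": j.ravel(),
            "target": i.ravel(),
            "bin": t.ravel(),
            "pdona": pmean.ravel(),
        }
    )
    return df[df["ref"] != df["target"]].reset_index(drop=True)


def _pdona_full_table(series) -> pd.DataFrame:
    M, J, I, T = series.pdona.shape
    m, j, i, t = np.meshgrid(
        np.arange(M), np.arange(J), np.arange(I), np.arange(T), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "trial": m.ravel(),
            "ref": j.ravel(),
            "target": i.ravel(),
            "bin": t.ravel(),
            "pdona": series.pdona.ravel(),
            "excluded_reason": np.broadcast_to(
                series.excluded[:, :, :, None], series.pdona.shape
            ).ravel(),
        }
    )
    return df[df["ref"] != df["target"]].reset_index(drop=True)
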