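"""Data model and tabular I/O for sessions of simultaneously recorded spike trains.

A session is a set of trials; each trial holds one sorted spike-time list per
neuron (trial-relative seconds) plus a behavioral lick label.  All trials share
an :class:`EpochSchedule` of three consecutive task epochs (sample, delay,
response) laid out on a fixed latent-model bin grid.

Conventions used throughout the package (stated once here, reused everywhere):

* time bins are half-open ``[T*S_bin, (T+1)*S_bin)`` with 0-based indices;
* a spike exactly on an edge belongs to the later bin;
* the fine grid subdivides each latent bin into 60 steps of ``dt = S_bin/60``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

EPOCH_LABELS = ("sample", "delay", "response")

#: fine steps per latent-model bin
STEPS_PER_BIN = 60


class ValidationError(ValueError):
    """Raised when spike data violate the session contract."""


@dataclass(frozen=True)
class EpochSchedule:
    """Latent-model bin grid with three consecutive behavioral epochs.

    Parameters
    ----------
    s_bin
        Latent-model bin size in seconds (default 67.4 ms).
    bins_per_epoch
        Number of latent bins in the sample, delay and response epochs.
        Epochs are contiguous and ordered sample -> delay -> response.
    """

    s_bin: float = 0.0674
    bins_per_epoch: tuple[int, int, int] = (20, 20, 20)

    def __post_init__(self) -> None:
        if self.s_bin <= 0:
            raise ValueError("s_bin must be positive")
        if len(self.bins_per_epoch) != len(EPOCH_LABELS):
            raise ValueError("bins_per_epoch must give one count per epoch")
        if any(int(b) <= 0 for b in self.bins_per_epoch):
            raise ValueError("each epoch needs at least one bin")

    @property
    def dt(self) -> float:
        """Fine time step, ``s_bin / 60``, in seconds."""
        return self.s_bin / STEPS_PER_BIN

    @property
    def n_bins(self) -> int:
        return int(sum(self.bins_per_epoch))

    @property
    def trial_duration(self) -> float:
        return self.n_bins * self.s_bin

    @property
    def epoch_bin_edges(self) -> np.ndarray:
        """Cumulative bin index at which each epoch starts, plus the total."""
        return np.concatenate([[0], np.cumsum(self.bins_per_epoch)])

    def epoch_slice(self, label: str) -> slice:
        """Bin-index slice covered by the named epoch."""
        e = EPOCH_LABELS.index(label)
        edges = self.epoch_bin_edges
        return slice(int(edges[e]), int(edges[e + 1]))

    def epoch_of_bins(self, bins: np.ndarray) -> np.ndarray:
        """Vectorized epoch index (0, 1, 2) for an array of bin indices."""
        bins = np.asarray(bins)
        if np.any(bins < 0) or np.any(bins >= self.n_bins):
            raise IndexError("bin index out of range")
        return np.searchsorted(self.epoch_bin_edges[1:], bins, side="right")

    def bin_edges(self) -> np.ndarray:
        """Edges of all latent bins, shape ``(n_bins + 1,)`` seconds."""
        return np.arange(self.n_bins + 1) * self.s_bin

    def epoch_times(self) -> pd.DataFrame:
        """Start/end time of each epoch in trial-relative seconds."""
        edges = self.epoch_bin_edges * self.s_bin
        return pd.DataFrame(
            {
                "epoch": list(EPOCH_LABELS),
                "start_s": edges[:-1],
                "end_s": edges[1:],
            }
        )


def epoch_of_bin(schedule: EpochSchedule, T: int) -> str:
    """Epoch label of latent bin ``T`` (0-based)."""
    if not 0 <= T < schedule.n_bins:
        raise IndexError(f"bin index {T} outside [0, {schedule.n_bins})")
    return EPOCH_LABELS[int(schedule.epoch_of_bins(np.asarray([T]))[0])]


@dataclass
class SpikeTrainSet:
    """One session: trials x neurons of sorted spike times plus metadata.

    Attributes
    ----------
    spikes
        ``spikes[m][i]`` is a 1-D float array of strictly increasing
        trial-relative spike times (seconds) of neuron ``i`` in trial ``m``.
    schedule
        The shared epoch/bin layout; every spike must lie in
        ``[0, schedule.trial_duration)``.
    lick_labels
        Optional per-trial behavioral label, ``"ipsi"`` or ``"contra"``.
    group_labels
        Optional per-neuron functional-group label (taken as input, e.g.
        contralateral ramping-up / ipsilateral ramping-up / ramping-down /
        rest); the package never derives these.
    """

    spikes: list[list[np.ndarray]]
    schedule: EpochSchedule
    lick_labels: np.ndarray | None = None
    group_labels: np.ndarray | None = None
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.spikes = [
            [np.asarray(s, dtype=float) for s in trial] for trial in self.spikes
        ]
        self.validate()

    @property
    def n_trials(self) -> int:
        return len(self.spikes)

    @property
    def n_neurons(self) -> int:
        return len(self.spikes[0]) if self.spikes else 0

    def spike_counts(self) -> np.ndarray:
        """Total spikes per (trial, neuron)."""
        return np.array(
            [[len(s) for s in trial] for trial in self.spikes], dtype=int
        )

    def validate(self) -> None:
        if not self.spikes:
            raise ValidationError("session has no trials")
        n_neurons = len(self.spikes[0])
        if n_neurons == 0:
            raise ValidationError("session has no neurons")
        t_end = self.schedule.trial_duration
        bad: list[tuple[int, int]] = []
        for m, trial in enumerate(self.spikes):
            if len(trial) != n_neurons:
                raise ValidationError(
                    f"trial {m} has {len(trial)} neurons, expected {n_neurons}"
                )
            for i, s in enumerate(trial):
                if s.ndim != 1:
                    raise ValidationError(f"spike list (trial {m}, neuron {i}) not 1-D")
                if s.size and (s[0] < 0 or s[-1] >= t_end):
                    raise ValidationError(
                        f"spike time outside [0, {t_end:.4f}) in (trial {m}, neuron {i})"
                    )
                if s.size > 1 and np.any(np.diff(s) <= 0):
                    bad.append((m, i))
        if bad:
            raise ValidationError(f"non-monotone spike times in (trial, neuron): {bad}")
        if self.lick_labels is not None:
            self.lick_labels = np.asarray(self.lick_labels)
            if len(self.lick_labels) != self.n_trials:
                raise ValidationError("lick_labels length must equal n_trials")
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels)
            if len(self.group_labels) != n_neurons:
                raise ValidationError("group_labels length must equal n_neurons")


@dataclass
class BinnedCounts:
    """Spike counts on the latent-model bin grid.

    ``counts[m, i, T]`` is the number of spikes of neuron ``i`` in trial ``m``
    falling in bin ``T`` (half-open edges).  Summing over ``T`` recovers the
    spike-list length for every (trial, neuron).
    """

    counts: np.ndarray  # (n_trials, n_neurons, n_bins) int
    schedule: EpochSchedule
    convention: str = "half-open [T*S_bin, (T+1)*S_bin), 0-based"

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    def per_epoch_totals(self) -> np.ndarray:
        """Spike totals per (trial, neuron, epoch)."""
        edges = self.schedule.epoch_bin_edges
        return np.stack(
            [
                self.counts[:, :, int(edges[e]) : int(edges[e + 1])].sum(axis=2)
                for e in range(len(EPOCH_LABELS))
            ],
            axis=2,
        )


def bin_spikes(spikes: SpikeTrainSet, schedule: EpochSchedule | None = None) -> BinnedCounts:
    """Bin every spike list onto the latent-model grid.

    Uses the half-open convention: a spike exactly on a bin edge is assigned
    to the later bin.  Raises :class:`ValidationError` if any spike lies at or
    beyond the last bin edge.
    """
    schedule = schedule or spikes.schedule
    n_bins = schedule.n_bins
    out = np.zeros((spikes.n_trials, spikes.n_neurons, n_bins), dtype=int)
    for m, trial in enumerate(spikes.spikes):
        for i, s in enumerate(trial):
            if s.size == 0:
                continue
            idx = np.floor(s / schedule.s_bin).astype(int)
            if idx.min() < 0 or idx.max() >= n_bins:
                raise ValidationError(
                    f"spike outside the bin grid in (trial {m}, neuron {i})"
                )
            np.add.at(out[m, i], idx, 1)
    return BinnedCounts(counts=out, schedule=schedule)


# ---------------------------------------------------------------------------
# Native tabular format
#
# spikes table:  session_id, trial, neuron, spike_time_s
# epochs table:  trial, epoch, start_s, end_s, lick_label
# groups table:  neuron, group_label            (optional)
# ---------------------------------------------------------------------------

_SPIKE_COLS = ["session_id", "trial", "neuron", "spike_time_s"]
_EPOCH_COLS = ["trial", "epoch", "start_s", "end_s", "lick_label"]


def _paths(path: str | Path) -> tuple[Path, Path, Path]:
    base = Path(path)
    return (
        base.with_suffix(".spikes.csv"),
        base.with_suffix(".epochs.csv"),
        base.with_suffix(".groups.csv"),
    )


def save_session(spikes: SpikeTrainSet, path: str | Path) -> list[Path]:
    """Write a session to the native delimited-text format.

    ``path`` is a basename; ``<path>.spikes.csv`` and ``<path>.epochs.csv``
    are always written, ``<path>.groups.csv`` only when group labels exist.
    Returns the written paths.
    """
    spike_path, epoch_path, group_path = _paths(path)
    spike_path.parent.mkdir(parents=True, exist_ok=True)

    rows = []
    for m, trial in enumerate(spikes.spikes):
        for i, s in enumerate(trial):
            for t in s:
                rows.append((spikes.session_id, m, i, t))
    df = pd.DataFrame(rows, columns=_SPIKE_COLS)
    df.to_csv(spike_path, index=False, float_format="%.9f")

    licks = (
        spikes.lick_labels
        if spikes.lick_labels is not None
        else np.full(spikes.n_trials, "", dtype=object)
    )
    epoch_times = spikes.schedule.epoch_times()
    erows = [
        (m, row.epoch, row.start_s, row.end_s, licks[m])
        for m, row in itertools.product(range(spikes.n_trials), epoch_times.itertuples())
    ]
    pd.DataFrame(erows, columns=_EPOCH_COLS).to_csv(
        epoch_path, index=False, float_format="%.9f"
    )

    written = [spike_path, epoch_path]
    if spikes.group_labels is not None:
        pd.DataFrame(
            {"neuron": np.arange(spikes.n_neurons), "group_label": spikes.group_labels}
        ).to_csv(group_path, index=False)
        written.append(group_path)
    return written


def load_session(
    path: str | Path,
    format: str = "native",
    schedule: EpochSchedule | None = None,
) -> SpikeTrainSet:
    """Read a session from the native tabular format.

    The epoch table must describe the same three contiguous epochs in every
    trial; the schedule is reconstructed from it (bin size defaults to
    67.4 ms unless ``schedule`` overrides it).  Spike tables with unsorted or
    out-of-range times are rejected with a :class:`ValidationError`.
    """
    if format != "native":
        raise ValueError(f"unknown format {format!r}; only 'native' is supported")
    spike_path, epoch_path, group_path = _paths(path)
    if not spike_path.exists() or not epoch_path.exists():
        raise FileNotFoundError(f"missing session tables for basename {path}")

    sdf = pd.read_csv(spike_path)
    if list(sdf.columns) != _SPIKE_COLS:
        raise ValidationError(f"spike table columns must be {_SPIKE_COLS}")
    edf = pd.read_csv(epoch_path, keep_default_na=False)
    if list(edf.columns) != _EPOCH_COLS:
        raise ValidationError(f"epoch table columns must be {_EPOCH_COLS}")
    if edf.empty:
        raise ValidationError("epoch table is empty: epoch boundaries are required")

    # epoch layout must be identical across trials
    ref = None
    for m, grp in edf.groupby("trial"):
        layout = grp.sort_values("start_s")[["epoch", "start_s", "end_s"]].to_numpy()
        if list(layout[:, 0]) != list(EPOCH_LABELS):
            raise ValidationError(
                f"trial {m}: epochs must be {EPOCH_LABELS} in temporal order"
            )
        if not np.allclose(layout[:-1, 2].astype(float), layout[1:, 1].astype(float)):
            raise ValidationError(f"trial {m}: epochs must be contiguous")
        if ref is None:
            ref = layout
        elif not np.allclose(
            layout[:, 1:].astype(float), ref[:, 1:].astype(float), atol=1e-9
        ):
            raise ValidationError("per-trial epoch boundaries differ; a common schedule is required")

    if schedule is None:
        s_bin = EpochSchedule().s_bin
        durations = ref[:, 2].astype(float) - ref[:, 1].astype(float)
        bins = durations / s_bin
        if not np.allclose(bins, np.round(bins), atol=1e-6):
            raise ValidationError(
                "epoch durations are not multiples of the default 67.4 ms bin; "
                "pass an explicit schedule"
            )
        schedule = EpochSchedule(
            s_bin=s_bin, bins_per_epoch=tuple(int(b) for b in np.round(bins))
        )

    trials = sorted(set(edf["trial"].astype(int)))
    if trials != list(range(len(trials))):
        raise ValidationError("trial indices must be 0..M-1 without gaps")
    n_neurons = int(sdf["neuron"].max()) + 1 if len(sdf) else 0
    if n_neurons == 0:
        raise ValidationError("spike table holds no spikes; cannot infer neuron count")

    session_id = str(sdf["session_id"].iloc[0])
    spike_lists: list[list[np.ndarray]] = [
        [np.empty(0) for _ in range(n_neurons)] for _ in trials
    ]
    for (m, i), grp in sdf.groupby(["trial", "neuron"]):
        spike_lists[int(m)][int(i)] = grp["spike_time_s"].to_numpy(dtype=float)

    licks = None
    lick_col = edf.drop_duplicates("trial").sort_values("trial")["lick_label"]
    if (lick_col.astype(str) != "").any():
        licks = lick_col.astype(str).to_numpy()

    groups = None
    if group_path.exists():
        gdf = pd.read_csv(group_path)
        groups = np.full(n_neurons, "rest", dtype=object)
        groups[gdf["neuron"].to_numpy(dtype=int)] = gdf["group_label"].to_numpy()

    return SpikeTrainSet(
        spikes=spike_lists,
        schedule=schedule,
        lick_labels=licks,
        group_labels=groups,
        session_id=session_id,
    )
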