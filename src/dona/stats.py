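"""Downstream statistics on interaction series.

* Epoch-preference classification: a unit (neuron or ordered pair) prefers
  an epoch when its trial-averaged interaction values over that epoch's bins
  are larger than over each of the other two epochs (one-sided Wilcoxon
  rank-sum tests at the configured level, with larger medians).  Units that
  beat exactly one other epoch form the residual "two-epoch" category;
  units that beat none are "none".
* Proportion comparisons: pairwise chi-squared tests on 2x2 preferred /
  not-preferred tables between epochs or between same-group and
  different-group pairs, with an exact-test fallback for sparse tables.
* Lick decoding: per-neuron logistic regression of the ipsilateral-lick
  probability on log spike counts (reduced model) plus log interaction
  strength (full model), compared by AIC.
* NCC baseline: per latent bin, the across-trial correlation of two
  neurons' spike counts, aggregated per neuron as the root mean square over
  its pairings.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .io import EPOCH_LABELS, BinnedCounts, EpochSchedule

EPS_LOG = 1e-6


@dataclass
class EpochPreference:
    """Per-unit epoch-preference labels with the underlying test results."""

    table: pd.DataFrame  # unit, label, per-epoch medians and p-values
    alpha_level: float

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    def counts(self) -> dict[str, int]:
        lab = self.table["label"]
        out = {e: int((lab == e).sum()) for e in EPOCH_LABELS}
        out["two-epoch"] = int((lab == "two-epoch").sum())
        out["none"] = int((lab == "none").sum())
        return out


def classify_epoch_preference(
    values: np.ndarray,
    schedule: EpochSchedule,
    alpha_level: float = 0.05,
) -> EpochPreference:
    """Classify each unit by the epoch in which its interaction is largest.

    ``values`` is ``(n_units, n_bins)`` of trial-averaged series, or
    ``(n_trials, n_units, n_bins)`` which is averaged over trials first.
    Units containing NaNs are skipped with label ``"skipped"``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 3:
        values = values.mean(axis=0)
    if values.shape[1] != schedule.n_bins:
        raise ValueError("bin count does not match the schedule")
    slices = [schedule.epoch_slice(e) for e in EPOCH_LABELS]

    rows = []
    for u in range(values.shape[0]):
        v = values[u]
        row: dict = {"unit": u}
        if np.any(~np.isfinite(v)):
            row["label"] = "skipped"
            rows.append(row)
            continue
        per_epoch = [v[s] for s in slices]
        medians = [float(np.median(x)) for x in per_epoch]
        wins = np.zeros(3, dtype=int)
        for e in range(3):
            for f in range(3):
                if e == f:
                    continue
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    p = sps.mannwhitneyu(
                        per_epoch[e], per_epoch[f], alternative="greater"
                    ).pvalue
                row[f"p_{EPOCH_LABELS[e]}_gt_{EPOCH_LABELS[f]}"] = float(p)
                if p < alpha_level and medians[e] > medians[f]:
                    wins[e] += 1
        for e, lab in enumerate(EPOCH_LABELS):
            row[f"median_{lab}"] = medians[e]
        if wins.max() == 2:
            row["label"] = EPOCH_LABELS[int(np.argmax(wins))]
        elif wins.max() == 1:
            row["label"] = "two-epoch"
        else:
            row["label"] = "none"
        rows.append(row)
    return EpochPreference(table=pd.DataFrame(rows), alpha_level=alpha_level)


def _prop_test(k_a: int, n_a: int, k_b: int, n_b: int) -> tuple[float, float, str, bool]:
    """Chi-squared test on a 2x2 proportion table; exact fallback when an
    expected cell drops below 5."""
    table = np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]], dtype=float)
    if table.sum() == 0:
        return np.nan, np.nan, "undefined", True
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if expected.min() < 5:
        _, p = sps.fisher_exact(table.astype(int))
        return np.nan, float(p), "fisher", True
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p), "chi2", False


def proportion_tests(
    labels: np.ndarray,
    same_group: np.ndarray | None = None,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Compare proportions of epoch-preferring units between epochs and,
    optionally, between same-group and different-group units within epochs.

    ``labels`` holds one epoch-preference label per unit; ``same_group`` is an
    optional boolean array marking units (pairs) whose members share a
    functional group.
    """
    labels = np.asarray(labels)
    groupings: dict[str, np.ndarray] = {"all": np.ones(len(labels), dtype=bool)}
    if same_group is not None:
        same_group = np.asarray(same_group, dtype=bool)
        groupings = {"same-group": same_group, "different-group": ~same_group}

    rows = []
    for gname, mask in groupings.items():
        n = int(mask.sum())
        counts = {e: int(np.sum(labels[mask] == e)) for e in EPOCH_LABELS}
        for a, b in (("sample", "delay"), ("delay", "response"), ("sample", "response")):
            chi2, p, method, flagged = _prop_test(counts[a], n, counts[b], n)
            rows.append(
                {
                    "comparison": f"{a} vs {b}",
                    "grouping": gname,
                    "k_a": counts[a],
                    "n_a": n,
                    "k_b": counts[b],
                    "n_b": n,
                    "statistic": chi2,
                    "p_value": p,
                    "method": method,
                    "significant": bool(p < alpha_level) if np.isfinite(p) else False,
                    "flagged": flagged,
                }
            )
    if same_group is not None:
        n_s = int(same_group.sum())
        n_d = int((~same_group).sum())
        for e in EPOCH_LABELS:
            k_s = int(np.sum(labels[same_group] == e))
            k_d = int(np.sum(labels[~same_group] == e))
            chi2, p, method, flagged = _prop_test(k_s, n_s, k_d, n_d)
            rows.append(
                {
                    "comparison": f"same vs different in {e}",
                    "grouping": "between",
                    "k_a": k_s,
                    "n_a": n_s,
                    "k_b": k_d,
                    "n_b": n_d,
                    "statistic": chi2,
                    "p_value": p,
                    "method": method,
                    "significant": bool(p < alpha_level) if np.isfinite(p) else False,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DecodingFit:
    """Per-neuron logistic decoding of the lick response."""

    coef: dict[str, float]
    pvalues: dict[str, float]
    aic_full: float
    aic_reduced: float
    n_trials: int
    flags: list[str] = field(default_factory=list)
    epoch: str = "delay"

    @property
    def preferred(self) -> str:
        return "full" if self.aic_full < self.aic_reduced else "reduced"


def fit_decoder(
    n_sp: np.ndarray,
    dona_summary: np.ndarray,
    labels: np.ndarray,
    epoch: str = "delay",
    eps_log: float = EPS_LOG,
) -> DecodingFit:
    """Fit full (counts + interaction) and reduced (counts only) logistic
    models of the ipsilateral-lick probability and compare their AICs.

    ``n_sp`` and ``dona_summary`` are per-trial predictors (spike count and
    interaction summary in the chosen epoch); ``labels`` are "ipsi"/"contra".
    """
    n_sp = np.asarray(n_sp, dtype=float)
    dona_summary = np.asarray(dona_summary, dtype=float)
    y = (np.asarray(labels) == "ipsi").astype(float)
    if len(y) < 20:
        raise ValueError("need at least 20 trials for decoding")
    if y.min() == y.max():
        raise ValueError("both lick classes must be present")

    x_sp = np.log(n_sp + eps_log)
    x_dona = np.log(dona_summary + eps_log)
    X_full = sm.add_constant(np.column_stack([x_sp, x_dona]))
    X_red = sm.add_constant(x_sp[:, None])

    flags: list[str] = []

    def _fit(X):
        nonlocal flags
        model = sm.Logit(y, X)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            try:
                res = model.fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", True) or np.any(
                    np.abs(res.params) > 50
                ):
                    raise RuntimeError("separation suspected")
                return res.params, res.pvalues, res.aic
            except Exception:
                flags.append("penalized-fallback")
                res = model.fit_regularized(alpha=1.0, disp=0, maxiter=500)
                k = X.shape[1]
                return res.params, np.full(k, np.nan), 2 * k - 2 * model.loglike(res.params)

    par_f, p_f, aic_f = _fit(X_full)
    par_r, p_r, aic_r = _fit(X_red)
    return DecodingFit(
        coef={"c0": float(par_f[0]), "c_sp": float(par_f[1]), "c_dona": float(par_f[2])},
        pvalues={
            "c0": float(p_f[0]),
            "c_sp": float(p_f[1]),
            "c_dona": float(p_f[2]),
        },
        aic_full=float(aic_f),
        aic_reduced=float(aic_r),
        n_trials=len(y),
        flags=flags,
        epoch=epoch,
    )


def decoder_population_summary(
    fits: list[DecodingFit], alpha_level: float = 0.05
) -> pd.DataFrame:
    """Population-level summary: fraction of neurons with significant
    coefficients (binomial test against the nominal rate) and the fraction
    preferring the full model by AIC."""
    n = len(fits)
    rows = []
    for name in ("c_sp", "c_dona"):
        k = sum(1 for f in fits if np.isfinite(f.pvalues[name]) and f.pvalues[name] < alpha_level)
        binom = sps.binomtest(k, n, p=alpha_level, alternative="greater")
        rows.append(
            {
                "quantity": f"significant {name}",
                "count": k,
                "total": n,
                "fraction": k / n,
                "binomial_p": float(binom.pvalue),
            }
        )
    k_full = sum(1 for f in fits if f.preferred == "full")
    rows.append(
        {
            "quantity": "full model preferred (AIC)",
            "count": k_full,
            "total": n,
            "fraction": k_full / n,
            "binomial_p": np.nan,
        }
    )
    return pd.DataFrame(rows)


@dataclass
class NCCResult:
    """Across-trial count correlations in one latent bin."""

    rho_pairs: np.ndarray  # (n_neurons, n_neurons), NaN where undefined
    rho: np.ndarray  # (n_neurons,) root-mean-square over valid pairings
    bin_index: int
    flagged: np.ndarray | None = None  # neurons with zero count variance

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = np.zeros(len(self.rho), dtype=bool)


def ncc(counts: BinnedCounts, T: int) -> NCCResult:
    """Normalized correlation coefficient per neuron in latent bin ``T``.

    The pair coefficient is the Pearson correlation across trials of the two
    neurons' counts in the bin; the per-neuron value is the root mean square
    over its valid pairings (zero-variance neurons are excluded from the
    average with an adjusted denominator and flagged).
    """
    if counts.n_trials < 3:
        raise ValueError("need at least 3 trials for across-trial correlations")
    if not 0 <= T < counts.n_bins:
        raise IndexError("bin index out of range")
    X = counts.counts[:, :, T].astype(float)  # (trials, neurons)
    N = X.shape[1]
    sd = X.std(axis=0)
    zero_var = sd == 0
    rho_pairs = np.full((N, N), np.nan)
    ok = ~zero_var
    if ok.sum() >= 2:
        with np.errstate(invalid="ignore"):
            sub = np.corrcoef(X[:, ok].T)
        rho_pairs[np.ix_(ok, ok)] = sub
    np.fill_diagonal(rho_pairs, np.nan)
    valid = np.isfinite(rho_pairs)
    denom = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.sqrt(np.nansum(rho_pairs**2, axis=1) / denom)
    rho[denom == 0] = np.nan
    return NCCResult(rho_pairs=rho_pairs, rho=rho, bin_index=T, flagged=zero_var)


def ncc_series(counts: BinnedCounts) -> np.ndarray:
    """Per-neuron NCC for every bin, shape (n_neurons, n_bins)."""
    return np.stack([ncc(counts, T).rho for T in range(counts.n_bins)], axis=1)
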