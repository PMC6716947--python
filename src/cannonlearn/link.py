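"""Linking single-trial EEG signal strength to learning behavior.

Trial-wise signal strength is the dot product between a cluster's t map and
the trial's epoch restricted to the cluster's member points, z-scored across
trials.  Strengths enter the circular update regression through two key
terms: PE x EEG (*direct learning*, a context-independent modulation of the
learning rate) and PE x condition x EEG (*conditional learning*, a
modulation whose sign flips between changepoint and oddball contexts).
A sliding-window variant masks the unthresholded surprise t map with 40 ms
windows to trace when the EEG-learning relationship emerges, with a
temporal cluster-mass sign-flip test across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .cluster import ClusterResult, EpochArray, find_clusters, group_tmap, signflip_permutation
from .regression import SubjectFit, fit_map_circular_regression

LINK_TERMS = ("intercept", "pe", "pe_eeg", "pe_condition_eeg")
LINK_TERMS_PRED = LINK_TERMS + ("pe_pred_lr",)

# priors: broad on intercept/PE, SD 0.1 on EEG terms, SD 1 on the competing
# behavioral-prediction term (10x weaker regularization than the EEG terms,
# so shared variance is preferentially explained by the behavioral model)
PRIOR_SD_BASE = (5.0, 5.0, 0.1, 0.1)
PRIOR_SD_PRED = PRIOR_SD_BASE + (1.0,)

__all__ = [
    "LINK_TERMS",
    "LINK_TERMS_PRED",
    "trial_signal_strength",
    "fit_link_regression",
    "sliding_window_strength",
    "coefficient_timecourse_test",
    "binned_learning_rates",
]


def _zscore_trials(strength: np.ndarray) -> np.ndarray:
    sd = strength.std(ddof=0)
    if sd == 0:
        return strength - strength.mean()
    return (strength - strength.mean()) / sd


def trial_signal_strength(
    epochs: EpochArray, cluster: ClusterResult, t_map: np.ndarray
) -> np.ndarray:
    """Per-trial dot product of the cluster-masked t map with each epoch.

    Returns strengths z-scored across trials (mean 0, SD 1).
    """
    if cluster.size == 0:
        raise ValueError("cluster has no member points")
    ch, ti = cluster.channels, cluster.time_indices
    if ch.max() >= epochs.n_channels or ti.max() >= epochs.n_times:
        raise ValueError("cluster points fall outside the epoch grid")
    weights = t_map[ch, ti]
    strength = np.einsum("p,pt->t", weights, epochs.data[ch, ti, :])
    return _zscore_trials(strength)


def fit_link_regression(
    updates,
    delta,
    condition,
    strength,
    pred_lr=None,
    n_restarts: int = 5,
    seed: int = 0,
) -> SubjectFit:
    """Circular MAP regression of updates on PE and EEG interaction terms.

    Rows with non-finite updates (e.g. the session-final trial) are dropped.
    With ``pred_lr`` supplied, the behavioral model's predicted learning
    rate competes for variance through a PE x pred(LR) term.
    """
    updates = np.asarray(updates, dtype=float)
    delta = np.asarray(delta, dtype=float)
    condition = np.asarray(condition, dtype=float)
    strength = np.asarray(strength, dtype=float)
    arrays = [delta, condition, strength]
    if pred_lr is not None:
        arrays.append(np.asarray(pred_lr, dtype=float))
    if any(a.shape != updates.shape for a in arrays):
        raise ValueError("all trial vectors must share one length")

    keep = np.isfinite(updates)
    cols = [
        np.ones(keep.sum()),
        delta[keep],
        delta[keep] * strength[keep],
        delta[keep] * condition[keep] * strength[keep],
    ]
    terms, priors = LINK_TERMS, PRIOR_SD_BASE
    if pred_lr is not None:
        cols.append(delta[keep] * arrays[3][keep])
        terms, priors = LINK_TERMS_PRED, PRIOR_SD_PRED
    X = np.column_stack(cols)
    return fit_map_circular_regression(
        updates[keep], X, priors, n_restarts=n_restarts, seed=seed, terms=terms
    )


def sliding_window_strength(
    epochs: EpochArray,
    surprise_t_map: np.ndarray,
    window_ms: float = 40.0,
    step_ms: float | None = None,
    analysis_range=(300.0, 700.0),
    baseline_window=(-100.0, 0.0),
):
    """Windowed dot products with the unthresholded surprise t map.

    Windows of ``window_ms`` slide over ``analysis_range`` in steps of
    ``step_ms`` (default one sample).  ERPs are baseline corrected first and
    strengths are z-scored within each window.  Returns ``(strengths,
    window_starts)`` with strengths shaped (windows, trials) and starts in ms.
    """
    lo, hi = analysis_range
    if lo < epochs.times[0] or hi > epochs.times[-1] + 1.0 / epochs.srate * 1000.0:
        raise ValueError(f"analysis range {analysis_range} outside epoch range")
    if step_ms is None:
        step_ms = 1000.0 / epochs.srate
    corrected = epochs.baseline_correct(baseline_window)
    starts = np.arange(lo, hi - window_ms + 0.5 * step_ms, step_ms)
    strengths = np.empty((len(starts), epochs.n_trials))
    for w, start in enumerate(starts):
        mask = corrected.time_mask(start, start + window_ms)
        weights = surprise_t_map[:, mask]
        raw = np.einsum("ct,ctr->r", weights, corrected.data[:, mask, :])
        strengths[w] = _zscore_trials(raw)
    return strengths, starts


def coefficient_timecourse_test(
    coef_series: np.ndarray,
    step_ms: float,
    smooth_sd_ms: float = 8.0,
    alpha_form: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
):
    """Temporal cluster test on per-subject coefficient time courses.

    Series (subjects x windows) are smoothed with a Gaussian kernel
    (``smooth_sd_ms``, reflected edges, truncated at 4 SD), tested against
    zero per window, and contiguous two-tailed suprathreshold runs are
    cluster-mass corrected by sign-flip permutation.  Returns ``(clusters,
    t_series)``; cluster time indices are window indices.
    """
    coef_series = np.asarray(coef_series, dtype=float)
    if coef_series.ndim != 2:
        raise ValueError("coef_series must be (subjects, windows)")
    if coef_series.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    sigma = smooth_sd_ms / step_ms
    smoothed = (
        gaussian_filter1d(coef_series, sigma, axis=1, mode="reflect", truncate=4.0)
        if sigma > 0
        else coef_series
    )
    maps = smoothed[:, np.newaxis, :]  # single pseudo-channel
    t_map, dof = group_tmap(maps)
    no_adj = np.zeros((1, 1), dtype=bool)
    clusters = find_clusters(t_map, dof, alpha_form, no_adj)
    if clusters:
        clusters = signflip_permutation(
            maps, clusters, no_adj, alpha_form, n_perm=n_perm, seed=seed
        )
    return clusters, t_map[0]


def binned_learning_rates(
    updates, delta, strength, condition, n_bins: int = 5
) -> pd.DataFrame:
    """Learning rate (slope of update on PE) per signal-strength bin.

    Trials are quantile-binned by strength within each condition; the slope
    comes from a per-bin least-squares fit with intercept.  Rows with
    non-finite updates are dropped first.
    """
    df = pd.DataFrame(
        {
            "update": np.asarray(updates, dtype=float),
            "delta": np.asarray(delta, dtype=float),
            "strength": np.asarray(strength, dtype=float),
            "condition": np.asarray(condition, dtype=float),
        }
    ).dropna()
    if len(df) < n_bins * 10:
        raise ValueError(f"need at least {n_bins * 10} usable trials")
    rows = []
    for cond, grp in df.groupby("condition"):
        try:
            bins = pd.qcut(grp["strength"], n_bins, labels=False, duplicates="raise")
        except ValueError as err:
            raise ValueError("empty or degenerate strength bin") from err
        for b in range(n_bins):
            sel = grp[bins == b]
            if len(sel) < 2:
                raise ValueError(f"bin {b} in condition {cond} has too few trials")
            X = np.column_stack([np.ones(len(sel)), sel["delta"]])
            coef, *_ = np.linalg.lstsq(X, sel["update"], rcond=None)
            rows.append(
                {
                    "condition": cond,
                    "bin": b,
                    "mean_strength": sel["strength"].mean(),
                    "slope": coef[1],
                    "n_trials": len(sel),
                }
            )
    return pd.DataFrame(rows)
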