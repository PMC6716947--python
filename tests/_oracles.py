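"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np

from cannonlearn.task import CHANGEPOINT, ODDBALL, TaskSession


def grid_filter_predictions(
    session: TaskSession,
    hazard: float,
    noise_kappa: float,
    drift_kappa: float,
    n_grid: int = 360,
    prior_kappa: float = 10.0,
) -> np.ndarray:
    """Exact mixture-filtering Bayesian observer on a discretized circle.

    Maintains the full posterior over the cannon aim on ``n_grid`` points,
    propagating it through the condition's generative process (uniform
    re-aim mixture for changepoints; Von Mises drift convolution plus
    uniform-outlier likelihood for oddballs) and returns the posterior-mean
    prediction made before each outcome.  The prior starts as a Von Mises
    centered on the true initial aim, emulating the instructed training.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)

    def vm(x, mu, k):
        return np.exp(k * np.cos(x - mu)) / (2.0 * np.pi * np.i0(k))

    p = vm(theta, session.aim[0], prior_kappa)
    p /= p.sum()
    if session.condition == ODDBALL:
        kern = vm(theta, 0.0, drift_kappa)
        kern /= kern.sum()
        fk = np.fft.rfft(kern)

    preds = np.empty(session.n_trials)
    for t in range(session.n_trials):
        z = (p * np.exp(1j * theta)).sum()
        preds[t] = np.angle(z) % (2.0 * np.pi)
        x = session.outcome[t]
        if session.condition == CHANGEPOINT:
            p_pred = (1.0 - hazard) * p + hazard / n_grid
            like = vm(x, theta, noise_kappa)
        else:
            p_pred = np.fft.irfft(np.fft.rfft(p) * fk, n=n_grid)
            p_pred = np.maximum(p_pred, 0.0)
            p_pred /= p_pred.sum()
            like = (1.0 - hazard) * vm(x, theta, noise_kappa) + hazard / (2.0 * np.pi)
        p = p_pred * like
        p /= p.sum()
    return preds


def floodfill_clusters(t_map: np.ndarray, threshold: float, adjacency: np.ndarray):
    """Breadth-first connected components of signed suprathreshold points.

    Returns a list of (set of (channel, time) points, sign, mass) tuples,
    independent of the package's sparse-graph implementation.
    """
    n_ch, n_t = t_map.shape
    visited = np.zeros((n_ch, n_t), dtype=bool)
    out = []
    for c0 in range(n_ch):
        for t0 in range(n_t):
            if visited[c0, t0] or abs(t_map[c0, t0]) <= threshold:
                continue
            sign = 1 if t_map[c0, t0] > 0 else -1
            stack = [(c0, t0)]
            visited[c0, t0] = True
            members = []
            while stack:
                c, t = stack.pop()
                members.append((c, t))
                neighbors = [(c, t - 1), (c, t + 1)] + [
                    (c2, t) for c2 in range(n_ch) if adjacency[c, c2]
                ]
                for c2, t2 in neighbors:
                    if 0 <= c2 < n_ch and 0 <= t2 < n_t and not visited[c2, t2]:
                        v = t_map[c2, t2]
                        if abs(v) > threshold and (v > 0) == (sign > 0):
                            visited[c2, t2] = True
                            stack.append((c2, t2))
            tvals = np.array([abs(t_map[c, t]) for c, t in members])
            out.append((frozenset(members), sign, tvals.mean() * len(members)))
    return out
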