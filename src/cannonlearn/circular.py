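"""Circular (angular) helpers shared across the package.

Convention: positions live on [0, 2*pi), signed differences in (-pi, pi],
everything in radians. Degrees appear only at file/CLI boundaries.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

TWO_PI = 2.0 * np.pi

__all__ = [
    "wrap_position",
    "wrap_signed",
    "circular_distance",
    "circular_mean",
    "fit_kappa",
]


def wrap_position(theta):
    """Wrap angles onto [0, 2*pi)."""
    return np.mod(theta, TWO_PI)


def wrap_signed(theta):
    """Wrap angles onto the signed interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.mod(theta, TWO_PI)
    out = np.where(wrapped > np.pi, wrapped - TWO_PI, wrapped)
    return out if out.ndim else float(out)


def circular_distance(a, b):
    """Signed shortest arc from ``b`` to ``a``, in (-pi, pi].

    ``circular_distance(outcome, prediction)`` is the prediction error a
    subject makes when the cannonball lands at ``outcome`` while the shield
    sits at ``prediction``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("circular_distance requires finite angles")
    return wrap_signed(a - b)


def circular_mean(theta, weights=None):
    """Mean direction of a sample of angles (weighted if given), in [0, 2*pi)."""
    theta = np.asarray(theta, dtype=float)
    z = np.exp(1j * theta)
    if weights is not None:
        z = z * np.asarray(weights, dtype=float)
    return float(wrap_position(np.angle(z.sum())))


def fit_kappa(samples) -> float:
    """Maximum-likelihood Von Mises concentration of an angular sample.

    The location parameter is estimated jointly; only kappa is returned.
    """
    samples = wrap_signed(np.asarray(samples, dtype=float))
    if samples.size < 2:
        raise ValueError("need at least two samples to estimate kappa")
    kappa, _, _ = stats.vonmises.fit(samples, fscale=1)
    return float(kappa)
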