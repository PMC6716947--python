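"""Reduced Bayesian observer for the cannon task.

The model approximates full Bayesian inference over the cannon aim with a
single Gaussian belief, which collapses to an error-driven rule whose
learning rate is set trial-by-trial from two latent variables:

* ``tau`` — *relative uncertainty*, the fraction of predictive variance due
  to imperfect knowledge of the aim rather than outcome noise (analogous to
  a Kalman gain);
* ``omega`` — the posterior probability that the latest outcome arose from
  the rare-event process (an oddball or a changepoint, by condition).

In the oddball condition surprise should *suppress* learning (an oddball
carries no information about the aim): ``alpha = tau * (1 - omega)``.  In
the changepoint condition surprise should *amplify* learning (a changepoint
invalidates prior beliefs): ``alpha = omega + tau * (1 - omega)``.

The recursion is driven by an observed prediction-error sequence, so it can
condition on a subject's own predictions rather than the model's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import circular_distance, wrap_position
from .task import CHANGEPOINT, CONDITIONS, ODDBALL, TaskSession

TAU_FLOOR = 1e-6  # keep tau strictly inside (0, 1) to avoid division blow-ups

__all__ = [
    "LearnerParams",
    "BeliefTrace",
    "update_uncertainty_oddball",
    "update_uncertainty_changepoint",
    "event_probability",
    "learning_rate_oddball",
    "learning_rate_changepoint",
    "run_learner",
]


@dataclass(frozen=True)
class LearnerParams:
    """Observer's assumed environment statistics.

    ``noise_var`` and ``drift_var`` are Gaussian-approximation variances in
    radians^2; the defaults 1/10 and 1/30 are the large-kappa equivalents of
    the task's Von Mises concentrations (10 and 30).
    """

    hazard: float = 0.14
    noise_var: float = 1.0 / 10.0
    drift_var: float = 1.0 / 30.0
    tau_init: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError("hazard must be in [0, 1]")
        if self.noise_var <= 0:
            raise ValueError("noise_var must be positive")
        if self.drift_var < 0:
            raise ValueError("drift_var must be non-negative")
        if not 0.0 < self.tau_init < 1.0:
            raise ValueError("tau_init must lie in (0, 1)")


@dataclass
class BeliefTrace:
    """Per-trial normative latents aligned to a prediction-error sequence."""

    prediction: np.ndarray
    delta: np.ndarray
    tau: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    sigma_mu2: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self.delta)),
                "prediction": self.prediction,
                "delta": self.delta,
                "tau": self.tau,
                "omega": self.omega,
                "alpha": self.alpha,
                "sigma_mu2": self.sigma_mu2,
            }
        )


def _clip_tau(tau: float) -> float:
    return float(np.clip(tau, TAU_FLOOR, 1.0 - TAU_FLOOR))


def _check_tau(tau: float) -> None:
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")


def update_uncertainty_oddball(tau, omega, delta, params: LearnerParams):
    """Propagate estimation variance and relative uncertainty (oddball rule).

    The four terms are: uncertainty carried through if the outcome was an
    oddball (no information), the posterior variance if it was not, the
    variance contributed by disagreement between those two conditional
    means (which differ by ``delta * tau``), and the aim drift expected
    before the next outcome.
    """
    _check_tau(tau)
    s2, t = params.noise_var, tau
    sigma_mu2 = (
        omega * s2 * t / (1.0 - t)
        + (1.0 - omega) * s2 * t
        + omega * (1.0 - omega) * (delta * t) ** 2
        + params.drift_var
    )
    tau_next = _clip_tau(sigma_mu2 / (sigma_mu2 + s2))
    return float(sigma_mu2), tau_next


def update_uncertainty_changepoint(tau, omega, delta, params: LearnerParams):
    """Changepoint analogue of the uncertainty propagation.

    After a changepoint a single outcome is informative, so the conditional
    variance is the full noise variance and the conditional means differ by
    ``delta * (1 - tau)``; the aim does not drift in this condition.
    """
    _check_tau(tau)
    s2, t = params.noise_var, tau
    sigma_mu2 = (
        omega * s2
        + (1.0 - omega) * s2 * t
        + omega * (1.0 - omega) * (delta * (1.0 - t)) ** 2
    )
    tau_next = _clip_tau(sigma_mu2 / (sigma_mu2 + s2))
    return float(sigma_mu2), tau_next


def event_probability(delta, tau_next, params: LearnerParams) -> float:
    """Posterior probability that the new prediction error reflects a rare event.

    A mixture of the uniform rare-event density (H / 2pi) and a linear
    Gaussian centered on the prediction with variance ``noise_var /
    (1 - tau)``; the same expression serves for changepoint probability.
    """
    _check_tau(tau_next)
    h = params.hazard
    if h == 0.0:
        return 0.0
    if h == 1.0:
        return 1.0
    var = params.noise_var / (1.0 - tau_next)
    density = np.exp(-0.5 * delta**2 / var) / np.sqrt(2.0 * np.pi * var)
    uniform = h / (2.0 * np.pi)
    return float(uniform / (uniform + (1.0 - h) * density))


def learning_rate_oddball(tau_next, omega_next) -> float:
    """Uncertainty drives learning; oddball probability suppresses it."""
    return float(tau_next * (1.0 - omega_next))


def learning_rate_changepoint(tau_next, omega_next) -> float:
    """Changepoint probability drives a (partial) reset toward the outcome."""
    return float(omega_next + tau_next * (1.0 - omega_next))


def run_learner(
    params: LearnerParams,
    condition: str,
    deltas=None,
    session: TaskSession | None = None,
    predictions=None,
    reset_blocks: bool = True,
    initial_prediction: float = 0.0,
) -> BeliefTrace:
    """Run the observer along a prediction-error sequence.

    Three driving modes:

    * ``deltas`` given — latents condition on the supplied errors; the
      recorded predictions accumulate the model's own updates from
      ``initial_prediction`` (informational only in this mode).
    * ``session`` + ``predictions`` — subject mode: errors are computed as
      the circular distance from each prediction to the outcome.
    * ``session`` alone — self-driven: the model makes its own predictions,
      starting at ``initial_prediction``, updating by ``alpha * delta``.

    ``reset_blocks`` restarts ``tau`` at ``tau_init`` on block boundaries
    (sessions only; a plain delta sequence is treated as one block).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    update_uncertainty = (
        update_uncertainty_oddball if condition == ODDBALL else update_uncertainty_changepoint
    )
    learning_rate = (
        learning_rate_oddball if condition == ODDBALL else learning_rate_changepoint
    )

    self_driven = False
    block_starts = None
    if deltas is not None:
        deltas = np.asarray(deltas, dtype=float)
        if not np.all(np.isfinite(deltas)):
            raise ValueError("prediction errors must be finite")
        if np.any(deltas <= -np.pi) or np.any(deltas > np.pi):
            raise ValueError("prediction errors must lie in (-pi, pi]")
        n = len(deltas)
    elif session is not None:
        n = session.n_trials
        if reset_blocks:
            block_starts = np.flatnonzero(np.diff(session.block_index, prepend=-1))
        if predictions is not None:
            predictions = np.asarray(predictions, dtype=float)
            if len(predictions) != n:
                raise ValueError(
                    f"predictions length {len(predictions)} != session trials {n}"
                )
            deltas = circular_distance(session.outcome, predictions)
        else:
            self_driven = True
    else:
        raise ValueError("provide either a delta sequence or a session")

    pred = np.empty(n)
    delta_out = np.empty(n)
    tau = np.empty(n)
    omega = np.empty(n)
    alpha = np.empty(n)
    sigma_mu2 = np.empty(n)

    current_pred = float(wrap_position(initial_prediction))
    current_tau = params.tau_init
    for t in range(n):
        if block_starts is not None and t in block_starts and t > 0:
            current_tau = params.tau_init
        if self_driven:
            pred[t] = current_pred
            d = float(circular_distance(session.outcome[t], current_pred))
        elif predictions is not None:
            pred[t] = predictions[t]
            d = float(deltas[t])
        else:
            pred[t] = current_pred
            d = float(deltas[t])
        delta_out[t] = d
        tau[t] = current_tau
        omega[t] = event_probability(d, current_tau, params)
        alpha[t] = learning_rate(current_tau, omega[t])
        sigma_mu2[t], current_tau = update_uncertainty(current_tau, omega[t], d, params)
        current_pred = float(wrap_position(current_pred + alpha[t] * d))

    return BeliefTrace(
        prediction=pred,
        delta=delta_out,
        tau=tau,
        omega=omega,
        alpha=alpha,
        sigma_mu2=sigma_mu2,
    )
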