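"""Synthetic agents, ERP-like epochs, and cohorts with known ground truth.

Every analysis stage in the package is exercised end-to-end on data from
this module: task sessions from the generative processes, agents whose
update behavior carries planted regression structure (including a
conditional EEG-gain coupling whose sign flips with condition), and
channel x time x trial epoch arrays in which a surprise-modulated
outcome-locked positivity is scaled by the same per-trial gain that drives
the agent's learning.  Ground truth (per-trial generative slope and gain)
is returned alongside so recovery tests never peek at the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .circular import circular_distance, wrap_position, wrap_signed
from .cluster import EpochArray
from .learner import (
    LearnerParams,
    event_probability,
    learning_rate_changepoint,
    learning_rate_oddball,
    update_uncertainty_changepoint,
    update_uncertainty_oddball,
)
from .task import (
    CHANGEPOINT,
    ODDBALL,
    TaskConfig,
    TaskSession,
    generate_session,
    score_hit,
)

NORMATIVE = "normative"
REGRESSION_GENERATIVE = "regression_generative"

# Default planted coefficients on the same (standardized-modulator) scale the
# update regression reports: intercept, PE, PE x uncertainty, PE x surprise,
# PE x surprise x condition, PE x hit.
DEFAULT_GENERATIVE_BETAS = (0.0, 0.6, 0.15, 0.0, 0.7, -0.1)

# Reference moments (mean, SD) of the normative latents under the default
# task and learner parameters, pooled over both conditions and restricted to
# regression-included trials (post-oddball and session-final rows dropped),
# because that is the set the fit z-scores modulators over.  Used to
# standardize modulators during sequential generation (the fit
# re-standardizes with sample moments).  Calibrated once by damped
# fixed-point iteration over long simulated cohorts.
MODULATOR_REFERENCE = {"tau": (0.4816, 0.1460), "omega": (0.327, 0.3885)}

__all__ = [
    "NORMATIVE",
    "REGRESSION_GENERATIVE",
    "DEFAULT_GENERATIVE_BETAS",
    "AgentSpec",
    "ErpTemplateSpec",
    "SubjectData",
    "schematic_montage",
    "simulate_agent",
    "simulate_epochs",
    "build_cohort",
    "export_cohort",
    "read_dryad_export",
]


@dataclass(frozen=True)
class AgentSpec:
    """How a synthetic subject turns prediction errors into updates.

    ``normative`` agents apply the model's learning rate; ``regression_
    generative`` agents apply a planted linear combination of standardized
    modulators plus ``conditional_eeg_gain * gamma_t * condition``, where
    ``gamma_t`` is the same per-trial gain that scales their ERP template.
    """

    kind: str = REGRESSION_GENERATIVE
    motor_noise_kappa: float = 10.0
    generative_betas: tuple[float, ...] = DEFAULT_GENERATIVE_BETAS
    conditional_eeg_gain: float = 0.1
    gamma_sd: float = 1.0

    def __post_init__(self):
        if self.kind not in (NORMATIVE, REGRESSION_GENERATIVE):
            raise ValueError(f"unknown agent kind: {self.kind}")
        if self.motor_noise_kappa <= 0:
            raise ValueError("motor_noise_kappa must be positive")
        if not np.isfinite(self.conditional_eeg_gain):
            raise ValueError("conditional_eeg_gain must be finite")
        if len(self.generative_betas) != 6:
            raise ValueError("generative_betas must have 6 entries")


@dataclass(frozen=True)
class ErpTemplateSpec:
    """Outcome-locked template: Gaussian bumps in space and time.

    The default mimics an anterior-to-posterior progression: a frontocentral
    component peaking ~350 ms and a parietal component peaking ~500 ms,
    both amplified on rare-event trials (``surprise_modulation``) and scaled
    by the per-trial gain ``(1 + gamma_t)``.
    """

    peak_ms: tuple[float, ...] = (350.0, 500.0)
    width_ms: tuple[float, ...] = (50.0, 80.0)
    focus_y: tuple[float, ...] = (0.45, -0.45)  # anterior (+y) then posterior
    spatial_sd: float = 0.5
    amplitude: tuple[float, ...] = (1.0, 0.8)
    surprise_modulation: float = 0.5
    trial_gain_sd: float = 1.0
    noise_sd: float = 1.0
    srate: float = 500.0
    tmin_ms: float = -200.0
    tmax_ms: float = 1000.0

    def __post_init__(self):
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (len(self.peak_ms) == len(self.width_ms) == len(self.focus_y) == len(self.amplitude)):
            raise ValueError("component tuples must share one length")


@dataclass
class SubjectData:
    """One synthetic subject: sessions, behavior, epochs, and ground truth."""

    subject_id: int
    sessions: dict[str, TaskSession]
    behavior: pd.DataFrame
    epochs: EpochArray | None
    truth: dict


def schematic_montage(n_channels: int = 32) -> tuple[list[str], np.ndarray]:
    """Deterministic 2-D head layout: a vertex channel plus concentric rings."""
    if n_channels < 4:
        raise ValueError("need at least 4 channels")
    names = [f"CH{i:02d}" for i in range(n_channels)]
    positions = [(0.0, 0.0)]
    remaining = n_channels - 1
    n_rings = 3 if n_channels <= 40 else 4
    ring_sizes = np.diff(np.round(np.linspace(0, remaining, n_rings + 1))).astype(int)
    for r, size in enumerate(ring_sizes, start=1):
        radius = r / n_rings
        angles = 2.0 * np.pi * np.arange(size) / max(size, 1) + 0.25 * r
        positions.extend((radius * np.cos(a), radius * np.sin(a)) for a in angles)
    return names, np.asarray(positions[:n_channels])


def _latent_steps(condition: str):
    if condition == ODDBALL:
        return update_uncertainty_oddball, learning_rate_oddball
    return update_uncertainty_changepoint, learning_rate_changepoint


def simulate_agent(
    session: TaskSession,
    agent: AgentSpec,
    learner: LearnerParams,
    seed: int,
    reset_blocks: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Roll one agent through a session.

    Returns a tidy behavior table (one row per trial) and a ground-truth
    dict with the per-trial generative slope and gain ``gamma``.
    The agent starts each session with an informed prediction (a Von Mises
    draw around the true aim), emulating the instructed training phase.
    """
    rng = np.random.default_rng(seed)
    n = session.n_trials
    cond_code = 1.0 if session.condition == CHANGEPOINT else -1.0
    update_uncertainty, learning_rate = _latent_steps(session.condition)
    ref = MODULATOR_REFERENCE

    gamma = rng.normal(0.0, agent.gamma_sd, size=n)
    noiseless = not np.isfinite(agent.motor_noise_kappa)

    pred = np.empty(n)
    delta = np.empty(n)
    update = np.full(n, np.nan)
    tau_arr = np.empty(n)
    omega_arr = np.empty(n)
    alpha_arr = np.empty(n)
    hit = np.empty(n)
    gen_slope = np.empty(n)

    b = np.asarray(agent.generative_betas, dtype=float)
    current_pred = float(wrap_position(session.aim[0] + rng.vonmises(0.0, learner.noise_var**-1)))
    tau = learner.tau_init
    block_starts = np.flatnonzero(np.diff(session.block_index, prepend=-1))
    for t in range(n):
        if reset_blocks and t in block_starts and t > 0:
            tau = learner.tau_init
        pred[t] = current_pred
        d = float(circular_distance(session.outcome[t], current_pred))
        delta[t] = d
        omega = event_probability(d, tau, learner)
        alpha = learning_rate(tau, omega)
        tau_arr[t], omega_arr[t], alpha_arr[t] = tau, omega, alpha
        hit[t] = 1.0 if score_hit(session.outcome[t], current_pred, session.shield_half_width[t]) else -1.0

        if agent.kind == NORMATIVE:
            slope = alpha
            intercept = 0.0
        else:
            z_tau = (tau - ref["tau"][0]) / ref["tau"][1]
            z_omega = (omega - ref["omega"][0]) / ref["omega"][1]
            slope = (
                b[1]
                + b[2] * z_tau
                + b[3] * z_omega
                + b[4] * z_omega * cond_code
                + b[5] * hit[t]
                + agent.conditional_eeg_gain * gamma[t] * cond_code
            )
            intercept = b[0]
        gen_slope[t] = slope

        if t < n - 1:
            u = intercept + slope * d
            if not noiseless:
                u = u + rng.vonmises(0.0, agent.motor_noise_kappa)
            u = float(wrap_signed(u))
            update[t] = u
            current_pred = float(wrap_position(current_pred + u))

        _, tau = update_uncertainty(tau, omega, d, learner)

    behavior = pd.DataFrame(
        {
            "trial": np.arange(n),
            "block": session.block_index,
            "condition_name": session.condition,
            "condition": cond_code,
            "prediction": pred,
            "outcome": session.outcome,
            "delta": delta,
            "update": update,
            "hit": hit,
            "is_changepoint": session.is_changepoint.astype(int),
            "is_oddball": session.is_oddball.astype(int),
            "tau": tau_arr,
            "omega": omega_arr,
            "alpha": alpha_arr,
            "shield_half_width": session.shield_half_width,
        }
    )
    truth = {
        "gen_slope": gen_slope,
        "gamma": gamma,
        "betas": b.copy(),
        "conditional_eeg_gain": agent.conditional_eeg_gain,
        "kind": agent.kind,
    }
    return behavior, truth


def simulate_epochs(
    session_events: np.ndarray,
    template: ErpTemplateSpec,
    seed: int,
    gamma: np.ndarray | None = None,
    n_channels: int = 32,
) -> tuple[EpochArray, np.ndarray]:
    """Generate ERP-like epochs for a sequence of trials.

    ``session_events`` is the per-trial rare-event flag (changepoint or
    oddball).  Each trial's epoch is the component sum scaled by
    ``(1 + surprise_modulation * event) * (1 + gamma_t)`` plus white noise.
    Returns the epochs and the gain sequence actually used.
    """
    rng = np.random.default_rng(seed)
    events = np.asarray(session_events, dtype=float)
    n_trials = len(events)
    if gamma is None:
        gamma = rng.normal(0.0, template.trial_gain_sd, size=n_trials)
    gamma = np.asarray(gamma, dtype=float)
    if len(gamma) != n_trials:
        raise ValueError("gamma must have one entry per trial")

    names, positions = schematic_montage(n_channels)
    step = 1000.0 / template.srate
    times = np.arange(template.tmin_ms, template.tmax_ms, step)

    base = np.zeros((n_channels, len(times)))
    for peak, width, fy, amp in zip(
        template.peak_ms, template.width_ms, template.focus_y, template.amplitude
    ):
        spatial = np.exp(
            -((positions[:, 0]) ** 2 + (positions[:, 1] - fy) ** 2)
            / (2.0 * template.spatial_sd**2)
        )
        temporal = np.exp(-((times - peak) ** 2) / (2.0 * width**2))
        base += amp * np.outer(spatial, temporal)

    gain = (1.0 + template.surprise_modulation * events) * (1.0 + gamma)
    data = base[:, :, np.newaxis] * gain[np.newaxis, np.newaxis, :]
    if template.noise_sd > 0:
        data = data + rng.normal(0.0, template.noise_sd, size=data.shape)

    epochs = EpochArray(
        data=data,
        times=times,
        srate=template.srate,
        channel_names=names,
        channel_positions=positions,
    )
    return epochs, gamma


def build_cohort(
    n_subjects: int = 39,
    master_seed: int = 0,
    agent: AgentSpec = AgentSpec(),
    learner: LearnerParams = LearnerParams(),
    task_kwargs: dict | None = None,
    template: ErpTemplateSpec | None = ErpTemplateSpec(),
    n_channels: int = 32,
    with_epochs: bool = True,
) -> list[SubjectData]:
    """Simulate a cohort: both conditions per subject, 240 trials each.

    Per-subject randomness derives deterministically from ``master_seed``
    via a seed sequence; the same master seed reproduces the cohort exactly.
    ``with_epochs=False`` skips EEG generation for behavior-only studies.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    task_kwargs = dict(task_kwargs or {})
    seed_roots = np.random.SeedSequence(master_seed).spawn(n_subjects)
    cohort = []
    for s, root in enumerate(seed_roots):
        sub_seeds = root.generate_state(5) % (2**31)
        sessions, frames, truths = {}, [], {}
        for i, condition in enumerate((CHANGEPOINT, ODDBALL)):
            cfg = TaskConfig(
                condition=condition, rng_seed=int(sub_seeds[i]), **task_kwargs
            )
            session = generate_session(cfg)
            behavior, truth = simulate_agent(
                session, agent, learner, seed=int(sub_seeds[2 + i])
            )
            behavior.insert(0, "subject", s)
            sessions[condition] = session
            frames.append(behavior)
            truths[condition] = truth
        behavior = pd.concat(frames, ignore_index=True)
        gen_slope = np.concatenate(
            [truths[c]["gen_slope"] for c in (CHANGEPOINT, ODDBALL)]
        )
        gamma = np.concatenate([truths[c]["gamma"] for c in (CHANGEPOINT, ODDBALL)])
        truth = {
            "gen_slope": gen_slope,
            "gamma": gamma,
            "betas": truths[CHANGEPOINT]["betas"],
            "conditional_eeg_gain": agent.conditional_eeg_gain,
            "kind": agent.kind,
        }
        epochs = None
        if with_epochs and template is not None:
            events = np.concatenate(
                [sessions[c].is_event for c in (CHANGEPOINT, ODDBALL)]
            )
            epochs, _ = simulate_epochs(
                events,
                template,
                seed=int(sub_seeds[4]),
                gamma=gamma,
                n_channels=n_channels,
            )
        cohort.append(
            SubjectData(
                subject_id=s,
                sessions=sessions,
                behavior=behavior,
                epochs=epochs,
                truth=truth,
            )
        )
    return cohort


def export_cohort(cohort: list[SubjectData], out_dir) -> None:
    """Write a cohort in the on-disk layout :func:`read_dryad_export` expects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in cohort:
        sub.behavior.to_csv(out / f"sub-{sub.subject_id:02d}_behavior.csv", index=False)
        if sub.epochs is not None:
            sub.epochs.save_h5(out / f"sub-{sub.subject_id:02d}_epochs.h5")


def read_dryad_export(path):
    """Load a local behavioral/EEG export into the package's containers.

    Expects a directory of ``sub-XX_behavior.csv`` tables (columns as written
    by :func:`export_cohort`) with optional ``sub-XX_epochs.h5`` epoch files.
    Returns ``(behavior, epochs, report)``: dicts keyed by subject label and
    a per-subject validation table of trial counts and alignment.  Epochs
    whose trial axis disagrees with the behavior table raise an error naming
    the subject; a behavioral-only export loads with ``epochs`` empty.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"export directory not found: {root}")
    behavior_files = sorted(root.glob("sub-*_behavior.csv"))
    if not behavior_files:
        raise FileNotFoundError(f"no sub-*_behavior.csv files under {root}")

    required = {"subject", "condition", "delta", "update", "outcome", "prediction"}
    behavior, epochs, rows = {}, {}, []
    for bf in behavior_files:
        label = bf.name.split("_behavior")[0]
        table = pd.read_csv(bf)
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"{label}: behavior table missing columns {sorted(missing)}")
        behavior[label] = table
        ef = root / f"{label}_epochs.h5"
        has_epochs = ef.exists()
        if has_epochs:
            ep = EpochArray.load_h5(ef)
            if ep.n_trials != len(table):
                raise ValueError(
                    f"{label}: epochs carry {ep.n_trials} trials but behavior "
                    f"table has {len(table)} rows"
                )
            epochs[label] = ep
        counts = table.groupby("condition_name").size().to_dict() if "condition_name" in table.columns else {}
        rows.append(
            {
                "subject": label,
                "n_trials": len(table),
                "n_changepoint": counts.get(CHANGEPOINT, 0),
                "n_oddball": counts.get(ODDBALL, 0),
                "has_epochs": has_epochs,
            }
        )
    report = pd.DataFrame(rows)
    return behavior, epochs, report
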