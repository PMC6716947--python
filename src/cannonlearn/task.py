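"""Generative model of the cannon task.

Two statistical contexts share a hazard rate H = 0.14 of rare events but give
those events opposite meanings:

* **changepoint** — the cannon's aim is stationary on most trials and is
  re-sampled uniformly with probability H per trial; every cannonball is a
  Von Mises draw (concentration ``noise_kappa``) around the current aim.
* **oddball** — the aim performs a Von Mises random walk (concentration
  ``drift_kappa``) on every trial; with probability H the cannonball ignores
  the aim entirely and lands uniformly on the circle.

Sessions are the unit of simulation: ``n_blocks * trials_per_block`` trials
with per-trial aim, outcome, event flags, and a randomly sized shield.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .circular import TWO_PI, circular_distance, wrap_position

CHANGEPOINT = "changepoint"
ODDBALL = "oddball"
CONDITIONS = (CHANGEPOINT, ODDBALL)

DEFAULT_SHIELD_RANGE = (np.deg2rad(5.0), np.deg2rad(60.0))

__all__ = [
    "CHANGEPOINT",
    "ODDBALL",
    "CONDITIONS",
    "TaskConfig",
    "TaskSession",
    "generate_changepoint_session",
    "generate_oddball_session",
    "generate_session",
    "score_hit",
]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the generative process for one session."""

    hazard: float = 0.14
    noise_kappa: float = 10.0
    drift_kappa: float = 30.0
    n_blocks: int = 4
    trials_per_block: int = 60
    condition: str = CHANGEPOINT
    shield_width_range: tuple[float, float] = DEFAULT_SHIELD_RANGE
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError(f"hazard must be in [0, 1], got {self.hazard}")
        if self.noise_kappa <= 0:
            raise ValueError("noise_kappa must be positive")
        if self.drift_kappa <= 0:
            raise ValueError("drift_kappa must be positive")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        lo, hi = self.shield_width_range
        if not (0 < lo <= hi <= np.pi):
            raise ValueError("shield_width_range must satisfy 0 < lo <= hi <= pi")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass
class TaskSession:
    """Trial-wise record of one simulated session."""

    condition: str
    aim: np.ndarray
    outcome: np.ndarray
    is_changepoint: np.ndarray
    is_oddball: np.ndarray
    block_index: np.ndarray
    shield_half_width: np.ndarray

    def __post_init__(self):
        n = len(self.aim)
        for name in ("outcome", "is_changepoint", "is_oddball", "block_index", "shield_half_width"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} has length != {n}")
        if self.condition == CHANGEPOINT and self.is_oddball.any():
            raise ValueError("changepoint sessions cannot carry oddball flags")
        if self.condition == ODDBALL and self.is_changepoint.any():
            raise ValueError("oddball sessions cannot carry changepoint flags")
        if n and (self.is_changepoint[0] or self.is_oddball[0]):
            raise ValueError("first trial of a session cannot be a rare event")

    @property
    def n_trials(self) -> int:
        return len(self.aim)

    @property
    def is_event(self) -> np.ndarray:
        """Rare-event flag regardless of condition."""
        return self.is_changepoint | self.is_oddball

    def to_frame(self) -> pd.DataFrame:
        """Tidy table, one row per trial; angles in degrees at this boundary."""
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "block": self.block_index,
                "condition": self.condition,
                "aim_deg": np.rad2deg(self.aim),
                "outcome_deg": np.rad2deg(self.outcome),
                "is_changepoint": self.is_changepoint.astype(int),
                "is_oddball": self.is_oddball.astype(int),
                "shield_half_width_deg": np.rad2deg(self.shield_half_width),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaskSession":
        condition = str(df["condition"].iloc[0])
        return cls(
            condition=condition,
            aim=wrap_position(np.deg2rad(df["aim_deg"].to_numpy(float))),
            outcome=wrap_position(np.deg2rad(df["outcome_deg"].to_numpy(float))),
            is_changepoint=df["is_changepoint"].to_numpy(bool),
            is_oddball=df["is_oddball"].to_numpy(bool),
            block_index=df["block"].to_numpy(int),
            shield_half_width=np.deg2rad(df["shield_half_width_deg"].to_numpy(float)),
        )

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)

    @classmethod
    def load_csv(cls, path) -> "TaskSession":
        return cls.from_frame(pd.read_csv(path))


def _session_scaffold(cfg: TaskConfig, rng: np.random.Generator):
    n = cfg.n_trials
    block_index = np.repeat(np.arange(cfg.n_blocks), cfg.trials_per_block)
    lo, hi = cfg.shield_width_range
    shield = rng.uniform(lo, hi, size=n)
    return n, block_index, shield


def generate_changepoint_session(cfg: TaskConfig) -> TaskSession:
    """Simulate one changepoint-condition session."""
    if cfg.condition != CHANGEPOINT:
        raise ValueError("config condition must be 'changepoint'")
    rng = np.random.default_rng(cfg.rng_seed)
    n, block_index, shield = _session_scaffold(cfg, rng)

    flags = rng.random(n) < cfg.hazard
    flags[0] = False
    aim = np.empty(n)
    aim[0] = rng.uniform(0.0, TWO_PI)
    for t in range(1, n):
        aim[t] = rng.uniform(0.0, TWO_PI) if flags[t] else aim[t - 1]
    outcome = wrap_position(aim + rng.vonmises(0.0, cfg.noise_kappa, size=n))

    return TaskSession(
        condition=CHANGEPOINT,
        aim=aim,
        outcome=outcome,
        is_changepoint=flags,
        is_oddball=np.zeros(n, dtype=bool),
        block_index=block_index,
        shield_half_width=shield,
    )


def generate_oddball_session(cfg: TaskConfig) -> TaskSession:
    """Simulate one oddball-condition session."""
    if cfg.condition != ODDBALL:
        raise ValueError("config condition must be 'oddball'")
    rng = np.random.default_rng(cfg.rng_seed)
    n, block_index, shield = _session_scaffold(cfg, rng)

    increments = rng.vonmises(0.0, cfg.drift_kappa, size=n)
    increments[0] = rng.uniform(0.0, TWO_PI)
    aim = wrap_position(np.cumsum(increments))

    flags = rng.random(n) < cfg.hazard
    flags[0] = False
    outcome = wrap_position(aim + rng.vonmises(0.0, cfg.noise_kappa, size=n))
    outcome[flags] = rng.uniform(0.0, TWO_PI, size=int(flags.sum()))

    return TaskSession(
        condition=ODDBALL,
        aim=aim,
        outcome=outcome,
        is_changepoint=np.zeros(n, dtype=bool),
        is_oddball=flags,
        block_index=block_index,
        shield_half_width=shield,
    )


def generate_session(cfg: TaskConfig) -> TaskSession:
    """Dispatch on ``cfg.condition``."""
    if cfg.condition == CHANGEPOINT:
        return generate_changepoint_session(cfg)
    return generate_oddball_session(cfg)


def score_hit(outcome, shield_center, shield_half_width):
    """True where the cannonball falls within the shield (boundary inclusive)."""
    half = np.asarray(shield_half_width, dtype=float)
    if np.any(half <= 0) or np.any(half > np.pi):
        raise ValueError("shield half-width must lie in (0, pi]")
    return np.abs(circular_distance(outcome, shield_center)) <= half
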