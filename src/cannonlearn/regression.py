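"""Trial-wise update regression with Von Mises errors.

Behavioral learning is summarized by regressing each trial's *update* (the
signed circular change in shield position) on the prediction error and on
interactions of the prediction error with model-derived modulators
(uncertainty, surprise, their interaction with condition) and with hit
feedback.  Errors around the predicted update are Von Mises distributed and
coefficients carry zero-centered Gaussian priors; fitting is maximum a
posteriori over the coefficients and the residual concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .circular import circular_distance, wrap_signed

DEFAULT_TERMS = (
    "intercept",
    "pe",
    "pe_uncertainty",
    "pe_surprise",
    "pe_surprise_condition",
    "pe_hit",
)

__all__ = [
    "DEFAULT_TERMS",
    "UpdateRegressionSpec",
    "SubjectFit",
    "DesignMatrices",
    "compute_pe_update",
    "build_design_matrix",
    "fit_map_circular_regression",
    "group_coefficient_test",
    "predicted_learning_rate",
]


@dataclass(frozen=True)
class UpdateRegressionSpec:
    """Term list, priors, and preprocessing switches for the update model.

    ``prior_sd`` applies per term (default 5 on every coefficient, the width
    used for standardized behavioral predictors).  Only the modulators
    (uncertainty, surprise) are z-scored; the prediction error itself is
    left in radians so its coefficient reads as a learning rate.
    """

    terms: tuple[str, ...] = DEFAULT_TERMS
    prior_sd: tuple[float, ...] = (5.0,) * len(DEFAULT_TERMS)
    standardize: bool = True
    exclude_post_oddball: bool = True

    def __post_init__(self):
        if len(self.prior_sd) != len(self.terms):
            raise ValueError("prior_sd must align with terms")
        if any(s <= 0 for s in self.prior_sd):
            raise ValueError("prior_sd entries must be positive")


@dataclass
class SubjectFit:
    """MAP estimate for one subject."""

    terms: tuple[str, ...]
    beta: np.ndarray
    kappa_resid: float
    logpost: float
    n_trials_used: int

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])


@dataclass
class DesignMatrices:
    """Design matrix plus the pieces needed downstream.

    ``modulators`` holds, per non-intercept term, the multiplier of the
    prediction error (so ``X[:, j] = delta * modulators[:, j-1]``); it is
    what :func:`predicted_learning_rate` weights by the fitted betas.
    """

    terms: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    modulators: np.ndarray


def compute_pe_update(predictions, outcomes):
    """Per-trial signed prediction error and update.

    ``delta_t`` is the circular distance from the prediction to the outcome;
    ``update_t`` the circular distance from this trial's prediction to the
    next one.  The final trial has no update and is returned as NaN.
    """
    predictions = np.asarray(predictions, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if predictions.shape != outcomes.shape:
        raise ValueError("predictions and outcomes must have equal length")
    if predictions.size < 2:
        raise ValueError("need at least two trials")
    delta = circular_distance(outcomes, predictions)
    update = np.full_like(delta, np.nan)
    update[:-1] = circular_distance(predictions[1:], predictions[:-1])
    return delta, update


def _zscore(x, mask):
    mu = x[mask].mean()
    sd = x[mask].std(ddof=0)
    if sd < 1e-10:
        warnings.warn(
            "near-degenerate modulator column (constant across included trials); "
            "centering only",
            stacklevel=3,
        )
        return x - mu
    return (x - mu) / sd


def build_design_matrix(trials: pd.DataFrame, spec: UpdateRegressionSpec) -> DesignMatrices:
    """Assemble the update-regression design from a tidy trial table.

    ``trials`` needs columns ``delta``, ``update``, ``tau``, ``omega``,
    ``condition`` (+1 changepoint / -1 oddball), ``hit`` (+1 blocked / -1
    missed) and ``is_oddball``.  Rows with undefined updates and — when
    ``spec.exclude_post_oddball`` — rows immediately following an oddball
    are masked out; modulators are z-scored across the included rows.
    """
    required = {"delta", "update", "tau", "omega", "condition", "hit"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")

    delta = trials["delta"].to_numpy(float)
    update = trials["update"].to_numpy(float)
    tau = trials["tau"].to_numpy(float)
    omega = trials["omega"].to_numpy(float)
    condition = trials["condition"].to_numpy(float)
    hit = trials["hit"].to_numpy(float)

    mask = np.isfinite(update)
    if spec.exclude_post_oddball:
        if "is_oddball" not in trials.columns:
            raise ValueError("exclude_post_oddball requires an is_oddball column")
        post_oddball = np.zeros(len(trials), dtype=bool)
        post_oddball[1:] = trials["is_oddball"].to_numpy(bool)[:-1]
        mask &= ~post_oddball

    if spec.standardize:
        tau = _zscore(tau, mask)
        omega = _zscore(omega, mask)

    columns = {
        "intercept": np.ones_like(delta),
        "pe": delta,
        "pe_uncertainty": delta * tau,
        "pe_surprise": delta * omega,
        "pe_surprise_condition": delta * omega * condition,
        "pe_hit": delta * hit,
    }
    modulator_of = {
        "pe": np.ones_like(delta),
        "pe_uncertainty": tau,
        "pe_surprise": omega,
        "pe_surprise_condition": omega * condition,
        "pe_hit": hit,
    }
    unknown = [t for t in spec.terms if t not in columns]
    if unknown:
        raise ValueError(f"unknown terms: {unknown}")

    X = np.column_stack([columns[t][mask] for t in spec.terms])
    mods = np.column_stack(
        [modulator_of[t][mask] for t in spec.terms if t != "intercept"]
    )
    return DesignMatrices(
        terms=spec.terms, X=X, y=update[mask], mask=mask, modulators=mods
    )


def _neg_logpost(theta, y, X, prior_prec, fixed_kappa, log_kappa_prior_sd=10.0):
    """Negative log posterior and gradient over (beta, [log kappa])."""
    p = X.shape[1]
    beta = theta[:p]
    kappa = fixed_kappa if fixed_kappa is not None else float(np.exp(theta[p]))
    resid = y - X @ beta
    cos_r = np.cos(resid)
    # log I0(kappa) via the exponentially scaled Bessel for stability
    log_i0 = np.log(special.i0e(kappa)) + kappa
    loglik = kappa * cos_r.sum() - len(y) * (np.log(2.0 * np.pi) + log_i0)
    logprior = -0.5 * float(beta @ (prior_prec * beta))
    grad_beta = kappa * (np.sin(resid) @ X) - prior_prec * beta

    if fixed_kappa is not None:
        return -(loglik + logprior), -grad_beta

    log_kappa = theta[p]
    logprior += -0.5 * (log_kappa / log_kappa_prior_sd) ** 2
    a_kappa = special.i1e(kappa) / special.i0e(kappa)
    grad_logk = kappa * (cos_r.sum() - len(y) * a_kappa) - log_kappa / log_kappa_prior_sd**2
    grad = np.concatenate([grad_beta, [grad_logk]])
    return -(loglik + logprior), -grad


def _candidate_inits(y, X, scale_column):
    """Initial coefficient guesses for the wrap-multimodal posterior.

    Plain OLS lands in a spurious basin when many linear predictions exceed
    pi in magnitude (large updates wrap around the circle and mimic a
    negative surprise slope), so additional candidates fit OLS on the rows
    whose prediction-error column is small enough that no plausible update
    can wrap.
    """
    candidates = [np.linalg.lstsq(X, y, rcond=None)[0]]
    if scale_column is not None and X.shape[1] > scale_column:
        scale = np.abs(X[:, scale_column])
        for thr in (0.6, 0.8, 1.0, 1.2):
            keep = scale < thr
            if keep.sum() >= X.shape[1] + 2:
                candidates.append(np.linalg.lstsq(X[keep], y[keep], rcond=None)[0])
    return candidates


def _refine(y, X, prior_prec, beta_init, fixed_kappa):
    """Two-stage polish: coefficients at a pinned concentration, then joint."""
    resid = wrap_signed(y - X @ beta_init)
    kappa_pin = float(np.clip(1.0 / max(np.var(resid), 1e-4), 0.1, 1e4))
    stage1 = optimize.minimize(
        _neg_logpost,
        beta_init,
        args=(y, X, prior_prec, fixed_kappa if fixed_kappa is not None else kappa_pin),
        jac=True,
        method="L-BFGS-B",
    )
    if fixed_kappa is not None:
        return stage1
    p = X.shape[1]
    x0 = np.concatenate([stage1.x[:p], [np.log(kappa_pin)]])
    bounds = [(None, None)] * p + [(-6.0, 14.0)]
    return optimize.minimize(
        _neg_logpost,
        x0,
        args=(y, X, prior_prec, None),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
    )


def fit_map_circular_regression(
    y,
    X,
    prior_sd,
    n_restarts: int = 5,
    seed: int = 0,
    fixed_kappa: float | None = None,
    terms: tuple[str, ...] | None = None,
    scale_column: int | None = 1,
) -> SubjectFit:
    """Maximize the Von Mises regression posterior over (beta, log kappa).

    The circular likelihood is multimodal whenever linear predictions can
    exceed half a turn, so optimization (L-BFGS-B, analytic gradients) runs
    from several structured initializations — ordinary least squares on all
    rows and on non-wrappable small-|PE| subsets (``scale_column`` names the
    design column whose magnitude drives wrapping; None disables) — plus
    jittered restarts up to ``n_restarts``; the best posterior optimum wins.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows to fit {p} coefficients")
    prior_sd = np.broadcast_to(np.asarray(prior_sd, dtype=float), (p,))
    prior_prec = 1.0 / prior_sd**2

    inits = _candidate_inits(y, X, scale_column)
    rng = np.random.default_rng(seed)
    best = None
    diagnostics = []
    for r in range(max(n_restarts, len(inits))):
        if r < len(inits):
            b_init = inits[r]
        else:
            base = best.x[:p] if best is not None else inits[0]
            b_init = base + rng.normal(0.0, 0.1, size=p)
        res = _refine(y, X, prior_prec, b_init, fixed_kappa)
        diagnostics.append(res.message)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            f"circular MAP regression failed to converge in {n_restarts} restarts: "
            f"{diagnostics}"
        )

    beta = best.x[:p]
    kappa = fixed_kappa if fixed_kappa is not None else float(np.exp(best.x[p]))
    return SubjectFit(
        terms=tuple(terms) if terms is not None else tuple(f"b{j}" for j in range(p)),
        beta=beta,
        kappa_resid=kappa,
        logpost=-float(best.fun),
        n_trials_used=n,
    )


def group_coefficient_test(fits: list[SubjectFit]) -> pd.DataFrame:
    """One-sample two-tailed t-test of each coefficient across subjects."""
    if len(fits) < 3:
        raise ValueError("need at least 3 subjects for a group test")
    terms = fits[0].terms
    if any(f.terms != terms for f in fits):
        raise ValueError("all fits must share the same term list")
    betas = np.vstack([f.beta for f in fits])
    n = betas.shape[0]
    mean = betas.mean(axis=0)
    sem = betas.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sem > 0, mean / np.where(sem > 0, sem, 1.0), np.where(mean == 0, 0.0, np.inf) * np.sign(mean))
    dof = n - 1
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame(
        {"term": terms, "mean": mean, "sem": sem, "t": t, "dof": dof, "p": p}
    )


def predicted_learning_rate(fit: SubjectFit, modulators: np.ndarray) -> np.ndarray:
    """Coefficient-weighted multiplier of the prediction error per trial.

    ``modulators`` is the matrix from :class:`DesignMatrices` (one column per
    non-intercept term); the predicted update is ``pred_lr * delta`` plus
    the intercept.
    """
    modulators = np.asarray(modulators, dtype=float)
    slopes = fit.beta[1:] if fit.terms[0] == "intercept" else fit.beta
    if modulators.shape[1] != len(slopes):
        raise ValueError("modulator columns must align with non-intercept terms")
    return modulators @ slopes
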