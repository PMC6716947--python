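# cannonlearn

Tools for studying how people adapt their *learning rate* to statistical
context in circular predictive-inference ("cannon") tasks, and how
feedback-locked EEG signals relate to that adaptation.

In the task, a hidden cannon shoots at a circle and the subject places a
shield where they predict the next cannonball will land.  Two contexts share
the same rate of rare events (hazard `H = 0.14`) but give them opposite
meanings.  In the **changepoint** context the cannon's aim is stationary but
occasionally re-aims uniformly at random, so a surprising outcome signals
that old beliefs are obsolete and learning should *increase*.  In the
**oddball** context the aim drifts slowly while occasional outcomes are
drawn uniformly and carry no information, so a surprising outcome should be
*ignored*.  The package provides:

- **`task`** — the generative model: Von Mises outcome noise (κ = 10)
  around the aim, uniform re-aiming with hazard 0.14 (changepoint) or a
  Von Mises random walk (κ = 30) with 0.14 uniform oddballs, in sessions of
  4 blocks × 60 trials; shield-hit scoring.
- **`learner`** — a reduced Bayesian observer that collapses the full
  posterior over the aim into one Gaussian belief.  Its learning rate
  combines *relative uncertainty* τ (the share of predictive variance due
  to not knowing the aim; a Kalman-gain analogue) with the posterior
  rare-event probability Ω:

  ```
  oddball:      α = τ(1 − Ω)          (surprise suppresses learning)
  changepoint:  α = Ω + τ(1 − Ω)      (surprise amplifies learning)

  Ω = (H/2π) / (H/2π + (1 − H) N(δ; 0, σ_N²/(1 − τ)))
  σ_μ² = Ω σ_N² τ/(1−τ) + (1−Ω) σ_N² τ + Ω(1−Ω)(δτ)² + σ_drift²   (oddball)
  τ' = σ_μ² / (σ_μ² + σ_N²)
  ```

  driven by the observed prediction errors δ, so it can condition on a
  subject's own predictions.
- **`regression`** — trial-wise update regression with Von Mises errors:
  updates are modeled as δ times a learning rate that varies with z-scored
  uncertainty, z-scored surprise (Ω), surprise × condition, and hit
  feedback, fit per subject by MAP (Gaussian priors, SD 5) with group-level
  t-tests.
- **`cluster`** — mass-univariate GLM over channel × time epoch arrays,
  surprise (changepoint + oddball) and learning (changepoint − oddball)
  contrasts, spatiotemporal clusters above a t threshold (forming
  p = 0.001), cluster mass = mean |t| × size, and sign-flip max-mass
  permutation correction (exact enumeration when 2^n ≤ n_perm).
- **`link`** — single-trial EEG signal strength (dot product of a cluster's
  t map with each trial's epoch, z-scored), *direct* (PE × EEG) and
  *conditional* (PE × condition × EEG) learning regressions with SD-0.1
  priors on EEG terms, a 40 ms sliding-window variant over 300–700 ms with
  8 ms Gaussian smoothing and a temporal cluster test, and binned
  learning-rate profiles.
- **`synthetic`** — agents and ERP-like epochs with planted, recoverable
  structure (including a conditional EEG gain whose sign flips with
  condition), cohort builders, and a reader for behavioral/EEG exports.

## Worked example

```python
import numpy as np
from cannonlearn import (TaskConfig, generate_session, LearnerParams,
                         run_learner, UpdateRegressionSpec, build_cohort,
                         build_design_matrix, fit_map_circular_regression,
                         group_coefficient_test)

# one oddball session and its normative belief trace
session = generate_session(TaskConfig(condition="oddball", rng_seed=3))
trace = run_learner(LearnerParams(), "oddball", session=session,
                    initial_prediction=float(session.aim[0]))
print(f"{session.is_oddball.mean():.3f}")      # 0.154  (oddball fraction)
print(f"{trace.alpha[session.is_oddball].mean():.3f}")   # 0.088
print(f"{trace.alpha[~session.is_event].mean():.3f}")    # 0.451
# surprising outcomes get *lower* learning rates in the oddball context

# recover planted regression structure from a small synthetic cohort
cohort = build_cohort(n_subjects=10, master_seed=5, with_epochs=False)
spec = UpdateRegressionSpec()
fits = []
for sub in cohort:
    dm = build_design_matrix(sub.behavior, spec)
    fits.append(fit_map_circular_regression(dm.y, dm.X, spec.prior_sd,
                                            terms=spec.terms, seed=sub.subject_id))
print(group_coefficient_test(fits).round(3).to_string(index=False))
```

The group table for the planted cohort (true PE slope 0.6, surprise ×
condition 0.7) comes back as:

```
                 term   mean   sem      t  dof     p
            intercept  0.003 0.004  0.580    9 0.576
                   pe  0.582 0.013 46.202    9 0.000
       pe_uncertainty  0.147 0.007 21.302    9 0.000
          pe_surprise  0.008 0.005  1.601    9 0.144
pe_surprise_condition  0.742 0.025 29.970    9 0.000
               pe_hit -0.117 0.014 -8.485    9 0.000
```

A positive `pe_surprise_condition` coefficient is the signature of
context-appropriate learning: surprise increases the learning rate under
changepoints and decreases it under oddballs.

A thin CLI wraps the same functions: `cannonlearn simulate`,
`fit-normative`, `fit-behavior`, `eeg-cluster`, `recover` (see
`cannonlearn --help`).

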