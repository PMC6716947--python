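# Methods

## The generative task

Both conditions run in sessions of 4 blocks × 60 trials on the circle
[0, 2π); all internal angles are radians (positions in [0, 2π), signed
differences in (−π, π]); degrees appear only in CSV files and the CLI.

- **Changepoint**: the aim is held and, with per-trial probability
  `hazard = 0.14` (an i.i.d. Bernoulli; no refractory period — the stated
  value is an *average* hazard and the i.i.d. process is the simplest one
  matching it), re-sampled uniformly.  Outcomes are Von Mises draws around
  the aim with concentration `noise_kappa = 10`.
- **Oddball**: the aim takes a Von Mises random-walk step (concentration
  `drift_kappa = 30`) every trial; with probability 0.14 the outcome is
  uniform on the circle and flagged as an oddball, otherwise Von Mises
  around the aim.

The concentrations are read as dimensionless Von Mises κ (the
"degrees" phrasing sometimes attached to them is treated as loose); both
are configuration fields, so a reading of κ ≈ (180/(10π))² ≈ 32.8 — an
angular SD of 10° — is reachable by overriding `noise_kappa`.  Trial 1 of
a session draws its aim uniformly and never carries an event flag.  The
aim process runs continuously across block boundaries.  Shield half-widths
are drawn uniformly from [5°, 60°] per trial (only "varied in size from
trial to trial" is prescribed; the uniform range is this package's
choice), and a hit is inclusive at the boundary.

## Reduced Bayesian observer

Exact inference would track every possible run length (changepoint) or
oddball history (oddball).  The observer instead collapses the predictive
mixture into a single Gaussian, yielding an error-driven rule with two
latents updated per trial: relative uncertainty τ and rare-event
probability Ω.  Per trial with prediction error δ:

1. Ω from the new δ: `Ω = (H/2π) / (H/2π + (1−H)·N(δ; 0, σ_N²/(1−τ)))`.
   The density is the *linear* (non-wrapped) Gaussian; δ itself is the
   wrapped signed error.  A side effect of the linear density is that
   Ω → 1 as τ → 1 regardless of δ; the observer is intended for the
   post-training regime where τ stays moderate.
2. learning rate: `α = τ(1−Ω)` (oddball) or `α = Ω + τ(1−Ω)` (changepoint).
3. prediction moves by α·δ on the circle.
4. uncertainty propagates:
   - oddball: `σ_μ² = Ω σ_N² τ/(1−τ) + (1−Ω) σ_N² τ + Ω(1−Ω)(δτ)² + σ_drift²`
   - changepoint: `σ_μ² = Ω σ_N² + (1−Ω) σ_N² τ + Ω(1−Ω)(δ(1−τ))²`
   and `τ' = σ_μ²/(σ_μ² + σ_N²)`.

The changepoint expressions mirror the oddball ones term by term: after a
changepoint one outcome is informative (conditional variance σ_N², mean
offset δ(1−τ)), whereas an oddball carries no information (prior variance
σ_N²τ/(1−τ) passes through, mean offset δτ), and only the oddball world
drifts.  Defaults: `σ_N² = 1/noise_kappa`, `σ_drift² = 1/drift_kappa`
(the large-κ Gaussian approximation of Von Mises noise), `tau_init = 0.5`,
τ clipped to [1e−6, 1−1e−6].  Initialization and block handling are not
externally prescribed; the package resets τ at block starts by default
(configurable), and the consistency identity
`σ_μ² + σ_N² = σ_N²/(1−τ')` holds after every update by construction.

The observer is validated against an exact brute-force filter (360-point
grid over the aim, exact event/no-event mixture propagation) on 50-trial
sessions: trial-wise updates correlate above 0.95 in both conditions.  For
that comparison both observers start from a matched informative prior
(Von Mises around the true initial aim, κ = 10, i.e. τ = 0.5), emulating
the instructed-training state; a self-driven oddball observer started from
total ignorance can attribute all of its large errors to oddballs and
stall, which is a property of the approximation, not a bug.

## Update regression

Per trial, `δ = circular_distance(outcome, prediction)` and
`update = circular_distance(next prediction, prediction)`; the final trial
of a session has no update.  Updates following an oddball are excluded by
default (they conflate learning with returning to a pre-oddball position).
The design is δ times: 1, z(τ), z(Ω), z(Ω)·condition, hit, plus an
intercept.  Condition is +1 (changepoint) / −1 (oddball); hit is +1
(blocked) / −1 (missed).  Only the modulators are z-scored (across
included trials, conditions pooled); δ is left in radians so its
coefficient reads directly as a learning rate.  Errors around the
predicted update are Von Mises with concentration κ; coefficients carry
zero-centered Gaussian priors (SD 5 for every term, including the
intercept — whether the intercept was regularized is not externally
prescribed, so it is a switch), and log κ carries a very broad log-normal
prior (SD 10) purely for numerical stability.

MAP fitting maximizes the posterior over (β, log κ) with L-BFGS-B and
analytic gradients.  The circular likelihood is multimodal whenever
|X·β| can exceed π: large planted updates wrap and, from a plain
least-squares start, the optimizer settles in a spurious basin in which
wrapped changepoint updates masquerade as a negative surprise slope.
Optimization therefore starts from several structured candidates — OLS on
all rows and OLS restricted to rows with |δ| below 0.6/0.8/1.0/1.2 rad,
where no plausible update can wrap — each refined in two stages (β at a
pinned κ estimated from wrapped residuals, then jointly), with jittered
restarts up to the requested count and best-posterior selection.  Group
inference is a one-sample two-tailed t-test per coefficient
(dof = n_subjects − 1); zero-SEM degenerate cases report t = ±∞.

## EEG cluster statistics

Epochs are channel × time × trial arrays with 2-D schematic channel
positions; the synthetic default is −200–1000 ms at 500 Hz.  Baseline
correction subtracts the per-trial, per-channel mean over −100–0 ms and is
applied uniformly before the GLM (externally only the sliding-window
analysis names a baseline; using one throughout is this package's choice).
The trial series at each (channel, time) is regressed by OLS onto
intercept, changepoint (0/1), oddball (0/1), condition (±1) and block/hit
(±1; the external coding of this regressor is unstated).  Surprise and
learning contrasts are the sum and difference of the changepoint and
oddball coefficients.  Channel adjacency defaults to a Delaunay
triangulation of the positions with edges longer than 1.5× the median
removed (no spatial rule is externally prescribed; a distance-threshold
fallback covers degenerate layouts, and explicit neighbor lists can be
supplied).  Temporal adjacency links consecutive samples only.  Clusters
are same-sign connected components of |t| > t(dof)-quantile points
(two-tailed forming threshold, default p = 0.001); mass is mean |t| ×
size, i.e. the sum of |t| over members.

Sign-flip permutation flips whole per-subject contrast maps, recomputes
the group t map (vectorized via the flip-invariant sum of squares, in
memory-bounded chunks) and records the maximum cluster mass.  With
2^n_subjects ≤ n_perm all sign patterns are enumerated and p-values are
exact fractions (the identity pattern guarantees p ≥ 2^−n); otherwise
Monte-Carlo sampling uses the +1-corrected estimate (1 + #exceed)/(1 +
n_perm), which can never be zero.  Ties between the observed and permuted
masses are counted with a 1e−9 relative tolerance so the identity flip
always registers as an exceedance.  Family-wise error of the whole
procedure is calibrated on null cohorts in the acceptance suite.

## EEG–behavior linkage

Trial signal strength is the dot product between a cluster's t map
(restricted to member points, zero elsewhere) and the trial's
baseline-corrected epoch, z-scored across trials.  The link regression
reuses the circular MAP machinery on intercept, δ, δ × strength (direct
learning) and δ × condition × strength (conditional learning), with
Gaussian priors of SD 0.1 on the EEG terms.  When the behavioral model's
predicted learning rate is included as δ × pred(LR), its prior is SD 1 —
ten times weaker regularization — so shared variance is preferentially
explained by the behavioral prediction.  The sliding-window variant masks
the *unthresholded* surprise t map with 40 ms windows over 300–700 ms
(step = one sample by default; the step is not externally prescribed),
z-scores per window (a global z-score is one switch away), smooths
per-subject coefficient series with a Gaussian kernel (SD 8 ms, reflected
edges, truncated at 4 SD) and applies the same cluster-mass sign-flip test
on the single temporal dimension with forming threshold p = 0.05.  Binned
learning-rate profiles quantile-bin trials by strength within condition
and fit per-bin least-squares slopes of update on δ.

## Synthetic data and what it does (not) show

Agents either follow the normative policy (update = α·δ plus Von Mises
motor noise, κ = 10 by default, ≈ 18° SD — a realistic level of
trial-to-trial response variability) or carry planted regression
structure: update = (Σ β_j·modulator_j + g·γ_t·condition)·δ + noise, with
γ_t ~ N(0, 1) i.i.d. the same per-trial gain that scales their ERP
template (no autocorrelation — a documented simplification).  Agents start
each session predicting near the true aim (Von Mises draw, κ = 10),
emulating the instructed-training phase.  Because the planted coefficients
live on the z-scored modulator scale while generation must proceed
sequentially, generation standardizes with frozen reference moments of τ
and Ω (mean of per-subject sample moments over regression-included trials,
conditions pooled — exactly the set the fit standardizes over), calibrated
once by damped fixed-point iteration over long simulated cohorts:
τ ~ (0.4816, 0.1460), Ω ~ (0.327, 0.3885).  The fit re-standardizes with
sample moments, so residual mismatch appears as (unbiased) per-subject
noise, not bias.

Epochs are sums of Gaussian space × time components — frontocentral
peaking at 350 ms and parietal at 500 ms, echoing an anterior-to-posterior
outcome-locked positivity — scaled by (1 + 0.5·event) and (1 + γ_t), plus
white noise (SD 1, i.e. SNR ≈ 1 at the template peak), on a deterministic
schematic montage (32 channels by default; tests use 8–16 for speed).
Cohorts derive per-subject seeds from one master seed via a seed sequence
and are byte-identical under the same master seed.

Passing recovery tests on these data show that the estimators are
unbiased and calibrated *under the generator's assumptions*: white
uncorrelated noise, a known template, i.i.d. gains, and agents that obey
the regression model.  They do not show robustness to real EEG features —
1/f noise, artifacts, autocorrelated gains, between-subject template
variability — nor do they reproduce dataset-specific cluster masses, which
depend on real preprocessing.

One structural finding from the recovery studies is documented here
because users of the conditional-linkage pipeline will encounter it: with
the multiplicative epoch gain ((1 + surprise_mod·event)(1 + γ)), the
cluster dot-product readout of γ is systematically diluted on event
trials — which carry the largest prediction errors and hence most of the
regression leverage — and the SD-0.1 prior shrinks the estimate further,
so a planted conditional gain of 0.1 is recovered as ≈ 0.075–0.078
(detection is unaffected; the null stays clean).  An additive event
modulation would remove most of this attenuation.

## Problem sizes and numerical choices

The acceptance suite runs 100 replicate behavior-only cohorts of 30
agents for regression recovery, 200 null cohorts (12 subjects, 8 channels
× 50 samples, 500 flips) for FWER calibration, and 13 EEG cohorts of 30
subjects on a 16-channel montage for the conditional-linkage study; the
generative-statistics script simulates 100,000 trials per condition.
These sizes give Monte-Carlo error well inside each check's tolerance.
Degenerate inputs are handled explicitly: constant modulator columns warn
and are centered only; zero-variance group tests report infinite t;
empty suprathreshold sets return empty cluster lists; empty strength bins
raise.  log κ is bounded in [−6, 14] during optimization; Bessel terms use
exponentially scaled forms.
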