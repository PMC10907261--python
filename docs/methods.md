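# Methods

## The experimental design being simulated

One synthetic participant completes three sessions on a 0–100 "how bad do
you feel" scale:

1. **Baseline** — 18 painful and 12 non-painful videos of a recipient,
   rated without any social information.  The mean painful-trial rating
   defines the participant's empathy anchor `Empathy_t0`.
2. **Observational learning** — 4 blocks × 12 trials (9 painful + 3
   non-painful per block; 48 trials, 36 painful).  Each trial: predict the
   demonstrator's rating, see the demonstrator's rating, rate one's own
   feeling.  Two recipients appear, one per pair of blocks; the recipient
   change coincides with the session midpoint (trial 24), which is also the
   half boundary of the half-split model.
3. **Generalization** — the baseline procedure with a new recipient, probing
   persistence of learned changes.

Demonstrator ratings are algorithmic: painful-trial draws are
Normal(baseline painful mean ± 3·5, SD 5) — plus for the high-empathy, minus
for the low-empathy group — and non-painful draws are Normal(baseline
non-painful mean, SD 5); draws are clipped to [0, 100] and rounded to
integers (a discrete slider).  Within-block painful/non-painful order is a
seeded uniform permutation; 9 + 3 per block is the only integer split
compatible with 36/12 across four equal blocks.

## Models

**Predictions (Rescorla–Wagner).**  With demonstrator rating R_t and
prediction P_t, δ_t = R_t − P_t and P_{t+1} = P_t + α·δ_t, P_1 = p0.
Free parameters: learning rate α ∈ [0, 1], initial prediction p0, Gaussian
response noise σ_pred.  By default the series runs over **all** 48 learning
trials in presentation order (the demonstrator rates both pain levels; a
painful-only option exists).  A consequence worth knowing: the single
prediction value's fixed point is the 9:3 painful/non-painful mixture mean,
so painful-trial prediction errors stay persistently positive for
high-group observers (≈ +12 points) rather than decaying to noise.  This is
what gives the second-half discounted sums enough size and variance to
identify the second-half weights; the painful-only alternative makes PEs
decay to demonstrator noise and leaves the half-split weights nearly
unidentifiable.

**Empathy ratings (discounted prediction-error family).**  The modeled
series is the 36 painful learning trials.  With sign-restricted discounted
sums S_sign(t) = Σ_{τ≤t} γ^{t−τ} δ_τ (positive / negative δ only; the
current trial's δ included, since observation precedes self-rating within a
trial):

* `M1_single`:             E_t = Empathy_t0 + W·S_all(t)
* `M2_signsplit`:          E_t = Empathy_t0 + W_pos·S_pos(t) + W_neg·S_neg(t)
* `M3_signsplit_halfsplit`: as M2 with (W1_pos, W1_neg) while t ≤ 24 and
  (W2_pos, W2_neg) afterwards.  The sums are continuous across the boundary;
  only the weights switch.

γ ∈ [0, 1] is shared across signs and halves (γ = 0 keeps only the latest
PE, γ = 1 weighs all equally).  `Empathy_t0` is fixed to the participant's
realized baseline painful mean, not fitted.  M1 and M2 are the natural
ablations of the half-split model; the published family's exact supplementary
equations were not available, so this reconstruction from the main-text
description should be treated as such.

## Fitting, evidence, model selection

Per participant, parameters are fitted by minimizing the negative log
posterior (LPP) in an unconstrained space (logit for α and γ, log for noise
SDs, identity for weights), with priors α, γ ~ Beta(1.1, 1.1), weights
~ Normal(0, 2), p0 ~ Normal(baseline mean, 10), log σ ~ Normal(log 5, 1).
Ratings are treated as continuous Gaussian observations with no truncation
correction — a deliberate simplification that matters for ceiling-clipped
subjects (below).  Optimization is multi-start L-BFGS-B (10 restarts drawn
from the priors plus one fixed start); richer update models additionally
warm-start from the embedded MAP solutions of their nested siblings, so a
richer model never fits worse in practice.

The log model evidence is approximated by Laplace:
LAME = log p(y, θ̂) + (k/2)·log 2π − ½·log det H, with H the central
finite-difference Hessian (relative step 1e-4) of the LPP at the MAP in the
transformed space.  Non-positive-definite Hessians are eigenvalue-floored at
1e-6 and flagged; in all observed fits, flat likelihood directions carry the
prior's own curvature (e.g. 0.25 for a weight), which is the correct
Bayesian behavior — an uninformed parameter costs ≈ 0 nats.

Group-level selection is random-effects BMS: the standard variational
Dirichlet update over per-subject model assignments (uniform Dirichlet(1)
prior), with exceedance probabilities estimated from 10⁵ Monte-Carlo draws
of the fitted Dirichlet.  A fixed-effects comparison (summed log evidence,
pairwise log Bayes factors) is provided as a diagnostic; protected
exceedance probabilities are not implemented.

## The synthetic observer and what it does (not) emulate

Ground-truth observers forward-run exactly the models above: latent RW
predictions over the demonstrator series (emitted with Gaussian noise, then
clipped), latent M1/M2/M3 empathy trajectories over the painful-trial PEs
(emitted with Gaussian noise, then clipped).  Baseline ratings are drawn
around `Empathy_t0` (painful) and a non-painful anchor (default 15, drawn
from U(10, 20) in cohorts).  Standalone observers default to 8-point
response noise on both series, which reproduces the modest fit quality of
real data (r² ≈ 0.2 for both predictions and empathy ratings); the recovery
harness (`CohortPriors`) uses 5-point noise on both series, the regime in
which recovery behavior is assessed.  Cohort ground truth is drawn as
α ~ U(0.1, 0.7), γ ~ U(0.3, 0.95), active weights ~ U(0.2, 1.0) with the
group-atypical (wrong-sign) weights fixed at 0, Empathy_t0, p0 ~ U(35, 65).

The update models say nothing about post-learning trials, so generalization
ratings persist at the learning-session average of the latent trajectory —
a generative choice emulating the empirically observed persistence (a
literal model extrapolation would decay back to baseline once PEs stop).
Helping time changes as 0.5 min per point of latent empathy change plus
8-minute noise (population rank correlation ≈ 0.35), and perceived pain
intensity as 0.07 points per point plus 0.8 noise.

Features of real data deliberately **not** emulated: response granularity
(participant ratings are continuous, only demonstrator ratings are integer),
missed responses, session-order and habituation effects, any demonstrator
impression dynamics, and rating-scale end-aversion.  Passing tests therefore
certify the machinery, not the psychology.

## Known limitations (measured, at seed 0)

* **Ceiling clipping.**  Under the prior ranges above, high-γ/high-W
  observers accumulate discounted sums of 80–150 points, pushing the latent
  empathy trajectory far past 100; about a third of cohort subjects have
  ≥ 20% of painful learning ratings pinned at the ceiling.  Because the
  Gaussian likelihood has no censoring term, these subjects' weights are
  compressed: the true-vs-fitted correlation for the active first-half
  weight is 0.70 over all 50 recovery subjects but 0.90 among subjects with
  < 20% clipped trials (α: 0.99, γ: 0.91 regardless).
* **M3 vs M2 margins are structurally small.**  A shared γ lets the
  sign-split model mimic much of the half contrast (lower γ plateaus the
  sums earlier), and subjects drawn with W1 ≈ W2 are genuinely M2-like, so
  the per-subject evidence margin for the half-split model is a few nats at
  best.  Across ten 26-subject cohorts generated from M3, it is the BMS
  winner in 9/10, but its exceedance probability exceeds 0.95 in only 4/10;
  single-cohort XP values range ≈ 0.25–1.0 across seeds.
* **Low-group within-session trend.**  The mixture-mean fixed point of the
  mixed RW series sits *below* the low-group painful demonstrator mean, so
  low-group painful PEs turn positive once predictions converge and the
  discounted negative sums decay; the low group shows the initial drop and a
  negative baseline-to-generalization change, but its within-session OLS
  slope is slightly positive rather than negative.  Sustained within-session
  decline is outside what this model family can generate once PEs decay.
* **M1/M2 near-equivalence.**  With atypical-sign weights at 0 and
  predominantly one-signed PEs, the one-weight model reproduces the
  sign-split model almost exactly; cohorts generated from M2 are therefore
  often selected as M1 (never as M3).
* Per-participant OLS slopes + group t tests replace by-participant
  random-intercept mixed models in the behavioral analyses: directions and
  effect sizes are preserved, exact p-values are not.

## Numerical choices

Box bounds in the transformed space (|logit| ≤ 16, σ ∈ [1e-2, 1e3]) keep the
objective finite; discounted sums and RW recursions are evaluated as linear
IIR filters (`scipy.signal.lfilter`), exact to ~1e-14 against loop oracles.
L-BFGS-B runs with ftol 1e-12 / gtol 1e-9, 500 iterations.  XP ties in the
Monte-Carlo argmax are measure-zero and ignored.  r² is the squared Pearson
correlation between model and observed series (an SSE-based variant is
available); constant series get r² = 0 with a warning.  All cohort
randomness descends from a single master seed through named child
`SeedSequence` streams, so runs are reproducible participant by participant.

Problem sizes used by the recovery harness and test battery — 50 subjects
for parameter recovery, 10 cohorts × 26 subjects for model recovery, 10⁵
Dirichlet samples for XP — are the package's standard desk-scale settings;
the CLI exposes all of them in the run config.
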