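# empathlearn

Computational modeling of the **observational learning of empathy**: how an
observer's empathic response to another person's pain shifts after watching a
demonstrator rate the same events as more (or less) painful than the observer
expected.

The package is aimed at computational-cognitive-neuroscience researchers who
want a tested, reproducible implementation of the full analysis chain for
this class of experiment:

* a **synthetic-data generator** for the three-session design (baseline →
  four-block observational learning → generalization, 0–100 rating scales,
  demonstrator ratings drawn around the participant's baseline mean ± 3·5
  with SD = 5), with ground-truth observers so everything is testable
  without any data download;
* a **Rescorla–Wagner model** of trial-wise predictions of the demonstrator's
  ratings, P_{t+1} = P_t + α·δ_t with observational prediction error
  δ_t = R_t − P_t, fitted per participant by MAP;
* a family of **discounted prediction-error models** of the observer's own
  empathy ratings,

  E_t = Empathy_t0 + Σ_sign W_(half(t), sign) · S_sign(t),
  S_sign(t) = Σ_{τ≤t} γ^{t−τ} δ_τ restricted to positive/negative δ,

  with a single weight (M1), sign-split weights (M2), or sign- and
  session-half-split weights W1_pos, W1_neg, W2_pos, W2_neg (M3);
* **model selection**: Laplace approximation to the log model evidence (LAME)
  per fit, and random-effects Bayesian model selection with exceedance
  probabilities (XP) at the group level, plus a fixed-effects comparison;
* **model-independent behavioral statistics**: per-participant learning
  trends, the pooled PE → Δempathy regression with participant-clustered
  errors, session change scores, and the empathy-change vs helping-time rank
  correlation;
* a **recovery harness** (parameter recovery correlations, model-recovery
  confusion matrices) that closes the loop on the whole machinery.

## Worked example

Simulate one 26-subject high-empathy-group cohort from the half-split model
(M3), fit all three candidate models per participant, and run group-level
model selection:

```python
import empathlearn as el

bms = el.xp_for_generated_cohort(n_subjects=26, seed=7)
for name, xp in zip(bms.model_names, bms.exceedance_probability):
    print(f"{name:24s} XP = {xp:.2f}")
```

prints

```
M1_single                XP = 0.03
M2_signsplit             XP = 0.06
M3_signsplit_halfsplit   XP = 0.92
```

i.e. the generating model is selected with exceedance probability 0.92 — the
probability, under the fitted Dirichlet over model frequencies, that M3 is
the most common generating model in the population.  Single-cohort XP values
vary across seeds at this sample size: subjects whose true first- and
second-half weights happen to be similar are genuinely well described by the
thriftier sign-split model (see `docs/methods.md`).

The same pipeline runs end to end from the shell:

```bash
empathlearn all --config configs/example.yaml --out runs/demo
```

```
wrote 52 participants to runs/demo
fitted 52 participants (0 skipped)
winning model: M2_signsplit (XP = 0.958)
wrote runs/demo/stats_report.json
```

(with both empathy groups pooled at this desk scale, the sign-split and
half-split models compete closely; see the methods note).  The stats report
for that run contains, among others, the mean baseline-to-generalization
empathy change per group (+22.6 points in the high, −3.4 in the low group)
and the Spearman correlation between empathy change and the change in
minutes participants would spend helping (ρ = 0.62 overall, n = 52).

Per-trial data live in a tidy CSV (one row per trial: participant, group,
session, block, trial index, pain level, recipient, demonstrator rating,
prediction, empathy rating), so hand-converted real datasets can be fed
through `empathlearn fit` / `empathlearn stats` unchanged.

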