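# Methods

`labreduce` implements a confidence-based "select and predict" recurrent
model that flags hemoglobin (Hgb) laboratory tests a hospitalized patient is
unlikely to need: tests whose next result the model predicts — with high,
explicitly-learned confidence — to be *normal* (at or above the lower bound
of the age/sex-specific normal range, the LBNR) and *stable* (no drop from
normal to abnormal relative to the previous observed result). Because the
private clinical cohorts such a model is built on cannot be shipped, the
package includes a synthetic inpatient-cohort generator that reproduces the
statistical structure the method assumes, so every component is testable
end to end.

## Data model

An encounter is a sequence of hourly *draws*. Raw events are aggregated to
one draw per (encounter, hour), duplicate measurements within an hour
averaged. The sequence is trimmed to the window [first observed Hgb … last
observed Hgb], capped at 30 draws (keeping the earliest — they carry the
admission context), and zero-padded. Each timestep is a 39-vector: 12 lab
values, 5 vital values, 3 demographic values (replicated), the
time-difference to the previous draw (hours), the Hgb change since the
previous observed Hgb, and 17 observation indicators. Missing analytes are
zero-imputed with indicator 0, so the model can distinguish "absent" from a
measured value.

Cohort filters mirror routine practice for this problem: encounters with any
systolic blood pressure below 90 mmHg (hemodynamic instability) or with
fewer than two observed Hgb results are excluded.

Label rules:

* normality `y_t = 1` iff `v_t >= LBNR(age, sex)`; the boundary counts as
  normal (a config switch flips to strict `>`); only the lower bound is
  used — high-Hgb (polycythemic) results are out of scope;
* stability `z_t = 0` only for a normal→abnormal drop between consecutive
  *observed* Hgb results; abnormal→abnormal and the first observation of an
  encounter are stable. This is the reading consistent with stability
  prevalence being far higher than normality prevalence;
* age bands: [0.5, 7) years → LBNR 10.5 g/dL, [7, 13) → 11.0, adult women
  12.0, adult men 14.0. Ages below 0.5 years are outside the table and are
  rejected.

Continuous feature columns are z-scored with training-set statistics
(computed over observed entries only); the time-difference and Hgb-change
columns are scaled but not centered so 0 keeps its sentinel meaning, and
padding rows stay identically zero.

## Network

A shared LSTM (hidden size 64) reads the full 39-dim inputs. Two
attention-based LSTM layers — a single instance used twice, so their
parameters are shared by construction — read the shared hidden states
concatenated with the original features: the stability branch sees only Hgb
change, demographics, time difference and the observation indicators (the
remaining columns are zero-masked so the shared recurrent weights keep one
input width); the other branch sees everything. Four 2-layer ReLU MLP heads
(hidden 32) produce per-timestep predictions: stability from branch 1;
normality, Hgb value and selection probability from branch 2. Each head
reads its branch's *last prefix hidden state* concatenated with the
*prefix-attention context*: the hidden state carries the up-to-date memory
of the encounter, the attention context re-weights long-range history.
Feeding the heads the pooled context alone starves them of a direct path to
the most recent draw and measurably degrades ranking below even a
single-layer baseline; the concatenation makes the deeper model a strict
superset of that baseline. Sigmoids bound the three probabilistic outputs;
a softplus keeps value predictions positive.

Attention is *causal prefix* feed-forward attention: an unbounded scalar
score `e_k = w·h_k + b` per timestep, softmax-normalized (with a constant
max-shift for numerical range) over timesteps `0..t-1`; the context for
predicting timestep `t` is the weighted sum of those hidden states. The
score map is deliberately not squashed: a bounded score caps the attention
contrast at `e^2` and forces the context towards a prefix average, which
dilutes the most recent draw and empirically caps the achievable prediction
confidence. Padded timesteps get weight zero; the first timestep of an
encounter has an empty prefix, so it has no prediction and is excluded from
every loss, metric and reduction decision. A whole-sequence softmax would
leak future draws into past predictions, which the stepwise reduction
protocol (below) forbids; causality is enforced structurally (a strictly
lower-triangular attention mask) and verified by perturbation tests.

Ablation space: `use_attention=False` replaces the context with the last
prefix hidden state; `use_selection=False` drops the selection head (its
outputs are then treated as always-selected); `vanilla_lstm=True` reduces to
the shared LSTM plus heads.

## Objective

With selection probabilities `p_t`, empirical coverage is
`phi(P) = mean(p_t)` over valid timesteps (observed Hgb with at least one
prior draw), pooled across the encounters of a mini-batch (a per-encounter
averaging mode exists behind a switch; batch pooling stabilizes the
constraint and is the default). The selective risk of a task is the
`p`-weighted mean of its binary cross-entropy, normalized by `phi`. The full
objective is

    L = alpha * [ r(f_Y) + r(f_Z) + lambda * max(0, c - phi)^2 ] + (1 - alpha) * L_aux

with target coverage `c`, `lambda = 32`, `alpha = 0.5`, and `L_aux` the
unweighted mean squared error of the value head over *all* valid timesteps —
the auxiliary task sees non-selected samples too, anchoring the shared
representation against a collapse onto easy samples. Only under-coverage is
penalized: selecting more than `c` costs nothing directly but dilutes the
selective risks. The cross-entropies are the standard negated form (the
objective is minimized). Timesteps with unobserved Hgb are excluded from
every term; input-corrupted timesteps (below) remain targets.

## Training

Adam (lr 5e-3, batch 64 encounters, gradient-norm clip 5), up to 70 epochs
with early stopping (patience 10) on a 10% validation split carved from the
training encounters; one model per target coverage in
{0.75, 0.8, 0.85, 0.9, 0.95, 1.0}. Three optimization choices matter and
are worth recording, because each cures a concrete failure mode observed
during development:

* *Learning-rate scale.* The recurrent network trained on this CPU autodiff
  stack needs a few thousand reasonably-large Adam steps; at lr 1e-3 and a
  few hundred steps the classifier heads provably underfit (they cannot even
  overfit a 60-encounter cohort) and every downstream selective behaviour
  silently degrades.
* *Selection warm-up (8 epochs).* The selective risks weight each sample's
  cross-entropy by `p_t`, so a sample the selector rejects contributes no
  classifier gradient. If selection starts before the heads are calibrated,
  the initially high-loss minority class (normal draws, ~20% prevalence) is
  rejected wholesale and then never learned — a self-reinforcing exclusion
  loop. The first epochs therefore train all heads with plain unweighted
  risks; the selection head joins afterwards.
* *Selection-head pacing.* The head's bias starts at `logit(c)` (training
  begins at the target coverage instead of being shoved there by the
  penalty) and its learning rate is scaled by 0.35: a fast selector lets the
  majority-class risk gradient and the one-sided penalty saturate every
  `p_t` against 1 before the risks can differentiate samples, freezing the
  selector in a region of vanishing sigmoid gradient.

Model selection is two-staged. Early stopping tracks the validation loss
(patience 10). The returned checkpoint is then, among post-warm-up epochs
whose validation loss is within 5% of the best, the one whose *realized
coverage* (fraction of valid timesteps with `p > 0.5`) is closest to the
target. That coverage is estimated as an even blend of the validation-set
rate (small but unbiased) and the rate on a large uncorrupted training pool
of 800 encounters (precise, at most slightly biased by selection-head
overfit): the trained selection probabilities form a dense band near the
threshold, so small-sample coverage estimates are noisy; the held-out split
is never touched. Selecting the snapshot on the coverage gap substantially
reduces the run-to-run variance of held-out coverage.

*Random mask corruption*: each epoch, 10% of observed Hgb inputs are
independently zeroed (value, indicator, and the Hgb-change entries derived
from that value — leaving the true change would leak the hidden value) to
simulate the downstream effect of omitted tests. The corrupted timestep's
own labels stay in the loss; only its use as an *input* to later predictions
is removed.

## Evaluation

Two protocols on held-out encounters. *No-reduction*: one forward pass on
full observations. *Reduction* (the deployment simulation): stepping through
t = 1, 2, …, whenever the model recommends omission — selected
(`p_t > tau`), predicted normal and predicted stable, all at cutoff 0.5 —
the true Hgb at t is zeroed out of all later inputs, exactly as a skipped
test would be absent; gold labels always come from the true values. The
per-metric gap between the protocols is the robustness statistic.

Metrics (prevalence, AUC, AUPRC, accuracy, precision, for both tasks) are
computed over selected timesteps. *Model coverage* is the selected fraction
of predictable timesteps (observed, t >= 1); *reduction rate* is the omitted
fraction of all observed Hgb tests. Value–normality consistency is the share
of predicted-normal selected timesteps whose predicted value clears
`(1 - m/100) * LBNR` for tolerance m in {0, 3, 5, 10}. A threshold sweep
re-runs the reduction protocol over tau in [0.05, 0.95] (step 0.05).
Selection-count monotonicity in tau is guaranteed for a fixed forward pass
(thresholding one score vector); under the reduction protocol different
thresholds induce different input histories, so the sweep's rows are each
internally consistent but only approximately nested.

## Synthetic cohort

The generator's job is to reproduce the statistical structure the method
assumes, not inpatient physiology. Its central design constraint is that
the study conditions — about 19.5% of observed Hgb draws normal, about 9.2%
of draws transitioning from normal to abnormal (i.e. roughly half of all
normal draws are followed by an abnormal one), a reducible fraction of
tests, and an identifiable low-confidence minority for the reject mechanism
to filter out — *jointly force a mixed population*. A homogeneous cohort
cannot satisfy them: if every normal run carried the ~47% per-draw
transition hazard the aggregate rates imply, no Hgb would ever be
confidently predictable and nothing could be reduced. Encounters therefore
fall into four acuity classes:

* **stably normal** (7%): high baseline (LBNR + 1.2), low volatility, zero
  drop hazard — routine monitoring of recovered patients; the draws the
  model can confidently call normal-and-stable, i.e. the reducible tests;
* **chronically abnormal** (12%): low baseline (LBNR − 1.8), low volatility,
  tiny hazard — stable anemia, confidently abnormal, selected but never
  recommended for omission;
* **acute** (76%): near-normal start (LBNR + 0.7), moderate graded
  volatility (log-normal severity), high drop hazard with partial baseline
  reversion (marrow response / transfusion abstraction) — these supply the
  normal→abnormal transitions and a difficulty continuum;
* **erratic outliers** (5%): boundary-straddling baseline, extreme
  volatility, frequent shallow drops — near coin-flip on both tasks,
  instantiating the assumption that the data contain a proportion of
  outliers the selective mechanism should reject.

Mechanics shared by all classes: the baseline moves by drift, discrete drop
events (class hazard × a global hazard scale, capped at 0.95 per draw) and
reversion toward its admission level; AR(1) measurement noise rides on top;
a currently-normal value is clamped at the LBNR unless a drop occurred that
step (or drift is negative), so noise alone never produces a
normal→abnormal transition and the zero-drop, zero-drift configuration is
exactly transition-free. The 11 auxiliary labs are linear in the current
Hgb (correlation 0.3) plus noise around physiologic means; vitals are
stationary noise with SBP clipped at 90 mmHg unless exclusion test-cases
are injected; the CBC panel (Hgb, Plt, WBC) shares one observation mask,
missing for 30% of draws — substantial natural missingness matters, because
the training-time corruption otherwise creates missing-predecessor inputs
that exist only at train time and inflate held-out coverage; with
comparable natural missingness in both phases the selector's "no recent
Hgb" rejection transfers to test. Other labs are missing independently
(~35%), vitals ~10%; first and last draws always carry a CBC. Draw counts
are truncated-geometric (mean 10, in [2, 30]) with geometric inter-draw
gaps (mean 6 h); demographics: 2% pediatric, balanced sexes, five race
codes.

Calibration targets the study prevalences by coordinate bisection: the
transition/prevalence ratio is monotone in the global hazard scale and
nearly independent of the global level offset, the prevalence monotone in
the offset (raw transition counts are *not* globally monotone in the hazard
— occupancy collapses at high hazard — which is why the ratio is the
bisected quantity). The pilot cohort is measured through the real
preprocessing and labeling pipeline; convergence is within 1 percentage
point on the pilot, with fresh-seed generalization limited by
encounter-level Monte-Carlo noise (±1–2 pp at these sizes).

What the generator does not model: transfusions as events, richer inter-lab
covariance than the single Hgb factor, informative missingness, circadian
draw patterns. Passing tests therefore show the method's machinery works
under the assumed structure, not that the clinical performance numbers of
any real cohort would be reproduced.

## Coverage enforcement and its limits

The quadratic penalty pins *mean* selection probability near `c`, but model
coverage is measured as the fraction of `p_t` above 0.5, and the two agree
only when the trained `p` is close to bimodal. Bimodality emerges when the
cohort contains (a) a clearly separable high-loss minority no larger than
the rejectable budget `1 - c` plus (b) a graded difficulty continuum for
intermediate coverage targets — conditions the mixture cohort provides. At
the smallest rejection budgets (c = 0.95) the marginal band can hold the
realized coverage a point or two above target; the original enforcement
claim allows the same ~2 pp band.

## Numerical choices

* The network and loss run on a small reverse-mode autodiff engine written
  on NumPy (`labreduce.autodiff`), gradient-checked against central finite
  differences; LSTM gates use the standard i/f/g/o layout with forget bias
  1; weights are uniform ±1/sqrt(fan-in).
* Cross-entropy probabilities are clamped to [1e-7, 1 - 1e-7].
* Problem sizes: the shipped experiments train on 2000-encounter cohorts
  (80/20 encounter-level split), where the coverage-enforcement behaviour
  stabilizes; smaller cohorts are used for structural tests.
* Determinism: every stochastic step (generation, splits, initialization,
  batching, dropout, corruption) flows from explicit seeds; two runs with
  one seed agree to float tolerance.

## Known limitations

* Training is desk-scale CPU NumPy; minutes per model, not suited to
  cohorts orders of magnitude larger.
* The value head shares its branch with normality/selection; its
  consistency with predicted normality is an emergent property checked by
  the evaluation, not a constraint.
* Reduction rates on the calibrated cohort are a few percent — the stable
  subpopulation size is pinned down by the label-prevalence targets, and
  with it the reducible mass.
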