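# Methods

## Model structure

The simulator is a discrete-time stock-and-flow model with exactly one
patient per tick; "patient visits" are the time unit, so feedback delays
and memory spans are counted in patients seen. The continuous
system-dynamics formulation the model descends from is approximated by
this per-visit discrete equivalent, which is the natural resolution at
which the decision process operates (one decision per patient) and makes
every run bit-reproducible from a single integer seed.

Each visit proceeds in a fixed order: (1) feedback events due this visit
are revealed; (2) remembered errors older than the memory window are
forgotten; (3) regret stocks are recomputed; (4) the threshold is
adjusted; (5) a patient is drawn and the referral decision is made and
classified; (6) if the decision was an error, its future revelation is
scheduled or lost. Revelation precedes the decision so that feedback can
influence the very next patient.

### Assessment

True severity Y and perceived severity X are standard bivariate normal
with correlation ρ. Disorder status is Y > c where c is the upper-tail
quantile at the prevalence; referral is X ≥ T (ties go to referral; a
measure-zero event under the continuous model, fixed for
reproducibility). Assessments are unidimensional and continuous by
assumption — no multi-informant or categorical structure.

### Feedback and regret

Only errors feed back. A committed FP (FN) is revealed after
`fp_delay` (`fn_delay`) visits with probability 1 − `fp_loss`
(1 − `fn_loss`); otherwise the physician never learns of it. Delays are
fixed constants rather than distributions, since the published values are
single numbers (50 and 250 visits). A revealed error enters the
physician's memory with influence 1, decaying linearly to 0 over
`memory_window` visits. The FP regret stock is the sum of decayed
influences of known FPs; the FN stock is the same sum over known FNs
multiplied by the FN regret weight w. Known errors influence the
threshold continuously while remembered (not as one-off impulses),
matching the linear-fade-of-memory assumption.

### Threshold adjustment

Each visit the threshold moves by

    ΔT = g · (R_FP − w·R_FN) / (R_FP + w·R_FN),

a bounded step (|ΔT| ≤ g) whose direction is set by which error type
currently dominates regret and whose size is the *relative* imbalance.
The normalization is a deliberate design choice. A raw proportional law
ΔT = g·(R_FP − w·R_FN) makes the oscillation amplitude scale with the
sheer volume of revealed errors, so interventions that increase feedback
(cutting FN loss from 73% to 20%, or tripling the regret weight) also
multiply the threshold swings several-fold, collapsing specificity far
below anything observed; no (g, memory) pair stabilizes all intervention
arms at once. Normalizing by total current regret makes the step size
scale-free in feedback volume — a physician's reaction is driven by which
kind of error dominates recent experience, not by the raw error count —
while preserving the qualitative contract: balanced regret leaves the
threshold unchanged, FN-dominant regret lowers it, doubling the gain
doubles the step. The threshold is clipped to ±4 SD, beyond which
referral rates are indistinguishable from 0 or 1.

Stationarity intuition: the threshold stops drifting, on average, where
FP-dominant and FN-dominant episodes balance over time. With the default
asymmetric feedback (FPs revealed quickly and usually, FNs slowly and
rarely) the stock imbalance favors FPs most of the time, punctuated by
sharp FN-driven corrections when a delayed batch of missed cases
surfaces — a sawtooth that keeps time-averaged specificity high while
costing sensitivity, and whose period is governed by the feedback delays.
This waveform, not the fixed point alone, produces the model's
characteristic operating points.

## Parameters

| parameter | default | meaning |
|---|---|---|
| rho | 0.65 | assessment accuracy (corr. of true and perceived severity) |
| prevalence | 0.15 | disorder fraction (upper tail of true severity) |
| fp_loss | 0.20 | P(FP never revealed) |
| fn_loss | 0.73 | P(FN never revealed) — the calibrated parameter |
| fp_delay | 50 | visits until a revealed FP is known |
| fn_delay | 250 | visits until a revealed FN is known |
| fn_regret_weight | 3 | regret per known FN relative to a known FP |
| adjustment_gain | 0.003 | max threshold step per visit (severity SD) |
| memory_window | 120 | visits for a known error's influence to fade to 0 |
| initial_threshold | Youden | starting threshold (Youden point for rho) |

`adjustment_gain` and `memory_window` have no published counterparts;
they are structural constants of this implementation, fixed once by
design calibration: the gain keeps the per-visit step small relative to
the severity scale (full drift across one FP-feedback delay ≤ 0.15 SD),
the memory window lies between the two feedback delays, and within those
ranges the pair was chosen so that the calibrated model jointly
reproduces the published base case and intervention results, then frozen.
They are recorded in every run manifest. The initial threshold defaults
to the Youden-index cut for the configured accuracy so burn-in starts
from a neutral screening operating point; with 2000 burn-in visits the
measured window is insensitive to this choice.

## Calibration

`fn_loss` (and optionally the structural constants) are fit by minimizing
the sum of squared differences between replicate-averaged window
sensitivity/specificity and the review targets (38.7%, 87.7%), following
the published procedure of adjusting FN loss to follow-up until model
output best matches the review. Every objective evaluation uses the same
replicate seed set (common random numbers), so calibration is a
deterministic function of its options; the optimizer is derivative-free
(coarse grid, then Nelder–Mead polish in a bounded box), appropriate for
a noisy simulation objective. Default evaluation: 20 replicates of 2000
burn-in + 3000 measured visits — about 450 diseased patients per run,
giving roughly ±0.5 pp standard error on mean sensitivity.

The model is deliberately underspecified: many (fn_loss, gain, memory)
combinations fit about equally well (the SSD valley along fn_loss is
flat within ~0.73–0.80). The suite therefore asserts an objective
ceiling, not uniqueness, and downstream analyses carry scenario
ensembles — the plausible ranges FP loss 10–60%, FN delay 1–5× FP delay,
regret weight 1–5, each crossed with the review's point estimate and its
95% CI bounds, each scenario recalibrated in fn_loss. The CI-bound
calibrations contribute most of the ensemble spread; sweeps run over the
range corners plus CI targets by default (the full 4×4×4×3 grid of 192
scenarios is available and is what `build_scenarios()` returns).

## Experiments

Virtual experiments apply the published overrides to the calibrated base
case on matched replicate seeds: (1) accuracy ρ 0.65→0.85, (2) FN loss
73%→20%, (3) FN regret weight 3→10, (4) all three. The screening
application is experiment 1 reported differently: referrals as a share of
the analytic screen-positive rate at the ρ=0.85 Youden threshold, and the
referral-rate relative risk against baseline. Relative risks always use
common seeds across arms (variance reduction for ratio estimates).
Threshold levels are compared on the threshold-probability scale,
P(disorder | score = threshold): the severity scale changes meaning when
ρ changes (the same numeric threshold corresponds to different evidence),
whereas the probability scale is the clinically interpretable one — on
it, the accuracy intervention makes physicians strictly *stricter* even
though referrals barely move.

Case-study recalibrations fit a published baseline referral rate instead
of sensitivity/specificity: the suicide-screening study (regret weight 1,
fn_loss calibrated to a 0.8% baseline referral rate, then ρ→0.85, then
regret→5.5) and the co-located-services study (fn_loss 80% giving a
~10–11% baseline rate, then ρ→0.85, then prevalence→25% with regret→8).

Oscillation is summarized by post-burn-in variance of the
threshold-probability trajectory, the dominant autocorrelation lag (first
local maximum of the ACF after its first sign change — the period of the
dominant cycle), and half the peak-to-trough range of a lightly smoothed
copy.

## Numerical choices

- Orthant probabilities of the bivariate normal come from scipy's exact
  bivariate CDF (machine precision in 2D), never Monte Carlo; Monte Carlo
  appears only as an independent oracle in tests.
- Youden and equal-error thresholds are found by bounded scalar
  optimization / Brent root finding on [−4, 4] to ~1e-8.
- Replicate sets are seeded seed, seed+1, …, seed+R−1; cross-seed
  summaries average per-run proportions, while within a run the
  proportions pool the whole measurement window.
- Degenerate inputs are errors, not silent results: rho=0 has no Youden
  maximizer; rho=1 has no conditional threshold probability; a
  measurement window with no diseased (or no healthy) patients raises an
  insufficient-sample error.
- Trajectory CSVs carry 17 significant digits; re-reading them with an
  exactly-rounding float parser reproduces the arrays bit-for-bit.

## What the simulations do and do not show

The engine generates its own data by construction (severities, feedback
losses), so passing tests demonstrate internal consistency with the
bivariate-normal assessment model and the stated feedback mechanism —
not that real referral processes behave this way. Real clinical data
would add physician heterogeneity, non-normal severity, correlated
patients, capacity constraints on referral services, and cognitive
mechanisms (hindsight bias, dual-process effects) that are all outside
this model's scope, as are multi-physician interaction and audit or
lawsuit shocks.

## Known limitations

- **Regret-theoretic indifference is not exactly recovered.** The weight
  w = (1−p)/p computed at the equal-error threshold probability should,
  under regret theory, equalize long-run sensitivity and specificity
  given symmetric feedback. In this engine the long-run threshold settles
  where the *time pattern* of FP- versus FN-dominant regret balances, not
  where expected regret magnitudes balance; because FN errors are several
  times rarer as events than FP errors near the equal-error point, the
  threshold sits systematically above the indifference point and
  sensitivity falls short of specificity by ~6–9 pp. A variant law that
  balances magnitudes (normalizing by a slow moving average of total
  regret) passes this check but no longer reproduces the published
  operating points; the trade-off is intrinsic to the bounded-step
  design and documented rather than hidden.
- **Weak response to the regret weight at extreme loss.** When nearly all
  FN feedback is lost (fn_loss → 1), the regret weight multiplies an
  almost-empty stock, so raising it has little effect — the suicide
  case study's final stage (regret 1→5.5 on a 99%-loss baseline) yields
  ~2.7× baseline referrals here rather than the published ~4.6×.
- The referral-rate change under the accuracy intervention is small and
  seed-dependent (≈0 to −7% across seed sets); its sign usually matches
  the published decline but the magnitude does not pin down to a point.
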