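# dynthresh

A system-dynamics simulator of clinical decision thresholds under
delayed, lossy outcome feedback, with developmental-behavioral screening
in pediatric primary care as the motivating application.

## The problem

Screening trials routinely find that physicians refer only a fraction of
children with positive screens, and that introducing an evidence-based
screener changes referral rates far less — sometimes in the opposite
direction — than expected. Threshold models of clinical decision-making
explain why: a referral decision has two parts, the *assessment* of a
patient's symptom severity and the *decision threshold* the assessment is
compared against. A screening instrument improves assessment accuracy,
but the threshold belongs to the physician, and it moves in response to
regret about known past errors — unnecessary referrals (false positives)
push it up, missed cases (false negatives) push it down. Because feedback
about errors is delayed and mostly lost (families drop out, missed
diagnoses surface years later, if ever), thresholds drift and oscillate,
and interventions aimed at accuracy alone can be absorbed by threshold
adaptation — a classic case of policy resistance.

## The model

One patient arrives per visit. True severity *Y* and the physician's
perceived severity *X* are standard bivariate normal with correlation
ρ (assessment accuracy); a patient has a disorder when *Y* falls in the
upper tail with mass equal to the prevalence (default 15%), and is
referred when *X* ≥ *T*, the current decision threshold. Each visit
yields a TP, FP, TN, or FN.

Errors generate feedback: an FP becomes known to the physician after
`fp_delay` visits with probability 1 − `fp_loss` (defaults 50 visits,
20% lost); an FN after `fn_delay` visits with probability 1 − `fn_loss`
(defaults 250 visits, 73% lost — physicians rarely learn about missed
cases). A known error contributes regret 1 at revelation, decaying
linearly to zero over `memory_window` visits; known FNs are weighted by
the FN regret weight *w* (default 3). Each visit the threshold takes a
bounded step toward the dominant regret,

    T ← T + g · (R_FP − w·R_FN) / (R_FP + w·R_FN),

where R_FP, R_FN are the decayed regret stocks and *g* is the adjustment
gain. Correct decisions generate no feedback: the model is about regret,
per regret theory, not reinforcement.

Thresholds are reported both on the severity scale and as **threshold
probabilities** — P(disorder | score exactly at the threshold), computed
from the conditional normal law of *Y* given *X*. The analytic module
provides the full closed-form signal-detection layer (orthant-probability
sensitivity/specificity, Youden operating points, equal-error weights),
which doubles as an oracle for validating the stochastic engine.

Free parameters without published estimates are set by simulation-based
calibration: the FN loss to follow-up is adjusted until replicate-averaged
sensitivity and specificity best match a systematic review of physician
detection of developmental-behavioral disorders (sensitivity 38.7%,
specificity 87.7%), by sum of squared differences under common random
numbers.

## Worked example

```
$ dynthresh simulate --seed 1 --replicates 5 --out demo
mean sensitivity 46.1%  mean specificity 91.1%  (5 runs)
```

Five replicate runs of the base case (2000 burn-in + 3000 measured
visits each, seeds 1–5). The first run's measurement window contains
214 TP, 207 FP, 2350 TN, 229 FN — sensitivity 48.3%, specificity 91.9%,
referral rate ≈ 14.8%: the physician detects under half of true cases
while staying highly specific, the signature of a threshold pushed up by
asymmetric feedback (FPs are seen quickly and often; FNs late and
rarely). `demo/` holds a per-visit trajectory CSV (threshold, threshold
probability, outcomes, regret stocks), a summary JSON, and a manifest
that reproduces the run bit-for-bit.

Calibration and the virtual experiments run the same way:

```
$ dynthresh calibrate --preset base_case --replicates 20 --seed 1
$ dynthresh experiment --id 1 --seed 11        # screening: rho 0.65 -> 0.85
$ dynthresh experiment --name suicide --seed 11
$ dynthresh sweep --experiment screening
```

The `experiment` subcommand calibrates the base case, applies the
published parameter overrides (increased accuracy ρ=0.85; improved FN
feedback, loss 73%→20%; increased FN regret, weight 3→10; all three
combined), and reports replicate-averaged sensitivity/specificity plus
the referral-rate relative risk against the baseline on matched seeds.

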