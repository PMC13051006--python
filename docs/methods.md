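# Methods

## Task and measures

The package analyses one-to-one face matching experiments in which each of
160 face pairs (16 of them, 10%, identity mismatches) is rated twice on a
6-point same/different confidence scale: once unaided and once with the
output of an automated face recognition (AFR) system. The AFR's raw
similarity lies in [−0.1, 1] with its decision threshold at 0.3; for
display the two sides of the threshold are stretched linearly onto [0, 0.5)
and [0.5, 1], so participants see a 0–1 score with the threshold at 0.5.
Three information regimes are distinguished: *graded* (the displayed
similarity score), *binary* (only the match/mismatch verdict), and *none*
(no aid; unaided ratings only).

Ratings 1–3 are different-decisions and 4–6 same-decisions. A hit is a
"same" response to a match pair, a false alarm a "same" response to a
mismatch pair. Sensitivity and bias follow the standard equal-variance
definitions, d′ = z(H) − z(F) and C = −(z(H) + z(F))/2, computed with
scipy's inverse normal CDF (`ndtri`; agreement with a high-precision
bisection oracle is asserted to 1e-12 in the tests). Rates of exactly 0 or
1 are replaced by 0.5/n and (n − 0.5)/n, where n is that participant's
trial count of the relevant pair type (144 or 16 in the full design, not
the total 160). Overall accuracy always uses uncorrected counts; the
correction touches only z-transformed quantities.

Criterion trajectories split the unaided trials into contiguous quarters of
the presentation order (40 trials each). Because orders are randomized per
participant, a quarter can lack mismatch (or match) trials; such blocks
yield a missing value and cohort means are taken over the defined values
rather than imputing or crashing.

### Change in confidence (CIC)

For unaided rating u and aided rating a, CIC is 0 when a = u,
(a − u)/(6 − u) when a > u, and (a − u)/(u − 1) when a < u: the observed
change divided by the maximum change possible in that direction, bounded in
[−1, 1]. The branch structure makes zero denominators unreachable (u = 6
admits no increase, u = 1 no decrease). Per-pair mean CIC over participants
is regressed (OLS) on displayed similarity, separately for match and
mismatch pairs, whose similarity values occupy disjoint ranges by design.

### Adherence, trust, reliability

Adherence = (acc_aided − acc_unaided)/(1 − acc_unaided). A participant
already perfect unaided has no headroom: the score is 0 if they remain
perfect, otherwise undefined (flagged missing, a 0/0 case) rather than
guessed. The trust scale sums ten 5-point items (range 10–50); no item is
reverse-coded by default — the scale's published form does not mark any —
but `reverse_coded` indices are accepted and configurable in the pipeline.
Cronbach's α uses sample variances (denominator n − 1). Split-half
reliability of pair-level rating profiles averages the Pearson correlation
between random half-cohorts' per-pair means over 100 seeded splits, with no
Spearman–Brown correction; both choices are configurable.

## Inferential statistics

The 2 × 2 mixed ANOVA (Aid within-subject, Experiment between-subject) is
computed by the split-plot decomposition: subject means carry the
between-group comparison, within-subject half-differences carry the aid
effect and the interaction. Effect sums of squares are Type III under
sum-to-zero contrasts — the convention of mainstream psychology software —
so with unbalanced groups the aid effect tests the unweighted average of
the group mean changes. Partial η² is SS_effect/(SS_effect + SS_error)
with the error from the matching stratum. Degenerate inputs (zero error
variance) yield flagged NaN rather than an arbitrary F. The implementation
is plain OLS algebra; tests verify it against an independently coded
balanced-design cell-means oracle, against `pingouin.mixed_anova` on
balanced data, against Type III model-comparison sums of squares computed
with `lstsq` on unbalanced data, and against a 1000-replicate null
simulation (type-I error and p-value uniformity).

Cross-cohort comparisons of the unaided criterion use unpaired Welch t
tests (Welch–Satterthwaite df, pooled-SD Cohen's d): the cohorts are
independent samples, so pairing has no basis even though the same face set
is shared. All p values are two-sided. Correlation tables report Pearson r,
with Spearman ρ (mid-rank ties) alongside for AFR-similarity rows, and
split-half reliabilities on the leading diagonal.

## The generative model

The simulator exists to give every pipeline stage a testable input with
known ground truth, and to reproduce the study's qualitative phenomena —
not to fit any particular dataset.

**Face set.** Exactly round(n_pairs × prevalence) mismatches. Latent
human evidence θ ~ N(d_true, τ²) for matches and N(0, τ²) for mismatches,
with d_true = 1.5 and τ = 0.5 (observer-noise units). The AFR raw score is
0.3 + 0.7·σ(k(θ + ζ)) for matches and −0.1 + 0.4·σ(k(θ + ζ)) for
mismatches, ζ ~ N(0, 0.8²), k = 0.6: the simulated AFR is 100% accurate at
the 0.3 threshold by construction, and the θ–score correlation on match
pairs lands near the 0.5 target (the latent correlation τ/√(τ² + 0.8²) ≈
0.53 minus a little sigmoid compression). Ethnicity labels
(White/Black/Asian/Mixed-Other at 0.54/0.14/0.21/0.11) are carried as
metadata only; no other-ethnicity effect is modelled.

**Unaided ratings.** Evidence e = θ + N(0, 1) is read off five ascending
cutpoints, base values (−1.0, −0.1, 0.75, 2.0, 3.5). The middle cutpoint
bisects the two evidence means so the starting binary criterion is ≈ 0.
The outer cutpoints are deliberately wide: unaided observers rarely commit
to a "definitely" response, which keeps headroom at both scale ends. This
matters for the CIC score — if unaided ratings saturate at 6, CIC is forced
to 0 there, and a spurious negative similarity–CIC relation appears in the
binary regime that the graded/binary contrast is supposed to isolate.

**Criterion drift.** All cutpoints shift down together by
drift_max·(1 − exp(−t/drift_tau)) at 0-based trial index t, a saturating
exponential: the fast-then-flat shape seen in binary-feedback trajectories.
Defaults: drift_max = 0.6, drift_tau = 20 trials under binary feedback;
0.25 and 120 under graded feedback. The *none* regime (no aid shown) uses
the binary constants: prevalence, not the aid itself, drives the drift —
empirically the unaided cohort's criterion is statistically
indistinguishable from the binary cohort's — and the graded score is what
tempers it.

**Aided ratings** are generated from the unaided rating (not re-sampled
evidence) so CIC has a well-defined generative meaning: graded shift
w_graded·2·(displayed − 0.5) with w_graded = 2 (zero at the threshold,
signed toward the AFR's side); binary shift ±w_binary with w_binary = 1;
plus N(0, 0.8) jitter, rounded and clipped to 1–6.

**Calibration.** The study's figures give no numeric anchors for the
unaided d′ or the drift magnitudes, so all constants were calibrated only
to the orderings the phenomena require — binary criterion more liberal than
graded, aided d′ above unaided in both regimes, match-pair CIC–similarity
r strongly positive under graded and near zero under binary, and a larger
quarter-1→2 criterion drop under binary — and then frozen. They are not
estimates of any dataset's parameters.

**What the generator does not emulate.** Individual differences in trust
and self-insight (questionnaire columns are exchangeable noise; the
participant-level correlation structure of real cohorts is absent),
response times, other-ethnicity effects, attention-check behaviour
(synthetic data are post-exclusion by construction), and any dependence of
observer noise on pair difficulty beyond the latent θ. Passing tests
therefore demonstrate correctness of the measures and statistics and the
qualitative mechanics of prevalence-driven bias — not quantitative fidelity
to any human cohort.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of 100–200 participants. The d′
parameter-recovery check compares the cohort mean of per-participant d′
(drift off, 200 participants) with the value obtained by numerical
integration over the pair distribution; because one face set contains only
16 mismatch pairs, a single experiment's cohort mean carries ≈ 0.13 SD of
pair-sampling noise, so the estimate averages 24 replicate face sets,
bringing the Monte-Carlo error well under the 0.1 recovery tolerance. The
small positive bias (≈ +0.03) that remains is the familiar convexity bias
of z applied to 16-trial false-alarm estimates, shared by any empirical
study of this design. Type-I-error calibration of the aid effect uses 1000
null replicates at the 54/56 group sizes of the two-cohort design.

Exclusion rules mirror the study protocol: familiarity with the (Polish)
match stimuli, both attention checks failed (one failure is tolerated;
judged on the unaided rating), completion time outside 7–60 minutes,
incomplete or duplicated sessions. Attention-check trials are stripped from
included participants' data before any computation. The canonical trial CSV
dialect is documented in `afrmatch.pipeline`; real exports are expected to
be mapped onto it by the user rather than guessed at.

Known limitations: the mixed ANOVA is specialised to the 2 × 2 design (two
within levels, two groups) rather than general factorial structures; the
drift model is phenomenological (a saturating exponential, not a
trial-by-trial criterion-updating process); and the aided-rating rule is a
shift on the rating scale, not a Bayesian combination of evidence with the
AFR's likelihood.
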