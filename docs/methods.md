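# Methods

This note documents the generative model behind the synthetic studies, the
statistical machinery of each analysis stage, the numerical conventions, and
what the test suite does and does not establish.

## Study design encoded in the defaults

A study has 24 participants, two languages per participant (native,
unfamiliar; order irrelevant in the model), 4 talkers × 10 sentences per
language, four training blocks plus one test block of 40 trials each (every
sentence × talker stimulus once per block, order shuffled), and left-eye
pupil area sampled at 1000 Hz from −500 to 4000 ms around stimulus onset.
The test block reuses the final training-block parameters but presents novel
sentence identities; sentence identity itself carries no effect, matching
analyses that ignore it.

## Generative model

**Talker acoustics.** Each talker is six independent draws (mean F0 ~
N(180, 40) Hz, F0 range ~ N(60, 20) Hz, speech rate ~ N(4.5, 0.8) syll/s,
jitter ~ |N(1.2, 0.4)| %, harmonicity ~ N(12, 3) dB, formant dispersion ~
N(1000, 150) Hz). Both languages use identical settings, so their
between-talker distance distributions are exchangeable by construction. The
acoustic similarity matrix (ASM) is the negated pairwise Euclidean distance
over z-scored features; for drift construction it is rescaled to σ ∈ [0, 1]
with σ(s, s) = 1.

**Decisions.** Accumulator *d* for stimulus *s* in block *t* has drift

μ_{d,s,t} = μ₀ + g(language, t) · [ w·1{d=s} + (1−w)·σ(d, s) ]

with drift floor μ₀ = 1, constant threshold b = 1.5, and non-decision offset
δ = 0.35 s. The cue weight *w* sets how much responding reflects talker
identity versus raw acoustic similarity: native w = 0.8, unfamiliar w = 0.2.
Passage times are exact inverse-Gaussian draws; the response is the argmin.
Per-participant heterogeneity multiplies the gain term by a lognormal(0,
0.12) factor drawn independently per language.

**Gain schedules.** Native g = (1.5, 2.05, 2.45, 2.7); unfamiliar
g = (1.26, 1.79, 2.19, 2.44). The unfamiliar schedule was calibrated by
quadrature on the analytic minimum-passage-time distribution so that the
expected log RT matches the native language in every block: in a race, the
unfamiliar language's stronger off-diagonal competitors speed the minimum
even though its target drift is lower, so speed is traded for accuracy, not
time. This realizes the design's "no RT language effect" condition while the
native language keeps a larger correct-choice drift margin (and hence higher
accuracy and a steeper logit-scale learning slope) in every block.

**Pupil traces.** trace(t) = B_p · (1 + (A/100)·h(t) + ε(t)) after onset and
B_p · (1 + ε) during baseline, with participant baseline B_p ~ N(1000, 100)
a.u., the conventional Erlang-family impulse response h(t) =
(t/t_max)^n · exp(n(1 − t/t_max)) with n = 10.1, t_max = 930 ms (unit peak),
and AR(1) noise (φ = 0.97 at 1000 Hz, stationary SD 1.5%). The response
amplitude is inversely tied to decision efficiency, A = max(0, a₀ − a₁ ·
μ_{s,s,t}), with per-language coefficients (native a₀ = 26, a₁ = 4;
unfamiliar a₀ = 34, a₁ = 6). The per-language coupling — echoing the
empirically larger EA-rate coefficient magnitude in the native language of
published fits — is what lets the pupil gap between languages shrink over
training even though the native language's drift grows faster. Blinks arrive
as a Poisson process (0.23 events/s; lognormal durations, median 250 ms,
σ = 0.5) and mask samples as missing; 0.23 Hz makes the strict 15% screen
reject ≈12% of trials.

## Analysis stages

**Accuracy models.** Logistic mixed models (training: language × centered
block; test: language) with per-participant random intercept and slopes,
native language as treatment-coded reference. statsmodels has no
maximum-likelihood logistic GLMM with random slopes, so estimation uses its
variational-Bayes `BinomialBayesMixedGLM`; posterior means/SDs serve as
estimates/SEs, which at thousands of trials per cell are indistinguishable
from ML for the purposes here. Single-df fixed factors get Type III Wald χ²
= z².

**RT models.** Linear mixed models of log RT via statsmodels `MixedLM`
(ML, not REML), after excluding trials whose |log RT − cell mean| strictly
exceeds 3 cell SDs within participant × language × block (language included
because the two languages are separate sessions). The screen is not
idempotent: re-running it recomputes cell statistics. p-values use the
normal (Wald) approximation; with hundreds of trials per participant the
Satterthwaite correction would be negligible.

**Race-model fitting.** Pooled across participants within a language
(population parameters; a per-participant option exists in the sampler's
data layout but desk-scale recovery uses pooled fits). Parameters: log
μ[d,s,t], log b[d,s,t] and a logit-scaled δ_s bounded by the per-stimulus
minimum observed decision time. Priors: lognormal(0, 1) on μ and b; blocks
coupled by a Gaussian random walk on the log scale (SD τ = 0.3, or
independent blocks by flag); uniform on δ_s. Sampling: component-wise
adaptive random-walk Metropolis with (log μ, log b) proposed jointly along
their posterior ridge (correlation 0.85; b/μ sets the passage-time mean, so
the two move together), proposal scales adapted during burn-in toward ~30%
acceptance, δ updated every other iteration. Density-branch likelihood terms
use sufficient statistics (n, Σ log τ, Σ 1/τ, Σ τ per response cell) so only
survival terms are computed per trial; kernels are numba-compiled. Default
schedule 6000/2000/5; intervals are 2.5/97.5 posterior percentiles.
Inference about learning uses the correct-trial (d = s) parameters,
aggregated across stimuli by averaging posterior draws, with block
differences flagged when 95% intervals do not overlap. The diffusion
coefficient is fixed at 1 for identifiability. Not modelled: starting-point
bias, across-trial drift variability, inter-accumulator inhibition.

**Pupil preprocessing.** Order: window [−500, 4000) (start-inclusive) →
50 Hz block means (bin timestamp = bin start; a bin is blink-flagged if any
source sample is; all-missing bins stay missing) → reject trials with
strictly more than 15% blink bins (screening therefore counts 50 Hz bins; a
flag screens at source rate instead) → widen each blink run by 120 ms per
side and fill linearly between the nearest valid samples (edge gaps extend
the nearest value) → baseline = mean of [−500, 0), output 100·(x−base)/base
on [0, 4000). Downsampling and normalization commute on blink-free traces
(both linear), which the suite verifies.

**Growth curve analysis.** Mean trace per participant × language × block on
the 200-bin 20-ms grid (the 50 Hz output after the baseline window is
dropped), stacked and fitted with `MixedLM` (ML): fixed effects (ot1..ot4) ×
language × block with all interactions, or time terms × EA-rate per language
on correct-trial means with the EA covariate taken as the posterior-mean
correct-choice drift per block (population-level, broadcast across
participants — the alignment the pooled fit supports). The orthonormal basis
comes from QR on powers 1..4 of the centered bin index, signs fixed so ot1
increases. Random effects: participant intercept plus independent
(diagonal-covariance) slopes on each time term — diagonal by default to aid
convergence on desk-scale data. A fourth-order fit is the default; the
order is configurable and log-likelihoods are reported, so a third-vs-fourth
order comparison is a one-line likelihood-ratio test.

**Error patterns.** Confusion matrices are row-normalized counts per
participant × language × block; rows without trials are missing, not zero.
The reliance statistic pairs each off-diagonal confusion cell (i, j) with
ASM(i, j) — the symmetric value serves both orders, inducing structural ties
handled by average ranks — and diagonals are excluded because only errors
are informative. Features are z-scored before distances by default (the six
features live on incommensurate scales); a flag disables this. The language
contrast is a paired Wilcoxon signed-rank test on per-participant mean ρ,
with mean ± SEM always reported. The acoustic-variance check is a
Mann-Whitney test on the 6 pairwise distances per language; with identical
samples the tie-degenerate p is defined as 1. Note the 6 distances share
talkers and are therefore dependent: the test's nominal type-I rate is
inflated (~13% under exact exchangeability), so the suite validates
exchangeability against a same-language baseline rather than the nominal 5%.

## Numerical conventions

- Inverse-Gaussian density and survival are computed in log space
  (`log_ndtr`-based), stable for large μ·b.
- Win probabilities and joint (choice, RT-bin) probabilities come from
  adaptive quadrature over f·ΠS products (tolerance 1e−10).
- The independent diffusion oracle steps all paths with Euler–Maruyama at
  0.1 ms, applying the exact Brownian-bridge within-step crossing
  probability exp(−2(b−x₀)(b−x₁)/dt) to remove the O(√dt) first-passage
  bias; same-step multi-accumulator crossings are tie-broken uniformly.
- RT tail trimming removes floor(f·n) fastest and slowest trials per
  participant × language with ties broken by stable input order.
- All randomness flows from a single seed through `numpy.random.SeedSequence`
  children; equal configurations give byte-identical outputs.

## Problem sizes used by the verification suite

Race-likelihood checks use 50,000 exact samples and a 100,000-path diffusion
oracle; posterior recovery uses 400 trials per stimulus per block over 20
seeded replicates; GCA calibration uses 200 coverage and 200 null replicates
on a reduced grid (10 participants × 2 languages × 2 blocks × 20 bins, fit
in ~0.15 s each), a grid chosen so Wald asymptotics hold while replication
stays cheap; the pipeline-level checks run the full 24-participant default
study once.

## What passing tests do and do not show

The generator draws choices from the same inverse-Gaussian race family the
fitter assumes, pupil traces from a smooth kernel plus AR(1) noise, and
blinks as missing spans. Passing recovery and pattern tests therefore show
the estimators are correct for their own model classes and that the pipeline
detects planted effects at realistic sizes — not that real eye-tracker data
meet these assumptions. Real data bring pupil foreshortening, gaze artifacts,
non-stationary baselines, feedback-driven sequential effects, and session
order effects, none of which are modelled; blink *detection* is likewise out
of scope (the mask is an input). The cross-participant hierarchy of the
decision model is population-pooled rather than fully hierarchical, a
documented simplification at desk scale.
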