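# talkerlearn

Simulation and analysis pipeline for **talker-identification learning**
experiments — the paradigm behind the *language familiarity effect* (LFE):
listeners identify who is speaking more accurately when the talkers use a
language the listener knows.

The package is aimed at auditory-cognition researchers who want a fully
synthetic, ground-truth-controlled replica of a two-language talker-learning
study (choices, response times, and trial-locked pupil traces) together with
the four analysis stages such studies use, each verifiable by parameter
recovery:

1. **Behavioral mixed models** — logistic mixed models of trial accuracy
   (language × block, per-participant random slopes, Type III Wald χ²) and
   linear mixed models of log response time after a 3-SD per-cell screen.
2. **Race diffusion model** — each K-alternative decision is a race of
   independent Wiener accumulators; accumulator *d* for stimulus *s* has
   drift μ<sub>d,s</sub> and threshold b<sub>d,s</sub>, so its first-passage
   time is inverse-Gaussian with mean b/μ and shape b². The response is the
   first accumulator to hit threshold and RT = δ<sub>s</sub> + min passage
   time. The trial likelihood is
   f(τ; μ<sub>d,s</sub>, b<sub>d,s</sub>) · Π<sub>d′≠d</sub>
   S(τ; μ<sub>d′,s</sub>, b<sub>d′,s</sub>), with parameters varying across
   learning blocks under a log-scale Gaussian random-walk prior, fitted by
   adaptive random-walk Metropolis (6000 iterations, 2000 burn-in, thin 5).
3. **Pupillometry** — windowing to −500..4000 ms, 50 Hz block-mean
   downsampling, a strict 15% blink-rejection screen, ±120 ms gap-widening
   linear interpolation, baseline percent-change normalization, and growth
   curve analysis (GCA): mixed-effects regression of the mean trace on
   fourth-order orthogonal polynomial time terms (ot1..ot4).
4. **Error-pattern analysis** — per-participant confusion matrices
   correlated (Spearman, off-diagonal cells only) with an acoustic
   similarity matrix built from six voice features (mean F0, F0 range,
   speech rate, jitter, harmonicity, formant dispersion; similarity =
   −Euclidean distance).

The synthetic generator plants the canonical LFE phenotype: higher native
accuracy in every block, no language difference in RT, larger and
slower-shrinking pupil responses in the unfamiliar language, negative
coupling between evidence-accumulation rate and pupil dilation, and
stronger confusion–acoustics correlation in the unfamiliar language.

## Worked example

```python
from talkerlearn import StudyConfig
from talkerlearn.pipeline import run_study_analysis

res = run_study_analysis(StudyConfig(rng_seed=1))

print(res["accuracy_table"].round(3))
print("RT language effect p =", round(res["rt_model"].term("lang01").p, 3))
g = res["gca_language_block"]
print("GCA language effect =", round(g.term("language01").estimate, 3))
print("GCA language x block =",
      round(g.term("language01:block_num").estimate, 3))
c = res["language_contrast"]
print("rho native/unfamiliar =",
      round(c["mean_native"], 3), round(c["mean_unfamiliar"], 3))
```

Output (seed 1):

```
block           1      2      3      4
language
native      0.559  0.664  0.715  0.750
unfamiliar  0.478  0.603  0.651  0.653
RT language effect p = 0.775
GCA language effect = 0.892
GCA language x block = -0.155
rho native/unfamiliar = 0.066 0.289
```

Reading the numbers: talker identification is more accurate in the native
language in every training block while response times do not differ by
language (p = 0.78); the unfamiliar language evokes a larger pupil response
(+0.89 percentage points on the GCA intercept) whose language gap shrinks
across blocks (negative language × block interaction); and listeners'
confusions track voice acoustics much more closely in the unfamiliar
language (mean Spearman ρ 0.29 vs 0.07).

A command-line interface mirrors the pipeline stage by stage
(`talkerlearn simulate|preprocess|behavior|ddm-fit|gca|asm|report`), reading
and writing plain CSV/JSON/YAML artifacts.

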