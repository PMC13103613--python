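"""Synthetic talker-learning studies with known ground truth.

Generates the three data streams of a two-language talker-identification
experiment: a talker acoustic-feature table per language, trial-level
choices and response times from a Wiener race whose drifts mix a talker
-identity cue with acoustic similarity, and trial-locked 1000 Hz pupil
traces whose amplitude decreases with the correct-choice drift rate (higher
evidence accumulation = lower processing cost = smaller dilation).

The cue weight w controls what errors look like: at w = 1 confusions carry
no acoustic structure, at w = 0 they are ordered purely by voice similarity.
The native language gets a high w and a high gain schedule (efficient from
the start), the unfamiliar language a low w and a lower but catching-up
schedule, so accuracy favours the native language in every block while the
between-language drift gap -- and with it the pupil-amplitude gap -- shrinks
over training.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .asm import ASM, asm_from_features, similarity_to_unit
from .ddm import race_win_probabilities
from .io_config import (
    FEATURE_NAMES,
    PupilTrace,
    StudyConfig,
    child_seed,
    save_config,
    write_pupil,
    write_trials,
)

__all__ = [
    "GroundTruth",
    "gen_talkers",
    "drift_schedule",
    "build_ground_truth",
    "gen_behavior",
    "gen_pupil",
    "gen_study",
    "pupil_kernel",
    "expected_patterns",
]


# ----------------------------------------------------------------------
# Talker acoustics
# ----------------------------------------------------------------------

def gen_talkers(config: StudyConfig, seed: int, language: str) -> pd.DataFrame:
    """Draw a talker x feature table for one language.

    Features are independent draws from per-feature location/scale settings
    (normal; jitter clipped at 0).  Both languages share the same settings,
    so their between-talker distance distributions are exchangeable.
    """
    if config.n_talkers < 2:
        raise ValueError("need at least 2 talkers")
    for name in FEATURE_NAMES:
        if config.feature_scales[name] < 0:
            raise ValueError(f"negative scale for feature {name!r}")
    lang_tag = config.language_names.index(language)
    rng = np.random.default_rng(child_seed(seed, 101, lang_tag))
    data = {"talker": np.arange(1, config.n_talkers + 1)}
    for name in FEATURE_NAMES:
        loc, scale = config.feature_locations[name], config.feature_scales[name]
        draws = rng.normal(loc, scale, size=config.n_talkers)
        if name == "jitter":
            draws = np.abs(draws)
        data[name] = draws
    return pd.DataFrame(data)


# ----------------------------------------------------------------------
# Drift schedules
# ----------------------------------------------------------------------

def drift_schedule(
    config: StudyConfig, asm: ASM, language: str, block: int
) -> tuple[np.ndarray, np.ndarray]:
    """Population drift and threshold matrices mu[d, s], b[d, s] for a block.

    mu[d, s] = mu_base + g(language, block) * [w 1{d=s} + (1-w) sigma(d, s)]
    with sigma the ASM rescaled to [0, 1] (self-similarity 1), so the
    correct accumulator always leads and error drifts are ordered by
    acoustic similarity in proportion to 1 - w.  Thresholds are constant.
    The test block (n_training_blocks + 1) reuses the final training gain.
    """
    lang = config.language(language)
    n_blocks = config.n_training_blocks
    if not 1 <= block <= n_blocks + 1:
        raise ValueError(f"block {block} out of range 1..{n_blocks + 1}")
    g = lang.gain_schedule[min(block, n_blocks) - 1]
    w = lang.cue_weight
    sigma = similarity_to_unit(asm)
    K = config.n_talkers
    ident = np.eye(K)
    mu = config.mu_base + g * (w * ident + (1.0 - w) * sigma)
    if np.any(mu <= 0):
        raise ValueError("drift schedule produced non-positive mu")
    b = np.full((K, K), config.threshold)
    return mu, b


# ----------------------------------------------------------------------
# Ground truth
# ----------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything needed to recompute expected quantities downstream."""

    languages: dict  # name -> {"cue_weight", "gain_schedule"}
    mu: dict  # name -> (K, K, n_training_blocks + 1) population drifts
    b: dict  # name -> same shape thresholds
    sigma: dict  # name -> (K, K) unit-rescaled similarity
    delta: np.ndarray  # (K,) per-stimulus offset, s
    mu_base: float  # shared drift floor
    participant_gain: dict  # name -> (P,) per-participant gain multipliers
    participant_baseline: np.ndarray  # (P,) pupil baselines, a.u.
    pupil_a0: dict  # name -> amplitude intercept, percent
    pupil_a1: dict  # name -> amplitude decrease per unit drift
    blink_rate_hz: float
    noise_sd: float
    noise_ar: float

    def to_dict(self) -> dict:
        return {
            "languages": self.languages,
            "mu": {k: v.tolist() for k, v in self.mu.items()},
            "b": {k: v.tolist() for k, v in self.b.items()},
            "sigma": {k: v.tolist() for k, v in self.sigma.items()},
            "delta": self.delta.tolist(),
            "mu_base": self.mu_base,
            "participant_gain": {
                k: v.tolist() for k, v in self.participant_gain.items()
            },
            "participant_baseline": self.participant_baseline.tolist(),
            "pupil_a0": self.pupil_a0,
            "pupil_a1": self.pupil_a1,
            # (per-language maps)
            "blink_rate_hz": self.blink_rate_hz,
            "noise_sd": self.noise_sd,
            "noise_ar": self.noise_ar,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            languages=d["languages"],
            mu={k: np.asarray(v) for k, v in d["mu"].items()},
            b={k: np.asarray(v) for k, v in d["b"].items()},
            sigma={k: np.asarray(v) for k, v in d["sigma"].items()},
            delta=np.asarray(d["delta"]),
            mu_base=float(d["mu_base"]),
            participant_gain={
                k: np.asarray(v) for k, v in d["participant_gain"].items()
            },
            participant_baseline=np.asarray(d["participant_baseline"]),
            pupil_a0={k: float(v) for k, v in d["pupil_a0"].items()},
            pupil_a1={k: float(v) for k, v in d["pupil_a1"].items()},
            blink_rate_hz=float(d["blink_rate_hz"]),
            noise_sd=float(d["noise_sd"]),
            noise_ar=float(d["noise_ar"]),
        )

    def participant_mu(self, language: str, participant: int) -> np.ndarray:
        """Per-participant drift array: the gain term scales multiplicatively."""
        base = self.mu[language]
        gain = self.participant_gain[language][participant - 1]
        # mu = mu_base + gain_p * (mu_pop - mu_base): the learning gain term
        # scales multiplicatively, the drift floor is shared
        return self.mu_base + gain * (base - self.mu_base)


def build_ground_truth(
    config: StudyConfig, features: dict[str, pd.DataFrame], seed: int
) -> GroundTruth:
    """Assemble the full generative parameter set for one study."""
    rng = np.random.default_rng(child_seed(seed, 202))
    n_total_blocks = config.n_training_blocks + 1
    mu, b, sigma, languages, pgain = {}, {}, {}, {}, {}
    for lang in config.languages:
        asm = asm_from_features(features[lang.name])
        sigma[lang.name] = similarity_to_unit(asm)
        K = config.n_talkers
        mu_arr = np.empty((K, K, n_total_blocks))
        b_arr = np.empty((K, K, n_total_blocks))
        for blk in range(1, n_total_blocks + 1):
            mu_arr[:, :, blk - 1], b_arr[:, :, blk - 1] = drift_schedule(
                config, asm, lang.name, blk
            )
        mu[lang.name] = mu_arr
        b[lang.name] = b_arr
        languages[lang.name] = {
            "cue_weight": lang.cue_weight,
            "gain_schedule": list(lang.gain_schedule),
        }
        pgain[lang.name] = np.exp(
            rng.normal(0.0, config.participant_gain_sd, size=config.n_participants)
        )
    baseline = np.maximum(
        rng.normal(
            config.pupil_baseline_mean,
            config.pupil_baseline_sd,
            size=config.n_participants,
        ),
        config.pupil_baseline_mean * 0.2,
    )
    a0_map = {
        lang.name: lang.pupil_a0 if lang.pupil_a0 is not None else config.pupil_a0
        for lang in config.languages
    }
    a1_map = {
        lang.name: lang.pupil_a1 if lang.pupil_a1 is not None else config.pupil_a1
        for lang in config.languages
    }
    return GroundTruth(
        languages=languages,
        mu=mu,
        b=b,
        sigma=sigma,
        delta=np.full(config.n_talkers, config.delta_s),
        mu_base=config.mu_base,
        participant_gain=pgain,
        participant_baseline=baseline,
        pupil_a0=a0_map,
        pupil_a1=a1_map,
        blink_rate_hz=config.blink_rate_hz,
        noise_sd=config.pupil_noise_sd,
        noise_ar=config.pupil_noise_ar,
    )


# ----------------------------------------------------------------------
# Behavior
# ----------------------------------------------------------------------

def gen_behavior(config: StudyConfig, truth: GroundTruth, seed: int) -> pd.DataFrame:
    """Simulate every trial of the study as an inverse-Gaussian race.

    Each sentence x talker stimulus appears once per block (order shuffled
    under the seed); training sentences are reused across training blocks and
    the test block uses novel sentence identities.  RTs are
    1000 * (delta_s + min passage time) in ms.
    """
    if config.trials_per_block != config.n_talkers * config.n_sentences:
        raise ValueError(
            "trials_per_block must equal n_talkers * n_sentences "
            f"({config.n_talkers} * {config.n_sentences}), got "
            f"{config.trials_per_block}"
        )
    rng = np.random.default_rng(child_seed(seed, 303))
    K = config.n_talkers
    rows = []
    for p in range(1, config.n_participants + 1):
        for lang in config.language_names:
            mu_p = truth.participant_mu(lang, p)
            b_arr = truth.b[lang]
            for blk in range(1, config.n_training_blocks + 2):
                phase = "training" if blk <= config.n_training_blocks else "test"
                sent_off = 0 if phase == "training" else config.n_sentences
                talkers = np.repeat(np.arange(1, K + 1), config.n_sentences)
                sentences = np.tile(
                    np.arange(1, config.n_sentences + 1) + sent_off, K
                )
                order = rng.permutation(len(talkers))
                talkers, sentences = talkers[order], sentences[order]
                n = len(talkers)
                mu_trial = mu_p[:, talkers - 1, blk - 1].T  # (n, K)
                b_trial = b_arr[:, talkers - 1, blk - 1].T
                passage = rng.wald(b_trial / mu_trial, b_trial**2)
                winner = np.argmin(passage, axis=1)
                rt_s = truth.delta[talkers - 1] + passage[np.arange(n), winner]
                for i in range(n):
                    rows.append(
                        (
                            p,
                            lang,
                            phase,
                            blk,
                            i + 1,
                            int(sentences[i]),
                            int(talkers[i]),
                            int(winner[i] + 1),
                            1000.0 * rt_s[i],
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "language",
            "phase",
            "block",
            "trial",
            "sentence",
            "stimulus_talker",
            "response_talker",
            "rt_ms",
        ],
    )


# ----------------------------------------------------------------------
# Pupil traces
# ----------------------------------------------------------------------

def pupil_kernel(t_ms: np.ndarray, n: float = 10.1, tmax_ms: float = 930.0) -> np.ndarray:
    """Erlang-family pupil impulse response, unit peak at t = tmax.

    h(t) = (t/tmax)^n exp(n (1 - t/tmax)) for t >= 0, 0 before onset.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    r = t[pos] / tmax_ms
    out[pos] = r**n * np.exp(n * (1.0 - r))
    return out


def gen_pupil(
    config: StudyConfig,
    trials: pd.DataFrame,
    truth: GroundTruth,
    seed: int,
) -> list[PupilTrace]:
    """One raw 1000 Hz pupil trace per trial record.

    trace = B_p (1 + (A/100) h(t) + eps(t)) after onset and B_p (1 + eps)
    during baseline, with A = max(0, a0 - a1 * mu_{s,s,block}) percent, eps
    AR(1) noise, and Poisson blink events masking lognormal-duration spans
    (masked samples are set to NaN).
    """
    rng = np.random.default_rng(child_seed(seed, 404))
    lo, hi = config.pupil_window_ms
    dt_ms = 1000.0 / config.sampling_rate_hz
    t_ms = lo + dt_ms * np.arange(config.n_pupil_samples)
    kern = pupil_kernel(t_ms, config.pupil_kernel_n, config.pupil_kernel_tmax_ms)
    phi = config.pupil_noise_ar
    innov_sd = config.pupil_noise_sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    duration_s = (hi - lo) / 1000.0

    if all(
        truth.pupil_a0[lang] - truth.pupil_a1[lang] * float(arr.min()) < 0
        for lang, arr in truth.mu.items()
    ):
        import warnings

        warnings.warn(
            "pupil amplitude is negative for all trials; traces will be flat",
            stacklevel=2,
        )

    traces = []
    for row in trials.itertuples(index=False):
        p = int(row.participant)
        lang = str(row.language)
        blk = int(row.block)
        s = int(row.stimulus_talker)
        mu_ss = truth.participant_mu(lang, p)[s - 1, s - 1, blk - 1]
        amp = max(0.0, truth.pupil_a0[lang] - truth.pupil_a1[lang] * mu_ss)
        bp = truth.participant_baseline[p - 1]
        if config.pupil_noise_sd > 0:
            innov = rng.normal(0.0, innov_sd, size=len(t_ms))
            innov[0] = rng.normal(0.0, config.pupil_noise_sd)
            eps = lfilter([1.0], [1.0, -phi], innov)
        else:
            eps = np.zeros(len(t_ms))
        samples = bp * (1.0 + (amp / 100.0) * kern + eps)
        mask = np.zeros(len(t_ms), dtype=bool)
        if truth.blink_rate_hz > 0:
            n_ev = rng.poisson(truth.blink_rate_hz * duration_s)
            if n_ev:
                starts = rng.uniform(lo, hi, size=n_ev)
                durs = 1000.0 * rng.lognormal(
                    np.log(config.blink_duration_mean_s),
                    config.blink_duration_sigma,
                    size=n_ev,
                )
                for st, du in zip(starts, durs):
                    mask |= (t_ms >= st) & (t_ms < st + du)
        samples = samples.copy()
        samples[mask] = np.nan
        traces.append(
            PupilTrace(
                participant=p,
                language=lang,
                block=blk,
                trial=int(row.trial),
                time_ms=t_ms.copy(),
                samples=samples,
                is_blink=mask,
                rate_hz=config.sampling_rate_hz,
                state="raw",
            )
        )
    return traces


# ----------------------------------------------------------------------
# Full-study generation
# ----------------------------------------------------------------------

def gen_study(config: StudyConfig, outdir: str | Path, seed: int | None = None) -> dict:
    """Generate and write a complete synthetic study.

    Writes trials.csv, pupil.csv, features_<language>.csv, truth.json and a
    manifest.json recording the config hash and seed.  Returns the artifact
    paths plus the in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed if seed is None else seed

    features = {
        lang: gen_talkers(config, seed, lang) for lang in config.language_names
    }
    truth = build_ground_truth(config, features, seed)
    trials = gen_behavior(config, truth, seed)
    traces = gen_pupil(config, trials, truth, seed)

    paths = {}
    for lang, table in features.items():
        path = outdir / f"features_{lang}.csv"
        table.to_csv(path, index=False)
        paths[f"features_{lang}"] = str(path)
    write_trials(trials, outdir / "trials.csv")
    paths["trials"] = str(outdir / "trials.csv")
    write_pupil(traces, outdir / "pupil.csv")
    paths["pupil"] = str(outdir / "pupil.csv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
    paths["truth"] = str(outdir / "truth.json")

    config_text = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "seed": int(seed),
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "n_trials": int(len(trials)),
        "n_traces": len(traces),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = str(outdir / "manifest.json")
    save_config(config, outdir / "config.yaml")
    return {
        "paths": paths,
        "features": features,
        "truth": truth,
        "trials": trials,
        "traces": traces,
    }


# ----------------------------------------------------------------------
# Generator-side expectations
# ----------------------------------------------------------------------

def expected_patterns(config: StudyConfig, truth: GroundTruth) -> pd.DataFrame:
    """Analytic expectations per language x block from the population
    parameters: probability correct (race win probability of the target
    accumulator, averaged over stimuli) and expected pupil amplitude.

    Used to verify the planted qualitative pattern without fitting.
    """
    rows = []
    K = config.n_talkers
    for lang in config.language_names:
        for blk in range(1, config.n_training_blocks + 2):
            pc = 0.0
            amp = 0.0
            for s in range(K):
                mu = truth.mu[lang][:, s, blk - 1]
                b = truth.b[lang][:, s, blk - 1]
                pc += race_win_probabilities(mu, b)[s]
                amp += max(
                    0.0, truth.pupil_a0[lang] - truth.pupil_a1[lang] * mu[s]
                )
            rows.append(
                {
                    "language": lang,
                    "block": blk,
                    "phase": "training" if blk <= config.n_training_blocks else "test",
                    "p_correct": pc / K,
                    "pupil_amplitude": amp / K,
                }
            )
    return pd.DataFrame(rows)
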