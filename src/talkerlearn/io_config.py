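"""Configuration, seed management, and tabular I/O for the talker-learning pipeline.

All pipeline artifacts are plain text: CSV tables with a one-line header for
trials, pupil samples, and talker acoustic features; YAML for run
configuration; JSON for ground-truth parameter dumps and fit summaries.
Times are in milliseconds throughout, pupil size in arbitrary units before
baseline normalization and in percent change afterwards.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "LanguageConfig",
    "StudyConfig",
    "TrialRecord",
    "PupilTrace",
    "load_config",
    "save_config",
    "read_trials",
    "write_trials",
    "trials_to_frame",
    "frame_to_trials",
    "read_pupil",
    "write_pupil",
    "child_seed",
    "FEATURE_NAMES",
]

#: The six voice-acoustic features used to characterise talkers.
FEATURE_NAMES = (
    "mean_f0",
    "f0_range",
    "speech_rate",
    "jitter",
    "harmonicity",
    "formant_dispersion",
)

TRIAL_COLUMNS = (
    "participant",
    "language",
    "phase",
    "block",
    "trial",
    "sentence",
    "stimulus_talker",
    "response_talker",
    "rt_ms",
)

PUPIL_KEY = ("participant", "language", "block", "trial")


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented range."""


@dataclass
class LanguageConfig:
    """Per-language generator settings.

    ``cue_weight`` (w) is the weight the simulated listener places on the
    talker-identity cue relative to raw acoustic similarity: w = 1 means
    errors carry no acoustic structure, w = 0 means errors are ordered purely
    by acoustic similarity.  ``gain_schedule`` gives the learning gain g for
    each training block (the test block reuses the last entry); drifts are
    mu_base + g * [w*1{d==s} + (1-w)*sigma(d,s)].  ``pupil_a0``/``pupil_a1``
    optionally override the global pupil amplitude map for this language
    (amplitude = max(0, a0 - a1 * correct-choice drift), percent units).
    """

    name: str
    cue_weight: float
    gain_schedule: tuple[float, ...]
    pupil_a0: float | None = None
    pupil_a1: float | None = None

    def validate(self, n_training_blocks: int) -> None:
        if not 0.0 <= self.cue_weight <= 1.0:
            raise ConfigError(
                f"languages[{self.name}].cue_weight must be in [0, 1], "
                f"got {self.cue_weight}"
            )
        if len(self.gain_schedule) != n_training_blocks:
            raise ConfigError(
                f"languages[{self.name}].gain_schedule must have "
                f"{n_training_blocks} entries, got {len(self.gain_schedule)}"
            )
        if any(g < 0 for g in self.gain_schedule):
            raise ConfigError(
                f"languages[{self.name}].gain_schedule entries must be >= 0"
            )
        if self.pupil_a0 is not None and self.pupil_a0 <= 0:
            raise ConfigError(
                f"languages[{self.name}].pupil_a0 must be > 0"
            )


# Default language conditions: a native language in which the listener
# weights identity cues heavily and learns fast, and an unfamiliar language
# in which responses lean on acoustic similarity and learning lags behind.
# The unfamiliar gain schedule is calibrated so the expected log response
# time matches the native language in every block (speed is traded for
# accuracy, not time), and the unfamiliar language carries a steeper pupil
# amplitude-vs-drift coupling so the between-language pupil gap narrows
# over training even though the native language learns faster.
_DEFAULT_LANGUAGES = (
    ("native", 0.8, (1.5, 2.05, 2.45, 2.7), 26.0, 4.0),
    ("unfamiliar", 0.2, (1.26, 1.79, 2.19, 2.44), 34.0, 6.0),
)


@dataclass
class StudyConfig:
    """Full description of one simulated study plus analysis settings.

    Defaults encode the study design: 24 participants, two languages
    (native, unfamiliar), 4 talkers x 10 sentences per language, 4 training
    blocks + 1 test block of 40 trials each, pupil sampled at 1000 Hz over
    -500..4000 ms relative to stimulus onset.
    """

    # --- design constants ---
    n_participants: int = 24
    n_talkers: int = 4
    n_sentences: int = 10
    n_training_blocks: int = 4
    trials_per_block: int = 40
    sampling_rate_hz: float = 1000.0
    pupil_window_ms: tuple[float, float] = (-500.0, 4000.0)
    rng_seed: int = 0
    languages: list[LanguageConfig] = field(
        default_factory=lambda: [
            LanguageConfig(name, w, sched, a0, a1)
            for name, w, sched, a0, a1 in _DEFAULT_LANGUAGES
        ]
    )

    # --- generator: decision model ---
    mu_base: float = 1.0  # drift floor shared by all accumulators (1/sqrt(s))
    threshold: float = 1.5  # decision threshold b (evidence units)
    delta_s: float = 0.35  # non-decision offset per stimulus (s)
    participant_gain_sd: float = 0.12  # lognormal SD of per-participant gain

    # --- generator: talker acoustics (location, scale per feature) ---
    feature_locations: dict[str, float] = field(
        default_factory=lambda: {
            "mean_f0": 180.0,
            "f0_range": 60.0,
            "speech_rate": 4.5,
            "jitter": 1.2,
            "harmonicity": 12.0,
            "formant_dispersion": 1000.0,
        }
    )
    feature_scales: dict[str, float] = field(
        default_factory=lambda: {
            "mean_f0": 40.0,
            "f0_range": 20.0,
            "speech_rate": 0.8,
            "jitter": 0.4,
            "harmonicity": 3.0,
            "formant_dispersion": 150.0,
        }
    )

    # --- generator: pupil model ---
    pupil_a0: float = 25.0  # amplitude intercept (percent of baseline)
    pupil_a1: float = 6.0  # amplitude decrease per unit correct-choice drift
    pupil_kernel_n: float = 10.1  # impulse-response shape exponent
    pupil_kernel_tmax_ms: float = 930.0  # impulse-response peak latency
    pupil_baseline_mean: float = 1000.0  # participant baseline, arbitrary units
    pupil_baseline_sd: float = 100.0
    pupil_noise_sd: float = 0.015  # stationary SD of AR(1) noise (fraction)
    pupil_noise_ar: float = 0.97  # AR(1) coefficient at the source rate
    blink_rate_hz: float = 0.23  # Poisson blink events per second
    blink_duration_mean_s: float = 0.25  # lognormal median blink duration
    blink_duration_sigma: float = 0.5  # lognormal sigma of blink duration

    # --- analysis parameters ---
    blink_threshold: float = 0.15  # reject trials with > this blink fraction
    interp_pad_ms: float = 120.0  # widen blink gaps by this much per side
    baseline_window_ms: float = 500.0  # pre-stimulus baseline length
    downsample_hz: float = 50.0
    rt_outlier_sd: float = 3.0  # log-RT screen, per participant x block
    rt_trim_fraction: float = 0.01  # tail trim before decision-model fitting
    mcmc_iters: int = 6000
    mcmc_burnin: int = 2000
    mcmc_thin: int = 5
    rw_tau: float = 0.3  # SD of the log-scale block random walk prior
    gca_order: int = 4

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        for key in (
            "n_participants",
            "n_talkers",
            "n_sentences",
            "n_training_blocks",
            "trials_per_block",
        ):
            v = getattr(self, key)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{key} must be a positive integer, got {v!r}")
        lo, hi = self.pupil_window_ms
        if not lo < 0.0 < hi:
            raise ConfigError(
                f"pupil_window_ms must straddle stimulus onset "
                f"(start < 0 < end), got {self.pupil_window_ms}"
            )
        for key in ("blink_threshold", "rt_trim_fraction"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{key} must be in [0, 1], got {v}")
        for key in (
            "sampling_rate_hz",
            "downsample_hz",
            "mu_base",
            "threshold",
            "pupil_baseline_mean",
        ):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be > 0, got {getattr(self, key)}")
        if self.delta_s < 0:
            raise ConfigError(f"delta_s must be >= 0, got {self.delta_s}")
        if not 0.0 <= self.pupil_noise_ar < 1.0:
            raise ConfigError(
                f"pupil_noise_ar must be in [0, 1), got {self.pupil_noise_ar}"
            )
        if self.gca_order < 1:
            raise ConfigError(f"gca_order must be >= 1, got {self.gca_order}")
        if self.mcmc_burnin >= self.mcmc_iters:
            raise ConfigError("mcmc_burnin must be smaller than mcmc_iters")
        for name in FEATURE_NAMES:
            if name not in self.feature_locations:
                raise ConfigError(f"feature_locations missing feature {name!r}")
            if name not in self.feature_scales:
                raise ConfigError(f"feature_scales missing feature {name!r}")
            if self.feature_scales[name] < 0:
                raise ConfigError(
                    f"feature_scales[{name!r}] must be >= 0, "
                    f"got {self.feature_scales[name]}"
                )
        if len(self.languages) < 1:
            raise ConfigError("at least one language must be configured")
        for lang in self.languages:
            lang.validate(self.n_training_blocks)

    # -- derived quantities --------------------------------------------
    @property
    def language_names(self) -> list[str]:
        return [lang.name for lang in self.languages]

    @property
    def test_block(self) -> int:
        """Internal block index of the test phase (training blocks + 1)."""
        return self.n_training_blocks + 1

    @property
    def n_pupil_samples(self) -> int:
        lo, hi = self.pupil_window_ms
        return int(round((hi - lo) * self.sampling_rate_hz / 1000.0))

    def language(self, name: str) -> LanguageConfig:
        for lang in self.languages:
            if lang.name == name:
                return lang
        raise KeyError(f"unknown language {name!r}")

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["languages"] = [
            {
                "name": lang.name,
                "cue_weight": lang.cue_weight,
                "gain_schedule": list(lang.gain_schedule),
                "pupil_a0": lang.pupil_a0,
                "pupil_a1": lang.pupil_a1,
            }
            for lang in self.languages
        ]
        d["pupil_window_ms"] = list(self.pupil_window_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "languages" in d:
            langs = []
            for entry in d["languages"]:
                entry = dict(entry)
                entry["gain_schedule"] = tuple(entry["gain_schedule"])
                langs.append(LanguageConfig(**entry))
            d["languages"] = langs
        if "pupil_window_ms" in d:
            d["pupil_window_ms"] = tuple(d["pupil_window_ms"])
        return cls(**d)


def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML study configuration; unspecified keys take the defaults.

    An empty file yields the all-defaults :class:`StudyConfig`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return StudyConfig.from_dict(data)


def save_config(config: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def child_seed(seed: int, *keys: int) -> int:
    """Derive a reproducible sub-seed (< 2**31) for a pipeline stage."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ----------------------------------------------------------------------
# Trial records
# ----------------------------------------------------------------------

@dataclass
class TrialRecord:
    """One behavioral trial: who spoke, what was answered, how fast."""

    participant: int
    language: str
    phase: str  # "training" or "test"
    block: int
    trial: int
    sentence: int
    stimulus_talker: int  # 1..K
    response_talker: int  # 1..K
    rt_ms: float
    correct: bool | None = None

    def __post_init__(self) -> None:
        if self.phase not in ("training", "test"):
            raise ValueError(
                f"phase must be 'training' or 'test', got {self.phase!r}"
            )
        if self.rt_ms <= 0:
            raise ValueError(f"rt_ms must be > 0, got {self.rt_ms}")


def trials_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if "correct" in df.columns:
        if df["correct"].isna().all():
            df = df.drop(columns=["correct"])
        else:
            df["correct"] = df["correct"].astype(int)
    return df


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    has_correct = "correct" in df.columns
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TrialRecord(
                participant=int(row.participant),
                language=str(row.language),
                phase=str(row.phase),
                block=int(row.block),
                trial=int(row.trial),
                sentence=int(getattr(row, "sentence", 0)),
                stimulus_talker=int(row.stimulus_talker),
                response_talker=int(row.response_talker),
                rt_ms=float(row.rt_ms),
                correct=bool(row.correct) if has_correct else None,
            )
        )
    return out


def _validate_trial_frame(df: pd.DataFrame, n_talkers: int | None) -> None:
    required = set(TRIAL_COLUMNS) - {"sentence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    bad_rt = df.index[df["rt_ms"] <= 0]
    if len(bad_rt):
        raise ValueError(
            f"non-positive rt_ms at row {bad_rt[0]} (column 'rt_ms')"
        )
    if n_talkers is not None:
        for col in ("stimulus_talker", "response_talker"):
            bad = df.index[(df[col] < 1) | (df[col] > n_talkers)]
            if len(bad):
                raise ValueError(
                    f"talker index out of range 1..{n_talkers} at row "
                    f"{bad[0]} (column {col!r})"
                )


def read_trials(path: str | Path, n_talkers: int | None = None) -> list[TrialRecord]:
    """Read a trial table (CSV or TSV, inferred from the extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    _validate_trial_frame(df, n_talkers)
    if "sentence" not in df.columns:
        df["sentence"] = 0
    return frame_to_trials(df)


def write_trials(records: Sequence[TrialRecord] | pd.DataFrame, path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else trials_to_frame(records)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)


# ----------------------------------------------------------------------
# Pupil traces
# ----------------------------------------------------------------------

@dataclass
class PupilTrace:
    """One trial's pupil time series with blink mask.

    ``samples`` are arbitrary units while ``state == 'raw'`` and percent
    change from baseline once preprocessed.  Blink-masked samples are NaN.
    """

    participant: int
    language: str
    block: int
    trial: int
    time_ms: np.ndarray
    samples: np.ndarray
    is_blink: np.ndarray
    rate_hz: float
    state: str = "raw"  # raw | preprocessed | rejected

    @property
    def key(self) -> tuple:
        return (self.participant, self.language, self.block, self.trial)

    def copy(self, **updates) -> "PupilTrace":
        d = {
            "participant": self.participant,
            "language": self.language,
            "block": self.block,
            "trial": self.trial,
            "time_ms": self.time_ms.copy(),
            "samples": self.samples.copy(),
            "is_blink": self.is_blink.copy(),
            "rate_hz": self.rate_hz,
            "state": self.state,
        }
        d.update(updates)
        return PupilTrace(**d)

    def blink_fraction(self) -> float:
        return float(np.mean(self.is_blink))


def _infer_rate(time_ms: np.ndarray, key: tuple) -> float:
    dt = np.diff(time_ms)
    if len(dt) == 0:
        raise ValueError(f"pupil trace for trial {key} has fewer than 2 samples")
    if np.any(dt <= 0):
        raise ValueError(f"non-monotone time in pupil trace for trial {key}")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(
            f"inconsistent sampling interval in pupil trace for trial {key}"
        )
    return 1000.0 / float(dt[0])


def read_pupil(path: str | Path) -> list[PupilTrace]:
    """Read a long-format pupil CSV into one trace per trial key."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = set(PUPIL_KEY) | {"time_ms", "pupil", "is_blink"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pupil table missing columns: {sorted(missing)}")
    traces = []
    for key, grp in df.groupby(list(PUPIL_KEY), sort=True):
        key = (int(key[0]), str(key[1]), int(key[2]), int(key[3]))
        t = grp["time_ms"].to_numpy(dtype=float)
        rate = _infer_rate(t, key)
        traces.append(
            PupilTrace(
                participant=int(key[0]),
                language=str(key[1]),
                block=int(key[2]),
                trial=int(key[3]),
                time_ms=t,
                samples=grp["pupil"].to_numpy(dtype=float),
                is_blink=grp["is_blink"].to_numpy(dtype=bool),
                rate_hz=rate,
                state=str(grp["state"].iloc[0]) if "state" in grp.columns else "raw",
            )
        )
    return traces


def write_pupil(traces: Sequence[PupilTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "participant": tr.participant,
                    "language": tr.language,
                    "block": tr.block,
                    "trial": tr.trial,
                    "time_ms": tr.time_ms,
                    "pupil": tr.samples,
                    "is_blink": tr.is_blink.astype(int),
                    "state": tr.state,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
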