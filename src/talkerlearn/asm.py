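"""Error-pattern analysis: acoustic similarity matrices and confusion linkage.

Talkers are characterised by six voice-acoustic features (mean F0, F0 range,
speech rate, jitter, harmonicity, formant dispersion).  An acoustic
similarity matrix (ASM) is the negated pairwise Euclidean distance matrix
over those features.  Reliance on acoustic cues is quantified as the
Spearman rank correlation between off-diagonal confusion proportions and the
corresponding ASM cells: the more a listener's errors follow voice
similarity, the higher the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io_config import FEATURE_NAMES

__all__ = [
    "ASM",
    "asm_from_features",
    "similarity_to_unit",
    "error_acoustic_correlation",
    "compare_languages",
    "compare_feature_variance",
]


@dataclass
class ASM:
    """Acoustic similarity matrix: symmetric, zero diagonal, off-diagonal <= 0."""

    values: np.ndarray  # K x K, similarity = -distance
    talkers: list[int]
    standardized: bool

    @property
    def n_talkers(self) -> int:
        return len(self.talkers)

    def pairwise_distances(self) -> np.ndarray:
        """The K(K-1)/2 distinct pairwise distances (upper triangle)."""
        iu = np.triu_indices(self.n_talkers, k=1)
        return -self.values[iu]


def _feature_matrix(features: pd.DataFrame) -> np.ndarray:
    missing = set(FEATURE_NAMES) - set(features.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return features.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)


def asm_from_features(features: pd.DataFrame, standardize: bool = True) -> ASM:
    """Build an ASM from a talker x feature table.

    Features are z-scored across talkers by default since the six features
    live on incommensurate scales (Hz, %, dB, syllables/s); pass
    ``standardize=False`` for raw-unit distances.
    """
    X = _feature_matrix(features)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 talkers to build an ASM")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite values")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if len(zero):
            raise ValueError(
                f"zero-variance feature {FEATURE_NAMES[zero[0]]!r} cannot be "
                "standardized"
            )
        X = (X - X.mean(axis=0)) / sd
    dist = squareform(pdist(X, metric="euclidean"))
    if "talker" in features.columns:
        talkers = [int(t) for t in features["talker"]]
    else:
        talkers = list(range(1, X.shape[0] + 1))
    return ASM(values=-dist, talkers=talkers, standardized=standardize)


def similarity_to_unit(asm: ASM) -> np.ndarray:
    """Rescale an ASM to [0, 1] with the diagonal (self-similarity) at 1.

    Used by the synthetic generator to turn similarities into drift-rate
    weights.  If all talkers are identical (every distance 0) the matrix is
    all ones.
    """
    v = asm.values
    vmin = v.min()
    if vmin == 0.0:
        return np.ones_like(v)
    return (v - vmin) / (0.0 - vmin)


def error_acoustic_correlation(
    confusion: np.ndarray, asm: ASM
) -> tuple[float, int]:
    """Spearman correlation between off-diagonal confusions and similarity.

    Pairs each off-diagonal confusion cell (i, j), i != j, with ASM(i, j);
    the symmetric ASM value serves both (i, j) and (j, i).  Missing confusion
    cells (rows with no trials) are dropped pairwise.  Ties are handled by
    average ranks.  Returns (rho, number of paired cells).
    """
    conf = np.asarray(confusion, dtype=float)
    K = asm.n_talkers
    if conf.shape != (K, K):
        raise ValueError(
            f"confusion matrix shape {conf.shape} does not match "
            f"{K} talkers"
        )
    off = ~np.eye(K, dtype=bool)
    c = conf[off]
    a = asm.values[off]
    keep = np.isfinite(c)
    c, a = c[keep], a[keep]
    if len(c) < 3:
        raise ValueError(
            f"need at least 3 valid off-diagonal pairs, got {len(c)}"
        )
    if np.all(c == c[0]) or np.all(a == a[0]):
        # A constant vector has no rank ordering; define rho = 0.
        return 0.0, int(len(c))
    rho = stats.spearmanr(c, a).statistic
    return float(rho), int(len(c))


def compare_languages(
    patterns: pd.DataFrame,
    native: str = "native",
    unfamiliar: str = "unfamiliar",
    per_block: bool = False,
) -> dict:
    """Paired contrast of acoustic reliance between the two languages.

    ``patterns`` has columns participant, language, block, rho.  Per
    participant the mean rho over blocks is taken (or per block when
    ``per_block``), and the paired difference unfamiliar - native is
    summarised with mean, SEM, and a Wilcoxon signed-rank test.  Positive
    difference = stronger acoustic reliance in the unfamiliar language.
    """
    required = {"participant", "language", "block", "rho"}
    missing = required - set(patterns.columns)
    if missing:
        raise ValueError(f"patterns table missing columns: {sorted(missing)}")
    group_cols = ["participant", "language"] + (["block"] if per_block else [])
    means = patterns.groupby(group_cols, sort=True)["rho"].mean().reset_index()
    wide = means.pivot_table(
        index=["participant"] + (["block"] if per_block else []),
        columns="language",
        values="rho",
    )
    for lang in (native, unfamiliar):
        if lang not in wide.columns:
            raise ValueError(f"language {lang!r} missing from patterns")
    if wide[[native, unfamiliar]].isna().any().any():
        bad = wide.index[wide[[native, unfamiliar]].isna().any(axis=1)][0]
        raise ValueError(f"participant {bad} lacks data for both languages")
    diff = (wide[unfamiliar] - wide[native]).to_numpy()
    out = {
        "n": int(len(diff)),
        "mean_native": float(wide[native].mean()),
        "mean_unfamiliar": float(wide[unfamiliar].mean()),
        "sem_native": float(wide[native].sem()),
        "sem_unfamiliar": float(wide[unfamiliar].sem()),
        "mean_difference": float(diff.mean()),
        "sem_difference": float(np.std(diff, ddof=1) / np.sqrt(len(diff)))
        if len(diff) > 1
        else float("nan"),
    }
    if len(diff) > 1 and np.any(diff != 0):
        res = stats.wilcoxon(diff)
        out["wilcoxon_statistic"] = float(res.statistic)
        out["p_value"] = float(res.pvalue)
    else:
        out["wilcoxon_statistic"] = float("nan")
        out["p_value"] = float("nan")
    return out


def compare_feature_variance(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    standardize: bool = False,
) -> dict:
    """Rank test on between-talker distances of two talker sets.

    Mann-Whitney U on the K(K-1)/2 pairwise Euclidean distances per
    language; checks that the acoustic spread of the two talker sets is
    comparable.  With identical samples the tie-degenerate p-value is
    defined as 1.
    """
    da = asm_from_features(features_a, standardize=standardize).pairwise_distances()
    db = asm_from_features(features_b, standardize=standardize).pairwise_distances()
    pooled = np.concatenate([da, db])
    if np.all(pooled == pooled[0]):
        # maximal ties: no evidence of any difference
        return {
            "statistic": float(len(da) * len(db) / 2.0),
            "p_value": 1.0,
            "n_a": int(len(da)),
            "n_b": int(len(db)),
        }
    res = stats.mannwhitneyu(da, db, alternative="two-sided")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_a": int(len(da)),
        "n_b": int(len(db)),
    }
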