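"""Accuracy coding, RT screening, confusion matrices, and mixed-model contrasts.

Training-phase accuracy is modelled with a logistic mixed model (fixed:
language, block, interaction; random per-participant intercept and slopes),
test-phase accuracy with language only.  Log response times get the same
treatment with linear mixed models (training fixed effects language + block,
no interaction).  The native language is the treatment-coded reference level
and block enters as a centered numeric covariate.  Fixed factors are
assessed with Type III Wald chi-square tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.regression.mixed_linear_model import MixedLM

from .io_config import trials_to_frame

__all__ = [
    "ModelSummary",
    "SeparationError",
    "score_accuracy",
    "exclude_rt_outliers",
    "confusion_matrix",
    "fit_accuracy_model",
    "fit_rt_model",
]


class SeparationError(RuntimeError):
    """Raised when a response cell is constant and the logistic fit degenerates."""


@dataclass
class ModelSummary:
    """Fixed-effect estimates and Type III Wald tests of one mixed model."""

    terms: pd.DataFrame  # term, estimate, se, stat, p
    wald: pd.DataFrame  # factor, chisq, df, p
    model: str
    phase: str
    converged: bool = True

    def term(self, name: str) -> pd.Series:
        row = self.terms[self.terms["term"] == name]
        if row.empty:
            raise KeyError(f"no term {name!r}; have {list(self.terms['term'])}")
        return row.iloc[0]


def _as_frame(trials) -> pd.DataFrame:
    return trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)


def score_accuracy(trials) -> pd.DataFrame:
    """Add a 0/1 ``correct`` column (stimulus == response); order preserved."""
    df = _as_frame(trials).copy()
    df["correct"] = (
        df["stimulus_talker"].to_numpy() == df["response_talker"].to_numpy()
    ).astype(int)
    return df


def exclude_rt_outliers(trials, k: float = 3.0) -> tuple[pd.DataFrame, dict]:
    """Screen log-RT outliers within participant x language x block cells.

    A trial is dropped when its |log rt - cell mean| strictly exceeds
    k * cell SD (sample SD); cells with zero SD exclude nothing.  Note the
    screen is not idempotent: re-running it on the kept trials recomputes
    cell statistics and may drop further trials.
    """
    df = _as_frame(trials).copy()
    if np.any(df["rt_ms"].to_numpy() <= 0):
        raise ValueError("rt_ms must be positive for log screening")
    logrt = np.log(df["rt_ms"].to_numpy())
    keep = np.ones(len(df), dtype=bool)
    grouped = df.groupby(["participant", "language", "block"], sort=False)
    for _, idx in grouped.indices.items():
        vals = logrt[idx]
        if len(vals) < 2:
            continue
        sd = vals.std(ddof=1)
        if sd == 0:
            continue
        keep[idx] = np.abs(vals - vals.mean()) <= k * sd
    report = {
        "n_total": int(len(df)),
        "n_excluded": int((~keep).sum()),
        "pct_excluded": float(100.0 * (~keep).sum() / len(df)) if len(df) else 0.0,
        "k": float(k),
    }
    return df.loc[keep].copy(), report


def confusion_matrix(
    trials,
    n_talkers: int | None = None,
    by: tuple[str, ...] = ("participant", "language", "block"),
) -> dict[tuple, np.ndarray]:
    """Row-normalized K x K confusion matrices per group.

    Cell (i, j) is the proportion of trials with stimulus i answered j.
    Rows with zero trials are NaN (missing, not zero).
    """
    df = _as_frame(trials)
    K = n_talkers or int(
        max(df["stimulus_talker"].max(), df["response_talker"].max())
    )
    for col in ("stimulus_talker", "response_talker"):
        vals = df[col].to_numpy()
        if np.any((vals < 1) | (vals > K)):
            raise ValueError(f"{col} outside 1..{K}")
    out = {}
    for key, grp in df.groupby(list(by), sort=True):
        counts = np.zeros((K, K))
        np.add.at(
            counts,
            (
                grp["stimulus_talker"].to_numpy() - 1,
                grp["response_talker"].to_numpy() - 1,
            ),
            1.0,
        )
        row_n = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = counts / row_n
        mat[row_n[:, 0] == 0, :] = np.nan
        out[key if isinstance(key, tuple) else (key,)] = mat
    return out


def _prepare_design(
    df: pd.DataFrame, phase: str, reference_language: str
) -> pd.DataFrame:
    if phase not in ("training", "test"):
        raise ValueError("phase must be 'training' or 'test'")
    sub = df[df["phase"] == phase].copy()
    if sub.empty:
        raise ValueError(f"no {phase}-phase trials")
    languages = sorted(sub["language"].unique())
    if reference_language not in languages:
        raise ValueError(
            f"reference language {reference_language!r} absent; have {languages}"
        )
    sub["lang01"] = (sub["language"] != reference_language).astype(float)
    if phase == "training":
        sub["blockc"] = sub["block"] - sub["block"].mean()
    return sub


def _check_separation(sub: pd.DataFrame) -> None:
    for lang, grp in sub.groupby("language"):
        m = grp["correct"].mean()
        if m in (0.0, 1.0):
            raise SeparationError(
                f"complete separation: all responses "
                f"{'correct' if m == 1.0 else 'incorrect'} in language "
                f"{lang!r}"
            )


def fit_accuracy_model(
    trials, phase: str, reference_language: str = "native"
) -> ModelSummary:
    """Logistic mixed model of trial accuracy.

    Training: correct ~ language * block with per-participant random
    intercept and random slopes for language and block; test: language only
    with a random language slope.  Estimated by variational Bayes (posterior
    means and SDs serve as estimates and standard errors); fixed factors are
    tested with Type III Wald chi-square statistics.
    """
    df = _as_frame(trials)
    if "correct" not in df.columns:
        df = score_accuracy(df)
    sub = _prepare_design(df, phase, reference_language)
    _check_separation(sub)
    sub["participant"] = sub["participant"].astype(str)

    if phase == "training":
        formula = "correct ~ lang01 * blockc"
        vc = {
            "pid": "0 + C(participant)",
            "pid_lang": "0 + C(participant):lang01",
            "pid_block": "0 + C(participant):blockc",
        }
        factors = ["lang01", "blockc", "lang01:blockc"]
    else:
        formula = "correct ~ lang01"
        vc = {
            "pid": "0 + C(participant)",
            "pid_lang": "0 + C(participant):lang01",
        }
        factors = ["lang01"]

    model = BinomialBayesMixedGLM.from_formula(formula, vc, sub)
    try:
        res = model.fit_vb()
    except Exception as exc:  # pragma: no cover - defensive
        raise SeparationError(f"logistic mixed model failed: {exc}") from exc

    names = model.exog_names
    est = res.fe_mean
    se = res.fe_sd
    z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    terms = pd.DataFrame(
        {"term": names, "estimate": est, "se": se, "stat": z, "p": p}
    )
    wald_rows = []
    for fac in factors:
        i = names.index(fac)
        chisq = float(z[i] ** 2)
        wald_rows.append(
            {
                "factor": fac,
                "chisq": chisq,
                "df": 1,
                "p": float(stats.chi2.sf(chisq, 1)),
            }
        )
    return ModelSummary(
        terms=terms,
        wald=pd.DataFrame(wald_rows),
        model="logistic mixed (VB)",
        phase=phase,
    )


def fit_rt_model(
    trials, phase: str, reference_language: str = "native"
) -> ModelSummary:
    """Linear mixed model of log response time (maximum likelihood).

    Training fixed effects: language + block (no interaction); test:
    language.  Random per-participant intercept and language slope.
    p-values use the normal (Wald) approximation.
    """
    df = _as_frame(trials)
    sub = _prepare_design(df, phase, reference_language)
    if sub["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants for a mixed model")
    sub["log_rt"] = np.log(sub["rt_ms"])

    formula = "log_rt ~ lang01 + blockc" if phase == "training" else "log_rt ~ lang01"
    model = MixedLM.from_formula(
        formula, groups="participant", re_formula="~ lang01", data=sub
    )
    res = model.fit(reml=False, method="lbfgs", maxiter=200)

    fe = res.fe_params
    se = res.bse_fe
    z = fe / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    terms = pd.DataFrame(
        {"term": fe.index, "estimate": fe.to_numpy(), "se": se.to_numpy(),
         "stat": z.to_numpy(), "p": np.asarray(p)}
    )
    factors = ["lang01"] + (["blockc"] if phase == "training" else [])
    wald_rows = []
    for fac in factors:
        i = list(fe.index).index(fac)
        chisq = float(z.iloc[i] ** 2)
        wald_rows.append(
            {"factor": fac, "chisq": chisq, "df": 1,
             "p": float(stats.chi2.sf(chisq, 1))}
        )
    return ModelSummary(
        terms=terms,
        wald=pd.DataFrame(wald_rows),
        model="linear mixed (ML)",
        phase=phase,
        converged=bool(res.converged),
    )
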