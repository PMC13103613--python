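"""Growth curve analysis of trial-averaged pupil traces.

The preprocessed percent-change traces are averaged per participant x
language x block, stacked over time bins, and regressed on first- through
fourth-order orthogonal polynomial time terms (ot1..ot4) with linear mixed
models: the language-by-block model carries fixed effects of every time
term, language, block and all their two- and three-way interactions; the
evidence-accumulation-rate model (fit per language, correct trials only)
carries the time terms, the EA-rate covariate, and their two-way
interactions.  Random structure: per-participant intercept and independent
random slopes on each time term (diagonal covariance by default to aid
convergence on desk-scale data).  Estimation is maximum likelihood (not
restricted); p-values use the normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .io_config import PupilTrace

__all__ = [
    "GCABasis",
    "GCAFit",
    "ortho_basis",
    "aggregate_traces",
    "fit_gca_language_block",
    "fit_gca_ea_rate",
]


@dataclass
class GCABasis:
    """Orthonormal polynomial regressors over the analysis time bins."""

    values: np.ndarray  # n_bins x order, columns ot1..ot_order
    bins: np.ndarray  # bin indices 0..n_bins-1

    @property
    def order(self) -> int:
        return self.values.shape[1]

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"ot{i + 1}" for i in range(self.order)]
        )
        df.insert(0, "bin", self.bins)
        return df


@dataclass
class GCAFit:
    """Fixed-effect table and fit diagnostics of one growth curve model."""

    terms: pd.DataFrame  # term, estimate, se, stat, p
    vc: dict  # variance components
    loglik: float
    converged: bool
    model: str
    n_obs: int

    def term(self, name: str) -> pd.Series:
        row = self.terms[self.terms["term"] == name]
        if row.empty:
            raise KeyError(f"no term {name!r}; have {list(self.terms['term'])}")
        return row.iloc[0]


def ortho_basis(n_bins: int, order: int = 4) -> GCABasis:
    """Orthonormal polynomial basis over ``n_bins`` time bins.

    Powers 1..order of the centered bin index are orthogonalized against the
    constant and each other (QR), then scaled to unit norm; ot1 is oriented
    to be strictly increasing.  Deterministic in exact arithmetic.
    """
    if n_bins <= order:
        raise ValueError(f"n_bins must exceed order ({n_bins} <= {order})")
    x = np.arange(n_bins, dtype=float)
    x = x - x.mean()
    V = np.column_stack([x**k for k in range(order + 1)])  # includes constant
    Q, _ = np.linalg.qr(V)
    basis = Q[:, 1:].copy()
    # fix signs: each column should start like +x^k (R's poly() convention)
    for j in range(order):
        if basis[-1, j] < 0:
            basis[:, j] *= -1.0
    basis /= np.linalg.norm(basis, axis=0)
    return GCABasis(values=basis, bins=np.arange(n_bins))


def aggregate_traces(
    preprocessed: list[PupilTrace],
    trials: pd.DataFrame | None = None,
    correct_only: bool = False,
) -> pd.DataFrame:
    """Pointwise mean trace per participant x language x block.

    ``correct_only`` restricts to correct trials (requires ``trials`` with a
    ``correct`` column, matched on participant/language/block/trial).
    Returns a long table with columns participant, language, block, bin,
    time_ms, pupil, n_trials.  Empty cells are simply absent.
    """
    if correct_only:
        if trials is None or "correct" not in trials.columns:
            raise ValueError(
                "correct_only requires a trial table with a 'correct' column"
            )
        lookup = {
            (int(r.participant), str(r.language), int(r.block), int(r.trial)):
                bool(r.correct)
            for r in trials.itertuples(index=False)
        }
        preprocessed = [
            tr for tr in preprocessed if lookup.get(tr.key, False)
        ]
    cells: dict[tuple, list[PupilTrace]] = {}
    for tr in preprocessed:
        if tr.state != "preprocessed":
            raise ValueError(
                f"trace for trial {tr.key} is {tr.state!r}, not preprocessed"
            )
        cells.setdefault((tr.participant, tr.language, tr.block), []).append(tr)
    frames = []
    for (p, lang, blk), trs in sorted(cells.items()):
        n_bins = len(trs[0].samples)
        stack = np.vstack([tr.samples for tr in trs])
        frames.append(
            pd.DataFrame(
                {
                    "participant": p,
                    "language": lang,
                    "block": blk,
                    "bin": np.arange(n_bins),
                    "time_ms": trs[0].time_ms,
                    "pupil": stack.mean(axis=0),
                    "n_trials": len(trs),
                }
            )
        )
    if not frames:
        raise ValueError("no preprocessed traces to aggregate")
    return pd.concat(frames, ignore_index=True)


def _attach_basis(df: pd.DataFrame, order: int) -> tuple[pd.DataFrame, GCABasis]:
    n_bins = int(df["bin"].max()) + 1
    basis = ortho_basis(n_bins, order)
    out = df.merge(basis.frame(), on="bin", how="left")
    return out, basis


def _fit_mixed(
    df: pd.DataFrame, formula: str, order: int, model_name: str
) -> GCAFit:
    ot_terms = [f"ot{i + 1}" for i in range(order)]
    vc = {name: f"0 + {name}" for name in ot_terms}
    df = df.copy()
    df["participant"] = df["participant"].astype(str)
    model = MixedLM.from_formula(
        formula, groups="participant", re_formula="1", vc_formula=vc, data=df
    )
    res = model.fit(reml=False, method="lbfgs", maxiter=500)
    fe = res.fe_params
    se = res.bse_fe
    z = fe.to_numpy() / se.to_numpy()
    p = 2.0 * stats.norm.sf(np.abs(z))
    terms = pd.DataFrame(
        {
            "term": list(fe.index),
            "estimate": fe.to_numpy(),
            "se": se.to_numpy(),
            "stat": z,
            "p": p,
        }
    )
    vc_out = {"participant_intercept": float(res.cov_re.iloc[0, 0])}
    for i, name in enumerate(ot_terms):
        vc_out[name] = float(res.vcomp[i])
    return GCAFit(
        terms=terms,
        vc=vc_out,
        loglik=float(res.llf),
        converged=bool(res.converged),
        model=model_name,
        n_obs=int(len(df)),
    )


def fit_gca_language_block(
    mean_traces: pd.DataFrame,
    order: int = 4,
    reference_language: str = "native",
) -> GCAFit:
    """Language-by-block growth curve model on training-phase mean traces.

    Fixed effects: (ot1 + .. + ot4) * language * block (all two- and
    three-way interactions); language treatment-coded with the native
    language as reference, block numeric.
    """
    df = mean_traces.copy()
    languages = sorted(df["language"].unique())
    if len(languages) < 2:
        raise ValueError("language-by-block model needs both languages")
    if reference_language not in languages:
        raise ValueError(
            f"reference language {reference_language!r} absent; have {languages}"
        )
    df["language01"] = (df["language"] != reference_language).astype(float)
    df["block_num"] = df["block"].astype(float)
    df, _ = _attach_basis(df, order)
    ot = " + ".join(f"ot{i + 1}" for i in range(order))
    formula = f"pupil ~ ({ot}) * language01 * block_num"
    return _fit_mixed(df, formula, order, "gca language x block")


def fit_gca_ea_rate(
    mean_traces: pd.DataFrame,
    ea_rates: pd.DataFrame,
    language: str,
    order: int = 4,
) -> GCAFit:
    """Growth curve model linking pupil shape to evidence accumulation rate.

    ``ea_rates`` carries the per participant x block covariate (columns
    participant, block, ea_rate; a population-level series may omit
    participant and is broadcast).  Fixed effects: time terms, EA rate, and
    all two-way time x EA interactions.
    """
    df = mean_traces[mean_traces["language"] == language].copy()
    if df.empty:
        raise ValueError(f"no mean traces for language {language!r}")
    ea = ea_rates.copy()
    if "ea_rate" not in ea.columns:
        raise ValueError("ea_rates must have an 'ea_rate' column")
    join_cols = ["participant", "block"] if "participant" in ea.columns else ["block"]
    merged = df.merge(ea[join_cols + ["ea_rate"]], on=join_cols, how="left")
    if merged["ea_rate"].isna().any():
        missing = (
            merged.loc[merged["ea_rate"].isna(), ["participant", "block"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise ValueError(f"ea_rates missing for cells: {missing}")
    if merged["ea_rate"].nunique() < 2:
        raise ValueError(
            "ea_rate covariate is constant across cells; model is rank "
            "deficient"
        )
    merged, _ = _attach_basis(merged, order)
    ot = " + ".join(f"ot{i + 1}" for i in range(order))
    formula = f"pupil ~ ({ot}) * ea_rate"
    return _fit_mixed(merged, formula, order, f"gca ea-rate ({language})")
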