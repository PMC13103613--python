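"""Multi-alternative Wiener race model: likelihood, sampling, Bayesian fitting.

The decision on each trial is modelled as a race among K independent
accumulators, one per response option.  Accumulator d for stimulus s is a
unit-diffusion Wiener process with drift mu[d, s] absorbed at threshold
b[d, s]; its first-passage time is inverse-Gaussian (Wald) with mean b/mu
and shape b^2.  The response is the first accumulator to reach threshold and
the response time is the winning passage time plus a per-stimulus
non-decision offset delta_s.  Drifts and thresholds may vary across learning
blocks, coupled by a log-scale Gaussian random-walk prior that encodes slow
change over training.

Fitting is by adaptive random-walk Metropolis on log mu, log b (per
response x stimulus x block) and a logit-scaled delta_s bounded by the
per-stimulus minimum observed decision time.  Priors are lognormal(0, 1) on
mu and b and uniform on delta_s; the diffusion coefficient is fixed at 1 for
identifiability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import integrate
from scipy.special import log_ndtr

from .io_config import StudyConfig, child_seed, trials_to_frame

__all__ = [
    "RaceParams",
    "PosteriorSummary",
    "ig_first_passage_density",
    "ig_survival",
    "race_loglik",
    "race_win_probabilities",
    "race_choice_window_probability",
    "simulate_race",
    "simulate_race_euler",
    "trim_rt_tails",
    "fit_ddm",
    "correct_params",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


# ----------------------------------------------------------------------
# Inverse-Gaussian first-passage law
# ----------------------------------------------------------------------

def _check_positive(**kwargs) -> None:
    for name, val in kwargs.items():
        if np.any(np.asarray(val) <= 0):
            raise ValueError(f"{name} must be strictly positive")


def ig_first_passage_density(t, mu, b):
    """First-passage density of a drift-mu, unit-diffusion Wiener process
    through barrier b, evaluated at time t (seconds).

    f(t) = b (2 pi t^3)^(-1/2) exp(-(b - mu t)^2 / (2 t)); computed in log
    space for stability.
    """
    t = np.asarray(t, dtype=float)
    _check_positive(t=t, mu=mu, b=b)
    logf = (
        np.log(b)
        - 0.5 * np.log(2.0 * np.pi * t**3)
        - (b - mu * t) ** 2 / (2.0 * t)
    )
    out = np.exp(logf)
    return out if out.shape else float(out)


def _ig_logsf_vec(t, mu, b):
    """log P(passage > t) for t > 0, stable for large mu*b."""
    t = np.asarray(t, dtype=float)
    sqrt_t = np.sqrt(t)
    log_a = log_ndtr((b - mu * t) / sqrt_t)
    log_b = 2.0 * mu * b + log_ndtr(-(b + mu * t) / sqrt_t)
    diff = log_b - log_a
    # survival = exp(log_a) - exp(log_b) with log_a >= log_b
    with np.errstate(invalid="ignore"):
        out = log_a + np.log1p(-np.exp(np.minimum(diff, 0.0)))
    return np.where(diff >= 0.0, -np.inf, out)


def ig_survival(t, mu, b):
    """P(first-passage time > t); survival(0) = 1, non-increasing in t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    _check_positive(mu=mu, b=b)
    tt = np.where(t > 0, t, 1.0)  # placeholder, overwritten below
    out = np.exp(_ig_logsf_vec(tt, mu, b))
    out = np.where(t > 0, out, 1.0)
    return out if out.shape else float(out)


# ----------------------------------------------------------------------
# Race parameters and likelihood
# ----------------------------------------------------------------------

@dataclass
class RaceParams:
    """Parameter bundle of the race: mu[d, s, block], b[d, s, block], delta[s].

    ``mu`` and ``b`` are indexed [response-1, stimulus-1, block-1] and must be
    strictly positive; ``delta`` (seconds) is the per-stimulus non-decision
    offset.
    """

    mu: np.ndarray
    b: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.mu.shape != self.b.shape or self.mu.ndim != 3:
            raise ValueError("mu and b must share a (K, K, n_blocks) shape")
        if np.any(self.mu <= 0) or np.any(self.b <= 0):
            raise ValueError("mu and b must be strictly positive")
        if np.any(self.delta < 0):
            raise ValueError("delta must be >= 0")
        if self.delta.shape[0] != self.mu.shape[1]:
            raise ValueError("delta must have one entry per stimulus")

    @property
    def n_options(self) -> int:
        return self.mu.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.mu.shape[2]


def race_loglik(trial: tuple, params: RaceParams, block: int) -> float:
    """Log-likelihood of one trial (response d, rt_ms, stimulus s), 1-based
    response and stimulus indices.

    With tau = rt/1000 - delta[s], the winning accumulator contributes its
    first-passage density and every loser the survival of its own passage
    law; returns -inf (flagged) when tau <= 0.
    """
    d, rt_ms, s = trial
    K = params.n_options
    if not (1 <= d <= K and 1 <= s <= K):
        raise IndexError(f"response/stimulus indices out of range 1..{K}")
    if not (1 <= block <= params.n_blocks):
        raise IndexError(f"block {block} out of range 1..{params.n_blocks}")
    tau = rt_ms / 1000.0 - params.delta[s - 1]
    if tau <= 0:
        return -np.inf
    mu = params.mu[:, s - 1, block - 1]
    b = params.b[:, s - 1, block - 1]
    ll = float(np.log(ig_first_passage_density(tau, mu[d - 1], b[d - 1])))
    for j in range(K):
        if j != d - 1:
            ll += float(_ig_logsf_vec(tau, mu[j], b[j]))
    return ll


def race_win_probabilities(mu, b) -> np.ndarray:
    """Analytic win probability of each accumulator, by quadrature.

    P(d) = integral_0^inf f(t; mu_d, b_d) prod_{j != d} S(t; mu_j, b_j) dt.
    """
    mu = np.asarray(mu, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_positive(mu=mu, b=b)
    K = len(mu)

    def integrand(t, d):
        val = ig_first_passage_density(t, mu[d], b[d])
        for j in range(K):
            if j != d:
                val *= ig_survival(t, mu[j], b[j])
        return val

    probs = np.empty(K)
    for d in range(K):
        probs[d], _ = integrate.quad(
            integrand, 0, np.inf, args=(d,), limit=200, epsabs=1e-10
        )
    return probs


def race_choice_window_probability(mu, b, d: int, t0: float, t1: float) -> float:
    """P(choice = d and decision time in [t0, t1]), by quadrature (d 0-based)."""
    mu = np.asarray(mu, dtype=float)
    b = np.asarray(b, dtype=float)
    K = len(mu)

    def integrand(t):
        val = ig_first_passage_density(t, mu[d], b[d])
        for j in range(K):
            if j != d:
                val *= ig_survival(t, mu[j], b[j])
        return val

    p, _ = integrate.quad(integrand, t0, t1, limit=200, epsabs=1e-10)
    return p


def simulate_race(
    params: RaceParams, s: int, block: int, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n (response, rt_s) pairs for stimulus s (1-based) in a block.

    Each accumulator's passage time is drawn exactly from the
    inverse-Gaussian law (mean b/mu, shape b^2); the response is the argmin
    and the decision time delta_s + min.  Returns 1-based responses and RTs
    in seconds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu = params.mu[:, s - 1, block - 1]
    b = params.b[:, s - 1, block - 1]
    passage = rng.wald(
        mean=np.broadcast_to(b / mu, (n, len(mu))),
        scale=np.broadcast_to(b**2, (n, len(mu))),
    )
    winner = np.argmin(passage, axis=1)
    rt = params.delta[s - 1] + passage[np.arange(n), winner]
    return winner + 1, rt


# ----------------------------------------------------------------------
# Euler-Maruyama diffusion oracle
# ----------------------------------------------------------------------

def simulate_race_euler(
    mu, b, dt: float = 1e-4, n_paths: int = 100_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force diffusion simulation of the race (independent oracle).

    Simulates every accumulator's Wiener path with Euler-Maruyama steps of
    ``dt`` seconds; a path finishes the moment its first accumulator crosses
    threshold.  Within-step crossings that end below threshold are detected
    with the exact Brownian-bridge crossing probability
    exp(-2 (b - x0)(b - x1) / dt), removing the O(sqrt(dt)) first-passage
    bias of naive endpoint checking.  Should two accumulators cross within
    the same step, the winner is drawn uniformly among them.  Returns
    (0-based winning accumulator, decision time) per path.  Used to validate
    the analytic likelihood, never for fitting.
    """
    mu = np.asarray(mu, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_positive(mu=mu, b=b, dt=dt)
    rng = np.random.default_rng(seed)
    K = len(mu)
    sdt = np.float32(math.sqrt(dt))
    drift = (mu * dt).astype(np.float32)
    b32 = b.astype(np.float32)
    choices = np.full(n_paths, -1, dtype=np.int64)
    times = np.zeros(n_paths)
    active = np.arange(n_paths)
    x = np.zeros((n_paths, K), dtype=np.float32)
    noise = np.empty_like(x)
    t = 0.0
    while active.size:
        t += dt
        n_act = active.size
        xv = x[:n_act]
        nv = noise[:n_act]
        rng.standard_normal(out=nv, dtype=np.float32)
        nv *= sdt
        xv += nv
        xv += drift
        crossed = xv >= b32
        # Brownian-bridge correction: an excursion may touch the barrier
        # inside the step even when the endpoint stays below it
        gap_new = b32 - xv
        cand = ~crossed & (gap_new < 0.04)
        if cand.any():
            rows_c, cols_c = np.nonzero(cand)
            x_prev = (
                xv[rows_c, cols_c]
                - nv[rows_c, cols_c]
                - drift[cols_c]
            )
            gap_prev = b32[cols_c] - x_prev
            p_cross = np.exp(
                -2.0 * np.maximum(gap_prev, 0.0) * gap_new[rows_c, cols_c] / dt
            )
            bridged = rng.random(rows_c.size) < p_cross
            crossed[rows_c[bridged], cols_c[bridged]] = True
        hit = crossed.any(axis=1)
        if hit.any():
            rows = np.flatnonzero(hit)
            # uniform tie-break among accumulators crossing in the same step
            score = crossed[rows] * (1.0 + rng.random((rows.size, K)))
            choices[active[rows]] = np.argmax(score, axis=1)
            times[active[rows]] = t
            keep = ~hit
            active = active[keep]
            x[: active.size] = xv[keep]
    return choices, times


# ----------------------------------------------------------------------
# RT tail trimming
# ----------------------------------------------------------------------

def trim_rt_tails(trials, fraction: float = 0.01) -> pd.DataFrame:
    """Drop the floor(fraction*n) fastest and slowest trials per
    participant x language group; ties broken by stable input order."""
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    keep_mask = np.ones(len(df), dtype=bool)
    positions = np.arange(len(df))
    for _, grp_idx in df.groupby(["participant", "language"], sort=False).indices.items():
        rt = df["rt_ms"].to_numpy()[grp_idx]
        k = int(np.floor(fraction * len(grp_idx)))
        if k == 0:
            continue
        order = np.argsort(rt, kind="stable")
        drop = np.concatenate([order[:k], order[-k:]])
        keep_mask[positions[grp_idx][drop]] = False
    return df.loc[keep_mask].copy()


# ----------------------------------------------------------------------
# MCMC fitting
# ----------------------------------------------------------------------

@njit(cache=True, inline="always")
def _log_ndtr_nb(x):  # pragma: no cover - numba
    if x >= 5.0:
        return math.log1p(-0.5 * math.erfc(x * 0.7071067811865476))
    if x > -37.0:
        return math.log(0.5 * math.erfc(-x * 0.7071067811865476))
    xx = x * x
    return (
        -0.5 * xx
        - math.log(-x)
        - 0.9189385332046727
        + math.log1p(-1.0 / xx + 3.0 / (xx * xx))
    )


@njit(cache=True, inline="always")
def _ig_logpdf_nb(t, mu, b):  # pragma: no cover - numba
    d = b - mu * t
    return math.log(b) - 0.5 * math.log(6.283185307179586 * t * t * t) - d * d / (2.0 * t)


@njit(cache=True, inline="always")
def _ig_logsf_nb(t, mu, b):  # pragma: no cover - numba
    st = math.sqrt(t)
    log_a = _log_ndtr_nb((b - mu * t) / st)
    log_b = 2.0 * mu * b + _log_ndtr_nb(-(b + mu * t) / st)
    diff = log_b - log_a
    if diff >= 0.0:
        return -1.0e300
    return log_a + math.log1p(-math.exp(diff))


@njit(cache=True)
def _part_ll(st, inv_st, suff, cell_off, roff, K, c, d, mu, b):  # pragma: no cover
    """Likelihood contribution of accumulator d over the trials of cell c:
    density for trials answered d (via sufficient statistics), survival for
    the rest.  ``suff[c, d]`` = (n, sum cpdf, sum 1/(2 tau), sum tau/2) over
    the trials of cell c answered d, where cpdf = -0.5 log(2 pi tau^3).
    """
    n = suff[c, d, 0]
    total = n * (math.log(b) + mu * b) + suff[c, d, 1] \
        - b * b * suff[c, d, 2] - mu * mu * suff[c, d, 3]
    a0 = roff[c * (K + 1) + d]
    a1 = roff[c * (K + 1) + d + 1]
    tmb = 2.0 * mu * b
    for i in range(cell_off[c], cell_off[c + 1]):
        if a0 <= i < a1:
            continue
        u1 = b * inv_st[i] - mu * st[i]
        u2 = -(b * inv_st[i] + mu * st[i])
        log_a = _log_ndtr_nb(u1)
        log_b = tmb + _log_ndtr_nb(u2)
        diff = log_b - log_a
        if diff >= 0.0:
            total += -1.0e300
        else:
            total += log_a + math.log1p(-math.exp(diff))
    return total


@njit(cache=True)
def _fill_tau_stats(rt, tau, st, inv_st, lo, hi, delta):  # pragma: no cover
    for i in range(lo, hi):
        tv = rt[i] - delta
        tau[i] = tv
        sv = math.sqrt(tv)
        st[i] = sv
        inv_st[i] = 1.0 / sv


@njit(cache=True)
def _fill_suff(tau, cell_off, roff, K, suff, c):  # pragma: no cover
    for d in range(K):
        a0 = roff[c * (K + 1) + d]
        a1 = roff[c * (K + 1) + d + 1]
        n = 0.0
        s_cpdf = 0.0
        s_i2t = 0.0
        s_ht = 0.0
        for i in range(a0, a1):
            t = tau[i]
            n += 1.0
            s_cpdf += -0.5 * math.log(6.283185307179586 * t * t * t)
            s_i2t += 0.5 / t
            s_ht += 0.5 * t
        suff[c, d, 0] = n
        suff[c, d, 1] = s_cpdf
        suff[c, d, 2] = s_i2t
        suff[c, d, 3] = s_ht


@njit(cache=True, inline="always")
def _chain_prior(x, k, arr, d, s, B, tau_rw, prior_sd, indep):  # pragma: no cover
    """Prior terms of the block chain that involve position k's value x."""
    lp = 0.0
    if indep or B == 1:
        z = x / prior_sd
        return -0.5 * z * z
    if k == 0:
        z = x / prior_sd
        lp -= 0.5 * z * z
    else:
        z = (x - arr[d, s, k - 1]) / tau_rw
        lp -= 0.5 * z * z
    if k + 1 < B:
        z = (arr[d, s, k + 1] - x) / tau_rw
        lp -= 0.5 * z * z
    return lp


@njit(cache=True)
def _mcmc_race(
    rt,
    stim,
    tau,
    cell_off,
    roff,
    K,
    B,
    delta_max,
    n_iter,
    burnin,
    thin,
    tau_rw,
    prior_sd,
    indep,
    delta_every,
    seed,
):  # pragma: no cover - numba
    np.random.seed(seed)
    n = rt.shape[0]
    lmu = np.zeros((K, K, B))
    lb = np.full((K, K, B), 0.405)  # threshold init 1.5
    zd = np.zeros(K)  # delta = delta_max * sigmoid(zd)
    delta = delta_max / (1.0 + np.exp(-zd))

    st = np.empty(n)
    inv_st = np.empty(n)
    suff = np.zeros((K * B, K, 4))
    for s in range(K):
        _fill_tau_stats(rt, tau, st, inv_st, cell_off[s * B], cell_off[s * B + B], delta[s])
        for blk in range(B):
            _fill_suff(tau, cell_off, roff, K, suff, s * B + blk)

    # cached likelihood parts per (d, cell)
    parts = np.zeros((K, K * B))
    for s in range(K):
        for blk in range(B):
            c = s * B + blk
            for d in range(K):
                parts[d, c] = _part_ll(
                    st, inv_st, suff, cell_off, roff, K, c, d,
                    math.exp(lmu[d, s, blk]), math.exp(lb[d, s, blk]),
                )

    scales = np.full((K, K, B), 0.25)
    zscales = np.full(K, 0.4)
    acc = np.zeros((K, K, B))
    zacc = np.zeros(K)
    acc_since = np.zeros((K, K, B))
    prop_since = np.zeros((K, K, B))
    zacc_since = np.zeros(K)
    zprop_since = np.zeros(K)
    n_prop = 0.0
    n_acc = 0.0
    zn_prop = 0.0
    zn_acc = 0.0

    n_draws = (n_iter - burnin) // thin
    mu_draws = np.empty((n_draws, K, K, B))
    b_draws = np.empty((n_draws, K, K, B))
    d_draws = np.empty((n_draws, K))
    draw = 0

    newparts = np.empty((K, B))
    tau_new = np.empty(n)
    st_new = np.empty(n)
    inv_st_new = np.empty(n)
    suff_new = np.zeros((K * B, K, 4))

    for it in range(n_iter):
        # --- joint (log mu, log b) updates per response x stimulus x block
        for s in range(K):
            for blk in range(B):
                c = s * B + blk
                for d in range(K):
                    sc = scales[d, s, blk]
                    # correlated proposal along the mu-b posterior ridge
                    # (b/mu sets the passage-time mean, so log mu and log b
                    # move together)
                    n1 = np.random.standard_normal()
                    n2 = np.random.standard_normal()
                    lmu_new = lmu[d, s, blk] + sc * n1
                    lb_new = lb[d, s, blk] + sc * (0.85 * n1 + 0.527 * n2)
                    new_part = _part_ll(
                        st, inv_st, suff, cell_off, roff, K, c, d,
                        math.exp(lmu_new), math.exp(lb_new),
                    )
                    dlp = new_part - parts[d, c]
                    dlp += _chain_prior(lmu_new, blk, lmu, d, s, B, tau_rw, prior_sd, indep)
                    dlp -= _chain_prior(lmu[d, s, blk], blk, lmu, d, s, B, tau_rw, prior_sd, indep)
                    dlp += _chain_prior(lb_new, blk, lb, d, s, B, tau_rw, prior_sd, indep)
                    dlp -= _chain_prior(lb[d, s, blk], blk, lb, d, s, B, tau_rw, prior_sd, indep)
                    prop_since[d, s, blk] += 1.0
                    if it >= burnin:
                        n_prop += 1.0
                    if dlp >= 0.0 or math.log(np.random.random()) < dlp:
                        lmu[d, s, blk] = lmu_new
                        lb[d, s, blk] = lb_new
                        parts[d, c] = new_part
                        acc_since[d, s, blk] += 1.0
                        if it >= burnin:
                            n_acc += 1.0

        # --- delta updates (every delta_every iterations)
        if it % delta_every == 0:
            for s in range(K):
                if delta_max[s] <= 0.0:
                    continue
                zs_new = zd[s] + zscales[s] * np.random.standard_normal()
                sig_new = 1.0 / (1.0 + math.exp(-zs_new))
                d_new = delta_max[s] * sig_new
                lo = cell_off[s * B]
                hi = cell_off[s * B + B]
                ok = True
                for i in range(lo, hi):
                    if rt[i] - d_new <= 0.0:
                        ok = False
                        break
                if ok:
                    _fill_tau_stats(rt, tau_new, st_new, inv_st_new, lo, hi, d_new)
                    for blk in range(B):
                        _fill_suff(tau_new, cell_off, roff, K, suff_new, s * B + blk)
                    dlp = 0.0
                    for blk in range(B):
                        c = s * B + blk
                        for d in range(K):
                            newparts[d, blk] = _part_ll(
                                st_new, inv_st_new, suff_new, cell_off, roff,
                                K, c, d,
                                math.exp(lmu[d, s, blk]), math.exp(lb[d, s, blk]),
                            )
                            dlp += newparts[d, blk] - parts[d, c]
                    sig_old = 1.0 / (1.0 + math.exp(-zd[s]))
                    # uniform prior on delta with logistic transform Jacobian
                    dlp += math.log(sig_new * (1.0 - sig_new))
                    dlp -= math.log(sig_old * (1.0 - sig_old))
                    zprop_since[s] += 1.0
                    if it >= burnin:
                        zn_prop += 1.0
                    if dlp >= 0.0 or math.log(np.random.random()) < dlp:
                        zd[s] = zs_new
                        delta[s] = d_new
                        for i in range(lo, hi):
                            tau[i] = tau_new[i]
                            st[i] = st_new[i]
                            inv_st[i] = inv_st_new[i]
                        for blk in range(B):
                            c = s * B + blk
                            for d in range(K):
                                parts[d, c] = newparts[d, blk]
                                for q in range(4):
                                    suff[c, d, q] = suff_new[c, d, q]
                        zacc_since[s] += 1.0
                        if it >= burnin:
                            zn_acc += 1.0

        # --- proposal adaptation during burn-in
        if it < burnin and (it + 1) % 100 == 0:
            for s in range(K):
                for blk in range(B):
                    for d in range(K):
                        if prop_since[d, s, blk] > 0:
                            rate = acc_since[d, s, blk] / prop_since[d, s, blk]
                            f = math.exp(2.0 * (rate - 0.3))
                            if f < 0.5:
                                f = 0.5
                            elif f > 2.0:
                                f = 2.0
                            scales[d, s, blk] *= f
                        acc_since[d, s, blk] = 0.0
                        prop_since[d, s, blk] = 0.0
            for s in range(K):
                if zprop_since[s] > 0:
                    rate = zacc_since[s] / zprop_since[s]
                    f = math.exp(2.0 * (rate - 0.44))
                    if f < 0.5:
                        f = 0.5
                    elif f > 2.0:
                        f = 2.0
                    zscales[s] *= f
                zacc_since[s] = 0.0
                zprop_since[s] = 0.0

        # --- record
        if it >= burnin and (it - burnin) % thin == 0 and draw < n_draws:
            for s in range(K):
                for blk in range(B):
                    for d in range(K):
                        mu_draws[draw, d, s, blk] = math.exp(lmu[d, s, blk])
                        b_draws[draw, d, s, blk] = math.exp(lb[d, s, blk])
                d_draws[draw, s] = delta[s]
            draw += 1

    acc_rate = n_acc / n_prop if n_prop > 0 else 0.0
    zacc_rate = zn_acc / zn_prop if zn_prop > 0 else 0.0
    return mu_draws, b_draws, d_draws, acc_rate, zacc_rate


@dataclass
class PosteriorSummary:
    """Posterior draws and summaries of a race-model fit.

    Arrays are indexed [response-1, stimulus-1, block-1].  Credible
    intervals are 95% pointwise (2.5th/97.5th percentiles of the thinned
    draws).
    """

    mu_mean: np.ndarray
    mu_lo: np.ndarray
    mu_hi: np.ndarray
    b_mean: np.ndarray
    b_lo: np.ndarray
    b_hi: np.ndarray
    delta_mean: np.ndarray
    delta_lo: np.ndarray
    delta_hi: np.ndarray
    mu_draws: np.ndarray
    b_draws: np.ndarray
    delta_draws: np.ndarray
    schedule: dict
    acceptance: dict
    language: str | None = None
    ess: dict = field(default_factory=dict)

    @property
    def n_options(self) -> int:
        return self.mu_mean.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.mu_mean.shape[2]

    def effective_sample_size(self) -> dict:
        """Effective sample counts for the correct-trial (d = s) parameters."""
        if self.ess:
            return self.ess
        import arviz as az

        out = {}
        K, _, B = self.mu_mean.shape
        for name, draws in (("mu", self.mu_draws), ("b", self.b_draws)):
            ess = np.empty((K, B))
            for s in range(K):
                for blk in range(B):
                    ess[s, blk] = float(az.ess(draws[:, s, s, blk][None, :]))
            out[name] = ess
        self.ess = out
        return out

    def to_dict(self) -> dict:
        return {
            "mu_mean": self.mu_mean.tolist(),
            "mu_lo": self.mu_lo.tolist(),
            "mu_hi": self.mu_hi.tolist(),
            "b_mean": self.b_mean.tolist(),
            "b_lo": self.b_lo.tolist(),
            "b_hi": self.b_hi.tolist(),
            "delta_mean": self.delta_mean.tolist(),
            "delta_lo": self.delta_lo.tolist(),
            "delta_hi": self.delta_hi.tolist(),
            "schedule": self.schedule,
            "acceptance": self.acceptance,
            "language": self.language,
        }


def fit_ddm(
    trials,
    config: StudyConfig | None = None,
    seed: int = 0,
    blocks_independent: bool = False,
    iters: int | None = None,
    burnin: int | None = None,
    thin: int | None = None,
    rw_tau: float | None = None,
    n_options: int | None = None,
    n_blocks: int | None = None,
) -> PosteriorSummary:
    """Fit the race model to training-phase trials of one language.

    Participants are pooled (population-level parameters); drifts and
    thresholds vary by block under a log-scale Gaussian random-walk prior
    unless ``blocks_independent``.  The default MCMC schedule is 6000
    iterations, 2000 burn-in, thinning 5.
    """
    config = config or StudyConfig()
    iters = iters if iters is not None else config.mcmc_iters
    burnin = burnin if burnin is not None else config.mcmc_burnin
    thin = thin if thin is not None else config.mcmc_thin
    rw_tau = rw_tau if rw_tau is not None else config.rw_tau
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")

    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    language = None
    if len(df):
        if "phase" in df.columns:
            df = df[df["phase"] == "training"]
        langs = df["language"].unique() if "language" in df.columns else []
        if len(langs) > 1:
            raise ValueError(
                f"fit_ddm expects trials of a single language, got {list(langs)}"
            )
        language = str(langs[0]) if len(langs) else None

    K = n_options or (int(df["stimulus_talker"].max()) if len(df) else None)
    B = n_blocks or (int(df["block"].max()) if len(df) else None)
    if K is None or B is None:
        raise ValueError(
            "n_options and n_blocks must be given when fitting without data"
        )

    if len(df):
        rt = df["rt_ms"].to_numpy(dtype=float) / 1000.0
        stim = df["stimulus_talker"].to_numpy(dtype=np.int64) - 1
        resp = df["response_talker"].to_numpy(dtype=np.int64) - 1
        blk = df["block"].to_numpy(dtype=np.int64) - 1
        if blk.max() >= B or stim.max() >= K or resp.max() >= K:
            raise ValueError("trial indices exceed declared K or block count")
        order = np.lexsort((resp, blk, stim))
        rt, stim, resp, blk = rt[order], stim[order], resp[order], blk[order]
    else:
        rt = np.empty(0)
        stim = np.empty(0, dtype=np.int64)
        resp = np.empty(0, dtype=np.int64)
        blk = np.empty(0, dtype=np.int64)

    # cell and response offsets into the sorted arrays
    cell_idx = stim * B + blk
    cell_off = np.zeros(K * B + 1, dtype=np.int64)
    np.add.at(cell_off[1:], cell_idx, 1) if len(cell_idx) else None
    cell_off = np.cumsum(cell_off)
    roff = np.zeros(K * B * (K + 1), dtype=np.int64)
    for c in range(K * B):
        lo, hi = cell_off[c], cell_off[c + 1]
        counts = np.bincount(resp[lo:hi], minlength=K)
        roff[c * (K + 1): c * (K + 1) + K + 1] = lo + np.concatenate(
            [[0], np.cumsum(counts)]
        )

    delta_max = np.zeros(K)
    for s in range(K):
        lo, hi = cell_off[s * B], cell_off[s * B + B]
        delta_max[s] = rt[lo:hi].min() if hi > lo else 1.0

    tau = np.empty_like(rt)
    mu_draws, b_draws, d_draws, acc, zacc = _mcmc_race(
        rt,
        stim,
        tau,
        cell_off,
        roff,
        K,
        B,
        delta_max,
        int(iters),
        int(burnin),
        int(thin),
        float(rw_tau),
        1.0,  # prior SD on log mu, log b
        bool(blocks_independent),
        2,  # delta update interval
        child_seed(seed, 777),
    )

    def summarize(draws):
        return (
            draws.mean(axis=0),
            np.percentile(draws, 2.5, axis=0),
            np.percentile(draws, 97.5, axis=0),
        )

    mu_mean, mu_lo, mu_hi = summarize(mu_draws)
    b_mean, b_lo, b_hi = summarize(b_draws)
    delta_mean, delta_lo, delta_hi = summarize(d_draws)
    return PosteriorSummary(
        mu_mean=mu_mean,
        mu_lo=mu_lo,
        mu_hi=mu_hi,
        b_mean=b_mean,
        b_lo=b_lo,
        b_hi=b_hi,
        delta_mean=delta_mean,
        delta_lo=delta_lo,
        delta_hi=delta_hi,
        mu_draws=mu_draws,
        b_draws=b_draws,
        delta_draws=d_draws,
        schedule={"iters": int(iters), "burnin": int(burnin), "thin": int(thin),
                  "rw_tau": float(rw_tau), "blocks_independent": bool(blocks_independent)},
        acceptance={"mu_b": float(acc), "delta": float(zacc)},
        language=language,
    )


def correct_params(summary: PosteriorSummary) -> dict:
    """Correct-trial (d = s) parameter tables with block-pair nonoverlap flags.

    Returns a per-stimulus table, a per-block aggregate (posterior draws
    averaged over stimuli, then summarised), and for each parameter and block
    pair a flag marking 95% interval nonoverlap on the aggregate series.
    """
    K, _, B = summary.mu_mean.shape
    rows = []
    for name, mean, lo, hi in (
        ("mu", summary.mu_mean, summary.mu_lo, summary.mu_hi),
        ("b", summary.b_mean, summary.b_lo, summary.b_hi),
    ):
        for s in range(K):
            for blk in range(B):
                rows.append(
                    {
                        "parameter": name,
                        "stimulus": s + 1,
                        "block": blk + 1,
                        "mean": float(mean[s, s, blk]),
                        "ci_lo": float(lo[s, s, blk]),
                        "ci_hi": float(hi[s, s, blk]),
                    }
                )
    table = pd.DataFrame(rows)

    agg_rows = []
    agg_ci = {}
    diag = np.arange(K)
    for name, draws in (("mu", summary.mu_draws), ("b", summary.b_draws)):
        # average the diagonal (d = s) draws over stimuli, then summarise
        agg_draws = draws[:, diag, diag, :].mean(axis=1)  # (n_draws, B)
        for blk in range(B):
            lo, hi = np.percentile(agg_draws[:, blk], [2.5, 97.5])
            agg_ci[(name, blk + 1)] = (float(lo), float(hi))
            agg_rows.append(
                {
                    "parameter": name,
                    "block": blk + 1,
                    "mean": float(agg_draws[:, blk].mean()),
                    "ci_lo": float(lo),
                    "ci_hi": float(hi),
                }
            )
    aggregate = pd.DataFrame(agg_rows)

    nonoverlap = {}
    for name in ("mu", "b"):
        for b1 in range(1, B + 1):
            for b2 in range(b1 + 1, B + 1):
                lo1, hi1 = agg_ci[(name, b1)]
                lo2, hi2 = agg_ci[(name, b2)]
                nonoverlap[(name, b1, b2)] = bool(hi1 < lo2 or hi2 < lo1)

    return {"table": table, "aggregate": aggregate, "nonoverlap": nonoverlap}
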