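"""Race-model primitives, likelihood/sampler agreement, trimming, MCMC fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from talkerlearn import ddm
from talkerlearn.ddm import RaceParams


def make_race_trials(mu, b, delta, n_per_cell, seed, language="x"):
    """Simulated trials from known race parameters, as a trial table."""
    params = RaceParams(mu=mu, b=b, delta=delta)
    K, _, B = mu.shape
    rows = []
    for s in range(1, K + 1):
        for blk in range(1, B + 1):
            d, rt = ddm.simulate_race(
                params, s, blk, n_per_cell, seed=seed + 97 * s + blk
            )
            for di, ri in zip(d, rt):
                rows.append(
                    (1, language, "training", blk, 0, 0, s, int(di), 1000.0 * ri)
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


class TestFirstPassageLaw:
    def test_density_closed_form_value(self):
        assert ddm.ig_first_passage_density(1.0, 1.0, 1.0) == pytest.approx(
            1.0 / math.sqrt(2 * math.pi), rel=1e-12
        )

    def test_density_vanishes_at_zero(self):
        assert ddm.ig_first_passage_density(1e-12, 1.0, 1.0) < 1e-100

    def test_density_integrates_to_one(self):
        total, err = integrate.quad(
            lambda t: ddm.ig_first_passage_density(t, 1.5, 2.0), 0, np.inf,
            limit=200,
        )
        assert abs(total - 1.0) < 1e-8

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ddm.ig_first_passage_density(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            ddm.ig_first_passage_density(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            ddm.ig_survival(-1.0, 1.0, 1.0)

    def test_survival_at_zero_is_one(self):
        assert ddm.ig_survival(0.0, 1.0, 1.0) == 1.0

    def test_survival_tail_negligible(self):
        assert ddm.ig_survival(100.0, 1.0, 1.0) < 1e-6

    def test_survival_consistent_with_density(self):
        for t in (0.2, 0.5, 1.0, 2.0, 5.0):
            integral, _ = integrate.quad(
                lambda u: ddm.ig_first_passage_density(u, 1.2, 1.8), 0, t,
                limit=200,
            )
            surv = ddm.ig_survival(t, 1.2, 1.8)
            assert abs(surv + integral - 1.0) < 1e-8

    def test_survival_non_increasing(self):
        t = np.linspace(0.01, 10, 100)
        s = ddm.ig_survival(t, 1.5, 1.0)
        assert np.all(np.diff(s) <= 0)


class TestRaceLikelihood:
    def test_single_accumulator_reduces_to_density(self):
        params = RaceParams(
            mu=np.full((1, 1, 1), 1.5),
            b=np.full((1, 1, 1), 2.0),
            delta=np.array([0.3]),
        )
        ll = ddm.race_loglik((1, 800.0, 1), params, 1)
        tau = 0.8 - 0.3
        assert ll == pytest.approx(
            math.log(ddm.ig_first_passage_density(tau, 1.5, 2.0)), rel=1e-10
        )

    def test_negative_decision_time_flagged(self):
        params = RaceParams(
            mu=np.full((1, 1, 1), 1.5),
            b=np.full((1, 1, 1), 2.0),
            delta=np.array([0.9]),
        )
        assert ddm.race_loglik((1, 800.0, 1), params, 1) == -np.inf

    def test_symmetric_race_win_probability_quarter(self):
        p = ddm.race_win_probabilities([1.2] * 4, [1.5] * 4)
        np.testing.assert_allclose(p, 0.25, atol=1e-8)

    @pytest.mark.parametrize(
        "mu, b",
        [
            ([2.0, 1.0, 1.0, 1.2], [1.5, 1.5, 1.5, 1.5]),
            ([0.7, 2.5], [1.0, 2.0]),
            ([1.1, 1.3, 0.9], [0.8, 1.7, 1.2]),
        ],
    )
    def test_probability_conservation(self, mu, b):
        assert abs(ddm.race_win_probabilities(mu, b).sum() - 1.0) < 1e-6

    def test_index_validation(self):
        params = RaceParams(
            mu=np.ones((2, 2, 1)), b=np.ones((2, 2, 1)), delta=np.zeros(2)
        )
        with pytest.raises(IndexError):
            ddm.race_loglik((3, 800.0, 1), params, 1)
        with pytest.raises(IndexError):
            ddm.race_loglik((1, 800.0, 1), params, 5)


class TestExactSampler:
    def test_lone_accumulator_mean_passage(self):
        params = RaceParams(
            mu=np.full((1, 1, 1), 2.0),
            b=np.full((1, 1, 1), 1.0),
            delta=np.zeros(1),
        )
        _, rt = ddm.simulate_race(params, 1, 1, 100_000, seed=0)
        # IG(mean b/mu = 0.5, shape b^2 = 1): var = mean^3 / shape
        se = math.sqrt(0.5**3 / 1.0 / 100_000)
        assert abs(rt.mean() - 0.5) <= 3 * se

    def test_dominant_accumulator_always_wins(self):
        mu = np.full((3, 3, 1), 0.5)
        for s in range(3):
            mu[s, s, 0] = 25.0
        params = RaceParams(mu=mu, b=np.full((3, 3, 1), 1.5), delta=np.zeros(3))
        d, _ = ddm.simulate_race(params, 2, 1, 5000, seed=1)
        assert (d == 2).mean() > 0.999

    def test_win_proportions_match_quadrature(self):
        mu = np.array([1.8, 1.1, 0.9, 1.3])
        b = np.array([1.5, 1.4, 1.6, 1.5])
        params = RaceParams(
            mu=mu[:, None, None] * np.ones((1, 1, 1)),
            b=b[:, None, None] * np.ones((1, 1, 1)),
            delta=np.zeros(1),
        )
        n = 50_000
        d, _ = ddm.simulate_race(params, 1, 1, n, seed=2)
        probs = ddm.race_win_probabilities(mu, b)
        for k in range(4):
            p_hat = (d == k + 1).mean()
            se = math.sqrt(probs[k] * (1 - probs[k]) / n)
            assert abs(p_hat - probs[k]) <= 3 * se

    def test_reproducible_under_seed(self):
        params = RaceParams(
            mu=np.ones((2, 2, 1)), b=np.ones((2, 2, 1)), delta=np.zeros(2)
        )
        d1, t1 = ddm.simulate_race(params, 1, 1, 100, seed=5)
        d2, t2 = ddm.simulate_race(params, 1, 1, 100, seed=5)
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_array_equal(t1, t2)


class TestTrimming:
    def _trials(self, rts, participant=1):
        n = len(rts)
        return pd.DataFrame(
            {
                "participant": participant,
                "language": "x",
                "phase": "training",
                "block": 1,
                "trial": np.arange(n),
                "stimulus_talker": 1,
                "response_talker": 1,
                "rt_ms": rts,
            }
        )

    def test_one_percent_each_tail(self):
        rts = np.linspace(300, 3000, 100)
        kept = ddm.trim_rt_tails(self._trials(rts), 0.01)
        assert len(kept) == 98
        assert kept["rt_ms"].min() > 300 and kept["rt_ms"].max() < 3000

    def test_small_group_floor_keeps_all(self):
        rts = np.linspace(300, 3000, 50)
        kept = ddm.trim_rt_tails(self._trials(rts), 0.01)
        assert len(kept) == 50

    def test_tie_break_by_input_order(self):
        rts = np.full(200, 800.0)
        df = self._trials(rts)
        kept = ddm.trim_rt_tails(df, 0.01)
        removed = sorted(set(df["trial"]) - set(kept["trial"]))
        assert removed == [0, 1, 198, 199]


class TestFitDDM:
    def test_recovery_reduced_schedule(self):
        K, B = 4, 2
        mu = np.full((K, K, B), 1.0)
        for s in range(K):
            mu[s, s, :] = 2.0
        b = np.full((K, K, B), 1.5)
        trials = make_race_trials(mu, b, np.full(K, 0.35), 200, seed=100)
        summ = ddm.fit_ddm(
            trials, seed=1, iters=2500, burnin=1000, thin=3
        )
        diag = np.arange(K)
        mu_ss = summ.mu_mean[diag, diag, :]
        b_ss = summ.b_mean[diag, diag, :]
        assert np.all(np.abs(mu_ss - 2.0) / 2.0 < 0.25)
        assert np.all(np.abs(b_ss - 1.5) / 1.5 < 0.25)
        assert np.all(np.abs(summ.delta_mean - 0.35) < 0.1)

    def test_chain_reproducible_under_seed(self):
        K, B = 2, 1
        mu = np.full((K, K, B), 1.2)
        trials = make_race_trials(
            mu, np.full((K, K, B), 1.0), np.zeros(K) + 0.2, 50, seed=7
        )
        s1 = ddm.fit_ddm(trials, seed=3, iters=600, burnin=200, thin=2)
        s2 = ddm.fit_ddm(trials, seed=3, iters=600, burnin=200, thin=2)
        np.testing.assert_array_equal(s1.mu_draws, s2.mu_draws)
        np.testing.assert_array_equal(s1.delta_draws, s2.delta_draws)

    def test_no_data_posterior_matches_prior(self):
        summ = ddm.fit_ddm(
            pd.DataFrame(
                columns=[
                    "participant", "language", "phase", "block", "trial",
                    "stimulus_talker", "response_talker", "rt_ms",
                ]
            ),
            seed=2,
            n_options=2,
            n_blocks=1,
            iters=4000,
            burnin=1000,
            thin=3,
        )
        # lognormal(0, 1) prior: mean of log draws ~ 0
        log_mu = np.log(summ.mu_draws)
        assert abs(log_mu.mean()) < 0.3
        assert 0.6 < log_mu.std() < 1.4

    def test_posterior_contraction_with_sample_size(self):
        K, B = 4, 1
        mu = np.full((K, K, B), 1.0)
        for s in range(K):
            mu[s, s, :] = 2.0
        b = np.full((K, K, B), 1.5)
        widths = []
        for n in (50, 200, 800):
            trials = make_race_trials(mu, b, np.full(K, 0.35), n, seed=50 + n)
            summ = ddm.fit_ddm(trials, seed=4, iters=2500, burnin=1000, thin=3)
            diag = np.arange(K)
            widths.append(
                float(
                    (summ.mu_hi[diag, diag, :] - summ.mu_lo[diag, diag, :]).mean()
                )
            )
        assert widths[0] > widths[1] > widths[2]

    def test_mixed_language_input_rejected(self):
        K, B = 2, 1
        mu = np.full((K, K, B), 1.2)
        a = make_race_trials(mu, np.full((K, K, B), 1.0), np.zeros(K), 10, 1, "a")
        bb = make_race_trials(mu, np.full((K, K, B), 1.0), np.zeros(K), 10, 1, "b")
        with pytest.raises(ValueError, match="single language"):
            ddm.fit_ddm(pd.concat([a, bb]), seed=0, iters=100, burnin=50)


class TestCorrectParams:
    def _summary_from_draws(self, mu_draws, b_draws):
        def summ(d):
            return d.mean(axis=0), np.percentile(d, 2.5, axis=0), np.percentile(d, 97.5, axis=0)

        mm, ml, mh = summ(mu_draws)
        bm, bl, bh = summ(b_draws)
        return ddm.PosteriorSummary(
            mu_mean=mm, mu_lo=ml, mu_hi=mh,
            b_mean=bm, b_lo=bl, b_hi=bh,
            delta_mean=np.zeros(mu_draws.shape[2]),
            delta_lo=np.zeros(mu_draws.shape[2]),
            delta_hi=np.zeros(mu_draws.shape[2]),
            mu_draws=mu_draws, b_draws=b_draws,
            delta_draws=np.zeros((mu_draws.shape[0], mu_draws.shape[2])),
            schedule={}, acceptance={},
        )

    def test_sixteen_entries_per_parameter(self, rng):
        draws = rng.lognormal(0, 0.1, size=(200, 4, 4, 4))
        out = ddm.correct_params(self._summary_from_draws(draws, draws.copy()))
        tab = out["table"]
        assert len(tab[tab.parameter == "mu"]) == 16
        assert len(out["aggregate"]) == 2 * 4

    def test_identical_blocks_no_nonoverlap(self, rng):
        base = rng.lognormal(0, 0.1, size=(300, 2, 2, 1))
        draws = np.repeat(base, 3, axis=3)  # same draws in all 3 blocks
        out = ddm.correct_params(self._summary_from_draws(draws, draws.copy()))
        assert not any(out["nonoverlap"].values())

    def test_separated_blocks_flagged(self, rng):
        draws = rng.lognormal(0, 0.05, size=(300, 2, 2, 2))
        draws[:, :, :, 1] *= 3.0  # block 2 clearly higher
        out = ddm.correct_params(self._summary_from_draws(draws, draws.copy()))
        assert out["nonoverlap"][("mu", 1, 2)]
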