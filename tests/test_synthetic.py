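"""Generator correctness: talkers, drift schedules, behavior, pupil, artifacts."""

import json

import numpy as np
import pandas as pd
import pytest

from talkerlearn import StudyConfig, behavior
from talkerlearn import synthetic_data as sd
from talkerlearn.asm import asm_from_features, error_acoustic_correlation
from talkerlearn.ddm import race_win_probabilities
from talkerlearn.io_config import FEATURE_NAMES, LanguageConfig, read_pupil


def one_language_config(w=0.5, **kwargs):
    defaults = dict(
        n_participants=4,
        n_sentences=3,
        trials_per_block=12,
        rng_seed=7,
        languages=[LanguageConfig("solo", w, (1.0, 1.2, 1.4, 1.5))],
    )
    defaults.update(kwargs)
    return StudyConfig(**defaults)


class TestTalkers:
    def test_shape_and_feature_names(self, small_config):
        table = sd.gen_talkers(small_config, 0, "native")
        assert len(table) == 4
        assert set(FEATURE_NAMES) <= set(table.columns)
        assert table["jitter"].min() >= 0

    def test_zero_scale_gives_identical_talkers(self):
        cfg = StudyConfig(feature_scales={k: 0.0 for k in FEATURE_NAMES})
        table = sd.gen_talkers(cfg, 0, "native")
        asm = asm_from_features(table, standardize=False)
        assert np.allclose(asm.values, 0.0)

    def test_languages_share_distance_distribution(self):
        """Between-talker distances are exchangeable across languages.

        The six pairwise distances of four talkers share talkers and are
        therefore dependent, which inflates the nominal rank-test rejection
        rate; the design intent (no systematic language difference) is
        checked by comparing the cross-language rejection rate against a
        same-language baseline, plus the pooled distance means.
        """
        from scipy.stats import mannwhitneyu

        n_rep = 200
        dists = {"native": [], "unfamiliar": []}
        for rep in range(n_rep):
            cfg2 = StudyConfig(rng_seed=rep)
            for lang in ("native", "unfamiliar"):
                dists[lang].append(
                    asm_from_features(
                        sd.gen_talkers(cfg2, rep, lang), standardize=False
                    ).pairwise_distances()
                )
        cross = np.mean(
            [
                mannwhitneyu(a, b).pvalue < 0.05
                for a, b in zip(dists["native"], dists["unfamiliar"])
            ]
        )
        within = np.mean(
            [
                mannwhitneyu(
                    dists["native"][i], dists["native"][(i + 1) % n_rep]
                ).pvalue
                < 0.05
                for i in range(n_rep)
            ]
        )
        se = np.sqrt(2 * 0.15 * 0.85 / n_rep)
        assert abs(cross - within) <= 3 * se
        mean_n = np.mean(np.concatenate(dists["native"]))
        mean_u = np.mean(np.concatenate(dists["unfamiliar"]))
        pooled_sd = np.std(np.concatenate(dists["native"]))
        assert abs(mean_n - mean_u) <= 3 * pooled_sd / np.sqrt(n_rep)


class TestDriftSchedule:
    def test_w1_off_diagonal_flat(self):
        cfg = one_language_config(w=1.0)
        asm = asm_from_features(sd.gen_talkers(cfg, 0, "solo"))
        mu, b = sd.drift_schedule(cfg, asm, "solo", 1)
        off = mu[~np.eye(4, dtype=bool)]
        assert np.allclose(off, cfg.mu_base)
        assert np.allclose(np.diag(mu), cfg.mu_base + 1.0)

    def test_w0_off_diagonal_ordered_by_similarity(self):
        cfg = one_language_config(w=0.0)
        asm = asm_from_features(sd.gen_talkers(cfg, 0, "solo"))
        mu, _ = sd.drift_schedule(cfg, asm, "solo", 2)
        off = ~np.eye(4, dtype=bool)
        order_mu = np.argsort(mu[off])
        order_sim = np.argsort(asm.values[off])
        np.testing.assert_array_equal(order_mu, order_sim)

    def test_native_margin_exceeds_unfamiliar_every_block(self, small_study):
        cfg, truth = small_study["config"], small_study["truth"]
        for blk in range(cfg.n_training_blocks + 1):
            margins = {}
            for lang in cfg.language_names:
                mu = truth.mu[lang][:, :, blk]
                m = [
                    mu[s, s] - np.max(np.delete(mu[:, s], s))
                    for s in range(cfg.n_talkers)
                ]
                margins[lang] = np.mean(m)
            assert margins["native"] > margins["unfamiliar"]


class TestBehavior:
    def test_trial_counts_and_stimulus_balance(self, small_study):
        cfg, trials = small_study["config"], small_study["trials"]
        expected = cfg.n_participants * 2 * (cfg.n_training_blocks + 1) * 12
        assert len(trials) == expected
        # every sentence x talker combination exactly once per block
        cell = trials[
            (trials.participant == 1)
            & (trials.language == "native")
            & (trials.block == 2)
        ]
        combos = set(zip(cell.stimulus_talker, cell.sentence))
        assert len(combos) == 12

    def test_default_study_size_is_9600(self):
        cfg = StudyConfig()
        n = cfg.n_participants * len(cfg.languages) * (
            cfg.n_training_blocks + 1
        ) * cfg.trials_per_block
        assert n == 9600

    def test_dominant_accumulator_wins(self):
        cfg = one_language_config(w=0.5, n_participants=2)
        feats = {"solo": sd.gen_talkers(cfg, 0, "solo")}
        truth = sd.build_ground_truth(cfg, feats, 0)
        for lang in truth.mu:
            mu = truth.mu[lang]
            for s in range(4):
                mu[s, s, :] = 50.0 * mu[:, s, :].max()
        truth.participant_gain = {
            k: np.ones_like(v) for k, v in truth.participant_gain.items()
        }
        trials = behavior.score_accuracy(sd.gen_behavior(cfg, truth, 0))
        assert trials["correct"].mean() > 0.99

    def test_symmetric_race_uniform_choices(self):
        cfg = one_language_config(w=0.5, n_participants=167)
        feats = {"solo": sd.gen_talkers(cfg, 0, "solo")}
        truth = sd.build_ground_truth(cfg, feats, 0)
        truth.mu["solo"][:] = 1.3
        truth.b["solo"][:] = 1.5
        truth.participant_gain["solo"] = np.ones(cfg.n_participants)
        trials = sd.gen_behavior(cfg, truth, 0)
        n = len(trials)
        assert n >= 10000
        se = np.sqrt(0.25 * 0.75 / (n / 4))
        for k in range(1, 5):
            prop = (trials.response_talker == k).mean()
            assert abs(prop - 0.25) <= 3 * se + 3 * np.sqrt(0.25 * 0.75 / n)

    def test_choice_proportions_match_analytic_win_probabilities(self):
        cfg = one_language_config(w=0.3, n_participants=834)
        feats = {"solo": sd.gen_talkers(cfg, 0, "solo")}
        truth = sd.build_ground_truth(cfg, feats, 0)
        truth.participant_gain["solo"] = np.ones(cfg.n_participants)
        trials = sd.gen_behavior(cfg, truth, 0)
        block1 = trials[trials.block == 1]
        assert len(block1) >= 10000
        for s in range(1, 5):
            sub = block1[block1.stimulus_talker == s]
            n = len(sub)
            probs = race_win_probabilities(
                truth.mu["solo"][:, s - 1, 0], truth.b["solo"][:, s - 1, 0]
            )
            for d in range(4):
                p_hat = (sub.response_talker == d + 1).mean()
                se = np.sqrt(probs[d] * (1 - probs[d]) / n)
                assert abs(p_hat - probs[d]) <= 3 * se


class TestPupilGenerator:
    def test_clean_trace_matches_kernel(self):
        cfg = one_language_config(
            n_participants=1,
            pupil_noise_sd=0.0,
            blink_rate_hz=0.0,
            pupil_baseline_sd=0.0,
            participant_gain_sd=0.0,
        )
        feats = {"solo": sd.gen_talkers(cfg, 0, "solo")}
        truth = sd.build_ground_truth(cfg, feats, 0)
        truth.pupil_a0 = {"solo": 10.0}
        truth.pupil_a1 = {"solo": 0.0}
        trials = sd.gen_behavior(cfg, truth, 0).head(1)
        trace = sd.gen_pupil(cfg, trials, truth, 0)[0]
        rel = 100.0 * (trace.samples / truth.participant_baseline[0] - 1.0)
        peak_idx = np.argmax(rel)
        assert trace.time_ms[peak_idx] == pytest.approx(930.0)
        assert rel[peak_idx] == pytest.approx(10.0, abs=1e-9)
        # baseline flat at zero
        assert np.allclose(rel[trace.time_ms < 0], 0.0)

    def test_a1_zero_equalizes_languages(self, small_config):
        cfg = small_config
        feats = {
            lang: sd.gen_talkers(cfg, 1, lang) for lang in cfg.language_names
        }
        truth = sd.build_ground_truth(cfg, feats, 1)
        truth.pupil_a0 = {lang: 12.0 for lang in truth.pupil_a0}
        truth.pupil_a1 = {lang: 0.0 for lang in truth.pupil_a1}
        exp = sd.expected_patterns(cfg, truth)
        amps = exp.pivot_table(
            index="block", columns="language", values="pupil_amplitude"
        )
        assert np.allclose(amps.iloc[:, 0], amps.iloc[:, 1])

    def test_blink_events_follow_poisson_rate(self):
        # short deterministic-duration blinks so mask runs ~ events
        cfg = one_language_config(
            n_participants=18,
            blink_rate_hz=0.2,
            blink_duration_mean_s=0.02,
            blink_duration_sigma=0.01,
            pupil_noise_sd=0.0,
        )
        feats = {"solo": sd.gen_talkers(cfg, 0, "solo")}
        truth = sd.build_ground_truth(cfg, feats, 0)
        trials = sd.gen_behavior(cfg, truth, 0)
        traces = sd.gen_pupil(cfg, trials, truth, 0)
        n_runs = []
        for tr in traces:
            m = tr.is_blink.astype(int)
            n_runs.append(int(np.sum(np.diff(np.concatenate([[0], m])) == 1)))
        n = len(n_runs)
        expected = 0.2 * 4.5
        se = np.sqrt(expected / n)  # Poisson variance
        assert n >= 1000
        assert abs(np.mean(n_runs) - expected) <= 3 * se + 0.02

    def test_expected_qualitative_pattern_of_defaults(self):
        cfg = StudyConfig(n_participants=2)
        feats = {
            lang: sd.gen_talkers(cfg, 0, lang) for lang in cfg.language_names
        }
        truth = sd.build_ground_truth(cfg, feats, 0)
        exp = sd.expected_patterns(cfg, truth)
        piv_acc = exp.pivot_table(
            index="block", columns="language", values="p_correct"
        )
        piv_amp = exp.pivot_table(
            index="block", columns="language", values="pupil_amplitude"
        )
        assert (piv_acc["native"] > piv_acc["unfamiliar"]).all()
        assert (piv_amp["native"] < piv_amp["unfamiliar"]).all()
        gap = (piv_amp["unfamiliar"] - piv_amp["native"]).to_numpy()[:4]
        assert np.all(np.diff(gap) < 0)


class TestCueWeightMonotonicity:
    def test_accuracy_up_reliance_down_in_w(self):
        accs, rhos = [], []
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            cfg = one_language_config(w=w, n_participants=42, rng_seed=5)
            feats = {"solo": sd.gen_talkers(cfg, 5, "solo")}
            truth = sd.build_ground_truth(cfg, feats, 5)
            trials = behavior.score_accuracy(sd.gen_behavior(cfg, truth, 5))
            train = trials[trials.phase == "training"]
            assert len(train) >= 2000
            accs.append(train["correct"].mean())
            conf = behavior.confusion_matrix(
                train, 4, by=("language",)
            )[("solo",)]
            asm = asm_from_features(feats["solo"])
            rho, _ = error_acoustic_correlation(conf, asm)
            rhos.append(rho)
        assert np.all(np.diff(accs) > 0)
        assert np.all(np.diff(rhos) < 0)


class TestGenStudy:
    def test_artifacts_and_determinism(self, tmp_path):
        cfg = one_language_config(
            n_participants=1, n_sentences=2, trials_per_block=8
        )
        out1 = sd.gen_study(cfg, tmp_path / "a", seed=3)
        sd.gen_study(cfg, tmp_path / "b", seed=3)
        for name in ("trials.csv", "pupil.csv", "truth.json", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
        # 4500 samples per trial at 1000 Hz over -500..4000 ms
        traces = read_pupil(tmp_path / "a" / "pupil.csv")
        assert all(len(tr.samples) == 4500 for tr in traces)
        assert len(traces) == len(out1["trials"])

    def test_truth_json_round_trip(self, tmp_path, small_study):
        truth = small_study["truth"]
        d = json.loads(json.dumps(truth.to_dict()))
        back = sd.GroundTruth.from_dict(d)
        for lang in truth.mu:
            np.testing.assert_allclose(back.mu[lang], truth.mu[lang])
            np.testing.assert_allclose(back.sigma[lang], truth.sigma[lang])
        np.testing.assert_allclose(back.delta, truth.delta)
        assert back.pupil_a0 == truth.pupil_a0
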