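"""End-to-end study analysis: simulate, preprocess, and run all four stages.

Single entry point used by the acceptance script and the pipeline-level
tests: generates a study from a configuration, then runs behavioral mixed
models, the race decision model, pupil preprocessing + growth curve
analysis, and the error-pattern analysis, returning every headline quantity
in one dictionary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import asm as asm_mod
from . import behavior, ddm, gca, pupil
from . import synthetic_data as sd
from .io_config import StudyConfig, child_seed

__all__ = ["run_study_analysis"]


def run_study_analysis(
    config: StudyConfig | None = None, seed: int | None = None
) -> dict:
    """Run the full pipeline on a freshly simulated study.

    Returns a dictionary with the simulated data, the fitted models for
    every stage, and scalar headline quantities.
    """
    config = config or StudyConfig()
    seed = config.rng_seed if seed is None else seed

    # --- generation ----------------------------------------------------
    features = {
        lang: sd.gen_talkers(config, seed, lang)
        for lang in config.language_names
    }
    truth = sd.build_ground_truth(config, features, seed)
    trials = behavior.score_accuracy(sd.gen_behavior(config, truth, seed))
    traces = sd.gen_pupil(config, trials, truth, seed)

    # --- behavior ------------------------------------------------------
    accuracy_table = (
        trials[trials.phase == "training"]
        .groupby(["language", "block"])["correct"]
        .mean()
        .unstack()
    )
    test_accuracy = (
        trials[trials.phase == "test"].groupby("language")["correct"].mean()
    )
    kept_rt, rt_report = behavior.exclude_rt_outliers(
        trials, config.rt_outlier_sd
    )
    ref = config.language_names[0]
    acc_model = behavior.fit_accuracy_model(trials, "training", ref)
    acc_model_test = behavior.fit_accuracy_model(trials, "test", ref)
    rt_model = behavior.fit_rt_model(kept_rt, "training", ref)
    rt_model_test = behavior.fit_rt_model(kept_rt, "test", ref)

    # --- decision model ------------------------------------------------
    training = trials[trials.phase == "training"]
    ddm_fits = {}
    correct_tables = {}
    for i, lang in enumerate(config.language_names):
        sub = ddm.trim_rt_tails(
            training[training.language == lang], config.rt_trim_fraction
        )
        summary = ddm.fit_ddm(sub, config, seed=child_seed(seed, 11, i))
        ddm_fits[lang] = summary
        correct_tables[lang] = ddm.correct_params(summary)

    # --- pupillometry --------------------------------------------------
    preprocessed, rejection_report = pupil.preprocess_all(traces, config)
    train_traces = [
        tr for tr in preprocessed if tr.block <= config.n_training_blocks
    ]
    agg = gca.aggregate_traces(train_traces)
    gca_fit = gca.fit_gca_language_block(agg, config.gca_order, ref)

    agg_correct = gca.aggregate_traces(train_traces, training, correct_only=True)
    gca_ea = {}
    for lang in config.language_names:
        cp = correct_tables[lang]["aggregate"]
        ea = cp[cp.parameter == "mu"][["block", "mean"]].rename(
            columns={"mean": "ea_rate"}
        )
        gca_ea[lang] = gca.fit_gca_ea_rate(
            agg_correct, ea, lang, config.gca_order
        )

    # --- error patterns ------------------------------------------------
    asms = {
        lang: asm_mod.asm_from_features(features[lang])
        for lang in config.language_names
    }
    confusions = behavior.confusion_matrix(training, config.n_talkers)
    rel_rows = []
    for (p, lang, blk), mat in confusions.items():
        rho, n_pairs = asm_mod.error_acoustic_correlation(mat, asms[lang])
        rel_rows.append(
            {"participant": p, "language": lang, "block": blk, "rho": rho}
        )
    reliance = pd.DataFrame(rel_rows)
    if len(config.language_names) == 2:
        native, unfamiliar = config.language_names
        language_contrast = asm_mod.compare_languages(
            reliance, native, unfamiliar
        )
        feature_variance = asm_mod.compare_feature_variance(
            features[native], features[unfamiliar]
        )
    else:
        language_contrast = {}
        feature_variance = {}

    return {
        "config": config,
        "seed": seed,
        "features": features,
        "truth": truth,
        "trials": trials,
        "accuracy_table": accuracy_table,
        "test_accuracy": test_accuracy,
        "rt_exclusion": rt_report,
        "acc_model": acc_model,
        "acc_model_test": acc_model_test,
        "rt_model": rt_model,
        "rt_model_test": rt_model_test,
        "ddm_fits": ddm_fits,
        "correct_params": correct_tables,
        "rejection_report": rejection_report,
        "gca_language_block": gca_fit,
        "gca_ea": gca_ea,
        "reliance": reliance,
        "language_contrast": language_contrast,
        "feature_variance": feature_variance,
    }
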