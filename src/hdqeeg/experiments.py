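"""Canned validation experiments on the synthetic cohort generator.

These experiments close the loop between the generator's ground truth
and the analysis pipeline: recovery of planted clinical correlations on
held-out subjects, recovery of planted informative features by the GA,
and null-calibration checks (label shuffling, zero-effect cohorts) that
expose the selection bias of in-sample feature search.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import classify as _classify
from . import clincorr as _clincorr
from .cohort import (
    AlphaPeak,
    CarrierResonance,
    CohortConfig,
    generate_cohort,
)
from .features import assemble_feature_vector
from .ga import GAConfig
from .io import apply_average_reference
from .spectra import compute_spectrum_set


def cohort_features(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort in memory and run it through spectra -> features.

    Returns (features: subjects x 2090, clinical table incl. group).
    """
    subjects, _ = generate_cohort(config)
    feats = {}
    rows = []
    for s in subjects:
        rec = apply_average_reference(s.recording)
        feats[s.subject_id] = assemble_feature_vector(compute_spectrum_set(rec))
        rows.append({"subject_id": s.subject_id, "group": s.group, **s.clinical})
    return pd.DataFrame(feats).T, pd.DataFrame(rows)


def correlation_recovery(
    train_seed: int = 11,
    validation_seed: int = 12,
    modality: str = "SDMT",
    n_validation: int = 200,
    ga: GAConfig | None = None,
    train_config: CohortConfig | None = None,
) -> dict:
    """Fit a clinical-correlation index and score it on fresh subjects.

    The index is fitted in-sample on one study-sized cohort, then applied
    to ``n_validation`` held-out subjects from the same generator; the
    held-out Pearson r measures how much of the planted coupling the
    index recovers without selection bias.
    """
    ga = ga or GAConfig(subset_size=20, population=100, generations=50, seed=train_seed)
    train_cfg = train_config or CohortConfig(seed=train_seed)
    fm, clin = cohort_features(train_cfg)
    index = _clincorr.ga_correlate(fm, clin, modality, ga)

    n_ctrl = int(round(n_validation * train_cfg.n_control / (train_cfg.n_control + train_cfg.n_carrier)))
    val_cfg = dataclasses.replace(
        train_cfg, n_control=n_ctrl, n_carrier=n_validation - n_ctrl, seed=validation_seed
    )
    fm_val, clin_val = cohort_features(val_cfg)
    val_r, val_p = _clincorr.index_correlation(index, fm_val, clin_val)

    coupling = train_cfg.clinical_coupling[modality]
    planted = max(coupling.planted_r().values(), key=abs) if coupling.latents else 0.0
    return {
        "modality": modality,
        "planted_r": float(abs(planted)),
        "in_sample_r": index.achieved_r,
        "validation_r": abs(float(val_r)),
        "validation_p": float(val_p),
        "n_validation": n_validation,
    }


def null_cohort_auc(
    seed: int,
    n_per_group: int = 10,
    duration: float = 60.0,
    ga: GAConfig | None = None,
) -> float:
    """Honest-mode cross-validated AUC on a zero-effect cohort.

    The generator plants no group contrast (effect scale 0, no alpha
    split, no resonance) and no clinical coupling enters the classifier,
    so the unbiased estimate should hover around chance.
    """
    config = CohortConfig(
        n_control=n_per_group,
        n_carrier=n_per_group,
        duration=duration,
        alpha_peak=AlphaPeak(split=False),
        carrier_resonance=CarrierResonance(amplitude=0.0),
        effect_scale=0.0,
        seed=seed,
    )
    fm, clin = cohort_features(config)
    y = (clin.set_index("subject_id").loc[fm.index, "group"] == "carrier").astype(int).to_numpy()
    ga = ga or GAConfig(subset_size=10, population=20, generations=8, seed=seed)
    cv = _classify.CVConfig(folds=3, repeats=1, seed=seed)
    result = _classify.evaluate_classifier(fm.to_numpy(float), y, ga, cv, mode="honest")
    return result.auc


def _null_feature_matrix(rng: np.random.Generator, n: int, p: int) -> tuple[np.ndarray, np.ndarray]:
    X = rng.standard_normal((n, p))
    y = np.repeat([0, 1], n // 2)
    return X, y


def label_shuffle_experiment(
    n_seeds: int = 100,
    n_subjects: int = 24,
    n_features: int = 300,
    seed: int = 0,
    ga: GAConfig | None = None,
) -> dict:
    """Selection bias demo: label-independent features, honest vs in-sample.

    For each seed a random feature matrix with shuffled labels is scored
    two ways: the GA's best in-sample cross-validated fitness (selection
    on all data — optimistically biased) and the honest nested-CV AUC.
    The honest estimate stays near 0.5 while the in-sample fitness does
    not, quantifying the overfitting risk of subset search at small n.
    """
    base = ga or GAConfig(subset_size=8, population=16, generations=8)
    honest, in_sample = [], []
    for k in range(n_seeds):
        run_seed = seed * 100003 + k
        rng = np.random.default_rng(run_seed)
        X, y = _null_feature_matrix(rng, n_subjects, n_features)
        cv = _classify.CVConfig(folds=3, repeats=1, seed=run_seed)
        ga_k = dataclasses.replace(base, seed=run_seed)
        _, trace = _classify.ga_select(X, y, ga_k, cv)
        in_sample.append(trace[-1])
        result = _classify.evaluate_classifier(X, y, ga_k, cv, mode="honest")
        honest.append(result.auc)
    return {
        "n_seeds": n_seeds,
        "mean_honest_auc": float(np.mean(honest)),
        "mean_in_sample_fitness": float(np.mean(in_sample)),
        "honest_aucs": honest,
        "in_sample_fitnesses": in_sample,
    }


def planted_feature_recovery(
    n_runs: int = 10,
    n_informative: int = 10,
    n_noise: int = 500,
    n_per_group: int = 100,
    effect_d: float = 1.0,
    seed: int = 0,
    ga: GAConfig | None = None,
) -> dict:
    """GA recovery of planted informative features among noise.

    Each run draws a two-group feature matrix whose first
    ``n_informative`` columns carry a standardized group difference of
    ``effect_d`` and counts how many of them the GA's selected subset
    recovers.  The default effect size keeps the subset fitness off its
    ceiling (a saturated AUC leaves no selection pressure to gather the
    remaining informative features) while staying well above the
    spurious group differences that chance hands the strongest of the
    noise features at this sample size.
    """
    base = ga or GAConfig(
        subset_size=n_informative, population=100, generations=25, mutation_rate=0.1
    )
    recovered = []
    for k in range(n_runs):
        run_seed = seed * 100003 + k + 1
        rng = np.random.default_rng(run_seed)
        n = 2 * n_per_group
        X = rng.standard_normal((n, n_informative + n_noise))
        y = np.repeat([0, 1], n_per_group)
        X[y == 1, :n_informative] += effect_d
        cv = _classify.CVConfig(folds=3, repeats=1, seed=run_seed)
        ga_k = dataclasses.replace(base, seed=run_seed)
        subset, _ = _classify.ga_select(X, y, ga_k, cv)
        recovered.append(int(sum(1 for i in subset if i < n_informative)))
    return {
        "n_runs": n_runs,
        "recovered_counts": recovered,
        "runs_with_6_of_10": int(sum(1 for r in recovered if r >= 6)),
    }
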