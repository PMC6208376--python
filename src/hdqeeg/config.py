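"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` bundles every stage's options and one global seed;
every stochastic stage derives its own seed from it deterministically,
so a run is reproducible bit-for-bit from config + seed.  Stages write
their artifacts under the output directory and later stages can resume
from disk when earlier ones are toggled off:

* ``simulate``  -> ``cohort/`` (per-subject EDF, clinical.csv, manifest.json)
* ``extract``   -> ``features.csv``, ``band_powers.csv``, ``spectra.npy``
* ``classify``  -> classifier metrics in the report, ``roc.csv``
* ``correlate`` -> per-modality index JSON + scatter / segment-profile CSVs
* ``stats``     -> ``spectral_stats.csv`` (contrast table), permutation test

``run_pipeline`` returns the report dict and writes ``report.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as _cohort
from . import classify as _classify
from . import clincorr as _clincorr
from . import features as _features
from . import stats as _stats
from .ga import GAConfig
from .io import apply_average_reference, read_edf
from .spectra import compute_spectrum_set

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "extract", "classify", "correlate", "stats")


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "hdqeeg_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # cohort
    n_control: int = 25
    n_carrier: int = 26
    duration: float = 180.0
    sampling_rate: float = 250.0
    target_bayes_auc: float | None = 0.95
    effect_scale: float | None = None     # overrides target_bayes_auc if set
    alpha_split_carriers: bool = True
    resonance_amplitude: float = 0.3
    # feature selection / classifier
    subset_size: int = 20
    ga_population: int = 30
    ga_generations: int = 15
    fitness_cv_repeats: int = 2
    cv_folds: int = 10
    cv_repeats: int = 10
    evaluation_mode: str = "paper"        # 'paper' | 'honest'
    compare_folds: tuple[int, ...] = (3, 5, 10)
    # clinical correlation (PCA fitness is cheap, so the GA runs larger)
    modalities: tuple[str, ...] = ("SDMT", "UHDRS-TMS")
    corr_ga_population: int = 100
    corr_ga_generations: int = 50
    corr_screen_size: int | None = 30
    segment_profiles: bool = True
    # stats
    n_permutations: int = 999

    def cohort_config(self) -> _cohort.CohortConfig:
        scale = self.effect_scale
        if scale is None:
            scale = (
                _cohort.effect_scale_for_bayes_auc(self.target_bayes_auc)
                if self.target_bayes_auc is not None
                else 1.0
            )
        return _cohort.CohortConfig(
            n_control=self.n_control,
            n_carrier=self.n_carrier,
            sampling_rate=self.sampling_rate,
            duration=self.duration,
            alpha_peak=_cohort.AlphaPeak(split=self.alpha_split_carriers),
            carrier_resonance=_cohort.CarrierResonance(amplitude=self.resonance_amplitude),
            effect_scale=float(scale),
            seed=derive_seed(self.seed, "cohort"),
        )

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("stages", "compare_folds", "modalities"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def _round_floats(obj, digits=10):
    if isinstance(obj, float):
        return round(obj, digits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages end to end; returns the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_dir = out / "cohort"
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: derive_seed(config.seed, s) for s in ALL_STAGES},
    }

    if "simulate" in config.stages:
        cc = config.cohort_config()
        subjects, manifest = _cohort.generate_cohort(cc)
        _cohort.write_cohort(subjects, manifest, cohort_dir)
        report["simulate"] = {
            "n_subjects": len(subjects),
            "effect_scale": cc.effect_scale,
            "planted_bayes_auc": manifest["bayes_auc"],
        }
        logger.info("simulated %d subjects into %s", len(subjects), cohort_dir)

    if not any(s in config.stages for s in ("extract", "classify", "correlate", "stats")):
        report = _round_floats(report)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        return report

    clinical = pd.read_csv(cohort_dir / "clinical.csv")

    if "extract" in config.stages:
        feats, powers, spectra = {}, {}, {}
        for sid in clinical["subject_id"]:
            rec = apply_average_reference(read_edf(cohort_dir / f"{sid}.edf"))
            ss = compute_spectrum_set(rec)
            feats[sid] = _features.assemble_feature_vector(ss)
            powers[sid] = _features.classical_band_powers(ss).stack()
            spectra[sid] = np.log10(np.maximum(ss.single_channel, _features.LOG_FLOOR))
        fm = pd.DataFrame(feats).T
        fm.to_csv(out / "features.csv", index_label="subject_id")
        bp = pd.DataFrame(powers).T
        bp.columns = [f"{ch}:{band}" for ch, band in bp.columns]
        bp.to_csv(out / "band_powers.csv", index_label="subject_id")
        bands = _features.BandSet.default()
        with open(out / "bands.json", "w") as fh:
            json.dump(
                {"band_edges_hz": [list(e) for e in bands.edges],
                 "classical_bands_hz": {k: list(v) for k, v in _features.CLASSICAL_BANDS.items()}},
                fh, indent=1,
            )
        np.save(out / "spectra.npy", np.stack([spectra[s] for s in clinical["subject_id"]]))
        logger.info("extracted features for %d subjects", len(feats))

    fm = pd.read_csv(out / "features.csv", index_col="subject_id")
    labels = (clinical.set_index("subject_id").loc[fm.index, "group"] == "carrier").astype(int)

    if "classify" in config.stages:
        ga = GAConfig(
            subset_size=config.subset_size,
            population=config.ga_population,
            generations=config.ga_generations,
            seed=derive_seed(config.seed, "classify"),
        )
        cv_fit = _classify.CVConfig(
            folds=config.cv_folds,
            repeats=config.fitness_cv_repeats,
            seed=derive_seed(config.seed, "classify-cv"),
        )
        X, y = fm.to_numpy(float), labels.to_numpy()
        result = _classify.evaluate_classifier(
            X, y, ga, dataclasses.replace(cv_fit, repeats=config.cv_repeats),
            mode=config.evaluation_mode, feature_names=list(fm.columns),
        )
        fold_aucs = {}
        if result.selected_features is not None:
            subset = [fm.columns.get_loc(f) for f in result.selected_features]
            for k in config.compare_folds:
                fold_aucs[str(k)] = _classify.cv_auc_fitness(
                    X, y, subset, dataclasses.replace(cv_fit, folds=k, repeats=config.cv_repeats)
                )
        pd.DataFrame(
            {
                "threshold": result.thresholds,
                "sensitivity": result.sensitivity,
                "specificity": result.specificity,
            }
        ).to_csv(out / "roc.csv", index=False)
        if result.selected_features is not None:
            final = _classify.train_index_model(
                X, y, subset, feature_names=list(fm.columns)
            )
            with open(out / "classifier_model.json", "w") as fh:
                json.dump(final.to_dict(), fh, indent=1)
        report["classify"] = {
            "mode": config.evaluation_mode,
            "auc": result.auc,
            "auc_by_folds": fold_aucs,
            "operating_point": result.operating_point,
            "youden_point": result.youden_point,
            "selected_features": result.selected_features,
        }
        logger.info("classifier AUC %.3f", result.auc)

    if "correlate" in config.stages:
        carriers = clinical[clinical["group"] == "carrier"]["subject_id"]
        profiles_features = None
        report["correlate"] = {}
        for modality in config.modalities:
            ga = GAConfig(
                subset_size=config.subset_size,
                population=config.corr_ga_population,
                generations=config.corr_ga_generations,
                seed=derive_seed(config.seed, f"correlate-{modality}"),
            )
            index = _clincorr.ga_correlate(
                fm, clinical, modality, ga, screen_size=config.corr_screen_size
            )
            with open(out / f"index_{modality}.json", "w") as fh:
                json.dump(
                    {
                        "modality": index.modality,
                        "subset": index.subset,
                        "loc": index.loc.tolist(),
                        "scale": index.scale.tolist(),
                        "loading": index.loading.tolist(),
                        "achieved_r": index.achieved_r,
                    },
                    fh,
                    indent=1,
                )
            scatter = pd.DataFrame(
                {
                    "subject_id": fm.index,
                    "index": index.apply(fm),
                    modality: clinical.set_index("subject_id").loc[fm.index, modality].to_numpy(),
                }
            )
            scatter.to_csv(out / f"scatter_{modality}.csv", index=False)
            report["correlate"][modality] = {"achieved_r": index.achieved_r}
            if config.segment_profiles:
                if profiles_features is None:
                    profiles_features = _segment_feature_profiles(cohort_dir, carriers)
                rows = []
                for sid, feats5 in profiles_features.items():
                    vals = index.apply(feats5)
                    rows.append({"subject_id": sid, **{f"segment{k+1}": v for k, v in enumerate(vals)}})
                pd.DataFrame(rows).to_csv(out / f"segment_profile_{modality}.csv", index=False)
        logger.info("correlation indices: %s", report["correlate"])

    if "stats" in config.stages:
        bp = pd.read_csv(out / "band_powers.csv", index_col="subject_id")
        bp.columns = pd.MultiIndex.from_tuples(c.split(":") for c in bp.columns)
        groups = clinical.set_index("subject_id")["group"]
        table = _stats.group_spectral_stats(bp, groups)
        table.to_csv(out / "spectral_stats.csv", index=False)
        log_spectra = np.load(out / "spectra.npy")
        observed, p = _stats.full_spectrum_group_test(
            log_spectra,
            groups.loc[fm.index].to_numpy(),
            n_perm=config.n_permutations,
            seed=derive_seed(config.seed, "stats"),
        )
        report["stats"] = {
            "n_significant_cells": int((table["p"] <= 0.05).sum()),
            "full_spectrum_statistic": observed,
            "full_spectrum_p": p,
        }
        logger.info("full-spectrum permutation p = %.4f", p)

    report = _round_floats(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _segment_feature_profiles(cohort_dir: Path, subject_ids) -> dict[str, pd.DataFrame]:
    """Per subject: feature vectors of the 5 consecutive sub-recordings."""
    from .clincorr import N_SUB_RECORDINGS
    from .io import EEGRecording

    out = {}
    for sid in subject_ids:
        rec = apply_average_reference(read_edf(Path(cohort_dir) / f"{sid}.edf"))
        piece = rec.n_times // N_SUB_RECORDINGS
        rows = []
        for k in range(N_SUB_RECORDINGS):
            sub = EEGRecording(
                rec.samples[:, k * piece: (k + 1) * piece],
                rec.sampling_rate,
                rec.channel_labels,
                reference_state="average",
            )
            rows.append(_features.assemble_feature_vector(compute_spectrum_set(sub)))
        out[sid] = pd.DataFrame(rows)
    return out
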