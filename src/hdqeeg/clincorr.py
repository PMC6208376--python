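"""Clinical-correlation indices: GA-searched PCA feature-subset scores.

For a chosen clinical modality (e.g. SDMT or UHDRS-TMS) a genetic
algorithm searches feature subsets whose first principal component score
maximally Pearson-correlates with the modality.  The fitted index — a
feature subset, per-feature standardization, and a unit-norm loading
vector oriented so the achieved correlation is positive — can then be
applied to new subjects, or evaluated within one subject on 5
consecutive sub-recordings to expose intra-recording variability.

GA-optimized in-sample correlations are upward-biased at small n; the
recommended protocol applies a fitted index to held-out subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .features import BandSet, assemble_feature_vector
from .ga import GAConfig, ga_optimize
from .io import EEGRecording, apply_average_reference
from .spectra import compute_spectrum_set

logger = logging.getLogger(__name__)

N_SUB_RECORDINGS = 5


@dataclass
class CorrelationIndex:
    modality: str
    subset: list[str]            # feature names
    loc: np.ndarray
    scale: np.ndarray
    loading: np.ndarray          # unit norm, oriented so achieved_r >= 0
    achieved_r: float

    def apply(self, features: pd.DataFrame | pd.Series) -> np.ndarray:
        """Index value(s) for new feature vectors (named columns)."""
        if isinstance(features, pd.Series):
            features = features.to_frame().T
        Z = (features[self.subset].to_numpy(float) - self.loc) / self.scale
        return Z @ self.loading


def pca_first_component(
    X: np.ndarray, orient_with: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """First principal axis and scores of an already-standardized matrix.

    Zero-variance columns must have been removed.  If ``orient_with`` is
    given, the loading sign is fixed so the scores correlate positively
    with it; otherwise the largest loading entry is made positive.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    loading = vt[0]
    scores = Xc @ loading
    if orient_with is not None:
        r = np.corrcoef(scores, orient_with)[0, 1]
        if r < 0:
            loading, scores = -loading, -scores
    elif loading[np.argmax(np.abs(loading))] < 0:
        loading, scores = -loading, -scores
    return loading, scores


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    loc = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    keep = scale > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance feature(s)", int((~keep).sum()))
    return loc, np.where(keep, scale, 1.0), keep


def ga_correlate(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    modality: str,
    ga: GAConfig,
    rng: np.random.Generator | None = None,
    screen_size: int | None = 30,
) -> CorrelationIndex:
    """Search for the feature subset whose PC1 best correlates with a score.

    Only complete cases (subjects with the modality present) enter the
    fit; the returned index is oriented so ``achieved_r >= 0``.

    ``screen_size`` restricts the GA search to the features with the
    largest marginal |Pearson r| against the modality (sure-independence
    screening).  At pilot-study sample sizes an unrestricted subset
    search maximizing in-sample correlation is dominated by selection
    noise — subsets that look good by chance generalize poorly — while a
    screened pool keeps the search among features that individually
    carry signal.  Pass ``None`` to search the full feature set.
    """
    scores = clinical.set_index("subject_id").loc[features.index, modality]
    mask = scores.notna().to_numpy()
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 complete cases for {modality}")
    y = scores.to_numpy(float)[mask]
    if np.std(y) == 0:
        raise ValueError(f"modality {modality} is constant")
    X = features.to_numpy(float)[mask]
    loc, scale, keep = _standardize(X)
    Z = (X - loc) / scale
    usable = np.flatnonzero(keep)
    if screen_size is not None and screen_size < len(usable):
        yc = y - y.mean()
        marginal = np.abs(
            (Z[:, usable] * yc[:, None]).sum(axis=0)
            / (len(y) * yc.std() + 1e-300)
        )
        usable = usable[np.argsort(marginal)[::-1][: max(screen_size, ga.subset_size)]]
        usable.sort()

    def fitness(subset: tuple[int, ...]) -> float:
        cols = usable[list(subset)]
        _, pc = pca_first_component(Z[:, cols])
        if pc.std() == 0:
            return 0.0
        return abs(float(np.corrcoef(pc, y)[0, 1]))

    best, _trace = ga_optimize(len(usable), fitness, ga, rng)
    cols = usable[list(best)]
    loading, pc = pca_first_component(Z[:, cols], orient_with=y)
    r = float(np.corrcoef(pc, y)[0, 1])
    return CorrelationIndex(
        modality=modality,
        subset=[features.columns[c] for c in cols],
        loc=loc[cols],
        scale=scale[cols],
        loading=loading,
        achieved_r=r,
    )


def index_correlation(
    index: CorrelationIndex, features: pd.DataFrame, clinical: pd.DataFrame
) -> tuple[float, float]:
    """Pearson r (and p) between the index and its modality on a cohort."""
    scores = clinical.set_index("subject_id").loc[features.index, index.modality]
    mask = scores.notna().to_numpy()
    values = index.apply(features)[mask]
    r, p = pearsonr(values, scores.to_numpy(float)[mask])
    return float(r), float(p)


def evaluate_index_on_segments(
    rec: EEGRecording,
    index: CorrelationIndex,
    bands: BandSet | None = None,
    log_transform: bool = True,
) -> dict:
    """Index values over 5 equal consecutive sub-recordings of one subject.

    The full spectra-to-features pipeline is rerun on each fifth of the
    recording (36 s for a 180-s input), so the profile reflects genuine
    re-estimation, not a split of precomputed features.
    """
    min_samples = N_SUB_RECORDINGS * int(round(2.0 * rec.sampling_rate))
    if rec.n_times < min_samples:
        raise ValueError(
            f"recording too short: need >= {min_samples / rec.sampling_rate:.0f} s "
            f"({N_SUB_RECORDINGS} sub-recordings of >= 2 s each)"
        )
    if rec.reference_state != "average":
        rec = apply_average_reference(rec)
    piece = rec.n_times // N_SUB_RECORDINGS
    values = []
    for k in range(N_SUB_RECORDINGS):
        sub = EEGRecording(
            rec.samples[:, k * piece: (k + 1) * piece],
            rec.sampling_rate,
            rec.channel_labels,
            reference_state="average",
        )
        feats = assemble_feature_vector(compute_spectrum_set(sub), bands, log_transform)
        values.append(float(index.apply(feats)[0]))
    return {"values": values, "mean": float(np.mean(values))}
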