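"""Band-feature reduction of spectra and classical band powers.

Each 91-bin spectrum is reduced to 11 features by averaging over
overlapping 8-Hz bands (starts 0, 4, ..., 40 Hz) under a triangular
Bartlett taper, the taper weights renormalized to unit sum so a constant
spectrum maps to that constant.  With 190 spectra per recording this
yields the canonical 190 x 11 = 2090-dimensional feature vector.

Classical (delta/theta/alpha/beta) log10 band powers of the
single-channel spectra are computed separately for group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import F_STEP, FREQUENCIES, N_BINS, SpectrumSet

N_BANDS = 11
BAND_WIDTH_HZ = 8.0
BAND_STEP_HZ = 4.0

#: Classical EEG bands, half-open [lo, hi) in Hz (delta starts at 0.5 to
#: exclude DC).
CLASSICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

LOG_FLOOR = 1e-30


@dataclass(frozen=True)
class BandSet:
    """The 11 overlapping Bartlett-tapered analysis bands."""

    edges: tuple[tuple[float, float], ...]   # (start, end) Hz, end may exceed 45
    weights: np.ndarray                      # (11, 91), zero outside each band

    @classmethod
    def default(cls) -> "BandSet":
        edges = []
        weights = np.zeros((N_BANDS, N_BINS))
        for k in range(N_BANDS):
            start = k * BAND_STEP_HZ
            end = start + BAND_WIDTH_HZ
            edges.append((start, end))
            center = start + BAND_WIDTH_HZ / 2
            tri = 1.0 - np.abs(FREQUENCIES - center) / (BAND_WIDTH_HZ / 2)
            w = np.clip(tri, 0.0, None)   # last band truncated at 45 Hz
            total = w.sum()
            weights[k] = w / total
        return cls(tuple(edges), weights)


_DEFAULT_BANDS = BandSet.default()


def default_bands() -> BandSet:
    return _DEFAULT_BANDS


def band_reduce(spectrum: np.ndarray, bands: BandSet | None = None) -> np.ndarray:
    """Reduce 91-bin spectra (last axis) to 11 band features each."""
    bands = bands or _DEFAULT_BANDS
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape[-1] != N_BINS:
        raise ValueError(f"expected {N_BINS}-bin spectra, got {spectrum.shape[-1]}")
    return spectrum @ bands.weights.T


def feature_names(channel_labels, pair_index) -> list[str]:
    """Deterministic '<spectrum>:band<k>' names, spectra-major, bands minor."""
    spec_names = list(channel_labels) + [
        f"{channel_labels[i]}x{channel_labels[j]}" for i, j in pair_index
    ]
    return [f"{s}:band{k}" for s in spec_names for k in range(N_BANDS)]


def assemble_feature_vector(
    ss: SpectrumSet,
    bands: BandSet | None = None,
    log_transform: bool = True,
) -> pd.Series:
    """The canonical 2090-feature vector of one recording.

    Ordered 19 single-channel spectra (canonical channel order) then 171
    pairs (lexicographic), 11 bands each, low to high.  With
    ``log_transform`` (the default) features are log10 band powers;
    nonpositive values are floored at a tiny epsilon first.
    """
    bands = bands or _DEFAULT_BANDS
    reduced = band_reduce(ss.all_spectra(), bands)  # (190, 11)
    values = reduced.ravel()
    if log_transform:
        n_floor = int(np.sum(values <= 0))
        if n_floor:
            import logging

            logging.getLogger(__name__).warning(
                "%d nonpositive band features floored before log10", n_floor
            )
        values = np.log10(np.maximum(values, LOG_FLOOR))
    names = feature_names(ss.channel_labels, ss.pair_index)
    return pd.Series(values, index=names, name="features")


def classical_band_powers(ss: SpectrumSet) -> pd.DataFrame:
    """log10 mean single-channel spectral power per (channel, classical band)."""
    rows = {}
    for band, (lo, hi) in CLASSICAL_BANDS.items():
        mask = (ss.frequencies >= lo - F_STEP / 4) & (ss.frequencies < hi - F_STEP / 4)
        mean_power = ss.single_channel[:, mask].mean(axis=1)
        rows[band] = np.log10(np.maximum(mean_power, LOG_FLOOR))
    return pd.DataFrame(rows, index=list(ss.channel_labels))


def feature_matrix(spectrum_sets, bands: BandSet | None = None, log_transform: bool = True) -> pd.DataFrame:
    """Stack per-recording feature vectors into a subjects x 2090 frame."""
    series = {sid: assemble_feature_vector(ss, bands, log_transform) for sid, ss in spectrum_sets.items()}
    return pd.DataFrame(series).T
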