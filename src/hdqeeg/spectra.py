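"""Robust auto- and cross-spectral estimation on the 0-45 Hz, 0.5 Hz grid.

The estimator follows a segment-ensemble design: the average-referenced
recording is cut into 2-s segments overlapping by 1 s, each segment is
Bartlett-windowed and Fourier-transformed, and a robust location estimate
(Tukey biweight) is taken per frequency bin over the ensemble.  Besides
the 19 single-channel power spectra, the magnitude of the cross-spectral
density is computed for all 171 electrode pairs — by the Wiener-Khinchin
theorem this is the power spectrum of the cross-correlation function of
the pair.

All spectra are one-sided densities: ``P_k = 2|X_k|^2 / (fs * sum(w^2))``
with the DC and Nyquist bins not doubled, so that summing ``P_k * df``
over the full grid recovers the mean power of the windowed signal
(Parseval).  Only the 91 bins 0.0, 0.5, ..., 45.0 Hz are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.signal.windows import bartlett as _scipy_bartlett

from .io import EEGRecording

SEGMENT_SECONDS = 2.0
HOP_SECONDS = 1.0
F_MAX = 45.0
F_STEP = 0.5
N_BINS = int(F_MAX / F_STEP) + 1  # 91, DC included

FREQUENCIES = np.arange(N_BINS) * F_STEP

#: Tukey biweight tuning constant (95% Gaussian efficiency).
BIWEIGHT_C = 4.685
_MAD_SCALE = 1.4826


@dataclass(frozen=True)
class SegmentEnsemble:
    """Overlapping 2-s segments of a recording."""

    segments: np.ndarray  # (n_segments, n_channels, window_length)
    window_length: int
    hop: int
    sampling_rate: float

    @property
    def count(self) -> int:
        return self.segments.shape[0]


@dataclass(frozen=True)
class SpectrumSet:
    """19 single-channel + 171 pairwise robust spectra for one recording."""

    frequencies: np.ndarray           # (91,)
    single_channel: np.ndarray        # (19, 91)
    pairwise: np.ndarray              # (171, 91)
    channel_labels: tuple[str, ...]
    pair_index: tuple[tuple[int, int], ...]

    @property
    def spectrum_names(self) -> list[str]:
        """Channel names followed by 'AxB' pair names, canonical order."""
        names = list(self.channel_labels)
        names += [
            f"{self.channel_labels[i]}x{self.channel_labels[j]}"
            for i, j in self.pair_index
        ]
        return names

    def all_spectra(self) -> np.ndarray:
        """(190, 91) stack, single-channel rows first."""
        return np.vstack([self.single_channel, self.pairwise])


def spectrum_set_to_frame(ss: SpectrumSet):
    """Tabular form: a frequency column plus 190 named spectrum columns."""
    import pandas as pd

    data = {"frequency_hz": ss.frequencies}
    for name, row in zip(ss.spectrum_names, ss.all_spectra()):
        data[name] = row
    return pd.DataFrame(data)


def frame_to_spectrum_set(frame, channel_labels: tuple[str, ...]) -> SpectrumSet:
    """Inverse of :func:`spectrum_set_to_frame` for the canonical montage."""
    n_ch = len(channel_labels)
    pairs = channel_pairs(n_ch)
    single = np.stack([frame[c].to_numpy(float) for c in channel_labels])
    pairwise = np.stack(
        [
            frame[f"{channel_labels[i]}x{channel_labels[j]}"].to_numpy(float)
            for i, j in pairs
        ]
    )
    return SpectrumSet(
        frame["frequency_hz"].to_numpy(float), single, pairwise, channel_labels, pairs
    )


def channel_pairs(n_channels: int = 19) -> tuple[tuple[int, int], ...]:
    """All unordered channel pairs (i < j), lexicographic in canonical order."""
    return tuple(combinations(range(n_channels), 2))


def segment_signal(rec: EEGRecording) -> SegmentEnsemble:
    """Cut into consecutive 2-s segments with 1-s overlap.

    A partial final segment is discarded; a recording shorter than one
    segment is an error.
    """
    if rec.reference_state != "average":
        raise ValueError("recording must be average-referenced before analysis")
    win = int(round(SEGMENT_SECONDS * rec.sampling_rate))
    hop = int(round(HOP_SECONDS * rec.sampling_rate))
    if rec.n_times < win:
        raise ValueError("recording shorter than one 2-s segment")
    n_seg = (rec.n_times - win) // hop + 1
    idx = np.arange(win)[None, :] + hop * np.arange(n_seg)[:, None]
    segments = rec.samples.T[idx].transpose(0, 2, 1)  # (n_seg, n_ch, win)
    return SegmentEnsemble(segments, win, hop, rec.sampling_rate)


def bartlett_weights(n: int) -> np.ndarray:
    """Triangular (Bartlett) window: w[k] = 1 - |2k/(n-1) - 1|."""
    if n < 2:
        raise ValueError("window length must be >= 2")
    return _scipy_bartlett(n, sym=True)


def _segment_ffts(ensemble: SegmentEnsemble) -> tuple[np.ndarray, float]:
    """Windowed rfft of every segment/channel, truncated to the 91-bin grid.

    Returns the complex coefficients (n_seg, n_ch, 91) and the density
    normalization ``1 / (fs * sum(w^2))``.
    """
    rate = ensemble.sampling_rate
    if rate < 2 * F_MAX + 2:
        raise ValueError(f"sampling rate {rate} Hz cannot resolve the 45 Hz bin")
    w = bartlett_weights(ensemble.window_length)
    fft = np.fft.rfft(ensemble.segments * w, axis=-1)
    # 2-s segments put the grid bins at k = 0, 1, ... directly
    fft = fft[..., :N_BINS]
    norm = 1.0 / (rate * float(np.sum(w**2)))
    return fft, norm


def segment_power_spectrum(segment: np.ndarray, rate: float) -> np.ndarray:
    """One-sided Bartlett-windowed periodogram of a single 2-s segment."""
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    ens = SegmentEnsemble(segment[None, ...], segment.shape[-1], segment.shape[-1], rate)
    fft, norm = _segment_ffts(ens)
    # re(X conj(X)) rather than |X|^2 so the self-pair cross spectrum is
    # bit-identical to the auto spectrum
    spec = 2.0 * norm * (fft[0] * np.conj(fft[0])).real
    spec[..., 0] /= 2.0  # DC not doubled
    return np.squeeze(spec)


def cross_spectrum(segment_a: np.ndarray, segment_b: np.ndarray, rate: float) -> np.ndarray:
    """Magnitude of the cross-spectral density of two same-length segments.

    For identical inputs this equals :func:`segment_power_spectrum` exactly.
    """
    seg = np.stack([np.asarray(segment_a, float), np.asarray(segment_b, float)])
    ens = SegmentEnsemble(seg[None, ...], seg.shape[-1], seg.shape[-1], rate)
    fft, norm = _segment_ffts(ens)
    cross = 2.0 * norm * np.abs(fft[0, 0] * np.conj(fft[0, 1]))
    cross[0] /= 2.0
    return cross


def robust_ensemble_estimate(
    per_segment: np.ndarray,
    c: float = BIWEIGHT_C,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> np.ndarray:
    """Tukey-biweight location per column over an (N, n_bins) ensemble.

    Initialized at the median with a fixed MAD scale; columns with zero
    MAD fall back to the median.  Vectorized over all bins at once.
    """
    x = np.atleast_2d(np.asarray(per_segment, dtype=float))
    if x.shape[0] == 1:
        return x[0].copy()
    med = np.median(x, axis=0)
    mad = _MAD_SCALE * np.median(np.abs(x - med), axis=0)
    degenerate = mad <= 0
    scale = np.where(degenerate, 1.0, c * mad)
    mu = med.copy()
    # iterate only the columns that have not yet converged
    active = np.arange(x.shape[1])
    xa, sa, mua = x, scale, mu
    for _ in range(max_iter):
        u = (xa - mua) / sa
        w = np.square(1.0 - u**2)
        w[np.abs(u) >= 1.0] = 0.0
        wsum = w.sum(axis=0)
        ok = wsum > 0
        new = np.where(ok, (w * xa).sum(axis=0) / np.where(ok, wsum, 1.0), mua)
        done = np.abs(new - mua) <= tol * (np.abs(new) + 1e-300)
        mu[active] = new
        if done.all():
            break
        keep = ~done
        active = active[keep]
        xa, sa, mua = xa[:, keep], sa[keep], new[keep]
    mu[degenerate] = med[degenerate]
    return mu


def compute_spectrum_set(rec: EEGRecording) -> SpectrumSet:
    """Full robust spectral decomposition of one recording.

    Produces the 19 single-channel spectra and the 171 pairwise
    cross-correlation spectra (19 + 171 = 190 spectra, 190 x 91 = 17290
    spectral values).
    """
    ens = segment_signal(rec)
    fft, norm = _segment_ffts(ens)  # (N, 19, 91)
    pairs = channel_pairs(rec.n_channels)
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])

    # single precision throughout the batched ensemble: the per-segment
    # periodograms feed a robust location estimate, where float32's ~1e-7
    # relative precision is far below the segment-to-segment variability
    re = fft.real.astype(np.float32)
    im = fft.imag.astype(np.float32)
    norm2 = np.float32(2.0 * norm)
    auto = norm2 * (re**2 + im**2)
    auto[..., 0] /= 2.0
    # |X_i conj(X_j)| expanded into real arithmetic
    cr = re[:, ii, :] * re[:, jj, :] + im[:, ii, :] * im[:, jj, :]
    ci = im[:, ii, :] * re[:, jj, :] - re[:, ii, :] * im[:, jj, :]
    cross = norm2 * np.sqrt(cr**2 + ci**2)
    cross[..., 0] /= 2.0

    n_seg = ens.count
    stacked = np.concatenate(
        [auto.reshape(n_seg, -1), cross.reshape(n_seg, -1)], axis=1
    )
    robust = robust_ensemble_estimate(stacked).astype(float)
    single = robust[: rec.n_channels * N_BINS].reshape(rec.n_channels, N_BINS)
    pairwise = robust[rec.n_channels * N_BINS:].reshape(len(pairs), N_BINS)
    return SpectrumSet(
        FREQUENCIES.copy(), single, pairwise, rec.channel_labels, pairs
    )
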