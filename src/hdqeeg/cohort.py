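"""Synthetic two-group resting-EEG cohort generator.

Emulates a control vs. HD-gene-carrier resting EEG study: each channel is
a sum of band-limited Gaussian-noise carriers (delta/theta/alpha/beta,
4th-order Butterworth band-passed white noise) whose per-subject log10
amplitudes are drawn from group-specific normal distributions, plus a
narrowband alpha peak (optionally split into two peaks) and an optional
extra ~22 Hz resonance in the carrier group.  Clinical scores are linear
functions of the latent spectral amplitudes plus Gaussian noise, so
correlation indices of known strength are planted and recoverable.

Group spectral contrasts default to an empirical reference table of
significant log10 band-power differences from a 25-control / 26-carrier
resting-EEG cohort (channel, classical band, group means, t, Cohen's d);
``effect_scale`` multiplies every planted difference, and
:func:`effect_scale_for_bayes_auc` converts a desired Bayes-optimal
class-separation AUC into the matching scale.

Amplitudes are calibrated analytically: for every band carrier the mean
in-band power spectral density per unit signal variance is computed from
the filter responses, so the planted log10 band powers come out on the
scale measured by the spectral pipeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import norm as _norm

from .features import CLASSICAL_BANDS
from .io import CANONICAL_CHANNELS, EEGRecording

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Reference group contrasts (log10 band power): control mean, carrier mean,
# pooled t (control minus carrier orientation), Cohen's d (carrier minus
# control orientation).  n = 25 controls / 26 carriers, df = 49.
# ---------------------------------------------------------------------------
REFERENCE_CONTRASTS: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("Fp1", "delta"): (4.5, 4.9, -3.0, 0.85),
    ("Fp2", "delta"): (4.5, 4.9, -2.9, 0.82),
    ("F3", "theta"): (3.3, 3.0, 2.8, -0.78),
    ("F4", "theta"): (3.3, 3.1, 2.5, -0.70),
    ("Fz", "theta"): (3.4, 3.1, 3.1, -0.88),
    ("C3", "delta"): (3.6, 3.8, -2.0, 0.57),
    ("C3", "theta"): (3.1, 2.9, 2.7, -0.74),
    ("C3", "alpha"): (3.2, 2.9, 2.3, -0.65),
    ("C4", "theta"): (3.1, 2.9, 3.0, -0.85),
    ("C4", "alpha"): (3.2, 2.9, 2.4, -0.66),
    ("Cz", "theta"): (3.3, 3.1, 2.3, -0.65),
    ("T3", "theta"): (3.3, 3.1, 2.3, -0.65),
    ("T3", "alpha"): (3.4, 3.1, 2.0, -0.56),
    ("T4", "delta"): (3.9, 4.1, -2.2, 0.62),
    ("T4", "theta"): (3.3, 3.1, 2.3, -0.66),
    ("T4", "alpha"): (3.4, 3.1, 2.0, -0.57),
    ("T5", "theta"): (3.5, 3.2, 2.7, -0.77),
    ("T5", "alpha"): (3.7, 3.4, 2.3, -0.65),
    ("T6", "delta"): (3.9, 4.1, -2.1, 0.58),
    ("T6", "theta"): (3.4, 3.2, 1.8, -0.51),
    ("Pz", "theta"): (3.2, 3.1, 2.2, -0.62),
    ("Pz", "alpha"): (3.5, 3.1, 2.1, -0.58),
}

#: Baseline log10 band power for channel/band cells with no planted contrast.
BASELINE_POWER = {"delta": 4.0, "theta": 3.3, "alpha": 3.4, "beta": 3.0}
#: Baseline between-subject SD of log10 band power for cells without contrast.
BASELINE_SD = 0.4

POSTERIOR_CHANNELS = ("T5", "P3", "Pz", "P4", "T6", "O1", "O2")

CLINICAL_SCORES = ("UHDRS-TMS", "SDMT", "SWR", "TFC", "BDI-II", "CAG", "age")


@dataclass(frozen=True)
class EffectEntry:
    """Planted group contrast for one (channel, band) cell, power scale."""

    control_mean: float
    carrier_mean: float
    sd: float

    @property
    def diff(self) -> float:
        """Control-minus-carrier mean difference."""
        return self.control_mean - self.carrier_mean

    @property
    def d(self) -> float:
        """Cohen's d, carrier-minus-control orientation."""
        return (self.carrier_mean - self.control_mean) / self.sd


def default_effect_table() -> dict[tuple[str, str], EffectEntry]:
    """All 19 x 4 cells; the reference contrasts where tabulated."""
    table = {}
    for ch in CANONICAL_CHANNELS:
        for band in CLASSICAL_BANDS:
            if (ch, band) in REFERENCE_CONTRASTS:
                cm, hm, _t, d = REFERENCE_CONTRASTS[(ch, band)]
                sd = abs(cm - hm) / abs(d)
                table[(ch, band)] = EffectEntry(cm, hm, sd)
            else:
                base = BASELINE_POWER[band]
                table[(ch, band)] = EffectEntry(base, base, BASELINE_SD)
    return table


@dataclass(frozen=True)
class AlphaPeak:
    center: float = 10.0       # Hz
    bandwidth: float = 2.0     # Hz
    amplitude: float = 1.0     # relative to the broadband alpha carrier
    split: bool = False        # two peaks instead of one (carrier group)
    split_separation: float = 3.0  # Hz between the two peaks
    channels: tuple[str, ...] = POSTERIOR_CHANNELS


@dataclass(frozen=True)
class CarrierResonance:
    """Optional extra narrowband resonance in the carrier group."""

    center: float = 22.0
    bandwidth: float = 2.0
    amplitude: float = 0.0     # 0 disables; relative to the beta carrier
    channels: tuple[str, ...] = ("T4", "T6")


@dataclass(frozen=True)
class Coupling:
    """Linear map from standardized latent amplitudes to a clinical score."""

    latents: tuple[tuple[str, float], ...]  # (("Fz:theta", weight), ...)
    noise_sd: float
    intercept: float
    clip: tuple[float, float] | None = None

    def planted_r(self) -> dict[str, float]:
        """Population Pearson r between the score and each latent."""
        total = sum(w**2 for _, w in self.latents) + self.noise_sd**2
        return {name: w / np.sqrt(total) for name, w in self.latents}


def noise_sd_for_r(r: float, score_sd: float = 1.0) -> float:
    """Noise SD giving Pearson correlation ``r`` for a unit-weight latent.

    With score = w*z + eps, w = score_sd*|r| and this noise SD, the
    population correlation between score and z is exactly ``r``.
    """
    if not 0 < abs(r) <= 1:
        raise ValueError("r must be in (0, 1]")
    return score_sd * float(np.sqrt(1.0 - r**2))


def default_clinical_coupling() -> dict[str, Coupling]:
    """Couplings planting the study-scale clinical correlations.

    Cognitive and motor scores are tied to posterior/central alpha
    amplitudes (lower alpha - worse scores, the dominant association in
    the resting-EEG literature this generator emulates): SDMT to
    temporo-parietal alpha at r = 0.86 and UHDRS-TMS to central alpha at
    r = -0.84 (the motor score rises as alpha power falls); SWR and TFC
    carry weaker couplings, BDI-II is pure noise.  Alpha is also the
    band the 8-Hz analysis features express most directly, so planted
    correlations of this strength are recoverable from the features.
    """
    return {
        "SDMT": Coupling((("T5:alpha", 0.86 * 10.0),), noise_sd_for_r(0.86, 10.0), 52.0),
        "UHDRS-TMS": Coupling((("C4:alpha", -0.84 * 7.0),), noise_sd_for_r(0.84, 7.0), 6.0, clip=(0.0, 124.0)),
        "SWR": Coupling((("O2:alpha", 0.5 * 15.0),), noise_sd_for_r(0.5, 15.0), 101.0),
        "TFC": Coupling((("C4:alpha", 0.4 * 1.2),), noise_sd_for_r(0.4, 1.2), 12.6, clip=(0.0, 13.0)),
        "BDI-II": Coupling((), 5.5, 5.0, clip=(0.0, 63.0)),
    }


@dataclass(frozen=True)
class CohortConfig:
    n_control: int = 25
    n_carrier: int = 26
    sampling_rate: float = 250.0
    duration: float = 180.0
    channel_labels: tuple[str, ...] = CANONICAL_CHANNELS
    effect_table: dict = field(default_factory=default_effect_table)
    alpha_peak: AlphaPeak = field(default_factory=AlphaPeak)
    carrier_resonance: CarrierResonance = field(default_factory=CarrierResonance)
    clinical_coupling: dict = field(default_factory=default_clinical_coupling)
    effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_carrier < 2:
            raise ValueError("need at least 2 subjects per group")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x sampling_rate must be integer")
        if len(self.channel_labels) != 19 or len(set(self.channel_labels)) != 19:
            raise ValueError("exactly 19 unique channel labels required")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")
        for (ch, band), entry in self.effect_table.items():
            if ch not in self.channel_labels:
                raise ValueError(f"effect_table references unknown channel {ch!r}")
            if band not in CLASSICAL_BANDS:
                raise ValueError(f"effect_table references unknown band {band!r}")
            if entry.sd <= 0:
                raise ValueError("effect_table SDs must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "control" | "carrier"
    recording: EEGRecording | None
    clinical: dict[str, float]
    latent_truth: dict[str, float]  # "Ch:band" -> log10 amplitude


# ---------------------------------------------------------------------------
# Latent (log10 amplitude) parameterization
# ---------------------------------------------------------------------------

def _planted_power_means(config: CohortConfig, ch: str, band: str) -> tuple[float, float, float]:
    """(control mean, carrier mean, sd) of log10 band POWER after scaling."""
    entry = config.effect_table[(ch, band)]
    mid = 0.5 * (entry.control_mean + entry.carrier_mean)
    half = 0.5 * entry.diff * config.effect_scale
    return mid + half, mid - half, entry.sd


def _carrier_components(
    config: CohortConfig, ch: str, band: str, group: str
) -> tuple[tuple[float, float, float], ...]:
    """((low Hz, high Hz, weight), ...) noise components of one band carrier."""
    lo, hi = CLASSICAL_BANDS[band]
    comps = [(lo, hi, 1.0)]
    ap = config.alpha_peak
    if band == "alpha" and ap.amplitude > 0 and ch in ap.channels:
        if ap.split and group == "carrier":
            for c in (ap.center - ap.split_separation / 2, ap.center + ap.split_separation / 2):
                comps.append((c - ap.bandwidth / 2, c + ap.bandwidth / 2, ap.amplitude / np.sqrt(2)))
        else:
            comps.append((ap.center - ap.bandwidth / 2, ap.center + ap.bandwidth / 2, ap.amplitude))
    res = config.carrier_resonance
    if band == "beta" and group == "carrier" and res.amplitude > 0 and ch in res.channels:
        comps.append((res.center - res.bandwidth / 2, res.center + res.bandwidth / 2, res.amplitude))
    return tuple(comps)


_SOS_CACHE: dict = {}
_DENSITY_CACHE: dict = {}


def _band_sos(lo: float, hi: float, fs: float) -> np.ndarray:
    key = (lo, hi, fs)
    if key not in _SOS_CACHE:
        _SOS_CACHE[key] = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return _SOS_CACHE[key]


def _mean_inband_density(components, band: str, fs: float) -> float:
    """Mean in-band PSD of the unit-variance carrier, analytic.

    The carrier is a weighted sum of independent band-passed white
    noises; its PSD shape is the weight-squared sum of the squared filter
    responses.  Normalizing the carrier to unit variance, the mean
    density over the classical band's 0.5 Hz bins is what the spectral
    pipeline measures per unit amplitude squared.
    """
    key = (components, band, fs)
    if key in _DENSITY_CACHE:
        return _DENSITY_CACHE[key]
    lo, hi = CLASSICAL_BANDS[band]
    dense = np.linspace(0.0, fs / 2, 4097)
    bins = np.arange(lo, hi - 0.125, 0.5)
    shape_dense = np.zeros_like(dense)
    shape_bins = np.zeros_like(bins)
    for flo, fhi, w in components:
        sos = _band_sos(flo, fhi, fs)
        _, h_d = signal.sosfreqz(sos, worN=dense, fs=fs)
        _, h_b = signal.sosfreqz(sos, worN=bins, fs=fs)
        shape_dense += w**2 * np.abs(h_d) ** 2
        shape_bins += w**2 * np.abs(h_b) ** 2
    variance = np.trapezoid(shape_dense, dense)  # one-sided integral
    m = float(shape_bins.mean() / variance)
    _DENSITY_CACHE[key] = m
    return m


def latent_distribution(
    config: CohortConfig, ch: str, band: str, group: str
) -> tuple[float, float]:
    """(mean, sd) of the latent log10 AMPLITUDE for one cell and group.

    Power is quadratic in amplitude, so latent moments are half the
    power-scale moments, with the carrier's in-band density folded in so
    the measured log10 band power matches the planted value.
    """
    ctrl, carr, sd = _planted_power_means(config, ch, band)
    target = ctrl if group == "control" else carr
    comps = _carrier_components(config, ch, band, group)
    m = _mean_inband_density(comps, band, config.sampling_rate)
    return 0.5 * (target - np.log10(m)), 0.5 * sd


def latent_mixture_stats(config: CohortConfig, latent: str) -> tuple[float, float]:
    """Population mean and SD of a latent over the two-group mixture."""
    ch, band = latent.split(":")
    m1, s1 = latent_distribution(config, ch, band, "control")
    m2, s2 = latent_distribution(config, ch, band, "carrier")
    p1 = config.n_control / (config.n_control + config.n_carrier)
    p2 = 1.0 - p1
    mean = p1 * m1 + p2 * m2
    var = p1 * s1**2 + p2 * s2**2 + p1 * p2 * (m1 - m2) ** 2
    return mean, float(np.sqrt(var))


def planted_bayes_auc(config: CohortConfig) -> float:
    """Bayes-optimal AUC of the planted latent class contrast.

    The latents are independent Gaussians with common within-group SD,
    so the optimal discriminant achieves AUC = Phi(Delta / sqrt(2)) with
    Delta the Mahalanobis distance between the group means.
    """
    d2 = 0.0
    for ch in config.channel_labels:
        for band in CLASSICAL_BANDS:
            ctrl, carr, sd = _planted_power_means(config, ch, band)
            d2 += ((ctrl - carr) / sd) ** 2
    return float(_norm.cdf(np.sqrt(d2 / 2.0)))


def effect_scale_for_bayes_auc(target_auc: float, config: CohortConfig | None = None) -> float:
    """Effect scale making the planted Bayes-optimal AUC equal ``target_auc``."""
    base = config or CohortConfig()
    d2 = 0.0
    for ch in base.channel_labels:
        for band in CLASSICAL_BANDS:
            entry = base.effect_table[(ch, band)]
            d2 += (entry.diff / entry.sd) ** 2
    if d2 == 0:
        raise ValueError("effect table plants no contrast")
    return float(np.sqrt(2.0) * _norm.ppf(target_auc) / np.sqrt(d2))


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------

def _subject_rng(config: CohortConfig, index: int) -> np.random.Generator:
    """Independent substream per subject index; stable under cohort growth."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))


def draw_latents(config: CohortConfig, group: str, rng: np.random.Generator) -> dict[str, float]:
    """Draw one subject's latent log10 amplitudes (canonical cell order)."""
    latents = {}
    for ch in config.channel_labels:
        for band in CLASSICAL_BANDS:
            mean, sd = latent_distribution(config, ch, band, group)
            latents[f"{ch}:{band}"] = float(rng.normal(mean, sd))
    return latents


def draw_clinical(
    config: CohortConfig, group: str, latents: dict[str, float], rng: np.random.Generator
) -> dict[str, float]:
    """Clinical scores from the latent couplings plus demographics."""
    clinical: dict[str, float] = {}
    for score, coupling in config.clinical_coupling.items():
        value = coupling.intercept
        for name, weight in coupling.latents:
            mean, sd = latent_mixture_stats(config, name)
            value += weight * (latents[name] - mean) / sd
        value += coupling.noise_sd * rng.standard_normal()
        if coupling.clip is not None:
            clipped = float(np.clip(value, *coupling.clip))
            if clipped != value:
                logger.debug("clipped %s from %.2f to %.2f", score, value, clipped)
            value = clipped
        clinical[score] = float(value)
    if group == "carrier":
        clinical["CAG"] = float(np.clip(np.round(rng.normal(43.2, 2.3)), 40, 55))
        clinical["age"] = float(np.clip(rng.normal(49.7, 8.5), 25, 75))
    else:
        clinical["CAG"] = float("nan")
        clinical["age"] = float(np.clip(rng.normal(52.7, 8.7), 25, 75))
    return clinical


def _synthesize_recording(
    config: CohortConfig, group: str, latents: dict[str, float], rng: np.random.Generator
) -> EEGRecording:
    n = config.n_samples
    fs = config.sampling_rate
    pad = int(round(2.0 * fs))  # discard the filter transient
    samples = np.empty((19, n))
    for c, ch in enumerate(config.channel_labels):
        total = np.zeros(n)
        for band in CLASSICAL_BANDS:
            comps = _carrier_components(config, ch, band, group)
            carrier = np.zeros(n)
            for flo, fhi, w in comps:
                white = rng.standard_normal(n + pad)
                filtered = signal.sosfilt(_band_sos(flo, fhi, fs), white)[pad:]
                carrier += w * filtered
            carrier /= carrier.std()
            total += 10.0 ** latents[f"{ch}:{band}"] * carrier
        samples[c] = total
    return EEGRecording(samples, fs, config.channel_labels)


def generate_subject(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "S000",
    signals: bool = True,
) -> SubjectRecord:
    """Generate one subject: latents -> clinical scores -> (optionally) EEG.

    ``signals=False`` skips waveform synthesis and leaves ``recording``
    as ``None`` — the fast path for latent-level calibration studies.
    """
    if group not in ("control", "carrier"):
        raise ValueError(f"unknown group {group!r}")
    latents = draw_latents(config, group, rng)
    clinical = draw_clinical(config, group, latents, rng)
    recording = _synthesize_recording(config, group, latents, rng) if signals else None
    return SubjectRecord(subject_id, group, recording, clinical, latents)


def generate_cohort(config: CohortConfig, signals: bool = True) -> tuple[list[SubjectRecord], dict]:
    """Generate the full cohort plus a ground-truth manifest.

    Controls come first (``C001`` ...), then carriers (``H001`` ...).
    Identical config and seed reproduce the cohort exactly.
    """
    subjects = []
    groups = ["control"] * config.n_control + ["carrier"] * config.n_carrier
    for i, group in enumerate(groups):
        prefix = "C" if group == "control" else "H"
        num = i + 1 if group == "control" else i + 1 - config.n_control
        subjects.append(
            generate_subject(config, group, _subject_rng(config, i), f"{prefix}{num:03d}", signals)
        )
    manifest = {
        "seed": config.seed,
        "n_control": config.n_control,
        "n_carrier": config.n_carrier,
        "effect_scale": config.effect_scale,
        "planted_d": {
            f"{ch}:{band}": -(_planted_power_means(config, ch, band)[0]
                              - _planted_power_means(config, ch, band)[1])
            / _planted_power_means(config, ch, band)[2]
            for ch in config.channel_labels
            for band in CLASSICAL_BANDS
        },
        "planted_r": {
            score: coupling.planted_r()
            for score, coupling in config.clinical_coupling.items()
        },
        "bayes_auc": planted_bayes_auc(config),
    }
    return subjects, manifest


# ---------------------------------------------------------------------------
# On-disk cohort layout: per-subject EDF + clinical CSV + manifest JSON
# ---------------------------------------------------------------------------

def write_cohort(subjects: list[SubjectRecord], manifest: dict, out_dir) -> None:
    from pathlib import Path

    from .io import write_edf_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        if s.recording is not None:
            write_edf_recording(out / f"{s.subject_id}.edf", s.recording, physical_max=8000.0)
        rows.append({"subject_id": s.subject_id, "group": s.group, **s.clinical})
    pd.DataFrame(rows).to_csv(out / "clinical.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path)
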