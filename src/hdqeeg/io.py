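"""Recording I/O and montage handling.

Defines the canonical 19-channel 10-20 analysis montage, the
:class:`EEGRecording` container, readers/writers for EDF and plain CSV
matrices, and the average-reference transform.  The canonical channel
order fixed here determines every downstream feature ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from ._edf import write_edf

logger = logging.getLogger(__name__)

#: Canonical 10-20 analysis channels, in the order all feature vectors use.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: Modern 10-10 names mapped back to the classic temporal labels.
CHANNEL_ALIASES: dict[str, str] = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

_CANONICAL_LOWER = {c.lower(): c for c in CANONICAL_CHANNELS}

#: Recordings shorter than this (seconds) are rejected by the readers.
MIN_DURATION_S = 60.0
#: Recordings longer than this are truncated to it.
MAX_DURATION_S = 180.0


class MissingChannelError(ValueError):
    """A required analysis channel is absent from the input file."""


def normalize_channel_label(raw: str) -> str | None:
    """Map a raw channel label onto the canonical 10-20 set.

    Handles case differences, ``EEG ``/reference prefixes and suffixes
    (``EEG Fp1-REF``), and the T7/T8/P7/P8 aliases.  Returns ``None`` for
    non-analysis leads (EOG, ECG, ...).
    """
    name = raw.strip()
    for prefix in ("EEG ", "eeg "):
        if name.startswith(prefix):
            name = name[len(prefix):]
    name = name.split("-")[0].strip()
    canon = _CANONICAL_LOWER.get(name.lower())
    if canon is not None:
        return canon
    alias = {k.lower(): v for k, v in CHANNEL_ALIASES.items()}.get(name.lower())
    return alias


@dataclass(frozen=True)
class EEGRecording:
    """A multichannel EEG recording in microvolts.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    sampling_rate : float
        Sampling frequency in Hz.  Must exceed twice the 45 Hz analysis
        cutoff.
    channel_labels : tuple of str
        One label per row of ``samples``.
    reference_state : {"as-recorded", "average"}
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] = CANONICAL_CHANNELS
    reference_state: str = "as-recorded"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if len(self.channel_labels) != samples.shape[0]:
            raise ValueError("channel_labels length must match sample rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain NaN or Inf")
        if self.sampling_rate <= 2 * 45.0:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz too low for the 45 Hz "
                "analysis cutoff (need > 90 Hz)"
            )
        if self.reference_state not in ("as-recorded", "average"):
            raise ValueError(f"unknown reference_state {self.reference_state!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.sampling_rate


def apply_average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the instantaneous mean across channels.

    After the transform the channel sum is zero at every time point.
    Applying it twice is an error (the operation would be a silent no-op).
    """
    if rec.reference_state == "average":
        raise ValueError("recording is already average-referenced")
    referenced = rec.samples - rec.samples.mean(axis=0, keepdims=True)
    return replace(rec, samples=referenced, reference_state="average")


def _select_analysis_channels(
    data: np.ndarray, labels: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Keep the 19 canonical channels, in canonical order; drop the rest."""
    canon_map: dict[str, int] = {}
    dropped: list[str] = []
    for i, raw in enumerate(labels):
        canon = normalize_channel_label(raw)
        if canon is None:
            dropped.append(raw)
        elif canon not in canon_map:  # first occurrence wins
            canon_map[canon] = i
    missing = [c for c in CANONICAL_CHANNELS if c not in canon_map]
    if missing:
        raise MissingChannelError(
            f"missing analysis channel(s): {', '.join(missing)}"
        )
    if dropped:
        logger.info("dropping %d non-EEG lead(s): %s", len(dropped), dropped)
    order = [canon_map[c] for c in CANONICAL_CHANNELS]
    return data[order], list(CANONICAL_CHANNELS)


def _truncate(samples: np.ndarray, rate: float) -> np.ndarray:
    n_max = int(round(MAX_DURATION_S * rate))
    duration = samples.shape[1] / rate
    if duration < MIN_DURATION_S:
        raise ValueError(
            f"recording is {duration:.1f} s; minimum is {MIN_DURATION_S:.0f} s"
        )
    if samples.shape[1] > n_max:
        logger.info("truncating recording to first %.0f s", MAX_DURATION_S)
        samples = samples[:, :n_max]
    return samples


def read_edf(path) -> EEGRecording:
    """Read an EDF file, returning the 19 analysis channels in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    samples, labels = _select_analysis_channels(data_uv, raw.ch_names)
    samples = _truncate(samples, raw.info["sfreq"])
    return EEGRecording(samples, float(raw.info["sfreq"]), tuple(labels))


def read_csv_matrix(path) -> EEGRecording:
    """Read a CSV sample matrix (one column per channel, header row of labels).

    The first line must be a ``# sampling_rate_hz=<rate>`` comment, as
    written by :func:`write_csv_matrix`.
    """
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# sampling_rate_hz="):
            raise ValueError(
                "CSV matrix must start with '# sampling_rate_hz=<rate>'"
            )
        rate = float(first.split("=", 1)[1])
        header = fh.readline().strip().split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    samples, labels = _select_analysis_channels(data.T, header)
    samples = _truncate(samples, rate)
    return EEGRecording(samples, rate, tuple(labels))


def write_csv_matrix(path, rec: EEGRecording) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={rec.sampling_rate:g}\n")
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.samples.T, delimiter=",", fmt="%.6f")


def write_edf_recording(path, rec: EEGRecording, physical_max: float = 2000.0) -> None:
    """Write a recording as 16-bit EDF (microvolt units, 1-s records)."""
    write_edf(
        path,
        rec.samples,
        rec.sampling_rate,
        list(rec.channel_labels),
        physical_max=physical_max,
    )


def read_recording(path, format: str | None = None) -> EEGRecording:
    """Read a recording, dispatching on ``format`` or the file extension."""
    fmt = format
    if fmt is None:
        name = str(path).lower()
        fmt = "EDF" if name.endswith(".edf") else "CSV-matrix"
    if fmt.upper() == "EDF":
        return read_edf(path)
    if fmt.upper() in ("CSV", "CSV-MATRIX"):
        return read_csv_matrix(path)
    raise ValueError(f"unknown recording format {format!r}")
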