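"""Minimal 16-bit EDF writer (1-second data records, fixed physical range)."""

from __future__ import annotations

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    samples: np.ndarray,
    sampling_rate: float,
    labels: list[str],
    physical_max: float = 2000.0,
    physical_dim: str = "uV",
) -> None:
    """Write ``samples`` (channels x time, microvolts) as EDF.

    The data are stored in 1-second records at 16-bit resolution over the
    symmetric physical range ``[-physical_max, physical_max]``; values
    outside it are clipped.  The sampling rate must be a whole number of
    samples per second and the signal is truncated to whole records.
    """
    samples = np.asarray(samples, dtype=float)
    n_ch, n_times = samples.shape
    if len(labels) != n_ch:
        raise ValueError("one label per channel required")
    spr = int(round(sampling_rate))
    if abs(sampling_rate - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = n_times // spr
    if n_records == 0:
        raise ValueError("recording shorter than one 1-s data record")
    samples = samples[:, : n_records * spr]

    scale = (_DIG_MAX - _DIG_MIN) / (2.0 * physical_max)
    digital = np.round((np.clip(samples, -physical_max, physical_max) + physical_max) * scale) + _DIG_MIN
    digital = digital.astype("<i2")

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),          # patient id
            _field("Startdate X X X X", 80),  # recording id
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (n_ch + 1)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),                  # record duration, seconds
            _field(str(n_ch), 4),
        ]
    )
    sig = b"".join(_field(lab, 16) for lab in labels)
    sig += b"".join(_field("", 80) for _ in labels)
    sig += b"".join(_field(physical_dim, 8) for _ in labels)
    sig += b"".join(_field(f"{-physical_max:g}", 8) for _ in labels)
    sig += b"".join(_field(f"{physical_max:g}", 8) for _ in labels)
    sig += b"".join(_field(str(_DIG_MIN), 8) for _ in labels)
    sig += b"".join(_field(str(_DIG_MAX), 8) for _ in labels)
    sig += b"".join(_field("", 80) for _ in labels)
    sig += b"".join(_field(str(spr), 8) for _ in labels)
    sig += b"".join(_field("", 32) for _ in labels)

    # record-major layout: for each 1-s record, all channels back to back
    records = digital.reshape(n_ch, n_records, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(np.ascontiguousarray(records).tobytes())


def quantization_step(physical_max: float = 2000.0) -> float:
    """Physical value of one digital unit for the writer's settings."""
    return 2.0 * physical_max / (_DIG_MAX - _DIG_MIN)
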