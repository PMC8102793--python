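"""Minimal European Data Format (EDF) writer.

EDF is a fixed-layout ASCII-header + 16-bit-integer format; this writer emits
one continuous multichannel recording with 1-second data records and physical
units of microvolts. Reading is delegated to :func:`mne.io.read_raw_edf`
(see :func:`read_edf_uv`), which also serves as the round-trip check in the
test suite. Amplitude resolution is ``2 * phys_max / 65535`` (~0.01 uV at the
default range); values outside the physical range are clipped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

DEFAULT_PHYS_MAX_UV = 327.68


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def write_edf(path: str | Path, data: np.ndarray, sampling_rate: float,
              channel_labels: list[str], phys_max: float = DEFAULT_PHYS_MAX_UV,
              patient_id: str = "X", recording_id: str = "synthetic") -> None:
    """Write a channels x samples array (microvolts) as an EDF file.

    ``sampling_rate`` must be an integer number of samples per second (EDF
    data records here are 1 s long). The final partial record, if any, is
    zero-padded.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    if len(channel_labels) != n_ch:
        raise ValueError("channel_labels must match the channel axis")
    spr = int(round(sampling_rate))
    if abs(spr - sampling_rate) > 1e-9:
        raise ValueError("sampling_rate must be an integer for 1 s EDF records")
    n_rec = int(np.ceil(n_samp / spr))

    dig_max, dig_min = 32767, -32768
    scale = dig_max / phys_max
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = np.clip(data, -phys_max, phys_max)
    digital = np.round(padded * scale).astype("<i2")

    header = b"".join([
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field("01.01.21", 8),
        _field("00.00.00", 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    per_signal = b"".join([
        b"".join(_field(lab[:16], 16) for lab in channel_labels),
        b"".join(_field("", 80) for _ in range(n_ch)),          # transducer
        b"".join(_field("uV", 8) for _ in range(n_ch)),
        b"".join(_field(f"{-phys_max:.2f}", 8) for _ in range(n_ch)),
        b"".join(_field(f"{phys_max:.2f}", 8) for _ in range(n_ch)),
        b"".join(_field(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(_field(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),          # prefiltering
        b"".join(_field(str(spr), 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ])

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        # record-interleaved: all samples of ch1 for record r, then ch2, ...
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def read_edf_uv(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file via MNE and return (channels x samples in uV, fs, labels)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)
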