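"""EDF (European Data Format) reading and writing for microvolt EEG.

Reading goes through MNE's EDF reader.  Writing is a small self-contained
encoder for the classic EDF layout — ASCII header blocks followed by
little-endian 16-bit data records — which is all the synthetic pipeline needs
to round-trip recordings through the same on-disk format clinical data
arrive in.  One data record spans 1 s, so the sampling rate must be an
integer; samples are scaled to the per-channel physical range and quantized
to the full 16-bit digital range.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .signal_prep import Recording

__all__ = ["write_edf", "read_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path, patient_id: str = "X",
              recording_id: str = "synthetic") -> None:
    """Write a Recording (microvolts) as classic EDF with 1 s data records."""
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer needs an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_ch = recording.n_channels
    n_records = recording.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one 1 s data record")
    data = recording.signal[:, : n_records * fs]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-3)
    scale = (_DIG_MAX) / phys_max  # symmetric physical range [-max, +max]
    digital = np.clip(np.rint(data * scale[:, None]), _DIG_MIN, _DIG_MAX).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field(patient_id, 80))
        fh.write(_field(recording_id, 80))
        fh.write(_field("01.01.00", 8))  # start date dd.mm.yy
        fh.write(_field("00.00.00", 8))  # start time
        fh.write(_field(str(header_bytes), 8))
        fh.write(_field("", 44))
        fh.write(_field(str(n_records), 8))
        fh.write(_field("1", 8))  # record duration, seconds
        fh.write(_field(str(n_ch), 4))
        for name in recording.channel_names:
            fh.write(_field(name, 16))
        for _ in range(n_ch):
            fh.write(_field("AgAgCl electrode", 80))
        for _ in range(n_ch):
            fh.write(_field("uV", 8))
        for p in phys_max:
            fh.write(_field(f"{-p:.6g}"[:8], 8))
        for p in phys_max:
            fh.write(_field(f"{p:.6g}"[:8], 8))
        fh.write(_field(str(_DIG_MIN), 8) * n_ch)
        fh.write(_field(str(_DIG_MAX), 8) * n_ch)
        for _ in range(n_ch):
            fh.write(_field("", 80))  # prefiltering
        fh.write(_field(str(fs), 8) * n_ch)  # samples per record
        fh.write(_field("", 32) * n_ch)
        # data records: per record, all samples of ch0, then ch1, ...
        blocks = digital.reshape(n_ch, n_records, fs)
        fh.write(np.ascontiguousarray(blocks.transpose(1, 0, 2)).tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording in microvolts (via MNE)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    return Recording(data.astype(np.float32), float(raw.info["sfreq"]),
                     list(raw.ch_names))
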