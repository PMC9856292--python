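"""EEG recording container and file I/O (CSV and EDF).

CSV recordings are plain numeric matrices, one row per sample, one column
per channel, with a header row of channel labels; values are microvolts.
EDF files are read through MNE. Writing uses a minimal EDF (16-bit)
encoder authored here, with one data record per file; round-trip fidelity
against MNE's reader is covered by the test suite.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, default_montage


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    Attributes
    ----------
    data
        Array of shape (n_samples, n_channels), in microvolts.
    fs
        Sampling rate in Hz.
    montage
        Channel labels, in column order.
    reference
        "raw" or "average"; "average" asserts every sample has zero
        channel mean.
    epoch_starts
        Start indices of the epochs concatenated in ``data``; transitions
        are never counted across these boundaries. A continuous recording
        has the single boundary 0.
    """

    data: np.ndarray
    fs: float
    montage: Montage = field(default_factory=default_montage)
    reference: str = "raw"
    epoch_starts: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a samples x channels matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[1]} columns but montage has "
                f"{self.montage.n_channels} channels"
            )
        if self.reference not in ("raw", "average"):
            raise ValueError("reference must be 'raw' or 'average'")
        if self.reference == "average" and self.n_samples:
            if np.abs(self.data.mean(axis=1)).max() > 1e-9:
                raise ValueError("reference='average' but channel means are nonzero")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "EEGRecording":
        return replace(self, **kw)


def read_recording(
    path: str | Path,
    format: str | None = None,
    montage: Montage | None = None,
) -> EEGRecording:
    """Read an EEG recording from CSV or EDF.

    The format is inferred from the suffix when not given. Channels are
    reordered to match ``montage`` (default: the file's own order for
    EDF/CSV when montage is None means 'use file order'; passing a montage
    enforces presence of each of its channels).
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lower().lstrip(".")
    if format == "csv":
        frame = pd.read_csv(path)
        labels = [str(c) for c in frame.columns]
        data = frame.to_numpy(dtype=np.float64)
        fs = None
    elif format == "edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        labels = list(raw.ch_names)
        data = raw.get_data().T * 1e6  # MNE holds volts internally
        fs = float(raw.info["sfreq"])
    else:
        raise ValueError(f"unsupported format: {format!r}")

    if montage is None:
        montage = Montage(tuple(labels))
        order = np.arange(len(labels))
    else:
        missing = [c for c in montage.channel_names if c not in labels]
        if missing:
            raise ValueError(f"recording is missing channels {missing}")
        order = np.array([labels.index(c) for c in montage.channel_names])

    if fs is None:
        raise ValueError(
            "CSV files carry no sampling rate; use read_csv_recording(path, fs=...)"
        )
    return EEGRecording(data[:, order], fs=fs, montage=montage)


def read_csv_recording(
    path: str | Path, fs: float, montage: Montage | None = None
) -> EEGRecording:
    """Read a CSV matrix recording; CSV carries no rate, so ``fs`` is explicit."""
    frame = pd.read_csv(path)
    labels = [str(c) for c in frame.columns]
    if montage is None:
        montage = Montage(tuple(labels))
        order = np.arange(len(labels))
    else:
        missing = [c for c in montage.channel_names if c not in labels]
        if missing:
            raise ValueError(f"recording is missing channels {missing}")
        order = np.array([labels.index(c) for c in montage.channel_names])
    return EEGRecording(frame.to_numpy(np.float64)[:, order], fs=fs, montage=montage)


def write_recording(rec: EEGRecording, path: str | Path, format: str | None = None) -> None:
    """Write a recording as CSV (header = channel labels, values in µV) or EDF."""
    path = Path(path)
    if format is None:
        format = path.suffix.lower().lstrip(".")
    if format == "csv":
        pd.DataFrame(rec.data, columns=list(rec.montage.channel_names)).to_csv(
            path, index=False
        )
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unsupported format: {format!r}")


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r}")
    return s.ljust(width).encode("ascii")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF writer: one data record, 16-bit samples, physical unit uV."""
    n_sig = rec.n_channels
    n_samp = rec.n_samples
    if n_samp == 0:
        raise ValueError("cannot write an empty recording")
    duration = n_samp / rec.fs
    dur_s = f"{duration:.6f}".rstrip("0").rstrip(".")[:8]

    pmax = np.maximum(np.ceil(np.abs(rec.data).max(axis=0)), 1.0)
    dig_max, dig_min = 32767, -32768

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X", 80),
            _edf_field("msdoc synthetic", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + n_sig), 8),
            _edf_field("", 44),
            _edf_field(1, 8),
            _edf_field(dur_s, 8),
            _edf_field(n_sig, 4),
        ]
    )
    sig = b""
    for fields, width in (
        ([c for c in rec.montage.channel_names], 16),
        ([""] * n_sig, 80),
        (["uV"] * n_sig, 8),
        ([f"{-p:.0f}" for p in pmax], 8),
        ([f"{p:.0f}" for p in pmax], 8),
        ([str(dig_min)] * n_sig, 8),
        ([str(dig_max)] * n_sig, 8),
        ([""] * n_sig, 80),
        ([str(n_samp)] * n_sig, 8),
        ([""] * n_sig, 32),
    ):
        sig += b"".join(_edf_field(f, width) for f in fields)

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for c in range(n_sig):
            # EDF decodes phys = (dig - dmin) * (pmax - pmin)/(dmax - dmin) + pmin
            slope = (2 * pmax[c]) / (dig_max - dig_min)
            scaled = np.round((rec.data[:, c] + pmax[c]) / slope + dig_min)
            ints = np.clip(scaled, dig_min, dig_max).astype("<i2")
            fh.write(struct.pack(f"<{n_samp}h", *ints))


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    """Write a per-sample integer class-label sequence as a one-column CSV."""
    pd.DataFrame({"label": np.asarray(labels, dtype=int)}).to_csv(path, index=False)


def read_labels(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["label"].to_numpy(dtype=int)
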