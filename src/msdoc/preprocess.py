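"""Preprocessing chain for resting-state EEG.

The chain mirrors standard clinical practice: 50 Hz notch, 0.1-40 Hz
band-pass, segmentation into fixed-length epochs with +/-150 µV amplitude
rejection, then average referencing of the retained epochs. Filters are
zero-phase (forward-backward) IIR: a 2nd-order notch at Q=30 and a
4th-order Butterworth band-pass. An optional cleaning hook slot stands in
for operator-driven ICA artifact removal, which this package does not
re-implement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .io import EEGRecording
from .montage import Montage


def notch_filter(rec: EEGRecording, freq: float = 50.0, q: float = 30.0) -> EEGRecording:
    """Remove a narrow band around ``freq`` (power-line hum), zero-phase."""
    if freq >= rec.fs / 2:
        raise ValueError("notch frequency must be below Nyquist")
    b, a = signal.iirnotch(freq, q, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.data, axis=0)
    return rec.copy_with(data=out)

def bandpass_filter(
    rec: EEGRecording, lo: float = 0.1, hi: float = 40.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass between ``lo`` and ``hi`` Hz."""
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= rec.fs / 2:
        raise ValueError("upper edge must be below Nyquist")
    sos = signal.butter(order, (lo, hi), btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=0)
    return rec.copy_with(data=out)

def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the instantaneous channel mean (idempotent)."""
    out = rec.data - rec.data.mean(axis=1, keepdims=True)
    return rec.copy_with(data=out, reference="average")


@dataclass
class EpochSet:
    """Equal-length epochs cut from one recording, with a keep/reject mask."""

    epochs: list[np.ndarray]
    fs: float
    montage: Montage
    kept_mask: np.ndarray = field(default_factory=lambda: np.array([], bool))

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def concatenate_kept(self) -> EEGRecording:
        """Concatenate retained epochs into one recording.

        Epoch boundaries are preserved in ``epoch_starts`` so that later
        stages never count microstate transitions across them.
        """
        kept = [e for e, k in zip(self.epochs, self.kept_mask) if k]
        if not kept:
            raise ValueError("no epochs survived rejection")
        starts = tuple(np.cumsum([0] + [len(e) for e in kept[:-1]]).tolist())
        return EEGRecording(
            np.vstack(kept), fs=self.fs, montage=self.montage, epoch_starts=starts
        )


def reject_epochs(
    rec: EEGRecording, epoch_s: float = 2.0, threshold_uv: float = 150.0
) -> EpochSet:
    """Split into consecutive epochs and reject any containing |v| > threshold.

    The trailing remainder shorter than one epoch is dropped. An EpochSet
    with an all-False mask is returned (not an error) when everything is
    rejected; callers decide how to proceed.
    """
    n_per = int(round(epoch_s * rec.fs))
    if n_per < 1:
        raise ValueError("epoch length must cover at least one sample")
    n_epochs = rec.n_samples // n_per
    epochs = [rec.data[i * n_per:(i + 1) * n_per] for i in range(n_epochs)]
    kept = np.array(
        [np.abs(e).max() <= threshold_uv for e in epochs], dtype=bool
    )
    return EpochSet(epochs=epochs, fs=rec.fs, montage=rec.montage, kept_mask=kept)


CleaningHook = Callable[[EEGRecording], EEGRecording]


def preprocess(
    rec: EEGRecording,
    notch: float | None = 50.0,
    band: Sequence[float] | None = (0.1, 40.0),
    epoch_s: float = 2.0,
    reject_uv: float = 150.0,
    cleaning_hook: CleaningHook | None = None,
) -> EEGRecording:
    """Full chain: notch -> band-pass -> [hook] -> epoch rejection -> average ref.

    Returns the concatenation of retained epochs, average-referenced, with
    epoch boundaries recorded.
    """
    if notch is not None:
        rec = notch_filter(rec, notch)
    if band is not None:
        rec = bandpass_filter(rec, *band)
    if cleaning_hook is not None:
        rec = cleaning_hook(rec)
    epochs = reject_epochs(rec, epoch_s=epoch_s, threshold_uv=reject_uv)
    return average_reference(epochs.concatenate_kept())
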