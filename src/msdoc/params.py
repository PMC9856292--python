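"""Temporal microstate parameters and transition syntax.

Duration is the mean lifetime of a class's segments (ms), occurrence the
number of its segments per second of labelled time, coverage the fraction
of samples it labels. Segments touching epoch boundaries are included in
the duration average, which keeps the identity
coverage = occurrence x duration exact. Syntax counts the between-class
transitions at within-epoch segment boundaries and normalises by the
grand total of between-class transitions (one global normaliser, not one
per row).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .microstates import Segmentation, _runs


def segments_of(seg: Segmentation) -> list[tuple[int, int, int]]:
    """Maximal constant-label runs as (class, start, length), split at epochs."""
    out: list[tuple[int, int, int]] = []
    for sl in seg.epoch_slices():
        out.extend(
            (cls, start + sl.start, length)
            for cls, start, length in _runs(seg.labels[sl])
        )
    return out


@dataclass
class ClassParams:
    """Per-class temporal statistics (arrays indexed by class)."""

    duration_ms: np.ndarray
    occurrence_per_s: np.ndarray
    coverage: np.ndarray
    gev: np.ndarray | None = None

    def to_frame(self, labels: tuple[str, ...] | None = None) -> pd.DataFrame:
        n = len(self.duration_ms)
        idx = list(labels) if labels else list(range(n))
        cols = {
            "duration_ms": self.duration_ms,
            "occurrence_per_s": self.occurrence_per_s,
            "coverage": self.coverage,
        }
        if self.gev is not None:
            cols["gev"] = self.gev
        return pd.DataFrame(cols, index=pd.Index(idx, name="class"))


def temporal_parameters(seg: Segmentation) -> ClassParams:
    """Duration, occurrence and coverage per class.

    Classes absent from the segmentation get zeros for all three.
    """
    if seg.n_samples == 0:
        raise ValueError("empty segmentation")
    K = seg.n_classes
    runs = segments_of(seg)
    total_s = seg.n_samples / seg.fs
    counts = np.zeros(K)
    samples = np.zeros(K)
    for cls, _, length in runs:
        counts[cls] += 1
        samples[cls] += length
    duration = np.divide(
        samples / seg.fs * 1000.0, counts, out=np.zeros(K), where=counts > 0
    )
    occurrence = counts / total_s
    coverage = samples / seg.n_samples
    return ClassParams(duration, occurrence, coverage)


@dataclass
class TransitionMatrix:
    """Directed between-class transition counts and globally normalised rates."""

    counts: np.ndarray
    probs: np.ndarray

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())


def transition_syntax(seg: Segmentation) -> TransitionMatrix:
    """Count within-epoch label changes; probs = counts / total count.

    With zero transitions the probability matrix is all-NaN (flagged, not
    an error): a single-class recording has no syntax.
    """
    if seg.n_samples == 0:
        raise ValueError("empty segmentation")
    K = seg.n_classes
    counts = np.zeros((K, K), dtype=int)
    for sl in seg.epoch_slices():
        lab = seg.labels[sl]
        if len(lab) < 2:
            continue
        src, dst = lab[:-1], lab[1:]
        change = src != dst
        np.add.at(counts, (src[change], dst[change]), 1)
    total = counts.sum()
    probs = counts / total if total > 0 else np.full((K, K), np.nan)
    return TransitionMatrix(counts=counts, probs=probs)


def symmetric_pair_rates(tm: TransitionMatrix) -> dict[tuple[int, int], tuple[float, float]]:
    """For each unordered class pair {i, j}, the directed rates (i->j, j->i)."""
    K = tm.probs.shape[0]
    return {
        (i, j): (float(tm.probs[i, j]), float(tm.probs[j, i]))
        for i in range(K)
        for j in range(i + 1, K)
    }
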