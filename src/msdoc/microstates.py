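"""Microstate segmentation: GFP, modified K-means, back-fitting, GEV.

The modified K-means treats scalp topographies as undirected axes: the
similarity between a sample map and a prototype is the *squared* spatial
(Pearson) correlation, so a map and its polarity-reversed copy are
identical for every quantity computed here. The prototype of a cluster is
the first principal direction of its member maps (the eigenvector of
their outer-product sum), which is the sign-invariant analogue of the
mean. Cluster quality is measured by global explained variance (GEV), the
GFP-squared-weighted mean of the squared correlations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .io import EEGRecording
from .montage import CLASS_NAMES, Montage, canonical_templates

_EPS = 1e-12


# ---------------------------------------------------------------------------
# GFP and peak extraction

@dataclass
class GFPSeries:
    """Global field power: spatial standard deviation across channels."""

    values: np.ndarray
    fs: float


def global_field_power(rec: EEGRecording) -> GFPSeries:
    """GFP_t = population SD of the instantaneous topography across channels."""
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    vals = np.sqrt(np.mean(data**2, axis=1))
    return GFPSeries(values=vals, fs=rec.fs)


def detect_gfp_peaks(gfp: GFPSeries, min_separation_ms: float = 10.0) -> np.ndarray:
    """Indices of local GFP maxima, thinned to a minimum separation.

    A peak satisfies gfp[t-1] < gfp[t] >= gfp[t+1]. When two peaks fall
    closer than ``min_separation_ms`` the larger survives (greedy, in
    decreasing amplitude order).
    """
    v = gfp.values
    if len(v) < 3:
        raise ValueError("need at least 3 samples to find interior maxima")
    cand = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])) + 1
    if cand.size == 0:
        return cand
    min_gap = int(np.ceil(min_separation_ms / 1000.0 * gfp.fs))
    if min_gap <= 1:
        return cand
    order = cand[np.argsort(v[cand])[::-1]]
    keep: list[int] = []
    taken = np.zeros(len(v), dtype=bool)
    for idx in order:
        if not taken[idx]:
            keep.append(idx)
            lo, hi = max(0, idx - min_gap + 1), min(len(v), idx + min_gap)
            taken[lo:hi] = True
    return np.sort(np.array(keep, dtype=int))


# ---------------------------------------------------------------------------
# Model and segmentation containers

@dataclass
class MicrostateModel:
    """K prototype topographies, each average-referenced and unit-norm."""

    maps: np.ndarray
    montage: Montage
    labels: tuple[str, ...] = ()
    polarity_invariant: bool = True

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 2:
            raise ValueError("maps must be K x n_channels")
        if not self.labels:
            self.labels = tuple(CLASS_NAMES[: self.K])
        if len(self.labels) != self.K or len(set(self.labels)) != self.K:
            raise ValueError("need K distinct class labels")
        means = np.abs(self.maps.mean(axis=1))
        norms = np.abs(np.linalg.norm(self.maps, axis=1) - 1.0)
        if means.max() > 1e-8 or norms.max() > 1e-8:
            raise ValueError("prototype maps must be zero-mean and unit-norm")

    @property
    def K(self) -> int:
        return self.maps.shape[0]


@dataclass
class Segmentation:
    """Per-sample class labels with per-sample squared-correlation fit."""

    labels: np.ndarray
    fit: np.ndarray
    fs: float
    n_classes: int
    epoch_starts: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.fit = np.asarray(self.fit, dtype=np.float64)
        if self.labels.shape != self.fit.shape:
            raise ValueError("labels and fit must be the same length")

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def epoch_slices(self) -> list[slice]:
        starts = list(self.epoch_starts) + [self.n_samples]
        return [slice(a, b) for a, b in zip(starts[:-1], starts[1:])]


# ---------------------------------------------------------------------------
# Normalisation helpers

def _normalize_maps(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean each row and scale to unit norm; returns (unit maps, norms)."""
    centred = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    unit = np.divide(
        centred, norms[:, None], out=np.zeros_like(centred),
        where=norms[:, None] > _EPS,
    )
    return unit, norms


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two topographies across channels."""
    ua, na = _normalize_maps(a[None, :])
    ub, nb = _normalize_maps(b[None, :])
    if na[0] <= _EPS or nb[0] <= _EPS:
        return 0.0
    return float(ua[0] @ ub[0])


def _principal_direction(maps: np.ndarray) -> np.ndarray:
    """First principal direction of a set of zero-mean maps (sign-invariant mean).

    Eigenvector of sum_m x_m x_m^T with the largest eigenvalue; lies in the
    zero-sum subspace whenever the inputs do, and is re-projected and
    normalised for numerical safety.
    """
    cov = maps.T @ maps
    _, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n <= _EPS:
        raise ValueError("degenerate cluster: no principal direction")
    return v / n


# ---------------------------------------------------------------------------
# Modified K-means

def _gev_of_assignment(unit: np.ndarray, w: np.ndarray, protos: np.ndarray,
                       assign: np.ndarray) -> float:
    r = np.einsum("mc,mc->m", unit, protos[assign])
    return float(np.sum(w * r**2) / np.sum(w))


def modified_kmeans(
    maps: np.ndarray,
    K: int,
    n_restarts: int = 20,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | None = None,
    montage: Montage | None = None,
) -> tuple[MicrostateModel, float]:
    """Cluster topographies into K classes by polarity-invariant K-means.

    Parameters
    ----------
    maps
        M x n_channels matrix of topographies (e.g. GFP-peak maps).
    K
        Number of microstate classes.
    n_restarts, max_iter, tol, seed
        Restart count, iteration cap, relative-GEV convergence tolerance,
        and RNG seed for the random prototype initialisations.

    Returns
    -------
    (model, gev)
        The best model over restarts and the GEV it attains on ``maps``.
    """
    maps = np.asarray(maps, dtype=np.float64)
    M = maps.shape[0]
    if K > M:
        raise ValueError(f"cannot fit K={K} classes to {M} maps")
    if K < 1:
        raise ValueError("K must be at least 1")
    unit, norms = _normalize_maps(maps)
    ok = norms > _EPS
    if not ok.all():
        unit, norms = unit[ok], norms[ok]
        M = unit.shape[0]
        if K > M:
            raise ValueError("too few non-degenerate maps for K classes")
    centred = unit * norms[:, None]
    w = norms**2  # GFP^2 weights (up to the common channel-count factor)

    rng = np.random.default_rng(seed)
    best_gev, best_protos = -np.inf, None
    for _ in range(n_restarts):
        idx = rng.choice(M, size=K, replace=False)
        protos = unit[idx].copy()
        prev_gev = -np.inf
        for _ in range(max_iter):
            r = unit @ protos.T
            assign = np.argmax(r**2, axis=1)
            # re-seed empty clusters from the worst-fitted map
            fit = r[np.arange(M), assign] ** 2
            for k in range(K):
                if not np.any(assign == k):
                    worst = int(np.argmin(fit))
                    assign[worst] = k
                    fit[worst] = 1.0
            for k in range(K):
                protos[k] = _principal_direction(centred[assign == k])
            gev = _gev_of_assignment(unit, w, protos, assign)
            if gev - prev_gev <= tol * max(abs(prev_gev), _EPS):
                break
            prev_gev = gev
        if gev > best_gev:
            best_gev, best_protos = gev, protos.copy()

    model = MicrostateModel(
        maps=best_protos,
        montage=montage if montage is not None else Montage(tuple(f"ch{i}" for i in range(maps.shape[1]))),
    )
    return model, best_gev


# ---------------------------------------------------------------------------
# Group-level prototype fitting

def aggregate_group_prototypes(
    recordings: list[EEGRecording],
    K: int = 4,
    peaks_per_subject: int = 1000,
    seed: int | None = None,
    n_restarts: int = 20,
    max_iter: int = 100,
    tol: float = 1e-6,
    min_peak_separation_ms: float = 10.0,
    order: bool = True,
) -> tuple[MicrostateModel, float]:
    """Fit group prototypes on GFP-peak maps pooled over all recordings.

    From each recording the highest-GFP peak topographies (up to
    ``peaks_per_subject``) are drawn; the pooled set is clustered with the
    modified K-means, and the resulting classes are labelled by matching
    against the canonical A-D reference maps (``order=True``).
    """
    if not recordings:
        raise ValueError("need at least one recording")
    montage = recordings[0].montage
    pooled = []
    for rec in recordings:
        if rec.montage.channel_names != montage.channel_names:
            raise ValueError("all recordings must share one montage")
        gfp = global_field_power(rec)
        peaks = detect_gfp_peaks(gfp, min_peak_separation_ms)
        if peaks.size == 0:
            continue
        if peaks.size > peaks_per_subject:
            top = np.argsort(gfp.values[peaks])[::-1][:peaks_per_subject]
            peaks = np.sort(peaks[top])
        data = rec.data - rec.data.mean(axis=1, keepdims=True)
        pooled.append(data[peaks])
    if not pooled:
        raise ValueError("no GFP peaks found in any recording")
    model, gev = modified_kmeans(
        np.vstack(pooled), K, n_restarts=n_restarts, max_iter=max_iter,
        tol=tol, seed=seed, montage=montage,
    )
    if order:
        model = order_classes(model, canonical_templates(montage, K))
    return model, gev


def order_classes(model: MicrostateModel, reference_maps: np.ndarray) -> MicrostateModel:
    """Relabel classes by optimal matching to reference topographies.

    Solves the assignment exactly over all K! permutations (K <= 6),
    maximising the summed absolute spatial correlation, then reorders rows
    so that row k corresponds to reference class k (A, B, C, ...).
    """
    reference_maps = np.asarray(reference_maps, dtype=np.float64)
    if reference_maps.shape[0] != model.K:
        raise ValueError("reference map count must equal model.K")
    if model.K > 6:
        raise ValueError("exhaustive matching supported for K <= 6")
    ref_unit, _ = _normalize_maps(reference_maps)
    absr = np.abs(model.maps @ ref_unit.T)  # model row i vs reference j
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(model.K)):
        score = sum(absr[i, perm[i]] for i in range(model.K))
        if score > best_score:
            best_score, best_perm = score, perm
    # model row i plays reference role perm[i]; reorder rows by role
    inv = np.argsort(np.array(best_perm))
    return replace(
        model,
        maps=model.maps[inv],
        labels=tuple(CLASS_NAMES[: model.K]),
    )


# ---------------------------------------------------------------------------
# Back-fitting and smoothing

def backfit(model: MicrostateModel, rec: EEGRecording) -> Segmentation:
    """Label every sample with the prototype of highest squared correlation.

    Zero-GFP samples inherit the previous sample's label (class 0 at the
    start) with fit 0. Exact ties go to the previous sample's label when it
    is among the tied classes, otherwise to the lowest class index.
    """
    if rec.n_channels != model.maps.shape[1]:
        raise ValueError("recording and model channel counts differ")
    unit, norms = _normalize_maps(rec.data)
    r2 = (unit @ model.maps.T) ** 2
    labels = np.argmax(r2, axis=1)
    fit = r2[np.arange(len(labels)), labels]

    zero = norms <= _EPS
    top2 = np.partition(r2, -2, axis=1)[:, -2:] if model.K > 1 else None
    tied = (
        np.zeros(len(labels), bool)
        if top2 is None
        else (top2[:, 1] - top2[:, 0]) <= 1e-15
    )
    special = np.flatnonzero(zero | tied)
    for t in special:
        prev = labels[t - 1] if t > 0 else 0
        if zero[t]:
            labels[t] = prev
            fit[t] = 0.0
        else:
            cand = np.flatnonzero(r2[t] >= r2[t, labels[t]] - 1e-15)
            labels[t] = prev if prev in cand else int(cand.min())
    return Segmentation(
        labels=labels, fit=fit, fs=rec.fs, n_classes=model.K,
        epoch_starts=rec.epoch_starts,
    )


def smooth_segmentation(seg: Segmentation, min_duration_ms: float = 30.0) -> Segmentation:
    """Absorb segments shorter than ``min_duration_ms`` into a neighbour.

    An offending segment is relabelled wholesale to whichever temporally
    adjacent segment shows the higher fit at the shared boundary sample;
    the pass repeats until stable. Segments touching an epoch boundary are
    exempt (their true extent is unobserved). ``min_duration_ms=0`` is the
    identity.
    """
    if min_duration_ms < 0:
        raise ValueError("min_duration_ms must be non-negative")
    min_len = int(np.ceil(min_duration_ms / 1000.0 * seg.fs))
    if min_len <= 1:
        return seg
    labels = seg.labels.copy()
    fit = seg.fit
    for sl in seg.epoch_slices():
        lab = labels[sl]
        f = fit[sl]
        changed = True
        while changed:
            changed = False
            runs = _runs(lab)
            for i, (cls, start, length) in enumerate(runs):
                if length >= min_len or i == 0 or i == len(runs) - 1:
                    continue
                left_cls = runs[i - 1][0]
                right_cls = runs[i + 1][0]
                left_fit = f[start - 1]
                right_fit = f[start + length]
                new = left_cls if left_fit >= right_fit else right_cls
                if new != cls:
                    lab[start:start + length] = new
                    changed = True
                    break
        labels[sl] = lab
    return replace(seg, labels=labels)


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (class, start, length)."""
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# Global explained variance

def global_explained_variance(
    model: MicrostateModel, rec: EEGRecording, seg: Segmentation
) -> tuple[float, np.ndarray]:
    """GEV of a labelled recording: total and per-class fractions.

    GEV = sum_t (GFP_t r_t)^2 / sum_t GFP_t^2 with r_t the spatial
    correlation between sample t and its assigned prototype; the per-class
    entries restrict the numerator to that class's samples and sum to the
    total.
    """
    if seg.n_samples != rec.n_samples:
        raise ValueError("segmentation and recording lengths differ")
    unit, norms = _normalize_maps(rec.data)
    denom = float(np.sum(norms**2))
    if denom <= _EPS:
        raise ValueError("GEV undefined for an all-zero recording")
    r = np.einsum("tc,tc->t", unit, model.maps[seg.labels])
    contrib = (norms * r) ** 2
    per_class = np.array(
        [contrib[seg.labels == k].sum() / denom for k in range(model.K)]
    )
    return float(per_class.sum()), per_class
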