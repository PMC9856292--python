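"""Synthetic multichannel EEG with a planted microstate structure.

The generator emulates the signal model that topographic segmentation
assumes: at every instant the scalp map is one fixed average-referenced
template (up to polarity), templates succeed one another as a semi-Markov
chain with dwell times in the tens of milliseconds, the whole map is
amplitude-modulated by an alpha-like (10 Hz) rectified-sinusoid envelope
so that GFP waxes and wanes, polarity flips on a slow (~1 s) random
schedule, and spatially uncorrelated Gaussian noise is added at a
controlled signal-to-noise ratio (mean signal GFP over mean noise GFP).

Dwell times are truncated-geometric in samples (memoryless beyond a
minimum) with a per-class mean; this is the simplest law with a
controllable mean and is a calibration choice, not an empirical fact
about patient EEG. The default minimum dwell (30 ms) matches the
segmentation's minimum-duration floor: states briefer than the floor the
analysis enforces are not identifiable from the segmentation, so the
generator does not plant them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import EEGRecording
from .montage import Montage, default_montage

DEFAULT_MIN_DWELL_MS = 30.0


@dataclass
class GroundTruth:
    """Planted generative state of a synthetic recording.

    Attributes
    ----------
    templates
        K x n_channels matrix; each row zero channel-mean and unit norm.
    transition_probs
        K x K row-stochastic matrix with zero diagonal (embedded chain).
    mean_dwell_ms
        Per-class expected dwell time in milliseconds (scalar broadcasts).
    snr
        Mean signal GFP over mean noise GFP; np.inf means noise-free.
    seed
        Seed the recording was generated from.
    label_sequence
        Realised per-sample true class indices (filled by the simulator).
    dwell_dist
        "geometric" (truncated at ``min_dwell_ms``) or "fixed".
    min_dwell_ms
        Shortest plantable dwell; keep at or above the segmentation's
        minimum-duration floor so durations stay identifiable.
    """

    templates: np.ndarray
    transition_probs: np.ndarray
    mean_dwell_ms: np.ndarray
    snr: float = 5.0
    seed: int = 0
    label_sequence: np.ndarray | None = None
    dwell_dist: str = "geometric"
    min_dwell_ms: float = DEFAULT_MIN_DWELL_MS

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, float)
        self.transition_probs = np.asarray(self.transition_probs, float)
        K = self.templates.shape[0]
        self.mean_dwell_ms = np.broadcast_to(
            np.asarray(self.mean_dwell_ms, float), (K,)
        ).copy()
        if (self.mean_dwell_ms <= 0).any():
            raise ValueError("mean dwell times must be positive")
        if self.min_dwell_ms < 0:
            raise ValueError("min dwell must be non-negative")
        _check_transition_matrix(self.transition_probs, K)

    @property
    def K(self) -> int:
        return self.templates.shape[0]


def _check_transition_matrix(P: np.ndarray, K: int) -> None:
    if P.shape != (K, K):
        raise ValueError("transition matrix shape must be K x K")
    if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition rows must be non-negative and sum to 1")
    if K > 1 and np.abs(np.diag(P)).max() > 1e-12:
        raise ValueError("transition matrix diagonal must be zero")


def make_templates(montage: Montage, K: int, seed: int,
                   max_abs_corr: float = 0.7) -> np.ndarray:
    """Draw K mutually distinct random template maps.

    Each map is zero-mean across channels and unit-norm; the set is
    redrawn until every pairwise |spatial correlation| is at most
    ``max_abs_corr``.
    """
    C = montage.n_channels
    if not 1 <= K < C:
        raise ValueError("need 1 <= K < n_channels")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        raw = rng.standard_normal((K, C))
        raw -= raw.mean(axis=1, keepdims=True)
        raw /= np.linalg.norm(raw, axis=1, keepdims=True)
        corr = raw @ raw.T
        if K == 1 or np.abs(corr[~np.eye(K, dtype=bool)]).max() <= max_abs_corr:
            return raw
    raise RuntimeError("could not draw sufficiently distinct templates")


def simulate_label_sequence(
    truth: GroundTruth, duration_s: float, fs: float, seed: int
) -> np.ndarray:
    """Semi-Markov per-sample class labels.

    Dwell lengths (in samples) are drawn per class with the requested
    mean, successor classes from the embedded transition matrix.
    """
    n = int(round(duration_s * fs))
    if n < 1:
        raise ValueError("duration must cover at least one sample")
    rng = np.random.default_rng(seed)
    K = truth.K
    mean_samples = truth.mean_dwell_ms / 1000.0 * fs
    min_samples = max(1, int(round(truth.min_dwell_ms / 1000.0 * fs)))
    labels = np.empty(n, dtype=int)
    pos = 0
    state = int(rng.integers(K))
    while pos < n:
        m = mean_samples[state]
        if truth.dwell_dist == "fixed":
            dwell = max(1, int(round(m)))
        elif truth.dwell_dist == "geometric":
            # dwell = (min-1) + Geometric(p), support >= min, mean = m
            excess = max(m - (min_samples - 1), 1.0)
            dwell = (min_samples - 1) + int(rng.geometric(1.0 / excess))
        else:
            raise ValueError(f"unknown dwell distribution {truth.dwell_dist!r}")
        labels[pos:pos + dwell] = state
        pos += dwell
        if K > 1:
            state = int(rng.choice(K, p=truth.transition_probs[state]))
    return labels


def synthesize_eeg(
    truth: GroundTruth,
    duration_s: float,
    fs: float,
    seed: int,
    montage: Montage | None = None,
    amplitude_uv: float = 50.0,
    envelope_hz: float = 10.0,
    envelope_floor: float = 0.1,
    polarity_flip_mean_s: float = 1.0,
) -> tuple[EEGRecording, GroundTruth]:
    """Render a synthetic recording from a ground-truth specification.

    Sample t is ``a_t * s_t * amplitude_uv * template[L_t]`` plus white
    noise scaled to the requested SNR, where a_t is a strictly positive
    rectified-sinusoid envelope and s_t a slowly flipping polarity sign.
    Returns the recording (reference "raw": the noise is not
    average-referenced) and a copy of the truth carrying the realised
    label sequence.
    """
    if truth.snr <= 0:
        raise ValueError("snr must be positive (np.inf for noise-free)")
    ss = np.random.SeedSequence(seed)
    seed_labels, seed_env, seed_flip, seed_noise = ss.spawn(4)
    labels = simulate_label_sequence(
        truth, duration_s, fs, seed=seed_labels.generate_state(1)[0] % (2**31)
    )
    n = len(labels)
    t = np.arange(n) / fs

    rng_env = np.random.default_rng(seed_env)
    phase = rng_env.uniform(0, 2 * np.pi)
    envelope = envelope_floor + np.abs(np.sin(2 * np.pi * envelope_hz * t + phase))

    rng_flip = np.random.default_rng(seed_flip)
    sign = np.ones(n)
    pos, cur = 0, 1.0
    while pos < n:
        gap = max(1, int(round(rng_flip.exponential(polarity_flip_mean_s) * fs)))
        sign[pos:pos + gap] = cur
        pos += gap
        cur = -cur
    signal = (amplitude_uv * envelope * sign)[:, None] * truth.templates[labels]

    if np.isfinite(truth.snr):
        rng_noise = np.random.default_rng(seed_noise)
        noise = rng_noise.standard_normal(signal.shape)
        sig_gfp = np.sqrt(np.mean(
            (signal - signal.mean(axis=1, keepdims=True)) ** 2, axis=1))
        noi_gfp = np.sqrt(np.mean(
            (noise - noise.mean(axis=1, keepdims=True)) ** 2, axis=1))
        scale = sig_gfp.mean() / truth.snr / noi_gfp.mean()
        signal = signal + scale * noise

    if montage is None:
        C = truth.templates.shape[1]
        montage = default_montage() if C == 19 else Montage(
            tuple(f"ch{i}" for i in range(C))
        )
    elif montage.n_channels != truth.templates.shape[1]:
        raise ValueError("montage width does not match templates")
    rec = EEGRecording(signal, fs=fs, montage=montage)
    return rec, replace(truth, label_sequence=labels, seed=seed)


# ---------------------------------------------------------------------------
# Analytic ground-truth summaries

def embedded_stationary(transition_probs: np.ndarray) -> np.ndarray:
    """Stationary distribution of the embedded (jump) chain."""
    P = np.asarray(transition_probs, float)
    K = P.shape[0]
    if K == 1:
        return np.ones(1)
    A = np.vstack([P.T - np.eye(K), np.ones(K)])
    b = np.concatenate([np.zeros(K), [1.0]])
    nu, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(nu, 0, None) / np.clip(nu, 0, None).sum()


def stationary_coverage(truth: GroundTruth) -> np.ndarray:
    """Long-run fraction of time in each class: nu_k m_k / sum_j nu_j m_j."""
    nu = embedded_stationary(truth.transition_probs)
    w = nu * truth.mean_dwell_ms
    return w / w.sum()


def expected_syntax(truth: GroundTruth) -> np.ndarray:
    """Expected transition rates normalised over all between-class transitions.

    Each visit to class k emits exactly one outgoing transition, so the
    long-run rate of k->j transitions is nu_k P_kj, already normalised.
    """
    nu = embedded_stationary(truth.transition_probs)
    return nu[:, None] * truth.transition_probs


def uniform_offdiagonal(K: int) -> np.ndarray:
    """Row-stochastic zero-diagonal matrix with uniform off-diagonal mass."""
    if K == 1:
        return np.ones((1, 1))
    P = np.full((K, K), 1.0 / (K - 1))
    np.fill_diagonal(P, 0.0)
    return P
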