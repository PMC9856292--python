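"""Electrode montages and canonical microstate reference topographies.

The default montage is the 19-channel international 10-20 set used for
clinical resting-state EEG. Channel positions are schematic 2D head
coordinates (x: left -1 to right +1, y: posterior -1 to anterior +1),
sufficient for constructing the canonical A-D reference maps used to
give fitted microstate classes their conventional names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Paper-order 10-20 labels with schematic head coordinates.
_POSITIONS_1020: dict[str, tuple[float, float]] = {
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
    "P3": (-0.43, -0.55), "P4": (0.43, -0.55), "Pz": (0.0, -0.50),
    "T5": (-0.81, -0.59), "T6": (0.81, -0.59),
    "C3": (-0.50, 0.0), "C4": (0.50, 0.0), "Cz": (0.0, 0.0),
    "T3": (-1.00, 0.0), "T4": (1.00, 0.0),
    "F3": (-0.43, 0.55), "F4": (0.43, 0.55), "Fz": (0.0, 0.50),
    "F7": (-0.81, 0.59), "F8": (0.81, 0.59),
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
}

STANDARD_1020_19 = tuple(_POSITIONS_1020)


@dataclass(frozen=True)
class Montage:
    """An ordered set of EEG channel labels.

    Parameters
    ----------
    channel_names
        Unique channel labels, in recording column order.
    """

    channel_names: tuple[str, ...] = field(default=STANDARD_1020_19)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        if len(set(names)) != len(names):
            raise ValueError("montage channel labels must be unique")
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def positions(self) -> np.ndarray:
        """Schematic (x, y) positions, shape (n_channels, 2).

        Only defined for channels in the standard 10-20 dictionary.
        """
        try:
            return np.array([_POSITIONS_1020[c] for c in self.channel_names])
        except KeyError as err:
            raise KeyError(f"no schematic position for channel {err}") from err


def default_montage() -> Montage:
    """The 19-channel 10-20 montage (O1 ... Fp2)."""
    return Montage(STANDARD_1020_19)


def _zero_mean_unit(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate (constant) reference map")
    return v / n


def canonical_templates(montage: Montage, K: int = 4) -> np.ndarray:
    """Canonical reference topographies for classes A..F, shape (K, n_channels).

    Classes follow the conventional orientations: A a left-right diagonal
    (left-posterior to right-anterior gradient), B its mirror image, C a
    rostral-caudal (anterior-posterior) gradient, D a frontocentral maximum.
    E and F (used only for K of 5 or 6) are parieto-occipital and frontal
    focal maps. Each row is average-referenced and unit-norm; matching
    against them is polarity-invariant, so signs are conventions only.
    """
    if not 1 <= K <= 6:
        raise ValueError("canonical templates defined for K between 1 and 6")
    pos = montage.positions()
    x, y = pos[:, 0], pos[:, 1]
    maps = [
        x + y,                                            # A
        -x + y,                                           # B
        -y,                                               # C
        np.exp(-((x / 0.6) ** 2 + ((y - 0.25) / 0.6) ** 2)),  # D
        np.exp(-((x / 0.6) ** 2 + ((y + 0.65) / 0.5) ** 2)),  # E
        np.exp(-(((x + 0.6) / 0.5) ** 2 + (y / 0.5) ** 2)),   # F
    ]
    return np.vstack([_zero_mean_unit(m) for m in maps[:K]])


CLASS_NAMES = ("A", "B", "C", "D", "E", "F")
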