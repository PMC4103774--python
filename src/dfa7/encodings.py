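"""Cumulative-sum representations of a DNA sequence.

Two families of tracks are produced:

* the Z-curve: at step n the three components measure the cumulative
  purine-pyrimidine (x), amino-keto (y) and weak-strong (z) base-count
  imbalances of the first n bases;
* cumulative nucleotide-distance series: T_alpha(n) sums the 1-based
  positions at which base alpha occurs among the first n bases.  Because a
  position i contributes i (not 1), these series weight late occurrences
  more heavily and so carry positional information the Z-curve discards.
  Three combined series D1-D3 pair the four T_alpha with the same
  purine/pyrimidine, amino/keto and weak/strong groupings as the Z-curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .sequence_io import GeneSequence

_BASES = "ACGT"

# Per-base step directions for (x, y, z): purine-pyrimidine, amino-keto,
# weak-strong.  A is purine, amino and weak; it increments all three axes.
_STEPS = {
    "A": (1, 1, 1),
    "C": (-1, 1, -1),
    "G": (1, -1, -1),
    "T": (-1, -1, 1),
}


@dataclass(frozen=True)
class ZCurveTrack:
    """Cumulative Z-curve components and the underlying base counts."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    counts: dict[str, np.ndarray]  # cumulative A_n, C_n, G_n, T_n

    def __len__(self) -> int:
        return len(self.x)

    @property
    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.x, self.y, self.z


@dataclass(frozen=True)
class DistanceTracks:
    """Cumulative position-sum series per base and their combined series."""

    T: dict[str, np.ndarray]  # T_A, T_C, T_G, T_T
    D1: np.ndarray
    D2: np.ndarray
    D3: np.ndarray

    def __len__(self) -> int:
        return len(self.D1)

    @property
    def combined(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.D1, self.D2, self.D3


def _base_indicators(bases: str) -> dict[str, np.ndarray]:
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    return {b: arr == ord(b) for b in _BASES}


def zcurve_components(seq: GeneSequence) -> ZCurveTrack:
    """Compute the three Z-curve component series of ``seq``.

    x_n = (A_n + G_n) - (C_n + T_n)
    y_n = (A_n + C_n) - (G_n + T_n)
    z_n = (A_n + T_n) - (G_n + C_n)

    where A_n .. T_n are cumulative occurrence counts over the first n bases.
    Each component changes by exactly +-1 per base.
    """
    ind = _base_indicators(seq.bases)
    counts = {b: np.cumsum(ind[b], dtype=np.int64) for b in _BASES}
    steps = {b: _STEPS[b] for b in _BASES}
    sx = sum(int(steps[b][0]) * ind[b] for b in _BASES)
    sy = sum(int(steps[b][1]) * ind[b] for b in _BASES)
    sz = sum(int(steps[b][2]) * ind[b] for b in _BASES)
    return ZCurveTrack(
        x=np.cumsum(sx, dtype=np.int64),
        y=np.cumsum(sy, dtype=np.int64),
        z=np.cumsum(sz, dtype=np.int64),
        counts=counts,
    )


#: Default combination of the four distance series into three, mirroring the
#: Z-curve axes.  Each entry maps a combined-series name to per-base weights.
DEFAULT_COMBINATION: Mapping[str, Mapping[str, int]] = {
    "D1": {"A": 1, "G": 1, "C": -1, "T": -1},  # purine - pyrimidine
    "D2": {"A": 1, "C": 1, "G": -1, "T": -1},  # amino - keto
    "D3": {"A": 1, "T": 1, "G": -1, "C": -1},  # weak - strong
}


def cumulative_distances(
    seq: GeneSequence,
    combination: Mapping[str, Mapping[str, int]] = DEFAULT_COMBINATION,
) -> DistanceTracks:
    """Compute T_alpha position-sum series and the combined series D1-D3.

    T_alpha(n) = sum of 1-based positions i <= n where base alpha occurs,
    so the increment at step n is n if position n holds alpha, else 0, and
    the four series always sum to n(n+1)/2.  The combined series apply the
    ``combination`` weights (by default the Z-curve pairings) to the T_alpha.
    """
    ind = _base_indicators(seq.bases)
    positions = np.arange(1, len(seq.bases) + 1, dtype=np.int64)
    T = {b: np.cumsum(np.where(ind[b], positions, 0)) for b in _BASES}
    D = {
        name: sum(int(w) * T[b] for b, w in weights.items())
        for name, weights in combination.items()
    }
    return DistanceTracks(T=T, D1=D["D1"], D2=D["D2"], D3=D["D3"])


def combined_series(
    tracks: DistanceTracks,
    combination: Mapping[str, Mapping[str, int]] = DEFAULT_COMBINATION,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recombine already-computed T_alpha series under ``combination``."""
    D = {
        name: sum(int(w) * tracks.T[b] for b, w in weights.items())
        for name, weights in combination.items()
    }
    return D["D1"], D["D2"], D["D3"]


def complement(seq: GeneSequence) -> GeneSequence:
    """Base-complemented copy (A<->T, C<->G), same orientation."""
    table = str.maketrans("ACGT", "TGCA")
    return GeneSequence(id=seq.id, bases=seq.bases.translate(table), label=seq.label)
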