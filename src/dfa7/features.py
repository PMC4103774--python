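"""Assembly of the 7-dimensional feature vector per sequence.

The features are: n1-n3, scaling exponents of the Z-curve components;
n4-n6, scaling exponents of the eigenvalue tracks of the cross-fluctuation
matrix over the combined cumulative-distance series; and sigma, the sample
standard deviation (denominator n-1) of the first six.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import encodings, fluctuation
from .sequence_io import GeneSequence

FEATURE_NAMES = ("n1", "n2", "n3", "n4", "n5", "n6", "sigma")


class FeatureError(ValueError):
    """Raised when a sequence cannot yield a feature vector."""


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the feature-extraction pipeline.

    min_length:
        shortest sequence accepted (must fit >= 3 window widths).
    l_min, l_max_cap:
        bounds of the power-of-two window-width grid.
    fluctuation_method:
        "end" (window-end increments, default) or "dfa1" (linear detrend)
        for the single-series exponents n1-n3.
    combination:
        weights mapping the four distance series onto D1-D3.
    """

    min_length: int = 256
    l_min: int = 4
    l_max_cap: int = 1024
    fluctuation_method: str = "end"
    combination: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: encodings.DEFAULT_COMBINATION
    )

    def window_grid(self, n: int) -> tuple[int, ...]:
        return fluctuation.default_window_grid(
            n, l_min=self.l_min, l_max_cap=self.l_max_cap
        )


@dataclass(frozen=True)
class FeatureVector7:
    """The ordered features (n1..n6, sigma) for one sequence.

    An eigenvalue-track exponent can be undefined (degenerate track); it is
    stored as NaN with its validity flag False, and sigma is then computed
    over the defined subset.  Such vectors are excluded from training by
    default (``is_complete`` is False).
    """

    sequence_id: str
    n1: float
    n2: float
    n3: float
    n4: float
    n5: float
    n6: float
    sigma: float
    defined: tuple[bool, bool, bool, bool, bool, bool] = (True,) * 6

    @property
    def exponents(self) -> tuple[float, ...]:
        return (self.n1, self.n2, self.n3, self.n4, self.n5, self.n6)

    @property
    def is_complete(self) -> bool:
        return all(self.defined)

    def values(self) -> np.ndarray:
        """The 7-vector (n1..n6, sigma) as floats; NaN where undefined."""
        return np.array([*self.exponents, self.sigma], dtype=float)


def sample_sd(values: Sequence[float]) -> float:
    """Sample standard deviation, sqrt(sum((v - mean)^2) / (count - 1))."""
    if len(values) < 2:
        raise ValueError(f"need at least 2 values, got {len(values)}")
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    return float(np.std(arr, ddof=1))


def feature_vector(
    seq: GeneSequence, config: FeatureConfig = FeatureConfig()
) -> FeatureVector7:
    """Run the full pipeline on one sequence.

    Z-curve components -> single-series exponents (n1-n3); cumulative
    distance series -> combined series -> fluctuation matrices -> eigenvalue
    tracks -> their exponents (n4-n6); sigma = sample SD of the six.
    """
    n = len(seq)
    if n < config.min_length:
        raise FeatureError(
            f"sequence {seq.id!r} has length {n} < minimum {config.min_length}"
        )
    try:
        widths = config.window_grid(n)

        zc = encodings.zcurve_components(seq)
        zfits = fluctuation.zcurve_exponents(
            zc, widths, method=config.fluctuation_method
        )

        tracks = encodings.cumulative_distances(seq, config.combination)
        cfits = fluctuation.cross_exponents(*tracks.combined, widths)
    except fluctuation.FluctuationError as exc:
        raise FeatureError(f"sequence {seq.id!r}: {exc}") from exc

    exps: list[float] = [f.slope for f in zfits]
    defined = [True, True, True]
    for fit in cfits:
        if fit is None:
            exps.append(math.nan)
            defined.append(False)
        else:
            exps.append(fit.slope)
            defined.append(True)

    usable = [e for e, d in zip(exps, defined) if d]
    if len(usable) < 2:
        raise FeatureError(f"sequence {seq.id!r}: too few defined exponents")
    if not all(defined):
        warnings.warn(
            f"sequence {seq.id!r}: sigma computed over {len(usable)} defined "
            "exponents; vector marked incomplete",
            stacklevel=2,
        )
    sigma = sample_sd(usable)
    return FeatureVector7(seq.id, *exps, sigma=sigma, defined=tuple(defined))


def feature_matrix(
    seqs: Sequence[GeneSequence],
    config: FeatureConfig = FeatureConfig(),
    *,
    skip_errors: bool = False,
) -> tuple[np.ndarray, list[str], list[int | None]]:
    """Feature vectors for many sequences as an (n, 7) array.

    Incomplete vectors (undefined exponents) are skipped with a warning, as
    are too-short sequences when ``skip_errors`` is set.  Returns the array,
    the kept ids, and their labels.
    """
    rows, ids, labels = [], [], []
    for s in seqs:
        try:
            fv = feature_vector(s, config)
        except FeatureError:
            if not skip_errors:
                raise
            warnings.warn(f"skipping sequence {s.id!r}", stacklevel=2)
            continue
        if not fv.is_complete:
            warnings.warn(
                f"skipping incomplete feature vector for {s.id!r}", stacklevel=2
            )
            continue
        rows.append(fv.values())
        ids.append(s.id)
        labels.append(s.label)
    if not rows:
        raise FeatureError("no usable sequences")
    return np.array(rows), ids, labels
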