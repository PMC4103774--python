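"""Scaling engine: windowed fluctuation statistics and log-log exponents.

The estimator follows the end-increment (random-walk displacement) form of
detrended fluctuation analysis: slide a window of width ``l`` along a
cumulative series, record the increment between the two window ends at every
start site, and summarise the increments.  For a single series the
fluctuation F(l) is the standard deviation of those increments; for a triple
of series the 3x3 fluctuation matrix F_jk(l) is their increment covariance,
whose ordered eigenvalue tracks lambda_1(l) >= lambda_2(l) >= lambda_3(l)
capture the joint (cross-correlated) growth.  Power-law growth F ~ l**beta
appears as a straight line on a log-log plot; the exponent is the ordinary
least-squares slope of log F on log l.  An uncorrelated walk gives a
single-series exponent near 1/2 (covariance eigenvalues near l**1);
persistence pushes the exponents up, bounded series push them to 0.

A linearly-detrended (DFA-1) single-series variant is available behind the
``method`` switch for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

SYMMETRY_TOL = 1e-9


class FluctuationError(ValueError):
    """Raised for invalid window widths, degenerate tracks, etc."""


@dataclass(frozen=True)
class ScalingFit:
    """A log-log least-squares fit of fluctuation values vs window widths."""

    widths: tuple[int, ...]
    values: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float

    @property
    def points(self) -> list[tuple[int, float]]:
        return list(zip(self.widths, self.values))


@dataclass(frozen=True)
class MatrixTrack:
    """Fluctuation matrices and eigenvalue tracks over a window-width grid."""

    widths: tuple[int, ...]
    matrices: np.ndarray  # shape (n_widths, 3, 3), symmetric PSD
    eigenvalues: np.ndarray  # shape (n_widths, 3), sorted descending


def default_window_grid(
    n: int, *, l_min: int = 4, l_max_cap: int = 1024
) -> tuple[int, ...]:
    """Powers of two from ``l_min`` up to min(l_max_cap, largest power <= n/4).

    Log-spaced widths give equal weight per octave in the log-log fit; the
    n/4 ceiling keeps many windows per width so each F(l) is well averaged.
    """
    if n < 4 * l_min:
        raise FluctuationError(
            f"series of length {n} too short for minimum window width {l_min}"
        )
    widths = []
    l = l_min
    while l <= min(l_max_cap, n // 4):
        widths.append(l)
        l *= 2
    return tuple(widths)


def window_increments(series: np.ndarray, l: int) -> np.ndarray:
    """End-to-end increments of every width-``l`` window (step 1).

    Delta(i, l) = series[i + l] - series[i] for all N - l start sites.
    """
    series = np.asarray(series)
    n = len(series)
    if not 1 <= l <= n - 1:
        raise FluctuationError(f"window width {l} invalid for series of length {n}")
    return series[l:] - series[:-l]


def cross_fluctuation(series_j: np.ndarray, series_k: np.ndarray, l: int) -> float:
    """Covariance of the two series' window-end increments at width ``l``.

    F_jk(l) = mean(Dj * Dk) - mean(Dj) * mean(Dk) over all start sites
    (population normalisation).  F_jj(l) is then the squared single-series
    fluctuation.
    """
    a = np.asarray(series_j, dtype=float)
    b = np.asarray(series_k, dtype=float)
    if len(a) != len(b):
        raise FluctuationError(f"series length mismatch: {len(a)} vs {len(b)}")
    da = window_increments(a, l)
    db = window_increments(b, l)
    if len(da) < 2:
        raise FluctuationError(f"width {l} leaves fewer than 2 windows")
    return float(np.mean(da * db) - np.mean(da) * np.mean(db))


def fluctuation_matrix(
    d1: np.ndarray, d2: np.ndarray, d3: np.ndarray, l: int
) -> np.ndarray:
    """3x3 increment-covariance matrix of the three series at width ``l``."""
    series = [np.asarray(s, dtype=float) for s in (d1, d2, d3)]
    if len({len(s) for s in series}) != 1:
        raise FluctuationError("the three series must have equal length")
    inc = np.stack([window_increments(s, l) for s in series])
    if inc.shape[1] < 2:
        raise FluctuationError(f"width {l} leaves fewer than 2 windows")
    m = np.cov(inc, ddof=0)
    return (m + m.T) / 2.0  # cancel float asymmetry


def eigen_tracks(matrices: Iterable[np.ndarray]) -> np.ndarray:
    """Descending eigenvalues of each symmetric matrix; shape (n, 3)."""
    out = []
    for m in matrices:
        m = np.asarray(m, dtype=float)
        if np.max(np.abs(m - m.T)) > SYMMETRY_TOL:
            raise FluctuationError("matrix is not symmetric within tolerance")
        out.append(np.linalg.eigvalsh(m)[::-1])
    return np.array(out)


def matrix_track(
    d1: np.ndarray, d2: np.ndarray, d3: np.ndarray, widths: Sequence[int]
) -> MatrixTrack:
    mats = np.stack([fluctuation_matrix(d1, d2, d3, l) for l in widths])
    return MatrixTrack(
        widths=tuple(int(l) for l in widths),
        matrices=mats,
        eigenvalues=eigen_tracks(mats),
    )


def loglog_slope(points: Sequence[tuple[float, float]]) -> ScalingFit:
    """Least-squares slope of log(F) vs log(l).

    Natural logarithms; the base cancels in the slope.  Any non-positive F
    is an error here — callers that tolerate dropped points filter first.
    """
    if len(points) < 3:
        raise FluctuationError(f"need at least 3 points to fit, got {len(points)}")
    widths = [p[0] for p in points]
    values = [p[1] for p in points]
    for l, f in points:
        if f <= 0:
            raise FluctuationError(f"non-positive fluctuation value {f} at width {l}")
    if any(b <= a for a, b in zip(widths, widths[1:])):
        raise FluctuationError("window widths must be strictly increasing")
    res = stats.linregress(np.log(widths), np.log(values))
    return ScalingFit(
        widths=tuple(int(l) for l in widths),
        values=tuple(float(v) for v in values),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def _dfa1_fluctuation(series: np.ndarray, l: int) -> float:
    """DFA-1: RMS residual around per-box linear trends (non-overlapping)."""
    series = np.asarray(series, dtype=float)
    n_boxes = len(series) // l
    if n_boxes < 1:
        raise FluctuationError(f"width {l} too large for DFA-1 on length {len(series)}")
    t = np.arange(l, dtype=float)
    resid_sq = 0.0
    for b in range(n_boxes):
        seg = series[b * l : (b + 1) * l]
        coef = np.polyfit(t, seg, 1)
        resid_sq += float(np.sum((seg - np.polyval(coef, t)) ** 2))
    return float(np.sqrt(resid_sq / (n_boxes * l)))


def single_series_fluctuation(series: np.ndarray, l: int, method: str = "end") -> float:
    """F(l) for one cumulative series.

    ``"end"`` (default): standard deviation of the window-end increments,
    i.e. sqrt(F_jj).  ``"dfa1"``: RMS residual around per-box linear trends.
    """
    if method == "end":
        return float(np.sqrt(cross_fluctuation(series, series, l)))
    if method == "dfa1":
        return _dfa1_fluctuation(series, l)
    raise ValueError(f"unknown fluctuation method {method!r}")


def _fit_track(
    widths: Sequence[int], values: Sequence[float], what: str
) -> ScalingFit | None:
    """Fit one track, dropping non-positive values; None if degenerate."""
    pts = [(l, v) for l, v in zip(widths, values) if v > 0]
    if len(pts) < len(widths):
        warnings.warn(
            f"{what}: dropped {len(widths) - len(pts)} non-positive "
            "fluctuation value(s) before fitting",
            stacklevel=3,
        )
    if len(pts) < 3:
        return None
    return loglog_slope(pts)


def zcurve_exponents(
    track, widths: Sequence[int] | None = None, method: str = "end"
) -> tuple[ScalingFit, ScalingFit, ScalingFit]:
    """Scaling exponents of the three Z-curve components (n1, n2, n3).

    For each component the fluctuation F(l) over the width grid is fitted on
    log-log axes; the slopes are the exponents, in axis order x, y, z.
    """
    x, y, z = track.components
    if widths is None:
        widths = default_window_grid(len(x))
    if len(widths) < 3:
        raise FluctuationError("need at least 3 window widths")
    fits = []
    for name, series in zip("xyz", (x, y, z)):
        values = [single_series_fluctuation(series, l, method) for l in widths]
        fit = _fit_track(widths, values, f"Z-curve component {name}")
        if fit is None:
            raise FluctuationError(
                f"Z-curve component {name}: fewer than 3 positive fluctuation "
                "values; exponent undefined"
            )
        fits.append(fit)
    return tuple(fits)


def cross_exponents(
    d1: np.ndarray,
    d2: np.ndarray,
    d3: np.ndarray,
    widths: Sequence[int] | None = None,
) -> tuple[ScalingFit | None, ScalingFit | None, ScalingFit | None]:
    """Scaling exponents of the eigenvalue tracks (n4, n5, n6).

    The eigenvalues are of the covariance-scale fluctuation matrix (no
    square root), so for uncorrelated diffusive series the slopes sit near
    twice the single-series exponents.  A track that is non-positive at
    nearly every width (e.g. duplicated input series make lambda_2 and
    lambda_3 vanish) yields ``None`` — an undefined exponent — rather than
    a fit to noise.
    """
    if widths is None:
        widths = default_window_grid(len(np.asarray(d1)))
    if len(widths) < 3:
        raise FluctuationError("need at least 3 window widths")
    mt = matrix_track(d1, d2, d3, widths)
    # eigenvalues of exactly degenerate matrices come back as numerical dust
    # (~1e-15 relative); treat anything below a relative floor as zero
    floor = np.max(mt.eigenvalues) * 1e-12
    eigenvalues = np.where(mt.eigenvalues > floor, mt.eigenvalues, 0.0)
    fits = []
    for k in range(3):
        fit = _fit_track(mt.widths, eigenvalues[:, k], f"eigenvalue track {k + 1}")
        if fit is None:
            warnings.warn(
                f"eigenvalue track {k + 1} is degenerate; exponent undefined",
                stacklevel=2,
            )
        fits.append(fit)
    return tuple(fits)
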