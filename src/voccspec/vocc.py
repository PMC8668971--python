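"""Full-lag 2D cross-correlation and the variance-of-cross-correlation curve.

For two same-shape slices X, Y (M x N) the cross-correlation at lag (i, j) is

    C(i, j) = sum_{m,n} X(m, n) Y(m - i, n - j),

with Y taken as 0 outside its support ("full" correlation), so C has shape
(2M-1, 2N-1) over vertical lags i in [-(M-1), M-1] and horizontal lags
j in [-(N-1), N-1].  The VoCC curve collapses C to one value per column lag j:
the sample variance (denominator 2M-2) of C(., j) over the 2M-1 row lags.
A consistent texture across slices yields VoCC curves that barely change from
slice pair (1,2) to slice pair (2,3); independently textured slices do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "VoCCCurve",
    "cross_correlate_2d",
    "cross_correlate_2d_direct",
    "column_lags",
    "vocc",
    "vocc_pair",
    "curves_to_frame",
]


@dataclass
class VoCCCurve:
    """Variance of cross-correlation vs. column lag for one slice pair."""

    lags: np.ndarray
    variance: np.ndarray
    pair_id: str = "pair12"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.lags.shape != self.variance.shape or self.lags.ndim != 1:
            raise ValueError("lags and variance must be 1D arrays of equal length")
        if np.any(self.variance < -1e-12) or not np.all(np.isfinite(self.variance)):
            raise ValueError("variance must be finite and non-negative")
        self.variance = np.maximum(self.variance, 0.0)

    def __len__(self) -> int:
        return self.lags.size


def _check_pair(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("inputs must be 2D arrays")
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    return X, Y


def cross_correlate_2d(X: np.ndarray, Y: np.ndarray, method: str = "auto") -> np.ndarray:
    """Full-lag 2D cross-correlation C(i, j) of two same-shape slices.

    Row r of the output is vertical lag i = r - (M-1); column c is horizontal
    lag j = c - (N-1).  ``method`` is passed to :func:`scipy.signal.correlate`
    ("auto" picks FFT for large inputs; "direct" forces the plain double sum).
    """
    X, Y = _check_pair(X, Y)
    return signal.correlate(X, Y, mode="full", method=method)


def cross_correlate_2d_direct(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Literal quadruple-loop evaluation of the lag sum (slow; for checks)."""
    X, Y = _check_pair(X, Y)
    M, N = X.shape
    C = np.zeros((2 * M - 1, 2 * N - 1))
    for r, i in enumerate(range(-(M - 1), M)):
        for c, j in enumerate(range(-(N - 1), N)):
            total = 0.0
            for m in range(M):
                for n in range(N):
                    mi, nj = m - i, n - j
                    if 0 <= mi < M and 0 <= nj < N:
                        total += X[m, n] * Y[mi, nj]
            C[r, c] = total
    return C


def column_lags(n_cols: int) -> np.ndarray:
    """Horizontal lag axis for a correlation matrix with ``n_cols`` columns.

    Full correlation of N-column inputs has 2N-1 columns, giving the
    symmetric axis j = -(N-1)..(N-1); even widths are centered the same way.
    """
    return np.arange(n_cols) - (n_cols - 1) // 2


def vocc(C: np.ndarray, pair_id: str = "pair12", transpose: bool = False) -> VoCCCurve:
    """Sample variance of C over row lags, one value per column lag.

    The denominator is rows-1 (2M-2 for an M-row input pair), i.e. the sample
    variance over the 2M-1 row lags within each column.  ``transpose=True``
    swaps the roles (variance over column lags per row lag) — a non-default
    variant, since the curve is conventionally indexed by column lag.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2:
        raise ValueError("cross-correlation matrix must be 2D")
    if not np.all(np.isfinite(C)):
        raise ValueError("cross-correlation matrix has non-finite entries")
    if transpose:
        C = C.T
    if C.shape[0] < 2:
        raise ValueError("variance over row lags needs at least 2 rows")
    var = C.var(axis=0, ddof=1)
    return VoCCCurve(column_lags(C.shape[1]), var, pair_id)


def vocc_pair(
    X: np.ndarray, Y: np.ndarray, pair_id: str = "pair12", method: str = "auto"
) -> VoCCCurve:
    """VoCC curve of one consecutive slice pair (correlate, then vary)."""
    return vocc(cross_correlate_2d(X, Y, method=method), pair_id=pair_id)


def curves_to_frame(
    curves: dict[str, VoCCCurve], subject_id: str = "", contrast: str = ""
) -> pd.DataFrame:
    """Tidy CSV-ready table: one row per (pair, lag)."""
    frames = [
        pd.DataFrame(
            {
                "lag": c.lags,
                "variance": c.variance,
                "pair_id": c.pair_id,
                "subject_id": subject_id,
                "contrast": contrast,
            }
        )
        for c in curves.values()
    ]
    return pd.concat(frames, ignore_index=True)
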