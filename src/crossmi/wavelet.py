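"""Periodized orthogonal dyadic wavelet transform (Daubechies family).

The transform is realized as an explicit orthogonal matrix built from the
periodized two-channel filter bank, cached per (length, levels, family).
This keeps Parseval's identity and perfect reconstruction exact to machine
precision, which the downstream maximum-entropy solver and the subband
entropy features both rely on.  Signals whose length is not a multiple of
``2**levels`` are zero-padded on the right up to the next multiple (the
padding rule); the inverse transform truncates back to the original length.

Only the filters this package uses are shipped: ``db3`` for the subband
entropy features and ``db4`` (four vanishing moments) for the wavelet-domain
source localization.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["WaveletStack", "dwt_forward", "dwt_inverse", "dwt_matrix", "DAUBECHIES"]

# Orthonormal decomposition low-pass filters h (sum = sqrt(2)).
DAUBECHIES: dict[str, np.ndarray] = {
    "db1": np.array([0.7071067811865476, 0.7071067811865476]),
    "db2": np.array(
        [
            0.48296291314469025,
            0.8365163037378079,
            0.22414386804185735,
            -0.12940952255092145,
        ]
    ),
    "db3": np.array(
        [
            0.3326705529509569,
            0.8068915093133388,
            0.4598775021193313,
            -0.13501102001039084,
            -0.08544127388224149,
            0.035226291882100656,
        ]
    ),
    "db4": np.array(
        [
            0.23037781330885523,
            0.7148465705525415,
            0.6308807679295904,
            -0.02798376941698385,
            -0.18703481171888114,
            0.030841381835986965,
            0.032883011666982945,
            -0.010597401784997278,
        ]
    ),
}


def _analysis_step_matrix(n: int, h: np.ndarray) -> np.ndarray:
    """Orthogonal (n x n) one-level analysis matrix for a periodized signal.

    Rows 0..n/2-1 produce approximation coefficients, rows n/2.. detail
    coefficients, with the quadrature-mirror high-pass g[m] = (-1)^m h[L-1-m].
    """
    L = len(h)
    if n % 2:
        raise ValueError("signal length must be even at every level")
    if n < L:
        raise ValueError(f"level too deep: periodized length {n} < filter length {L}")
    g = ((-1) ** np.arange(L)) * h[::-1]
    A = np.zeros((n, n))
    half = n // 2
    for k in range(half):
        for m in range(L):
            j = (2 * k + m) % n
            A[k, j] += h[m]
            A[half + k, j] += g[m]
    return A


@lru_cache(maxsize=32)
def dwt_matrix(n: int, levels: int, family: str = "db4") -> np.ndarray:
    """Full orthogonal DWT matrix T: coefficients = T @ signal.

    Output ordering: [approx_L | detail_L | detail_{L-1} | ... | detail_1].
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    h = DAUBECHIES[family]
    if n % (2**levels):
        raise ValueError(f"length {n} not divisible by 2**{levels}")
    T = np.eye(n)
    m = n
    for _ in range(levels):
        A = _analysis_step_matrix(m, h)
        step = np.eye(n)
        step[:m, :m] = A
        T = step @ T
        m //= 2
    return T


@dataclass
class WaveletStack:
    """Multichannel DWT coefficients in flat [aL | dL | ... | d1] layout.

    ``coefficients`` is (channels x n_padded); ``slices`` maps subband name
    ("a3", "d3", ..., "d1") to its column slice.  ``original_length`` records
    the pre-padding sample count so the inverse can truncate.
    """

    coefficients: np.ndarray
    n_levels: int
    family: str
    original_length: int

    @property
    def slices(self) -> dict[str, slice]:
        n = self.coefficients.shape[-1]
        out: dict[str, slice] = {}
        width = n >> self.n_levels
        out[f"a{self.n_levels}"] = slice(0, width)
        start = width
        for lev in range(self.n_levels, 0, -1):
            width = n >> lev
            out[f"d{lev}"] = slice(start, start + width)
            start += width
        return out

    def subband(self, name: str) -> np.ndarray:
        return self.coefficients[..., self.slices[name]]

    def scale_of_column(self) -> np.ndarray:
        """Per-column level tag: n_levels for aL, level j for dj."""
        n = self.coefficients.shape[-1]
        tags = np.empty(n, dtype=int)
        for name, sl in self.slices.items():
            tags[sl] = int(name[1:])
        return tags


def _pad(signal: np.ndarray, levels: int) -> np.ndarray:
    n = signal.shape[-1]
    block = 2**levels
    pad = (-n) % block
    if pad == 0:
        return signal
    width = [(0, 0)] * (signal.ndim - 1) + [(0, pad)]
    return np.pad(signal, width)


def dwt_forward(signal: np.ndarray, levels: int, family: str = "db4") -> WaveletStack:
    """Forward periodized orthogonal DWT of each row of ``signal``.

    Parameters
    ----------
    signal : (..., tau) array; rows are transformed independently.
    levels : decomposition depth; requires tau >= 2**levels.
    family : "db1".."db4".
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    n = x.shape[-1]
    if n < 2**levels:
        raise ValueError(f"signal length {n} < 2**levels = {2**levels}")
    xp = _pad(x, levels)
    T = dwt_matrix(xp.shape[-1], levels, family)
    coeffs = xp @ T.T
    return WaveletStack(coeffs, levels, family, n)


def dwt_inverse(stack: WaveletStack) -> np.ndarray:
    """Inverse transform; truncates back to the original signal length."""
    T = dwt_matrix(stack.coefficients.shape[-1], stack.n_levels, stack.family)
    x = stack.coefficients @ T
    return x[..., : stack.original_length]
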