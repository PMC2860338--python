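"""Invertible sparsifying transforms; orthonormal 2D Haar as the instance.

A sparsifying transform maps an image to a flat coefficient vector
``phi[gamma] = <f, basis[gamma]>`` in which the object of interest has few
significant entries.  The concrete transform here is the full-depth
separable orthonormal 2D Haar wavelet decomposition (unit-norm filters, so
Parseval holds exactly:  sum(phi^2) == sum(f^2)).  The interface is
abstract so any other invertible basis can be swapped in.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
import pywt

from .phantom import Image

__all__ = [
    "CoefficientVector",
    "SparsifyingTransform",
    "HaarTransform",
    "count_nonzero",
    "save_coefficients_csv",
]


@dataclass(frozen=True)
class CoefficientVector:
    """Flat vector of transform coefficients with its transform descriptor."""

    coeffs: np.ndarray
    transform: "SparsifyingTransform"

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float).ravel()
        if c.size != self.transform.n_coefficients:
            raise ValueError("coefficient length does not match transform size")
        if not np.all(np.isfinite(c)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coeffs", c)


class SparsifyingTransform(ABC):
    """Forward/inverse pair between an n x n image and N = n^2 coefficients."""

    n: int

    @property
    def n_coefficients(self) -> int:
        return self.n * self.n

    @abstractmethod
    def forward(self, f: Image | np.ndarray) -> CoefficientVector: ...

    @abstractmethod
    def inverse(self, c: CoefficientVector | np.ndarray) -> np.ndarray: ...


class HaarTransform(SparsifyingTransform):
    """Full-depth separable orthonormal 2D Haar decomposition.

    Requires a dyadic grid (n a power of two); decomposition depth is
    log2(n) so the approximation band is a single coefficient.
    """

    def __init__(self, n: int):
        if n < 2 or n & (n - 1):
            raise ValueError("grid side must be a power of two >= 2")
        self.n = int(n)
        self.levels = int(np.log2(n))
        # template decomposition to freeze the flat coefficient ordering
        tmpl = pywt.wavedec2(
            np.zeros((n, n)), "haar", mode="periodization", level=self.levels
        )
        _, self._slices = pywt.coeffs_to_array(tmpl)

    def forward(self, f: Image | np.ndarray) -> CoefficientVector:
        arr = f.values if isinstance(f, Image) else np.asarray(f, dtype=float)
        if arr.shape != (self.n, self.n):
            raise ValueError("image shape does not match transform size")
        coeffs = pywt.wavedec2(arr, "haar", mode="periodization", level=self.levels)
        flat, _ = pywt.coeffs_to_array(coeffs)
        return CoefficientVector(coeffs=flat.ravel(), transform=self)

    def inverse(self, c: CoefficientVector | np.ndarray) -> np.ndarray:
        flat = c.coeffs if isinstance(c, CoefficientVector) else np.asarray(c, float).ravel()
        if flat.size != self.n_coefficients:
            raise ValueError("coefficient length does not match transform size")
        coeffs = pywt.array_to_coeffs(
            flat.reshape(self.n, self.n), self._slices, output_format="wavedec2"
        )
        return pywt.waverec2(coeffs, "haar", mode="periodization")


def save_coefficients_csv(c: CoefficientVector, path) -> None:
    """Write coefficients as a flat (index, value) CSV for inspection."""
    arr = np.column_stack([np.arange(c.coeffs.size), c.coeffs])
    np.savetxt(path, arr, delimiter=",", header="index,value", comments="", fmt=["%d", "%.17g"])


def count_nonzero(c: CoefficientVector | np.ndarray, tol: float = 1e-8) -> int:
    """Number of coefficients with magnitude strictly above ``tol``."""
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    arr = c.coeffs if isinstance(c, CoefficientVector) else np.asarray(c, float)
    return int(np.count_nonzero(np.abs(arr) > tol))
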