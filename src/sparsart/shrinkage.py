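"""lp shrinkage operators and projection onto the lp ball.

The scalar map ``F_{w,p}(x) = x + w p sgn(x) |x|^{p-1}`` is strictly
increasing and odd for p > 1; its inverse ``S_{w,p}`` is the generalized
soft-thresholding (shrinkage) operator.  For p = 1 the inverse degenerates
to the classical soft threshold; for p = 3/2 and p = 2 closed forms exist;
for other p in (1, 2) the inverse is computed by safeguarded Newton
iteration.  Applying S componentwise with an adaptively chosen threshold mu
projects a coefficient vector onto the lp ball of a target radius — mu is
found by bisection on the (continuous, nonincreasing) radius-vs-threshold
curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShrinkageParams",
    "F",
    "S",
    "shrink_vector",
    "lp_radius",
    "project_to_ball",
]


@dataclass(frozen=True)
class ShrinkageParams:
    """Exponent p in [1, 2] and nonnegative uniform threshold weight w."""

    p: float
    w: float

    def __post_init__(self) -> None:
        if not 1.0 <= self.p <= 2.0:
            raise ValueError("p must lie in [1, 2]")
        if self.w < 0:
            raise ValueError("w must be nonnegative")


def F(x, params: ShrinkageParams):
    """F_{w,p}(x) = x + w*p*sgn(x)*|x|^(p-1); defined for p in (1, 2]."""
    if not 1.0 < params.p <= 2.0:
        raise ValueError("F requires p in (1, 2]; p=1 is handled directly by S")
    x = np.asarray(x, dtype=float)
    out = x + params.w * params.p * np.sign(x) * np.abs(x) ** (params.p - 1.0)
    return out if out.ndim else float(out)


def _invert_F(y: np.ndarray, p: float, w: float, tol: float = 1e-10) -> np.ndarray:
    """Solve x + w*p*x^(p-1) = y for x >= 0 elementwise (y >= 0).

    Safeguarded Newton: iterates are clipped into a shrinking bisection
    bracket [lo, hi] with 0 <= x <= y, so convergence is global.
    """
    lo = np.zeros_like(y)
    hi = y.copy()
    x = y / (1.0 + w * p)  # decent start; exact for p = 2
    for _ in range(100):
        g = x + w * p * np.where(x > 0, x, 1.0) ** (p - 1.0) * (x > 0) - y
        done = np.abs(g) <= tol * np.maximum(1.0, y)
        if done.all():
            break
        hi = np.where(g > 0, x, hi)
        lo = np.where(g < 0, x, lo)
        with np.errstate(divide="ignore", over="ignore"):
            dg = 1.0 + w * p * (p - 1.0) * np.where(x > 0, x, 1.0) ** (p - 2.0)
            xn = x - g / dg
        bad = ~((xn > lo) & (xn < hi)) | ~np.isfinite(xn)
        x = np.where(bad, 0.5 * (lo + hi), xn)
    return x


def S(y, params: ShrinkageParams):
    """Generalized soft-thresholding: the inverse of F (soft threshold at p=1)."""
    p, w = params.p, params.w
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    a = np.abs(y)
    if w == 0:
        out = y.astype(float)
    elif p == 1.0:
        out = np.sign(y) * np.maximum(a - w, 0.0)
    elif p == 2.0:
        out = y / (1.0 + 2.0 * w)
    elif p == 1.5:
        # stable form of  a - 3w(sqrt(9w^2 + 16a) - 3w)/8  (avoids cancellation)
        root = np.sqrt(9.0 * w * w + 16.0 * a)
        out = np.sign(y) * (a - 6.0 * w * a / (root + 3.0 * w))
    else:
        out = np.sign(y) * _invert_F(a, p, w)
    return float(out[0]) if scalar else out


def shrink_vector(c: np.ndarray, params: ShrinkageParams) -> np.ndarray:
    """Componentwise S over a coefficient array."""
    return S(np.asarray(c, dtype=float), params)


def lp_radius(c: np.ndarray, p: float) -> float:
    """(sum |c|^p)^(1/p) — the lp radius of the vector in the sparse space."""
    if not 1.0 <= p <= 2.0:
        raise ValueError("p must lie in [1, 2]")
    a = np.abs(np.asarray(c, dtype=float))
    if a.size == 0:
        return 0.0
    m = a.max()
    if m == 0:
        return 0.0
    # scale by the max for overflow-safe powers
    return float(m * np.sum((a / m) ** p) ** (1.0 / p))


def project_to_ball(
    c: np.ndarray,
    R_target: float,
    p: float,
    tol: float = 1e-8,
    max_bisect: int = 200,
) -> tuple[np.ndarray, float]:
    """Project onto the lp ball of radius ``R_target`` via adaptive threshold.

    If the vector already lies inside the ball it is returned unchanged with
    mu = 0.  Otherwise mu > 0 is found by bisection so that the shrunk
    vector's lp radius equals ``R_target`` within ``tol * max(1, R_target)``.

    Returns
    -------
    (projected, mu)
    """
    if R_target < 0:
        raise ValueError("R_target must be nonnegative")
    c = np.asarray(c, dtype=float)
    if lp_radius(c, p) <= R_target:
        return c.copy(), 0.0
    if R_target == 0.0:
        # shrinking by the largest magnitude kills every component at p = 1;
        # for p > 1 the exact answer is the zero vector as well
        return np.zeros_like(c), float(np.max(np.abs(c)))

    lo, hi = 0.0, float(np.max(np.abs(c)))
    # for p > 1 shrinking by max|c| leaves a small positive radius; widen
    while lp_radius(shrink_vector(c, ShrinkageParams(p, hi)), p) > R_target:
        hi *= 2.0
    atol = tol * max(1.0, R_target)
    mu = hi
    for _ in range(max_bisect):
        mu = 0.5 * (lo + hi)
        r = lp_radius(shrink_vector(c, ShrinkageParams(p, mu)), p)
        if abs(r - R_target) <= atol:
            break
        if r > R_target:
            lo = mu
        else:
            hi = mu
    return shrink_vector(c, ShrinkageParams(p, mu)), mu
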