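"""Reconstruction iterations: SART, ISTA, and sparsity-projected SART.

The workhorse is a SART-type projected-gradient scheme.  Classical SART
updates ``f <- f + lambda * rt`` with the doubly normalized residual
``rt = Lam_colsum A^T Lam_rowsum (g - A f)``.  The sparsity-constrained
variant rescales that residual by a constant ``alpha`` (estimated from the
matrix norms so the normalized step has the right magnitude), takes an
adaptive step ``beta = ||rt||^2 / ||A rt||^2``, and after every step
projects the iterate's coefficients in a sparsifying basis onto the lp
ball whose radius matches the true object.  Scheme labels:

==========  =================================================================
A           alpha-scaled SART step + projection onto the fixed ball R*
B           same step, projection disabled (plain accelerated SART)
C           as A but with a radius schedule growing from 0.4 R* to R*
AD/BD/CD    direct (unweighted) counterparts: alpha = 1, identity weights,
            so the step is plain A^T(g - A f) projected-gradient
==========  =================================================================

Convergence is tracked by the relative reconstruction error
``E^k = 100 * ||f^k - f*|| / ||f*||`` against the ground-truth object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Sinogram, SystemMatrix
from .phantom import Image
from .shrinkage import ShrinkageParams, lp_radius, project_to_ball, shrink_vector
from .sparsify import SparsifyingTransform

__all__ = [
    "SolverConfig",
    "ConvergenceLog",
    "DivergenceError",
    "rre",
    "sart_residual",
    "sart_step",
    "estimate_alpha",
    "step_size_beta",
    "interior_radius",
    "ista_step",
    "run_scheme",
]

SCHEMES = ("A", "B", "C", "AD", "BD", "CD")


class DivergenceError(RuntimeError):
    """Raised when the iteration blows up; try a smaller alpha0."""


@dataclass(frozen=True)
class SolverConfig:
    """Parameters of one reconstruction run.

    ``rre_stop`` is in percent; ``r_star`` is the target lp radius of the
    solution's transform coefficients (computed from the ground truth when
    omitted).  ``lambda_relax`` only drives classical SART (`sart_step`).
    """

    scheme: str = "A"
    p: float = 1.0
    alpha0: float = 2.0
    lambda_relax: float = 1.0
    max_iter: int = 20000
    rre_stop: float = 0.1
    r_star: float | None = None
    proj_tol: float = 1e-8
    nonneg: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if not 1.0 <= self.p <= 2.0:
            raise ValueError("p must lie in [1, 2]")
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if not 0 < self.lambda_relax < 2:
            raise ValueError("lambda_relax must lie in (0, 2)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @property
    def direct(self) -> bool:
        """Direct variants use alpha = 1 and identity weighting diagonals."""
        return self.scheme.endswith("D")

    @property
    def projected(self) -> bool:
        return self.scheme[0] in ("A", "C")


@dataclass
class ConvergenceLog:
    """Per-iteration solver record plus the final image."""

    iterations: list[int] = field(default_factory=list)
    rre_percent: list[float] = field(default_factory=list)
    beta: list[float] = field(default_factory=list)
    mu: list[float] = field(default_factory=list)
    discrepancy: list[float] = field(default_factory=list)
    final_image: Image | None = None
    stop_iteration: int = 0

    def append(self, k: int, e: float, b: float, m: float, d: float) -> None:
        self.iterations.append(k)
        self.rre_percent.append(e)
        self.beta.append(b)
        self.mu.append(m)
        self.discrepancy.append(d)

    @property
    def final_rre(self) -> float:
        return self.rre_percent[-1]


def rre(f: np.ndarray | Image, f_star: np.ndarray | Image) -> float:
    """Relative reconstruction error in percent: 100 ||f - f*|| / ||f*||."""
    fv = f.ravel() if isinstance(f, Image) else np.asarray(f, float).ravel()
    sv = f_star.ravel() if isinstance(f_star, Image) else np.asarray(f_star, float).ravel()
    denom = np.linalg.norm(sv)
    if denom == 0:
        raise ValueError("reference image must be nonzero")
    return float(100.0 * np.linalg.norm(fv - sv) / denom)


def _weights(A: SystemMatrix, direct: bool) -> tuple[np.ndarray, np.ndarray]:
    if direct:
        M, N = A.shape
        return np.ones(M), np.ones(N)
    return A.lam_row, A.lam_col


def sart_residual(
    A: SystemMatrix,
    g: Sinogram | np.ndarray,
    f: np.ndarray,
    direct: bool = False,
) -> np.ndarray:
    """Doubly normalized residual backprojection Lam^{+N} A^T Lam^{M+} (g - A f)."""
    gv = g.values if isinstance(g, Sinogram) else np.asarray(g, float).ravel()
    lam_row, lam_col = _weights(A, direct)
    res = gv - A.weights @ f
    return lam_col * (A.weights.T @ (lam_row * res))


def sart_step(
    f: np.ndarray,
    A: SystemMatrix,
    g: Sinogram | np.ndarray,
    lambda_relax: float = 1.0,
) -> np.ndarray:
    """One classical SART update f + lambda * rt (relaxation in (0, 2))."""
    return f + lambda_relax * sart_residual(A, g, f)


def estimate_alpha(A: SystemMatrix, alpha0: float = 2.0) -> float:
    """Residual rescaling constant for the weighted scheme.

    alpha = alpha0 * sqrt( max_n (A^T A 1)_n /
                           max_n (Lam^{+N} A^T Lam^{M+} Lam^{M+} A Lam^{+N} 1)_n ),
    i.e. alpha0 times the ratio of the infinity-norm bounds of the plain and
    the SART-weighted normal operators.  Direct variants bypass this and use
    alpha = 1.
    """
    W = A.weights
    N = W.shape[1]
    num = np.max(W.T @ (W @ np.ones(N)))
    v = A.lam_col.copy()
    v = W @ v
    v *= A.lam_row**2
    v = W.T @ v
    v *= A.lam_col
    den = np.max(v)
    if den <= 0 or num <= 0:
        raise ValueError("system matrix has no interacting rows/pixels")
    return float(alpha0 * np.sqrt(num / den))


def step_size_beta(A: SystemMatrix, r: np.ndarray) -> float:
    """Steepest-descent-like step ||r||^2 / ||A r||^2 for the residual direction."""
    rn = float(np.dot(r, r))
    if rn == 0:
        raise ValueError("residual is zero; iteration has converged")
    Ar = A.weights @ r
    arn = float(np.dot(Ar, Ar))
    if arn == 0:
        raise DivergenceError("A r = 0 for nonzero r: stagnation")
    return rn / arn


def interior_radius(k: int, max_iter: int, R_star: float) -> float:
    """Growing radius schedule R^k = (0.4 + 0.6 (k / max_iter)^0.05) R*."""
    return (0.4 + 0.6 * (k / max_iter) ** 0.05) * R_star


def ista_step(
    f: np.ndarray,
    A: SystemMatrix,
    g: Sinogram | np.ndarray,
    transform: SparsifyingTransform,
    params: ShrinkageParams,
) -> np.ndarray:
    """One iterative soft-thresholding step S_{w,p}(f + A^T(g - A f)).

    Reference implementation of the unaccelerated thresholded Landweber
    iteration; the caller must renormalize A so ||A^T A|| < 1.
    """
    gv = g.values if isinstance(g, Sinogram) else np.asarray(g, float).ravel()
    z = f + A.weights.T @ (gv - A.weights @ f)
    c = transform.forward(z.reshape(transform.n, transform.n))
    return transform.inverse(shrink_vector(c.coeffs, params)).ravel()


def run_scheme(
    config: SolverConfig,
    A: SystemMatrix,
    g: Sinogram | np.ndarray,
    f_true: Image | np.ndarray,
    transform: SparsifyingTransform | None = None,
    log_every: int = 1,
    f0: np.ndarray | None = None,
) -> ConvergenceLog:
    """Run one reconstruction scheme from a zero start (or ``f0``).

    Stops when the RRE against ``f_true`` drops below ``config.rre_stop``
    percent or ``config.max_iter`` is reached.  For the projected schemes a
    sparsifying ``transform`` is required; the ball radius defaults to the
    lp radius of the true object's coefficients.

    Raises
    ------
    DivergenceError
        If the error exceeds 10x its initial value or turns non-finite;
        reduce ``alpha0`` in that case.
    """
    gv = g.values if isinstance(g, Sinogram) else np.asarray(g, float).ravel()
    tv = f_true.ravel() if isinstance(f_true, Image) else np.asarray(f_true, float).ravel()
    pixel_size = f_true.pixel_size if isinstance(f_true, Image) else 1.0
    n = int(np.sqrt(tv.size))

    if config.projected:
        if transform is None:
            raise ValueError(f"scheme {config.scheme} requires a sparsifying transform")
        r_star = config.r_star
        if r_star is None:
            r_star = lp_radius(transform.forward(tv.reshape(n, n)).coeffs, config.p)

    alpha = 1.0 if config.direct else estimate_alpha(A, config.alpha0)
    lam_row, lam_col = _weights(A, config.direct)
    W = A.weights
    WT = W.T.tocsr()

    f = np.zeros(W.shape[1]) if f0 is None else np.asarray(f0, float).ravel().copy()
    e0 = rre(f, tv)
    log = ConvergenceLog()
    for k in range(1, config.max_iter + 1):
        res = gv - W @ f
        rt = lam_col * (WT @ (lam_row * res))
        rn = float(np.dot(rt, rt))
        if rn == 0:  # exact data consistency: nothing left to do
            log.append(k, rre(f, tv), 0.0, 0.0, float(np.linalg.norm(res)))
            break
        Ar = W @ rt
        arn = float(np.dot(Ar, Ar))
        if arn == 0:
            raise DivergenceError("A r = 0 for nonzero r: stagnation")
        beta = rn / arn
        f = f + alpha * beta * rt

        mu = 0.0
        if config.projected:
            target = (
                interior_radius(k, config.max_iter, r_star)
                if config.scheme[0] == "C"
                else r_star
            )
            c = transform.forward(f.reshape(n, n))
            proj, mu = project_to_ball(c.coeffs, target, config.p, tol=config.proj_tol)
            f = transform.inverse(proj).ravel()
        if config.nonneg:
            # attenuation coefficients are physically nonnegative; clamping is
            # the standard algebraic-reconstruction practice
            np.maximum(f, 0.0, out=f)

        e = rre(f, tv)
        if not np.isfinite(e) or e > 10.0 * max(e0, 1.0):
            raise DivergenceError(
                f"scheme {config.scheme} diverged at iteration {k} "
                f"(RRE {e:.3g}% vs initial {e0:.3g}%); reduce alpha0"
            )
        if k % log_every == 0 or k == config.max_iter or e < config.rre_stop:
            log.append(k, e, beta, mu, float(np.linalg.norm(res)))
        if e < config.rre_stop:
            break

    log.stop_iteration = log.iterations[-1] if log.iterations else 0
    log.final_image = Image(values=f.reshape(n, n), pixel_size=pixel_size)
    return log
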