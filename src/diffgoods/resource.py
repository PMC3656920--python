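"""Steady-state solvers for the diffusible resource on the periodic lattice.

A producer at site x0 sources the resource at flux p; the resource diffuses
with constant D (5-point discrete Laplacian, lattice spacing 1 cell length)
and is consumed/degraded at first-order rate gamma:

    p * delta_{x,x0} + D * lap(c) - gamma * c = 0.

Because cell division is far slower than diffusion, the field is assumed to
relax instantly: after every replacement event the dynamics see the exact
steady state for the current configuration.  The screened-Poisson operator
is translation invariant on the torus, so the steady state is obtained
exactly by diagonalizing it with the FFT; the field of an arbitrary
producer configuration is the superposition of translated single-source
kernels, which also yields an O(L^2) incremental update per flipped site.

The only remaining length scale is the diffusion length lambda = sqrt(D/gamma),
the characteristic decay length of the single-source kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .lattice import PRODUCER, ConfigurationError


@dataclass(frozen=True)
class ResourceParams:
    """Physical parameters of the resource field.

    Either ``D`` or ``lam`` may be given; with ``gamma`` fixed they are
    redundant (``lam**2 = D / gamma``).  ``k_s`` is the half-saturation
    constant of the Michaelis-Menten uptake variant; ``inf`` selects the
    linear model.
    """

    lam: float | None = None
    D: float | None = None
    p: float = 1.0
    gamma: float = 1.0
    k_s: float = float("inf")
    # derived, filled in __post_init__
    _D: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        if (self.lam is None) == (self.D is None):
            raise ConfigurationError("specify exactly one of lam or D")
        if self.p <= 0 or self.gamma <= 0:
            raise ConfigurationError("p and gamma must be positive")
        D = self.D if self.D is not None else self.lam ** 2 * self.gamma
        if D < 0:
            raise ConfigurationError("diffusion constant must be >= 0")
        if not self.k_s > 0:
            raise ConfigurationError("k_s must be positive (inf for the linear model)")
        object.__setattr__(self, "_D", float(D))

    @property
    def diffusion(self) -> float:
        """Diffusion constant D = lam**2 * gamma."""
        return self._D

    @property
    def diffusion_length(self) -> float:
        return float(np.sqrt(self._D / self.gamma))

    @property
    def saturating(self) -> bool:
        return np.isfinite(self.k_s)


def _laplacian_symbol(L: int) -> np.ndarray:
    """Eigenvalues of minus the discrete Laplacian on the L x L torus."""
    k = 2.0 * np.pi * np.fft.fftfreq(L)
    return (2.0 - 2.0 * np.cos(k))[:, None] + (2.0 - 2.0 * np.cos(k))[None, :]


def single_source_kernel(L: int, params: ResourceParams) -> np.ndarray:
    """Steady-state field of a single producer at the origin of the torus.

    Exact spectral solution of the screened-Poisson equation; satisfies
    flux balance ``gamma * sum(c) == p`` and decays with characteristic
    length ``lam`` (a 2D modified-Bessel K0 profile at distances >> 1).
    """
    if params.saturating:
        raise ConfigurationError("single_source_kernel applies to the linear model only")
    sym = _laplacian_symbol(L)
    chat = params.p / (params.gamma + params.diffusion * sym)
    return np.fft.ifft2(chat).real


def steady_state_field(grid: np.ndarray, params: ResourceParams) -> np.ndarray:
    """Exact linear steady state for an arbitrary producer configuration.

    Computed spectrally; identical (to rounding) to superposing translated
    single-source kernels over all producer sites.
    """
    if params.saturating:
        raise ConfigurationError("use steady_state_field_saturating for finite k_s")
    src = (grid == PRODUCER).astype(float)
    sym = _laplacian_symbol(grid.shape[0])
    chat = params.p * np.fft.fft2(src) / (params.gamma + params.diffusion * sym)
    return np.fft.ifft2(chat).real


def solve_direct(grid: np.ndarray, params: ResourceParams) -> np.ndarray:
    """Reference linear solve via the assembled sparse operator.

    Builds (gamma*I - D*lap) explicitly and solves with a sparse LU
    factorization.  O(L^3)-ish; used for cross-validation of the spectral
    path, not in the simulation loop.
    """
    L = grid.shape[0]
    n = L * L
    idx = np.arange(n)
    r, c = idx // L, idx % L
    rows, cols, vals = [idx], [idx], [np.full(n, params.gamma + 4.0 * params.diffusion)]
    for rr, cc in (((r - 1) % L, c), ((r + 1) % L, c), (r, (c - 1) % L), (r, (c + 1) % L)):
        rows.append(idx)
        cols.append(rr * L + cc)
        vals.append(np.full(n, -params.diffusion))
    A = scipy.sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    b = params.p * (grid == PRODUCER).astype(float).ravel()
    return scipy.sparse.linalg.spsolve(A.tocsc(), b).reshape(L, L)


def update_field_incremental(
    field_: np.ndarray, site: tuple[int, int], to_producer: bool, kernel: np.ndarray
) -> np.ndarray:
    """Field after flipping one site, by kernel superposition (in place).

    *kernel* must be the single-source kernel of the same L and parameters;
    the result equals a fresh solve of the post-flip grid up to rounding.
    """
    shifted = np.roll(kernel, shift=site, axis=(0, 1))
    if to_producer:
        field_ += shifted
    else:
        field_ -= shifted
    return field_


class SolverError(RuntimeError):
    """Raised when the saturating-uptake iteration fails to converge."""


def steady_state_field_saturating(
    grid: np.ndarray,
    params: ResourceParams,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> np.ndarray:
    """Self-consistent steady state with Michaelis-Menten uptake.

    Solves  p*1_producer + D*lap(c) - gamma * c * k_s / (k_s + c) = 0
    by damped fixed-point iteration: the saturation deficit of the uptake
    term is moved to the source side and the screened-Poisson problem is
    re-solved spectrally until the residual max-norm falls below *tol*.
    As k_s -> inf this reverts to the linear model.
    """
    if not params.saturating:
        return steady_state_field(grid, params)
    L = grid.shape[0]
    sym = _laplacian_symbol(L)
    denom = params.gamma + params.diffusion * sym
    src = params.p * (grid == PRODUCER).astype(float)
    c = np.fft.ifft2(np.fft.fft2(src) / denom).real  # linear solution as start
    c = np.maximum(c, 0.0)
    for _ in range(max_iter):
        # gamma*c*Ks/(Ks+c) = gamma*c - gamma*c^2/(Ks+c): fold the correction
        # into the source and re-solve the linear operator.
        extra = params.gamma * c * c / (params.k_s + c)
        c_new = np.fft.ifft2(np.fft.fft2(src + extra) / denom).real
        c_next = (1.0 - damping) * c + damping * np.maximum(c_new, 0.0)
        resid = residual_saturating(grid, c_next, params)
        c = c_next
        if np.abs(resid).max() < tol:
            return c
    raise SolverError(
        f"saturating solver did not reach tol={tol:g} in {max_iter} iterations "
        f"(final residual {np.abs(resid).max():.3e})"
    )


def residual_saturating(grid: np.ndarray, c: np.ndarray, params: ResourceParams) -> np.ndarray:
    """Pointwise residual of the saturating steady-state equation."""
    lap = (
        np.roll(c, 1, 0) + np.roll(c, -1, 0) + np.roll(c, 1, 1) + np.roll(c, -1, 1) - 4.0 * c
    )
    uptake = params.gamma * c * params.k_s / (params.k_s + c)
    return params.p * (grid == PRODUCER) + params.diffusion * lap - uptake


def save_field(path, c: np.ndarray) -> None:
    """Dump a field as a plain-text matrix at full double precision."""
    np.savetxt(path, c, fmt="%.17g")
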