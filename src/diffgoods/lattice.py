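"""Periodic square-lattice geometry, cell grids, and initial conditions.

The population lives on an L x L torus.  Every site holds exactly one cell
of one of two types; there are no vacancies.  Types are encoded as int8:

* ``PRODUCER = 1`` — secretes the diffusible resource (type A in the
  mutualism variant),
* ``NONPRODUCER = 0`` — benefits without producing (type B).

Neighborhoods are strictly von Neumann (the 4 cardinal neighbors) with
periodic wrap on both axes.  A *boundary* cell has at least one cardinal
neighbor of the other type; only boundary cells can change the
configuration when they divide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

PRODUCER = 1
NONPRODUCER = 0

_INIT_KINDS = ("mixed_50_50", "segregated_halves", "single_invader")


class ConfigurationError(ValueError):
    """Raised for invalid lattice sizes or malformed initial conditions."""


@dataclass(frozen=True)
class InitialCondition:
    """Specification of the starting configuration.

    kind
        ``mixed_50_50``: exactly ``L**2 // 2`` producers placed uniformly
        at random (on odd ``L**2`` the extra cell is a nonproducer);
        ``segregated_halves``: producers in columns ``[0, L/2)``,
        nonproducers in ``[L/2, L)``;
        ``single_invader``: a uniform sea of the opposite type with one
        invader at a random site.
    invader_type
        Cell type of the single invader (``single_invader`` only).
    """

    kind: str
    invader_type: int = NONPRODUCER

    def __post_init__(self) -> None:
        if self.kind not in _INIT_KINDS:
            raise ConfigurationError(
                f"unknown initial condition {self.kind!r}; expected one of {_INIT_KINDS}"
            )
        if self.invader_type not in (PRODUCER, NONPRODUCER):
            raise ConfigurationError(f"invalid invader_type {self.invader_type!r}")


def make_grid(L: int, init: InitialCondition, rng: np.random.Generator) -> np.ndarray:
    """Build an ``L x L`` int8 cell grid realizing *init*.

    Deterministic given the state of *rng*.
    """
    if not isinstance(L, (int, np.integer)) or L < 2:
        raise ConfigurationError(f"lattice size must be an integer >= 2, got {L!r}")
    L = int(L)
    n = L * L
    if init.kind == "mixed_50_50":
        flat = np.zeros(n, dtype=np.int8)
        producers = rng.choice(n, size=n // 2, replace=False)
        flat[producers] = PRODUCER
        return flat.reshape(L, L)
    if init.kind == "segregated_halves":
        if L % 2:
            raise ConfigurationError("segregated_halves requires even L")
        grid = np.zeros((L, L), dtype=np.int8)
        grid[:, : L // 2] = PRODUCER
        return grid
    # single_invader
    grid = np.full((L, L), PRODUCER if init.invader_type == NONPRODUCER else NONPRODUCER,
                   dtype=np.int8)
    site = rng.integers(n)
    grid[site // L, site % L] = init.invader_type
    return grid


def neighbor_indices(L: int) -> np.ndarray:
    """Flat indices of the 4 cardinal neighbors of every site.

    Returns an array of shape ``(4, L*L)``: rows are up, down, left, right
    (with periodic wrap), columns are sites in row-major order.
    """
    idx = np.arange(L * L)
    r, c = idx // L, idx % L
    return np.stack([
        ((r - 1) % L) * L + c,
        ((r + 1) % L) * L + c,
        r * L + (c - 1) % L,
        r * L + (c + 1) % L,
    ])


def boundary_mask(grid: np.ndarray, nbr: np.ndarray | None = None) -> np.ndarray:
    """Boolean L x L mask of boundary cells (>=1 differing cardinal neighbor)."""
    L = grid.shape[0]
    if nbr is None:
        nbr = neighbor_indices(L)
    flat = grid.ravel()
    diff = (flat[nbr] != flat[None, :]).any(axis=0)
    return diff.reshape(L, L)


def boundary_sites(grid: np.ndarray) -> set[tuple[int, int]]:
    """The set of (row, col) boundary sites of *grid*."""
    rr, cc = np.nonzero(boundary_mask(grid))
    return set(zip(rr.tolist(), cc.tolist()))


def cross_type_edges(grid: np.ndarray) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All directed (divider, target) pairs of adjacent differing-type sites.

    Each undirected boundary edge contributes exactly two directed events.
    """
    L = grid.shape[0]
    nbr = neighbor_indices(L)
    flat = grid.ravel()
    diff = flat[nbr] != flat[None, :]
    d, t = np.nonzero(diff)
    dividers = nbr[d, t]
    return [((int(a) // L, int(a) % L), (int(b) // L, int(b) % L))
            for a, b in zip(dividers, t)]


def minimal_image_distance(a: tuple[int, int], b: tuple[int, int], L: int) -> float:
    """Euclidean distance between sites under the minimal-image convention."""
    dr = (a[0] - b[0]) % L
    dc = (a[1] - b[1]) % L
    dr = min(dr, L - dr)
    dc = min(dc, L - dc)
    return float(np.hypot(dr, dc))


def save_snapshot(path: str | Path, grid: np.ndarray) -> None:
    """Write a grid as a plain-text matrix (one lattice row per line)."""
    np.savetxt(path, grid, fmt="%d")


def load_snapshot(path: str | Path) -> np.ndarray:
    """Read a grid written by :func:`save_snapshot`."""
    grid = np.loadtxt(path, dtype=np.int8)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ConfigurationError(f"snapshot at {path} is not a square matrix")
    if not np.isin(grid, (PRODUCER, NONPRODUCER)).all():
        raise ConfigurationError(f"snapshot at {path} contains labels outside {{0, 1}}")
    return grid
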