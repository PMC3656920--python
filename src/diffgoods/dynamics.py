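"""Growth laws, event rates, and the exact Gillespie replacement loop.

The population evolves as a spatial Moran process: a dividing cell places
its daughter onto one of its 4 cardinal neighbors.  Same-type replacements
do not change the configuration, so the event set contains exactly the
directed cross-type pairs (divider, target); each event occurs at rate
g(divider)/4, the 1/4 normalizing per-event rates to the per-cell growth
rate.  Waiting times and event identities are sampled with the exact
Doob-Gillespie algorithm: tau ~ Exp(sum of rates), event k with
probability rate_k / total.

Growth laws (rates in units of the basal rate g0):

* competition:   NP: g0 + alpha*c,        P: g0 - kappa + alpha*c
* neutral:       both types g0 (production and cost forced to zero)
* mutualism:     both types g0 - kappa + alpha*c_other, where c_other is
  the field produced by the complementary type
* competition_saturating: benefit alpha*c*k_s/(k_s + c) instead of alpha*c

The resource field is restored to the exact steady state after every
replacement (incrementally, by kernel superposition, for the linear
models; by a fresh nonlinear solve for the saturating variant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .lattice import (
    NONPRODUCER,
    PRODUCER,
    ConfigurationError,
    InitialCondition,
    make_grid,
    neighbor_indices,
)
from .resource import (
    ResourceParams,
    single_source_kernel,
    steady_state_field,
    steady_state_field_saturating,
    update_field_incremental,
)

VARIANTS = ("competition", "neutral", "mutualism", "competition_saturating")


@dataclass(frozen=True)
class GrowthParams:
    """Growth-law parameters.

    g0
        Basal growth rate; the unit of time is 1/g0.
    kappa
        Production cost, ``0 <= kappa <= g0`` so producer growth is
        non-negative at zero resource.  Defaults to g0 (the largest
        admissible cost, the regime where coexistence would be easiest
        to detect).
    alpha
        Benefit per unit resource concentration.
    """

    alpha: float = 0.0
    kappa: float | None = None
    g0: float = 1.0
    variant: str = "competition"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.g0 <= 0:
            raise ConfigurationError("g0 must be positive")
        if self.kappa is None:
            object.__setattr__(self, "kappa", 0.0 if self.variant == "neutral" else self.g0)
        if not 0.0 <= self.kappa <= self.g0:
            raise ConfigurationError("kappa must satisfy 0 <= kappa <= g0")
        if self.alpha < 0:
            raise ConfigurationError("alpha must be >= 0")
        if self.variant == "neutral" and (self.kappa != 0.0 or self.alpha != 0.0):
            raise ConfigurationError("the neutral variant requires kappa = alpha = 0")


def growth_rate(cell_type, c, params: GrowthParams):
    """Per-cell growth rate of the competition model (linear benefit)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("resource concentration must be non-negative")
    cost = np.where(np.asarray(cell_type) == PRODUCER, params.kappa, 0.0)
    return params.g0 - cost + params.alpha * c


def growth_rate_mutualism(cell_type, c_other, params: GrowthParams):
    """Growth rate when the benefit comes from the complementary type's resource."""
    c_other = np.asarray(c_other, dtype=float)
    if np.any(c_other < 0):
        raise ValueError("resource concentration must be non-negative")
    return params.g0 - params.kappa + params.alpha * c_other


def growth_rate_saturating(cell_type, c, params: GrowthParams, k_s: float):
    """Competition growth with Michaelis-Menten benefit alpha*c*k_s/(k_s+c)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("resource concentration must be non-negative")
    cost = np.where(np.asarray(cell_type) == PRODUCER, params.kappa, 0.0)
    if np.isinf(k_s):
        benefit = params.alpha * c
    else:
        benefit = params.alpha * c * k_s / (k_s + c)
    return params.g0 - cost + benefit


@dataclass
class EventTable:
    """Admissible directed replacement events and their rates.

    ``dividers`` and ``targets`` are flat site indices; ``rates`` are the
    per-event rates g(divider)/4.  ``total_rate`` is zero iff the grid is
    uniform.
    """

    dividers: np.ndarray
    targets: np.ndarray
    rates: np.ndarray
    total_rate: float


@dataclass
class FixationResult:
    """Outcome of a run: the absorbing type (if absorbed) and when."""

    winner: int | None
    fixation_time: float
    event_count: int
    absorbed: bool


class Simulation:
    """Stateful spatial Moran process with resource coupling.

    Holds the grid, the steady-state field(s), the simulation clock, and
    an explicit RNG; the whole trajectory is reproducible bit-for-bit
    from (initial grid, parameters, seed).
    """

    def __init__(
        self,
        grid: np.ndarray,
        growth: GrowthParams,
        resource: ResourceParams | None = None,
        rng: np.random.Generator | int | None = None,
        include_noop_clock: bool = False,
    ) -> None:
        """If *include_noop_clock* is set, the waiting-time clock sums the
        full growth rate of every boundary cell (counting same-type,
        no-op replacements); the default clock counts cross-type events
        only.  The choice rescales time but leaves the sequence of
        configurations untouched, since no-ops change nothing.
        """
        grid = np.asarray(grid, dtype=np.int8)
        if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
            raise ConfigurationError("grid must be a square 2D array")
        self.grid = grid.copy()
        self.growth = growth
        self.L = grid.shape[0]
        self.n = self.L * self.L
        self.nbr = neighbor_indices(self.L)
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.include_noop_clock = include_noop_clock
        self.time = 0.0
        self.event_count = 0
        self.n_producers = int((self.grid == PRODUCER).sum())

        if growth.variant == "neutral":
            self.resource = None
            self.kernel = None
            self.field = None
            self.field_b = None
        else:
            if resource is None:
                raise ConfigurationError(f"variant {growth.variant!r} requires resource parameters")
            if growth.variant == "competition_saturating" and not resource.saturating:
                raise ConfigurationError("competition_saturating requires finite k_s")
            self.resource = resource
            if growth.variant == "competition_saturating":
                self.kernel = None
                self.field = steady_state_field_saturating(self.grid, resource)
                self.field_b = None
            else:
                self.kernel = single_source_kernel(self.L, resource)
                self.field = steady_state_field(self.grid, resource)
                if growth.variant == "mutualism":
                    # complementary resource, produced by the type-0 cells
                    self.field_b = steady_state_field(
                        np.asarray(self.grid == NONPRODUCER, dtype=np.int8), resource
                    )
                else:
                    self.field_b = None

    # ------------------------------------------------------------------ rates

    def growth_rates(self) -> np.ndarray:
        """Flat array of per-cell growth rates for the current state."""
        g = self.growth
        flat = self.grid.ravel()
        if g.variant == "neutral":
            return np.full(self.n, g.g0)
        if g.variant == "competition":
            return growth_rate(flat, self.field.ravel(), g)
        if g.variant == "competition_saturating":
            return growth_rate_saturating(flat, self.field.ravel(), g, self.resource.k_s)
        # mutualism: type 1 cells benefit from the type-0 field and vice versa
        c_other = np.where(flat == PRODUCER, self.field_b.ravel(), self.field.ravel())
        return growth_rate_mutualism(flat, c_other, g)

    def event_table(self) -> EventTable:
        flat = self.grid.ravel()
        diff = flat[self.nbr] != flat[None, :]
        d, t = np.nonzero(diff)
        dividers = self.nbr[d, t]
        rates = self.growth_rates()[dividers] * 0.25
        return EventTable(dividers, t, rates, float(rates.sum()))

    # ------------------------------------------------------------------- step

    def _sample(self, rates_flat: np.ndarray, total: float) -> int:
        """Index into *rates_flat* chosen with probability rate/total."""
        cum = np.cumsum(rates_flat)
        u = self.rng.random() * cum[-1]
        k = int(np.searchsorted(cum, u, side="right"))
        return min(k, rates_flat.size - 1)

    def step(self) -> tuple[int, int, float] | None:
        """One Gillespie step: returns (divider, target, tau) or None if absorbed.

        The waiting time tau is drawn from Exp(total_rate) and added to the
        clock *before* the replacement is applied, so ``self.time`` is the
        time at which the returned event occurs.
        """
        flat = self.grid.ravel()
        diff = flat[self.nbr] != flat[None, :]
        if not diff.any():
            return None
        if self.growth.variant == "neutral":
            # all rates equal g0/4: uniform choice among events
            d, t = np.nonzero(diff)
            total = d.size * self.growth.g0 * 0.25
            k = int(self.rng.integers(d.size))
            divider, target = int(self.nbr[d[k], t[k]]), int(t[k])
            if self.include_noop_clock:
                total = diff.any(axis=0).sum() * self.growth.g0
        else:
            g = self.growth_rates()
            rates = np.where(diff, g[self.nbr] * 0.25, 0.0).ravel()
            total = float(rates.sum())
            k = self._sample(rates, total)
            divider, target = int(self.nbr[k // self.n, k % self.n]), int(k % self.n)
            if self.include_noop_clock:
                total = float(g[diff.any(axis=0)].sum())
        tau = self.rng.exponential(1.0 / total)
        self.time += tau
        self._apply(divider, target)
        return divider, target, tau

    def _apply(self, divider: int, target: int) -> None:
        new_type = self.grid.ravel()[divider]
        old_type = self.grid.ravel()[target]
        if new_type == old_type:
            raise ValueError("stale event: divider and target have the same type")
        self.grid.ravel()[target] = new_type
        self.n_producers += 1 if new_type == PRODUCER else -1
        self.event_count += 1
        site = (target // self.L, target % self.L)
        v = self.growth.variant
        if v == "competition":
            update_field_incremental(self.field, site, new_type == PRODUCER, self.kernel)
        elif v == "mutualism":
            update_field_incremental(self.field, site, new_type == PRODUCER, self.kernel)
            update_field_incremental(self.field_b, site, new_type == NONPRODUCER, self.kernel)
        elif v == "competition_saturating":
            self.field = steady_state_field_saturating(self.grid, self.resource)

    def refresh_fields(self) -> None:
        """Re-solve the field(s) from scratch (bounds round-off drift in long runs)."""
        if self.growth.variant in ("competition", "mutualism"):
            self.field = steady_state_field(self.grid, self.resource)
        if self.growth.variant == "mutualism":
            self.field_b = steady_state_field(
                np.asarray(self.grid == NONPRODUCER, dtype=np.int8), self.resource
            )

    # ------------------------------------------------------------------- runs

    @property
    def absorbed(self) -> bool:
        return self.n_producers in (0, self.n)

    @property
    def np_fraction(self) -> float:
        return 1.0 - self.n_producers / self.n

    def run_until_fixation(
        self,
        max_events: int | None = None,
        record_stride: int | None = None,
        max_time: float | None = None,
        refresh_every: int = 100_000,
    ) -> tuple[FixationResult, "np.recarray"]:
        """Iterate build/sample/apply until absorption (or a cap).

        Returns the outcome plus a trajectory recarray with fields
        (event_index, time, np_fraction, divider_type) sampled every
        *record_stride* events (default L^2) and at the final state.
        ``max_time`` stops the run once the clock passes a horizon (the
        run is then reported unabsorbed unless the grid is uniform).
        """
        if max_events is None:
            max_events = 50 * self.n * self.n
        if record_stride is None:
            record_stride = self.n
        rec: list[tuple[int, float, float, int]] = [
            (self.event_count, self.time, self.np_fraction, -1)
        ]
        while not self.absorbed and self.event_count < max_events:
            if max_time is not None and self.time >= max_time:
                break
            out = self.step()
            if out is None:
                break
            divider, _, _ = out
            if self.event_count % record_stride == 0:
                rec.append(
                    (self.event_count, self.time, self.np_fraction,
                     int(self.grid.ravel()[divider]))
                )
            if refresh_every and self.event_count % refresh_every == 0:
                self.refresh_fields()
        if rec[-1][0] != self.event_count:
            rec.append((self.event_count, self.time, self.np_fraction, -1))
        traj = np.rec.fromrecords(
            rec, names=["event_index", "time", "np_fraction", "divider_type"]
        )
        winner = None
        if self.absorbed:
            winner = PRODUCER if self.n_producers == self.n else NONPRODUCER
        result = FixationResult(
            winner=winner,
            fixation_time=self.time,
            event_count=self.event_count,
            absorbed=self.absorbed,
        )
        return result, traj

    def iter_events(self, max_events: int) -> Iterator[tuple[int, int, float]]:
        """Yield (divider, target, tau) until absorption or *max_events*."""
        while not self.absorbed and self.event_count < max_events:
            out = self.step()
            if out is None:
                return
            yield out


def simulate(
    L: int,
    growth: GrowthParams,
    resource: ResourceParams | None = None,
    init: InitialCondition | None = None,
    seed: int | np.random.Generator | None = None,
    **run_kwargs,
) -> tuple[FixationResult, np.recarray]:
    """Convenience wrapper: build a grid, run to fixation, return the outcome."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if init is None:
        init = InitialCondition("mixed_50_50")
    grid = make_grid(L, init, rng)
    sim = Simulation(grid, growth, resource, rng)
    return sim.run_until_fixation(**run_kwargs)
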