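"""Scripted experiments: phase diagram, critical benefit, size scaling,
time series, and the mutualism positive control.

Every experiment is deterministic given (configuration, seed): each
repetition draws its own child generator from a single seeded
``SeedSequence``, so runs are independent and reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import FixationResult, GrowthParams, Simulation
from .lattice import (
    NONPRODUCER,
    PRODUCER,
    ConfigurationError,
    InitialCondition,
    boundary_mask,
    make_grid,
    save_snapshot,
)
from .observables import (
    BiasCurve,
    RDFCurve,
    bias_vs_fraction,
    fixation_statistics,
    radial_distribution,
    selection_bias,
    wilson_interval,
)
from .resource import ResourceParams

log = logging.getLogger("diffgoods")

#: Balanced benefit coefficient at diffusion length 10: one unit of resource
#: speeds growth 49-fold over basal, and with mean concentration ~1/2 at
#: 50-50 the mean boundary growth is ~25x the neutral clock.
BALANCED_ALPHA_LAMBDA10 = 49.0

#: Balanced benefit at diffusion length 10 on the reduced 16x16 lattice, from
#: this package's critical-benefit bisection (fixation probability 0.5 from a
#: 50-50 mixed start; bracket [212.5, 237.5]).  The balance point moves with
#: system size because periodic wrap flattens the field once lam ~ L/2.
BALANCED_ALPHA_LAMBDA10_L16 = 225.0


def _child_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _one_run(
    L: int,
    growth: GrowthParams,
    resource: ResourceParams | None,
    init: InitialCondition,
    rng: np.random.Generator,
    **run_kwargs,
) -> tuple[FixationResult, np.recarray, Simulation]:
    grid = make_grid(L, init, rng)
    sim = Simulation(grid, growth, resource, rng)
    res, traj = sim.run_until_fixation(**run_kwargs)
    return res, traj, sim


def fixation_probability(
    L: int,
    growth: GrowthParams,
    resource: ResourceParams | None,
    init: InitialCondition,
    reps: int,
    seed: int | None,
    target: int = PRODUCER,
    **run_kwargs,
):
    """Fixation probability of *target* over *reps* independent runs."""
    results = []
    for rng in _child_rngs(seed, reps):
        res, _, _ = _one_run(L, growth, resource, init, rng,
                             record_stride=10 ** 9, **run_kwargs)
        if not res.absorbed:
            raise RuntimeError("run hit max_events before absorption; raise the cap")
        results.append(res)
    return fixation_statistics(results, target)


# ------------------------------------------------------------ phase diagram


def phase_diagram(
    lams,
    alphas,
    L: int = 32,
    reps: int = 20,
    seed: int | None = None,
    kappa: float | None = None,
) -> pd.DataFrame:
    """Producer-fixation probability on a (lambda, alpha) grid.

    Each cell runs *reps* competitions from a 50-50 random initial
    condition to fixation.  Returns a tidy frame with Wilson 95% CIs.
    """
    rows = []
    for i, lam in enumerate(lams):
        for j, alpha in enumerate(alphas):
            growth = GrowthParams(alpha=alpha, kappa=kappa, variant="competition")
            res = fixation_probability(
                L, growth, ResourceParams(lam=lam), InitialCondition("mixed_50_50"),
                reps, None if seed is None else seed + 7919 * i + 104729 * j,
                target=PRODUCER,
            )
            log.info("phase point lam=%g alpha=%g: P fixes %d/%d", lam, alpha,
                     res.n_wins, res.n_runs)
            rows.append(dict(lam=lam, alpha=alpha, p_fix=res.probability,
                             ci_low=res.ci_low, ci_high=res.ci_high, reps=res.n_runs))
    return pd.DataFrame(rows)


# ----------------------------------------------------------- critical alpha


@dataclass
class CriticalAlphaResult:
    alpha_star: float
    bracket: tuple[float, float]
    probes: pd.DataFrame
    converged: bool


class BracketError(RuntimeError):
    """Raised when fixation probability sits on one side at both bracket ends."""


def critical_alpha(
    lam: float,
    L: int = 32,
    reps_per_probe: int = 50,
    tol: float = 0.1,
    seed: int | None = None,
    bracket: tuple[float, float] | None = None,
    max_probes: int = 12,
) -> CriticalAlphaResult:
    """Bisect for the benefit alpha* at which producer fixation is 50-50.

    Producer fixation probability (mixed 50-50 init, kappa = g0) is
    monotone non-decreasing in alpha, so bisection applies.  A probe moves
    the bracket only when its Wilson 95% CI excludes 0.5; a probe whose CI
    straddles 0.5 is accepted as balanced once the bracket is narrower
    than *tol* (relative), and bisection continues on the midpoint
    otherwise.
    """
    if bracket is None:
        bracket = (0.0, max(4.0 * lam * lam, 8.0))
    lo, hi = bracket
    probes = []
    rngseed = np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31)

    def probe(alpha: float, k: int) -> tuple[float, float, float]:
        growth = GrowthParams(alpha=alpha, variant="competition")
        res = fixation_probability(
            L, growth, ResourceParams(lam=lam), InitialCondition("mixed_50_50"),
            reps_per_probe, int(rngseed) + 611953 * k, target=PRODUCER,
        )
        log.info("critical-alpha probe alpha=%.4g: p=%.3f [%.3f, %.3f]",
                 alpha, res.probability, res.ci_low, res.ci_high)
        probes.append(dict(alpha=alpha, p_fix=res.probability,
                           ci_low=res.ci_low, ci_high=res.ci_high, reps=res.n_runs))
        return res.probability, res.ci_low, res.ci_high

    _, lo_cl, lo_ch = probe(lo, 0)
    if lo_cl > 0.5:
        raise BracketError(f"producers already favored at alpha={lo}")
    _, hi_cl, hi_ch = probe(hi, 1)
    if hi_ch < 0.5:
        raise BracketError(f"producers still disfavored at alpha={hi}")
    mid = 0.5 * (lo + hi)
    converged = False
    for k in range(2, max_probes + 2):
        mid = 0.5 * (lo + hi)
        _, cl, ch = probe(mid, k)
        if cl > 0.5:
            hi = mid
        elif ch < 0.5:
            lo = mid
        elif (hi - lo) <= tol * max(mid, 1.0):
            converged = True
            break
        else:
            # ambiguous probe mid-bracket: shrink toward the midpoint anyway
            lo, hi = 0.5 * (lo + mid), 0.5 * (mid + hi)
        if (hi - lo) <= tol * max(0.5 * (lo + hi), 1.0):
            converged = True
            mid = 0.5 * (lo + hi)
            break
    return CriticalAlphaResult(mid, (lo, hi), pd.DataFrame(probes), converged)


def grids_at_fraction(
    growth: GrowthParams,
    resource: ResourceParams | None,
    L: int,
    thresholds,
    reps: int,
    seed: int | None = None,
    init: InitialCondition | None = None,
) -> dict[float, list[np.ndarray]]:
    """Configurations captured at the first crossing of given NP fractions.

    Runs *reps* simulations to fixation from *init* (default 50-50 mixed)
    and snapshots the grid the first time the NP fraction reaches each
    threshold (from either side).  Used to compare spatial structure of
    different models at matched composition.
    """
    init = init or InitialCondition("mixed_50_50")
    out: dict[float, list[np.ndarray]] = {float(t): [] for t in thresholds}
    for rng in _child_rngs(seed, reps):
        grid = make_grid(L, init, rng)
        sim = Simulation(grid, growth, resource, rng)
        prev = sim.np_fraction
        seen = set()
        while not sim.absorbed and len(seen) < len(out):
            if sim.step() is None:
                break
            f = sim.np_fraction
            for t in out:
                if t not in seen and (prev < t <= f or f <= t < prev):
                    out[t].append(sim.grid.copy())
                    seen.add(t)
            prev = f
    return out


# ------------------------------------------------------------- size scaling


def size_scaling(
    growth: GrowthParams,
    resource: ResourceParams | None,
    Ls,
    reps: int,
    seed: int | None = None,
    invader_type: int = NONPRODUCER,
) -> pd.DataFrame:
    """Invader fixation probability and conditional time vs. linear size L."""
    rows = []
    for i, L in enumerate(Ls):
        init = InitialCondition("single_invader", invader_type=invader_type)
        res = fixation_probability(
            L, growth, resource, init, reps,
            None if seed is None else seed + 15485863 * i, target=invader_type,
        )
        log.info("size L=%d: invader fixes %d/%d", L, res.n_wins, res.n_runs)
        rows.append(dict(L=L, p_fix=res.probability, ci_low=res.ci_low,
                         ci_high=res.ci_high, reps=res.n_runs,
                         mean_fixation_time=res.mean_conditional_time,
                         neutral_expectation=1.0 / (L * L)))
    return pd.DataFrame(rows)


# -------------------------------------------------------------- time series


def time_series(
    L: int,
    growth: GrowthParams,
    resource: ResourceParams | None,
    init: InitialCondition,
    seed: int | None,
    out_dir,
    snapshot_stride: int = 0,
    max_events: int | None = None,
) -> tuple[FixationResult, pd.DataFrame]:
    """Single run writing periodic snapshots, boundary masks, and a trajectory CSV."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    grid = make_grid(L, init, rng)
    sim = Simulation(grid, growth, resource, rng)
    stride = snapshot_stride or sim.n
    rows = []

    def snap() -> None:
        tag = f"ev{sim.event_count:08d}_t{sim.time:.6f}"
        save_snapshot(out / f"snapshot_{tag}.txt", sim.grid)
        np.savetxt(out / f"boundary_{tag}.txt",
                   boundary_mask(sim.grid, sim.nbr).astype(np.int8), fmt="%d")

    snap()
    cap = max_events if max_events is not None else 50 * sim.n * sim.n
    while not sim.absorbed and sim.event_count < cap:
        out_step = sim.step()
        if out_step is None:
            break
        divider, _, _ = out_step
        rows.append(dict(event_index=sim.event_count, time=sim.time,
                         np_fraction=sim.np_fraction,
                         divider_type=int(sim.grid.ravel()[divider])))
        if sim.event_count % stride == 0:
            snap()
    snap()
    traj = pd.DataFrame(rows, columns=["event_index", "time", "np_fraction", "divider_type"])
    traj.to_csv(out / "trajectory.csv", index=False)
    winner = None
    if sim.absorbed:
        winner = PRODUCER if sim.n_producers == sim.n else NONPRODUCER
    return (FixationResult(winner, sim.time, sim.event_count, sim.absorbed), traj)


# ---------------------------------------------------------------- mutualism


@dataclass
class MutualismResult:
    survival_fraction: float
    n_runs: int
    horizon: float
    neutral_mean_absorption_time: float
    neutral_absorbed_before_horizon: float
    rdf: RDFCurve


def neutral_absorption_time(L: int, reps: int, seed: int | None,
                            init: InitialCondition | None = None) -> float:
    """Mean absorption time of the neutral model from a 50-50 mixed start."""
    init = init or InitialCondition("mixed_50_50")
    times = []
    for rng in _child_rngs(seed, reps):
        res, _, _ = _one_run(L, GrowthParams(variant="neutral"), None, init, rng,
                             record_stride=10 ** 9)
        times.append(res.fixation_time)
    return float(np.mean(times))


def mutualism_experiment(
    lam: float = 4.0,
    alpha: float = 1.0,
    L: int = 16,
    reps: int = 20,
    seed: int | None = None,
    horizon_factor: float = 10.0,
    init: InitialCondition | None = None,
    neutral_reps: int | None = None,
) -> MutualismResult:
    """Coexistence positive control.

    Measures the neutral mean absorption time at the same L, then runs the
    mutualism model to ``horizon_factor`` times that horizon; a run
    "survives" if both types are still present at the horizon.  Returns
    the survival fraction, the fraction of neutral controls absorbed
    before the horizon, and the pooled steady-state RDF of the surviving
    final configurations.

    With the symmetric cost kappa = g0 the growth law reduces to
    g = alpha * c_other, so alpha rescales the clock but leaves the
    embedded configuration chain unchanged; the default alpha = 1 makes
    mutualistic boundary growth comparable to the basal rate, so the
    neutral-horizon comparison is like-for-like in time.
    """
    init = init or InitialCondition("segregated_halves")
    neutral_reps = neutral_reps or reps
    t_neutral = neutral_absorption_time(L, neutral_reps, seed)
    horizon = horizon_factor * t_neutral
    growth = GrowthParams(alpha=alpha, variant="mutualism")
    resource = ResourceParams(lam=lam)
    survived = 0
    finals = []
    seq = np.random.SeedSequence(seed).spawn(2 * reps + neutral_reps)
    for s in seq[:reps]:
        rng = np.random.default_rng(s)
        grid = make_grid(L, init, rng)
        sim = Simulation(grid, growth, resource, rng)
        sim.run_until_fixation(max_time=horizon, max_events=10 ** 9, record_stride=10 ** 9)
        if not sim.absorbed:
            survived += 1
            finals.append(sim.grid.copy())
    n_absorbed_early = 0
    for s in seq[reps: reps + neutral_reps]:
        rng = np.random.default_rng(s)
        grid = make_grid(L, init, rng)
        sim = Simulation(grid, GrowthParams(variant="neutral"), None, rng)
        sim.run_until_fixation(max_time=horizon, max_events=10 ** 9, record_stride=10 ** 9)
        if sim.absorbed and sim.time <= horizon:
            n_absorbed_early += 1
    rdf = radial_distribution(finals, PRODUCER) if finals else RDFCurve(
        np.array([]), np.array([]), np.array([]))
    log.info("mutualism: %d/%d survived to horizon %.3g; neutral absorbed %d/%d",
             survived, reps, horizon, n_absorbed_early, neutral_reps)
    return MutualismResult(survived / reps, reps, horizon, t_neutral,
                           n_absorbed_early / neutral_reps, rdf)
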