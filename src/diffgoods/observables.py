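"""Measurement layer: selection bias, radial distribution function,
decay-length fits, and fixation statistics.

Selection bias is the probability that the next replacement event is a
nonproducer replacing a producer; 0.5 means the drift is unbiased.  The
radial distribution function (RDF) around a reference type is the mean
fraction of same-type cells at minimal-image Euclidean distance r from a
reference cell, pooled over all reference cells of all supplied
configurations (which weights each configuration by its reference-cell
count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .dynamics import EventTable, FixationResult, GrowthParams, Simulation
from .lattice import NONPRODUCER, PRODUCER, InitialCondition, make_grid


class UniformGridError(ValueError):
    """Raised when an observable is undefined on a single-type grid."""


class FitError(RuntimeError):
    """Raised when a decay fit has no usable positive excess."""


def selection_bias(table: EventTable, grid: np.ndarray) -> float:
    """P(next event is NP replacing P), from the current event table."""
    if table.total_rate <= 0.0 or table.dividers.size == 0:
        raise UniformGridError("selection bias is undefined on a uniform grid")
    flat = grid.ravel()
    np_replaces_p = (flat[table.dividers] == NONPRODUCER) & (flat[table.targets] == PRODUCER)
    return float(table.rates[np_replaces_p].sum() / table.total_rate)


# --------------------------------------------------------------------- RDF


@dataclass
class RDFCurve:
    """Radial distribution function on integer-width distance bins.

    ``fraction[i]`` is the mean fraction of reference-type cells among all
    cells at minimal-image distance ~ ``r[i]`` from a reference cell;
    ``n_obs[i]`` counts the pooled (center, offset) observations.
    """

    r: np.ndarray
    fraction: np.ndarray
    n_obs: np.ndarray


def _offset_bins(L: int, binning: str) -> tuple[np.ndarray, np.ndarray]:
    """Distance-bin index of every lattice offset (0 = excluded).

    ``binning="integer"``: width-1 bins centered at 1..L/2 (matches the
    lattice granularity at large r).  ``binning="exact"``: one bin per
    distinct minimal-image distance <= L/2 (resolves r=1 vs r=sqrt(2)).
    Returns (bin index per offset, bin-center distances).
    """
    idx = np.arange(L)
    d = np.minimum(idx, L - idx)
    r = np.sqrt(d[:, None].astype(float) ** 2 + d[None, :] ** 2)
    if binning == "integer":
        centers = np.arange(1.0, L // 2 + 1)
        bins = np.rint(r).astype(int)
        bins[(bins < 1) | (bins > L // 2) | (r > L / 2)] = 0
    elif binning == "exact":
        r2 = (d[:, None] ** 2 + d[None, :] ** 2).astype(int)
        ok = (r2 > 0) & (r <= L / 2)
        uniq = np.unique(r2[ok])
        centers = np.sqrt(uniq.astype(float))
        lookup = {v: i + 1 for i, v in enumerate(uniq.tolist())}
        bins = np.where(ok, np.vectorize(lambda v: lookup.get(v, 0))(r2), 0)
    else:
        raise ValueError(f"unknown binning {binning!r}")
    bins[0, 0] = 0  # the center cell is excluded
    return bins, centers


def radial_distribution(
    grids: Iterable[np.ndarray],
    reference_type: int = NONPRODUCER,
    binning: str = "integer",
) -> RDFCurve:
    """Pooled RDF of *reference_type* over one or more configurations.

    Pair counts per lattice offset are obtained from the FFT
    autocorrelation of the type-indicator field, then pooled into
    integer-centered distance bins of width one cell length covering
    (0, L/2].  Pooling all centers across configurations weights each
    configuration by its number of reference cells.
    """
    pair_sum = center_sum = None
    bins = centers = None
    for grid in grids:
        L = grid.shape[0]
        if bins is None:
            bins, centers = _offset_bins(L, binning)
            nbins = centers.size
            pair_sum = np.zeros(nbins + 1)
            center_sum = np.zeros(nbins + 1)
            counts = np.bincount(bins.ravel(), minlength=nbins + 1).astype(float)
        elif grid.shape[0] != bins.shape[0]:
            raise ValueError("all grids must share the same L")
        ind = (grid == reference_type).astype(float)
        n_ref = ind.sum()
        if n_ref == 0:
            continue
        f = np.fft.fft2(ind)
        corr = np.fft.ifft2(f * np.conj(f)).real  # pairs of reference cells per offset
        pair_sum += np.bincount(bins.ravel(), weights=corr.ravel(), minlength=nbins + 1)
        center_sum += n_ref * counts
    if center_sum is None or center_sum[1:].sum() == 0:
        return RDFCurve(np.array([]), np.array([]), np.array([]))
    with np.errstate(invalid="ignore"):
        frac = pair_sum[1:] / center_sum[1:]
    return RDFCurve(centers.astype(float), frac, center_sum[1:])


# --------------------------------------------------------------- decay fits


def fit_exponential_decay(
    r: np.ndarray,
    values: np.ndarray,
    r_min: float,
    r_max: float,
    plateau: float | None = None,
    kind: str = "exponential",
) -> float:
    """Decay length of a radially decaying profile over [r_min, r_max].

    With ``kind="exponential"`` fits log(values - plateau) ~ -r/ell by
    least squares and returns ell; the plateau defaults to the mean of the
    outermost quartile of bins.  ``kind="bessel2d"`` fits
    log(sqrt(r) * (values - plateau)) instead — the large-r asymptotics of
    the 2D screened-diffusion point-source kernel, c(r) ~ K0(r/lam) ~
    exp(-r/lam)/sqrt(r) — which is the consistent estimator of the
    screening length lam for such kernels.
    """
    r = np.asarray(r, dtype=float)
    values = np.asarray(values, dtype=float)
    if kind not in ("exponential", "bessel2d"):
        raise ValueError(f"unknown fit kind {kind!r}")
    if plateau is None:
        outer = r >= np.quantile(r, 0.75)
        plateau = float(values[outer].mean())
    window = (r >= r_min) & (r <= r_max)
    excess = values[window] - plateau
    ok = excess > 0
    if ok.sum() < 3:
        raise FitError("need >= 3 bins with positive excess over the plateau")
    x = r[window][ok]
    y = np.log(excess[ok])
    if kind == "bessel2d":
        y = y + 0.5 * np.log(x)
    slope = np.polyfit(x, y, 1)[0]
    if slope >= 0:
        raise FitError("profile does not decay over the requested window")
    return -1.0 / slope


# -------------------------------------------------------- fixation statistics


@dataclass
class FixationSummary:
    probability: float
    ci_low: float
    ci_high: float
    n_runs: int
    n_wins: int
    mean_conditional_time: float | None


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Wilson score 95% CI for a binomial proportion."""
    if n == 0:
        return 0.0, 1.0
    phat = k / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def fixation_statistics(results: Sequence[FixationResult], target: int) -> FixationSummary:
    """Fixation probability of *target* with Wilson 95% CI and the mean
    fixation time conditioned on *target* winning.

    Unabsorbed results are an error: silently dropping them would bias the
    estimate toward fast outcomes.
    """
    if any(not res.absorbed for res in results):
        raise ValueError("fixation_statistics requires all runs to be absorbed")
    n = len(results)
    wins = [res for res in results if res.winner == target]
    k = len(wins)
    lo, hi = wilson_interval(k, n)
    mean_t = float(np.mean([w.fixation_time for w in wins])) if k else None
    return FixationSummary(k / n if n else 0.0, lo, hi, n, k, mean_t)


# ------------------------------------------------------------- bias curves


@dataclass
class BiasCurve:
    """Selection bias pooled by population NP fraction."""

    np_fraction: np.ndarray
    bias: np.ndarray
    n_obs: np.ndarray


def bias_vs_fraction(
    sims: Iterable[Simulation],
    max_events: int | None = None,
    n_display_bins: int = 50,
) -> BiasCurve:
    """Run each simulation to absorption, recording the selection bias of
    every visited configuration against its NP fraction.

    Bias observations are accumulated on fine bins of width 1/L^2 and
    aggregated to about *n_display_bins* for output; pooling across runs
    weights each fraction bin by its event count.
    """
    fine_sum = fine_n = None
    n_fine = None
    for sim in sims:
        if fine_sum is None:
            n_fine = sim.n + 1
            fine_sum = np.zeros(n_fine)
            fine_n = np.zeros(n_fine)
        cap = max_events if max_events is not None else 50 * sim.n * sim.n
        while not sim.absorbed and sim.event_count < cap:
            table = sim.event_table()
            if table.total_rate <= 0:
                break
            b = selection_bias(table, sim.grid)
            i = round(sim.np_fraction * sim.n)
            fine_sum[i] += b
            fine_n[i] += 1
            sim.step()
    if fine_sum is None:
        return BiasCurve(np.array([]), np.array([]), np.array([]))
    group = max(1, n_fine // n_display_bins)
    edges = np.arange(0, n_fine + group, group)
    frac, bias, nobs = [], [], []
    for a, b_ in zip(edges[:-1], edges[1:]):
        n_in = fine_n[a:b_].sum()
        if n_in == 0:
            continue
        centers = np.arange(a, min(b_, n_fine)) / (n_fine - 1)
        w = fine_n[a:b_]
        frac.append(float((centers * w).sum() / n_in))
        bias.append(float(fine_sum[a:b_].sum() / n_in))
        nobs.append(float(n_in))
    return BiasCurve(np.array(frac), np.array(bias), np.array(nobs))


def save_curve_csv(path, curve, xname: str) -> None:
    """Write an RDFCurve or BiasCurve as CSV (x, value, n_obs)."""
    if isinstance(curve, RDFCurve):
        cols = (curve.r, curve.fraction, curve.n_obs)
        yname = "fraction"
    else:
        cols = (curve.np_fraction, curve.bias, curve.n_obs)
        yname = "bias"
    with open(path, "w") as fh:
        fh.write(f"{xname},{yname},n_obs\n")
        for row in zip(*cols):
            fh.write(f"{row[0]:.10g},{row[1]:.10g},{row[2]:.10g}\n")
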