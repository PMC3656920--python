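# Methods

## The model

`diffgoods` simulates competition between resource **producers** (P) and
**nonproducers** (NP) on a fully occupied L×L square lattice with periodic
boundaries. Two processes are coupled:

1. **A spatial Moran process.** Every site holds exactly one cell. When a
   cell divides, its daughter replaces one of the four cardinal neighbors.
   Same-type replacements do not change the configuration, so the event set
   is the set of directed cross-type adjacent pairs (divider → target); a
   divider with growth rate g initiates each of its cross-type events at
   rate g/4 (the 1/4 converts a per-cell division rate into per-neighbor
   event rates). Waiting times and event identities are sampled exactly
   (Doob–Gillespie): τ ~ Exp(Σ rates), event k with probability
   rate_k / Σ rates. Only boundary cells — cells with at least one
   differing cardinal neighbor — carry events, so interior cells play no
   dynamical role.

2. **A screened-diffusion resource field.** Each producer sources a
   diffusible resource at flux p; the resource diffuses with constant D
   (5-point discrete Laplacian, lattice spacing = 1 cell length) and is
   consumed at first-order rate γ by every (always-occupied) site:

       p·1_producer + D ∇²c − γ c = 0.

   Because cell division is orders of magnitude slower than diffusion, the
   field is assumed to relax instantly: after every replacement event the
   growth rates see the exact steady state of the current configuration.
   The single remaining length scale is the diffusion length λ = √(D/γ),
   the screening length of the field around one producer.

Growth laws (time unit 1/g0):

| variant | producer / type A | nonproducer / type B |
|---|---|---|
| competition | g0 − κ + α·c | g0 + α·c |
| neutral | g0 | g0 |
| mutualism | g0 − κ + α·c_B | g0 − κ + α·c_A |
| competition_saturating | g0 − κ + α·c·K_s/(K_s+c) | g0 + α·c·K_s/(K_s+c) |

The benefit enters additively. A multiplicative form (g0 − κ)(1 + αc)
with the standard maximal cost κ = g0 would pin producer growth at zero
for every concentration, contradicting producer dominance at short λ and
high benefit; the additive form also reproduces the reference arithmetic
(α = 49 with one unit of resource gives a 50× growth rate, i.e. a 49-fold
speed-up over basal; at a 50-50 composition mean c = p/(2γ) = 1/2 by flux
balance, so boundary cells grow ≈ 25× the neutral clock — both quantities
are recomputed by `scripts/acceptance.py` and the test suite).

In the mutualism variant each type secretes its own resource and benefits
only from the resource of the *other* type; with the symmetric maximal
cost κ = g0 the law reduces to g = α·c_other, which makes the embedded
configuration chain independent of α (α only rescales the clock).

## Parameters and defaults

| symbol | meaning | default | why |
|---|---|---|---|
| g0 | basal growth rate (time⁻¹) | 1 | unit of time |
| κ | production cost (time⁻¹) | g0 | largest admissible cost — growth at c=0 stays non-negative; the regime where coexistence would be easiest to detect |
| α | benefit per unit concentration (time⁻¹ per resource unit) | experiment-specific | the swept axis of the phase diagram |
| p | production flux per producer | 1 | sets the resource unit |
| γ | consumption/decay rate (time⁻¹) | 1 | absorbed into λ |
| λ | diffusion length √(D/γ) (cell lengths) | 10 (competition), 4 (mutualism) | "long" relative to a cell; mutualism λ chosen < L/2 so kin domains fit the control lattice |
| K_s | Michaelis–Menten half-saturation (resource units) | ∞ (linear) | finite only in the saturating variant |

Neutrality is obtained by forcing p = κ = α = 0: every directed boundary
event then has rate g0/4 and the selection bias (probability that the next
event is NP replacing P) is exactly 0.5 on any mixed configuration, since
each undirected boundary edge contributes one NP→P and one P→NP event of
equal rate.

## Solvers and numerical choices

* **Linear steady state.** The screened-Poisson operator on the torus is
  translation invariant, so it is diagonalized exactly by the 2D FFT:
  ĉ(k) = p·ŝ(k) / (γ + D·ω(k)) with ω(k) = 4 − 2cos k_x − 2cos k_y.
  One O(L² log L) solve yields both the single-source kernel and the field
  of an arbitrary producer set. A unit test cross-checks the spectral
  solution against an assembled sparse-LU solve to 1e−10 relative
  max-norm, and flux balance Σγc = p·(#producers) holds to 1e−10.
* **Per-event updates.** By linearity, flipping one site adds or subtracts
  the kernel translated to that site — an O(L²) update whose drift after
  10³ events stays below 1e−9 of the field maximum (tested); long runs
  re-solve from scratch every 10⁵ events as a safety net.
* **Saturating uptake.** With finite K_s the consumption term becomes
  γ·c·K_s/(K_s+c). The solver moves the saturation deficit to the source
  side and iterates damped fixed-point re-solves (damping 0.5, default
  residual tolerance 1e−10, max 10 000 iterations), raising a solver error
  with the final residual if the uptake capacity γ·K_s·L² cannot absorb
  the production flux. In the K_s → ∞ limit it matches the linear solver;
  at small K_s the field is verifiably more homogeneous. The saturation
  was placed in the uptake (with the matching Michaelis–Menten benefit in
  the growth law) — both stated limits hold, and saturating uptake only
  flattens gradients further, reinforcing the main conclusion.
* **Decay-length fits.** The steady field around a point source on a 2D
  torus is the screened-Poisson Green's function ~ K₀(r/λ) ∝ e^{−r/λ}/√r
  at r ≫ 1. A plain log-linear fit over r ∈ [2λ, 4λ] therefore
  *underestimates* λ by roughly λ/(2r̄) (≈ 14% at λ=10): the consistent
  estimator of the screening length fits log(c·√r) against r
  (`fit_exponential_decay(..., kind="bessel2d")`), which recovers λ=10 to
  ~1% on a 256×256 torus. The plain exponential fit remains the default
  and is appropriate for RDF tails, which are empirically exponential.
* **RDF binning.** Distances use the minimal-image convention. Default
  bins are width-1 annuli centered at integer r (matching lattice
  granularity); `binning="exact"` resolves every distinct lattice distance
  (e.g. r=1 vs r=√2), which matters for checkerboard-scale structure.
  Pooling all reference centers across configurations weights each
  configuration by its reference-cell count.
* **Tie-breaks and degenerate inputs.** Uniform grids have an empty event
  table (total rate 0) and are reported as immediately absorbed;
  selection bias on a uniform grid raises an explicit error rather than
  returning a number. On odd L² the 50-50 initial condition gives the
  extra cell to the nonproducer.
* **Reproducibility.** One `numpy` Generator per simulation; experiments
  spawn independent child generators from a single `SeedSequence`, so
  every experiment is bit-for-bit reproducible from (config, seed).

## The critical benefit and the balance point

For fixed λ there is a critical benefit α*(λ, L) at which producer and
nonproducer fixation are equally likely from a 50-50 random start;
`critical_alpha` locates it by bisection, moving the bracket only when a
probe's Wilson 95% CI excludes 0.5. Two structural facts matter when
comparing scales:

* α* grows with λ, steeply once λ approaches L/2, because diffusion (and,
  at that scale, periodic wrap) flattens the field and shrinks the
  producer–nonproducer concentration gap Δc at the boundary that selection
  acts on (at random 50-50 configurations: Δc ≈ 0.026 at λ=4/L=32 but
  ≈ 0.0048 at λ=10/L=32, and smaller still at L=16). Bisections run with
  this package (reproducible via ``diffgoods critical-alpha``) give
  α*(λ=4, L=32) = 34.4 (bracket 31.25–37.5) and
  α*(λ=10, L=32) = 175 (bracket 162.5–187.5).
* the balanced benefit therefore depends on the lattice size once λ ~ L/2:
  on the reduced 16×16 lattice at λ=10 the package's bisection gives
  α* = 225 (bracket [212.5, 237.5]), frozen as
  `BALANCED_ALPHA_LAMBDA10_L16` and used by the reduced-scale neutrality
  tests. The canonical 49-fold anchor (`BALANCED_ALPHA_LAMBDA10`) balances
  cost against benefit at boundary gaps of ~1/49, which in this
  parameterization corresponds to diffusion lengths just under 5 cell
  lengths at L=32 rather than 10; its role in this package is the clock
  arithmetic (the 25× boundary speed-up), which holds at any λ because
  flux balance pins the mean concentration.

At the measured balance point the headline negative result holds exactly
as stated: the selection-bias curve is flat at 0.5 across NP fractions,
and RDFs at matched 25% and 75% NP fractions are indistinguishable from
the neutral model's within pooled sampling error — no balancing
selection, hence no coexistence, emerges from the shared resource.

## What the experiments show (and at what scale)

Test-suite problem sizes are chosen so the full suite runs on one CPU in
minutes: neutral 1/N fixation uses L ∈ {3, 4} with 50 000 runs each
(estimates within 3 SE of 1/9 and 1/16); the neutrality property suite
runs at L=16 with ~100 captured configurations per composition; the
mutualism control runs 20 runs at L=16 to 10× the measured neutral
absorption horizon (survival ≥ 95% of runs required, with the neutral
control absorbing and the mutualism RDF decaying from kin correlation at
r=1 to the 0.5 plateau by r≈6). The 32×32 phase diagram and full-scale
critical-benefit searches are available through the CLI but take hours,
not minutes.

## What the synthetic dynamics do and do not emulate

The simulator *is* the model: a two-type, fully occupied lattice with
instantaneous field relaxation. It does not represent vacancies, cell
death, mutation, motility, population expansion, multiple resources
beyond the symmetric two-field mutualism, resource transients, or
off-lattice geometry. Conclusions about real microbial consortia
therefore inherit the model's assumptions — in particular the timescale
separation between diffusion and division, and competition restricted to
domain boundaries in a saturated population.

## Known limitations

* The saturating variant re-solves the nonlinear field after every event
  (no incremental update exists for a nonlinear operator), so it is
  ~100× slower per event and practical only for small lattices.
* `critical_alpha` assumes producer fixation probability is monotone in
  α at fixed λ; probes near the balance point need many repetitions
  because the CI-based stopping rule is sequential.
* Fixation-time comparisons across variants use the Gillespie clock in
  units of 1/g0; variants with different mean growth rates run their
  configuration chains at different speeds, so times should be compared
  only after the documented clock-rate normalization (e.g. the ~25×
  factor at the balanced benefit).
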