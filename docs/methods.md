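# Methods

## The model class

`ssan` simulates well-stirred chemical reaction networks whose discrete state
`X(t)` (molecule counts of `N` species) evolves by `M` reaction channels.  A
reaction `R_j` carries a stoichiometric change vector `nu_j` and a propensity
`a_j(x)`: the probability of one firing in `[t, t+dt)` is `a_j(x) dt`.  With
constant propensities this is the classical jump Markov process sampled
exactly by the Gillespie direct method.

The package's core extends this to *doubly stochastic* systems: each
propensity may be modulated by a bounded, colored extrinsic-noise factor,

    a_j(x, t) = g_j(t) * a_j(x),        g_j = 1 + zeta_c(t),

where `zeta_c` is the value of the noise channel bound to the reaction
(several reactions may share one channel) and `|zeta| <= B <= 1`, so the
perturbation has unit mean and the propensity stays nonnegative.  The firing
process of each reaction is then an inhomogeneous Poisson process whose
intensity is itself random — a Cox process.  Generalized (non-mass-action)
reactions may instead depend on the whole noise vector nonlinearly; this is
how the noisy Michaelis-Menten reduction and the toggle switch's repressed
synthesis are expressed.

## Bounded noise

The default channel is the Sine-Wiener process

    zeta(t) = B sin( sqrt(2/tau) W(t) ),

with `W` a standard Wiener process.  It is bounded by construction, has zero
mean, variance `(B^2/2)(1 - e^{-4t/tau})`, autocorrelation time `tau`, and an
arcsine stationary marginal `1/(pi sqrt(B^2 - x^2))` on `(-B, B)` — the
bounded-sine image of a wide Gaussian phase.  The implementation samples the
Wiener driver exactly on a grid of spacing `h` (the *noise granularity*) and
applies the sine transform pointwise, so the marginal law at the grid nodes
carries no discretization bias; between nodes, values are interpolated
linearly.  `h` must be much smaller than `tau`; the package enforces
`h <= tau/10` and defaults to `tau/100`.

Generic channels integrate a user-supplied Langevin equation
`dxi = mu(xi, x) dt + sigma(xi, x) dW` by Euler-Maruyama on the same grid;
drift and diffusion may read the (frozen) molecule counts, which covers
extrinsic noises that are not fully independent of the chemical state.  A
deterministic sinusoidal "channel" `zeta = eps sin(2 pi t / T_p)` expresses
periodically perturbed rates through the same interface.

Randomness is organized as one jump-decision stream plus one independent
sub-stream per channel, all spawned from the run seed, and channel
increments are consumed in fixed-size blocks.  Consequently (i) a noise
realization is bitwise reproducible from `(seed, h)` regardless of how
lazily it is queried, and (ii) the noise realization of a run does not
change when the event density changes.

## Exact simulation with time-varying propensities

Between jumps the counts are frozen, so each reaction's cumulative hazard
over a candidate waiting time is

    Lambda_j(tau) = Integral_t^{t+tau} g_j(t') dt' * a_j(x)

(and the analogous integral of the full nonlinear propensity for generalized
reactions).  The next jump time solves `sum_j Lambda_j(tau) = ln(1/r1)` with
`r1 ~ U(0,1)`.  The integrand is known at the noise-grid nodes and treated
as piecewise linear (consistent with the interpolation of the noise itself),
so the solver marches segment by segment, accumulating trapezoids, and
solves the bracketing segment in closed form — a quadratic in the offset,
with the linear-integrand special cases handled explicitly.  No iterative
root refinement is needed beyond this; the `root_tolerance` configuration
knob exists for degenerate-case checks.  Generalized propensities may
declare discontinuity times (`time_breakpoints`); integration segments are
split there and the integrand is evaluated one-sided (times nudged into the
open segment), so step-function rates integrate exactly — this is what makes
the piecewise-constant hazard inversion exact to machine precision rather
than `O(h)`.

The firing reaction is selected with probability proportional to the
perturbed propensities evaluated at the solved firing instant.  If the total
propensity is exactly zero there (possible only when a maximum-intensity
noise crosses `g = 0` precisely at the root), the engine re-evaluates one
tick later and otherwise raises.  The noise state is never reset at jumps:
channels are external, continuing processes.  With every channel disabled
the whole machinery reduces algebraically to the direct method (closed-form
exponential waiting times), which is also the fast path taken.

Counts are recorded right-continuously on the output grid (the value after
an event at the event time); noise values on the grid are interpolated from
the retained realization after the run.

## Stochastic quasi-steady-state reduction

The enzyme-substrate-product motif `E+S -> C` (k1), `C -> E+S` (k-1),
`C -> E+P` (k2) reduces to the single reaction `S -> P` with rate
`k2 E_tot S / (K_M + S)`, `K_M = (k-1 + k2)/k1`, when the complex is in
quasi-steady state.  Validity is assessed by the Segel–Slemrod separation
ratio `E_tot / (S0 + K_M)` with a configurable threshold (default 0.05).
With bounded noises on the rate constants both the Michaelis constant and
the catalytic factor become time dependent:

    K_M(t) = (k-1 g_{-1} + k2 g_2) / (k1 g_1),
    v(t)   = k2 g_2 E_tot S / (K_M(t) + S),

which the engine treats as one generalized reaction with direct access to
the noise vector.  The time-dependent validity condition is checked a priori
and conservatively: the worst case of the ratio over the noise box
`|zeta_j| <= B_j` by interval arithmetic (the supremum is governed by the
infimum of `K_M`), rather than along realizations — realization-independent
and strict.  `B = 1` on the binding-rate channel makes `K_M` unbounded above
and the check fails conservatively.  A zero crossing of the binding factor
at maximum intensity returns `K_M = +inf`, driving the reduced propensity to
zero rather than erroring.

## Case-study fixtures and their default parameters

All numeric parameters below are the package's own choices, selected once so
that each network sits clearly inside the qualitative regime it is meant to
exhibit, and kept fixed; the model *structures* are the standard published
motifs.

**Enzyme kinetics.**  Condition A (`k1=0.01, k-1=1, k2=1, E_tot=10,
S0=1000`; `K_M=200`) has separation ratio `10/1200 ~ 0.0083`, deep inside
validity; condition B (`k1=1, k-1=5, k2=5, E_tot=100, S0=100`; `K_M=10`)
has ratio `~0.91`.  Horizons: 300 time units for A (full substrate
conversion takes ~240), 3 for B.  The fast pre-steady-state transient of A
is `1/(k1 (S0+K_M)) ~ 0.08` time units; comparisons "past the transient"
start at 5% of the horizon.

**Futile cycle.**  Two opposing enzyme arms `S <-> S*` with single enzyme
copies and a 100-copy substrate pool.  The arms are deliberately asymmetric:
the forward enzyme is saturated (`K_M,f = 4.5`), the backward enzyme is
binding-limited (`K_M,b ~ 43`) with twice the catalytic capacity, so the
backward flux is roughly proportional to its binding rate.  Noise-free, the
flux balance holds `S*` in a narrow unimodal band near 43.  A Sine-Wiener
factor (`B = 0.9`, `tau = 100` — slow against the cycle's ~15-time-unit
relaxation) on the backward binding moves the balance point to `~43/g`:
because the stationary law of `g` concentrates at `0.1` and `1.9`, the state
parks either at a sharp low level (~23) or — when `g` is too small to carry
the forward flux at all — at near-complete conversion, producing the
noise-induced bimodal transition.  The `with_F` variant instead sequesters
the backward enzyme with a slowly fluctuating species F (mean 10 copies,
~60-unit relaxation), the purely intrinsic route to the same phenomenon.
Ensemble densities are read at `t = 250`.  The regime boundary is
parameter-sensitive; the defaults live in `FUTILE_DEFAULTS` and any entry
can be overridden for scanning.

**Toggle switch.**  Two genes with kinetically equivalent synthesis
(`k_synth = 0.5 /min`, modulated by the shared perturbation `w(t)`),
translation `1 /min` per mRNA, and first-order degradation (10-minute mRNA
and protein lifetimes).  Repression uses the all-sites-free probability
`p_free = (1 + K_a P_other)^(-m)` with `m = 2` sites and `K_a = 0.25`; these
two numbers are modeling assumptions, surfaced as configuration.  The
unrepressed state is ~5 mRNA / ~50 protein copies, and a winning protein
represses its competitor ~180-fold, so the switch is strongly bistable over
the simulated hours.  The initial condition gives gene b a 3-mRNA head
start.  In periodic mode `w = 1 + eps sin(2 pi t/T_p)` (default `eps = 0.5`,
`T_p = 60` min); in bounded-noise mode `w = 1 + zeta` with matched amplitude
and timescale.  The noise-speed scan uses `tau` in {30, 15, 7.5, 3.75} min
at `B = 0.9`: noise slower than the ~10-minute protein lifetime opens
windows in which the repressed gene escapes (the perturbation gates both
genes' synthesis, so a long high-`w` window lets the loser accumulate),
while faster noise is low-pass filtered away; the mass of the first peak of
the head-started gene's competitor therefore grows as `tau` shrinks.  That
first peak is the fully repressed state at 0–2 protein copies; quantifying
it uses a fixed basin cut of 2, which isolates it both from the expressed
mode (>= 25 copies) and from expressing cells transiently dipped to ~5
copies by a deep noise excursion.  The adjacent-step differences of this
mass are of the same order as its binomial Monte-Carlo error at practical
ensemble sizes, so monotonicity is asserted statistically: a one-sided
linear-contrast trend test at the 1% level plus the absence of any
significant adjacent inversion.

## Ensembles, densities, modality

Ensembles run with derived seeds `base_seed + i` and are embarrassingly
parallel in contract (results are independent of execution order).
Empirical densities use unit integer bins; the density-vs-time matrix
stacks per-time densities (rows ascending count, columns ascending time).
Mode counting smooths a density with a Gaussian kernel — bandwidth by the
`1.06 sigma n^{-1/5}` rule-of-thumb unless given — and counts local maxima
whose prominence exceeds 5% of the global maximum; boundary peaks count.
The rule-of-thumb is known to oversmooth strongly multimodal data, which is
why the bandwidth is an explicit argument; the mode counts reported for the
case studies are stable under ±25% bandwidth changes.  Periodicity of a
density-vs-time matrix is detected by correlating columns at increasing
lags after removing each count-row's time mean, with parabolic refinement
of the correlation peak.

## What the tests do and do not show

The validation suite checks the simulator against closed-form laws
(exponential/Poisson marginals, hand-inverted hazards, the Sine-Wiener
moment and stationary laws), checks algebraic degenerations (noise-free
SSAn vs. SSA), verifies exact conservation laws, and reproduces the three
case studies' qualitative phenomenology at the documented repo-chosen
parameters.  Statistical assertions use explicit levels (chi-square and KS
at 1%, moment checks at 4 standard errors, Monte-Carlo-error-aware
monotonicity for the noise-speed scan).  Passing them shows the *simulator*
is exact and the *phenomena* are reproduced in the stated regimes; it does
not calibrate any fixture against experimental data, and the fixtures'
numeric rates are illustrative, not measured.

Problem sizes used by the default test run and by `scripts/acceptance.py`
(ensemble counts between 120 and 10,000 runs per check, horizons between 1
and 480 time units, down-scaled model instances for the engine-equivalence
check) are the package's choices for routine validation on a single CPU;
all of them can be raised freely in user code.

## Known limitations

- The hazard integration is exact for piecewise-linear integrands only;
  smooth nonlinear noise dependence incurs `O(h^2)` quadrature error per
  segment, controlled by the granularity `h`.
- Channels with very small `tau` (hence small `h`) make the grid marching
  the dominant cost; no tau-leaping or hybrid acceleration is provided.
- `langevin_generic` channels are not bounded unless the user's drift and
  diffusion make them so; bound checking applies only to the bounded kinds.
- The worst-case noisy validity check is conservative: it can reject
  parameter sets whose realized trajectories would in fact track well.
- Mode counting on heavily skewed densities is sensitive to the smoothing
  bandwidth; use the explicit-bandwidth argument and the stability band
  when in doubt.
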