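# Methods

## The cell

Each cell is a dimensionless two-variable relaxation oscillator with a fast
membrane potential `V` and a slow recovery current `W`:

    tau_m dV/dt = -I_fast(V) - W + I_el + I_in
        dW/dt = (W_inf(V) - W) / tau_w(V)

with, writing `u = (V - v_mid)/v_scale` for the cell's normalized voltage
and `s(x) = 1/(1+e^x)`,

    I_fast(V) = g_fast * fast_shape * (u^3/3 - u)
    W_inf(V)  = w_floor + g_slow * s(-(u - theta_slow)/k_slow)
    tau_w(V)  = tau_w_max + (tau_w_min - tau_w_max) * s(-(u - theta_tw)/k_tw)

The fast current is N-shaped, so the V-nullcline `W = -I_fast(V) + I` is a
cubic with two knees at `V = v_mid -+ v_scale`, `W = -+ (2/3) g_fast *
fast_shape`; because the applied current enters additively, any current
offset shifts the whole nullcline (and both knees) vertically by exactly
that amount — the property all the phase-plane diagnostics rest on.  The
slow current activates sigmoidally with depolarization and relaxes with a
voltage-dependent time constant: fast (`tau_w_min = 5`) in the active phase,
slow (`tau_w_max = 50`) in the silent phase.

Two features produce the short duty cycle that the multiphase repertoire depends on:
the 10:1 ratio of the slow time constants, and the position of the silent
asymptote `w_floor` a small distance `delta = |w_floor| - (2/3) g_fast *
fast_shape = 0.025` *below* the left knee.  The silent-phase `W` decays
toward `w_floor` and crawls more and more slowly as it approaches the knee,
stretching the silent phase to ~190 time units while the active phase lasts
~3.5, i.e. a duty cycle of 1.8 %.

### Parameters

Anchored constants (identical for all cells): `g_fast = 2`, `g_slow = 2`,
`tau_w_min = 5`, `tau_w_max = 50`, `k_tw = 0.2`, `theta_tw = 0.16`.  The
gating sigmoids act on the normalized voltage `u`; the model is
dimensionless and these constants live in the cell's own voltage unit,
while gap-junction, stimulus and noise currents act on physical `V`.

Package shape constants (this package's model definition; defaults in
`CellParams` and `gapring/defaults.yaml`):

| constant     | default | role |
|--------------|---------|------|
| `fast_shape` | 0.3     | amplitude of the cubic; knee height 0.4 |
| `v_mid`      | 0.0     | centre of the N-shaped region |
| `v_scale`    | 0.28    | half-width of the cubic in physical V; converts between the cell's internal voltage unit and the scale on which coupling currents act |
| `theta_slow` | 0.16    | slow-activation midpoint (u units) |
| `k_slow`     | 0.1     | slow-activation steepness (u units) |
| `w_floor`    | -0.425  | silent asymptote of `W_inf`; sets the duty cycle |
| `tau_m`      | 0.3     | membrane time constant; sets jump speed and the finite-time protection of deflected cells |

`v_scale`, `w_floor` and `tau_m` were calibrated once, jointly, against the
two quantitative behaviours the model must exhibit: a free-cell duty cycle
of 1–2 %, and collapse of the fully coupled 24-cell anti-phase pattern
between `g_el = 0.22` and `0.23` on the 0.01 grid.  With those fixed, the
ring-vs-all-to-all boundary spread (0.38 vs 0.23 at sigma = 0.002), the
1/3 and 1/4 phase shifts, the ordered within-group firing at low
connectivity and the asymmetric 22/2 pattern all follow without further
adjustment.

## Coupling, noise, stimuli

Gap junctions are ohmic: `I_el(i) = (g_el / N_cc) * sum_j (V_j - V_i)` over
the neighbours of `i`.  Connectivity is a ring in which each cell couples to
its `N_cc/2` nearest neighbours per side; `N_cc = N-1` adds the antipodal
connection so the graph is complete; a chain uses the same windows without
wrap-around (edge cells keep `g_el/N_cc` per synapse and hence a weaker
total — a documented choice switchable with `chain_renormalize`).  The
per-cell total conductance is `g_el` for every connectivity, so sweeps over
`N_cc` compare topologies at fixed total electrical load.

Noise is a piecewise-constant current: an independent `N(0, sigma^2)` value
per cell, redrawn every 0.2 time units and held in between
(`sigma ∈ {0.002, 0.01, 0.02}`).  Stimuli are current pulses of amplitude
±1 lasting 0.2 time units, optionally repeated back-to-back ("successive
attempts"); the switching recipe pulses group `m` (positively, with the
complement pulsed negatively) at time `t0 + m T/k`, which forces the groups
to fire `T/k` apart.  This recipe is one concrete choice among many
spatial/temporal stimulus profiles that can split synchrony; it is recorded
in every trajectory's metadata.

## Integration

The production solver is a fixed-step RK4 advancing an integer number of
steps inside each 0.2-unit hold interval, so the piecewise-constant input is
honoured exactly and runs are bit-reproducible given (seed, config).  The
step is `h = 0.1`: with `tau_m = 0.3` and the calibrated cubic the fastest
local relaxation rate reaches ~20–25 per time unit at the trajectory's
outer reaches, so RK4 is stable at `h = 0.1` but not at `h = 0.2`
(the 0.2-unit clock survives as the noise hold interval, with two solver
steps per hold).  An adaptive
Runge–Kutta(4,5) (`rtol = 1e-6`) integrating hold-by-hold serves as the
reference; the free-cell period agrees to < 0.01 % and pattern
classification agrees across a spot-check grid (enforced in the test
suite).  The hot loop is compiled with numba.

## Protocol and classification

Patterns are produced the way the stability domains are defined: establish
at weak coupling (IP by symmetric initialisation; multiphase states either
by the pulse recipe or by placing groups at staggered phases of the free
cycle), then raise `g_el` one 0.01 step at a time with a ~2-period settle at
each value.  This continuation matters: near its existence boundary the
anti-phase state is reachable only from an adjacent anti-phase state, not
from a cold start.

The classifier detects active-phase onsets/offsets as threshold crossings at
the inter-knee midpoint (`V = v_mid`) with a 0.5-time-unit debounce,
computes per-cell circular mean onset phases against the reference cell over
≥ 3 cycles, and clusters them by single linkage on the circle with gap
tolerance `tol_phase = 0.02` cycles (so the ordered but contiguous
within-group lags at low `N_cc` chain into one group, while groups a
sizeable fraction of a cycle apart never merge).  Runs whose phases drift
more than `tol_phase` per cycle are labelled transitional.  "Stable under
noise" means: after 250 time units of noise plus noise-free settling, the
label (phase count and cell partition, group numbering ignored) is unchanged;
at `sigma > 0` each grid point takes the majority verdict over 3 noise seeds.
Classification windows cover ≥ 4 reference cycles; slow-converging states
(the 22/2 asymmetric split, the 6-phase pattern whose coupled period is about
twice the free one) get 30–40-period transients before classification.

## Phase-plane diagnostics

DTK (distance to knee) is measured at the instants the active group's mean
`W` crosses zero rising: each silent cell's instantaneous gap current
defines a shifted nullcline whose left knee sits at `-knee_W + I_el`, and
DTK is the cell's `W` minus that knee `W` — a vertical distance, chosen
because jump-up is triggered by `W` relative to the knee (a Euclidean
variant is available behind a flag).  Records are averaged over ≥ 3 cycles.
Two caveats are inherent to the quasi-static reading: the gap current is
frozen at the sampled instant, and a cell slightly *below* the shifted knee
can still survive because escaping through the fold takes time of order
`tau_m`; the minimal DTK therefore crosses a little below zero within a grid
step or two of the collapse boundary instead of stopping exactly at zero.
DTK is used as a trend indicator — it shrinks toward zero approaching every
boundary and rank-correlates positively with the remaining `Delta g_el` —
not as an exact existence criterion.

The maximal-phase-count bound is the inequality on the silent-phase budget:
`k` phases require `T/k - dt > dt`, i.e. `k < T/(2 dt)` strictly.
`max_phases` evaluates it; shortening `tau_w_min` to 2 (the one parameter
the 6-phase setup varies) roughly halves the duty cycle to 0.9 % and the
ring at `g_el = 0.08` then sustains six distinct phase clusters.  In this
model the six groups keep the compressed spacing they were seeded with
(about 1/12 of the coupled cycle between successive groups, with one long
gap) rather than relaxing to uniform 1/6 spacing; the claim checked is six
distinct stationary clusters, not uniformity.

## What the simulations do and do not establish

All results are desk-scale simulations of the stated conditions (N = 24 or
60 cells, runs of a few hundred time units, 0.01 conductance grids, 3 noise
seeds); boundaries are quoted ±0.01, the grid resolution, and the classifier
is one concrete operationalization of "same pattern", so boundary values
carry its phase tolerance on top of the grid step.  The generator *is* the model: passing tests show the
implemented dynamical system behaves as described, not that any biological
network does.

Known limitations (the non-anchored functional forms and shape constants are
this package's own choices; different choices within the same constraints
could move the boundaries below):

- The symmetric 4-phase pattern occupies a narrow coupling range
  (`g_el ≈ 0.01–0.09`) at every connectivity; its confinement to
  `N_cc < 14` at the lowest noise level does not emerge here (it appears
  only at `sigma = 0.02`).
- A nearest-neighbour chain behaves almost exactly like the ring, so the
  chain-vs-complete robustness increase comes out near 70 % rather than
  about 50 %.
- With the printed synaptic constants the reciprocal-excitation pair shows
  the up-shifted nullcline and right-sided deflection, but its saturated
  drive exceeds this calibration's knee margin, so that comparison pair
  synchronizes instead of sustaining anti-phase.
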