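# gapring

Multistable phase-locking in networks of electrically coupled relaxation
oscillators.

Developing neural circuits often consist of oscillating cells connected by
nothing but gap junctions.  Electrical coupling is usually thought of as a
synchronizing force, yet a ring of relaxation oscillators with a short duty
cycle supports a whole family of stable activity patterns that *coexist*
with synchrony: anti-phase locking, 3-, 4- and (at shorter duty cycles)
6-phase patterns, and asymmetric two-group rhythms.  `gapring` is a tested
simulator and analysis toolkit for exploring this multistability: it builds
ring / chain / all-to-all networks, switches them between coexisting
patterns with brief current pulses, tests pattern robustness against frozen
current noise, maps stability domains over coupling strength and
connectivity, and computes the phase-plane diagnostics (nullclines, knees,
critical deflections, distance-to-knee) that explain why patterns exist and
where they die.

## Model

Each cell is a dimensionless fast–slow oscillator,

    tau_m dV_i/dt = -I_fast(V_i) - W_i + I_el,i + I_in,i
        dW_i/dt = (W_inf(V_i) - W_i) / tau_w(V_i)

with an N-shaped instantaneous current `I_fast` (cubic V-nullcline),
sigmoidal slow activation `W_inf`, and a slow time constant `tau_w(V)` that
interpolates between 5 (depolarized) and 50 (hyperpolarized) through
`s(x) = 1/(1+e^x)` — giving a duty cycle of ~1.8 %.  Cells couple
electrically,

    I_el,i = (g_el / N_cc) * sum_{j in nbr(i)} (V_j - V_i),

where `N_cc` is the number of connected neighbours per cell (2 = pure ring,
N-1 = all-to-all) and the total conductance per cell is `g_el` regardless of
`N_cc`.  See `docs/methods.md` for the full parameterization and the
numerical choices.

## A worked example

Switch a fully coupled 24-cell network out of synchrony with ±1 current
pulses (0.2 time units, delivered to contiguous groups a third of a period
apart), then classify what it settles into:

```python
import numpy as np
from gapring import (CellParams, build_adjacency, partition, identical_init,
                     integrate, switch_pattern, classify_trajectory,
                     free_cycle)

cell = CellParams()
cyc = free_cycle(cell)                       # free-cell limit cycle
net = build_adjacency(24, "complete", 23, g_el=0.12)
part = partition(24, [8, 8, 8])

ip = integrate(net, cell, identical_init(net, cell), (0, 2.2 * cyc["T"]))
traj = switch_pattern(net, cell, ip.final_state(), part, cycle=cyc)
probe = integrate(net, cell, traj.final_state(), (0, 4.6 * cyc["T"]))
label = classify_trajectory(probe)
print(label.n_phases, np.round(label.phi, 3))
```

prints

```
3 [0.332 0.333 0.335]
```

three groups of eight cells firing at phase shifts of 1/3 of the ~200-unit
cycle — a 3-phase pattern that now persists indefinitely without input, and
that coexists with the synchronous state it was switched out of.  The
examples/ directory has one short script per capability (free-cell
geometry, switching, collapse boundaries, DTK diagnostics, asymmetric
groups); each prints the numbers it computes and a line on what they mean.

A thin CLI covers the shell workflows:

```bash
gapring preset-list
gapring simulate --preset fig1b2 --out out/
gapring map --pattern 2 --ncc 2,10,23 --gel 0.05:0.45:0.01
```

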