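# stpnet

Discrete-time excitatory/inhibitory neural networks with dynamic
(short-term plastic) synapses: simulation of the stochastic network, its
macroscopic mean-field map, and the full bifurcation toolchain used to
map the network's oscillatory states and their phase–amplitude
cross-frequency coupling (CFC).

## The model

Two populations of binary neurons — excitatory (E) and inhibitory (I) —
fire stochastically,

```
Prob[s_i(t+1) = 1] = g_β[h_i(t)],      g_β[h] = (1 + tanh(βh)) / 2,
h_i = Σ_{j≠i} J^{ξξ}_{ij} a_j + Σ_j J^{ξη}_{ij} a_j + I^ξ,
```

and every synapse carries a Tsodyks–Markram-style state: a synaptic
current `a` (decay constant τ_a), a releasable-resource fraction `x`
(depression, recovery constant τ_R) and a calcium variable `u`
(facilitation, constant τ_F, baseline release fraction U_se):

```
a(t+1) = a − a/τ_a + s·x·u/U_se
x(t+1) = x + (1−x)/τ_R − s·x·u
u(t+1) = u + (U_se−u)/τ_F + U_se(1−u)·s
```

With uniform all-to-all weights `J/N`, population averaging closes the
dynamics into a deterministic 8-dimensional map for
`Ω = (m0E, m0I, A0E, A0I, X0E, X0I, U0E, U0I)`.  The package provides:

* all three model levels (`stochastic`, `microscopic`, `macroscopic`)
  behind one `simulate()` front end;
* Newton fixed points, the analytic 8×8 Jacobian, and eigenvalue
  stability classification (`fixed_points`);
* Neimark–Sacker bifurcation localisation by bisection, 1-D bifurcation
  diagrams, 2-D phase diagrams and forward/backward hysteresis sweeps
  (`bifurcation`);
* full Lyapunov spectra by QR re-orthonormalisation, with zero-exponent
  counting to tell invariant closed curves (1 zero) from two-tori
  (2 zeros) (`lyapunov`);
* ϵ-slab section slices with ST0/ST1 classification and torus-
  bifurcation signatures (`slice_torus`);
* spectral period estimation and phase–amplitude CFC metrics
  (`oscillation`).

The interesting regimes ship as named presets (`fig3B` … `fig11`): the
slow excitatory oscillation (OSE), the fast inhibitory oscillation
(OSI), and — for the bidirectionally coupled network — the OS1C
(fast-only closed curve), OS2T (slow+fast two-torus, continuous CFC)
and OS2C (slow+fast closed curve, intermittent CFC) states.

## Worked example

```python
import numpy as np
from stpnet import NetworkParams, locate_ns, lyapunov_spectrum, simulate
from stpnet.oscillation import dominant_period, items_per_slow_cycle
from stpnet.presets import get_preset

# Where does the excitatory network start to oscillate?
p = NetworkParams.single("E", J0=2.0, I=-1.0, tau_a=2.5)
print(locate_ns(p, "J_EE", (0.5, 2.5)).value)     # 1.6299967765808105

# Period of the slow oscillation at J0 = 2
traj = simulate("macroscopic", p, n_steps=14_096, transient=10_000)
print(dominant_period(traj.column("m0E")).period)  # 64.0

# The coupled network in its intermittent-CFC state
p11 = get_preset("fig11").params
print(lyapunov_spectrum(p11).zero_count)           # 1  (closed curve)
t = simulate("macroscopic", p11, n_steps=40_000, transient=10_000)
items, _ = items_per_slow_cycle(t.column("m0I"), t.column("m0E"))
print(items)                                       # 10.0
```

The first number is the coupling strength at which a complex eigenvalue
pair of the fixed-point Jacobian crosses the unit circle (a
Neimark–Sacker bifurcation, birth of the slow oscillation); the last is
the mean number of full-amplitude fast cycles the inhibitory population
fits into one slow excitatory cycle — the candidate "number of items"
an intermittent CFC could encode.

The same analyses are scriptable from the shell:

```
stpnet presets
stpnet locate-ns --preset fig6E --param J_EE --bracket 0.5 2.5 --out out/
stpnet lyapunov --preset fig10 --out out/
stpnet slice --preset fig9 --coord A0I --value 1.7 --out out/
stpnet cfc --preset fig11 --out out/
```

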