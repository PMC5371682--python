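# Methods

## Model

The network consists of two populations of `N_ξ` binary neurons,
ξ ∈ {E, I}.  A neuron fires at the next step with probability
`g_β[h] = (1 + tanh(βh))/2` of its synaptic input
`h_i = Σ_{j≠i} J^{ξξ}_{ij} a_j + Σ_j J^{ξη}_{ij} a_j + I^ξ`; the noise
temperature `T = 1/β` sets how sharply the population follows its
input.  Each synapse's transmission is dynamic: the synaptic current
`a` decays with constant `τ_a` and is incremented by `s·x·u/U_se`; the
releasable-resource fraction `x` (depression) is consumed by `s·x·u`
and recovers with `τ_R`; the calcium variable `u` (facilitation) is
pushed up by `U_se(1−u)s` and relaxes to `U_se` with `τ_F`.  The ratio
`τ_R/τ_F` selects depression- (≫1) or facilitation-dominated (≪1)
synapses.  All updates are strictly synchronous: every right-hand side
uses time-t values only, and the spike that drives the synapse update
is the *previous* spike.

Three levels of description are implemented:

* **stochastic** — per-neuron Bernoulli draws (one uniform variate per
  neuron per step, from an explicit seeded `numpy` generator recorded
  in run metadata); the recurrent sum excludes the self term `j = i`.
* **microscopic mean field** — per-neuron noise averages
  `(m_i, A_i, X_i, U_i)` under the factorisation of `⟨s x u⟩` that
  holds when weights are O(1/N); general per-pair weight tables are
  accepted.
* **macroscopic mean field** — with uniform weights `J/N` the
  population averages close into a deterministic 8-D map for
  `Ω = (m0E, m0I, A0E, A0I, X0E, X0I, U0E, U0I)`.  The O(1/N)
  self-term correction is ignored at this level.

Default constants follow the studied regime: `T = 0.8`, `U_se = 0.1`,
`τ_R = 70`, and `τ_F = τ_R / 11.7` exactly (the ratio is the quoted
quantity; we do not round τ_F to 6 — both choices were checked and
shift the single-network bifurcation points by < 0.03 %).

**Initial conditions.**  Unless a state is supplied, runs start from
the synaptic rest point with open-loop activities: `m = g_β[I]`,
`A = 10⁻³` (a small nudge off the exactly invariant `A = 0` subspace),
`X = 1`, `U = U_se`.  States are never clipped: leaving the admissible
region (`m, X, U ∈ [0,1]`, `A ≥ 0`) raises a diagnostic, since for
admissible parameters (`τ ≥ 1`, `U_se ∈ (0,1]`) the map preserves it.

## Fixed points and stability

Stationarity eliminates the synaptic variables:
`Ū = U_se(1+τ_F m)/(1+τ_F U_se m)`, `X̄ = 1/(1+τ_R Ū m)`,
`Ā = τ_a Ū m X̄ / U_se`, giving the composite drive
`D(m) = τ_a m (1+τ_F m) / (1 + (τ_F+τ_R)U_se m + U_se τ_F τ_R m²)`
and a two-equation system in `(m̄_E, m̄_I)`.  This reduced system is
solved by damped Newton (step halving, analytic chain-rule Jacobian,
residual tolerance 10⁻¹², at most 100 iterations) from an 11×11 grid
of starts over (0,1)²; converged roots closer than 10⁻⁶ are merged and
all distinct roots are reported sorted by `m̄_E`.

Stability comes from the analytic 8×8 Jacobian (blocked per
subnetwork, rows m, A, X, U; all cross-subnetwork entries are zero
except the m-row couplings through A).  A fixed point is *stable* when
the leading eigenvalue modulus is below 1 (tolerance 10⁻⁸),
*NS-unstable* when the leading crossing eigenvalue is a complex pair
(the Neimark–Sacker scenario that births the oscillations here), and
*other-unstable* for a real crossing.  For a decoupled system the 4×4
block of the subnetwork of interest is used so the inert partner's
eigenvalues cannot mask the crossing.

Neimark–Sacker points are localised by bisection on (leading modulus −
1), continuing the fixed point across the bracket (bracket tolerance
10⁻⁶ by default); the bisected values are insensitive to halving the
initial bracket to within that tolerance.

## Sweeps and attractor taxonomy

One- and two-parameter sweeps are continuation runs: each grid point
warm-starts from the previous attractor (10⁴-step transient, 4096
analysis steps — the spectral window).  Single networks are labelled
SS (stable fixed point), OSE (oscillation with recurrent gain J₀ > 0)
or OSI (J₀ < 0); the single-network phase diagrams are evaluated as
one vectorised batch over all grid cells.  Coupled-network cells are
labelled by two features: the presence of a slow spectral component in
`m0E` (period above 20 steps), and the number of zero Lyapunov
exponents — OS1C (fast only), OS2T (slow+fast, 2 zeros: two-torus),
OS2C (slow+fast, 1 zero: closed curve), with ambiguous exponent
patterns flagged indeterminate rather than guessed.

**Hysteresis sweeps** run both directions with warm starts.  The
declared hysteresis interval is based on the slow-component amplitude
(max − min of `m0E` over the window), which jumps discontinuously
between coexisting branches; exponent counts blur exactly at a torus
bifurcation, where the contracting pair sits inside any finite zero
tolerance, and would otherwise produce spurious single-point
disagreements.

## Lyapunov spectra

The full 8-exponent spectrum uses the standard Jacobian-product QR
method along the post-transient orbit (re-orthonormalisation every
step by default; the spectrum is stable to within 2×10⁻⁴ under
doubling the iteration count or stretching the interval to 5).
Defaults: 10⁵ iterations after a 10⁴-step transient; the zero
tolerance is 10⁻³ nats/step, calibrated so the provably neutral
tangential direction of a quasi-periodic single-network orbit counts
as zero at that length.  An exponent between one and two times the
tolerance raises an ambiguity flag.  The exponent sum is checked
against the orbit average of log|det K| (they agree identically up to
rounding, both being the volume-contraction rate).

## Section slices

A slice collects orbit points within `ϵ` of a coordinate-aligned
hyperplane (for such sections the coordinate offset *is* the Euclidean
distance); `ϵ = 0.001` by default, points collected on the fly from a
scalar fast loop (default target 4000 points, cap 2×10⁶ iterations) —
a closed curve (MT1) leaves isolated clumps (ST0), a two-torus (MT2) a
filling curve (ST1).

Classification is sample-doubling based, comparing a deterministic
random half-sample with the full sample: ST0 requires the
single-linkage cluster count to be identical for both and the maximum
cluster diameter to stay tight (below 10 % of the point-set spread);
ST1 requires the largest nearest-neighbour gap to shrink by at least
the factor 0.8 as the sample doubles (curve filling).  The linkage cut
is 10× the median nearest-neighbour spacing, floored at 10⁻³ of the
spread so densely revisited clumps do not shatter into float-noise
clusters.  Everything else is indeterminate — including, deliberately,
a closed curve winding so densely that its finite crossing set cannot
saturate at a realistic sample size.

**Torus-bifurcation signatures.**  Near a subcritical Neimark–Sacker
bifurcation of the closed curve (MT1NS) the newborn torus section
appears at a finite distance from the old ST0; near a saddle-node
cycle (MT1SNC) the new curve passes through the old curve's location.
The signature is therefore the *closest approach* of the
post-bifurcation set to the pre-bifurcation set, compared against
max(1 % of the post-set's extent, 5× its median fill spacing).  A
Hausdorff-type bulk distance is reported but not used for the verdict:
the two measurements are taken at two different parameter values, and
the resulting O(0.03) drift of the whole attractor would swamp it,
while it cannot fake a close approach.  Around the subcritical side
the pre-bifurcation state must be reached by continuation from deeper
inside its branch (the default initial state lands on the coexisting
torus inside the hysteresis window).

## Oscillation and CFC metrics

The **period** of a time course is `window / bin` of the
lowest-frequency local maximum of its rectangular-window periodogram
(4096 samples, mean removed) whose power reaches 5 % of the spectral
maximum; both the threshold and a largest-peak variant are exposed.
The **slow phase** band-passes ±50 % around the slow spectral peak and
takes the analytic-signal angle.  The **CFC profile** detects fast
peaks (minimum prominence 1 % of the series range), assigns each an
amplitude (peak minus preceding trough), a local period (peak
spacing) and the slow phase at its time, and bins by phase: mode
*none* when the modulation depth is below 10 % of the maximum bin
amplitude, *intermittent* when some bin is suppressed (empty or below
25 % of the maximum bin), *continuous* otherwise.

**Items per slow cycle** counts fast peaks between slow-phase wraps,
excluding suppressed peaks (amplitude below 25 % of the largest — the
same suppression notion as the mode label).  The exclusion matters
only for the intermittent state, where part of each slow cycle carries
residual ripple rather than full fast cycles; counting that ripple
would overstate the candidate item capacity by ~30 %.  For the
continuous (torus) state the count equals the slow/fast period ratio.

## Problem sizes

Defaults were chosen so every analysis runs on one CPU core in seconds
to a couple of minutes: 31×31 grids for the single-network phase
diagrams (vectorised, ~2 s each), 10⁵ Lyapunov iterations (~3 s),
4000-point slices (≲ 10⁷ map iterations, ≲ 15 s), 9-point hysteresis
sweeps with 5×10⁴-iteration spectra (~45 s), stochastic runs with
N = 10⁴ neurons per population.

## Known limitations

* **Closure bias.**  The macroscopic map factorises the population
  mean of `s·x·u` into `m·X·U`.  The per-neuron correlation between a
  neuron's own `x` and `u` histories leaves an N-*independent*
  population covariance (measured relative bias of ⟨xu⟩ against X·U:
  −1 % to −6 % depending on the operating point).  Consequently the
  pointwise deviation between stochastic population averages and the
  macroscopic trajectory floors at that bias (plus phase diffusion on
  oscillatory attractors) instead of contracting like N^(−1/2)
  indefinitely; the agreement is good but not asymptotically exact.
* **Printed inhibitory example.**  At the quoted single-network OSI
  parameter set (J₀, I, τ_a) = (−10, 1, 12.5) this map has a stable
  fixed point (leading modulus 0.985) and no coexisting oscillation;
  the sources are inconsistent about the inhibitory input for that
  example (the coupled-network reference states use I^I = 16, at which
  the isolated inhibitory network oscillates with period 5.77, inside
  the quoted OSI band, as does I = 1 at τ_a = 2.5).  Presets keep each
  quoted set verbatim.
* **Phase-diagram windows.**  The oscillatory-region period extremes
  depend on the (J₀, I) window, which the source figures do not print.
  On the assumed windows (J₀ ∈ (0,6], I ∈ [−2,1] for OSE;
  J₀ ∈ [−15,0), I ∈ [−2,3] for OSI) the slow oscillation keeps slowing
  as I decreases below ≈ −1.2, reaching periods of a few hundred
  steps; restricted to the I = −1 line the OSE period spans
  [34.4, 78.8], matching the quoted band.
* **Near-bifurcation slices.**  Within ≈ 0.5 % of the saddle-node
  cycle point the stable closed curve winds thousands of times around
  the incipient torus; its slice is indistinguishable from an ST1 at
  any practical sample size, so the ST0 verdict there is not
  certifiable geometrically (the covering signature still is).
* Passing tests on the synthetic/preset regimes demonstrate internal
  consistency of the map and its analysis, not biological realism; the
  binary-neuron and uniform-connectivity assumptions are idealisations.
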