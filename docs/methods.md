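# Methods

`corticrit` simulates a layered, columnar model of early visual
processing and ships the complete analysis toolkit used to decide
whether — and where — its flash-evoked activity is critical.  This note
records the model, the estimators, the calibrated defaults and their
rationale, the numerical choices, and what the desk-scale protocols can
and cannot show.

## Model

**Architecture.** Six square sheets: an Input sheet of `(10L)^2`
photoreceptors, four bulk layers of `L x L` neurons each (LGN, and the
V1 layers IVCbeta, II/III and VI), and an Output sheet of `(10L)^2`
axon terminals bound for V2.  Directed projections:
`Input -> LGN` (deterministic 10x10 block map, no synapses),
`LGN -> IVCb`, the interlayer loop `IVCb <-> VI`, the corticothalamic
feedback `VI -> LGN`, `IVCb -> II/III`, and `II/III -> Output` (passive
sink).  Every bulk neuron has 100 dendritic compartments, a soma and 10
axonal compartments.

**Wiring (quenched disorder).** Each presynaptic neuron emits a fixed,
layer-dependent number of synapses (see the table below).  Per synapse:
a postsynaptic neuron is drawn from a rounded isotropic 2-D Gaussian
(per-axis sd 3.3 grid units) truncated to the `l x l` excitatory field
in front of the presynaptic cell (`l = 7`; one column holds
`N_c = 4 l^2 = 196` neurons); draws outside the field or the lattice are
rejected and redrawn, so out-degrees are exact and edge neurons aim
inward.  The axonal compartment is a truncated exponential in the
distance from the axon tip (rate 0.5; most synapses leave the tip); the
dendritic compartment is a rounded Gaussian (mean 50, sd 10) truncated
to 1..100.  Multiple synapses between the same pair are allowed.  The
wiring is frozen for a trial and redrawn between trials; all ensemble
statistics average over this quenched disorder.

**Dynamics.** Discrete time, 1 step ≙ 1 ms.  A delivery of amplitude
`E` (the EPSP, the control parameter, in mV) lands on dendritic
compartment `m` and advances one compartment per step toward the soma,
attenuated by `lambda = 0.996` per hop: it arrives after `m` steps
scaled by `lambda^m`.  A non-refractory soma whose summed arriving
potential reaches `v_T = 10 mV` spikes; the soma holds no memory across
steps, so threshold crossing requires temporally coincident arrivals.
A spike enters axonal compartment 1 on the next step and shifts tipward,
triggering every synapse attached to the compartment it occupies.
After a spike the soma is reset to the refractory value `R`.

**Refractoriness and absorbing dynamics.** `R` exists to stop the
interlayer loops from re-exciting themselves.  Finite values large
enough to block two-leg echoes (`R > 220`) still fail for slow fronts:
regions activated early can be re-excited by echoes of regions activated
hundreds of steps later.  The default therefore sets `R` beyond any
achievable re-excitation interval — each neuron fires at most once per
trial — which makes the dynamics provably absorbing for every `E` and
makes `N_R` (distinct neurons fired) coincide with the summed activity.
`R` is configurable for exploration; trials that hit the `max_steps` cap
are flagged, never silently truncated.

**Stimulus and avalanches.** A trial flashes a 30x30 photoreceptor
square once (snapped to the block grid, so it lights exactly 3x3 LGN
neurons; a corner flash behaves equivalently).  Because dendritic
traversal takes ~50 steps, soma activity `A(t)` arrives in waves
separated by silent stretches; an avalanche is all activity between two
consecutive zeros of `A(t)` and its size `s` is the summed spike count.
The partition conserves total activity exactly.

## Calibrated structural defaults

The per-layer out-degree table is not derivable from first principles;
it is the package's reconstruction, calibrated once against the model's
published landmarks and then frozen:

| projection       | synapses / presynaptic neuron |
|------------------|------|
| LGN -> IVCb      | 890  |
| IVCb -> VI       | 761  |
| VI -> IVCb       | 870  |
| VI -> LGN        | 229  |
| IVCb -> II/III   | 184  |
| II/III -> Output | 382  |

Calibration anchors, in order of priority:

1. **Total synapse count.**  The table sums to 3316 synapses per bulk
   neuron, so the largest simulated lattice (`L = 99`) carries
   32 500 116 ≈ 32.5e6 synapses.
2. **Phase-diagram landmarks.**  The Griffiths region must contain
   `E = 1.15 mV` with the percolation edge near `E ~ 1.2 mV`; the flash
   must ignite the stimulated column from `E ~ 1.05`; `rho -> 1` in the
   percolating phase requires the `VI -> LGN` feedback (without it a
   quarter of the bulk can never fire and `rho` saturates at 0.76).
   These landmarks fix the split between the ignition drive
   (`LGN -> IVCb`), the loop legs and the recruitment projections.

One consequence is accepted deliberately: the measured inward density,
`<n_syn> = 7.335` per dendritic compartment, puts the naive mean-field
threshold at `E_th = 1.66 mV` rather than the full-scale reference value
1.88 mV (which corresponds to `<n_syn> = 6.5`).  With the dynamics as
reconstructed here, no table satisfies both the mean-field anchor and
the phase-diagram landmarks simultaneously; the landmarks won because
every downstream scientific claim (exponents, scaling, correlations) is
dynamical.  The mean-field *formula* and its qualitative property —
`E_th` overestimates the true transition because it assumes perfectly
coincident arrivals — hold regardless.

The excitatory-field sd (3.3, vs. the `l/2 = 3.5` rule of thumb) and the
axonal exponential rate (0.5) were fixed at the same time; the phase
landmarks are mildly sensitive to the former and insensitive to the
latter.

## Estimators

**Order parameter and susceptibility.**  `rho = <N_R/N>` over rewiring
trials; `chi = N var(N_R/N)` with the unbiased (n−1) variance;
`chi_rho = chi / rho`.  Finite-size scaling fits are log–log
regressions over at least three lattice sizes; the Griffiths-phase
detector accepts an `E` when `rho` decays and `chi_rho` grows with `L`
with `R^2 >= 0.9` and a one-sided slope sign test at 95% (two-sided
p-values are halved; with only 3–4 sizes a two-sided test is
needlessly conservative).  Exponent errors use regression standard
errors; bootstrap over trials is available where trial-level data are in
memory.

**Avalanche distributions.**  All fitting is done on the raw
complementary cumulative distribution `F(s) = P(size >= s)`;
logarithmic binning (base 2) is for display only.  The truncated
power-law form `F(s) = c1 s^(1-alpha) + c2` is fitted by nonlinear least
squares with relative (sigma = F) weighting, lower bound `s >= 3` to
skip discreteness, and an upper bound iterated to the running cutoff
estimate.  The cutoff is the root of the fitted curve,
`Z = (-c2/c1)^(1/(1-alpha))`, defined when `c1` and `c2` have opposite
signs; a pure power law (tiny or positive `c2`) is reported as "no
cutoff detected" with `Z = inf`.  `Z ~ L^D` is a log–log regression over
`>= 3` sizes.  Distribution collapse rescales to
`s^(alpha-1) F(s)` vs `s / L^D` and scores the mean pairwise RMS
distance between log-curves on a common log-spaced support.

**Two-range fits.**  In the weakly percolating phase the columnar
structure prints a bump at `s ~ N_c = 196` separating two power-law
ranges.  The lower range is fitted at fixed range `[3, N_c]`.  For the
upper range the dominating-avalanche mode — the single system-spanning
avalanche of each percolated trial, whose size is set by `rho N` rather
than by the power-law background — is excluded (per trial with
`N_R/N > 0.5`, the largest avalanche is dropped, or, in
`fit_two_range`, the fit is capped at the support gap preceding the
pileup), and the support is subsampled log-uniformly so every decade
carries equal weight.

**Maximum-likelihood power-law test.**  Discrete MLE of
`p(s) ∝ s^-alpha` on `[s_min, s_max]` via the Hurwitz-zeta normalizer,
with a Kolmogorov–Smirnov goodness-of-fit p-value from a parametric
bootstrap (default 100 resamples, refitting alpha each time).

**Correlations.**  The avalanche-sequence autocorrelation `C(t')` (lag
in avalanche index) is ensemble-averaged with unbiased per-lag
normalization and fitted by `t'^(-theta) exp(-t'/tau)` on the positive
range; `tau` converts to time steps via the mean inter-avalanche
interval.  The power spectrum embeds each avalanche size at its onset
time on the time-step grid (so frequencies are Hz under 1 ts = 1 ms),
averages trial periodograms on a common log-spaced grid, and fits
`S ~ f^-b` below 100 Hz; an index-domain periodogram is available as an
option.  DFA integrates the mean-removed activity series, detrends
order-1 polynomials in non-overlapping windows log-spaced from 8 to
length/4, and regresses RMS fluctuation on window size.  All three are
validated on synthetic truth: sharply truncated discrete power laws,
AR(1) (tau = −1/ln phi), and circulant-embedding fractional Gaussian
noise (DFA g = H; spectral b = 2H−1; theta + b = 1).

## Numerical and implementation choices

* Two simulator backends advance the identical dynamics: an explicit
  compartment-array reference (readable, used for unit validation) and
  an event-driven compiled engine that schedules, per spike and synapse,
  a soma arrival of `lambda^m` at `t + k + m` in a circular buffer.
  Test-side, whole spike trains are asserted equal between the two.
* Determinism: every ensemble derives one independent wiring seed per
  (grid point, trial) from the master seed via `SeedSequence`; results
  do not depend on execution order, and sweeps resume by skipping
  completed points (partial points are written to a side name and
  renamed atomically).
* Threshold ties: the soma comparison is `arrival >= v_T` in float32
  scaled units (`lambda^m` sums compared against `v_T/E`); exact ties
  are measure-zero and not specially handled.
* Degenerate inputs are errors, not NaNs: empty networks, constant
  series for DFA/autocorrelation, fewer than 3 sizes for scaling fits,
  fewer than 100 in-range samples for the ML test.  `chi_rho` at
  `rho = 0` is NaN and flagged by the Griffiths detector.

## Desk-scale protocols and their limits

The full-scale study (`L = 99`, 100–300 trials per point) is far beyond
an interactive budget; the shipped protocols scale the lattice down and
keep the trial counts (`L = 20` with 300 trials at the Griffiths working
point `E = 1.15`; `L ∈ {10, 20, 40}` for cutoff scaling; `L ∈ {32, 40}`
at `E = 1.88`).  What this shows and what it does not:

* The avalanche exponent at the working point (`alpha ~ 1.4`) and the
  cutoff growth `Z ~ L^D` with `D` near 1 are reproduced, but both
  estimators inherit genuine Griffiths variability: independent
  300-trial ensembles scatter `alpha` by ~0.1, and `D` at these sizes
  measures ~1.2 (the pseudo-critical point drifts upward slightly
  between `L = 10` and `L = 40`, which steepens `Z(L)`).
* At `E = 1.88` the columnar bump at `N_c` and a second, steeper range
  above it are present, but the range spans barely a decade before the
  dominating-avalanche pileup; the measured upper exponent (~3) is a
  desk-scale quantity, not the asymptotic one (~1.7 at `L <= 99`, where
  the range extends as `L^3`).
* Full-scale-only reference values — `beta/nu_perp = 0.55(3)`,
  `gamma/nu_perp = 3.1(2)`, `E_c = 1.19 mV`, `b = 0.97(5)`,
  `tau = 16.2 ts`, `mu = 0.90(1)` — are recorded here for orientation;
  the desk protocols compute the same estimators but at `L <= 40` their
  values are size-limited and are not asserted against these numbers.
* The generator emulates flash-evoked propagation in a noiseless,
  purely excitatory network with uniform synaptic weight; real cortical
  data add background activity, inhibition, weight heterogeneity and
  measurement subsampling, none of which these tests probe.
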