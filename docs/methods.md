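# Methods

## Model

`thalcor` simulates a pair of coupled corticothalamic circuits ("module I"
and "module II"), each consisting of four neural-mass populations: an
excitatory pyramidal population (PY), an inhibitory interneuron population
(IN), the excitatory specific relay nucleus (SRN) and the inhibitory
thalamic reticular nucleus (TRN).  Each population carries one dimensionless
mean membrane potential; the full state is the eight-vector
`(py1, in1, srn1, trn1, py2, in2, srn2, trn2)`.

Within a module the circuit is the classic Taylor-type corticothalamic
loop.  Cortical potentials enter synapses through the steep sigmoid

    Q(x) = 1 / (1 + eps^(-x)),        eps = 250000,

and thalamic potentials through the linear activation

    K(y) = a y + b,                   a = 2.8, b = 0.5.

Each population's equation has the form

    dV/dt = tau * (eps_V - V + [intra-module synaptic drive]) + [cross-module drive]

with per-population rate constants `tau = (26, 32.5, 2.6, 2.6)` in 1/s and
background inputs `eps = (-0.35, -3.4, -2, -5)` for (PY, IN, SRN, TRN).
Note the rate constant **multiplies** the relaxation bracket: the taus are
rates, not time constants.  With the coupling strengths
`h1..h9 = (1.8, 1.5, 1, 4, 3, 0.6, h7, h8, 0.2)` this operating point
produces a 2–4 Hz spike-wave discharge (SWD) over part of the
`(h7, h8) ∈ [1.5, 2.5] × [9, 11]` plane, the model's proxy for absence
seizures.  `h7` (PY→TRN) and `h8` (SRN→TRN) are the two excitatory pathways
onto TRN and are the swept control parameters.

Six long-range projections connect homologous populations of the two
modules at strength `h_i / 6`: PY↔PY (`h1/6`), IN→PY (`h2/6`), PY→IN
(`h4/6`) in the cortex; TRN→SRN (`h6/6`), SRN→TRN (`h8/6`) and TRN→TRN
(`h9/6`) in the thalamus.  Cross-module inputs are added *outside* the
tau-scaled bracket (they act as weak unscaled perturbations; a
`cross_in_tau` switch moves them inside for sensitivity checks).  Cortical
cross terms use `Q`, thalamic cross terms use `K`, mirroring the
intra-module activations.  Three topologies are supported: `bidirectional`
(all six two-way links), `unidirectional` (module I receives, module II
runs autonomously — the analysed module is the downstream one), and
`uncoupled`.

The analysed signal is the module-I cortical mean field
`0.5 (PY1 + IN1)`, a surrogate EEG.

## Integration

Fixed-step classic RK4 with `dt = 0.25 ms`, horizon 30 s; the first 10 s
are discarded from all statistics.  Stimulation currents are evaluated at
the RK4 sub-step times (a 4 ms pulse spans 16 steps; sub-step sampling
keeps pulse edges phase-accurate).  The inner loop is a numba-compiled
kernel vectorised over a batch axis, so an entire parameter grid with all
its ensemble repeats integrates in one pass; the pure-numpy
`thalcor.model.rhs` is the reference implementation and a unit test pins
the kernel to it to machine precision.  Trajectories breaching an overflow
guard (|V| > 1e6) are frozen and labelled divergent rather than raising, so
sweeps survive pathological corners; divergent cells are excluded from the
SWD-area denominator (switchable).

Initial conditions are drawn uniformly from `[-1, 1]^8` (the model's
attractors live at order-1 magnitudes given the background inputs) with a
seeded generator; a master seed fully determines every output byte.
Ensemble statistics combine per-run state labels by majority vote with ties
broken toward the more pathological state (SWD > simple oscillation > low
firing > saturated); trajectories themselves are never averaged.

## Stimulation protocols

All protocols drive the two TRN populations.  The stimulation current
enters the TRN equations *inside* the tau-scaled bracket
(`stim_in_tau=True`), i.e. it is processed like the synaptic inputs.  This
placement is a model design choice: with the current outside the bracket a
3 mA pulse train *enlarges* the seizure territory (the mean drive parks the
simple-oscillation band inside the SWD region), whereas inside the bracket
high-frequency stimulation converts SWD cells into simple-oscillation and
low-firing cells — the clinically expected outcome the therapy comparison
is built on.

- **DBS** — rectangular pulse train, amplitude `alpha = 3` (mA-equivalent),
  rate `f = 130 Hz`, width `delta = 4 ms`, applied to both TRNs
  simultaneously.  The pulse occupies the first `delta` of each period.
  (An equivalent Heaviside-product form `H[sin(2πt/ρ)]·(1−H[sin(2π(t+δ)/ρ)])`
  is exact only for `delta < rho/2`; at these settings `delta > rho/2`, so
  the package uses the direct rectangular form, whose RMS is
  `alpha·sqrt(delta/rho)`.)
- **CBBP** — biphasic pulse per period `T = 1/f`: anodic phase of width
  `delta`, cathodic phase filling the remainder.  The default amplitude
  convention is the *literal* one (anodic value numerically equal to
  `delta`, cathodic `−delta/(T−delta)`), which carries a small net cathodic
  charge of `delta² − delta` per period; this is the convention whose
  therapeutic effect matches the reported seizure-map outcomes.  A strictly
  charge-balanced variant (anodic `alpha`, cathodic `−alpha·delta/(T−delta)`,
  zero net charge) is available via `cbbp_literal=False`; note that a
  zero-mean drive at 130 Hz is dynamically inert in this model (the
  thalamic equations are linear in the stimulation and average it out), so
  the charge-balanced variant leaves the seizure map essentially at
  baseline.
- **CRS m:n** — coordinated reset: time is split into cycles of length
  `crs_cycle_length`; within each super-period of `m + n` cycles the first
  `m` are ON and the rest OFF, and ON cycles alternate their target
  (TRN1 first, alternation continuing across super-periods).  During an ON
  cycle the target receives the full 130 Hz pulse train.  1:0 is perpetual
  alternation, 3:2 stimulates three cycles then pauses two.

### The coordinated-reset cycle length

The cycle length is not a standard constant and the maps are *strongly
resonant* in it: per-target gating rates near the 2–4 Hz discharge band
entrain the very spike-wave rhythm being treated (a 0.2 s cycle drives the
whole plane into SWD), and the response is non-monotonic between 0.1 s and
2 s.  Following coordinated-reset practice the default is one period of the
pathological rhythm, `1/3 s` at the ~3 Hz discharge frequency, which sits
in a clean non-resonant regime.  At this value CRS 3:2 reduces the SWD area
to ~37 % (pauses let deep SWD cells relapse) while CRS 1:0 abolishes it
entirely — in this implementation perpetual alternation is *more* effective
than the intermediate ranking usually quoted for it, because each ON epoch
disrupts the discharge faster than the alternation gap lets it re-form.

## State classification

The post-transient mean field is classified into four regimes:

1. peak-to-peak < `amp_tol` (0.01) → fixed point: **I (saturated)** if the
   mean exceeds `saturation_level`, else **IV (low firing)**.  The model's
   two fixed-point branches sit near 0.46 and 0.16 mean-field units;
   the default midpoint is 0.31.
2. otherwise oscillatory: the dominant frequency is the largest peak of the
   mean-removed periodogram in (0.5, 50] Hz.  The trace is **III (SWD)**
   if the dominant frequency lies in [2, 4] Hz *and* the median number of
   prominent local maxima per fundamental period is ≥ 2 (the spike and the
   wave); else **II (simple oscillation)**.

A maximum counts as prominent when its prominence exceeds
`peak_prominence_rel` (default 0.16) times the trace's peak-to-peak
amplitude.  This threshold was calibrated once against the six labelled
reference points of the one-dimensional bifurcation analysis
(`h7 ∈ {1.5, 2.1, 2.5}` at `h8 ∈ {9.2, 10.2}`): the secondary ripple of a
simple oscillation has relative prominence below ~0.14 and the wave maximum
of a spike-wave cycle above ~0.19, and 0.16 is the midpoint of the
admissible interval.  The *median* per-period count (rather than a global
peak count divided by the number of periods) makes the rule robust to the
switching transients that intermittent stimulation superimposes on
otherwise simple oscillations.

The decimated storage rate for sweeps (500 Hz) comfortably covers the
0.5–50 Hz analysis band with 0.05 Hz spectral resolution over the 20 s
window.

## Sweeps and therapy metrics

State maps are computed on a grid over `(h7, h8) ∈ [1.5, 2.5] × [9, 11]`
(default 41 × 41 for production figures; the acceptance checks use 21 × 21
with 3 repeats per cell), with per-cell majority-vote labels and the median
dominant frequency over repeats.  `swd_area_fraction` is the percentage of
non-divergent cells labelled SWD.  The therapy comparison reports, per
protocol: the treated SWD area, the reduction `100 (A0 − A) / A0` against
the unstimulated baseline, the RMS of the recorded total stimulus current
`beta1·u + beta2·u` over the post-transient window, and that RMS as a
percentage of the largest-RMS scheme.  The raw RMS column is the
authoritative energy measure; the percentage normalisation is a reporting
convention only.

## Known limitations

- Under these equations the low-firing regime does not occur inside the
  `[1.5, 2.5] × [9, 11]` box: the SWD attractor at (2.5, 10.2) is global
  (checked across initial-condition ranges up to `[-5, 5]^8`), and low
  firing first appears beyond `h8 ≈ 11.5`.  Reference accounts place a
  low-firing corner at high (h7, h8) inside the box; its absence here
  inflates the unstimulated SWD area (≈ 54 % versus ≈ 42–44 % with the
  corner present) and turns the (2.5, 10.2) reference point into SWD
  instead of low firing.
- The four-state ranking of therapies is reproduced except that CRS 1:0 is
  fully suppressive rather than intermediate (see above); consequently
  reduction ratios for CBBP and CRS overshoot the commonly quoted values.
- The synthetic classifier fixtures are analytic waveforms built from the
  decision rule itself; they verify the classifier's branches, not the
  model, and passing them says nothing about real EEG.
- No adaptive stepping, stochastic terms, transmission delays, or spatially
  continuous fields; two discrete modules only.
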