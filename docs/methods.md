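# Methods

## Neuron model

The canonical unit is a conductance-based rate neuron,

    τ · dv/dt = −α·v + (β − v)·E − (γ + κ·v)·I,

with non-negative weighted drives E (excitatory) and I (inhibitory).  The
reversal-potential structure confines the state to (−γ/κ, β) for κ > 0; the
fixed point under constant drives is

    v* = (β·E − γ·I) / (α + E + κ·I),

which the test suite uses as a closed-form oracle.  Defaults: τ = 10 ms,
α = β = γ = κ = 1 (dimensionless state in (−1, 1), shunting inhibition).
The output non-linearity g(v) defaults to rectification (`max(v, 0)`); a
logistic option is available, and both are non-negative and non-decreasing.

The spiking mapping keeps the state equation, replaces g by a fixed
threshold (0.5) with reset to 0, subtracts an adaptation current w with
dw/dt = (a·v − w)/τ_w between spikes and w → w + b at each spike
(a = 0, b = 0.05, τ_w = 100 ms: mild spike-frequency adaptation), and
converts incoming spike trains into conductances with exponential synapses:
g decays by exp(−dt/τ_syn) per step and jumps by weight·increment per
spike.  Under Poisson input at rate ρ the stationary mean conductance is
ρ·weight·increment·τ_syn, which the tests verify against simulation.

### Integration

States are advanced by **exponential Euler** at dt = 0.1 ms: for drives
frozen within a step the equation is linear, τ·dv/dt = A − B·v with
B = α + E + κ·I, so the update relaxes v exactly towards A/B by
exp(−B·dt/τ).  A forward-Euler variant was tried first and rejected: in
the shunting regime the total conductance B is unbounded (values of 50 and
more occur in normal operation), forward Euler is unstable once
dt·B/τ > 2, and the instability manifested as strongly inhibited units
firing at the 1/dt ceiling.  Exponential Euler is unconditionally stable,
preserves the reversal-potential bounds exactly, and has the same fixed
points, so the equilibrium oracles are unaffected.

### Operating point

The synaptic gain (increment 1.25, τ_syn = 10 ms for both channels) was
chosen so that, at the default input statistics, S-T units respond down to
low input rates (tens of Hz) instead of being cut off by the threshold, and
W-S units fire in a graded regime well below the 1/dt rate ceiling.  Both
properties are what make the W-S tuning curves monotone and smoothly
shifted across the weight ladder; outside this regime the population
response saturates or collapses to all-or-nothing and the linear readout
degrades.

## Network

Two mirror-symmetric hemispheres; per hemisphere, n_freq = 64 S-T units
and 64 × 7 W-S units (1024 neurons total; input channels are virtual spike
sources and are not counted).  Kernel fan-ins are stored as explicit
weighted edge lists with zero padding at the band-range boundaries — never
as a convolution primitive, mirroring distributed event-based hardware
where no such primitive exists.  The smoothing kernel is a normalized
binomial of width 3 (0.25, 0.5, 0.25); `quantize_kernel` maps kernels onto
integer levels for fixed-resolution weights and returns the scale that
minimizes the maximum dequantization error over scalar rescalings.

All edges carry a one-step delay and units update synchronously
(input → S-T → W-S is the only path, so the graph settles feed-forward).
`build_network_with_relays` keeps the biological MNTB relay stage as
linear pass-through units; `eliminate_relays` composes each relay's in/out
edges into a direct edge (weight product, out-edge sign), which is exactly
equivalent in rate mode and is how the default network is defined.

## Synthetic ILD stimuli

An ILD x ∈ [−1, 1] maps to per-ear Poisson rates via a complementary
linear split with constant total: left = base·(1+x)/2,
right = base·(1−x)/2.  Only one frequency band is active, and only that
band is evaluated.  This keeps overall loudness independent of the cue and
makes x exactly recoverable as (L−R)/(L+R).

Defaults: base rate 2000 Hz, 4000 ms per stimulus, rates estimated from
the trailing half of each spike train (excluding onset transients).  These
two numbers are set by the statistics of the task, not by convenience: a
Poisson stimulus containing N spikes in the scoring window only determines
its own empirical ILD to about 1/√N, and decoding a 0.1-step grid exactly
requires the readout error to stay below 0.05.  With N ≈ 4000
(2000 Hz × 2 s window) the stimulus-intrinsic uncertainty is ≈ 0.016,
leaving headroom for network and regression noise; at, say, 500 Hz × 0.5 s
(N = 250, σ ≈ 0.06) exact decoding is statistically impossible for any
network.  The deterministic rate mode has no such floor and uses shorter
runs.

## Readout

Per band, u_ω = Σ_p r_ω,p·k_p + bias over the 14 W-S rates of both
hemispheres.  Weights are fitted by ordinary least squares on a single
band across the training sweep (rank-deficient designs fall back to the
minimum-norm solution and are flagged).  Evidence per candidate target t
is max(1 − c·|u_ω − u★_t|, 0) with c = 1 and clipping on by default; the
absolute difference makes an exact match the unique maximum, and a signed
variant is selectable.  Ties at the final argmax break towards the
smallest target.  With a single evaluated band this decoder reduces to
nearest-target rounding of u, so sweep accuracy is exactly the fraction of
stimuli whose readout error stays below half the grid step.

## Recorded-audio pipeline and its surrogate

Stereo WAV → per-ear gammatone filterbank (4th-order IIR, 64 ERB-spaced
channels in 100 Hz–8 kHz, envelope = per-1-ms-bin RMS) → Bernoulli spike
encoding with one possible spike per band and bin, probability gain ×
intensity → deterministic decimation (keep every k-th spike, default
k = 10) → network simulation → trailing-window rates → readout fitted on
one band (index 32) and one sound type (white noise) → evidence summed
over all bands → per-sound-type affine rescaling of the estimates onto
±90° → accuracy (after snapping to the 10° grid), MAE and RMSE.

The Bernoulli gain is normalized to the 99th percentile of the joint
left/right intensity distribution (rare bins above it are clipped) so that
typical bins reach a usable spike probability; normalizing to the absolute
peak left the network nearly silent.  Left and right share one gain, so
interaural ratios are preserved and no per-bin cross-normalization is
performed.

The study's own head-mounted recordings are external, so the package ships
a **synthetic surrogate generator**: stereo waveforms (white/pink noise,
tone, chirp) whose two channels carry amplitudes (1 ± az/90)/2.  The
surrogate reproduces the level cue only — no head-related filtering,
no spectral elevation cues, no reverberation — so passing tests show that
the pipeline recovers a level-difference code end to end, not that it
matches real acoustic performance.  The surrogate acceptance check runs at
reduced size (16 bands, 0.8 s recordings, decimation 2, synapse gain 5 to
match the lower per-band rates, white noise only) and requires the
pipeline to beat a label-shuffled control on MAE across seeds, plus exact
recovery in the constructed limit where W-S rates are exactly linear in
azimuth.

## Numerical and design choices

- dt = 0.1 ms everywhere; durations must be integer multiples of dt.
- All randomness flows through `numpy.random.SeedSequence`; per-stimulus
  streams are spawned children of the experiment seed, and identical
  seeds give bit-identical results.
- Excitatory and inhibitory streams use separate non-negative conductance
  channels; negative weights on a channel are a contract violation.
- Relay elimination only touches units with linear transfer and exactly
  one excitatory one-to-one in-edge and one out-edge; anything else is
  left untouched.
- Per-sound rescaling uses the min/max of the estimates (not the
  ground-truth range); sound types with constant estimates are excluded
  with a warning.
- The degenerate cases (empty spike trains, all-zero kernels, empty
  manifests, constant estimates) raise or warn as documented in the
  docstrings rather than silently producing numbers.

## Limitations

- The synthetic sweep trains and evaluates on the same 21 stimuli, as in
  the original protocol; it measures decodability of the representation,
  not generalization.
- The surrogate audio experiment is a functional stand-in; its error
  figures are not comparable to measurements on real recordings.
- No axonal delays, no plasticity, no multi-compartment structure, and no
  modelling of any specific hardware's fixed-point arithmetic.
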