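# Methods

This note documents the model implemented in `orisel`, its assumptions,
the numerical methods, the conventions adopted where the design was
genuinely open, and the known limitations. Units throughout: degrees of
visual angle (deg), seconds (s), millivolts (mV), impulses per second
(Hz), dimensionless contrast.

## Model

### Cascade

The early visual pathway is modelled as a feedforward cascade of seven
stages. Each stage is a single nonlinear first-order differential
equation per neuron: the generator potential p (membrane potential at
the axon initial segment relative to spike threshold) relaxes toward the
weighted sum of its rectified inputs with time constant tau, and the
impulse rate is a(t) = g_rect * max(p, 0). Stages and their time
constants:

| stage | neuron                   | tau (s)            | notes |
|-------|--------------------------|--------------------|-------|
| 1     | photoreceptor            | 0.01               | hyperpolarised by light (minus sign on the stimulus dot product); no spikes |
| 2     | bipolar cell             | 0.011 on / 0.009 off | sign flip n_j; no spikes |
| 3     | ganglion cell            | 0.011 / 0.009      | adds static depolarisation p_s = 1.9 mV |
| 4     | geniculate relay cell    | 0.011 / 0.009      | rectifies its input |
| 5     | inhibitory soma          | 0.01               | pooled geniculate drive |
| 6     | inhibitory axon/network  | 0.2                | integrates the rectified somal potential; a potential, not a rate |
| 7     | excitatory cortical cell | 0.01               | feedforward drive minus pooled stage-6 field |

Off channels are faster than on channels (9 vs 11 ms), reproducing the
measured few-millisecond off lead; together with the higher off-cell
density this produces dark dominance in cortical receptive fields.

The stimulus enters stage 1 through the centre mechanism
g_s/(pi r_s^2) exp(-d^2/r_s^2) with g_s = 62 mV per contrast unit and
r_s = 0.4 deg; there is no surround mechanism, and stimuli are defined
as contrast, not luminance. The model is deterministic: no membrane
noise anywhere.

### Convergence normalisation

The geniculocortical (g_c = 3.5, r_c = 0.95 deg) and
inhibitory-to-excitatory (g_e = 2.2, r_e = 0.95 deg) convergence sums
are discrete sums over sources of a Gaussian profile whose plane
integral equals the gain — the same normalisation the centre mechanism
obeys. Each sum therefore carries the area-per-source quadrature element
(patch area / channel count for geniculate sources; grid-cell area for
cortical sources), so that the total convergence gain is g_c
(respectively g_e) independent of source density. This choice anchors
the resting chain: geniculate rest p_s = 1.9 mV pools to
g_c * p_s ≈ 6.7 mV at the inhibitory soma (resting rate ≈ 48 Hz, well
above the geniculate 14 Hz), and the excitatory cell rests at
(1 - g_e) * g_c * p_s ≈ -8 mV, i.e. several millivolts below threshold,
in line with the ~9 mV resting hyperpolarisation the gain g_e was chosen
to produce. Taking the sums without the area element instead makes every
resting potential scale with source density (hundreds of mV), which is
physically untenable; the normalised reading is used throughout.

### Mosaic

Off channels sit on a square grid of spacing 0.19 deg with a node at the
patch centre; on channels on a 0.20 deg grid offset by half a spacing in
both axes, so the four nodes nearest the centre are equidistant from it.
Every node is perturbed by independent Gaussian deviates (SD 0.038 deg
on, 0.037 deg off) and is not clipped back into the patch. Node
inclusion convention: with n = floor(half_width / on_spacing), the off
grid has (2n+1)^2 nodes and the on grid (2n)^2 — for the standard 8x8
deg patch, 1681 + 1600 = 3281 channels, and 441 + 400 = 841 at the
4x4 deg desk scale. The convention is not uniquely determined by the
published channel total; this is the smallest one that reproduces it.

With these perturbations the nearest neighbour of a channel has opposite
sign more than 90% of the time, the on/off mosaics are statistically
independent by the density-recovery-profile test, and the realised SD of
the normalised same-sign nearest-neighbour distance is ~0.22 (the
calibration target for this spread was 0.189; the discrepancy is a
property of min-over-neighbours statistics, and the generator keeps the
stated perturbation values rather than retuning them).

Cortical neurons (one excitatory and one inhibitory per node) sit on an
unperturbed square grid with 0.1 deg spacing (0.2 deg at desk scale),
node at the patch centre: 81^2 = 6561 nodes at full scale.

## Solvers

### Time domain

All stages are integrated simultaneously with an exponential update per
step: each equation is a driven first-order low-pass, for which
relaxation toward a constant drive is exact. The drive over a step is
taken as the average of its start and end values (trapezoidal drive),
making the scheme second-order accurate for smooth stimuli; left-endpoint
sampling would leave O(omega*dt) ~ 1% errors at the default dt = 1 ms.
The step must satisfy dt <= min(tau_j)/5. Inhibitory pooling over the
cortical grid uses the separability of the Gaussian: two small matrix
products per step, exact (no truncation). The geniculocortical matrix is
truncated at 3 r_c (relative weight < e^-9 outside).

Drives: gratings use the closed-form Gaussian dot product
g_s c exp(-r_s^2 psi^2/4) cos(psi u_j - omega t); square flashes use the
exact Gaussian-rectangle integral (product of erf terms); arbitrary
movies use a Riemann sum on their raster, frames held piecewise
constant.

### Frequency domain (gratings only)

For a drifting grating every channel of a given sign shares one periodic
waveform up to the time shift psi*u_j/omega, so the subcortical stages
are solved once per sign: linear stages divide each harmonic by
(1 + i tau m omega); rectifications are applied by reconstructing one
cycle in time, rectifying, and re-transforming — exact in a single
forward pass because the cascade is feedforward. The cortical drive for
all nodes and all probe directions is then one matrix product of the
convergence matrix with phase-shifted per-sign harmonics. Static (DC)
terms are carried as explicit DC coefficients. Defaults: 128 samples and
32 harmonics per cycle for analyses (64/16 inside the development loop,
where accept/reject decisions are insensitive to the tail); harmonic
energy above the budget is < 1e-4 of the total at default parameters.

The two paths are cross-checked on every stage over one steady-state
cycle; the operational tolerance for "agreement to round-off" is a
relative L-infinity deviation < 1e-3 (the two discretisations differ, so
machine epsilon is unattainable); the achieved deviation at defaults is
about 6e-4. The time-domain transient for this comparison is discarded
over 2 s (ten inhibitory time constants); ordinary periodic-response
measurements discard 0.5 s (one stimulus period).

## Development

At cycle 0 every weight w_jk = 1 and the inhibitory-to-excitatory gain
is 1 (so excitatory cells rest exactly at threshold); the gain ramps
linearly to g_e = 2.2 over the run, mirroring the maturation of
inhibition. Each cycle: one geniculate channel is chosen uniformly at
random; all its weights are raised by 0.2 (clamped to [0, 2]); the model
is probed with gratings drifting in 16 evenly spaced directions; each
excitatory neuron keeps the raise if its maximum response increased
relative to the previous cycle, and otherwise has that weight set 0.2
below its previous value (clamped). After the per-neuron accept/reject,
the settled model is re-evaluated once and that value becomes the next
cycle's reference. The cycle count is five trial cycles per channel,
rounded to the nearest thousand: 16 000 at full scale, 4000 at desk
scale.

"Maximum response" is implemented as the maximum over probe directions
of the peak steady-state excitatory impulse rate. The modulation (F1)
amplitude is available as an alternative measure; at the desk scale it
degrades the map stability across development (correlation 0.60 vs 0.98)
and improves nothing, so peak rate is the default.

The probe responses are maintained incrementally: the drive harmonics
are updated in place when one channel's weights change (exact, because
the cascade is feedforward), and rebuilt from scratch every 1000 cycles
to bound accumulated round-off. One desk-scale run (841 channels, 441
nodes, 4000 cycles) takes about two minutes on one CPU.

Outcomes at the desk scale: the median excitatory membrane-potential
modulation amplitude grows about tenfold across development while the
iceberg holds peak rates near their pre-development level; the
orientation-preference maps before and after development correlate at
~0.98 (silenced nodes excluded); roughly a quarter of central neurons
end the run fully silenced by mature inhibition.

A caution from the exhaustively enumerable two-channel toy model (one
on- and one off-channel, one neuron, inhibition off): under the
peak-rate measure the optimum keeps both weights high, because the
rectified geniculate rates contribute DC regardless of sign and nothing
subtracts it without inhibition; under the modulation measure the
optimum is the segregated corner, but greedy hill climbing from equal
weights can still ride the symmetric diagonal into a both-high local
maximum. On/off segregation in the full model is a collective effect
that relies on inhibition cancelling the common DC.

## Stimuli

Gratings default to the standard probe: contrast 0.3, 0.5 cycles/deg,
2 Hz. Sparse noise is one 1x1 deg square per trial at the nodes of a
0.25 deg grid, 50 ms duration, contrast +/-1, each trial simulated
independently from rest for 300 ms (flash plus decay) with the peak rate
over the whole trial recorded. Receptive-field contours are traced by
marching squares at 0.05/0.5/0.95 of each polarity's peak rate;
thresholding makes receptive fields smaller than the weight maps that
generate them.

## Map analyses

Conventions:

- Preferred orientation is the orientation of the grating's bars: the
  preferred motion direction (argmax of the 16-direction tuning curve)
  plus 90 deg, folded modulo 180. Nodes with all-zero tuning curves are
  flagged and excluded from correlations.
- Tuning curves are fitted with a sum of two von Mises lobes separated
  by 180 deg (baseline, two amplitudes, shared concentration, preferred
  direction; multi-start least squares). Bandwidth is the half width at
  half height of the fitted curve, with half height midway between the
  curve's maximum and minimum; for a single lobe this reduces to
  arccos(1 + ln((1+e^(-2 kappa))/2)/kappa).
- Relative modulation F1/F0 is the fundamental Fourier amplitude of the
  rate over one steady-state cycle divided by its mean; it lies in
  [0, 2], is pi/2 for a half-wave-rectified sinusoid and approaches 2
  for a single-bin impulse train.
- Map periodicity: orientations are doubled to direction-free unit
  vectors; the real and imaginary parts of the central 5x5 deg crop are
  Fourier transformed with DC suppressed; the radial location of each
  peak magnitude is found on the discrete frequency grid (bins of
  0.2 cycles/deg) and the periodicity is the reciprocal. Cortical
  distance uses the areal magnification 0.45 mm^2/deg^2.
- Pinwheels are 2x2 plaquettes around which the doubled angle winds by
  +/-360 deg. The doubled-angle field is first smoothed circularly with
  SD equal to one grid spacing: an argmax over finitely many probe
  directions carries one-pixel orientation jitter that the winding rule
  would otherwise count as singularities (several per deg^2 of pure
  jitter). Smoothing SD, bin count and the rule itself are parameters.
- Map association is the Pearson correlation computed jointly over the
  stacked (cos 2theta, sin 2theta) components; identical maps give +1,
  maps differing by 90 deg everywhere give -1; a permutation p-value is
  available.
- The Gabor-bank map prediction treats channels as +/-1 impulses and
  evaluates the dot product with Gabors (SD 0.7 deg, 0.5 cycles/deg,
  8 orientations, 8 phases) exactly at the probe points — impulses make
  rasterisation unnecessary. The predicted orientation is the bar
  orientation of the best Gabor over orientations and phases.
- The subcortical difference map assigns +1/-1 impulse mass per channel
  on a 0.02 deg raster (padded so no smoothed mass is lost), smooths
  with the centre-mechanism profile exp(-d^2/r_s^2), and takes the
  radial FFT peak over the central 6x6 deg (the full-patch transform is
  dominated by boundary truncation). The closed-form counterpart — the
  transform of the difference of two slightly offset centre profiles —
  peaks at sqrt(2)/(2 pi r_s) = 0.56 cycles/deg, periodicity 1.8 deg.

Pre-development maps are computed with the inhibitory gain at its
development starting value (1.0); at the mature gain the pre-development
modulation is entirely subthreshold and no map exists.

## What the generator emulates, and what passing tests show

The mosaic generator reproduces the interleaved-lattice statistics of
on/off beta-cell arrays (opposite-sign nearest neighbours, on/off
independence, the calibrated spread of same-sign spacings) but is not a
biological point process: no dmin-style interaction, no global density
gradients, no soma-size constraints. The probe grating stands in for
both retinal waves and post-eye-opening stimulation; no retinal wave
dynamics are modelled. Passing tests therefore show that the cascade,
plasticity rule and analyses behave as specified on this idealised
retina — not that real retinas would produce identical maps.

## Known limitations

- Winner-take-all orientation maps built from argmax tuning have
  iso-orientation domains at the scale of the convergence window with
  weakly correlated orientations in adjacent domains. Their
  doubled-angle spectra peak near twice the domain size (~0.3-0.45
  cycles/deg here), not at the subcortical difference-map frequency: a
  synthetic field with an exact 0.56 cycles/deg ring spectrum, run
  through the same Gabor argmax procedure, peaks at 0.23 cycles/deg.
  Published map-periodicity estimates that coincide with the subcortical
  frequency are not reproduced by this construction; the package reports
  what its procedure measures.
- Post-development inhibition thresholds responses down to one or two of
  the 16 probe directions for most neurons, so fitted bandwidths floor
  near the fit's resolution limit (~3-4 deg HWHH) and a fraction of
  neurons are silenced outright. The depth of this iceberg relative to
  the modulation is independent of the convergence normalisation.
- Contrast sensitivity: the maximum gradient of excitatory potential
  amplitude versus contrast at the optimal grating is ~50 mV per
  contrast unit post-development at desk scale, below the ~70 the
  cortical gain was nominally calibrated to.
- The full-scale 16 000-cycle development run is supported but takes
  hours; all development-dependent results here use the desk-scale
  configuration (4x4 deg patch, 0.2 deg cortical spacing, 4000 cycles).
- Monocular, monochromatic, contrast-defined stimuli only; no surround
  mechanism, no recurrent excitation, no membrane noise.
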