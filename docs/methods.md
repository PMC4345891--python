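# Methods

## Coordinates and geometry

All geometry uses 0-based pixel coordinates, origin at the top-left,
half-open rectangular bounds `[x0, x1) × [y0, y1)`, row-major arrays.
A pixel `(r, c)` has its center at `(c + 0.5, r + 0.5)`.

**Rasterization.** A DMD pixel is ON iff its *center*, mapped back to
camera coordinates through the inverse of the affine calibration
transform, lies inside the ROI. Boundary rules: inside-or-on for
rectangles and ellipses (`(dx/rx)² + (dy/ry)² ≤ 1`); strict interior
under the even-odd (crossing-number) rule for polygons, so
self-intersecting vertex lists behave predictably. SmartGrid cells use
half-open membership instead, so sibling cells partition the DMD
pixels exactly — manual ROIs may overlap, grid cells never do. The
point-in-polygon test is implemented directly (a ten-line vectorized
crossing-number scan) because the membership rule, including its
boundary semantics, is part of the contract being tested; the test
suite checks it against shapely as an independent oracle.

**Integer vs nominal cell bounds.** A grid cell carries two bounds.
Its *pixel* bounds are integers: a span of W pixels split into c
columns gives widths `⌊W/c⌋` or `⌈W/c⌉`, remainder pixels assigned
left-to-right — this drives rasterization and guarantees exact tiling.
Its *nominal* bounds carry the exact fractional subdivision (724 px
split 3-ways is 241.33) and drive physical-dimension reporting, which
rounds to the nearest micrometre (ties away from zero). This is why a
724 × 551 µm cell subdivides to cells reported as 241 × 184 µm and then
80 × 61 µm, independent of which integer-width child is queried.

**DMD resolution** is a configuration parameter, default 684 × 608
(rows × cols). The camera→DMD registration is a user-supplied affine;
`CalibrationTransform.uniform_scale` provides the common case of
mapping the camera field onto the full DMD.

## Protocols

Timelines are symbolic (seconds), not DAQ-clocked. The
inter-stimulus interval is defined onset-to-onset; the trigger
precedes each onset by `trig_delay` (default 0 s). Randomization is an
explicit Fisher–Yates driven by a seeded `numpy` generator, shuffled
independently per repeat; the realized order is stored in the protocol
metadata so the association of responses to patterns is always
invertible. Sequences start at 0.5 s by default so a pre-stimulus
baseline window always exists. Paired stimulation permits
`latency < exposure` (overlapping exposures of two patterns), realized
in the simulator as summed drive; whether particular hardware can
project that is outside this package's concern.

## The rig simulator

The simulator emulates what the acquisition side of a DMD
photostimulation rig records, not the optics or biophysics in detail:

* membrane: a single-compartment leaky integrator,
  `dV/dt = (V_rest − V)/τ_m + drive(t) + noise`, forward-Euler
  integrated at the recording sample rate (drive at sample k first
  affects sample k+1). Euler at 10 kHz with τ_m ≥ 5 ms keeps peak
  errors well under 1 % of the analytic saturating-exponential
  response;
* drive: `gain × (sensitivity mass under the mask) / (total
  sensitivity)` in mV/ms, summed over concurrently active exposures.
  Normalizing by total sensitivity makes full-field illumination give
  drive = `gain`, so a long full-field pulse saturates at
  `gain · τ_m` mV above rest;
* noise: an Ornstein–Uhlenbeck process obtained by feeding white
  increments scaled by `noise_sd · √(2·dt/τ_m)` through the same
  membrane filter; `noise_sd` is the stationary voltage SD. The
  default 0.5 mV matches typical whole-cell recording noise;
* spikes (optional): when V crosses threshold, a triangular waveform
  (+100 mV over 2 ms) is inserted, then V is clamped to rest for a
  5 ms refractory period and integration resumes. Sustained
  suprathreshold drive therefore re-fires after each refractory
  period. Ground-truth spike times are stored in the recording
  metadata;
* trigger channel: 5 V TTL-like square pulses starting at each
  trigger time, lasting `min(5 ms, exposure)`.

Identical inputs and seed give bit-identical recordings. Defaults:
V_rest −65 mV, τ_m 20 ms, gain 1 mV/ms, spiking disabled.

What the simulator does **not** emulate: ChR2 kinetics
(desensitization, off-kinetics), dendritic cable filtering, optical
scattering/PSF, electrode artifacts, and slow drift. Passing tests
therefore demonstrate that the *analysis chain* is correct and
self-consistent, not that it reproduces any particular biological
voltage.

## Epoch extraction

Triggers are rising crossings `x[k−1] < θ ≤ x[k]`; θ defaults to the
midpoint of the trace's min and max (robust to non-TTL amplitudes),
with a debounce gap defaulting to half the inter-stimulus interval.
Association is strictly ordinal — k-th trigger ↔ k-th scheduled event —
which, combined with the stored randomization, inverts any shuffling.
Stimulus onset is trigger + `trig_delay`. Window defaults: 50 ms pre,
500 ms post; epochs that would run off the recording are excluded with
a warning rather than silently truncated.

## Evaluation

Per-trial evaluation, then the mean of surviving trial values (rather
than evaluating the mean waveform): this preserves trial-level
rejection bookkeeping; the mean waveform is stored too, so either view
is reproducible. Defaults: response window Δt = 100 ms, baseline
window 50 ms, clip off (the 30 mV cap is a presentation default in the
renderer only, where `heat_to_alpha` shares the evaluator's clip rule).

Latency (time to a fraction of peak, default 0.5) and rise time
(10 %→90 %) interpolate linearly between samples; a trace whose peak
does not exceed baseline returns `nan` (an undefined-result flag, not
an exception), as does a pattern whose every trial was rejected.

Spike detection: upward crossing of −20 mV with instantaneous slope
≥ 20 mV/ms, spanning until the voltage falls back below the amplitude
threshold. Rejection applies two individually toggleable sub-rules:
a spike *starting before onset* that overlaps the response window, and
any spike inside the baseline window. Stimulus-evoked spikes (onset
after stimulus onset) never cause rejection.

The integration index is `AB − (A + B)` on the condition-aggregated
heats; with the passive membrane it is zero up to integration
tolerance (the membrane ODE is linear), and a spike threshold placed
between the single- and combined-mask drives makes it positive.

## Problem sizes

The test suite and examples run everything at desk scale, chosen as
the smallest sizes that still exercise each property: 9×9 grids on a
162-px field (18-px cells with a σ = 6 px sensitivity blob, i.e. a
soma about a third of a coarse cell), 3 repeats, 10 kHz sampling,
20 ms exposures at 200 ms ISI; the rasterization oracle uses DMD grids
up to 128×128 and 200 random shapes. The spatial-recovery check runs
100 independently seeded experiments and requires the hottest cell to
contain the blob center in at least 95 — the few expected misses are
blobs landing within a fraction of a pixel of a cell edge, where the
two adjacent cells receive near-equal drive and noise decides the
argmax.

## Known limitations

* The cell model is deliberately minimal; quantitative voltages are
  not comparable to real neurons.
* Ordinal trigger–event association assumes no missed or spurious
  triggers (a count mismatch is an error, not repaired).
* The heat-map renderer draws region outlines and alpha fills; it does
  not reproduce interactive figure behavior — per-region waveform
  exports indexed in the sidecar JSON replace click-to-inspect.
* `SmartGrid.merge` requires sibling leaves whose union is an exact
  rectangle; merging across parents is rejected rather than re-parented.
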