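# optomap

Patterned optogenetic stimulation design, rig simulation, and
stimulus–response heat mapping — as a hardware-free Python library.

DMD-based photostimulation (a digital micromirror device projecting
arbitrary binary light patterns through a microscope) lets an
experimenter depolarize a ChR2-expressing neuron at many locations —
whole cells or subcellular regions — while recording the membrane
potential with whole-cell patch clamp. `optomap` implements the
computational core of such an experiment for people who design,
simulate, or re-analyze these mapping experiments:

1. **geometry** — manual ROIs (rectangles, ellipses, polygons) and a
   hierarchical **SmartGrid** tiling of the field of view, rasterized
   to DMD pattern masks through an affine camera→DMD calibration;
2. **protocol** — explicit trigger/exposure timelines: randomized
   sequential stimulation, paired stimulation with a latency, and
   summation batteries (A, B, A∪B);
3. **rigsim** — a simulator standing in for the rig: a
   leaky-integrator neuron with ChR2-like drive and a TTL trigger
   channel, so the whole pipeline runs at desk scale;
4. **epochs** — trigger detection on the recorded TTL channel and
   extraction of per-stimulus voltage epochs;
5. **evaluate** — per-epoch "heat" statistics (peak depolarization,
   latency, rise time, or any registered custom evaluator), rejection
   of epochs contaminated by spontaneous spikes, per-pattern
   aggregation, and the paired-integration index;
6. **report** — heat-map figures, waveform exports, a hash-manifested
   experiment archive, and an append-only experiment log.

## The model at the core

The evaluated "heat" of region *i* is the baseline-referenced peak
depolarization

&nbsp;&nbsp;&nbsp;&nbsp;h_i = max_{t ∈ [t_on, t_on + Δt]} V(t) − ⟨V⟩_baseline,

optionally capped (`min(h_i, clip)`, conventionally 30 mV) so action
potentials do not dwarf subthreshold responses on the map. The
simulated cell obeys

&nbsp;&nbsp;&nbsp;&nbsp;τ_m dV/dt = (V_rest − V) + τ_m · g · s(M(t)) + noise,

where s(M) is the fraction of the cell's spatial sensitivity covered
by the active mask M, g is the full-field drive (mV/ms), and an
optional threshold inserts a stereotyped spike. Paired-integration
analysis reports `AB − (A + B)`: zero for a passive membrane, positive
when the joint stimulus recruits a nonlinearity.

## Worked example

`examples/02_autostim_heatmap.py` maps a simulated neuron whose light
sensitivity is a Gaussian blob centered at DMD pixel (75, 95), using a
9×9 grid, 3 randomized repeats per cell:

```
protocol: 243 stimuli (81 patterns x 3 repeats, randomized)
recording: 49.5 s at 10000 Hz
cell 0.41: heat 7.18 mV (n=3, rejected=0)
cell 0.40: heat 2.37 mV (n=3, rejected=0)
cell 0.32: heat 2.22 mV (n=3, rejected=0)
wrote scratch/examples/heatmap.png
```

Cell `0.41` (grid row 4, column 5) is exactly the cell containing the
blob: the map recovers the cell's light-sensitive region from the
voltage traces alone, with its neighbors partially lit by the blob's
tails. `examples/03_paired_integration.py` shows the integration
analysis:

```
passive membrane   : A=6.33  B=6.33  AB=12.66  index=+0.000 mV
spiking nonlinearity: A=6.33  B=6.33  AB=109.04  index=+96.379 mV
```

The passive cell sums linearly (index ≈ 0); adding a spike threshold
between the single- and combined-mask drives makes only the joint
stimulus fire, so summation turns strongly supralinear.

The other examples cover grid design and mask export
(`01_grid_and_masks.py`) and the custom-evaluator registry
(`04_custom_evaluator.py`). A thin CLI wraps the same functions
(`optomap grid / masks / roi / protocol / simulate / segment /
heatmap / paired / archive`).

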