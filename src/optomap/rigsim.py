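"""Rig simulator: synthesizes what the acquisition hardware would record.

Stands in for the physical rig — DMD, amplifier headstage and DAQ — so
that every downstream stage (trigger detection, epoch extraction, heat
mapping, integration analysis) can be exercised at desk scale.  The
simulated cell is a leaky integrator driven by a ChR2-like photocurrent
proportional to the overlap between the illuminated mask and a spatial
sensitivity map:

    dV/dt = (v_rest - V)/tau_m + drive(t) + noise

where ``drive(t) = gain * sum_active <mask, sensitivity> / sum(sensitivity)``
in mV/ms, so that full-field illumination produces a drive equal to
``gain``.  An optional spike nonlinearity inserts a stereotyped
triangular action-potential waveform when V crosses threshold, followed
by a refractory clamp to rest.  Noise is an Ornstein–Uhlenbeck process
filtered by the same membrane time constant; ``noise_sd`` is its
stationary standard deviation in mV.

The trigger channel carries a 5 V TTL-like square pulse starting at
each event's trigger time and lasting min(5 ms, exposure).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.signal import lfilter

__all__ = [
    "CellModel",
    "Recording",
    "simulate",
    "make_sensitivity_map",
    "save_recording",
    "load_recording",
]

TRIGGER_AMPLITUDE_V = 5.0
TRIGGER_MAX_WIDTH_S = 0.005


@dataclass
class CellModel:
    """Parameters of the simulated ChR2-expressing neuron.

    Defaults describe a typical cultured hippocampal neuron under
    whole-cell current clamp: rest near -65 mV, membrane time constant
    20 ms, and ~0.5 mV of membrane noise.  ``gain`` is the photocurrent
    drive (mV/ms) at full-field illumination; with the defaults a long
    full-field exposure saturates at gain * tau_m = 20 mV above rest.
    """

    v_rest: float = -65.0            # mV
    tau_m: float = 20.0              # ms
    sensitivity: np.ndarray | None = None  # over DMD pixels; None = uniform
    gain: float = 1.0                # mV/ms at full overlap
    spike_threshold: float | None = None   # mV; None disables spiking
    spike_amplitude: float = 100.0   # mV above the crossing voltage
    spike_duration: float = 2.0      # ms
    refractory: float = 5.0          # ms clamp to rest after a spike
    noise_sd: float = 0.5            # mV, stationary

    def __post_init__(self):
        if not self.tau_m > 0:
            raise ValueError("tau_m must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sensitivity is not None:
            self.sensitivity = np.asarray(self.sensitivity, dtype=float)
            if (self.sensitivity < 0).any():
                raise ValueError("sensitivity must be nonnegative")


@dataclass
class Recording:
    """Sampled multi-channel trace (voltage in mV, trigger in V)."""

    sample_rate: float
    channels: dict
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def make_sensitivity_map(kind: str, params: dict, dmd_shape,
                         seed: int | None = None) -> np.ndarray:
    """Build a nonnegative spatial sensitivity map over DMD pixels.

    ``gaussian_blob`` emulates a compact soma: an isotropic 2-D Gaussian
    with ``center=(row, col)`` and ``sigma`` in pixels.  ``dendrite_path``
    lays a Gaussian-profile ridge of width ``sigma`` along the polyline
    ``points`` (list of (row, col)), emulating a dendritic branch.
    """
    rows, cols = dmd_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if kind == "gaussian_blob":
        r0, c0 = params["center"]
        sigma = float(params["sigma"])
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        if sigma == 0:
            m = np.zeros(dmd_shape)
            m[int(round(r0)), int(round(c0))] = 1.0
        else:
            m = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma ** 2))
    elif kind == "dendrite_path":
        pts = np.asarray(params["points"], dtype=float)
        sigma = float(params["sigma"])
        if not sigma > 0:
            raise ValueError("sigma must be positive")
        if len(pts) < 2:
            raise ValueError("dendrite_path needs at least two points")
        p = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        d2 = np.full(p.shape[0], np.inf)
        for a, b in zip(pts[:-1], pts[1:]):
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0:
                proj = np.zeros(p.shape[0])
            else:
                proj = np.clip((p - a) @ ab / denom, 0.0, 1.0)
            nearest = a + proj[:, None] * ab
            d2 = np.minimum(d2, ((p - nearest) ** 2).sum(axis=1))
        m = np.exp(-d2 / (2 * sigma ** 2)).reshape(dmd_shape)
    else:
        raise ValueError(f"unknown sensitivity map kind {kind!r}")
    if m.sum() == 0:
        raise ValueError("sensitivity map is zero everywhere")
    return m


def _mask_overlap(mask_grid: np.ndarray, sensitivity: np.ndarray | None) -> float:
    """Fraction of total sensitivity covered by the ON pixels."""
    if sensitivity is None:
        return mask_grid.mean()
    if sensitivity.shape != mask_grid.shape:
        raise ValueError(
            f"sensitivity shape {sensitivity.shape} != mask shape {mask_grid.shape}"
        )
    total = sensitivity.sum()
    if total == 0:
        raise ValueError("sensitivity map is zero everywhere")
    return float(sensitivity[mask_grid].sum() / total)


def _integrate(v0: float, x: np.ndarray, decay: float) -> np.ndarray:
    """Run V[k] = decay*V[k-1] + x[k] with V[-1] = v0 (vectorized IIR)."""
    y, _ = lfilter([1.0], [1.0, -decay], x, zi=np.array([decay * v0]))
    return y


def simulate(protocol, masks, cell: CellModel, sample_rate: float = 10_000.0,
             seed: int = 0, duration: float | None = None) -> Recording:
    """Simulate the analog recording produced by running a protocol.

    ``masks`` maps pattern id -> :class:`~optomap.geometry.PatternMask`
    (a list of masks is accepted and indexed by mask id).  Every pattern
    referenced by the protocol must have a mask.  Membrane voltage is
    Euler-integrated at the sample rate.  Deterministic under ``seed``.
    """
    if sample_rate < 1000:
        raise ValueError("sample_rate must be >= 1 kHz")
    if not isinstance(masks, dict):
        masks = {m.id: m for m in masks}
    missing = [ev.pattern_id for ev in protocol.events if ev.pattern_id not in masks]
    if missing:
        raise KeyError(f"no mask for pattern id(s): {sorted(set(missing))}")

    if duration is None:
        duration = protocol.end_time + 0.6
    dt = 1.0 / sample_rate
    n = int(round(duration * sample_rate))
    tau_s = cell.tau_m / 1000.0

    # per-pattern drive amplitudes (mV/ms -> mV/s for the ODE)
    overlap = {pid: _mask_overlap(masks[pid].grid, cell.sensitivity)
               for pid in {ev.pattern_id for ev in protocol.events}}

    drive = np.zeros(n)
    trigger = np.zeros(n)
    for ev in protocol.events:
        i0 = int(round(ev.onset_time * sample_rate))
        i1 = int(round((ev.onset_time + ev.exposure) * sample_rate))
        if i1 > n:
            raise ValueError(
                f"event {ev.index} exposure extends past the recording "
                f"(ends {ev.onset_time + ev.exposure:.3f} s, duration {duration:.3f} s)"
            )
        drive[i0:i1] += cell.gain * overlap[ev.pattern_id] * 1000.0  # mV/s
        t0 = int(round(ev.trigger_time * sample_rate))
        t1 = t0 + max(1, int(round(min(TRIGGER_MAX_WIDTH_S, ev.exposure) * sample_rate)))
        trigger[t0:min(t1, n)] = TRIGGER_AMPLITUDE_V

    rng = np.random.default_rng(seed)
    # OU noise realized through the same leaky filter as the membrane
    if cell.noise_sd > 0:
        xi = cell.noise_sd * np.sqrt(2.0 * dt / tau_s) * rng.standard_normal(n)
    else:
        xi = np.zeros(n)

    decay = 1.0 - dt / tau_s
    # forward Euler: V[k] = decay*V[k-1] + x[k-1], so drive at sample k
    # first affects V[k+1]
    x = dt * (cell.v_rest / tau_s + drive) + xi

    v = np.empty(n)
    v[0] = cell.v_rest
    spike_indices: list[int] = []
    if cell.spike_threshold is None:
        v[1:] = _integrate(cell.v_rest, x[:-1], decay)
    else:
        d_samp = max(1, int(round(cell.spike_duration / 1000.0 * sample_rate)))
        r_samp = max(1, int(round(cell.refractory / 1000.0 * sample_rate)))
        half = max(1, d_samp // 2)
        up = np.linspace(0.0, 1.0, half, endpoint=False)
        down = np.linspace(1.0, 0.0, d_samp - half)
        tri = np.concatenate([up, down])
        start, v0 = 1, cell.v_rest
        while start < n:
            seg = _integrate(v0, x[start - 1:n - 1], decay)
            above = np.nonzero(seg >= cell.spike_threshold)[0]
            if above.size == 0:
                v[start:] = seg
                break
            k = start + int(above[0])
            v[start:k] = seg[: above[0]]
            spike_indices.append(k)
            v_cross = seg[above[0]]
            stop = min(k + d_samp, n)
            v[k:stop] = v_cross + cell.spike_amplitude * tri[: stop - k]
            rstop = min(stop + r_samp, n)
            v[stop:rstop] = cell.v_rest
            start, v0 = rstop, cell.v_rest
            if start >= n:
                break

    meta = {
        "seed": int(seed),
        "protocol": protocol.to_dict(),
        "spike_indices": spike_indices,
        "n_events": len(protocol.events),
    }
    return Recording(sample_rate=float(sample_rate),
                     channels={"voltage": v, "trigger": trigger},
                     metadata=meta)


# ---------------------------------------------------------------------------
# Archive I/O
# ---------------------------------------------------------------------------

def save_recording(recording: Recording, path) -> None:
    """Write a recording as an HDF5 archive (one dataset per channel,
    sample rate and provenance metadata as attributes)."""
    with h5py.File(path, "w") as f:
        for name, data in recording.channels.items():
            f.create_dataset(name, data=np.asarray(data, dtype=np.float64))
        f.attrs["sample_rate"] = recording.sample_rate
        f.attrs["metadata"] = json.dumps(recording.metadata)


def load_recording(path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording archive not found: {path}")
    with h5py.File(path, "r") as f:
        channels = {name: f[name][...] for name in f.keys()}
        sample_rate = float(f.attrs["sample_rate"])
        metadata = json.loads(f.attrs.get("metadata", "{}"))
    return Recording(sample_rate=sample_rate, channels=channels,
                     metadata=metadata)
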