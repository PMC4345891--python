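"""Trigger detection, signal scaling, and trigger-aligned epoch extraction.

The DMD emits a TTL output pulse before each pattern exposure; that
pulse is recorded as an analog channel alongside the membrane voltage.
Segmentation finds the rising edge of each pulse, matches the k-th
trigger to the k-th scheduled event (the randomized order is stored in
the protocol, so this ordinal association inverts any shuffling), and
cuts a voltage slice spanning a pre-stimulus baseline window and a
post-stimulus response window.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import h5py
import numpy as np

__all__ = [
    "Epoch",
    "scale_signal",
    "detect_triggers",
    "segment",
    "save_epochs",
    "load_epochs",
    "TriggerCountError",
    "TruncatedEpochWarning",
]


class TriggerCountError(ValueError):
    """Detected trigger count does not match the protocol event count."""


class TruncatedEpochWarning(UserWarning):
    """An epoch window extended past the recording and was excluded."""


@dataclass
class Epoch:
    """A per-stimulus voltage slice tagged with its pattern.

    ``samples`` covers ``[onset - pre, onset + post)`` in mV;
    ``onset_index`` is the sample index of stimulus onset within the
    slice (equal to ``round(pre * sample_rate)``).
    """

    pattern_id: str
    condition: str
    trial_index: int
    samples: np.ndarray
    onset_index: int
    sample_rate: float

    @property
    def time(self) -> np.ndarray:
        """Time axis in seconds, zero at stimulus onset."""
        return (np.arange(len(self.samples)) - self.onset_index) / self.sample_rate


def scale_signal(raw, gain: float, offset: float = 0.0) -> np.ndarray:
    """Affine scaling of a raw DAQ signal into physical units
    (``out = raw * gain + offset``), e.g. amplifier volts to mV."""
    if gain == 0:
        raise ValueError("gain must be nonzero")
    return np.asarray(raw, dtype=float) * gain + offset


def detect_triggers(trigger_trace, sample_rate: float,
                    threshold: float | None = None,
                    min_gap: float = 0.001) -> list[int]:
    """Indices of rising threshold crossings in the trigger channel.

    A crossing is sample ``k`` with ``x[k-1] < threshold <= x[k]``.
    ``threshold`` defaults to the midpoint of the trace's min and max.
    Crossings closer than ``min_gap`` seconds to the previously
    accepted one are discarded (debounce).
    """
    x = np.asarray(trigger_trace, dtype=float)
    if x.size == 0:
        return []
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    if threshold is None:
        lo, hi = float(x.min()), float(x.max())
        if lo == hi:
            return []
        threshold = 0.5 * (lo + hi)
    crossings = np.nonzero((x[:-1] < threshold) & (x[1:] >= threshold))[0] + 1
    gap = int(round(min_gap * sample_rate))
    accepted: list[int] = []
    for k in crossings:
        if not accepted or k - accepted[-1] >= gap:
            accepted.append(int(k))
    return accepted


def segment(recording, protocol, pre: float = 0.05, post: float = 0.5,
            trig_delay: float | None = None, threshold: float | None = None,
            min_gap: float | None = None,
            voltage_channel: str = "voltage") -> list[Epoch]:
    """Cut the voltage trace into per-stimulus epochs.

    Triggers are detected on the trigger channel and matched ordinally
    to the protocol's events; the stimulus onset is the trigger index
    plus ``trig_delay`` (defaulting to the protocol's).  Epochs whose
    window would exceed the recording bounds are excluded with a
    :class:`TruncatedEpochWarning`.

    Raises :class:`TriggerCountError` (reporting both counts) when the
    number of detected triggers differs from the number of events.
    """
    sr = recording.sample_rate
    if min_gap is None:
        min_gap = protocol.inter_stimulus_interval / 2.0
    if trig_delay is None:
        trig_delay = protocol.trig_delay
    triggers = detect_triggers(recording.channels["trigger"], sr,
                               threshold=threshold, min_gap=min_gap)
    events = protocol.events
    if len(triggers) != len(events):
        raise TriggerCountError(
            f"detected {len(triggers)} triggers but the protocol has "
            f"{len(events)} events"
        )
    voltage = np.asarray(recording.channels[voltage_channel], dtype=float)
    pre_n = int(round(pre * sr))
    post_n = int(round(post * sr))
    delay_n = int(round(trig_delay * sr))
    out: list[Epoch] = []
    trial_counts: dict[str, int] = {}
    for trig, ev in zip(triggers, events):
        onset = trig + delay_n
        lo, hi = onset - pre_n, onset + post_n
        trial = trial_counts.get(ev.pattern_id, 0)
        trial_counts[ev.pattern_id] = trial + 1
        if lo < 0 or hi > len(voltage):
            warnings.warn(
                f"epoch for event {ev.index} ({ev.pattern_id}) exceeds the "
                "recording bounds; excluded as truncated",
                TruncatedEpochWarning, stacklevel=2)
            continue
        out.append(Epoch(pattern_id=ev.pattern_id, condition=ev.condition,
                         trial_index=trial, samples=voltage[lo:hi].copy(),
                         onset_index=pre_n, sample_rate=sr))
    return out


def save_epochs(epochs, path) -> None:
    """Write epochs as an HDF5 archive: stacked slices plus a JSON index."""
    epochs = list(epochs)
    if not epochs:
        raise ValueError("no epochs to save")
    lengths = {len(e.samples) for e in epochs}
    with h5py.File(path, "w") as f:
        if len(lengths) == 1:
            f.create_dataset("samples", data=np.stack([e.samples for e in epochs]))
        else:  # ragged: one dataset per epoch
            g = f.create_group("samples_ragged")
            for i, e in enumerate(epochs):
                g.create_dataset(str(i), data=e.samples)
        index = [{"pattern_id": e.pattern_id, "condition": e.condition,
                  "trial_index": e.trial_index, "onset_index": e.onset_index,
                  "sample_rate": e.sample_rate} for e in epochs]
        f.attrs["index"] = json.dumps(index)


def load_epochs(path) -> list:
    with h5py.File(path, "r") as f:
        index = json.loads(f.attrs["index"])
        if "samples" in f:
            stack = f["samples"][...]
            slices = [stack[i] for i in range(len(index))]
        else:
            g = f["samples_ragged"]
            slices = [g[str(i)][...] for i in range(len(index))]
    return [Epoch(samples=s, **rec) for rec, s in zip(index, slices)]
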