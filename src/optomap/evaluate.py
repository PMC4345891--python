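"""Per-epoch response evaluation, artifact rejection and aggregation.

The default "heat" statistic is the maximum depolarization: the
difference between the peak membrane potential inside a user-specified
response window after stimulus onset and the mean membrane potential
over a baseline window immediately before onset.  An optional clip
caps the reported heat so that action potentials do not dwarf
subthreshold responses on a map (a 30 mV cap is the conventional
presentation level).

Evaluators are registered by name with an :class:`EvaluatorSpec` whose
ordered parameter descriptors can be queried before invocation — the
contract that lets front-ends build parameter forms and lets users plug
in custom statistics (latency, rise time, ...).

Epochs contaminated by *spontaneous* action potentials are rejected:
an epoch is discarded when a spike whose onset precedes the stimulus
overlaps the response window, or when any spike falls inside the
baseline window.  Spikes evoked by the stimulus itself (onset after
stimulus onset) do not trigger rejection.

Undefined results (flat traces, zero surviving trials) are reported as
``nan`` rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParamDescriptor",
    "EvaluatorSpec",
    "HeatResult",
    "register_evaluator",
    "get_evaluator",
    "list_evaluators",
    "baseline",
    "heat_max_depolarization",
    "latency_evaluator",
    "rise_time_evaluator",
    "detect_spikes",
    "reject_epoch",
    "aggregate",
    "integration_index",
    "clip_heat",
]


# ---------------------------------------------------------------------------
# Evaluator registry
# ---------------------------------------------------------------------------

@dataclass
class ParamDescriptor:
    name: str
    type: type
    default: object = None
    units: str = ""
    required: bool = False


@dataclass
class EvaluatorSpec:
    """A named evaluator mapping ``(epoch, **params) -> scalar`` with
    queryable, ordered parameter descriptors."""

    name: str
    parameters: list
    func: object
    units: str = "mV"

    def defaults(self) -> dict:
        return {p.name: p.default for p in self.parameters if not p.required}

    def __call__(self, epoch, **params):
        merged = self.defaults()
        merged.update(params)
        missing = [p.name for p in self.parameters
                   if p.required and p.name not in merged]
        if missing:
            raise ValueError(f"evaluator {self.name!r} missing required "
                             f"parameter(s): {missing}")
        return self.func(epoch, **merged)


_REGISTRY: dict[str, EvaluatorSpec] = {}


def register_evaluator(spec: EvaluatorSpec, overwrite: bool = False) -> EvaluatorSpec:
    if spec.name in _REGISTRY and not overwrite:
        raise ValueError(f"evaluator {spec.name!r} already registered")
    _REGISTRY[spec.name] = spec
    return spec


def get_evaluator(name: str) -> EvaluatorSpec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown evaluator {name!r}; registered evaluators: "
            f"{sorted(_REGISTRY)}"
        ) from None


def list_evaluators() -> list[str]:
    return sorted(_REGISTRY)


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def clip_heat(value: float, clip: float | None) -> float:
    """Cap a heat value at ``clip`` (no-op when clip is None).  The
    same rule is used by the renderer so map and statistic agree."""
    if clip is None or math.isnan(value):
        return value
    return min(value, clip)


def _window_samples(epoch, window_s: float) -> int:
    return int(round(window_s * epoch.sample_rate))


def baseline(epoch, baseline_window: float = 0.05) -> float:
    """Mean membrane potential over ``[onset - baseline_window, onset)``."""
    n = _window_samples(epoch, baseline_window)
    if n < 1:
        raise ValueError("baseline window contains zero samples")
    if n > epoch.onset_index:
        raise ValueError(
            f"baseline window ({baseline_window}s = {n} samples) exceeds the "
            f"pre-stimulus span ({epoch.onset_index} samples)"
        )
    return float(np.mean(epoch.samples[epoch.onset_index - n:epoch.onset_index]))


def _response(epoch, response_window: float) -> np.ndarray:
    m = _window_samples(epoch, response_window)
    if m < 1:
        raise ValueError("response window contains zero samples")
    lo = epoch.onset_index
    if lo + m > len(epoch.samples):
        raise ValueError(
            f"response window ({response_window}s) exceeds the post-stimulus span"
        )
    return epoch.samples[lo:lo + m]


def heat_max_depolarization(epoch, response_window: float = 0.1,
                            baseline_window: float = 0.05,
                            clip: float | None = None) -> float:
    """Peak depolarization: max(V) over the response window minus the
    pre-stimulus baseline, optionally capped at ``clip`` mV."""
    base = baseline(epoch, baseline_window)
    raw = float(np.max(_response(epoch, response_window))) - base
    return clip_heat(raw, clip)


def _interp_crossing(rel: np.ndarray, target: float, sr: float) -> float:
    """First time (ms) the trace ``rel`` reaches ``target``, linearly
    interpolated between samples; assumes rel[i] >= target for some i."""
    idx = int(np.nonzero(rel >= target)[0][0])
    if idx == 0:
        return 0.0
    lo, hi = rel[idx - 1], rel[idx]
    frac = 0.0 if hi == lo else (target - lo) / (hi - lo)
    return (idx - 1 + frac) / sr * 1000.0


def latency_evaluator(epoch, response_window: float = 0.1,
                      fraction: float = 0.5,
                      baseline_window: float = 0.05) -> float:
    """Time (ms) from onset until the depolarization first reaches
    ``fraction`` of its peak above baseline; ``nan`` when the epoch
    never depolarizes."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    base = baseline(epoch, baseline_window)
    rel = _response(epoch, response_window) - base
    peak = float(rel.max())
    if peak <= 0:
        return float("nan")
    return _interp_crossing(rel, fraction * peak, epoch.sample_rate)


def rise_time_evaluator(epoch, response_window: float = 0.1,
                        baseline_window: float = 0.05) -> float:
    """10%-to-90% rise time (ms) of the peak depolarization above
    baseline, linearly interpolated; ``nan`` when undefined."""
    base = baseline(epoch, baseline_window)
    rel = _response(epoch, response_window) - base
    peak = float(rel.max())
    if peak <= 0:
        return float("nan")
    t10 = _interp_crossing(rel, 0.1 * peak, epoch.sample_rate)
    t90 = _interp_crossing(rel, 0.9 * peak, epoch.sample_rate)
    return t90 - t10


# ---------------------------------------------------------------------------
# Spike detection and epoch rejection
# ---------------------------------------------------------------------------

def detect_spikes(trace, sample_rate: float, amp_threshold: float = -20.0,
                  slope_threshold: float = 20.0) -> list[tuple[int, int]]:
    """Detect action potentials in a voltage trace (mV).

    A spike starts at an upward crossing of ``amp_threshold`` whose
    instantaneous slope is at least ``slope_threshold`` (mV/ms) and
    spans until the voltage falls back below the amplitude threshold.
    Returns ``(onset_idx, end_idx)`` pairs with ``end_idx`` exclusive.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 2:
        return []
    slope = np.diff(x) * sample_rate / 1000.0  # mV/ms
    rising = (x[:-1] < amp_threshold) & (x[1:] >= amp_threshold) \
        & (slope >= slope_threshold)
    onsets = np.nonzero(rising)[0] + 1
    spikes: list[tuple[int, int]] = []
    last_end = -1
    for k in onsets:
        if k < last_end:
            continue
        below = np.nonzero(x[k:] < amp_threshold)[0]
        end = int(k + below[0]) if below.size else len(x)
        spikes.append((int(k), end))
        last_end = end
    return spikes


def reject_epoch(epoch, response_window: float = 0.1,
                 baseline_window: float = 0.05,
                 spike_params: dict | None = None,
                 check_overlap: bool = True,
                 check_baseline: bool = True) -> tuple[bool, str]:
    """Decide whether an epoch is contaminated by spontaneous spikes.

    Returns ``(keep, reason)``.  Rejected when a spike that *starts
    before stimulus onset* overlaps the response window, or when any
    spike occurs inside the baseline window; either sub-rule can be
    toggled off.  Spikes evoked after onset never cause rejection.
    """
    spike_params = spike_params or {}
    spikes = detect_spikes(epoch.samples, epoch.sample_rate, **spike_params)
    onset = epoch.onset_index
    resp_end = onset + _window_samples(epoch, response_window)
    base_start = onset - _window_samples(epoch, baseline_window)
    for s0, s1 in spikes:
        if check_overlap and s0 < onset and s1 > onset and s0 < resp_end:
            return False, "spontaneous spike overlaps stimulation"
        if check_baseline and s0 < onset and s1 > base_start:
            return False, "spike in baseline window"
    return True, ""


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class HeatResult:
    """Aggregated response for one pattern.

    ``heat`` is the mean of the surviving per-trial values (``nan``
    when every trial was rejected); per-trial values and the mean
    waveform are both retained so either view can be reproduced.
    """

    pattern_id: str
    heat: float
    n_trials: int
    n_rejected: int
    trial_values: list = field(default_factory=list)
    rejected_reasons: list = field(default_factory=list)
    evaluator: str = "max_depolarization"
    params: dict = field(default_factory=dict)
    mean_waveform: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "pattern_id": self.pattern_id,
            "heat": None if math.isnan(self.heat) else self.heat,
            "n_trials": self.n_trials,
            "n_rejected": self.n_rejected,
            "trial_values": list(self.trial_values),
            "rejected_reasons": list(self.rejected_reasons),
            "evaluator": self.evaluator,
            "params": self.params,
        }


def aggregate(epochs, evaluator: str = "max_depolarization",
              params: dict | None = None, reject: bool = True,
              reject_params: dict | None = None,
              group_by: str = "pattern_id") -> list[HeatResult]:
    """Group epochs, apply rejection, evaluate per trial, and average.

    ``group_by`` is ``pattern_id`` (heat mapping) or ``condition``
    (paired/integration batteries).  Trials are conserved:
    ``n_trials + n_rejected`` equals the number of epochs per group.
    """
    epochs = list(epochs)
    params = dict(params or {})
    reject_params = dict(reject_params or {})
    spec = get_evaluator(evaluator)
    if epochs:
        rates = {e.sample_rate for e in epochs}
        if len(rates) > 1:
            raise ValueError(f"epochs mix sample rates: {sorted(rates)}")
    groups: dict[str, list] = {}
    for e in epochs:
        groups.setdefault(getattr(e, group_by), []).append(e)
    results = []
    for key, group in groups.items():
        values, reasons, kept = [], [], []
        for e in group:
            if reject:
                keep, reason = reject_epoch(e, **reject_params)
                if not keep:
                    reasons.append(reason)
                    continue
            values.append(float(spec(e, **params)))
            kept.append(e)
        heat = float(np.mean(values)) if values else float("nan")
        mean_wf = (np.mean([e.samples for e in kept], axis=0)
                   if kept and len({len(e.samples) for e in kept}) == 1 else None)
        results.append(HeatResult(pattern_id=key, heat=heat,
                                  n_trials=len(values),
                                  n_rejected=len(group) - len(values),
                                  trial_values=values,
                                  rejected_reasons=reasons,
                                  evaluator=evaluator, params=params,
                                  mean_waveform=mean_wf))
    return results


def integration_index(heat_a: float, heat_b: float, heat_ab: float) -> float:
    """Summation nonlinearity: ``heat_AB - (heat_A + heat_B)`` in mV.

    Positive values indicate supralinear summation (the combined
    stimulus depolarizes more than the sum of its parts); zero is
    linear summation; ``nan`` propagates undefined inputs.
    """
    if any(math.isnan(v) for v in (heat_a, heat_b, heat_ab)):
        return float("nan")
    return heat_ab - (heat_a + heat_b)


# ---------------------------------------------------------------------------
# Built-in registry entries
# ---------------------------------------------------------------------------

register_evaluator(EvaluatorSpec(
    name="max_depolarization",
    parameters=[
        ParamDescriptor("response_window", float, 0.1, "s"),
        ParamDescriptor("baseline_window", float, 0.05, "s"),
        ParamDescriptor("clip", float, None, "mV"),
    ],
    func=heat_max_depolarization,
    units="mV",
))

register_evaluator(EvaluatorSpec(
    name="latency",
    parameters=[
        ParamDescriptor("response_window", float, 0.1, "s"),
        ParamDescriptor("fraction", float, 0.5, ""),
        ParamDescriptor("baseline_window", float, 0.05, "s"),
    ],
    func=latency_evaluator,
    units="ms",
))

register_evaluator(EvaluatorSpec(
    name="rise_time",
    parameters=[
        ParamDescriptor("response_window", float, 0.1, "s"),
        ParamDescriptor("baseline_window", float, 0.05, "s"),
    ],
    func=rise_time_evaluator,
    units="ms",
))
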