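"""Stimulation protocols: explicit trigger/exposure timelines.

A protocol is an ordered list of :class:`StimEvent`, each naming the
pattern to project, the trigger time (the TTL pulse that precedes the
exposure), the exposure onset (``trigger + trig_delay``) and the
exposure duration.  Three builders cover the common experiments:

* :func:`build_autostim` — stimulate each pattern in the list, in order
  or in a seeded randomized order, ``repeats`` times;
* :func:`build_pairedstim` — two patterns per trial with a fixed
  latency between their onsets;
* :func:`build_integration_battery` — each of two patterns alone plus
  the grouped union, per repeat, for summation/integration analysis.

Times are in seconds.  The inter-stimulus interval (ISI) is defined
onset-to-onset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "StimEvent",
    "Protocol",
    "build_autostim",
    "build_pairedstim",
    "build_integration_battery",
    "combined_pattern_id",
]


@dataclass
class StimEvent:
    index: int
    pattern_id: str
    trigger_time: float
    onset_time: float
    exposure: float
    condition: str = "stim"


@dataclass
class Protocol:
    mode: str
    events: list
    inter_stimulus_interval: float
    trig_delay: float = 0.0
    repeats: int = 1
    randomize: bool = False
    seed: int = 0
    paired_latency: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def pattern_ids(self) -> list[str]:
        """Distinct pattern ids, in first-appearance order."""
        seen = []
        for ev in self.events:
            if ev.pattern_id not in seen:
                seen.append(ev.pattern_id)
        return seen

    @property
    def end_time(self) -> float:
        return max(ev.onset_time + ev.exposure for ev in self.events)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        d = dict(d)
        d["events"] = [StimEvent(**ev) for ev in d["events"]]
        return cls(**d)

    @classmethod
    def from_json(cls, source) -> "Protocol":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


def _fisher_yates(items: list, rng: np.random.Generator) -> list:
    """In-place-style Fisher–Yates shuffle returning a new list."""
    out = list(items)
    for i in range(len(out) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        out[i], out[j] = out[j], out[i]
    return out


def _autolog(log, text: str) -> None:
    if log is not None:
        from .report import log_append

        log_append(log, text, source="auto")


def build_autostim(pattern_ids, exposure: float = 0.02, isi: float = 0.2,
                   repeats: int = 1, randomize: bool = False, seed: int = 0,
                   trig_delay: float = 0.0, start: float = 0.5,
                   log=None) -> Protocol:
    """Sequential single-pattern stimulation of every pattern in the list.

    With ``randomize=True`` the pattern order is shuffled independently
    for every repeat with a seeded Fisher–Yates; the realized order is
    recorded in ``metadata['order']`` so the randomization can always
    be inverted offline.
    """
    pattern_ids = list(pattern_ids)
    if not pattern_ids:
        raise ValueError("at least one pattern is required")
    if not exposure > 0:
        raise ValueError("exposure must be positive")
    if isi < exposure:
        raise ValueError(
            f"isi ({isi}) < exposure ({exposure}): exposures would overlap"
        )
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if trig_delay < 0:
        raise ValueError("trig_delay must be >= 0")
    rng = np.random.default_rng(seed)
    order = []
    events = []
    k = 0
    for _ in range(repeats):
        seq = _fisher_yates(pattern_ids, rng) if randomize else list(pattern_ids)
        order.append(seq)
        for pid in seq:
            trigger = start + k * isi
            events.append(StimEvent(index=k, pattern_id=pid,
                                    trigger_time=trigger,
                                    onset_time=trigger + trig_delay,
                                    exposure=exposure))
            k += 1
    proto = Protocol(mode="autostim", events=events,
                     inter_stimulus_interval=isi, trig_delay=trig_delay,
                     repeats=repeats, randomize=randomize, seed=seed,
                     metadata={"order": order})
    _autolog(log, f"build_autostim: {len(pattern_ids)} patterns, "
                  f"repeats={repeats}, randomize={randomize}, seed={seed}")
    return proto


def build_pairedstim(pattern_a: str, pattern_b: str, paired_latency: float,
                     exposure: float = 0.02, isi: float = 0.5,
                     repeats: int = 1, seed: int = 0, trig_delay: float = 0.0,
                     start: float = 0.5, log=None) -> Protocol:
    """Paired stimulation: pattern A at t, pattern B at t + latency.

    The two patterns may be identical, independent or partially
    overlapping; a latency shorter than the exposure yields
    deliberately overlapping exposures within a trial.
    """
    if paired_latency < 0:
        raise ValueError("paired_latency must be >= 0")
    if not exposure > 0:
        raise ValueError("exposure must be positive")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    events = []
    for r in range(repeats):
        t_a = start + r * isi
        for offset, (pid, cond) in zip(
                (0.0, paired_latency), ((pattern_a, "A"), (pattern_b, "B"))):
            trigger = t_a + offset
            events.append(StimEvent(index=len(events), pattern_id=pid,
                                    trigger_time=trigger,
                                    onset_time=trigger + trig_delay,
                                    exposure=exposure, condition=cond))
    proto = Protocol(mode="pairedstim", events=events,
                     inter_stimulus_interval=isi, trig_delay=trig_delay,
                     repeats=repeats, randomize=False, seed=seed,
                     paired_latency=paired_latency)
    _autolog(log, f"build_pairedstim: {pattern_a!r}+{pattern_b!r}, "
                  f"latency={paired_latency}, repeats={repeats}")
    return proto


def combined_pattern_id(pattern_a: str, pattern_b: str) -> str:
    """Conventional id of the grouped A-union-B pattern mask."""
    return f"{pattern_a}+{pattern_b}"


def build_integration_battery(pattern_a: str, pattern_b: str,
                              exposure: float = 0.02, isi: float = 0.2,
                              repeats: int = 3, randomize: bool = True,
                              seed: int = 0, trig_delay: float = 0.0,
                              start: float = 0.5, log=None) -> Protocol:
    """Summation battery: per repeat, A alone, B alone and A+B together.

    The grouped condition uses the pattern id from
    :func:`combined_pattern_id`; the corresponding OR-ed mask must be
    supplied at simulation/export time.  Condition labels ``A``, ``B``
    and ``AB`` are recorded on each event and in
    ``metadata['conditions']``.
    """
    if pattern_a == pattern_b:
        raise ValueError("pattern_a and pattern_b must differ")
    if not exposure > 0:
        raise ValueError("exposure must be positive")
    if isi < exposure:
        raise ValueError(f"isi ({isi}) < exposure ({exposure})")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    pid_ab = combined_pattern_id(pattern_a, pattern_b)
    conditions = [(pattern_a, "A"), (pattern_b, "B"), (pid_ab, "AB")]
    rng = np.random.default_rng(seed)
    events = []
    realized = []
    k = 0
    for _ in range(repeats):
        seq = _fisher_yates(conditions, rng) if randomize else list(conditions)
        realized.append([cond for _, cond in seq])
        for pid, cond in seq:
            trigger = start + k * isi
            events.append(StimEvent(index=k, pattern_id=pid,
                                    trigger_time=trigger,
                                    onset_time=trigger + trig_delay,
                                    exposure=exposure, condition=cond))
            k += 1
    proto = Protocol(mode="autostim", events=events,
                     inter_stimulus_interval=isi, trig_delay=trig_delay,
                     repeats=repeats, randomize=randomize, seed=seed,
                     metadata={"conditions": realized,
                               "battery": {"A": pattern_a, "B": pattern_b,
                                           "AB": pid_ab}})
    _autolog(log, f"build_integration_battery: {pattern_a!r}/{pattern_b!r}, "
                  f"repeats={repeats}, seed={seed}")
    return proto
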