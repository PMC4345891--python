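"""Plugging a custom response statistic into the evaluator registry.

Evaluators declare their parameters up front, so tools can query what
to pass before invoking them.  Here a charge-transfer-like statistic
(area under the depolarization) is registered and used alongside the
built-in latency evaluator on the same epochs.
"""

import numpy as np

import optomap as om
from optomap.evaluate import EvaluatorSpec, ParamDescriptor, get_evaluator

mask = om.PatternMask("full", np.ones((20, 20), dtype=bool))
protocol = om.build_autostim(["full"], exposure=0.05, isi=0.3, repeats=3)
cell = om.CellModel(noise_sd=0.2)
rec = om.simulate(protocol, [mask], cell, 10_000, seed=3)
eps = om.segment(rec, protocol, pre=0.05, post=0.2)


def depolarization_area(epoch, response_window, baseline_window):
    base = om.baseline(epoch, baseline_window)
    n = int(response_window * epoch.sample_rate)
    rel = epoch.samples[epoch.onset_index:epoch.onset_index + n] - base
    return float(np.trapezoid(rel) / epoch.sample_rate * 1000.0)  # mV*ms


om.register_evaluator(EvaluatorSpec(
    name="depolarization_area",
    parameters=[ParamDescriptor("response_window", float, 0.1, "s"),
                ParamDescriptor("baseline_window", float, 0.05, "s")],
    func=depolarization_area,
    units="mV*ms",
))

spec = get_evaluator("depolarization_area")
print("registered evaluator:", spec.name)
for p in spec.parameters:
    print(f"  param {p.name} ({p.units or 'unitless'}), default {p.default}")

for name in ("max_depolarization", "latency", "depolarization_area"):
    (res,) = om.aggregate(eps, evaluator=name)
    print(f"{name}: {res.heat:.2f} {get_evaluator(name).units} "
          f"(mean of {res.n_trials} trials)")

# max_depolarization is the peak above baseline; latency is the time to
# half-peak; the custom statistic integrates the depolarization over
# the response window -- all interchangeable on the same epochs.
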