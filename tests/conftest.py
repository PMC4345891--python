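import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import optomap as om
from optomap.epochs import Epoch

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def identity_transform():
    return om.CalibrationTransform.identity()


@pytest.fixture
def make_epoch():
    """Factory for synthetic epochs with explicit samples."""

    def _make(samples, onset_index=500, sample_rate=10_000.0,
              pattern_id="p", condition="stim", trial_index=0):
        return Epoch(pattern_id=pattern_id, condition=condition,
                     trial_index=trial_index,
                     samples=np.asarray(samples, dtype=float),
                     onset_index=onset_index, sample_rate=sample_rate)

    return _make


@pytest.fixture(scope="session")
def small_experiment():
    """A complete desk-scale mapping experiment: 3x3 grid over a 30x30
    field, randomized sequence with 2 repeats, simulated with a
    sensitivity blob in the center cell, segmented and aggregated."""
    grid = om.grid_create((0, 0, 30, 30), 3, 3)
    transform = om.CalibrationTransform.identity()
    dmd_shape = (30, 30)
    masks = {m.id: m for m in grid.export(
        [c.id for c in grid.leaves()], grouped=False,
        transform=transform, dmd_shape=dmd_shape)}
    protocol = om.build_autostim(list(masks), exposure=0.02, isi=0.2,
                                 repeats=2, randomize=True, seed=11)
    sens = om.make_sensitivity_map("gaussian_blob",
                                   {"center": (15.0, 15.0), "sigma": 4.0},
                                   dmd_shape)
    cell = om.CellModel(sensitivity=sens, noise_sd=0.3)
    recording = om.simulate(protocol, masks, cell, sample_rate=10_000.0, seed=7)
    eps = om.segment(recording, protocol, pre=0.05, post=0.15)
    results = om.aggregate(eps, params={"response_window": 0.1})
    from types import SimpleNamespace as ns
    return ns(grid=grid, transform=transform, dmd_shape=dmd_shape,
              masks=masks, protocol=protocol, cell=cell,
              recording=recording, epochs=eps, results=results)
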