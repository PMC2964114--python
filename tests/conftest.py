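import numpy as np
import pytest

import htsaxs as hx
from htsaxs.devices import RobotMethod


@pytest.fixture
def quiet_config():
    """Noise-free, bubble-free bench so reductions are exactly checkable."""
    cfg = hx.SimulationConfig()
    cfg.detector.readout_noise_sd = 0.0
    cfg.detector.readout_offset = 0.0
    cfg.robot.p_bubble = 0.0
    return cfg


@pytest.fixture
def loaded_beamline(quiet_config):
    """A bench with a sample already in the cell (well A1)."""
    bl = hx.Beamline(quiet_config, seed=0)
    bl.robot.execute(RobotMethod.LOAD_SAMPLE, well=hx.parse_well("A1"))
    return bl


def make_plan(n_wells=4, buffer_first=True, wash_every=None, wash_last=False,
              exposure_times=(0.5, 5.0, 0.5), prefix="lys", directory="."):
    """Small screening plan over the first n_wells plate positions."""
    wells = hx.all_wells()[:n_wells]
    rows = []
    for i, w in enumerate(wells):
        wash = wash_last and i == n_wells - 1
        if wash_every is not None:
            wash = (i + 1) % wash_every == 0
        rows.append(
            hx.PlanRow(w, selected=True, is_buffer=buffer_first and i % 4 == 0,
                       wash_after=wash)
        )
    return hx.ScreeningPlan(rows=rows, exposure_times=exposure_times, prefix=prefix,
                            directory=directory)


@pytest.fixture
def plan_factory():
    return make_plan


def brute_force_variance(values):
    """Two-pass population variance, independent of the implementation."""
    vals = [float(v) for v in np.asarray(values).ravel()]
    mean = sum(vals) / len(vals)
    return sum((v - mean) ** 2 for v in vals) / len(vals)
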