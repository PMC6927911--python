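import pytest

from nanosip import (
    ExperimentConfig,
    SimulationConfig,
    SubstratePool,
    simulate_community,
)
from nanosip.io import ControlSource, write_roi_table

SPOT_POOLS = {
    "C": SubstratePool("C", 2.62e-3, 13.1, label="bicarbonate"),
    "N": SubstratePool("N", 50e-9, 98.0, label="amino acids"),
}


@pytest.fixture
def spot_pools():
    return dict(SPOT_POOLS)


@pytest.fixture
def sim_dataset():
    """A small simulated community under SPOT-like study conditions."""
    return simulate_community(SimulationConfig(seed=11, n_cells=200))


@pytest.fixture
def screen_setup(tmp_path, sim_dataset, spot_pools):
    """Simulated ROI + control files plus a matching experiment config."""
    roi = tmp_path / "roi.csv"
    control = tmp_path / "control.csv"
    write_roi_table(sim_dataset.roi_frame(), roi)
    write_roi_table(sim_dataset.control_frame(), control)
    config = ExperimentConfig(
        site="SPOT-sim",
        pools=spot_pools,
        control=ControlSource(file=str(control)),
        seed=11,
    )
    return config, roi, sim_dataset
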