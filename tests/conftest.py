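import numpy as np
import pytest

from npmhub.docking import DockingConfig, EnergyBreakdown, PeptideModel, Pose
from npmhub.synthetic_data import ToyReceptorSpec, make_toy_receptor, presets


@pytest.fixture(scope="session")
def toy_receptor():
    return make_toy_receptor(ToyReceptorSpec())


@pytest.fixture(scope="session")
def preset_table():
    return presets()


@pytest.fixture
def wt_preset(preset_table):
    return preset_table["wt_fbw7g"]


def make_pose(sequence: str, dofs=None, parent_start: int = 1) -> Pose:
    """Pose with zero energy bookkeeping, for tests that only need geometry."""
    model = PeptideModel(sequence, parent_start)
    if dofs is None:
        dofs = np.zeros(model.n_dof)
    dofs = np.asarray(dofs, dtype=float)
    return Pose(model=model, dofs=dofs, coords=model.coordinates(dofs),
                energy=EnergyBreakdown(0.0, 0.0), provenance={"id": 0})


@pytest.fixture
def small_dock_config():
    return DockingConfig(runs=4, anneal_steps=120, template_anneal_steps=80,
                         max_combos=4, full_template_count=10, seed=0)
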