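import numpy as np
import pytest

from tumorvasc import dosrecon, synthkit


@pytest.fixture(scope="session")
def extinction_table():
    return dosrecon.ExtinctionTable.default()


@pytest.fixture(scope="session")
def default_cohort():
    """The default two-group study dataset (deterministic)."""
    return synthkit.simulate_cohort(synthkit.CohortDesign())


@pytest.fixture(scope="session")
def trained_dos_model():
    """A small (fast) trained neural inverse shared across DOS tests."""
    feats, labels = dosrecon.make_training_set(n=6000, noise_sd=0.01, seed=11)
    return dosrecon.train_inverse_model(feats, labels, seed=11)


@pytest.fixture(scope="session")
def point_scan():
    """Raw scan of a single point absorber at known position."""
    shape = (64, 6, 95)
    amap = np.zeros(shape)
    amap[30, 3, 49] = 1.0  # x=610 um, z=990 um at 20 um voxels
    phantom = synthkit.VesselPhantom(
        absorption_map=amap,
        voxel_size=20.0,
        centerlines=[],
        true_volume_fraction=100.0 / amap.size,
        domain_size=(1.28, 0.12, 1.9),
    )
    config = synthkit.ScanConfig(sound_speed_true=1500.0, field_of_view=(1.28, 0.12, 1.9))
    return synthkit.simulate_oa_scan(phantom, config), (30, 3, 49)
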