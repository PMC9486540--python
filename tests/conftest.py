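import numpy as np
import pytest

from mgstrat import (CellLabelMap, PhenotypeParams, SimulationConfig,
                     detect_nuclei, generate_field, segment_cells)


@pytest.fixture(scope="session")
def noiseless_config():
    """Small noiseless field: exact ground truth for detector validation."""
    return SimulationConfig(seed=11, image_size=256, n_cells_per_field=30,
                            read_noise_sd=0.0, shot_noise=False)


@pytest.fixture(scope="session")
def noisy_config():
    """Same field at the generator's default camera-noise settings."""
    return SimulationConfig(seed=11, image_size=256, n_cells_per_field=30)


@pytest.fixture(scope="session")
def cat1():
    return PhenotypeParams.archetype("cat1")


@pytest.fixture(scope="session")
def segmented_noiseless(noiseless_config, cat1):
    """(field, truth, cells) for one noiseless NHS-only field, segmented."""
    field, truth = generate_field(noiseless_config, cat1, "NHS_only")
    nuclei = detect_nuclei(field)
    cells = segment_cells(field, nuclei)
    return field, truth, cells


@pytest.fixture()
def toy_cells():
    """A 3-cell label map on a 12x12 grid for spot bookkeeping tests."""
    labels = np.zeros((12, 12), dtype=np.int32)
    labels[0:4, :] = 1
    labels[4:8, :] = 2
    labels[8:12, :] = 3
    return CellLabelMap(nuclei_labels=labels.copy(), cell_labels=labels)
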