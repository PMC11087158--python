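import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from oardose.core_grid import DoseGrid, GridHeader, StructureMask


@pytest.fixture
def header():
    return GridHeader(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240425)


def make_dose(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    values = np.asarray(values, dtype=float)
    return DoseGrid(values, GridHeader(values.shape, spacing, origin))


def make_mask(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    values = np.asarray(values, dtype=bool)
    return StructureMask(values, GridHeader(values.shape, spacing, origin))


def cube_mask(shape, lo, hi, spacing=(1.0, 1.0, 1.0)):
    """Axis-aligned solid cube [lo, hi) in voxel indices."""
    occ = np.zeros(shape, dtype=bool)
    occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return make_mask(occ, spacing=spacing)
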