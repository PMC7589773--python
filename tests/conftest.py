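import numpy as np
import pytest

from rsmap import (FilterParams, ImagingModel, SyntheticSpec, make_toy_model,
                   synthesize_potential)
from rsmap.simulate import _grid_template


@pytest.fixture(scope="session")
def helix_model():
    """A 16-residue helical toy model with hydrogens, waters and B-factors."""
    return make_toy_model(SyntheticSpec(n_residues=16, fold="helix", seed=7))


@pytest.fixture(scope="session")
def helix_selfmap(helix_model):
    """Noise-free potential of the helix model filtered at d_half = 1.5 Å."""
    spec = SyntheticSpec(n_residues=16, fold="helix", seed=7)
    grid = _grid_template(helix_model, spec)
    im = ImagingModel(filt=FilterParams(1.5, 5))
    return synthesize_potential(helix_model, grid, im), im


@pytest.fixture(scope="session")
def small_model():
    """A minimal 6-residue coil model without waters (fast geometry checks)."""
    return make_toy_model(SyntheticSpec(n_residues=6, fold="coil",
                                        n_waters=0, seed=3))
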