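import io

import numpy as np
import pytest

from beescape import LandscapeYear, ModelParams, ResourceLookup, default_lookup


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def lut() -> ResourceLookup:
    return default_lookup()


@pytest.fixture()
def simple_lut() -> ResourceLookup:
    """Minimal lookup with round numbers for hand arithmetic."""
    csv = """\
code,name,coverage_p1,coverage_p2,attract_p1,attract_p2,nesting_quality,is_agricultural
0,bare,0.0,0.0,0.0,0.0,0.0,0
1,crop,0.8,0.0,1.0,1.0,0.5,1
2,meadow,0.5,0.5,2.0,2.0,1.0,0
90,margin,0.1,0.1,1.0,1.0,1.0,0
91,flower_strip,0.0,0.9,0.0,3.0,0.05,1
"""
    return ResourceLookup.from_csv(io.StringIO(csv))


def make_land(landuse, edge_length=None, cell_size=25.0) -> LandscapeYear:
    landuse = np.asarray(landuse)
    if edge_length is None:
        edge_length = np.zeros_like(landuse, dtype=float)
    return LandscapeYear(landuse, np.asarray(edge_length, float), cell_size=cell_size)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
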