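import numpy as np
import pytest
from hypothesis import settings

import pbcwhole as pw

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture
def dodec():
    return pw.rhombic_dodecahedron(1.0)


def pipeline_point_shifts(fixture, **kwargs):
    """Run the pipeline on a fixture and return per-point lattice shifts."""
    result = pw.make_whole_frame(
        fixture.points, fixture.box, resolution=fixture.resolution, **kwargs
    )
    delta = result.points.coords - fixture.points.coords
    shifts = pw.to_fractional(delta, fixture.box)
    rounded = np.round(shifts).astype(int)
    assert np.abs(shifts - rounded).max() < 1e-9, "displacements must be lattice shifts"
    return result, rounded


def assert_global_shift_per_object(point_shifts, oracle, fixture):
    """Pipeline and oracle shifts may differ only by one shift per object."""
    for obj in range(oracle.point_object.max() + 1):
        members = oracle.point_object == obj
        diffs = np.unique(point_shifts[members] - oracle.point_shift[members], axis=0)
        assert len(diffs) == 1, f"object {obj} not reconstructed up to a global shift"
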