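import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

import voxelskel as vs


@pytest.fixture(scope="session")
def cylinder_phantom():
    return vs.make_cylinder(4, 48)


@pytest.fixture(scope="session")
def cylinder_grid(cylinder_phantom):
    return vs.grid_from_phantom(cylinder_phantom)


@pytest.fixture(scope="session")
def cylinder_skeleton(cylinder_grid):
    return vs.thin(cylinder_grid)


@pytest.fixture(scope="session")
def torus_phantom():
    return vs.make_torus(8, 2)


@pytest.fixture(scope="session")
def torus_grid(torus_phantom):
    return vs.grid_from_phantom(torus_phantom)


@pytest.fixture(scope="session")
def torus_skeleton(torus_grid):
    return vs.thin(torus_grid)


@pytest.fixture(scope="session")
def y_phantom():
    return vs.make_y_junction(2.5, 2.0)


@pytest.fixture(scope="session")
def y_skeleton(y_phantom):
    return vs.thin(vs.grid_from_phantom(y_phantom))


@pytest.fixture(scope="session")
def elliptical_suite():
    """Thinned elliptical tubes with known ER, mid-span exposure samples."""
    samples = []
    per_phantom = []
    for a in (2, 3, 4, 6, 8):
        b = 2
        ph = vs.make_elliptical_tube(a, b, 2 * a + 14)
        grid = vs.grid_from_phantom(ph)
        sk = vs.thin(grid)
        zs = sorted(v.index[2] for v in sk.voxels)
        zlo, zhi = zs[0] + 3, zs[-1] - 3
        rows = []
        for v in sk.voxels:
            if zlo <= v.index[2] <= zhi and v.exposure[0] > 0:
                rows.append((v.exposure, a / b))
        samples.extend(rows)
        per_phantom.append((ph, grid, sk, rows))
    return {"samples": samples, "per_phantom": per_phantom}
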