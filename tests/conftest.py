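from __future__ import annotations

import numpy as np
import pytest

from ablapath import (
    Box,
    Ellipsoid,
    PhantomConfig,
    PlanningConfig,
    Sphere,
    VoxelGrid,
    generate_phantom,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Stock 64^3 phantom: offset liver, 10 mm tumor, bone slab + vessel."""
    return generate_phantom(PhantomConfig(seed=1))


def aperture_phantom_config(seed: int = 7) -> PhantomConfig:
    """Liver boxed in by bone walls with a single square window on +x.

    Only rays passing through the window from the +x skin region can reach
    the tumor, so the feasible region's geometry is known analytically.
    """
    walls = []
    t = 6.0  # wall thickness mm
    r = 40.0  # inner half-extent of the bone box
    hole = 14.0  # half-size of the window on the +x face
    walls.append(("bone", Box((-r - t, -r - t, -r - t), (-r, r + t, r + t))))   # -x
    walls.append(("bone", Box((-r, -r - t, -r - t), (r, -r, r + t))))           # -y
    walls.append(("bone", Box((-r, r, -r - t), (r, r + t, r + t))))             # +y
    walls.append(("bone", Box((-r, -r, -r - t), (r, r, -r))))                   # -z
    walls.append(("bone", Box((-r, -r, r), (r, r, r + t))))                     # +z
    # +x face with a (2*hole)^2 window around the axis
    walls.append(("bone", Box((r, -r - t, -r - t), (r + t, -hole, r + t))))
    walls.append(("bone", Box((r, hole, -r - t), (r + t, r + t, r + t))))
    walls.append(("bone", Box((r, -hole, -r - t), (r + t, hole, -hole))))
    walls.append(("bone", Box((r, -hole, hole), (r + t, hole, r + t))))
    # the grid and skin are sized so the bone box (corner radius ~80 mm)
    # sits strictly inside the eroded skin: no wall touches the shell
    return PhantomConfig(
        shape=(88, 88, 88),
        spacing=(2.0, 2.0, 2.0),
        skin=Ellipsoid((0, 0, 0), (84.0, 82.0, 82.0)),
        liver=Ellipsoid((0.0, 0.0, 0.0), (30.0, 26.0, 26.0)),
        tumor=Sphere((6.0, 3.0, 0.0), 9.0),
        obstacles=tuple(walls),
        seed=seed,
    )


@pytest.fixture(scope="session")
def aperture_phantom():
    return generate_phantom(aperture_phantom_config())


@pytest.fixture(scope="session")
def planned_aperture(aperture_phantom):
    """Feasible set of the aperture phantom at a stride that keeps tests fast."""
    from ablapath import plan_feasible_set

    volume, truth = aperture_phantom
    config = PlanningConfig(skin_stride=9, min_capsule_angle_deg=10.0)
    return volume, truth, config, plan_feasible_set(volume, config)


@pytest.fixture
def unit_grid():
    return VoxelGrid(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))
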