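import logging

import numpy as np
import pytest

from oarvar.contours import ContourSlice, Delineation, DelineationSet, Polygon2D
from oarvar.grid import BinaryMask, GridSpec

logging.getLogger("oarvar").setLevel(logging.ERROR)


def square(side=10.0, x0=0.0, y0=0.0):
    return Polygon2D(
        ((x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side))
    )


def prism_delineation(side=10.0, n_slices=5, spacing=2.0, **kw):
    meta = dict(
        patient_id="p1", scan_time="plan", observer_id="o1",
        organ="organ", laterality="left",
    )
    meta.update(kw)
    slices = tuple(
        ContourSlice(z=spacing * k, polygons=(square(side),))
        for k in range(n_slices)
    )
    return Delineation(slice_spacing=spacing, slices=slices, **meta)


def ball_mask(radius, grid=None, center=(0.0, 0.0, 0.0)):
    if grid is None:
        grid = GridSpec((-15.0, -15.0, -15.0), (1.0, 1.0, 1.0), (31, 31, 31))
    xs, ys, zs = (grid.axis_centers(a) for a in range(3))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    occ = (
        (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
        <= radius**2
    )
    return BinaryMask(grid, occ)


@pytest.fixture
def unit_square():
    return Polygon2D(((0, 0), (1, 0), (1, 1), (0, 1)))


@pytest.fixture
def prism():
    return prism_delineation()


@pytest.fixture
def ball_grid():
    return GridSpec((-15.0, -15.0, -15.0), (1.0, 1.0, 1.0), (31, 31, 31))


@pytest.fixture
def concentric_balls(ball_grid):
    return [ball_mask(r, ball_grid) for r in (8.0, 9.0, 10.0, 11.0, 12.0)]


def random_valid_set(rng, n_delineations=3):
    """Randomized valid DelineationSet for round-trip property tests."""
    delins = []
    for i in range(n_delineations):
        spacing = float(rng.choice([1.0, 2.0, 2.5]))
        n_slices = int(rng.integers(1, 5))
        slices = []
        for k in range(n_slices):
            n_poly = int(rng.integers(1, 3))
            polys = []
            for _ in range(n_poly):
                n_v = int(rng.integers(3, 9))
                ang = np.sort(rng.uniform(0, 2 * np.pi, n_v))
                rad = rng.uniform(2, 12, n_v)
                cx, cy = rng.uniform(-30, 30, 2)
                polys.append(
                    Polygon2D(
                        tuple(
                            (cx + r * np.cos(a), cy + r * np.sin(a))
                            for r, a in zip(rad, ang)
                        )
                    )
                )
            slices.append(ContourSlice(z=spacing * k, polygons=tuple(polys)))
        delins.append(
            Delineation(
                patient_id=f"p{i}",
                scan_time="plan" if i % 2 == 0 else "rep",
                observer_id=f"o{i}",
                organ=f"organ{i % 2}",
                laterality=["left", "right", "midline"][i % 3],
                slice_spacing=spacing,
                slices=tuple(slices),
            )
        )
    return DelineationSet(delins, {"note": "random"})
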