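import numpy as np
import pytest
from shapely.geometry import Polygon

import hippostereo as hs
from hippostereo.phantom import _build_regions


def make_animal(v_dg=2.00, v_ca3=3.15, nd_dg=0.0, nd_ca3=0.0, seed=0, group="Con"):
    """Phantom with exact configured region volumes and seeded intensities."""
    regions = _build_regions(v_dg, v_ca3)
    rng = np.random.default_rng(seed)
    markers = {
        "DG": hs.seed_markers(regions["DG"], nd_dg, rng),
        "CA3": hs.seed_markers(regions["CA3"], nd_ca3, rng),
    }
    return hs.AnimalPhantom(
        animal_id="t-01",
        group=group,
        regions=regions,
        markers=markers,
        covariates={"blood_glucose": 100.0, "plasma_cu": 7.3},
    )


def square_stack(side=1.0, n_sections=1, thickness=1.0, origin=(0.0, 0.0)):
    """Stack whose DG profile is a constant axis-aligned square."""
    x0, y0 = origin
    poly = Polygon([(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)])
    solid = hs.ExtrudedPolygon(polygon=poly, z_min=0.0, z_max=n_sections * thickness)
    regions = {"DG": hs.RegionSolid(label="DG", shape=solid)}
    markers = {"DG": hs.MarkerSet(label="DG", points=np.empty((0, 3)), true_intensity=0.0)}
    return hs.SectionStack(regions, markers, thickness, 0.0, n_sections)


@pytest.fixture
def control_animal():
    return make_animal()


@pytest.fixture
def default_params():
    return hs.default_group_parameters()
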