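"""Synthetic animal phantoms with known ground truth.

Every downstream estimator in this package is validated against phantoms:
per-animal 3-D region solids for the dentate gyrus (DG) and CA3 with
closed-form volumes, apoptotic-cell markers seeded as a homogeneous spatial
Poisson process at a known intensity, and per-animal covariates (blood
glucose, plasma Cu) drawn jointly with the region quantities through a
Gaussian copula.  Phantoms are cut into serial coronal slabs the same way a
microtome produces sections, so the Cavalieri and dissector estimators can
be exercised end to end without any external data.

All lengths are in mm, volumes in mm^3, and numerical densities in mm^-3.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping, Sequence

import numpy as np
import shapely
from scipy import stats as _sps
from shapely.geometry import Polygon

GROUPS = ("Con", "Ins", "VitC", "Dia")
REGIONS = ("DG", "CA3")

#: Variable ordering used by the copula correlation matrix.
VARIABLE_ORDER = ("V_DG", "V_CA3", "ND_DG", "ND_CA3", "BG", "Cu")


# ---------------------------------------------------------------------------
# planar profiles (cross sections)
# ---------------------------------------------------------------------------

class EllipseProfile:
    """Axis-aligned elliptical cross-section of an ellipsoid."""

    __slots__ = ("center", "semi_axes")

    def __init__(self, center: tuple[float, float], semi_axes: tuple[float, float]):
        self.center = (float(center[0]), float(center[1]))
        self.semi_axes = (float(semi_axes[0]), float(semi_axes[1]))

    @property
    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]

    @property
    def is_empty(self) -> bool:
        return self.semi_axes[0] <= 0.0 or self.semi_axes[1] <= 0.0

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        (cx, cy), (rx, ry) = self.center, self.semi_axes
        return (cx - rx, cy - ry, cx + rx, cy + ry)

    def contains_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Strict interior test, vectorised over coordinate arrays."""
        (cx, cy), (rx, ry) = self.center, self.semi_axes
        if self.is_empty:
            return np.zeros(np.shape(x), dtype=bool)
        return ((np.asarray(x) - cx) / rx) ** 2 + ((np.asarray(y) - cy) / ry) ** 2 < 1.0

    def contains_box(self, x0: float, y0: float, x1: float, y1: float) -> bool:
        # an ellipse is convex: a rectangle is inside iff its corners are
        xs = np.array([x0, x0, x1, x1])
        ys = np.array([y0, y1, y0, y1])
        return bool(self.contains_xy(xs, ys).all())

    def to_polygon(self, n_vertices: int = 128) -> Polygon:
        t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
        (cx, cy), (rx, ry) = self.center, self.semi_axes
        return Polygon(np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)]))


class PolygonProfile:
    """Polygonal cross-section backed by a shapely geometry."""

    __slots__ = ("polygon",)

    def __init__(self, polygon: Polygon):
        self.polygon = polygon

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    @property
    def is_empty(self) -> bool:
        return self.polygon.is_empty or self.polygon.area <= 0.0

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return tuple(self.polygon.bounds)

    def contains_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return shapely.contains_xy(self.polygon, np.asarray(x), np.asarray(y))

    def contains_box(self, x0: float, y0: float, x1: float, y1: float) -> bool:
        return bool(self.polygon.contains(shapely.box(x0, y0, x1, y1)))

    def to_polygon(self, n_vertices: int = 128) -> Polygon:  # noqa: ARG002
        return self.polygon


Profile = EllipseProfile | PolygonProfile


# ---------------------------------------------------------------------------
# solids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid with semi-axes ``(a, b, c)`` centred at ``center``.

    The c semi-axis runs along z (the rostrocaudal sectioning axis).
    """

    semi_axes: tuple[float, float, float]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0.0:
            raise ValueError(f"degenerate ellipsoid: semi-axes {self.semi_axes}")

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def z_range(self) -> tuple[float, float]:
        c = self.semi_axes[2]
        return (self.center[2] - c, self.center[2] + c)

    def profile_at(self, z: float) -> EllipseProfile | None:
        a, b, c = self.semi_axes
        dz = (z - self.center[2]) / c
        if abs(dz) >= 1.0:
            return None
        s = math.sqrt(1.0 - dz * dz)
        return EllipseProfile((self.center[0], self.center[1]), (a * s, b * s))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        d = (p - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (d ** 2).sum(axis=1) < 1.0

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        r = np.asarray(self.semi_axes)
        return c - r, c + r


@dataclass(frozen=True)
class ExtrudedPolygon:
    """Planar profile polygon extruded along z over ``[z_min, z_max]``."""

    polygon: Polygon
    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        if self.z_max <= self.z_min:
            raise ValueError("degenerate extrusion: non-positive z extent")
        if self.polygon.is_empty or self.polygon.area <= 0.0:
            raise ValueError("degenerate extrusion: empty profile polygon")

    @property
    def volume(self) -> float:
        return float(self.polygon.area) * (self.z_max - self.z_min)

    @property
    def z_range(self) -> tuple[float, float]:
        return (self.z_min, self.z_max)

    def profile_at(self, z: float) -> PolygonProfile | None:
        if self.z_min <= z < self.z_max:
            return PolygonProfile(self.polygon)
        return None

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        in_z = (p[:, 2] >= self.z_min) & (p[:, 2] < self.z_max)
        in_xy = shapely.contains_xy(self.polygon, p[:, 0], p[:, 1])
        return in_z & in_xy

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        x0, y0, x1, y1 = self.polygon.bounds
        return np.array([x0, y0, self.z_min]), np.array([x1, y1, self.z_max])


Solid = Ellipsoid | ExtrudedPolygon


@dataclass(frozen=True)
class RegionSolid:
    """A named anatomical region (DG or CA3) with an analytic solid shape."""

    label: str
    shape: Solid

    def __post_init__(self) -> None:
        if self.label not in REGIONS:
            raise ValueError(f"unknown region label {self.label!r}; expected one of {REGIONS}")


def true_volume(solid: Solid | RegionSolid) -> float:
    """Exact closed-form volume of a region solid.

    Ellipsoid: 4/3*pi*a*b*c.  Extrusion: profile area x z extent.
    """
    shape = solid.shape if isinstance(solid, RegionSolid) else solid
    return shape.volume


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerSet:
    """Apoptotic-cell markers of one region.

    Each cell is reduced to a single unique reference point (its "top"), so
    it belongs to exactly one section slab and dissector counting is
    unambiguous.
    """

    label: str
    points: np.ndarray  # (N, 3) float array, mm
    true_intensity: float  # expected count per mm^3

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "points", pts)
        if self.true_intensity < 0:
            raise ValueError("negative marker intensity")

    def __len__(self) -> int:
        return self.points.shape[0]


def seed_markers(
    solid: Solid | RegionSolid,
    intensity: float,
    seed: int | np.random.Generator,
) -> MarkerSet:
    """Seed a homogeneous Poisson point process inside a region solid.

    The count is Poisson(intensity x true volume); point locations are
    uniform inside the solid (rejection sampling from the bounding box).
    """
    if intensity < 0:
        raise ValueError("negative marker intensity")
    label = solid.label if isinstance(solid, RegionSolid) else "DG"
    shape = solid.shape if isinstance(solid, RegionSolid) else solid
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = int(rng.poisson(intensity * shape.volume))
    lo, hi = shape.bounding_box
    box_vol = float(np.prod(hi - lo))
    accept_rate = max(shape.volume / box_vol, 1e-3)
    chunks: list[np.ndarray] = []
    remaining = n
    while remaining > 0:
        m = int(remaining / accept_rate * 1.2) + 16
        cand = rng.uniform(lo, hi, size=(m, 3))
        good = cand[shape.contains(cand)]
        take = good[:remaining]
        chunks.append(take)
        remaining -= take.shape[0]
    points = np.concatenate(chunks) if chunks else np.empty((0, 3))
    return MarkerSet(label=label, points=points, true_intensity=float(intensity))


# ---------------------------------------------------------------------------
# animals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnimalPhantom:
    """One synthetic animal: two region solids, their markers, covariates."""

    animal_id: str
    group: str
    regions: Mapping[str, RegionSolid]
    markers: Mapping[str, MarkerSet]
    covariates: Mapping[str, float]  # blood_glucose (mg/dL), plasma_cu (ug/dL)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")

    def true_volumes(self) -> dict[str, float]:
        return {r: true_volume(s) for r, s in self.regions.items()}

    def true_intensities(self) -> dict[str, float]:
        return {r: m.true_intensity for r, m in self.markers.items()}


# ---------------------------------------------------------------------------
# sectioning
# ---------------------------------------------------------------------------

class Section:
    """One coronal slab ``[z, z + t)`` of a phantom.

    Region profiles are the solid cross-sections at the slab midplane;
    markers belong to the slab whose half-open z interval contains their
    reference point (a point exactly on a boundary goes to the upper slab).
    """

    __slots__ = ("stack", "index")

    def __init__(self, stack: "SectionStack", index: int):
        self.stack = stack
        self.index = index

    @property
    def thickness(self) -> float:
        return self.stack.thickness

    @property
    def z_interval(self) -> tuple[float, float]:
        z0 = self.stack.z_start + self.index * self.stack.thickness
        return (z0, z0 + self.stack.thickness)

    @property
    def profiles(self) -> dict[str, Profile | None]:
        return {label: self.profile(label) for label in self.stack.region_labels}

    def profile(self, region_label: str) -> Profile | None:
        return self.stack._profile(self.index, region_label)

    def markers_in_slab(self, region_label: str) -> np.ndarray:
        """2-D (x, y) coordinates of this slab's markers for one region."""
        return self.stack._markers_in_slab(self.index, region_label)


class SectionStack:
    """Ordered serial coronal sections of one phantom at a fixed thickness."""

    def __init__(
        self,
        regions: Mapping[str, RegionSolid],
        markers: Mapping[str, MarkerSet],
        thickness: float,
        z_start: float,
        total_count: int,
    ):
        self.regions = dict(regions)
        self.markers = dict(markers)
        self.thickness = float(thickness)
        self.z_start = float(z_start)
        self.total_count = int(total_count)
        self._profile_cache: dict[tuple[int, str], Profile | None] = {}
        # slab index per marker, computed once
        self._slab_of: dict[str, np.ndarray] = {}
        for label, mset in self.markers.items():
            z = mset.points[:, 2] if len(mset) else np.empty(0)
            k = np.floor((z - self.z_start) / self.thickness).astype(int)
            if len(k) and (k.min() < 0 or k.max() >= self.total_count):
                raise ValueError("marker outside the sectioned z extent")
            self._slab_of[label] = k

    @property
    def region_labels(self) -> tuple[str, ...]:
        return tuple(self.regions)

    @property
    def sections(self) -> list[Section]:
        return [Section(self, i) for i in range(self.total_count)]

    def section(self, index: int) -> Section:
        if not 0 <= index < self.total_count:
            raise IndexError(f"section index {index} out of range 0..{self.total_count - 1}")
        return Section(self, index)

    def __len__(self) -> int:
        return self.total_count

    def __iter__(self) -> Iterator[Section]:
        return iter(self.sections)

    def _profile(self, index: int, region_label: str) -> Profile | None:
        key = (index, region_label)
        if key not in self._profile_cache:
            z_mid = self.z_start + (index + 0.5) * self.thickness
            self._profile_cache[key] = self.regions[region_label].shape.profile_at(z_mid)
        return self._profile_cache[key]

    def _markers_in_slab(self, index: int, region_label: str) -> np.ndarray:
        if region_label not in self.markers:
            return np.empty((0, 2))
        sel = self._slab_of[region_label] == index
        return self.markers[region_label].points[sel, :2]

    def marker_count(self, region_label: str) -> int:
        return len(self.markers.get(region_label, ()))


def section_phantom(animal: AnimalPhantom, thickness: float) -> SectionStack:
    """Cut a phantom into serial coronal slabs of the given thickness.

    Slabs are half-open ``[z0 + k t, z0 + (k+1) t)`` starting at the lowest
    z of either region and tiling the full rostrocaudal extent.
    """
    if thickness <= 0:
        raise ValueError("section thickness must be positive")
    z_lo = min(r.shape.z_range[0] for r in animal.regions.values())
    z_hi = max(r.shape.z_range[1] for r in animal.regions.values())
    n = int(math.ceil((z_hi - z_lo) / thickness - 1e-12))
    if z_lo + n * thickness < z_hi:  # guard against float round-down
        n += 1
    return SectionStack(animal.regions, animal.markers, thickness, z_lo, n)


# ---------------------------------------------------------------------------
# group parameters and cohort generation
# ---------------------------------------------------------------------------

def _load_fixture() -> dict:
    with resources.files("hippostereo.data").joinpath("printed_group_means.json").open() as fh:
        return json.load(fh)


def nearest_correlation(matrix: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Nearest correlation matrix by Higham's alternating projections."""
    a = np.asarray(matrix, dtype=float)
    y = a.copy()
    ds = np.zeros_like(a)
    for _ in range(n_iter):
        rk = y - ds
        w, v = np.linalg.eigh(rk)
        x = (v * np.clip(w, 0.0, None)) @ v.T
        ds = x - rk
        y = x.copy()
        np.fill_diagonal(y, 1.0)
    return y


#: default shape aspect ratios (a, b, c) used before volume scaling; the DG
#: is modelled as a slender rostrocaudally elongated solid, CA3 slightly
#: broader, both spanning a few mm along z as rat hippocampal subfields do.
_REGION_ASPECTS = {"DG": (0.5, 0.5, 2.5), "CA3": (0.7, 0.7, 2.2)}
_REGION_GAP = 0.2  # mm of clearance between the two solids along x


@dataclass
class GroupParameters:
    """Simulation targets per study arm.

    ``volume``/``density`` map region -> group -> (mean, sd); covariates map
    group -> (mean, sd).  ``correlation`` is the 6x6 Gaussian-copula target
    over :data:`VARIABLE_ORDER`; marginals are Normal truncated below at
    ``trunc_floor_frac`` x mean to exclude non-physical values.
    """

    volume: dict[str, dict[str, tuple[float, float]]]
    density: dict[str, dict[str, tuple[float, float]]]
    blood_glucose: dict[str, tuple[float, float]]
    plasma_cu: dict[str, tuple[float, float]]
    correlation: np.ndarray = field(default_factory=lambda: np.eye(len(VARIABLE_ORDER)))
    trunc_floor_frac: float = 0.1

    def validate(self) -> None:
        for region in REGIONS:
            for group in GROUPS:
                for table, name in ((self.volume, "volume"), (self.density, "density")):
                    mean, sd = table[region][group]
                    if name == "volume" and mean <= 0:
                        raise ValueError(f"non-positive {name} mean for {group}/{region}")
                    if mean < 0 or sd < 0:
                        raise ValueError(f"invalid {name} parameters for {group}/{region}")
        for group in GROUPS:
            for table in (self.blood_glucose, self.plasma_cu):
                mean, sd = table[group]
                if mean <= 0 or sd < 0:
                    raise ValueError(f"invalid covariate parameters for {group}")
        r = np.asarray(self.correlation, dtype=float)
        k = len(VARIABLE_ORDER)
        if r.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(r, r.T) or np.abs(r).max() > 1 + 1e-9:
            raise ValueError("correlation matrix must be symmetric with entries in [-1, 1]")
        if np.linalg.eigvalsh(r).min() < -1e-8:
            raise ValueError("correlation matrix is not positive semi-definite")

    def group_means(self, group: str) -> dict[str, float]:
        return {
            "V_DG": self.volume["DG"][group][0],
            "V_CA3": self.volume["CA3"][group][0],
            "ND_DG": self.density["DG"][group][0],
            "ND_CA3": self.density["CA3"][group][0],
            "BG": self.blood_glucose[group][0],
            "Cu": self.plasma_cu[group][0],
        }


def default_group_parameters() -> GroupParameters:
    """Study-arm defaults: the printed group summaries shipped with the package."""
    fx = _load_fixture()

    def _tbl(block: dict) -> dict[str, dict[str, tuple[float, float]]]:
        return {region: {g: tuple(block[region][g]) for g in GROUPS} for region in REGIONS}

    corr = nearest_correlation(np.asarray(fx["correlation_targets"]["matrix"], dtype=float))
    return GroupParameters(
        volume=_tbl(fx["volume_mm3"]),
        density=_tbl(fx["density_per_mm3"]),
        blood_glucose={g: tuple(fx["blood_glucose_mg_dl"][g]) for g in GROUPS},
        plasma_cu={g: tuple(fx["plasma_cu_ug_dl"][g]) for g in GROUPS},
        correlation=corr,
    )


def _truncated_normal_ppf(u: np.ndarray, mean: float, sd: float, floor: float) -> np.ndarray:
    """Quantile of Normal(mean, sd) truncated below at ``floor``."""
    if sd == 0.0:
        return np.full_like(np.asarray(u, dtype=float), mean)
    a = (floor - mean) / sd
    return _sps.truncnorm.ppf(u, a=a, b=np.inf, loc=mean, scale=sd)


def _build_regions(v_dg: float, v_ca3: float) -> dict[str, RegionSolid]:
    """Two non-overlapping ellipsoids scaled to the drawn true volumes."""
    solids: dict[str, Solid] = {}
    radii_x = {}
    for label, vol in (("DG", v_dg), ("CA3", v_ca3)):
        a, b, c = _REGION_ASPECTS[label]
        s = (vol / (4.0 / 3.0 * math.pi * a * b * c)) ** (1.0 / 3.0)
        solids[label] = Ellipsoid(semi_axes=(a * s, b * s, c * s))
        radii_x[label] = a * s
    # shift CA3 along x so the two solids cannot overlap
    dx = radii_x["DG"] + radii_x["CA3"] + _REGION_GAP
    ca3 = solids["CA3"]
    solids["CA3"] = Ellipsoid(semi_axes=ca3.semi_axes, center=(dx, 0.0, 0.0))
    return {label: RegionSolid(label=label, shape=shape) for label, shape in solids.items()}


def make_cohort(
    params: GroupParameters,
    n_per_group: int,
    seed: int,
    with_markers: bool = True,
) -> list[AnimalPhantom]:
    """Generate the full four-arm cohort.

    Per animal, the sextuple (V_DG, V_CA3, ND_DG, ND_CA3, BG, Cu) is drawn
    from a Gaussian copula at the configured correlation with truncated
    Normal marginals; region geometry is scaled so its closed-form volume
    equals the drawn value, and markers are seeded at the drawn intensity.
    ``with_markers=False`` skips marker seeding (volume-only studies).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    params.validate()
    rng = np.random.default_rng(seed)
    corr = np.asarray(params.correlation, dtype=float)
    w, v = np.linalg.eigh(corr)
    chol_like = v * np.sqrt(np.clip(w, 0.0, None))  # works for PSD, not just PD

    cohort: list[AnimalPhantom] = []
    for group in GROUPS:
        z = rng.standard_normal((n_per_group, len(VARIABLE_ORDER))) @ chol_like.T
        u = _sps.norm.cdf(z)
        marg = {
            "V_DG": params.volume["DG"][group],
            "V_CA3": params.volume["CA3"][group],
            "ND_DG": params.density["DG"][group],
            "ND_CA3": params.density["CA3"][group],
            "BG": params.blood_glucose[group],
            "Cu": params.plasma_cu[group],
        }
        draws = {}
        for j, name in enumerate(VARIABLE_ORDER):
            mean, sd = marg[name]
            draws[name] = _truncated_normal_ppf(u[:, j], mean, sd, params.trunc_floor_frac * mean)
        for i in range(n_per_group):
            regions = _build_regions(float(draws["V_DG"][i]), float(draws["V_CA3"][i]))
            markers = {}
            for label in REGIONS:
                intensity = float(draws[f"ND_{label}"][i])
                if with_markers:
                    markers[label] = seed_markers(regions[label], intensity, rng)
                else:
                    markers[label] = MarkerSet(label=label, points=np.empty((0, 3)),
                                               true_intensity=intensity)
            cohort.append(
                AnimalPhantom(
                    animal_id=f"{group}-{i + 1:02d}",
                    group=group,
                    regions=regions,
                    markers=markers,
                    covariates={
                        "blood_glucose": float(draws["BG"][i]),
                        "plasma_cu": float(draws["Cu"][i]),
                    },
                )
            )
    return cohort


def truth_table(cohort: Sequence[AnimalPhantom]):
    """Ground-truth table (one row per animal) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for a in cohort:
        vols = a.true_volumes()
        rows.append(
            {
                "animal_id": a.animal_id,
                "group": a.group,
                "true_V_DG": vols["DG"],
                "true_V_CA3": vols["CA3"],
                "true_ND_DG": a.markers["DG"].true_intensity,
                "true_ND_CA3": a.markers["CA3"].true_intensity,
                "BG": a.covariates["blood_glucose"],
                "Cu": a.covariates["plasma_cu"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _solid_to_dict(shape: Solid) -> dict:
    if isinstance(shape, Ellipsoid):
        return {"kind": "ellipsoid", "semi_axes": list(shape.semi_axes),
                "center": list(shape.center)}
    return {
        "kind": "extrusion",
        "polygon": [list(xy) for xy in shape.polygon.exterior.coords],
        "z_min": shape.z_min,
        "z_max": shape.z_max,
    }


def _solid_from_dict(d: dict) -> Solid:
    if d["kind"] == "ellipsoid":
        return Ellipsoid(semi_axes=tuple(d["semi_axes"]), center=tuple(d["center"]))
    return ExtrudedPolygon(polygon=Polygon(d["polygon"]), z_min=d["z_min"], z_max=d["z_max"])


def cohort_to_json(cohort: Sequence[AnimalPhantom]) -> str:
    payload = []
    for a in cohort:
        payload.append(
            {
                "animal_id": a.animal_id,
                "group": a.group,
                "regions": {r: _solid_to_dict(s.shape) for r, s in a.regions.items()},
                "markers": {
                    r: {"points": m.points.tolist(), "true_intensity": m.true_intensity}
                    for r, m in a.markers.items()
                },
                "covariates": dict(a.covariates),
            }
        )
    return json.dumps(payload, indent=1)


def cohort_from_json(text: str) -> list[AnimalPhantom]:
    cohort = []
    for d in json.loads(text):
        regions = {r: RegionSolid(label=r, shape=_solid_from_dict(sd))
                   for r, sd in d["regions"].items()}
        markers = {
            r: MarkerSet(label=r, points=np.asarray(md["points"]).reshape(-1, 3),
                         true_intensity=md["true_intensity"])
            for r, md in d["markers"].items()
        }
        cohort.append(
            AnimalPhantom(
                animal_id=d["animal_id"],
                group=d["group"],
                regions=regions,
                markers=markers,
                covariates=d["covariates"],
            )
        )
    return cohort


def stack_to_json(stack: SectionStack, n_vertices: int = 64) -> str:
    """Serialize a section stack as JSON polygons with z intervals."""
    sections = []
    for s in stack:
        profs = {}
        for label in stack.region_labels:
            p = s.profile(label)
            if p is None or p.is_empty:
                profs[label] = None
            else:
                profs[label] = [list(xy) for xy in p.to_polygon(n_vertices).exterior.coords]
        sections.append(
            {
                "index": s.index,
                "z_interval": list(s.z_interval),
                "profiles": profs,
                "markers_in_slab": {
                    label: s.markers_in_slab(label).tolist() for label in stack.region_labels
                },
            }
        )
    return json.dumps({"thickness": stack.thickness, "z_start": stack.z_start,
                       "total_count": stack.total_count, "sections": sections})
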