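"""Catalogue of potentially predictive variables (PPVs).

Declares the full variable set used for the nitrogen-oxide land-use
regressions — traffic surrogates, land-use areas, (log-)distances,
population densities, traffic/distance product ratios and terrain — each
with its buffer radius and a-priori effect direction, and computes each
variable as a raster over the city, extracting station values into a
design table.

Variable naming follows the field convention ``KIND.RADIUS`` for
buffered variables (e.g. ``GRS.500`` = m^2 of green space within 500 m)
and ``DIST to KIND`` / ``LNDIST to KIND`` for distances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import (GridSpec, RasterGrid, euclidean_distance, focal_sum,
                     kernel_density, log_distance, nodata_to_zero, rasterize,
                     slope_from_dem)
from .synth import FACILITY_KINDS, LANDUSE_TYPES, CityScene

# buffer radii (m) per variable family
RADII_5 = (100, 200, 300, 400, 500)
RADII_7 = (100, 200, 300, 400, 500, 750, 1000)
RADII_BG = (400, 500)
RADII_POP = tuple(range(500, 3001, 250))  # 11 kernel radii

_TRAFFIC_KINDS = ("ST", "HW", "RDa", "RDb", "BG")
_TRAFFIC_RADII = {"ST": RADII_5, "HW": RADII_5, "RDa": RADII_7,
                  "RDb": RADII_7, "BG": RADII_BG}

_LU_SIGNS = {"RES": -1, "GRS": -1, "URF": 0, "IND": +1, "OFIC": +1,
             "TRS": +1, "SNS": 0, "AGR": -1, "ARD": -1, "OTHR": 0}

# point/zone features that only enter through distance variables
_SPECIAL_DIST = (("FWY", -1), ("TACZ", -1), ("TACAP", -1), ("SPLND", +1),
                 ("PRSC", +1), ("SCSC", +1), ("PST", -1), ("PRK", +1),
                 ("MSQ", +1), ("HZRFAC", 0), ("FV", 0), ("BST", -1),
                 ("AIR", 0), ("AMB", 0))

_FACILITY_CODE = {"SPLND": "sport_land", "PRSC": "primary_school",
                  "SCSC": "high_school", "PST": "petrol_station",
                  "PRK": "park", "MSQ": "mosque",
                  "HZRFAC": "hazardous_facility", "FV": "food_shop",
                  "BST": "bus_terminal", "AIR": "airport", "AMB": "ambulance"}

_PRODUCT_FAMILIES = (  # (name prefix, numerator kind, squared denominator)
    ("STD", "ST", False), ("HWD", "HW", False),
    ("STSQD", "ST", True), ("HWSQD", "HW", True),
    ("RDaD", "RDa", False), ("RDbD", "RDb", False),
    ("RDaSQD", "RDa", True), ("RDbSQD", "RDb", True),
    ("BGD", "BG", False), ("BGSQD", "BG", True))

# buffer distance (m) added around the TACZ to form the critical-episode
# extended control zone (TACAP); the zone boundary is policy, not geometry,
# so this is a generator convention
TACAP_BUFFER = 300.0


@dataclass(frozen=True)
class PPVSpec:
    """One potentially predictive variable."""

    name: str
    ppv_class: str          # traffic|landuse|distance|population|product|geographic
    source: str             # feature-kind key
    radius: float | None = None
    transform: str = "identity"   # identity | log (for LNDIST)
    sign_prior: int = 0           # +1, -1, or 0 (no a-priori direction)
    squared: bool = False         # product variables: BG/sq(DIST)

    def to_dict(self) -> dict:
        return {"name": self.name, "class": self.ppv_class,
                "source": self.source, "radius": self.radius,
                "transform": self.transform,
                "sign_prior": {1: "+", -1: "-", 0: "none"}[self.sign_prior]}


def build_catalog(scene: CityScene | None = None,
                  radii_config: dict | None = None) -> list[PPVSpec]:
    """The default PPV catalogue (210 variables in 6 classes).

    Class sizes: traffic 26, land use 50, distance 58, population 22,
    product 52, geographic 2.  When a scene is given, its layers are
    checked so every catalogued variable is computable.
    """
    rc = radii_config or {}
    traffic_radii = {k: tuple(rc.get(k, _TRAFFIC_RADII[k]))
                     for k in _TRAFFIC_KINDS}
    lu_radii = tuple(rc.get("landuse", RADII_5))
    pop_radii = tuple(rc.get("population", RADII_POP))

    if scene is not None:
        _check_scene_kinds(scene)

    specs: list[PPVSpec] = []
    for kind in _TRAFFIC_KINDS:
        for r in traffic_radii[kind]:
            specs.append(PPVSpec(f"{kind}.{r}", "traffic", kind, r,
                                 sign_prior=+1))
    for lu in LANDUSE_TYPES:
        for r in lu_radii:
            specs.append(PPVSpec(f"{lu}.{r}", "landuse", lu, r,
                                 sign_prior=_LU_SIGNS[lu]))
    # distances to every traffic and land-use kind (sign flipped), then
    # to the special features with their own priors
    dist_kinds = ([(k, -1) for k in _TRAFFIC_KINDS]
                  + [(lu, -_LU_SIGNS[lu]) for lu in LANDUSE_TYPES]
                  + list(_SPECIAL_DIST))
    for kind, sign in dist_kinds:
        specs.append(PPVSpec(f"DIST to {kind}", "distance", kind,
                             sign_prior=sign))
        specs.append(PPVSpec(f"LNDIST to {kind}", "distance", kind,
                             transform="log", sign_prior=sign))
    for fam, attr in (("PD", "total"), ("TPDC", "adjusted")):
        for r in pop_radii:
            specs.append(PPVSpec(f"{fam}.{r}", "population", attr, r,
                                 sign_prior=+1))
    for fam, num, sq in _PRODUCT_FAMILIES:
        for r in traffic_radii[num]:
            specs.append(PPVSpec(f"{fam}.{r}", "product", num, r,
                                 sign_prior=+1, squared=sq))
    specs.append(PPVSpec("ELEV", "geographic", "dem", sign_prior=0))
    specs.append(PPVSpec("SLP", "geographic", "slope", sign_prior=0))
    return specs


def sign_priors(catalog: list[PPVSpec] | None = None) -> dict[str, int]:
    return {s.name: s.sign_prior for s in (catalog or build_catalog())}


def catalog_summary(catalog: list[PPVSpec]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in catalog:
        counts[s.ppv_class] = counts.get(s.ppv_class, 0) + 1
    counts["total"] = len(catalog)
    return counts


def write_catalog(catalog: list[PPVSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in catalog], fh, indent=1)


def _check_scene_kinds(scene: CityScene) -> None:
    road_classes = {a.get("class") for _, a in scene.roads}
    for cls in ("street", "highway", "major_road"):
        if cls not in road_classes:
            raise ValueError(f"scene missing road class '{cls}'")
    lu = {a.get("type") for _, a in scene.landuse}
    missing = set(LANDUSE_TYPES) - lu
    if missing:
        raise ValueError(f"scene missing land-use types {sorted(missing)}")
    fk = {a.get("kind") for _, a in scene.facilities}
    missing = set(FACILITY_KINDS) - fk
    if missing:
        raise ValueError(f"scene missing facility kinds {sorted(missing)}")
    if len(scene.bridges) == 0:
        raise ValueError("scene missing bridges")
    if len(scene.taczone) == 0:
        raise ValueError("scene missing the traffic access control zone")


# ---------------------------------------------------------------------------
# computation


class PPVComputer:
    """Computes PPV rasters for one scene, caching shared intermediates
    (presence rasters, distance transforms, focal sums)."""

    def __init__(self, scene: CityScene, grid: GridSpec | None = None):
        self.scene = scene
        self.grid = grid or scene.grid
        self._presence: dict[str, RasterGrid] = {}
        self._distance: dict[str, RasterGrid] = {}
        self._dem: RasterGrid | None = None

    # -- base layers ----------------------------------------------------
    def _layer_for(self, kind: str):
        from .vector import VectorLayer
        sc = self.scene
        if kind == "ST":
            return sc.roads.filter(**{"class": "street"})
        if kind in ("HW", "FWY"):
            return sc.roads.filter(**{"class": "highway"})
        if kind == "RDa":
            return sc.roads.filter(**{"class": "major_road"})
        if kind == "RDb":
            return sc.roads
        if kind == "BG":
            return sc.bridges
        if kind in LANDUSE_TYPES:
            return sc.landuse.filter(type=kind)
        if kind == "TACZ":
            return sc.taczone
        if kind == "TACAP":
            buffered = VectorLayer()
            for g, a in sc.taczone:
                buffered.add(g.buffer(TACAP_BUFFER, quad_segs=16),
                             kind="tacap")
            return buffered
        if kind in _FACILITY_CODE:
            return sc.facilities.filter(kind=_FACILITY_CODE[kind])
        raise KeyError(f"unknown feature kind {kind}")

    def presence(self, kind: str) -> RasterGrid:
        if kind not in self._presence:
            self._presence[kind] = rasterize(self._layer_for(kind), self.grid,
                                             mode="presence")
        return self._presence[kind]

    def distance(self, kind: str) -> RasterGrid:
        if kind not in self._distance:
            self._distance[kind] = euclidean_distance(self.presence(kind))
        return self._distance[kind]

    def dem_on_grid(self) -> RasterGrid:
        if self._dem is None:
            dem = self.scene.dem
            if dem.grid == self.grid:
                self._dem = dem
            else:  # nearest-cell resample onto the working grid
                X, Y = self.grid.cell_centers()
                vals = np.array([dem.sample(list(zip(xr, yr)))
                                 for xr, yr in zip(X, Y)])
                self._dem = RasterGrid(vals, self.grid.origin,
                                       self.grid.cell_size)
        return self._dem

    # -- one PPV ----------------------------------------------------------
    def compute(self, spec: PPVSpec) -> RasterGrid:
        cs = self.grid.cell_size
        if spec.ppv_class == "traffic":
            # pixel count within the buffer x pixel size = metres of line
            fs = focal_sum(self.presence(spec.source), spec.radius)
            return fs.like(fs.values * cs)
        if spec.ppv_class == "landuse":
            fs = focal_sum(self.presence(spec.source), spec.radius)
            return fs.like(fs.values * cs * cs)  # pixel count -> m^2
        if spec.ppv_class == "distance":
            d = self.distance(spec.source)
            return log_distance(d) if spec.transform == "log" else d
        if spec.ppv_class == "population":
            return kernel_density(self.scene.population, spec.radius,
                                  self.grid, weight_attr=spec.source)
        if spec.ppv_class == "product":
            fs = focal_sum(self.presence(spec.source), spec.radius)
            num = fs.values * cs
            den = np.maximum(self.distance(spec.source).values, cs)
            if spec.squared:
                den = den ** 2
            return RasterGrid(num / den, self.grid.origin, cs)
        if spec.ppv_class == "geographic":
            dem = self.dem_on_grid()
            return dem.copy() if spec.source == "dem" else slope_from_dem(dem)
        raise ValueError(f"unknown PPV class {spec.ppv_class}")

    def compute_all(self, specs: list[PPVSpec]) -> dict[str, RasterGrid]:
        return {s.name: nodata_to_zero(self.compute(s)) for s in specs}


def compute_ppv(spec: PPVSpec, scene: CityScene,
                grid: GridSpec | None = None) -> RasterGrid:
    """Convenience wrapper: one PPV raster without explicit caching."""
    return PPVComputer(scene, grid).compute(spec)


def compute_station_ppvs(scene: CityScene, stations, names: list[str],
                         grid: GridSpec | None = None) -> pd.DataFrame:
    """PPV values at station cells for the named subset of the catalogue."""
    catalog = {s.name: s for s in build_catalog()}
    comp = PPVComputer(scene, grid)
    data = {}
    for nm in names:
        if nm not in catalog:
            raise KeyError(f"unknown PPV {nm}")
        data[nm] = nodata_to_zero(comp.compute(catalog[nm])).sample(stations)
    return pd.DataFrame(data, index=[f"S{i:02d}" for i in range(len(stations))])


def extract_station_values(rasters: dict[str, RasterGrid], stations,
                           responses: pd.DataFrame | None = None,
                           ) -> pd.DataFrame:
    """Design table: one row per station, PPV columns from the grid cell
    under the station, optionally joined with response means."""
    ids = [f"S{i:02d}" for i in range(len(stations))]
    cols = {}
    for name, rast in rasters.items():
        try:
            cols[name] = rast.sample(stations)
        except ValueError as exc:
            bad = next(i for i, (x, y) in enumerate(stations)
                       if not rast.grid.contains(x, y))
            raise ValueError(f"station {ids[bad]} outside raster extent "
                             f"for {name}") from exc
    df = pd.DataFrame(cols, index=ids)
    df.insert(0, "x", [p[0] for p in stations])
    df.insert(1, "y", [p[1] for p in stations])
    if responses is not None:
        resp = responses.copy()
        resp.index = ids if len(resp) == len(ids) else resp.index
        df = df.join(resp)
    return df
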