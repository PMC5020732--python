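"""Synthetic city generator with known ground truth.

Builds a self-contained planar city — roads on a jittered grid, land-use
polygons by seeded region growing, facilities, a central traffic access
control zone (TACZ), population centroids and a DEM — together with
hourly pollutant series (NO, NO2, NOx) at monitoring stations generated
from a log-linear concentration model with seasonal source shifts,
multiplicative diurnal cycle, log-normal hourly noise and configurable
missingness.  Everything is a pure function of (config, seed), so the
downstream regression machinery can be tested against a known truth.

Units: metres for geometry, ppb for concentrations.  Seasons follow the
Northern-hemisphere heating convention: warmer = April-September,
cooler = October-March.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, box

from .raster import GridSpec, RasterGrid
from .vector import VectorLayer

WARMER_MONTHS = (4, 5, 6, 7, 8, 9)
COOLER_MONTHS = (10, 11, 12, 1, 2, 3)

LANDUSE_TYPES = ("RES", "GRS", "URF", "IND", "OFIC",
                 "TRS", "SNS", "AGR", "ARD", "OTHR")

FACILITY_KINDS = ("primary_school", "high_school", "petrol_station",
                  "bus_terminal", "airport", "hazardous_facility",
                  "mosque", "park", "food_shop", "ambulance", "sport_land")

# target fraction of blocks per land-use type (rough megacity mix)
_LU_SHARES = {"RES": 0.30, "GRS": 0.10, "URF": 0.05, "IND": 0.10,
              "OFIC": 0.10, "TRS": 0.05, "SNS": 0.05, "AGR": 0.10,
              "ARD": 0.10, "OTHR": 0.05}

# mean facility counts for the default 2 km x 2 km extent, scaled by area
_FACILITY_DENSITY = {"primary_school": 12, "high_school": 8,
                     "petrol_station": 8, "bus_terminal": 4, "airport": 1,
                     "hazardous_facility": 4, "mosque": 10, "park": 8,
                     "food_shop": 15, "ambulance": 5, "sport_land": 6}

# persons per m^2 of block area by land-use type
_POP_DENSITY = {"RES": 0.012, "GRS": 0.0005, "URF": 0.004, "IND": 0.002,
                "OFIC": 0.006, "TRS": 0.001, "SNS": 0.0005, "AGR": 0.0008,
                "ARD": 0.0002, "OTHR": 0.003}


@dataclass(frozen=True)
class CityConfig:
    """Size/density knobs of the generator; defaults are the study scale
    used throughout the tests (a 2 km x 2 km city at 10 m cells)."""

    width: float = 2000.0
    height: float = 2000.0
    cell_size: float = 10.0
    street_spacing: float = 150.0
    major_spacing: float = 500.0
    n_highways: int = 2
    block_size: float = 125.0
    taczone_radius: float = 350.0
    dem_base: float = 1100.0
    dem_gradient: float = 0.04   # m of elevation per m northward
    dem_noise: float = 25.0      # sd of smoothed DEM noise, m

    def __post_init__(self) -> None:
        if self.width * self.height < 1e6:
            raise ValueError("extent must be at least 1 km^2")
        if self.taczone_radius <= 0:
            raise ValueError("taczone radius must be positive")
        if self.street_spacing <= 0 or self.major_spacing <= 0:
            raise ValueError("road spacings must be positive")
        if self.n_highways < 1:
            raise ValueError("need at least one highway")


@dataclass
class CityScene:
    """All GIS layers of one synthetic city."""

    config: CityConfig
    roads: VectorLayer
    bridges: VectorLayer
    landuse: VectorLayer
    facilities: VectorLayer
    taczone: VectorLayer
    population: VectorLayer
    dem: RasterGrid

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (0.0, 0.0, self.config.width, self.config.height)

    @property
    def grid(self) -> GridSpec:
        return self.dem.grid

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.config.width and 0.0 <= y <= self.config.height

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("roads", "bridges", "landuse", "facilities",
                     "taczone", "population"):
            getattr(self, name).write(out / f"{name}.geojson")
        self.dem.write_ascii(out / "dem.asc")


@dataclass
class SeasonEffect:
    """Season-specific modifiers of the ground-truth model: a multiplier
    on the base level and per-variable multipliers on the coefficients."""

    base: float = 1.0
    coef: dict[str, float] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """The generative log-linear concentration model.

    log C(station, hour) = log(base_level * season.base)
                           + sum_i coef_i * season.coef_i * x_i(station)
                           + N(0, noise_sd)

    with x_i the value of the named predictor variable at the station.
    """

    active_ppvs: dict[str, float]
    seasonal_shift: dict[str, SeasonEffect] = field(
        default_factory=lambda: {"warmer": SeasonEffect(),
                                 "cooler": SeasonEffect()})
    noise_sd: float = 0.4
    base_level: float = 40.0
    no_share: float = 0.59       # NO fraction of NOx at the mean
    diurnal_amplitude: float = 0.3

    def __post_init__(self) -> None:
        if self.base_level <= 0:
            raise ValueError("base_level must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.no_share < 1:
            raise ValueError("no_share must be in (0, 1)")
        for s in ("warmer", "cooler"):
            if s not in self.seasonal_shift:
                raise ValueError(f"seasonal_shift must define '{s}'")

    def coef_in_season(self, name: str, season: str) -> float:
        eff = self.seasonal_shift[season]
        return self.active_ppvs[name] * eff.coef.get(name, 1.0)


def default_ground_truth() -> GroundTruth:
    """A realistic default: traffic-zone proximity, primary-school
    remoteness, green space and slope drive the surface, with a stronger
    cooler season (residential heating)."""
    return GroundTruth(
        active_ppvs={"DIST to TACZ": -4.0e-4, "LNDIST to PRSC": 0.35,
                     "GRS.500": -3.0e-6, "SLP": -4.4e-2},
        seasonal_shift={"warmer": SeasonEffect(base=0.75),
                        "cooler": SeasonEffect(base=1.35)},
        noise_sd=0.4, base_level=40.0)


@dataclass
class HourlySeries:
    """One station's hourly NO/NO2/NOx tracks over one calendar year."""

    station_id: str
    data: pd.DataFrame  # index: DatetimeIndex (8760 h); columns no,no2,nox

    def __post_init__(self) -> None:
        if len(self.data) != 8760:
            raise ValueError("series must cover 8760 hours")
        for col in ("no", "no2", "nox"):
            if col not in self.data.columns:
                raise ValueError(f"missing column {col}")


def year_index(year: int = 2010) -> pd.DatetimeIndex:
    idx = pd.date_range(f"{year}-01-01", periods=8760, freq="h")
    return idx


def season_of(months: pd.Index) -> np.ndarray:
    return np.where(np.isin(months, WARMER_MONTHS), "warmer", "cooler")


# ---------------------------------------------------------------------------
# city generation


def _make_roads(cfg: CityConfig, rng: np.random.Generator) -> VectorLayer:
    roads = VectorLayer()
    w, h = cfg.width, cfg.height

    def lines(spacing: float, cls: str, jitter: float) -> None:
        for x in np.arange(spacing, w, spacing):
            xj = float(np.clip(x + rng.uniform(-jitter, jitter), 1, w - 1))
            roads.add(LineString([(xj, 0), (xj, h)]), **{"class": cls})
        for y in np.arange(spacing, h, spacing):
            yj = float(np.clip(y + rng.uniform(-jitter, jitter), 1, h - 1))
            roads.add(LineString([(0, yj), (w, yj)]), **{"class": cls})

    lines(cfg.street_spacing, "street", cfg.street_spacing * 0.25)
    lines(cfg.major_spacing, "major_road", cfg.major_spacing * 0.15)
    for k in range(cfg.n_highways):
        if k % 2 == 0:
            y = float(rng.uniform(0.25, 0.75) * h)
            roads.add(LineString([(0, y), (w, y)]), **{"class": "highway"})
        else:
            x = float(rng.uniform(0.25, 0.75) * w)
            roads.add(LineString([(x, 0), (x, h)]), **{"class": "highway"})
    return roads


def _make_bridges(cfg: CityConfig, roads: VectorLayer,
                  rng: np.random.Generator) -> VectorLayer:
    """Short overpass segments at crossings of major roads/highways."""
    bridges = VectorLayer()
    big = [g for g, a in roads if a["class"] in ("major_road", "highway")]
    pts = []
    for i, g1 in enumerate(big):
        for g2 in big[i + 1:]:
            inter = g1.intersection(g2)
            if inter.geom_type == "Point":
                pts.append(inter)
    rng.shuffle(pts)
    for p in pts[: max(4, len(pts) // 2)]:
        ang = rng.uniform(0, np.pi)
        dx, dy = 30 * np.cos(ang), 30 * np.sin(ang)
        bridges.add(LineString([(p.x - dx, p.y - dy), (p.x + dx, p.y + dy)]))
    return bridges


def _make_landuse(cfg: CityConfig,
                  rng: np.random.Generator) -> tuple[VectorLayer, np.ndarray]:
    """Seeded region growing on a block lattice -> contiguous patches."""
    nbx = max(4, int(round(cfg.width / cfg.block_size)))
    nby = max(4, int(round(cfg.height / cfg.block_size)))
    label = -np.ones((nby, nbx), dtype=int)
    ntypes = len(LANDUSE_TYPES)
    shares = np.array([_LU_SHARES[t] for t in LANDUSE_TYPES])
    n_seeds = np.maximum(1, np.round(shares * nbx * nby * 0.15)).astype(int)
    free = [(i, j) for i in range(nby) for j in range(nbx)]
    rng.shuffle(free)
    frontier: list[tuple[int, int]] = []
    it = iter(free)
    for t in range(ntypes):
        for _ in range(n_seeds[t]):
            for i, j in it:
                if label[i, j] < 0:
                    label[i, j] = t
                    frontier.append((i, j))
                    break
    # grow: repeatedly pick a labelled frontier block, spread to a neighbour
    while frontier:
        k = rng.integers(len(frontier))
        i, j = frontier[k]
        nbrs = [(i + di, j + dj) for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= i + di < nby and 0 <= j + dj < nbx
                and label[i + di, j + dj] < 0]
        if not nbrs:
            frontier.pop(k)
            continue
        ni, nj = nbrs[rng.integers(len(nbrs))]
        label[ni, nj] = label[i, j]
        frontier.append((ni, nj))

    layer = VectorLayer()
    bw, bh = cfg.width / nbx, cfg.height / nby
    for i in range(nby):
        for j in range(nbx):
            t = LANDUSE_TYPES[label[i, j]]
            layer.add(box(j * bw, cfg.height - (i + 1) * bh,
                          (j + 1) * bw, cfg.height - i * bh), type=t)
    return layer, label


def _make_facilities(cfg: CityConfig, rng: np.random.Generator) -> VectorLayer:
    fac = VectorLayer()
    area_scale = (cfg.width * cfg.height) / 4e6
    for kind in FACILITY_KINDS:
        n = max(1, int(rng.poisson(_FACILITY_DENSITY[kind] * area_scale)))
        xs = rng.uniform(5, cfg.width - 5, n)
        ys = rng.uniform(5, cfg.height - 5, n)
        for x, y in zip(xs, ys):
            fac.add(Point(float(x), float(y)), kind=kind)
    return fac


def _make_population(cfg: CityConfig, landuse: VectorLayer,
                     rng: np.random.Generator) -> VectorLayer:
    pop = VectorLayer()
    for geom, attrs in landuse:
        dens = _POP_DENSITY[attrs["type"]]
        total = float(dens * geom.area * rng.uniform(0.6, 1.4))
        adjusted = total * float(rng.uniform(0.55, 0.75))
        c = geom.centroid
        pop.add(Point(c.x, c.y), total=total, adjusted=adjusted)
    return pop


def _make_dem(cfg: CityConfig, rng: np.random.Generator) -> RasterGrid:
    from scipy.ndimage import gaussian_filter
    nrows = int(round(cfg.height / cfg.cell_size))
    ncols = int(round(cfg.width / cfg.cell_size))
    grid = GridSpec(nrows, ncols, (0.0, cfg.height), cfg.cell_size)
    _, Y = grid.cell_centers()
    noise = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=6)
    sd = noise.std() or 1.0
    z = cfg.dem_base + cfg.dem_gradient * Y + cfg.dem_noise * noise / sd
    return RasterGrid(z, grid.origin, cfg.cell_size)


def generate_city(config: CityConfig | None = None, seed: int = 0) -> CityScene:
    """Deterministically generate a complete city scene.

    All layer kinds needed by the predictor-variable catalogue are present
    by construction: every land-use type gets at least one seed block and
    every facility kind at least one point.
    """
    cfg = config or CityConfig()
    rng = np.random.default_rng(seed)
    roads = _make_roads(cfg, rng)
    if len(roads) == 0:
        raise ValueError("degenerate config: no roads generated")
    bridges = _make_bridges(cfg, roads, rng)
    landuse, _ = _make_landuse(cfg, rng)
    facilities = _make_facilities(cfg, rng)
    tac = VectorLayer()
    tac.add(Point(cfg.width / 2, cfg.height / 2)
            .buffer(cfg.taczone_radius, quad_segs=16), kind="taczone")
    population = _make_population(cfg, landuse, rng)
    dem = _make_dem(cfg, rng)
    return CityScene(cfg, roads, bridges, landuse, facilities, tac,
                     population, dem)


def place_stations(scene: CityScene, n: int = 23,
                   seed: int = 0) -> list[tuple[float, float]]:
    """n monitoring-station locations, uniform over the extent with a
    margin so every station has a full grid cell under it."""
    rng = np.random.default_rng(seed)
    m = 2 * scene.config.cell_size
    xs = rng.uniform(m, scene.config.width - m, n)
    ys = rng.uniform(m, scene.config.height - m, n)
    return [(float(x), float(y)) for x, y in zip(xs, ys)]


# ---------------------------------------------------------------------------
# concentrations


def _check_truth_signs(truth: GroundTruth) -> None:
    from .ppv import sign_priors
    priors = sign_priors()
    for name, coef in truth.active_ppvs.items():
        prior = priors.get(name)
        if prior not in (None, 0) and np.sign(coef) != prior:
            raise ValueError(
                f"ground-truth coefficient for {name} contradicts its "
                f"a-priori sign ({'+' if prior > 0 else '-'})")


def simulate_concentrations(scene: CityScene,
                            stations: list[tuple[float, float]],
                            truth: GroundTruth, seed: int = 0,
                            year: int = 2010,
                            station_ppvs: pd.DataFrame | None = None,
                            ) -> list[HourlySeries]:
    """Hourly NO/NO2/NOx series at each station from the ground truth.

    NO and NO2 are generated as shares of the modelled NOx level with
    independent hourly log-normal noise; NOx is their sum at every hour,
    so the species identity holds exactly.  A smooth diurnal cycle
    (normalized to annual mean 1) modulates all stations identically.
    """
    for x, y in stations:
        if not scene.contains(x, y):
            raise ValueError(f"station ({x}, {y}) outside the city extent")
    _check_truth_signs(truth)
    if station_ppvs is None:
        from .ppv import compute_station_ppvs
        station_ppvs = compute_station_ppvs(
            scene, stations, list(truth.active_ppvs))
    rng = np.random.default_rng(seed)
    idx = year_index(year)
    seasons = season_of(idx.month)
    hours = idx.hour.to_numpy()
    diurnal = np.exp(truth.diurnal_amplitude
                     * np.cos(2 * np.pi * (hours - 18) / 24.0))
    diurnal = diurnal / diurnal.mean()

    out = []
    for si, (x, y) in enumerate(stations):
        xrow = station_ppvs.iloc[si]
        log_level = np.empty(8760)
        for s in ("warmer", "cooler"):
            m = seasons == s
            contrib = sum(truth.coef_in_season(nm, s) * xrow[nm]
                          for nm in truth.active_ppvs)
            log_level[m] = (np.log(truth.base_level
                                   * truth.seasonal_shift[s].base) + contrib)
        eps_no = rng.normal(0, truth.noise_sd, 8760)
        eps_no2 = rng.normal(0, truth.noise_sd, 8760)
        no = truth.no_share * np.exp(log_level + eps_no) * diurnal
        no2 = (1 - truth.no_share) * np.exp(log_level + eps_no2) * diurnal
        df = pd.DataFrame({"no": no, "no2": no2, "nox": no + no2}, index=idx)
        out.append(HourlySeries(station_id=f"S{si:02d}", data=df))
    return out


# ---------------------------------------------------------------------------
# missingness


def _mcar_mask(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    k = int(round(rate * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def _block_mask(n: int, rate: float, rng: np.random.Generator,
                mean_len: int = 24) -> np.ndarray:
    """Contiguous instrument-outage gaps totalling round(rate*n) hours."""
    target = int(round(rate * n))
    mask = np.zeros(n, dtype=bool)
    while mask.sum() < target:
        need = target - int(mask.sum())
        length = max(1, min(int(rng.geometric(1.0 / mean_len)), need))
        start = int(rng.integers(0, n - length + 1))
        mask[start:start + length] = True
    # trim overshoot from the end of the last-added run, keeping runs contiguous
    excess = int(mask.sum()) - target
    if excess > 0:
        idx = np.flatnonzero(mask)
        mask[idx[-excess:]] = False
    return mask


def apply_missingness(series: HourlySeries, rate: float,
                      mechanism: str = "mcar", seed: int = 0) -> HourlySeries:
    """Blank out a fraction of each pollutant track.

    MCAR removes exactly round(rate*8760) hours per track (so the
    realized rate is within one hour of the request); the block mechanism
    removes the same total in contiguous outages of geometric length.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if mechanism not in ("mcar", "block"):
        raise ValueError("mechanism must be 'mcar' or 'block'")
    df = series.data.copy()
    if rate == 0:
        return HourlySeries(series.station_id, df)
    rng = np.random.default_rng(seed)
    n = len(df)
    for col in ("no", "no2", "nox"):
        mask = (_mcar_mask(n, rate, rng) if mechanism == "mcar"
                else _block_mask(n, rate, rng))
        df.loc[mask, col] = np.nan
    return HourlySeries(series.station_id, df)


def series_to_frame(series: list[HourlySeries], pollutant: str) -> pd.DataFrame:
    """hours x stations matrix for one pollutant (NaN = missing)."""
    return pd.DataFrame({s.station_id: s.data[pollutant] for s in series})


def write_series_csv(series: list[HourlySeries], path) -> None:
    rows = []
    for s in series:
        d = s.data.copy()
        d.insert(0, "station_id", s.station_id)
        d.insert(1, "timestamp", d.index.strftime("%Y-%m-%dT%H:%M:%S"))
        rows.append(d.reset_index(drop=True))
    pd.concat(rows).to_csv(path, index=False, float_format="%.6g")


def read_series_csv(path) -> list[HourlySeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for sid, grp in df.groupby("station_id", sort=True):
        g = grp.set_index("timestamp")[["no", "no2", "nox"]]
        out.append(HourlySeries(str(sid), g))
    return out
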