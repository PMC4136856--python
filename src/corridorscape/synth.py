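"""Synthetic valley-corridor landscapes with known ground truth.

Generates the study-system template every downstream stage is tested
against: a north–south river valley bisecting two forested mountain blocks,
a winding two-lane road along the valley floor with residences clustered
beside it, cropland near the road, nature reserves on both flanks, and the
covariate layers (elevation, slope, forest age and composition, bamboo,
distances to infrastructure) a camera-trap occupancy study would assemble.
True occupancy and detection parameters are known, so surveys, validation
transects and the whole estimation pipeline can be checked against the
generating model.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from shapely.geometry import LineString, Point, Polygon

from .covariates import distance_to_features, slope_from_elevation
from .features import Cropland, FeatureSet, Reserve, Residence, Road
from .grid import CovariateStack, RasterGrid
from .occupancy import DetectionHistory

FOREST_AGE_LABELS = ["secondary", "primary"]
FOREST_COMP_LABELS = ["nonforest", "conifer", "mixed", "broadleaf"]
BAMBOO_LABELS = ["absent", "present"]
RESERVE_LABELS = ["none", "provincial", "national"]


@dataclass
class LandscapeConfig:
    """Geometry and feature parameters of a generated valley landscape."""

    n_rows: int = 100
    n_cols: int = 120
    cell_size: float = 100.0          # m; the study's working resolution
    origin_x: float = 0.0
    origin_y: float = 0.0
    valley_col_frac: float = 0.5      # valley axis position (fraction of width)
    valley_width_m: float = 2000.0
    valley_wind_amp_m: float = 1500.0  # sinuosity amplitude of the axis
    valley_wind_period_m: float = 4000.0
    base_elevation_m: float = 1200.0  # valley floor
    relief_amplitude_m: float = 1400.0
    noise_relief_m: float = 200.0
    n_residences: int = 24
    large_residence_frac: float = 0.3
    residence_road_sd_m: float = 250.0  # perpendicular scatter from the road
    cropland_fraction: float = 0.05
    bamboo_prevalence: float = 0.45
    bamboo_elev_center_m: float = 1600.0
    bamboo_elev_sd_m: float = 500.0
    patch_scale_cells: float = 6.0    # forest age / composition patch size
    human_strip_width_m: float = 1200.0  # farmland/settlement belt by the road
    seed: int = 0

    def __post_init__(self):
        if self.valley_width_m <= 0 or self.relief_amplitude_m < 0:
            raise ValueError("widths and amplitudes must be positive")
        if not 0 <= self.cropland_fraction <= 1:
            raise ValueError("cropland_fraction must be in [0, 1]")
        if self.valley_width_m >= self.n_cols * self.cell_size:
            raise ValueError("valley wider than the grid")


@dataclass
class TrueModel:
    """Generating occupancy (beta) and detection (alpha) parameters.

    ``occ_terms`` maps a stack layer to (coefficient, center, scale): the
    layer enters the logit as coef * (x - center) / scale, so coefficients
    are on an interpretable per-SD-like scale.  Detection is logit-linear
    with a lure effect, temperature-class offsets (low is the reference)
    and a camera-view effect.
    """

    occ_intercept: float = 0.0
    occ_terms: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    det_intercept: float = 0.0
    det_lure: float = 0.0
    det_temp_medium: float = 0.0
    det_temp_high: float = 0.0
    det_camera_view: float = 0.0

    def __post_init__(self):
        vals = [self.occ_intercept, self.det_intercept, self.det_lure,
                self.det_temp_medium, self.det_temp_high, self.det_camera_view]
        vals += [v for t in self.occ_terms.values() for v in t]
        if not np.all(np.isfinite(vals)):
            raise ValueError("true-model parameters must be finite")

    @classmethod
    def panda_like(cls) -> "TrueModel":
        """Defaults shaped like the field system: occupancy favours low
        elevation, gentle slope, bamboo and primary forest, and distance
        from roads and large residences; detection is helped by scent lure
        and low temperature and unaffected by camera view."""
        return cls(
            occ_intercept=0.2,
            occ_terms={
                "elevation": (-1.6, 1900.0, 500.0),
                "slope": (-0.9, 18.0, 12.0),
                "bamboo": (1.8, 0.0, 1.0),
                "forest_age": (1.6, 0.0, 1.0),
                "dist_road": (1.4, 2500.0, 2000.0),
                "dist_large_residence": (1.2, 3000.0, 2500.0),
            },
            det_intercept=-0.3,
            det_lure=1.0,
            det_temp_medium=-0.5,
            det_temp_high=-1.0,
            det_camera_view=0.0,
        )

    def detection_logit(self, lure, temperature, camera_view):
        return (self.det_intercept
                + self.det_lure * np.asarray(lure, float)
                + self.det_temp_medium * (np.asarray(temperature) == 1)
                + self.det_temp_high * (np.asarray(temperature) == 2)
                + self.det_camera_view * np.asarray(camera_view, float))


@dataclass
class SurveyDesign:
    """Camera-array survey layout mirroring a rotating-panel design:
    ``n_arrays`` east-west blocks, ``sites_per_array`` cameras per block
    per period, deployments of ``deployment_days`` (uniform range) cut into
    ``occasion_days`` occasions, minimum spacing between concurrent sites."""

    n_arrays: int = 8
    sites_per_array: int = 3
    n_periods: int = 10
    deployment_days: tuple[int, int] = (30, 50)
    occasion_days: int = 5
    lure_prob: float = 0.85
    camera_limited_prob: float = 0.4
    min_spacing_m: float = 500.0

    def __post_init__(self):
        if min(self.n_arrays, self.sites_per_array, self.n_periods,
               self.occasion_days) < 1:
            raise ValueError("design counts must be positive")
        if self.deployment_days[0] > self.deployment_days[1]:
            raise ValueError("bad deployment-day range")


# ---------------------------------------------------------------------------
# Landscape generation
# ---------------------------------------------------------------------------

def _smooth_field(rng, shape, scale_cells) -> np.ndarray:
    """Zero-mean, unit-variance smooth Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), scale_cells, mode="reflect")
    return (f - f.mean()) / (f.std() + 1e-12)


def generate_landscape(config: LandscapeConfig) -> tuple[CovariateStack, FeatureSet]:
    """Build the covariate stack and feature set of one valley landscape."""
    rng = np.random.default_rng(config.seed)
    shape = (config.n_rows, config.n_cols)
    template = RasterGrid(np.zeros(shape), config.cell_size,
                          config.origin_x, config.origin_y)
    xs, ys = template.cell_centers()

    # valley axis: x position as a function of y (winding north-south)
    def axis_x(y):
        return (config.origin_x + config.valley_col_frac * config.n_cols
                * config.cell_size
                + config.valley_wind_amp_m
                * np.sin(2 * np.pi * y / config.valley_wind_period_m))

    # elevation: ridge-valley profile + correlated noise
    dx = xs - axis_x(ys)
    sigma = config.valley_width_m / 2.0
    profile = 1.0 - np.exp(-0.5 * (dx / sigma) ** 2)
    elev_vals = (config.base_elevation_m
                 + config.relief_amplitude_m * profile
                 + config.noise_relief_m
                 * _smooth_field(rng, shape, config.patch_scale_cells))
    elevation = template.like(elev_vals)
    slope, slope_class = slope_from_elevation(elevation)

    # road: polyline tracking the valley axis
    y_pts = np.linspace(ys.min(), ys.max(), max(config.n_rows // 2, 8))
    road_line = LineString(np.column_stack([axis_x(y_pts), y_pts]))
    roads = [Road(road_line, "provincial")]

    # residences: clustered along the road
    residences = []
    if config.n_residences > 0:
        stations = rng.uniform(0, road_line.length, config.n_residences)
        n_large = int(round(config.large_residence_frac * config.n_residences))
        is_large = np.zeros(config.n_residences, dtype=bool)
        is_large[rng.choice(config.n_residences, n_large, replace=False)] = True
        for s, big in zip(np.sort(stations), is_large):
            base = road_line.interpolate(s)
            px = base.x + rng.normal(0, config.residence_road_sd_m)
            py = base.y + rng.normal(0, config.residence_road_sd_m)
            hh = int(rng.integers(3, 15)) if big else int(rng.integers(1, 3))
            residences.append(Residence.from_households(Point(px, py), hh))

    # cropland: rectangles near the road covering ~cropland_fraction of area
    cropland = []
    total_area = config.n_rows * config.n_cols * config.cell_size ** 2
    target = config.cropland_fraction * total_area
    area = 0.0
    while area < target:
        s = rng.uniform(0, road_line.length)
        c = road_line.interpolate(s)
        w = rng.uniform(300, 800)
        h = rng.uniform(300, 800)
        off = rng.uniform(-600, 600)
        poly = shapely.box(c.x + off - w / 2, c.y - h / 2,
                           c.x + off + w / 2, c.y + h / 2)
        cropland.append(Cropland(poly))
        area += poly.area

    # reserves: national blocks on both flanks, none in the valley
    x0, x1 = xs.min(), xs.max()
    y0, y1 = ys.min(), ys.max()
    margin = config.valley_width_m * 1.5
    cx = config.origin_x + config.valley_col_frac * config.n_cols * config.cell_size
    reserves = [
        Reserve(shapely.box(x0, y0, cx - margin, y1), "national"),
        Reserve(shapely.box(cx + margin, y0, x1, y1), "national"),
    ]
    features = FeatureSet(roads, residences, cropland, reserves)

    # the human-dominated valley strip: farmland and settlement along the
    # road where mature forest and bamboo understory are absent
    dist_road_grid = distance_to_features(template, features, "road")
    human_strip = dist_road_grid.values < config.human_strip_width_m

    # forest age: secondary near the valley floor, patchy primary on flanks
    age_field = profile * 2.0 - 1.0 + 0.8 * _smooth_field(
        rng, shape, config.patch_scale_cells)
    forest_age = template.like(
        ((age_field > 0) & ~human_strip).astype(float))

    # forest composition: four classes from a smooth field + elevation
    comp_field = (_smooth_field(rng, shape, config.patch_scale_cells)
                  + (elev_vals - elev_vals.mean()) / elev_vals.std())
    q = np.quantile(comp_field, [0.15, 0.45, 0.75])
    forest_comp = template.like(np.digitize(comp_field, q).astype(float))

    # bamboo: Bernoulli with probability peaked in the preferred band
    band = np.exp(-0.5 * ((elev_vals - config.bamboo_elev_center_m)
                          / config.bamboo_elev_sd_m) ** 2)
    logit0 = np.log(config.bamboo_prevalence / (1 - config.bamboo_prevalence))
    pb = expit(logit0 + 2.0 * (band - band.mean())
               + 0.8 * _smooth_field(rng, shape, config.patch_scale_cells))
    bamboo = template.like(
        ((rng.random(shape) < pb) & ~human_strip).astype(float))

    # reserve-type raster from polygons
    pts = shapely.points(xs.ravel(), ys.ravel())
    res_codes = np.zeros(xs.size)
    for r in features.reserves:
        inside = shapely.contains(r.geometry, pts)
        res_codes[inside] = RESERVE_LABELS.index(r.level)
    reserve_type = template.like(res_codes.reshape(shape))

    layers = {
        "elevation": elevation,
        "slope": slope,
        "slope_class": slope_class,
        "forest_age": forest_age,
        "forest_comp": forest_comp,
        "bamboo": bamboo,
        "reserve_type": reserve_type,
        "dist_road": dist_road_grid,
        "dist_small_residence": distance_to_features(
            template, features, "residence", "small"),
        "dist_large_residence": distance_to_features(
            template, features, "residence", "large"),
        "dist_residence": distance_to_features(template, features, "residence"),
        "dist_cropland": distance_to_features(template, features, "cropland"),
    }
    kinds = {n: "continuous" for n in layers}
    for n in ("slope_class", "forest_age", "forest_comp", "bamboo",
              "reserve_type"):
        kinds[n] = "categorical"
    labels = {
        "slope_class": ["lt5", "5to20", "gt20"],
        "forest_age": FOREST_AGE_LABELS,
        "forest_comp": FOREST_COMP_LABELS,
        "bamboo": BAMBOO_LABELS,
        "reserve_type": RESERVE_LABELS,
    }
    return CovariateStack(layers, kinds, labels), features


# ---------------------------------------------------------------------------
# Truth and surveys
# ---------------------------------------------------------------------------

def simulate_truth(stack: CovariateStack, truth: TrueModel) -> RasterGrid:
    """True occupancy-probability surface psi = logistic(beta . x)."""
    grid = stack.grid
    eta = np.full(grid.shape, truth.occ_intercept, dtype=float)
    valid = np.ones(grid.shape, dtype=bool)
    for name, (coef, center, scale) in truth.occ_terms.items():
        if name not in stack:
            raise ValueError(f"truth references missing layer {name!r}")
        layer = stack[name]
        valid &= layer.valid_mask
        x = np.where(layer.valid_mask, layer.values, center)
        eta += coef * (x - center) / scale
    psi = expit(eta)
    return grid.like(np.where(valid, psi, grid.nodata))


def _place_sites(psi: RasterGrid, design: SurveyDesign, rng) -> list[tuple[int, int]]:
    """Rotating-panel site placement: arrays are vertical bands spanning the
    east-west axis; each period draws ``sites_per_array`` cells per array
    respecting the minimum spacing (bounded retries)."""
    n_rows, n_cols = psi.shape
    band_w = n_cols // design.n_arrays
    if band_w < 1:
        raise ValueError("more arrays than grid columns")
    sites: list[tuple[int, int]] = []
    min_cells = design.min_spacing_m / psi.cell_size
    for _period in range(design.n_periods):
        period_sites: list[tuple[int, int]] = []
        for a in range(design.n_arrays):
            c0, c1 = a * band_w, (a + 1) * band_w
            placed = 0
            for _try in range(500):
                if placed >= design.sites_per_array:
                    break
                r = int(rng.integers(0, n_rows))
                c = int(rng.integers(c0, c1))
                if psi.is_nodata(psi.values[r, c]):
                    continue
                ok = all(np.hypot(r - rr, c - cc) >= min_cells
                         for rr, cc in period_sites)
                if ok:
                    period_sites.append((r, c))
                    placed += 1
            if placed < design.sites_per_array:
                raise RuntimeError(
                    "cannot satisfy site spacing; relax min_spacing_m or "
                    "enlarge the grid")
        sites.extend(period_sites)
    return sites


def build_site_table(stack: CovariateStack, rows, cols) -> pd.DataFrame:
    """Covariate values of the stack at a list of cells."""
    grid = stack.grid
    recs = {"site_id": np.arange(len(rows)), "row": rows, "col": cols}
    xy = np.array([grid.cell_center(r, c) for r, c in zip(rows, cols)])
    recs["x"], recs["y"] = xy[:, 0], xy[:, 1]
    for name in stack.names():
        recs[name] = [stack[name].values[r, c] for r, c in zip(rows, cols)]
    return pd.DataFrame(recs)


def simulate_surveys(
    psi_map: RasterGrid,
    stack: CovariateStack,
    truth: TrueModel,
    design: SurveyDesign,
    seed: int = 0,
) -> tuple[pd.DataFrame, DetectionHistory]:
    """Draw latent occupancy and detection histories at surveyed sites.

    Latent z_site ~ Bernoulli(psi at site) once per site (closed
    population); y_(site,occasion) ~ Bernoulli(z * p_occasion) with p from
    the true detection parameters and occasion covariates (lure and camera
    view constant per deployment, temperature class from the deployment
    period's season).
    """
    rng = np.random.default_rng(seed)
    cells = _place_sites(psi_map, design, rng)
    rows = [r for r, _ in cells]
    cols = [c for _, c in cells]
    table = build_site_table(stack, rows, cols)
    n_sites = len(cells)
    psi = np.array([psi_map.values[r, c] for r, c in cells])
    z = (rng.random(n_sites) < psi).astype(float)

    lo, hi = design.deployment_days
    n_days = rng.integers(lo, hi + 1, n_sites)
    n_occ = n_days // design.occasion_days
    max_occ = int(n_occ.max())
    lure = (rng.random(n_sites) < design.lure_prob).astype(float)
    camera = (rng.random(n_sites) < design.camera_limited_prob).astype(float)
    # temperature from the period's season (3-class annual cycle)
    per_period = design.n_arrays * design.sites_per_array
    period = np.arange(n_sites) // per_period
    temp = (period % 3).astype(float)

    y = np.full((n_sites, max_occ), np.nan)
    occ_cov = {
        "lure": np.tile(lure[:, None], (1, max_occ)),
        "camera_view": np.tile(camera[:, None], (1, max_occ)),
        "temperature": np.tile(temp[:, None], (1, max_occ)),
    }
    p = expit(truth.detection_logit(lure, temp, camera))
    for i in range(n_sites):
        k = int(n_occ[i])
        if k == 0:
            k = 1  # ensure at least one occasion per site
        y[i, :k] = (rng.random(k) < z[i] * p[i]).astype(float)
    table["lure"] = lure
    table["camera_view"] = camera
    table["temperature"] = temp
    table["true_z"] = z
    table["true_psi"] = psi
    history = DetectionHistory(y, occ_cov, list(table["site_id"]))
    return table, history


def simulate_validation_transects(
    psi_map: RasterGrid,
    n_segments: int,
    seed: int = 0,
    segment_length_m: float = 250.0,
    segments_per_transect: int = 6,
    low_psi_fraction: float = 0.0,
    low_psi_quantile: float = 0.5,
    use_seed: int | None = None,
) -> pd.DataFrame:
    """Independent sign-transect segments for map validation.

    Mimics a walked sign survey: straight transects are dropped at random
    positions and bearings, each divided into consecutive
    ``segment_length_m`` segments; the raw sign record of a segment is
    Bernoulli(psi at its center).  The transect structure matters for the
    downstream absence rule — a segment only counts as a confirmed absence
    when no sign was found within 1 km, which requires spatially contiguous
    runs of no-sign segments in poor habitat.  ``low_psi_fraction`` starts
    that share of transects in habitat below the map's
    ``low_psi_quantile``, so unused areas are surveyed too.

    Latent use is a property of the landscape, not of the survey: it is
    drawn once per cell from ``use_seed`` (default: ``seed``), so repeated
    or follow-up surveys of the same landscape see a consistent occupancy
    pattern.  Columns: transect_id, x, y, row, col, sign (0/1), psi_true.
    """
    if n_segments <= 0:
        raise ValueError("n_segments must be positive")
    rng = np.random.default_rng(seed)
    valid = np.argwhere(psi_map.valid_mask)
    # optional stratification: a fraction of transects start in
    # low-suitability habitat, emulating a survey designed to cover
    # unused as well as used areas
    cut = np.quantile(psi_map.values[psi_map.valid_mask], low_psi_quantile)
    low = valid[psi_map.values[valid[:, 0], valid[:, 1]] < cut]
    recs = []
    use_rng = np.random.default_rng(seed if use_seed is None else use_seed)
    z_map = use_rng.random(psi_map.shape) < psi_map.values
    x_min = psi_map.origin_x
    x_max = psi_map.origin_x + psi_map.n_cols * psi_map.cell_size
    y_min = psi_map.origin_y
    y_max = psi_map.origin_y + psi_map.n_rows * psi_map.cell_size
    transect = 0
    attempts = 0
    while len(recs) < n_segments and attempts < 200 * n_segments:
        attempts += 1
        pool = low if (len(low) and rng.random() < low_psi_fraction) else valid
        r, c = pool[rng.integers(len(pool))]
        x0, y0 = psi_map.cell_center(int(r), int(c))
        theta = rng.uniform(0, 2 * np.pi)
        dx = np.cos(theta) * segment_length_m
        dy = np.sin(theta) * segment_length_m
        placed = 0
        for k in range(segments_per_transect):
            x, y = x0 + k * dx, y0 + k * dy
            if not (x_min < x < x_max and y_min < y < y_max):
                break
            rr, cc = psi_map.index_of(x, y)
            if not psi_map.valid_mask[rr, cc]:
                break
            psi = psi_map.values[rr, cc]
            # latent use is shared by every segment crossing a cell: sign
            # records cluster at the occupancy scale while each segment
            # keeps its Bernoulli(psi) marginal
            sign = int(z_map[rr, cc])
            recs.append((transect, x, y, rr, cc, sign, psi))
            placed += 1
            if len(recs) >= n_segments:
                break
        if placed:
            transect += 1
    df = pd.DataFrame(
        recs, columns=["transect_id", "x", "y", "row", "col", "sign",
                       "psi_true"])
    df["segment_length_m"] = segment_length_m
    return df
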