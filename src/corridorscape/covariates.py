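"""Model-ready covariates: distances, slope, collinearity screen, form choice.

Turns the raw layer stack and feature sets into the site-level covariate
table the occupancy model consumes.  Distance layers measure Euclidean
meters from each cell center to the nearest feature of a class; slope comes
from the 8-neighbour Horn finite-difference kernel; collinearity screening
applies the conventional pairwise |r| < 0.7 rule with a deterministic greedy
elimination; functional-form choice compares raw, log and quadratic
single-covariate occupancy models by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .features import FeatureSet
from .grid import RasterGrid

COLLINEARITY_THRESHOLD = 0.7
SLOPE_CLASS_EDGES = (5.0, 20.0)  # degrees; classes [0,5), [5,20), [20,90]
SLOPE_CLASS_LABELS = ("lt5", "5to20", "gt20")


# ---------------------------------------------------------------------------
# Distance layers
# ---------------------------------------------------------------------------

def distance_to_features(
    grid: RasterGrid,
    features: FeatureSet,
    kind: str,
    class_filter: str | None = None,
    cap: float | None = None,
) -> RasterGrid:
    """Distance (m) from every cell center to the nearest matching feature.

    ``kind`` is one of ``road``, ``residence``, ``cropland``; ``class_filter``
    restricts to a road class or residence size class.  When no feature
    matches, every cell gets ``cap`` (default: the grid diagonal), keeping
    the covariate finite.
    """
    if kind == "road":
        geoms = features.road_geometries(class_filter)
    elif kind == "residence":
        geoms = features.residence_geometries(class_filter)
    elif kind == "cropland":
        if class_filter is not None:
            raise ValueError("cropland has no class filter")
        geoms = [c.geometry for c in features.cropland]
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    cap = grid.diagonal if cap is None else cap
    if not geoms:
        return grid.like(np.full(grid.shape, cap))
    xs, ys = grid.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    target = shapely.union_all(geoms)
    d = shapely.distance(pts, target).reshape(grid.shape)
    return grid.like(np.minimum(d, cap))


# ---------------------------------------------------------------------------
# Slope
# ---------------------------------------------------------------------------

def slope_from_elevation(elev: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Slope in degrees (Horn kernel) and its categorical class raster.

    Edge cells use replicated-edge (one-sided) differences.  Class codes
    index :data:`SLOPE_CLASS_LABELS`: 0 = [0°, 5°), 1 = [5°, 20°),
    2 = [20°, 90°].  Nodata propagates; slope is invariant to adding a
    constant to the elevation field.
    """
    if not elev.valid_mask.any():
        raise ValueError("elevation raster is entirely nodata")
    z = np.where(elev.valid_mask, elev.values, np.nan)
    # fill nodata with nearest finite value along rows for the kernel only
    zp = np.pad(z, 1, mode="edge")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2]; f = zp[1:-1, 2:]
    g = zp[2:, :-2]; h = zp[2:, 1:-1]; i = zp[2:, 2:]
    cs = elev.cell_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cs)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    bad = ~np.isfinite(slope) | elev.nodata_mask
    slope_vals = np.where(bad, elev.nodata, slope)
    classes = np.digitize(np.where(bad, 0.0, slope), SLOPE_CLASS_EDGES).astype(float)
    classes = np.where(bad, elev.nodata, classes)
    return elev.like(slope_vals), elev.like(classes)


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    retained: list[str]
    dropped: list[tuple[str, str]]  # (name, reason)
    correlation: pd.DataFrame


def screen_collinearity(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    threshold: float = COLLINEARITY_THRESHOLD,
    priority: list[str] | None = None,
) -> ScreenResult:
    """Greedy elimination until all pairwise |r| < ``threshold``.

    Zero-variance covariates are dropped first (reported).  While any pair
    violates the threshold, the worst pair's member with the larger mean
    absolute correlation to all remaining covariates is dropped; ties break
    by ``priority`` (earlier names are kept), then alphabetically (the
    later name is dropped).  The result is idempotent and insensitive to
    column order given a priority list.
    """
    covariates = list(covariates or table.columns)
    if len(covariates) < 2:
        raise ValueError("need at least two covariates to screen")
    if len(table) < 3:
        raise ValueError("need at least three sites to estimate correlations")
    dropped: list[tuple[str, str]] = []
    live = []
    for name in covariates:
        if np.std(table[name].to_numpy(dtype=float)) == 0:
            dropped.append((name, "zero variance"))
        else:
            live.append(name)
    corr_full = table[sorted(live)].corr()

    def keep_rank(name: str) -> tuple:
        if priority and name in priority:
            return (0, priority.index(name), name)
        return (1, 0, name)

    live = sorted(live)
    while len(live) > 1:
        r = corr_full.loc[live, live].to_numpy()
        np.fill_diagonal(r, 0.0)
        absr = np.abs(r)
        if absr.max() < threshold:
            break
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        pair = sorted((live[i], live[j]))
        mean_abs = {
            n: np.mean([abs(corr_full.loc[n, m]) for m in live if m != n])
            for n in pair
        }
        if not np.isclose(mean_abs[pair[0]], mean_abs[pair[1]]):
            victim = max(pair, key=lambda n: mean_abs[n])
        else:
            victim = max(pair, key=keep_rank)
        live.remove(victim)
        dropped.append((victim, f"|r|>={threshold} with {[p for p in pair if p != victim][0]}"))
    return ScreenResult(live, dropped, corr_full)


# ---------------------------------------------------------------------------
# Functional-form choice
# ---------------------------------------------------------------------------

@dataclass
class FormChoice:
    covariate: str
    form: str  # "raw" | "log" | "quadratic"
    aics: dict[str, float]

    def __post_init__(self):
        fitted = {k: v for k, v in self.aics.items() if np.isfinite(v)}
        if fitted and self.aics[self.form] > min(fitted.values()) + 1e-9:
            raise ValueError("chosen form must minimise AIC")


FORM_ORDER = ("raw", "log", "quadratic")  # tie preference: simpler first


def select_covariate_form(history, table: pd.DataFrame, covariate: str,
                          **fit_kwargs) -> FormChoice:
    """Pick raw vs log(x+1) vs quadratic for one continuous covariate.

    Fits three single-occupancy-covariate models with an intercept-only
    detection model and returns the minimal-AIC form; exact AIC ties go to
    the simpler form (raw > log > quadratic).  Non-convergent candidates
    are recorded with AIC = inf and excluded.
    """
    from .occupancy import ModelSpec, fit_occupancy

    x = table[covariate].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError(f"covariate {covariate!r} has zero variance")
    aics = {}
    for form in FORM_ORDER:
        if form == "log" and np.any(x < 0):
            aics[form] = float("inf")
            continue
        spec = ModelSpec(occ_terms=[(covariate, form)], det_terms=[])
        fit = fit_occupancy(spec, history, table, **fit_kwargs)
        aics[form] = fit.aic if fit.converged else float("inf")
    finite = {f: a for f, a in aics.items() if np.isfinite(a)}
    if not finite:
        raise RuntimeError(f"no candidate form converged for {covariate!r}")
    best_aic = min(finite.values())
    for form in FORM_ORDER:  # simpler-form tie break
        if np.isfinite(aics[form]) and aics[form] <= best_aic + 1e-9:
            return FormChoice(covariate, form, aics)
    raise AssertionError("unreachable")
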