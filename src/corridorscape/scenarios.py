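"""Management scenarios and their comparison statistics.

Three landscape edits mirror the management options weighed for valley
corridors: forest/bamboo restoration (young forest inside a region becomes
mature forest with a bamboo understory), residence relocation (residences of
a size class removed), and tunnel construction (a road segment is carried
underground, so the abandoned surface section stops acting as a barrier).
Each scenario's stack re-derives every dependent layer (distances, forest
age, bamboo), the averaged occupancy model re-predicts suitability, the cost
surface is re-inverted, and the 25 fixed pathway geometries found under the
baseline are re-costed.  Scenarios are compared with a two-way ANOVA
(scenario + pathway, no interaction) and paired t-tests with Holm's
step-down adjustment at family-wise alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Polygon
from shapely.ops import substring

from .connectivity import CostSurface, PathSet, cost_surface, path_cost_on_surface
from .covariates import distance_to_features
from .features import FeatureSet, Road
from .grid import CovariateStack
from .occupancy import AveragedModel, predict_suitability

FAMILYWISE_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------

@dataclass
class RestoreForest:
    region: Polygon


@dataclass
class RemoveResidences:
    size_class: str = "large"
    region: Polygon | None = None


@dataclass
class Tunnel:
    road_index: int
    start_m: float
    end_m: float

    def __post_init__(self):
        if self.end_m <= self.start_m:
            raise ValueError("tunnel segment must have positive length")


@dataclass
class ScenarioSpec:
    name: str
    edits: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Applying edits
# ---------------------------------------------------------------------------

_DISTANCE_LAYERS = {
    "dist_road": ("road", None),
    "dist_small_residence": ("residence", "small"),
    "dist_large_residence": ("residence", "large"),
    "dist_residence": ("residence", None),
    "dist_cropland": ("cropland", None),
}


def apply_scenario(
    stack: CovariateStack, features: FeatureSet, spec: ScenarioSpec
) -> tuple[CovariateStack, FeatureSet]:
    """Apply a scenario's edits (in declared order) and recompute every
    derived layer whose inputs changed; untouched layers stay identical."""
    stack = stack.copy()
    features = features.copy()
    grid = stack.grid
    dirty: set[str] = set()
    for edit in spec.edits:
        if isinstance(edit, RestoreForest):
            xs, ys = grid.cell_centers()
            inside = shapely.contains(
                edit.region, shapely.points(xs.ravel(), ys.ravel())
            ).reshape(grid.shape)
            if not inside.any():
                warnings.warn(f"{spec.name}: restoration region off-grid; no-op")
            if "forest_age" in stack:
                lay = stack["forest_age"]
                lay.values[inside & lay.valid_mask] = 1.0  # primary
            if "bamboo" in stack:
                lay = stack["bamboo"]
                lay.values[inside & lay.valid_mask] = 1.0  # present
        elif isinstance(edit, RemoveResidences):
            before = len(features.residences)
            def _keep(res):
                if res.size_class != edit.size_class:
                    return True
                if edit.region is not None and not edit.region.contains(res.geometry):
                    return True
                return False
            features.residences = [r for r in features.residences if _keep(r)]
            if len(features.residences) == before:
                warnings.warn(f"{spec.name}: no residences matched; no-op")
            dirty.update(k for k, (kind, _) in _DISTANCE_LAYERS.items()
                         if kind == "residence")
        elif isinstance(edit, Tunnel):
            road = features.roads[edit.road_index]
            line = road.geometry
            if edit.start_m >= line.length:
                warnings.warn(f"{spec.name}: tunnel beyond road end; no-op")
                continue
            parts = []
            if edit.start_m > 0:
                parts.append(substring(line, 0, edit.start_m))
            if edit.end_m < line.length:
                parts.append(substring(line, edit.end_m, line.length))
            features.roads.pop(edit.road_index)
            for p in parts:
                if p.length > 0:
                    features.roads.append(Road(p, road.road_class))
            dirty.add("dist_road")
        else:
            raise TypeError(f"unknown edit {type(edit).__name__}")
    for name in dirty & set(stack.names()):
        kind, cls = _DISTANCE_LAYERS[name]
        stack.layers[name] = distance_to_features(grid, features, kind, cls)
    return stack, features


# ---------------------------------------------------------------------------
# Re-costing fixed pathways
# ---------------------------------------------------------------------------

@dataclass
class ScenarioComparison:
    matrix: pd.DataFrame           # path x scenario cost indices
    summary: pd.DataFrame          # per-scenario mean and SE
    anova: pd.DataFrame
    pairwise: pd.DataFrame


def scenario_costs(
    stack: CovariateStack,
    features: FeatureSet,
    scenarios: list[ScenarioSpec],
    avg: AveragedModel,
    paths: PathSet,
    cost_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Cost-index matrix M[path, scenario] for the FIXED baseline pathway
    geometries, re-costed under each scenario's re-predicted suitability.

    The first column, ``baseline``, is computed from the unedited stack and
    equals the original pathway indices.  Paths crossing cells a scenario
    makes impassable become NaN with a warning.
    """
    cost_kwargs = cost_kwargs or {}
    edited_layers = {"dist_road": "tunnel/road edits",
                     "dist_large_residence": "residence edits",
                     "dist_small_residence": "residence edits",
                     "forest_age": "restoration", "bamboo": "restoration"}
    model_covs = {name for name, _ in avg.terms
                  if any(abs(v) > 1e-12 and (c == name or c.startswith(name))
                         for c, v in avg.coefficients.items()
                         for _ in [0])}
    missing = [n for n in edited_layers if n not in model_covs]
    if missing:
        warnings.warn(
            "averaged model carries no effect for "
            f"{sorted(missing)}; scenarios editing only these layers will "
            "show zero predicted change")
    feasible = [p for p in paths.paths if p.flag != "infeasible"]
    labels = [f"{p.source_label}-{p.sink_label}" for p in feasible]
    cols: dict[str, list[float]] = {}
    worlds = [("baseline", stack, features)]
    for sc in scenarios:
        st, ft = apply_scenario(stack, features, sc)
        worlds.append((sc.name, st, ft))
    for name, st, _ft in worlds:
        psi = predict_suitability(avg, st)
        cs = cost_surface(psi, **cost_kwargs)
        vals = []
        for p in feasible:
            try:
                total, length = path_cost_on_surface(p.cells, cs)
                vals.append(total * 100.0 / length)
            except ValueError:
                warnings.warn(f"path {p.source_label}-{p.sink_label} infeasible "
                              f"under scenario {name!r}")
                vals.append(np.nan)
        cols[name] = vals
    return pd.DataFrame(cols, index=labels)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def two_way_anova(matrix: pd.DataFrame) -> pd.DataFrame:
    """Two-factor ANOVA without interaction on a complete path x scenario
    matrix (one observation per cell).

    Rows are the pathway factor, columns the scenario factor; each factor's
    mean square is tested against the residual mean square.
    """
    M = matrix.to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("cost matrix must be complete (no missing cells)")
    n_p, n_s = M.shape
    if n_p < 2 or n_s < 2:
        raise ValueError("need at least two levels per factor")
    grand = M.mean()
    ss_scen = n_p * ((M.mean(axis=0) - grand) ** 2).sum()
    ss_path = n_s * ((M.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((M - grand) ** 2).sum()
    ss_resid = ss_total - ss_scen - ss_path
    df_s, df_p = n_s - 1, n_p - 1
    df_r = df_s * df_p
    ms_s, ms_p, ms_r = ss_scen / df_s, ss_path / df_p, ss_resid / df_r

    def _f(ms, df):
        if ms_r <= 0:  # degenerate: no residual variation
            return (0.0, 1.0) if np.isclose(ms, 0.0) else (np.inf, 0.0)
        f = ms / ms_r
        return f, float(stats.f.sf(f, df, df_r))

    f_s, p_s = _f(ms_s, df_s)
    f_p, p_p = _f(ms_p, df_p)
    rows = [
        ("scenario", df_s, ss_scen, ms_s, f_s, p_s),
        ("pathway", df_p, ss_path, ms_p, f_p, p_p),
        ("residual", df_r, ss_resid, ms_r, np.nan, np.nan),
    ]
    return pd.DataFrame(rows, columns=["factor", "df", "SS", "MS", "F", "p"])


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjustment: sort raw p ascending, multiply the i-th
    smallest by (m - i), enforce monotonicity, cap at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = np.maximum.accumulate(p[order] * (m - np.arange(m)))
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def holm_paired_tests(
    matrix: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    alpha: float = FAMILYWISE_ALPHA,
) -> pd.DataFrame:
    """Paired t-tests on per-path cost differences with Holm correction.

    Zero-variance difference vectors make t undefined: reported with
    t = NaN and raw p = 1.  Adjusted p is never below raw p and is
    non-decreasing in raw-p order.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two paths for a paired test")
    recs = []
    for a, b in comparisons:
        d = matrix[a].to_numpy(float) - matrix[b].to_numpy(float)
        if np.allclose(d.std(ddof=1), 0.0):
            recs.append((a, b, float(d.mean()), np.nan, 1.0))
            continue
        t, p = stats.ttest_rel(matrix[a], matrix[b])
        recs.append((a, b, float(d.mean()), float(t), float(p)))
    df = pd.DataFrame(recs, columns=["a", "b", "mean_diff", "t", "p_raw"])
    df["p_holm"] = holm_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["p_holm"] < alpha
    return df


def compare_scenarios(
    matrix: pd.DataFrame,
    comparisons: list[tuple[str, str]] | None = None,
) -> ScenarioComparison:
    """Full comparison bundle: means +/- SE, ANOVA, Holm-adjusted paired
    tests (default: every scenario against baseline plus all scenario
    pairs)."""
    clean = matrix.dropna()
    if len(clean) < len(matrix):
        warnings.warn(f"{len(matrix) - len(clean)} infeasible paths excluded "
                      "from comparison")
    cols = list(clean.columns)
    if comparisons is None:
        comparisons = [(c, cols[0]) for c in cols[1:]]
        comparisons += [(a, b) for i, a in enumerate(cols[1:]) for b in cols[1 + i + 1:]]
    summary = pd.DataFrame({
        "mean": clean.mean(),
        "se": clean.std(ddof=1) / np.sqrt(len(clean)),
    })
    return ScenarioComparison(
        matrix=clean,
        summary=summary,
        anova=two_way_anova(clean),
        pairwise=holm_paired_tests(clean, comparisons),
    )
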