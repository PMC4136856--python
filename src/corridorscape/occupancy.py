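"""Single-season occupancy modelling with imperfect detection.

The model: each site i is occupied with probability ``psi_i`` (logit-linear
in site covariates); given occupancy, the species is detected on occasion t
with probability ``p_it`` (logit-linear in occasion covariates).  With
detection history y the per-site likelihood is the zero-inflated binomial

    L_i = psi_i * prod_t p_it^y_it (1 - p_it)^(1 - y_it)
          + (1 - psi_i) * 1[all y_it = 0],

missing occasions dropping out of the product.  Model selection is by AIC:
detection covariates are chosen first under the full occupancy model, then
all subsets of occupancy covariates are ranked, and models within 2 AIC of
the best are averaged (zero substitution) into one predictive equation.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

log = logging.getLogger(__name__)

DET_COVARIATES = ("lure", "temperature", "camera_view")
TEMPERATURE_LABELS = ("low", "medium", "high")  # <5, 5-15, >15 degrees C
LOGIT_BOUND = 15.0
_EPS = 1e-12


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class DetectionHistory:
    """Site-by-occasion binary detections with occasion covariates.

    ``y`` is float with NaN marking missing occasions.  Occasion covariate
    arrays are aligned with ``y``: ``lure`` and ``camera_view`` binary,
    ``temperature`` coded 0/1/2 for low/medium/high.
    """

    y: np.ndarray
    occasion_covariates: dict[str, np.ndarray] = field(default_factory=dict)
    site_ids: list = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("detection history must be 2-D (sites x occasions)")
        obs = ~np.isnan(self.y)
        if not obs.any(axis=1).all():
            raise ValueError("every site needs at least one observed occasion")
        vals = self.y[obs]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("detections must be 0/1 (NaN for missing)")
        for name, arr in self.occasion_covariates.items():
            if np.asarray(arr).shape != self.y.shape:
                raise ValueError(f"occasion covariate {name!r} shape mismatch")
        if self.site_ids is None:
            self.site_ids = list(range(self.y.shape[0]))

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]


@dataclass
class ModelSpec:
    """One candidate model: occupancy terms (name, form) + detection terms.

    Forms: ``raw``, ``log`` (log(x+1)), ``quadratic`` (z and z^2),
    ``categorical`` (dummy columns against the first category).  Detection
    terms are a subset of :data:`DET_COVARIATES`.  Both parts include
    intercepts implicitly.
    """

    occ_terms: list[tuple[str, str]] = field(default_factory=list)
    det_terms: list[str] = field(default_factory=list)

    def __post_init__(self):
        names = [n for n, _ in self.occ_terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate occupancy terms")
        if len(set(self.det_terms)) != len(self.det_terms):
            raise ValueError("duplicate detection terms")
        for t in self.det_terms:
            if t not in DET_COVARIATES:
                raise ValueError(f"unknown detection covariate {t!r}")

    def label(self) -> str:
        occ = ", ".join(n for n, _ in self.occ_terms) or "(intercept)"
        return occ


@dataclass
class FitResult:
    spec: ModelSpec
    beta: np.ndarray            # occupancy coefficients, logit scale
    alpha: np.ndarray           # detection coefficients, logit scale
    beta_names: list[str]
    alpha_names: list[str]
    loglik: float
    converged: bool
    boundary: bool = False
    message: str = ""
    standardization: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.beta) + len(self.alpha)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def coef(self) -> dict[str, float]:
        out = {f"psi:{n}": v for n, v in zip(self.beta_names, self.beta)}
        out.update({f"p:{n}": v for n, v in zip(self.alpha_names, self.alpha)})
        return out


# ---------------------------------------------------------------------------
# Detection-history construction
# ---------------------------------------------------------------------------

def build_detection_history(
    deployments: pd.DataFrame,
    detections: pd.DataFrame,
    segment_days: int = 5,
) -> tuple[DetectionHistory, list]:
    """Collapse daily camera records into fixed-length occasions.

    ``deployments`` needs columns ``site_id``, ``n_days`` and optionally the
    occasion covariates (``lure``, ``temperature``, ``camera_view``),
    constant within a deployment.  ``detections`` has ``site_id`` and
    ``day`` (0-based offset from deployment start).  Each deployment is cut
    into consecutive ``segment_days``-day segments; an occasion is 1 iff at
    least one detection falls inside it; the trailing partial segment is
    dropped.  Deployments shorter than one segment are excluded (returned
    in the second element) with a warning.
    """
    if segment_days < 1:
        raise ValueError("segment_days must be >= 1")
    det_by_site: dict = {}
    for _, r in detections.iterrows():
        det_by_site.setdefault(r["site_id"], []).append(int(r["day"]))
    rows, excluded, site_ids = [], [], []
    cov_rows = {name: [] for name in DET_COVARIATES if name in deployments.columns}
    n_occ_max = 0
    per_site = []
    for _, dep in deployments.iterrows():
        sid, n_days = dep["site_id"], int(dep["n_days"])
        days = det_by_site.get(sid, [])
        for d in days:
            if not 0 <= d < n_days:
                raise ValueError(
                    f"detection on day {d} outside deployment window of site {sid}"
                )
        n_occ = n_days // segment_days
        if n_occ == 0:
            warnings.warn(f"site {sid}: deployment of {n_days} d yields no "
                          f"complete {segment_days}-d occasion; excluded")
            excluded.append(sid)
            continue
        occ = np.zeros(n_occ)
        for d in days:
            idx = d // segment_days
            if idx < n_occ:
                occ[idx] = 1.0
        per_site.append((sid, occ, dep))
        n_occ_max = max(n_occ_max, n_occ)
    if not per_site:
        raise ValueError("no usable deployments")
    for sid, occ, dep in per_site:
        padded = np.full(n_occ_max, np.nan)
        padded[: len(occ)] = occ
        rows.append(padded)
        site_ids.append(sid)
        for name in cov_rows:
            cov_rows[name].append(np.full(n_occ_max, float(dep[name])))
    occ_cov = {k: np.array(v) for k, v in cov_rows.items()}
    return DetectionHistory(np.array(rows), occ_cov, site_ids), excluded


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def occupancy_design(
    spec: ModelSpec,
    table: pd.DataFrame,
    standardize: bool = True,
    constants: dict | None = None,
) -> tuple[np.ndarray, list[str], dict]:
    """Occupancy design matrix (with intercept) and the standardization
    constants actually used (computed from ``table`` unless supplied)."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["(intercept)"]
    used: dict[str, tuple[float, float]] = {}
    constants = constants or {}
    for name, form in spec.occ_terms:
        x = table[name].to_numpy(dtype=float)
        if form == "categorical":
            codes = x.astype(int)
            for c in sorted(set(codes))[1:]:
                cols.append((codes == c).astype(float))
                names.append(f"{name}[{c}]")
            continue
        if form == "log":
            if np.any(x < 0):
                raise ValueError(f"log form needs non-negative {name!r}")
            x = np.log1p(x)
        if name in constants:
            m, s = constants[name][:2]
        elif standardize:
            m, s = float(x.mean()), float(x.std())
            s = s if s > 0 else 1.0
        else:
            m, s = 0.0, 1.0
        # the observed range travels with the constants so that later
        # predictions (e.g. scenario-edited landscapes) never extrapolate
        # the logit-linear form beyond the data that fitted it
        used[name] = (m, s, float(x.min()), float(x.max()))
        z = (x - m) / s
        if form in ("raw", "log"):
            cols.append(z)
            names.append(name if form == "raw" else f"log({name})")
        elif form == "quadratic":
            cols.append(z); names.append(name)
            cols.append(z ** 2); names.append(f"{name}^2")
        else:
            raise ValueError(f"unknown form {form!r}")
    return np.column_stack(cols), names, used


def detection_design(
    spec: ModelSpec, history: DetectionHistory
) -> tuple[list[np.ndarray], list[str]]:
    """Per-occasion detection design: list of (n_sites, n_occ) arrays."""
    mats = [np.ones_like(history.y)]
    names = ["(intercept)"]
    for term in spec.det_terms:
        arr = history.occasion_covariates.get(term)
        if arr is None:
            raise ValueError(f"history lacks occasion covariate {term!r}")
        if term == "temperature":
            for code, lab in ((1, "medium"), (2, "high")):
                mats.append((arr == code).astype(float))
                names.append(f"temperature[{lab}]")
        else:
            mats.append(np.asarray(arr, dtype=float))
            names.append(term)
    return mats, names


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _nll_parts(params, X_occ, det_mats, y):
    nb = X_occ.shape[1]
    beta, alpha = params[:nb], params[nb:]
    psi = expit(X_occ @ beta)
    psi = np.clip(psi, _EPS, 1.0 - _EPS)
    eta = np.zeros_like(y)
    for a, D in zip(alpha, det_mats):
        eta = eta + a * D
    p = np.clip(expit(eta), _EPS, 1.0 - _EPS)
    obs = ~np.isnan(y)
    y0 = np.where(obs, y, 0.0)
    log_terms = np.where(obs, y0 * np.log(p) + (1.0 - y0) * np.log1p(-p), 0.0)
    c = np.exp(log_terms.sum(axis=1))
    z = np.where((y0 * obs).sum(axis=1) == 0, 1.0, 0.0)
    L = psi * c + (1.0 - psi) * z
    return beta, alpha, psi, p, obs, y0, c, z, L


def occupancy_negloglik(params, X_occ, det_mats, y) -> float:
    """Negative log-likelihood of the zero-inflated binomial occupancy
    model; missing occasions (NaN) skipped."""
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameters")
    *_, L = _nll_parts(params, X_occ, det_mats, y)
    return float(-np.log(L).sum())


def occupancy_negloglik_grad(params, X_occ, det_mats, y):
    """NLL and its analytic gradient (beta then alpha)."""
    params = np.asarray(params, dtype=float)
    beta, alpha, psi, p, obs, y0, c, z, L = _nll_parts(params, X_occ, det_mats, y)
    w = 1.0 / L
    # beta: dL/dpsi = c - z
    gpsi = -w * (c - z) * psi * (1.0 - psi)
    gbeta = X_occ.T @ gpsi
    # alpha: dL/dalpha_j = psi * c * sum_t (y - p) D_j
    resid = np.where(obs, y0 - p, 0.0)
    coef = -w * psi * c
    galpha = np.array([(coef * (resid * D).sum(axis=1)).sum() for D in det_mats])
    return float(-np.log(L).sum()), np.concatenate([gbeta, galpha])


def negloglik_for_spec(
    spec: ModelSpec, params, history: DetectionHistory, table: pd.DataFrame,
    standardize: bool = True,
) -> float:
    """Convenience wrapper building the designs from a spec."""
    X, _, _ = occupancy_design(spec, table, standardize=standardize)
    D, _ = detection_design(spec, history)
    return occupancy_negloglik(np.asarray(params, float), X, D, history.y)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_occupancy(
    spec: ModelSpec,
    history: DetectionHistory,
    table: pd.DataFrame,
    init: np.ndarray | None = None,
    n_starts: int = 5,
    jitter: float = 0.5,
    seed: int = 0,
    standardize: bool = True,
    bound: float = LOGIT_BOUND,
) -> FitResult:
    """Maximum-likelihood fit by L-BFGS with analytic gradient.

    Multi-start (default 5 jittered starts around ``init``, itself default
    0) takes the best converged optimum.  Estimates are capped at
    ``|coef| <= bound`` with a boundary flag so saturated fixtures (all
    detections, no detections) terminate cleanly.
    """
    X, bnames, consts = occupancy_design(spec, table, standardize=standardize)
    D, anames = detection_design(spec, history)
    npar = X.shape[1] + len(D)
    if npar >= history.n_sites:
        warnings.warn(f"{npar} parameters for {history.n_sites} sites: "
                      "model may be unidentifiable")
    rng = np.random.default_rng(seed)
    base = np.zeros(npar) if init is None else np.asarray(init, dtype=float)
    starts = [base] + [base + rng.normal(0, jitter, npar) for _ in range(n_starts - 1)]
    best = None
    bounds = [(-bound, bound)] * npar
    for s in starts:
        res = minimize(
            occupancy_negloglik_grad, s, args=(X, D, history.y),
            method="L-BFGS-B", jac=True, bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    nb = X.shape[1]
    params = np.clip(best.x, -bound, bound)
    boundary = bool(np.any(np.abs(params) >= bound - 1e-6))
    converged = bool(best.success or boundary)
    return FitResult(
        spec=spec, beta=params[:nb], alpha=params[nb:],
        beta_names=bnames, alpha_names=anames,
        loglik=-float(best.fun), converged=converged, boundary=boundary,
        message=str(best.message), standardization=consts,
    )


# ---------------------------------------------------------------------------
# Model selection and averaging
# ---------------------------------------------------------------------------

@dataclass
class ModelSet:
    """AIC-ranked fits with delta-AIC, Akaike weights, cumulative weight."""

    fits: list[FitResult]
    skipped: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.fits = sorted(self.fits, key=lambda f: f.aic)
        if not self.fits:
            raise ValueError("empty model set")
        aics = np.array([f.aic for f in self.fits])
        self.delta = aics - aics.min()
        w = np.exp(-self.delta / 2.0)
        self.weights = w / w.sum()
        self.cumulative = np.cumsum(self.weights)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "occupancy_covariates": [f.spec.label() for f in self.fits],
            "K": [f.k for f in self.fits],
            "AIC": [f.aic for f in self.fits],
            "delta_AIC": self.delta,
            "AIC_weight": self.weights,
            "cumulative_weight": self.cumulative,
        })


def select_detection_model(
    history: DetectionHistory,
    table: pd.DataFrame,
    occ_terms: list[tuple[str, str]],
    det_pool: list[str] | None = None,
    **fit_kwargs,
) -> tuple[list[str], ModelSet]:
    """Choose detection covariates under the full occupancy model.

    Fits the all-occupancy-covariate model once per subset of the detection
    pool (including the empty set) and returns the minimal-AIC subset; AIC
    ties go to fewer terms, then lexicographic order.
    """
    det_pool = list(det_pool if det_pool is not None else DET_COVARIATES)
    if len(det_pool) > 10:
        raise ValueError("detection pool too large for exhaustive enumeration")
    fits, skipped = [], []
    for k in range(len(det_pool) + 1):
        for combo in itertools.combinations(det_pool, k):
            spec = ModelSpec(occ_terms=list(occ_terms), det_terms=list(combo))
            fit = fit_occupancy(spec, history, table, **fit_kwargs)
            if fit.converged:
                fits.append(fit)
            else:
                skipped.append(spec.label() + f" det={combo}")
                log.warning("detection subset %s did not converge; skipped", combo)
    mset = ModelSet(fits, skipped)
    best_aic = mset.fits[0].aic
    candidates = [f for f in mset.fits if f.aic <= best_aic + 1e-9]
    best = min(candidates,
               key=lambda f: (len(f.spec.det_terms), tuple(sorted(f.spec.det_terms))))
    return list(best.spec.det_terms), mset


def all_subsets_selection(
    history: DetectionHistory,
    table: pd.DataFrame,
    det_terms: list[str],
    occ_pool: list[tuple[str, str]],
    **fit_kwargs,
) -> ModelSet:
    """Fit every subset of the occupancy-covariate pool with fixed
    detection terms; rank by AIC."""
    if len(occ_pool) > 12:
        raise ValueError("occupancy pool too large for exhaustive enumeration")
    fits, skipped = [], []
    for k in range(len(occ_pool) + 1):
        for combo in itertools.combinations(occ_pool, k):
            spec = ModelSpec(occ_terms=list(combo), det_terms=list(det_terms))
            fit = fit_occupancy(spec, history, table, **fit_kwargs)
            if fit.converged:
                fits.append(fit)
            else:
                skipped.append(spec.label())
                log.warning("occupancy subset %s did not converge; skipped",
                            spec.label())
    return ModelSet(fits, skipped)


@dataclass
class AveragedModel:
    """Model-averaged predictive equation from the delta-AIC <= 2 set.

    Coefficients use zero substitution: a model lacking a term contributes
    zero at that term's (renormalized) weight, so averaged coefficients and
    per-covariate importance weights are mutually consistent.
    """

    coefficients: dict[str, float]          # column name -> averaged beta
    det_coefficients: dict[str, float]
    importance: dict[str, float]            # covariate name -> summed weight
    terms: list[tuple[str, str]]            # union of (name, form) in top set
    standardization: dict[str, tuple[float, float]]
    top_weights: list[float] = field(default_factory=list)
    top_labels: list[str] = field(default_factory=list)

    def linear_predictor(self, columns: dict[str, np.ndarray]) -> np.ndarray:
        eta = np.full_like(next(iter(columns.values()), np.zeros(1)),
                           self.coefficients.get("(intercept)", 0.0), dtype=float)
        for name, coef in self.coefficients.items():
            if name == "(intercept)":
                continue
            eta = eta + coef * columns[name]
        return eta


def model_average(mset: ModelSet, delta_threshold: float = 2.0) -> AveragedModel:
    """Average coefficients over models with delta AIC <= threshold."""
    idx = np.where(mset.delta <= delta_threshold + 1e-9)[0]
    top = [mset.fits[i] for i in idx]
    w = mset.weights[idx]
    w = w / w.sum()
    coefs: dict[str, float] = {}
    det_coefs: dict[str, float] = {}
    importance: dict[str, float] = {}
    terms: dict[str, str] = {}
    consts: dict[str, tuple[float, float]] = {}
    for fit, wi in zip(top, w):
        for name, form in fit.spec.occ_terms:
            terms.setdefault(name, form)
            importance[name] = importance.get(name, 0.0) + wi
        for n, b in zip(fit.beta_names, fit.beta):
            coefs[n] = coefs.get(n, 0.0) + wi * b
        for n, a in zip(fit.alpha_names, fit.alpha):
            det_coefs[n] = det_coefs.get(n, 0.0) + wi * a
        consts.update(fit.standardization)
    return AveragedModel(
        coefficients=coefs, det_coefficients=det_coefs,
        importance={k: min(v, 1.0) for k, v in importance.items()},
        terms=[(n, f) for n, f in terms.items()],
        standardization=consts,
        top_weights=list(w), top_labels=[f.spec.label() for f in top],
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _term_columns(avg: AveragedModel, raw: dict[str, np.ndarray]) -> dict:
    """Design columns (matching coefficient names) from raw covariate
    arrays, applying each term's form and stored standardization."""
    cols: dict[str, np.ndarray] = {}
    for name, form in avg.terms:
        x = np.asarray(raw[name], dtype=float)
        if form == "categorical":
            codes = x.astype(int)
            for cname in avg.coefficients:
                if cname.startswith(f"{name}["):
                    code = int(cname[len(name) + 1:-1])
                    cols[cname] = (codes == code).astype(float)
            continue
        t = np.log1p(x) if form == "log" else x
        const = avg.standardization.get(name, (0.0, 1.0))
        m, s = const[0], const[1]
        if len(const) == 4:  # clamp to the fitted covariate range
            t = np.clip(t, const[2], const[3])
        z = (t - m) / s
        if form == "quadratic":
            cols[name] = z
            cols[f"{name}^2"] = z ** 2
        elif form == "log":
            cols[f"log({name})"] = z
        else:
            cols[name] = z
    return cols


def predict_suitability(avg: AveragedModel, stack) -> "RasterGrid":
    """Apply the averaged predictive equation cell-wise to a covariate
    stack; returns the occupancy-probability (suitability) raster with
    nodata propagated."""
    from .grid import RasterGrid  # noqa: F401 (typing)

    grid = stack.grid
    raw = {}
    valid = np.ones(grid.shape, dtype=bool)
    for name, _ in avg.terms:
        if name not in stack:
            raise ValueError(f"stack lacks layer {name!r}")
        layer = stack[name]
        valid &= layer.valid_mask
        raw[name] = np.where(layer.valid_mask, layer.values, 0.0).ravel()
    cols = _term_columns(avg, raw)
    if cols:
        eta = avg.linear_predictor(cols).reshape(grid.shape)
    else:
        eta = np.full(grid.shape, avg.coefficients.get("(intercept)", 0.0))
    psi = expit(eta)
    return grid.like(np.where(valid, psi, grid.nodata))


def predict_at_table(avg: AveragedModel, table: pd.DataFrame) -> np.ndarray:
    """The averaged equation evaluated at site-table rows."""
    raw = {name: table[name].to_numpy(dtype=float) for name, _ in avg.terms}
    if not raw:
        return np.full(len(table), expit(avg.coefficients.get("(intercept)", 0.0)))
    cols = _term_columns(avg, raw)
    return expit(avg.linear_predictor(cols))


def partial_response(
    avg: AveragedModel, table: pd.DataFrame, covariate: str,
    values: np.ndarray | None = None, n: int = 100,
    kinds: dict[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy probability as one covariate sweeps its observed range,
    all others held at their mean (continuous) or mode (categorical)."""
    names = [t for t, _ in avg.terms]
    if covariate not in names:
        raise ValueError(f"{covariate!r} not in averaged model")
    kinds = kinds or {}
    x = table[covariate].to_numpy(dtype=float)
    if values is None:
        values = np.linspace(x.min(), x.max(), n)
    values = np.asarray(values, dtype=float)
    raw = {}
    for name, form in avg.terms:
        col = table[name].to_numpy(dtype=float)
        if name == covariate:
            raw[name] = values
        elif form == "categorical" or kinds.get(name) == "categorical":
            vals, counts = np.unique(col, return_counts=True)
            raw[name] = np.full(len(values), vals[np.argmax(counts)])
        else:
            raw[name] = np.full(len(values), col.mean())
    psi = expit(avg.linear_predictor(_term_columns(avg, raw)))
    return values, psi
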