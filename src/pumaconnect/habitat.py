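"""Habitat quality for movement: spatial linear mixed models with
all-subsets AIC multimodel inference.

The response is the natural log of the BBMM occurrence probability at
random points inside each individual's buffered movement surface (floored
at the surface extent threshold). The model is

    y = X beta + b(animal) + e,

with a per-animal random intercept (variance sigma2_u) and residuals
carrying an exponential spatial covariance: within an animal, points at
distance d have residual covariance sigma2_s * exp(-d / rho), plus a
nugget tau2 on the diagonal. The marginal per-animal covariance is

    Sigma_a = sigma2_u * J + tau2 * I + sigma2_s * exp(-D_a / rho).

Fitting is by maximum likelihood (GLS with the profiled fixed effects);
variance components are estimated once under the global model and held
fixed across the all-subsets candidate fits, which then reduce to
generalized least squares on whitened data. Fixed-effect uncertainty uses
the cluster-robust (Huber-White) sandwich estimator, clustered by animal.
Candidate models are all subsets of the seven linear habitat terms, with
the ruggedness quadratic allowed only alongside its linear term; the
sex / age-class / capture-area indicators and the intercept appear in
every model. Akaike weights give per-term weights of evidence, natural
model-averaged coefficients and unconditional standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .bbmm import BBMMSurface
from .covariates import CovariateStack
from .raster import RasterGrid

log = logging.getLogger(__name__)

HABITAT_TERMS = ("ruggedness", "shrub", "human_mod", "riparian",
                 "dist_water", "forest", "tpi")
QUADRATIC_TERM = "ruggedness2"
INDICATOR_TERMS = ("young_adult", "male", "area_B", "area_C")
INTERCEPT = "intercept"
N_VARIANCE_PARAMS = 4  # sigma2_u, sigma2_s, rho, tau2

DEFAULT_FLOOR = 1e-5


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def sample_design(surface: BBMMSurface, buffer_mask: np.ndarray,
                  stack: CovariateStack, track, n_points: int, seed: int,
                  floor: float = DEFAULT_FLOOR) -> pd.DataFrame:
    """Random points in the buffered movement surface, as design rows.

    ``n_points`` should equal the number of filtered locations used to
    estimate the surface. The response is ln(max(surface value, floor));
    points falling in the buffer-only zone therefore score the floor.
    """
    if not buffer_mask.any():
        raise ValueError("empty buffered extent")
    grid = surface.probability
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(buffer_mask)
    pick = rng.integers(0, len(rows), size=n_points)
    # uniform position within each sampled cell
    jitter = rng.uniform(-0.5, 0.5, size=(n_points, 2))
    cx, cy = grid.cell_center(rows[pick], cols[pick])
    x = cx + jitter[:, 0] * grid.cell_size
    y = cy + jitter[:, 1] * grid.cell_size
    response = np.log(np.maximum(grid.values[rows[pick], cols[pick]], floor))

    out = stack.values_at(x, y)
    out.insert(0, "animal_id", track.animal_id)
    out.insert(1, "x", x)
    out.insert(2, "y", y)
    out.insert(3, "response", response)
    out[QUADRATIC_TERM] = out["ruggedness"] ** 2
    out["young_adult"] = float(track.age_class == "young_adult")
    out["male"] = float(track.sex == "M")
    out["area_B"] = float(track.capture_area == "B")
    out["area_C"] = float(track.capture_area == "C")
    return out


def design_matrix(rows: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    """Fixed-effects matrix: intercept, indicators, then the given terms."""
    cols = [np.ones(len(rows))]
    cols += [rows[t].to_numpy(dtype=float) for t in INDICATOR_TERMS]
    cols += [rows[t].to_numpy(dtype=float) for t in terms]
    return np.column_stack(cols)


def term_names(terms: tuple[str, ...]) -> list[str]:
    return [INTERCEPT, *INDICATOR_TERMS, *terms]


# ---------------------------------------------------------------------------
# the mixed model
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma2_u: float   # random-intercept variance
    sigma2_s: float   # spatial partial sill
    rho: float        # exponential range (m)
    tau2: float       # nugget / residual variance


@dataclass
class ModelFit:
    """One candidate model: terms, ML fit, covariances."""

    terms: tuple[str, ...]
    names: list[str]
    beta: np.ndarray
    loglik: float
    aic: float
    vcov_model: np.ndarray
    vcov_sandwich: np.ndarray | None = None
    components: VarianceComponents | None = None
    data_fingerprint: int = 0

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def se(self, name: str, sandwich: bool = True) -> float:
        v = self.vcov_sandwich if (sandwich and self.vcov_sandwich is not None) \
            else self.vcov_model
        i = self.names.index(name)
        return float(np.sqrt(v[i, i]))


def _cluster_blocks(rows: pd.DataFrame):
    """Per-animal index arrays and distance matrices."""
    blocks = []
    for _, grp in rows.groupby("animal_id", sort=True):
        idx = grp.index.to_numpy()
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        blocks.append((idx, d))
    return blocks


def _whiten(blocks, y, X, comp: VarianceComponents):
    """Per-cluster Cholesky whitening; returns stacked blocks + logdet."""
    Xw_blocks, yw_blocks, logdet = [], [], 0.0
    for idx, d in blocks:
        n = len(idx)
        cov = (comp.sigma2_u
               + comp.sigma2_s * np.exp(-d / max(comp.rho, 1e-12))
               + comp.tau2 * np.eye(n))
        L = linalg.cholesky(cov, lower=True)
        logdet += 2.0 * np.sum(np.log(np.diag(L)))
        Xw_blocks.append(linalg.solve_triangular(L, X[idx], lower=True))
        yw_blocks.append(linalg.solve_triangular(L, y[idx], lower=True))
    return Xw_blocks, yw_blocks, logdet


def _gls(Xw, yw):
    """GLS estimate and residual quadratic form on whitened data."""
    G = Xw.T @ Xw
    beta = linalg.solve(G, Xw.T @ yw, assume_a="pos")
    resid = yw - Xw @ beta
    return beta, float(resid @ resid), G


def _profile_nll(theta, blocks, y, X, reml):
    comp = VarianceComponents(*np.exp(theta))
    try:
        Xw_b, yw_b, logdet = _whiten(blocks, y, X, comp)
    except linalg.LinAlgError:
        return 1e12
    Xw = np.vstack(Xw_b)
    yw = np.concatenate(yw_b)
    try:
        _, rss, G = _gls(Xw, yw)
    except linalg.LinAlgError:
        return 1e12
    n = len(y)
    nll = 0.5 * (logdet + rss + n * np.log(2 * np.pi))
    if reml:
        sign, ld = np.linalg.slogdet(G)
        if sign <= 0:
            return 1e12
        nll += 0.5 * ld
    return nll


def estimate_variance_components(rows: pd.DataFrame,
                                 terms: tuple[str, ...] = HABITAT_TERMS
                                 + (QUADRATIC_TERM,),
                                 n_restarts: int = 2,
                                 reml: bool = True,
                                 ) -> VarianceComponents:
    """Variance components under the given (global) fixed effects.

    By default the profile objective carries the REML adjustment
    (+ half log det X' Sigma^-1 X): with few individuals and several
    animal-level fixed effects, plain ML shrinks the random-intercept
    variance by roughly the fraction of cluster-level parameters and the
    model SEs of animal-level coefficients lose their nominal coverage.
    Candidate-model likelihoods and AIC values are still computed as full
    ML at these fixed components.
    """
    rows = rows.reset_index(drop=True)
    if rows["animal_id"].nunique() < 2:
        raise ValueError("need at least two individuals")
    blocks = _cluster_blocks(rows)
    y = rows["response"].to_numpy(dtype=float)
    X = design_matrix(rows, terms)
    # initial guesses from the OLS residual variance and typical spacing
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2 = float(np.var(y - X @ beta0))
    med_d = np.median([np.median(d[d > 0]) if (d > 0).any() else 1.0
                       for _, d in blocks])
    starts = [np.log([s2 / 4, s2 / 4, med_d / 2, s2 / 2])]
    rng = np.random.default_rng(0)
    for _ in range(n_restarts - 1):
        starts.append(starts[0] + rng.uniform(-1, 1, 4))
    best = None
    for x0 in starts:
        res = optimize.minimize(_profile_nll, x0, args=(blocks, y, X, reml),
                                method="Nelder-Mead",
                                options={"maxiter": 600, "xatol": 1e-4,
                                         "fatol": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("variance-component optimization failed")
    return VarianceComponents(*np.exp(best.x))


def fit_lmm(rows: pd.DataFrame, terms: tuple[str, ...],
            components: VarianceComponents | None = None) -> ModelFit:
    """ML fit of one candidate model.

    If ``components`` is given the variance components are held fixed
    (the all-subsets regime); otherwise they are estimated under these
    terms. AIC counts all fixed effects plus the four variance parameters.
    """
    rows = rows.reset_index(drop=True)
    if components is None:
        components = estimate_variance_components(rows, terms)
    blocks = _cluster_blocks(rows)
    y = rows["response"].to_numpy(dtype=float)
    X = design_matrix(rows, terms)
    Xw_b, yw_b, logdet = _whiten(blocks, y, X, components)
    Xw = np.vstack(Xw_b)
    yw = np.concatenate(yw_b)
    beta, rss, G = _gls(Xw, yw)
    n, p = X.shape
    loglik = -0.5 * (logdet + rss + n * np.log(2 * np.pi))
    k = p + N_VARIANCE_PARAMS
    aic = -2.0 * loglik + 2.0 * k
    vcov_model = linalg.inv(G)
    fit = ModelFit(tuple(terms), term_names(tuple(terms)), beta, loglik, aic,
                   vcov_model, components=components,
                   data_fingerprint=_fingerprint(rows))
    fit.vcov_sandwich = sandwich_vcov(fit, rows)
    return fit


def _fingerprint(rows: pd.DataFrame) -> int:
    return hash((len(rows), round(float(rows["response"].sum()), 6)))


def sandwich_vcov(fit: ModelFit, rows: pd.DataFrame) -> np.ndarray:
    """Cluster-robust (Huber-White) covariance of the fixed effects.

    A^-1 (sum_a g_a g_a') A^-1 with per-animal GLS score contributions
    g_a = X_a' Sigma_a^-1 r_a and bread A = X' Sigma^-1 X.
    """
    rows = rows.reset_index(drop=True)
    blocks = _cluster_blocks(rows)
    if len(blocks) <= len(fit.names):
        log.warning("sandwich estimator: %d clusters for %d fixed effects",
                    len(blocks), len(fit.names))
    y = rows["response"].to_numpy(dtype=float)
    X = design_matrix(rows, fit.terms)
    Xw_b, yw_b, _ = _whiten(blocks, y, X, fit.components)
    A = np.zeros((X.shape[1], X.shape[1]))
    meat = np.zeros_like(A)
    for Xw, yw in zip(Xw_b, yw_b):
        A += Xw.T @ Xw
        g = Xw.T @ (yw - Xw @ fit.beta)
        meat += np.outer(g, g)
    Ainv = linalg.inv(A)
    return Ainv @ meat @ Ainv


# ---------------------------------------------------------------------------
# multimodel inference
# ---------------------------------------------------------------------------

def enumerate_subsets(habitat_terms: tuple[str, ...] = HABITAT_TERMS,
                      quadratic: str = QUADRATIC_TERM,
                      quadratic_parent: str = "ruggedness"
                      ) -> list[tuple[str, ...]]:
    """All subsets of the linear habitat terms, the quadratic allowed only
    with its parent; indicators and intercept are implicit in every model.

    Seven linear terms plus one hierarchical quadratic give 2^7 + 2^6 =
    192 candidate models, including the indicators-only model.
    """
    subsets = []
    for r in range(len(habitat_terms) + 1):
        for combo in combinations(habitat_terms, r):
            subsets.append(tuple(combo))
            if quadratic_parent in combo:
                subsets.append(tuple(combo) + (quadratic,))
    return subsets


def fit_all_subsets(rows: pd.DataFrame,
                    components: VarianceComponents) -> list[ModelFit]:
    """Fit every candidate model with shared variance components.

    The whitened global design is computed once; each subset is a GLS
    solve on its columns, so the 192 fits cost little more than one.
    """
    rows = rows.reset_index(drop=True)
    blocks = _cluster_blocks(rows)
    y = rows["response"].to_numpy(dtype=float)
    all_terms = HABITAT_TERMS + (QUADRATIC_TERM,)
    X = design_matrix(rows, all_terms)
    names_all = term_names(all_terms)
    Xw_b, yw_b, logdet = _whiten(blocks, y, X, components)
    Xw = np.vstack(Xw_b)
    yw = np.concatenate(yw_b)
    n = len(y)
    fp = _fingerprint(rows)

    fits = []
    for terms in enumerate_subsets():
        names = term_names(terms)
        cols = [names_all.index(t) for t in names]
        Xs = Xw[:, cols]
        beta, rss, G = _gls(Xs, yw)
        loglik = -0.5 * (logdet + rss + n * np.log(2 * np.pi))
        aic = -2.0 * loglik + 2.0 * (len(cols) + N_VARIANCE_PARAMS)
        vcov_model = linalg.inv(G)
        A = np.zeros((len(cols), len(cols)))
        meat = np.zeros_like(A)
        for Xb, yb in zip(Xw_b, yw_b):
            Xbs = Xb[:, cols]
            A += Xbs.T @ Xbs
            g = Xbs.T @ (yb - Xbs @ beta)
            meat += np.outer(g, g)
        Ainv = linalg.inv(A)
        fits.append(ModelFit(terms, names, beta, loglik, aic, vcov_model,
                             Ainv @ meat @ Ainv, components, fp))
    return fits


def compare_global_null(global_fit: ModelFit, null_fit: ModelFit,
                        margin: float = 10.0) -> dict:
    """Is the global model's AIC more than ``margin`` below the null's?"""
    delta = null_fit.aic - global_fit.aic
    return {"delta_aic": float(delta), "passes": bool(delta > margin)}


@dataclass
class AveragedHabitatModel:
    """Per-term weight of evidence, averaged coefficient, unconditional SE."""

    weight_of_evidence: dict[str, float]
    coefficients: dict[str, float]
    unconditional_se: dict[str, float]
    intercept: float
    intercept_se: float
    akaike_weights: np.ndarray = field(default_factory=lambda: np.array([]))

    def table(self) -> pd.DataFrame:
        """Coefficient table ordered by descending weight of evidence."""
        rows = [{"variable": v, "w_plus": self.weight_of_evidence[v],
                 "beta": self.coefficients[v],
                 "se": self.unconditional_se[v]}
                for v in self.weight_of_evidence]
        df = pd.DataFrame(rows).sort_values("w_plus", ascending=False,
                                            kind="stable")
        df = pd.concat([df, pd.DataFrame([{"variable": INTERCEPT,
                                           "w_plus": np.nan,
                                           "beta": self.intercept,
                                           "se": self.intercept_se}])],
                       ignore_index=True)
        return df


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    """exp(-delta/2) / sum, with delta relative to the minimum AIC."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def model_average(fits: list[ModelFit]) -> AveragedHabitatModel:
    """Natural model averaging over candidate fits.

    w+(v) sums the Akaike weights of models containing v; beta(v) averages
    coefficients over those models (weights renormalized); the
    unconditional SE folds between-model coefficient spread into the
    within-model (sandwich) variance.
    """
    if len({f.data_fingerprint for f in fits}) > 1:
        raise ValueError("fits were not produced on identical data")
    w = akaike_weights(np.array([f.aic for f in fits]))
    all_vars = list(dict.fromkeys(
        v for f in fits for v in f.names if v != INTERCEPT))
    w_plus, betas, ses = {}, {}, {}
    for v in all_vars:
        members = [(wi, f) for wi, f in zip(w, fits) if v in f.names]
        wv = float(sum(wi for wi, _ in members))
        w_plus[v] = wv
        if wv <= 0:
            betas[v], ses[v] = 0.0, 0.0
            continue
        coefs = np.array([f.coef(v) for _, f in members])
        wts = np.array([wi for wi, _ in members]) / wv
        beta_bar = float(wts @ coefs)
        var_u = float(wts @ (np.array([f.se(v) ** 2 for _, f in members])
                             + (coefs - beta_bar) ** 2))
        betas[v] = beta_bar
        ses[v] = float(np.sqrt(var_u))
    icoefs = np.array([f.coef(INTERCEPT) for f in fits])
    ibar = float(w @ icoefs)
    ivar = float(w @ (np.array([f.se(INTERCEPT) ** 2 for f in fits])
                      + (icoefs - ibar) ** 2))
    return AveragedHabitatModel(w_plus, betas, ses, ibar,
                                float(np.sqrt(ivar)), w)


# ---------------------------------------------------------------------------
# prediction and conductance
# ---------------------------------------------------------------------------

def predict_quality(avg: AveragedHabitatModel,
                    stack: CovariateStack) -> RasterGrid:
    """Map the averaged linear predictor over the standardized stack.

    Indicators sit at their reference level (adult female, reference
    capture area) and the random effect at zero, so the map is the
    population-level expectation for the reference class.
    """
    if not stack.is_standardized:
        raise ValueError("stack must be standardized with training parameters")
    g = stack.grid
    out = np.full(g.shape, avg.intercept, dtype=float)
    for v, beta in avg.coefficients.items():
        if v in INDICATOR_TERMS:
            continue
        if v == QUADRATIC_TERM:
            out += beta * stack.layers["ruggedness"].values ** 2
        else:
            if v not in stack.layers:
                raise KeyError(f"layer {v!r} missing from stack")
            out += beta * stack.layers[v].values
    return g.like(out)


def quality_to_conductance(quality: RasterGrid,
                           water_mask: np.ndarray | None = None,
                           canal_mask: np.ndarray | None = None,
                           epsilon: float = 1e-3) -> RasterGrid:
    """Min-max rescale habitat quality to conductance in (epsilon, 1].

    Water and canal cells are overridden with the minimum conductance,
    reflecting their assignment of minimum habitat quality. The rescale
    is monotone, so quality ordering is preserved elsewhere.
    """
    v = quality.values
    lo, hi = float(np.nanmin(v)), float(np.nanmax(v))
    if hi <= lo:
        raise ValueError("constant quality map cannot be rescaled")
    cond = epsilon + (1.0 - epsilon) * (v - lo) / (hi - lo)
    for m in (water_mask, canal_mask):
        if m is not None:
            cond = np.where(m, epsilon, cond)
    return quality.like(cond)
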