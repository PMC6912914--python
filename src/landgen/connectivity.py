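"""MLPE mixed models, AICc model selection and bootstrap hypothesis ranking.

Pairwise genetic differentiation y_ij between populations i and j is
modelled as

    y_ij = b0 + b1 * z(x_ij) + u_i + u_j + eps_ij

with a Gaussian random effect u per population (variance sigma_u^2) and a
pair-level residual (sigma_e^2) — the maximum-likelihood population
effects (MLPE) parameterization for non-independent pairwise data.  z is
the centered/scaled landscape distance.  Fitting is by maximum
likelihood throughout (never REML) so that AICc is comparable across
fixed-effect structures.

The marginal covariance is sigma_u^2 Z Z' + sigma_e^2 I where Z is the
pair-by-population incidence matrix.  For a complete pairwise design the
spectrum of Z Z' is closed-form, which makes each likelihood evaluation
O(n_pairs) — this is what keeps 10^4-replicate bootstraps cheap.  An
incomplete design falls back to dense Cholesky.

Four connectivity hypotheses are compared: null (intercept only),
geographic distance, terrain ruggedness + least-cost distance, terrain
ruggedness + commute distance.  AICc uses n = number of pairs and k =
all estimated parameters including the variance components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .core import PairwiseMatrix, Raster, SiteSet
from .landscape import (
    TransformSpec,
    commute_distances,
    euclidean_cell_distances,
    geographic_distances,
    least_cost_distances,
    terrain_ruggedness,
    transform_surface,
)

__all__ = [
    "MLPEFit",
    "MLPERegressor",
    "fit_mlpe",
    "aicc",
    "model_selection",
    "hypothesis_predictors",
    "evaluate_hypotheses",
    "bootstrap_ranking",
    "BootstrapSummary",
    "HYPOTHESES",
]

HYPOTHESES = ("null", "geographic", "topo_least_cost", "topo_commute")


@dataclass
class MLPEFit:
    beta: np.ndarray          # intercept (+ slope on the z-scaled predictor)
    sigma_u2: float
    sigma_e2: float
    loglik_ml: float
    n_pairs: int
    n_pops: int
    k_params: int
    var_fixed: float          # variance of the fitted fixed-effect values
    x_mean: float = 0.0
    x_sd: float = 1.0


# ---------------------------------------------------------------------------
# likelihood machinery

def _design(i_idx: np.ndarray, j_idx: np.ndarray, n_pops: int) -> bool:
    """True when the pair set is the complete i<j design."""
    return len(i_idx) == n_pops * (n_pops - 1) // 2


def _profile_eval_complete(lam: float, X: np.ndarray, y: np.ndarray,
                           i_idx: np.ndarray, j_idx: np.ndarray,
                           n_pops: int) -> tuple[float, np.ndarray, float]:
    """Profile log-likelihood at lambda = sigma_u^2/sigma_e^2, complete design.

    Uses Woodbury with Z'Z = (n-2) I + J, whose inverse is closed-form,
    and the known spectrum of Z Z' for log|I + lam Z Z'|.
    """
    n = len(y)
    m = n_pops

    def winv(v: np.ndarray) -> np.ndarray:
        # (I + lam Z Z')^{-1} v  via Woodbury
        if lam == 0:
            return v
        zt = np.bincount(i_idx, weights=v, minlength=m) + \
            np.bincount(j_idx, weights=v, minlength=m)
        alpha = m - 2 + 1.0 / lam
        # (Z'Z + I/lam)^{-1} = I/alpha - J/(alpha(alpha+m))
        w = zt / alpha - zt.sum() / (alpha * (alpha + m))
        return v - (w[i_idx] + w[j_idx])

    Wy = winv(y)
    WX = np.column_stack([winv(X[:, c]) for c in range(X.shape[1])])
    xtwx = X.T @ WX
    xtwy = X.T @ Wy
    beta = np.linalg.solve(xtwx, xtwy)
    r = y - X @ beta
    Wr = winv(r)
    sigma2 = float(r @ Wr) / n
    logdet = float(np.log1p(2 * (m - 1) * lam) + (m - 1) * np.log1p((m - 2) * lam))
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - 0.5 * logdet
    return float(ll), beta, sigma2


def _profile_eval_dense(lam: float, X: np.ndarray, y: np.ndarray,
                        ZZt: np.ndarray) -> tuple[float, np.ndarray, float]:
    n = len(y)
    W = np.eye(n) + lam * ZZt
    L = np.linalg.cholesky(W)
    sol = np.linalg.solve
    Ly = sol(L, y)
    LX = sol(L, X)
    Wy = sol(L.T, Ly)
    WX = sol(L.T, LX)
    beta = np.linalg.solve(X.T @ WX, X.T @ Wy)
    r = y - X @ beta
    Lr = sol(L, r)
    sigma2 = float(Lr @ Lr) / n
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - 0.5 * logdet
    return float(ll), beta, sigma2


def _fit_pairs(i_idx: np.ndarray, j_idx: np.ndarray, n_pops: int,
               X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """ML fit over lambda >= 0; returns (beta, sigma_u2, sigma_e2, loglik)."""
    complete = _design(i_idx, j_idx, n_pops)
    if complete:
        def ev(lam: float):
            return _profile_eval_complete(lam, X, y, i_idx, j_idx, n_pops)
    else:
        Z = np.zeros((len(y), n_pops))
        Z[np.arange(len(y)), i_idx] = 1.0
        Z[np.arange(len(y)), j_idx] = 1.0
        ZZt = Z @ Z.T

        def ev(lam: float):
            return _profile_eval_dense(lam, X, y, ZZt)

    def neg(t: float) -> float:
        return -ev(np.exp(t))[0]

    res = minimize_scalar(neg, bounds=(-14.0, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    cands = [0.0, float(np.exp(res.x))]
    best = None
    for lam in cands:
        ll, beta, sigma2 = ev(lam)
        if best is None or ll > best[0]:
            best = (ll, beta, sigma2, lam)
    ll, beta, sigma2, lam = best
    return beta, lam * sigma2, sigma2, ll


class MLPERegressor(RegressorMixin, BaseEstimator):
    """scikit-learn style MLPE mixed model for pairwise distance data.

    ``X`` has columns ``[pop_i, pop_j]`` (integer population indices) and
    optionally a third predictor column; ``y`` is the pairwise response.
    With no predictor column the model is intercept-only (the null
    connectivity hypothesis).

    Parameters
    ----------
    standardize : bool, default True
        Center/scale the predictor column before fitting, so the slope is
        per SD of distance.

    Attributes
    ----------
    beta_ : fixed-effect coefficients (intercept [+ slope])
    sigma_u2_, sigma_e2_ : variance components
    loglik_ : maximized ML log-likelihood
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] not in (2, 3):
            raise ValueError("X must have columns [pop_i, pop_j(, predictor)]")
        i_idx = X[:, 0].astype(int)
        j_idx = X[:, 1].astype(int)
        pops = np.unique(np.concatenate([i_idx, j_idx]))
        n_pops = len(pops)
        if n_pops < 4:
            raise ValueError("MLPE needs >= 4 populations")
        remap = {p: k for k, p in enumerate(pops)}
        i_idx = np.array([remap[p] for p in i_idx])
        j_idx = np.array([remap[p] for p in j_idx])
        if X.shape[1] == 3:
            x = X[:, 2].copy()
            if self.standardize:
                self.x_mean_ = float(x.mean())
                self.x_sd_ = float(x.std(ddof=0))
                if self.x_sd_ == 0:
                    raise ValueError("degenerate predictor (zero variance)")
                x = (x - self.x_mean_) / self.x_sd_
            else:
                self.x_mean_, self.x_sd_ = 0.0, 1.0
                if x.std(ddof=0) == 0:
                    raise ValueError("degenerate predictor (zero variance)")
            design = np.column_stack([np.ones_like(x), x])
        else:
            self.x_mean_, self.x_sd_ = 0.0, 1.0
            design = np.ones((len(y), 1))
        beta, su2, se2, ll = _fit_pairs(i_idx, j_idx, n_pops, design, y)
        self.beta_ = beta
        self.sigma_u2_ = float(su2)
        self.sigma_e2_ = float(se2)
        self.loglik_ = float(ll)
        self.n_pops_ = n_pops
        self.n_pairs_ = len(y)
        fitted = design @ beta
        self.var_fixed_ = float(fitted.var(ddof=0))
        self.k_params_ = design.shape[1] + 2  # betas + two variances
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] == 3 and len(self.beta_) == 2:
            x = (X[:, 2] - self.x_mean_) / self.x_sd_
            return self.beta_[0] + self.beta_[1] * x
        return np.full(X.shape[0], self.beta_[0])


def fit_mlpe(y: PairwiseMatrix, x: PairwiseMatrix | None) -> MLPEFit:
    """Fit the MLPE model of differentiation ``y`` on distance ``x``.

    ``x=None`` fits the intercept-only null.  Labels must match exactly.
    """
    if y.n < 4:
        raise ValueError("MLPE needs >= 4 populations")
    iu, ju, yv = y.condensed()
    if x is not None:
        if list(x.labels) != list(y.labels):
            raise ValueError("x and y labels differ")
        _, _, xv = x.condensed()
        X = np.column_stack([iu, ju, xv])
    else:
        X = np.column_stack([iu, ju])
    model = MLPERegressor().fit(X, yv)
    return MLPEFit(
        beta=model.beta_, sigma_u2=model.sigma_u2_, sigma_e2=model.sigma_e2_,
        loglik_ml=model.loglik_, n_pairs=model.n_pairs_, n_pops=model.n_pops_,
        k_params=model.k_params_, var_fixed=model.var_fixed_,
        x_mean=model.x_mean_, x_sd=model.x_sd_,
    )


# ---------------------------------------------------------------------------
# model selection

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 ll + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("n - k - 1 must be positive for AICc")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def model_selection(fits: list[MLPEFit], labels: list[str]) -> pd.DataFrame:
    """AICc table with delta, Akaike weights and marginal/conditional R^2.

    R2m = var(Xb) / (var(Xb) + 2 sigma_u^2 + sigma_e^2); R2c adds the
    random-effect variance 2 sigma_u^2 (each pair carries two population
    effects) to the numerator.
    """
    if len(fits) != len(labels):
        raise ValueError("fits/labels length mismatch")
    n_set = {f.n_pairs for f in fits}
    if len(n_set) != 1:
        raise ValueError("fits use different observation sets")
    rows = []
    for f, lab in zip(fits, labels):
        a = aicc(f.loglik_ml, f.k_params, f.n_pairs)
        denom = f.var_fixed + 2 * f.sigma_u2 + f.sigma_e2
        rows.append({
            "hypothesis": lab, "loglik": f.loglik_ml, "k": f.k_params,
            "AICc": a,
            "r2_marginal": f.var_fixed / denom,
            "r2_conditional": (f.var_fixed + 2 * f.sigma_u2) / denom,
        })
    df = pd.DataFrame(rows).set_index("hypothesis")
    df["delta_aicc"] = df["AICc"] - df["AICc"].min()
    w = np.exp(-df["delta_aicc"] / 2.0)
    df["weight"] = w / w.sum()
    return df[["AICc", "delta_aicc", "weight", "r2_marginal", "r2_conditional",
               "loglik", "k"]]


# ---------------------------------------------------------------------------
# the four hypotheses

def hypothesis_predictors(
    elev: Raster,
    sites: SiteSet,
    opt_specs: dict[str, TransformSpec],
    tri: Raster | None = None,
) -> dict[str, PairwiseMatrix | None]:
    """Build the predictor matrix for each connectivity hypothesis.

    ``opt_specs`` maps ``least_cost``/``commute`` to the (optimized)
    transform applied to the terrain ruggedness surface.  Geographic
    distance uses great circles when sites have lon/lat, else straight
    lines between cell centres.
    """
    if tri is None:
        tri = terrain_ruggedness(elev)
    if sites.lonlat is not None:
        geo = geographic_distances(sites)
    else:
        geo = euclidean_cell_distances(tri, sites)
    lcp = least_cost_distances(transform_surface(tri, opt_specs["least_cost"]), sites)
    com = commute_distances(transform_surface(tri, opt_specs["commute"]), sites)
    return {"null": None, "geographic": geo,
            "topo_least_cost": lcp, "topo_commute": com}


def evaluate_hypotheses(
    y: PairwiseMatrix,
    elev: Raster,
    sites: SiteSet,
    opt_specs: dict[str, TransformSpec],
    tri: Raster | None = None,
) -> pd.DataFrame:
    """Fit the four connectivity hypotheses and rank them by AICc."""
    preds = hypothesis_predictors(elev, sites, opt_specs, tri=tri)
    fits = [fit_mlpe(y, preds[h]) for h in HYPOTHESES]
    return model_selection(fits, list(HYPOTHESES))


# ---------------------------------------------------------------------------
# bootstrap ranking

@dataclass
class BootstrapSummary:
    n_boot: int
    frac: float
    table: pd.DataFrame  # per hypothesis: mean_rank, pct_best
    seed: int


def _rank_models(fits: list[MLPEFit]) -> np.ndarray:
    """AICc ranks (1 = best); ties broken by fewer parameters, then the
    fixed hypothesis order."""
    keys = [(aicc(f.loglik_ml, f.k_params, f.n_pairs), f.k_params, i)
            for i, f in enumerate(fits)]
    order = sorted(range(len(fits)), key=lambda i: keys[i])
    ranks = np.empty(len(fits), dtype=int)
    for r, i in enumerate(order):
        ranks[i] = r + 1
    return ranks


def bootstrap_ranking(
    y: PairwiseMatrix,
    predictors: dict[str, PairwiseMatrix | None],
    n_boot: int = 10_000,
    frac: float = 0.75,
    seed: int = 0,
) -> BootstrapSummary:
    """Bootstrap model ranking over random population subsets.

    Each replicate keeps floor(frac * n_pops) populations (sampled
    without replacement), restricts every matrix to them, refits all
    hypotheses and ranks by AICc.  Reports mean rank and the percentage
    of replicates in which each hypothesis was best.
    """
    labels = list(y.labels)
    n = len(labels)
    m = int(np.floor(frac * n))
    if m < 4:
        raise ValueError("subset size < 4 populations; raise frac or n_pops")
    names = [h for h in HYPOTHESES if h in predictors]
    rng = np.random.default_rng(seed)
    rank_sum = np.zeros(len(names))
    best_cnt = np.zeros(len(names))
    for _ in range(n_boot):
        keep = np.sort(rng.choice(n, size=m, replace=False))
        ysub = y.subset(keep)
        fits = []
        for h in names:
            p = predictors[h]
            fits.append(fit_mlpe(ysub, None if p is None else p.subset(keep)))
        ranks = _rank_models(fits)
        rank_sum += ranks
        best_cnt[ranks == 1] += 1
    table = pd.DataFrame({
        "hypothesis": names,
        "mean_rank": rank_sum / n_boot,
        "pct_best": 100.0 * best_cnt / n_boot,
    }).set_index("hypothesis")
    return BootstrapSummary(n_boot=n_boot, frac=frac, table=table, seed=seed)
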