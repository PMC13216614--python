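"""Driver models of species richness: GLM suites per 5° band and penalized
negative-binomial GAMs per hexagonal cell, ranked by AIC.

Workflow mirrors the depth-explicit driver analysis: screen covariates for
collinearity with pairwise Pearson correlations (temperature has priority
over O2, whose correlation is ~1 in shallow/mesopelagic layers), fit a
candidate suite of single-covariate Poisson GLMs per latitudinal band
(species counts; record count enters as a log-transformed candidate
covariate for the count response and is excluded for ES50, which already
controls effort), add an intercept-only null, and rank by AIC with the
"ΔAIC < 2 is inconclusive" rule and Akaike weights.  Per-cell responses are
modelled with a from-scratch penalized regression GAM: cubic B-spline bases
with second-difference penalties plus a shrinkage ridge (so smooths can be
selected out), a great-circle radial-basis spatial term for spatial
autocorrelation, GCV-selected smoothing parameters and a profiled NB
dispersion θ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "ModelFit", "CandidateSuite", "collinearity_screen", "fit_glm",
    "candidate_suite", "fit_gam", "gam_suite", "predict_response",
    "DELTA_AIC_RULE",
]

DELTA_AIC_RULE = 2.0

#: priority when dropping one member of a collinear pair; anchored by the
#: temperature-over-O2 choice, remainder a documented convention
_PRIORITY = ("temperature", "productivity", "nitrate", "o2")


def _priority_rank(name: str, order: list[str]) -> tuple:
    low = name.lower()
    for k, key in enumerate(_PRIORITY):
        if key in low:
            return (k, order.index(name))
    return (len(_PRIORITY), order.index(name))


def collinearity_screen(covariates: pd.DataFrame, threshold: float = 0.95
                        ) -> tuple[list[str], pd.DataFrame]:
    """Drop the lower-priority member of every pair with |r| >= threshold.

    Constant covariates are excluded with a warning.  Returns the retained
    names and the full pairwise Pearson correlation matrix.
    """
    if covariates.shape[1] < 2:
        raise ValueError("need at least 2 covariates")
    cols = list(covariates.columns)
    const = [c for c in cols if covariates[c].nunique(dropna=True) <= 1]
    for c in const:
        warnings.warn(f"constant covariate {c!r} excluded from screen")
    cols = [c for c in cols if c not in const]
    corr = covariates[cols].corr()
    retained = set(cols)
    pairs = [(abs(corr.loc[a, b]), a, b)
             for i, a in enumerate(cols) for b in cols[i + 1:]]
    for r, a, b in sorted(pairs, reverse=True):
        if r < threshold or not np.isfinite(r):
            continue
        if a in retained and b in retained:
            drop = max(a, b, key=lambda c: _priority_rank(c, cols))
            retained.discard(drop)
    return [c for c in cols if c in retained], corr


# ---------------------------------------------------------------------------
# GLM

@dataclass
class ModelFit:
    response: str
    family: str
    terms: list
    coefficients: pd.Series
    std_errors: pd.Series
    loglik: float
    k_effective: float
    aic: float
    delta_aic: float = np.nan
    akaike_weight: float = np.nan
    theta: float | None = None
    converged: bool = True
    _impl: object = field(default=None, repr=False, compare=False)

    @property
    def name(self) -> str:
        return "+".join(self.terms) if self.terms else "intercept"


def fit_glm(y, X: pd.DataFrame | None, family: str = "poisson",
            response: str = "y", theta: float | None = None,
            offset=None) -> ModelFit:
    """Fit a GLM (log-link Poisson / NB, identity Gaussian).

    ``X`` holds the non-intercept terms (may be None/empty for the null
    model); an intercept is always added.  The log-likelihood keeps all
    constants (ln y! for counts) so AICs are comparable across models and
    families.  Continuous ES50 responses use the Gaussian family on the same
    machinery.  Non-convergence is flagged on the fit, not silenced.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    if family in ("poisson", "negative_binomial"):
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("count family requires nonnegative integers")
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        exog = pd.DataFrame({"const": np.ones(y.size)})
        terms: list[str] = []
    else:
        X = pd.DataFrame(X)
        if len(X) != y.size:
            raise ValueError("rows of y and X differ")
        exog = sm.add_constant(X, has_constant="add")
        terms = list(X.columns)
    if family == "poisson":
        fam = sm.families.Poisson()
    elif family == "gaussian":
        fam = sm.families.Gaussian()
    elif family == "negative_binomial":
        fam = sm.families.NegativeBinomial(alpha=1.0 / (theta if theta else 1.0))
    else:
        raise ValueError(f"unknown family {family!r}")
    model = sm.GLM(y, exog, family=fam, offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-10)
    converged = bool(getattr(res, "converged", True)) and np.all(np.isfinite(res.params))
    k = res.df_model + 1 + (1 if family == "gaussian" else 0)
    llf = float(res.llf)
    return ModelFit(response=response, family=family, terms=terms,
                    coefficients=pd.Series(res.params, index=exog.columns),
                    std_errors=pd.Series(res.bse, index=exog.columns),
                    loglik=llf, k_effective=float(k),
                    aic=-2.0 * llf + 2.0 * k, theta=theta,
                    converged=converged, _impl=res)


@dataclass
class CandidateSuite:
    response: str
    fits: list                       # ranked by AIC then fewer parameters
    best_set: list = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "model": f.name, "family": f.family, "k": f.k_effective,
            "loglik": f.loglik, "aic": f.aic, "delta_aic": f.delta_aic,
            "akaike_weight": f.akaike_weight, "converged": f.converged,
        } for f in self.fits])


def _rank_suite(response: str, fits: list) -> CandidateSuite:
    amin = min(f.aic for f in fits)
    for f in fits:
        f.delta_aic = f.aic - amin
    ws = np.array([np.exp(-f.delta_aic / 2.0) for f in fits])
    ws = ws / ws.sum()
    for f, w in zip(fits, ws):
        f.akaike_weight = float(w)
    fits = sorted(fits, key=lambda f: (f.aic, f.k_effective))
    best = [f for f in fits if f.delta_aic <= DELTA_AIC_RULE]
    return CandidateSuite(response=response, fits=fits, best_set=best)


def candidate_suite(band_table: pd.DataFrame, response: str,
                    covariates: list[str], effort_col: str = "n_records",
                    threshold: float = 0.95, effort_as_offset: bool = False
                    ) -> CandidateSuite:
    """Single-covariate GLM suite per band plus the intercept-only null.

    ``response`` "s_obs" (counts, Poisson) or "es50" (continuous, Gaussian).
    For the count response the log record count competes as its own
    candidate covariate (set ``effort_as_offset`` to use it as an offset
    instead); for ES50 it is excluded because rarefaction already controls
    effort.  Covariates are z-scored; rows with missing response or
    covariates are dropped (>= 3 usable rows required).
    """
    fam = "poisson" if response == "s_obs" else "gaussian"
    cols = [c for c in covariates if c in band_table.columns]
    df = band_table[[response] + cols + ([effort_col] if effort_col in band_table else [])].copy()
    df = df.replace([np.inf, -np.inf], np.nan).dropna(subset=[response] + cols)
    df = df[df[effort_col] > 0] if (fam == "poisson" and effort_col in df) else df
    if len(df) < 3:
        raise ValueError("fewer than 3 usable bands")

    retained = _screen_or_passthrough(df, cols, threshold)
    y = df[response].to_numpy()
    offset = None
    if response == "s_obs" and effort_col in df:
        log_eff = np.log(df[effort_col].to_numpy(dtype=float))
        if effort_as_offset:
            offset = log_eff
        else:
            df["log_" + effort_col] = log_eff
            retained = retained + ["log_" + effort_col]

    fits = [fit_glm(y, None, family=fam, response=response, offset=offset)]
    for c in retained:
        z = (df[c] - df[c].mean()) / df[c].std(ddof=0)
        fits.append(fit_glm(y, pd.DataFrame({c: z}), family=fam,
                            response=response, offset=offset))
    return _rank_suite(response, fits)


def _screen_or_passthrough(df: pd.DataFrame, cols: list[str], threshold: float) -> list[str]:
    if len(cols) >= 2:
        kept, _ = collinearity_screen(df[cols], threshold=threshold)
        return kept
    return [c for c in cols if df[c].nunique(dropna=True) > 1]


# ---------------------------------------------------------------------------
# penalized negative-binomial GAM

def _bspline_basis(x: np.ndarray, xref: np.ndarray, k: int = 5) -> tuple[np.ndarray, dict]:
    """Cubic B-spline design with k basis functions, knots at quantiles."""
    from scipy.interpolate import BSpline

    deg = 3
    n_int = k - deg - 1                # interior knot count to yield k funcs
    qs = np.linspace(0, 1, n_int + 2)[1:-1]
    lo, hi = float(np.min(xref)), float(np.max(xref))
    interior = np.quantile(xref, qs)
    t = np.concatenate([[lo] * (deg + 1), interior, [hi] * (deg + 1)])
    info = {"knots": t, "deg": deg, "lo": lo, "hi": hi}
    return _eval_bspline(x, info), info


def _eval_bspline(x: np.ndarray, info: dict) -> np.ndarray:
    from scipy.interpolate import BSpline

    xc = np.clip(np.asarray(x, dtype=float), info["lo"], info["hi"])
    return BSpline.design_matrix(xc, info["knots"], info["deg"]).toarray()


def _sphere_xyz(lat, lon) -> np.ndarray:
    la, lo = np.deg2rad(np.asarray(lat, float)), np.deg2rad(np.asarray(lon, float))
    return np.stack([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)], axis=-1)


def _farthest_points(xyz: np.ndarray, k: int) -> np.ndarray:
    """Greedy maximin subset of row indices (deterministic, starts at 0)."""
    n = xyz.shape[0]
    k = min(k, n)
    sel = [0]
    d = np.arccos(np.clip(xyz @ xyz[0], -1, 1))
    for _ in range(1, k):
        j = int(np.argmax(d))
        sel.append(j)
        d = np.minimum(d, np.arccos(np.clip(xyz @ xyz[j], -1, 1)))
    return np.array(sel)


def _nb_loglik(y, mu, theta) -> float:
    mu = np.clip(mu, 1e-10, None)
    return float(np.sum(gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
                        + theta * np.log(theta / (theta + mu))
                        + y * np.log(mu / (theta + mu))))


def _nb_deviance(y, mu, theta) -> float:
    mu = np.clip(mu, 1e-10, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    t2 = (y + theta) * np.log((y + theta) / (mu + theta))
    return float(2.0 * np.sum(t1 - t2))


class _GamDesign:
    """Design matrix and block penalties for one GAM formula."""

    def __init__(self, table: pd.DataFrame, smooth_terms: list[str],
                 spatial: tuple[str, str] | None, k_basis: int = 5,
                 n_knots_spatial: int = 50, shrink: float = 1e-3):
        self.smooth_terms = list(smooth_terms)
        self.spatial = spatial
        self.k_basis = k_basis
        self.shrink = shrink
        self.blocks: list[tuple[str, slice]] = []
        self.basis_info: dict[str, dict] = {}
        self.col_means: dict[str, np.ndarray] = {}
        cols = [np.ones((len(table), 1))]
        pens: list[np.ndarray] = [np.zeros((1, 1))]
        start = 1
        for t in smooth_terms:
            B, info = _bspline_basis(table[t].to_numpy(float), table[t].to_numpy(float), k_basis)
            m = B.mean(axis=0)
            self.basis_info[t] = info
            self.col_means[t] = m
            B = B - m
            d2 = np.diff(np.eye(B.shape[1]), 2, axis=0)
            pens.append(d2.T @ d2 + shrink * np.eye(B.shape[1]))
            cols.append(B)
            self.blocks.append((t, slice(start, start + B.shape[1])))
            start += B.shape[1]
        if spatial is not None:
            xyz = _sphere_xyz(table[spatial[0]].to_numpy(), table[spatial[1]].to_numpy())
            knots = xyz[_farthest_points(xyz, n_knots_spatial)]
            d = np.arccos(np.clip(xyz @ knots.T, -1, 1))
            ell = np.median(np.arccos(np.clip(knots @ knots.T, -1, 1)))
            self.sp_knots, self.sp_ell = knots, max(ell, 1e-3)
            B = np.exp(-(d / self.sp_ell) ** 2)
            m = B.mean(axis=0)
            self.col_means["__spatial__"] = m
            B = B - m
            cols.append(B)
            pens.append(np.eye(B.shape[1]))
            self.blocks.append(("__spatial__", slice(start, start + B.shape[1])))
            start += B.shape[1]
        self.X = np.hstack(cols)
        self.S_blocks = pens
        self.p = self.X.shape[1]
        self.ranges = {t: (float(table[t].min()), float(table[t].max()))
                       for t in smooth_terms}

    def penalty(self, lambdas: dict[str, float]) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        S[0, 0] = 0.0
        for (name, sl), Sb in zip(self.blocks, self.S_blocks[1:]):
            S[sl, sl] = lambdas.get(name, 1.0) * Sb
        return S

    def design(self, newdata: pd.DataFrame) -> np.ndarray:
        cols = [np.ones((len(newdata), 1))]
        for t in self.smooth_terms:
            B = _eval_bspline(newdata[t].to_numpy(float), self.basis_info[t])
            cols.append(B - self.col_means[t])
        if self.spatial is not None:
            xyz = _sphere_xyz(newdata[self.spatial[0]].to_numpy(),
                              newdata[self.spatial[1]].to_numpy())
            d = np.arccos(np.clip(xyz @ self.sp_knots.T, -1, 1))
            cols.append(np.exp(-(d / self.sp_ell) ** 2) - self.col_means["__spatial__"])
        return np.hstack(cols)


def _pirls(y, X, S, theta, max_iter=50, tol=1e-8):
    """Penalized IRLS for the log-link NB; returns (beta, mu, edf, XtWX, H)."""
    n = y.size
    mu = np.clip(y + 0.5, 0.5, None)
    eta = np.log(mu)
    beta = None
    dev = _nb_deviance(y, mu, theta)
    for _ in range(max_iter):
        w = mu / (1.0 + mu / theta)
        z = eta + (y - mu) / mu
        XtW = X.T * w
        A = XtW @ X + S
        beta_new = np.linalg.solve(A + 1e-10 * np.eye(A.shape[0]), XtW @ z)
        eta = np.clip(X @ beta_new, -30, 30)
        mu = np.exp(eta)
        dev_new = _nb_deviance(y, mu, theta)
        done = abs(dev - dev_new) < tol * (abs(dev_new) + 0.1)
        beta, dev = beta_new, dev_new
        if done:
            break
    w = mu / (1.0 + mu / theta)
    XtW = X.T * w
    A = XtW @ X + S
    Ainv = np.linalg.inv(A + 1e-10 * np.eye(A.shape[0]))
    F = Ainv @ (XtW @ X)                  # edf matrix
    return beta, mu, float(np.trace(F)), Ainv, F


@dataclass
class GamFit(ModelFit):
    design: object = field(default=None, repr=False, compare=False)
    beta: np.ndarray = field(default=None, repr=False, compare=False)
    cov_beta: np.ndarray = field(default=None, repr=False, compare=False)
    lambdas: dict = field(default_factory=dict)
    edf_by_term: dict = field(default_factory=dict)
    gcv: float = np.nan

    def term_curve(self, term: str, grid=None, n: int = 100) -> pd.DataFrame:
        """Partial effect of one smooth on the linear-predictor scale."""
        lo, hi = self.design.ranges[term]
        if grid is None:
            grid = np.linspace(lo, hi, n)
        B = _eval_bspline(np.asarray(grid, float), self.design.basis_info[term])
        B = B - self.design.col_means[term]
        sl = dict(self.design.blocks)[term]
        eff = B @ self.beta[sl]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B,
                                          self.cov_beta[sl, sl], B), 0))
        return pd.DataFrame({"x": grid, "effect": eff,
                             "lower": eff - 1.96 * se, "upper": eff + 1.96 * se})


def fit_gam(cell_table: pd.DataFrame, response: str, smooth_terms: list[str],
            spatial: tuple[str, str] | None = ("center_lat", "center_lon"),
            family: str = "negative_binomial",
            theta_grid=None, lambda_grid=None, k_basis: int = 5,
            n_knots_spatial: int = 50, min_cells: int = 50) -> GamFit:
    """Penalized regression GAM for per-cell responses.

    Negative-binomial errors (log link) for overdispersed, zero-inflated
    species counts; each covariate gets a centred cubic B-spline basis
    (k=5) with a second-difference penalty plus shrinkage ridge, and the
    spatial term is a great-circle radial basis on farthest-point knots
    with a ridge penalty.  Smoothing parameters minimise GCV by coordinate
    search over a log-spaced grid; θ is profiled over a log-spaced grid
    (0.1–100) by maximum likelihood.  For a continuous response pass
    family="gaussian" (identity link via log of the working response is not
    used; the gaussian branch fits on the identity scale).
    """
    df = cell_table.dropna(subset=[response] + list(smooth_terms)
                           + (list(spatial) if spatial else [])).copy()
    if len(df) < min_cells:
        raise ValueError(f"need >= {min_cells} cells with data, have {len(df)}")
    y = df[response].to_numpy(dtype=float)
    if family == "negative_binomial" and (np.any(y < 0) or np.any(y != np.floor(y))):
        raise ValueError("negative binomial requires nonnegative integer counts")
    des = _GamDesign(df, smooth_terms, spatial, k_basis=k_basis,
                     n_knots_spatial=n_knots_spatial)
    X = des.X
    n = y.size
    if theta_grid is None:
        theta_grid = np.logspace(-1, 2, 7)
    if lambda_grid is None:
        lambda_grid = np.logspace(-2, 4, 7)
    if family == "gaussian":
        theta_grid = [np.inf]

    def fit_at(theta, lambdas):
        if family == "gaussian":
            S = des.penalty(lambdas)
            A = X.T @ X + S
            Ainv = np.linalg.inv(A + 1e-10 * np.eye(A.shape[0]))
            beta = Ainv @ (X.T @ y)
            mu = X @ beta
            F = Ainv @ (X.T @ X)
            edf = float(np.trace(F))
            rss = float(np.sum((y - mu) ** 2))
            gcv = n * rss / max(n - edf, 1e-6) ** 2
            scale = rss / max(n - edf, 1.0)
            ll = -0.5 * n * (np.log(2 * np.pi * scale) + rss / (n * scale))
            return beta, mu, edf, Ainv * scale, gcv, ll
        S = des.penalty(lambdas)
        beta, mu, edf, Ainv, F = _pirls(y, X, S, theta)
        dev = _nb_deviance(y, mu, theta)
        gcv = n * dev / max(n - edf, 1e-6) ** 2
        ll = _nb_loglik(y, mu, theta)
        w = mu / (1.0 + mu / theta)
        Vb = Ainv                         # bayesian posterior covariance
        return beta, mu, edf, Vb, gcv, ll

    term_names = [b[0] for b in des.blocks]
    best = None
    for theta in theta_grid:
        lambdas = {t: 1.0 for t in term_names}
        for _pass in range(2):
            for t in term_names:
                scores = []
                for lam in lambda_grid:
                    trial = dict(lambdas)
                    trial[t] = lam
                    scores.append((fit_at(theta, trial)[4], lam))
                lambdas[t] = min(scores)[1]
        beta, mu, edf, Vb, gcv, ll = fit_at(theta, lambdas)
        if best is None or ll > best[0]:
            best = (ll, theta, dict(lambdas), beta, mu, edf, Vb, gcv)
    ll, theta, lambdas, beta, mu, edf, Vb, gcv = best
    if family != "gaussian" and len(theta_grid) > 1 \
            and theta in (theta_grid[0], theta_grid[-1]):
        warnings.warn(f"NB dispersion search hit the grid boundary (theta={theta:g})")

    # per-term effective degrees of freedom
    S = des.penalty(lambdas)
    if family == "gaussian":
        F = np.linalg.inv(X.T @ X + S + 1e-10 * np.eye(des.p)) @ (X.T @ X)
    else:
        w = mu / (1.0 + mu / theta)
        XtW = X.T * w
        F = np.linalg.inv(XtW @ X + S + 1e-10 * np.eye(des.p)) @ (XtW @ X)
    edf_terms = {t: float(np.trace(F[sl, sl])) for t, sl in des.blocks}

    k_eff = edf + (0.0 if family == "gaussian" else 1.0)   # + theta
    fit = GamFit(response=response, family=family,
                 terms=list(smooth_terms) + (["spatial"] if spatial else []),
                 coefficients=pd.Series(beta),
                 std_errors=pd.Series(np.sqrt(np.maximum(np.diag(Vb), 0))),
                 loglik=float(ll), k_effective=float(k_eff),
                 aic=-2.0 * float(ll) + 2.0 * float(k_eff),
                 theta=None if family == "gaussian" else float(theta),
                 converged=True, design=des, beta=beta, cov_beta=Vb,
                 lambdas=lambdas, edf_by_term=edf_terms, gcv=float(gcv))
    return fit


def gam_suite(cell_table: pd.DataFrame, response: str, covariates: list[str],
              spatial=("center_lat", "center_lon"), threshold: float = 0.95,
              **gam_kw) -> CandidateSuite:
    """GAM candidate suite: intercept-only null, one single-smooth model per
    retained covariate (each with the spatial term), and an all-terms model."""
    fam = "negative_binomial" if response == "s_obs" else "gaussian"
    cols = [c for c in covariates if c in cell_table.columns]
    df = cell_table.replace([np.inf, -np.inf], np.nan).dropna(subset=[response] + cols)
    min_cells = gam_kw.get("min_cells", 50)
    if len(df) < min_cells:
        raise ValueError(f"need >= {min_cells} cells with data, have {len(df)}")
    retained = _screen_or_passthrough(df, cols, threshold)
    fits = []
    y = df[response].to_numpy(dtype=float)
    null = fit_glm(y.astype(int) if fam == "negative_binomial" else y, None,
                   family="poisson" if fam == "negative_binomial" else "gaussian",
                   response=response)
    if fam == "negative_binomial":
        # refit the null as NB with profiled theta for family comparability
        null = fit_gam(df, response, [], spatial=None, family=fam, **gam_kw)
    null.terms = []
    fits.append(null)
    for c in retained:
        fits.append(fit_gam(df, response, [c], spatial=spatial, family=fam, **gam_kw))
    if len(retained) > 1:
        fits.append(fit_gam(df, response, retained, spatial=spatial, family=fam, **gam_kw))
    return _rank_suite(response, fits)


def predict_response(fit: ModelFit, newdata: pd.DataFrame) -> pd.DataFrame:
    """Response-scale predictions with delta-method 95% intervals.

    For GAM fits, rows outside the fitted covariate ranges are flagged as
    extrapolation.  Unknown covariates raise.
    """
    if isinstance(fit, GamFit):
        missing = [t for t in fit.design.smooth_terms if t not in newdata.columns]
        if missing:
            raise KeyError(f"newdata lacks covariates {missing}")
        X = fit.design.design(newdata)
        eta = X @ fit.beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fit.cov_beta, X), 0))
        extrap = np.zeros(len(newdata), dtype=bool)
        for t, (lo, hi) in fit.design.ranges.items():
            v = newdata[t].to_numpy(dtype=float)
            extrap |= (v < lo) | (v > hi)
        if fit.family == "gaussian":
            pred, lo_, hi_ = eta, eta - 1.96 * se, eta + 1.96 * se
        else:
            pred, lo_, hi_ = np.exp(eta), np.exp(eta - 1.96 * se), np.exp(eta + 1.96 * se)
        return pd.DataFrame({"predicted": pred, "lower": lo_, "upper": hi_,
                             "extrapolation": extrap})
    res = fit._impl
    import statsmodels.api as sm

    exog = pd.DataFrame({c: (newdata[c] if c != "const" else 1.0)
                         for c in fit.coefficients.index})
    missing = [c for c in fit.coefficients.index
               if c != "const" and c not in newdata.columns]
    if missing:
        raise KeyError(f"newdata lacks covariates {missing}")
    pr = res.get_prediction(exog)
    sf = pr.summary_frame(alpha=0.05)
    return pd.DataFrame({"predicted": sf["mean"].to_numpy(),
                         "lower": sf["mean_ci_lower"].to_numpy(),
                         "upper": sf["mean_ci_upper"].to_numpy(),
                         "extrapolation": False})
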