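"""Phylogenetic generalised least squares (PGLS) ANCOVA.

The model is an analysis of covariance of a (possibly transformed) life
history trait on (possibly log) body weight, with breed age
(ancient vs modern) as a two-level factor and an optional weight x breed-age
interaction:

    g(trait) = b0 + b1 * f(weight) + b2 * 1[ancient] (+ b3 * f(weight) * 1[ancient]) + e

with residuals e ~ N(0, sigma^2 * V), where V is the phylogenetic covariance
of the breed tree under Pagel's lambda/kappa/delta transforms. Modern is the
reference level, so b2 is directly the "ancient - modern" contrast. With
V = I (or lambda = 0 on an ultrametric tree, which makes V a scalar matrix)
the fit reduces exactly to ordinary least squares.

Estimation is by GLS through the Cholesky factor of V: with V = L L', the
decorrelated regression of L^-1 y on L^-1 X gives

    beta = (X' V^-1 X)^-1 X' V^-1 y,   sigma^2 = r' V^-1 r / (n - k),

standard errors from sigma^2 (X' V^-1 X)^-1, two-sided p-values from
t(n - k), and R^2 / overall F against the V-weighted intercept-only model.
lambda/kappa/delta may be fixed or profiled by maximum likelihood
(sequential kappa -> delta -> lambda: coarse grid at step 0.05, then bounded
local refinement).

The core is exposed as a scikit-learn style estimator
(:class:`PGLSRegressor`); the module-level functions are thin wrappers.

Trait transforms follow the registry in :data:`TRAIT_SPECS`: lifespan is
analysed untransformed against weight in kg; the square root of litter size
against log weight; and log cancer mortality rate (the proportion of
diagnosed deaths attributed to cancer) against log weight. Natural
logarithms throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .phylogeny import apply_lambda, pagel_covariance

__all__ = [
    "ModelSpec",
    "TRAIT_SPECS",
    "PGLSRegressor",
    "PGLSFit",
    "JarqueBeraResult",
    "design_matrix",
    "transform_response",
    "fit_pgls",
    "estimate_pagel",
    "fit_trait_model",
    "anova_interaction",
    "predict",
    "jarque_bera",
    "cancer_mortality_rate",
    "add_cmr_column",
]

PAGEL_BOUNDS = {"lambda": (0.0, 1.0), "kappa": (0.0, 3.0), "delta": (1e-6, 3.0)}
_GRID_STEP = 0.05


# ---------------------------------------------------------------------------
# model specification and design
# ---------------------------------------------------------------------------

_FORWARD = {
    "identity": lambda v: v,
    "sqrt": np.sqrt,
    "log": np.log,
}
_BACKWARD = {
    "identity": lambda v: v,
    "sqrt": np.square,
    "log": np.exp,
}


@dataclass(frozen=True)
class ModelSpec:
    """Which trait is modelled, on what scale, against what weight scale."""

    trait: str
    response_column: str
    response_transform: str = "identity"
    weight_transform: str = "identity"
    include_interaction: bool = False

    def __post_init__(self):
        for t in (self.response_transform, self.weight_transform):
            if t not in _FORWARD:
                raise ValueError(f"unknown transform {t!r}; choose from {sorted(_FORWARD)}")


#: the trio of published model scales
TRAIT_SPECS: dict[str, ModelSpec] = {
    "lifespan": ModelSpec("lifespan", "lifespan_yr", "identity", "identity"),
    "litter": ModelSpec("litter", "litter_size", "sqrt", "log"),
    "cmr": ModelSpec("cmr", "cmr", "log", "log", include_interaction=True),
}


def _checked_transform(values, transform: str, breeds, what: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if transform in ("log", "sqrt"):
        bad = (v <= 0) if transform == "log" else (v < 0)
        if bad.any():
            names = ", ".join(str(b) for b in np.asarray(breeds)[bad][:5])
            raise ValueError(
                f"{transform} transform of {what} undefined for breed(s): {names}"
            )
    return _FORWARD[transform](v)


def design_matrix(spec: ModelSpec, breeds: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """ANCOVA design: intercept, transformed weight, ancient indicator
    (modern = reference), and optionally their interaction."""
    labels = breeds["label"].astype(str)
    levels = set(labels.unique())
    if not {"ancient", "modern"} <= levels:
        raise ValueError("factor has one level: need both 'ancient' and 'modern' breeds")
    w = _checked_transform(breeds["weight_kg"], spec.weight_transform, breeds["breed"], "weight")
    ind = (labels == "ancient").to_numpy(dtype=float)
    cols = [np.ones(len(breeds)), w, ind]
    names = ["intercept", "weight", "ancient"]
    if spec.include_interaction:
        cols.append(w * ind)
        names.append("weight:ancient")
    return np.column_stack(cols), names


def transform_response(spec: ModelSpec, breeds: pd.DataFrame) -> np.ndarray:
    return _checked_transform(
        breeds[spec.response_column], spec.response_transform, breeds["breed"], spec.trait
    )


def cancer_mortality_rate(cancer_deaths: float, diagnosed_deaths: float) -> float:
    """Proportion of diagnosed deaths attributed to cancer, in [0, 1]."""
    if diagnosed_deaths <= 0:
        raise ValueError("zero diagnosed deaths: cancer mortality rate undefined")
    if cancer_deaths < 0 or cancer_deaths > diagnosed_deaths:
        raise ValueError(
            f"need 0 <= cancer deaths ({cancer_deaths}) <= diagnosed deaths "
            f"({diagnosed_deaths})"
        )
    return float(cancer_deaths) / float(diagnosed_deaths)


def add_cmr_column(traits: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``cmr`` column computed from the death counts (NaN where
    counts are missing)."""
    out = traits.copy()
    cmr = []
    for _, row in out.iterrows():
        cd, dd = row.get("cancer_deaths"), row.get("diagnosed_deaths")
        if pd.isna(cd) or pd.isna(dd):
            cmr.append(np.nan)
        else:
            cmr.append(cancer_mortality_rate(float(cd), float(dd)))
    out["cmr"] = cmr
    return out


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


def _cholesky_psd(V: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, tolerating tiny negative eigenvalues."""
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        tr = float(np.trace(V))
        w = linalg.eigvalsh(V)
        if w.min() < -1e-8 * max(tr, 1.0):
            raise ValueError(
                f"covariance is not positive semi-definite (min eigenvalue {w.min():.3g})"
            ) from None
        jitter = max(1e-12 * tr, 1e-12)
        return linalg.cholesky(V + jitter * np.eye(len(V)), lower=True)


class PGLSRegressor(RegressorMixin, BaseEstimator):
    """Generalised least squares regression under a phylogenetic covariance.

    Parameters
    ----------
    covariance : array-like of shape (n, n), optional
        Residual covariance up to a scalar (e.g. a phylogenetic V). If a
        ``tree`` is given instead, the covariance is built from it under the
        Pagel parameters.
    tree : dendropy.Tree, optional
        Time-scaled tree whose tips match the sample order (pass
        ``taxon_order`` to align). Required when any Pagel parameter is to
        be estimated.
    lam, kappa, delta : float
        Pagel transform parameters (defaults 1, 1, 1 = plain Brownian
        covariance). Ignored entries of ``estimate`` are held fixed at these
        values.
    estimate : tuple of str
        Subset of {"lambda", "kappa", "delta"} to profile by maximum
        likelihood (sequential kappa -> delta -> lambda; grid step 0.05 then
        bounded refinement).
    taxon_order : sequence of str, optional
        Tip labels giving the row order of ``X`` and ``y``; required with a
        ``tree`` whose tip order differs from the data.

    Attributes
    ----------
    coef_ : ndarray of shape (k,)
        GLS coefficient estimates ``(X' V^-1 X)^-1 X' V^-1 y``.
    se_, tvalues_, pvalues_ : ndarray of shape (k,)
        Standard errors, t statistics and two-sided t(n-k) p-values.
    sigma2_ : float
        Residual variance on the transformed scale, RSS_V / (n - k).
    r2_, fvalue_, f_pvalue_ : float
        V-weighted coefficient of determination and overall F against the
        GLS intercept-only model, with its p-value.
    pagel_ : dict
        The lambda/kappa/delta actually used (estimated or fixed).
    resid_, phylo_resid_ : ndarray
        Raw residuals and decorrelated (L^-1 r) phylogenetic residuals.
    loglik_ : float
        Maximised multivariate-normal log-likelihood.
    """

    def __init__(
        self,
        covariance=None,
        tree=None,
        lam: float = 1.0,
        kappa: float = 1.0,
        delta: float = 1.0,
        estimate: tuple = (),
        taxon_order=None,
    ):
        self.covariance = covariance
        self.tree = tree
        self.lam = lam
        self.kappa = kappa
        self.delta = delta
        self.estimate = estimate
        self.taxon_order = taxon_order

    # -- internals ---------------------------------------------------------

    def _covariance_for(self, pagel: dict, n: int) -> np.ndarray:
        if self.tree is not None:
            # lambda only scales off-diagonals, so cache the (kappa, delta) base
            key = (float(pagel["kappa"]), float(pagel["delta"]))
            cache = getattr(self, "_v_cache", None)
            if cache is None or cache[0] != key:
                V = pagel_covariance(self.tree, lam=1.0, kappa=key[0], delta=key[1])
                if self.taxon_order is not None:
                    order = list(self.taxon_order)
                    missing = set(order) - set(V.index)
                    if missing:
                        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
                    V = V.loc[order, order]
                self._v_cache = (key, V.to_numpy(dtype=float))
            V = self._v_cache[1]
            if pagel["lambda"] != 1.0:
                V = apply_lambda(V, pagel["lambda"])
        elif self.covariance is not None:
            V = (
                self.covariance.to_numpy(dtype=float)
                if isinstance(self.covariance, pd.DataFrame)
                else np.asarray(self.covariance, dtype=float)
            )
            # fixed-V path still honours the lambda/delta dials
            if pagel["delta"] != 1.0:
                from .phylogeny import apply_delta

                V = apply_delta(V, pagel["delta"])
            if pagel["lambda"] != 1.0:
                V = apply_lambda(V, pagel["lambda"])
        else:
            V = np.eye(n)
        if V.shape != (n, n):
            raise ValueError(f"covariance shape {V.shape} does not match n={n}")
        return V

    @staticmethod
    def _gls(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> dict:
        n, k = X.shape
        L = _cholesky_psd(V)
        Xd = linalg.solve_triangular(L, X, lower=True)
        yd = linalg.solve_triangular(L, y, lower=True)
        if np.linalg.matrix_rank(Xd) < k:
            raise ValueError("design matrix is singular")
        XtX = Xd.T @ Xd
        XtX_inv = linalg.inv(XtX)
        beta = XtX_inv @ (Xd.T @ yd)
        rd = yd - Xd @ beta
        rss = float(rd @ rd)
        df2 = n - k
        sigma2 = rss / df2 if df2 > 0 else np.nan
        se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df2) if df2 > 0 else np.full(k, np.nan)
        # intercept-only GLS baseline for R^2 / F
        ones_d = linalg.solve_triangular(L, np.ones(n), lower=True)
        mu = float(ones_d @ yd) / float(ones_d @ ones_d)
        tss = float(np.sum((yd - mu * ones_d) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else np.nan
        df1 = k - 1
        if df1 > 0 and df2 > 0 and rss > 0:
            fval = ((tss - rss) / df1) / (rss / df2)
            fp = float(stats.f.sf(fval, df1, df2))
        else:
            fval, fp = np.nan, np.nan
        logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
        sigma2_ml = rss / n
        if sigma2_ml > 0:
            loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdetV + n)
        else:
            loglik = np.inf  # degenerate (noiseless) fit
        return dict(
            beta=beta, se=se, tvals=tvals, pvals=pvals, sigma2=sigma2, rss=rss,
            tss=tss, r2=r2, fval=fval, f_pvalue=fp, df1=df1, df2=df2,
            loglik=loglik, resid=y - X @ beta, phylo_resid=rd,
        )

    def _profile(self, y, X, pagel: dict) -> dict:
        """Sequential profile ML over the requested Pagel parameters."""
        wanted = [p for p in ("kappa", "delta", "lambda") if p in set(self.estimate)]
        if not wanted:
            return pagel
        if self.tree is None and any(p == "kappa" for p in wanted):
            raise ValueError("kappa estimation requires a tree")
        # a (near-)noiseless response makes the profile likelihood degenerate
        probe = self._gls(y, X, self._covariance_for(pagel, len(y)))
        if probe["rss"] <= 1e-10 * max(1.0, float(y @ y)):
            warnings.warn(
                "likelihood degenerate (residual variance ~ 0); returning "
                "boundary values for " + ", ".join(wanted),
                UserWarning,
                stacklevel=3,
            )
            for name in wanted:
                pagel[name] = PAGEL_BOUNDS[name][0]
            return pagel

        def nll(value, name):
            trial = dict(pagel)
            trial[name] = float(value)
            V = self._covariance_for(trial, len(y))
            ll = self._gls(y, X, V)["loglik"]
            return -ll if np.isfinite(ll) else -1e300

        for name in wanted:
            lo, hi = PAGEL_BOUNDS[name]
            grid = np.arange(lo, hi + 1e-9, _GRID_STEP)
            grid = np.clip(grid, lo, hi)
            lls = np.array([-nll(g, name) for g in grid])
            if not np.all(np.isfinite(lls)) or np.isinf(lls).any():
                # degenerate likelihood (e.g. noiseless response)
                warnings.warn(
                    f"likelihood degenerate while profiling {name}; returning "
                    "boundary value",
                    UserWarning,
                    stacklevel=3,
                )
                pagel[name] = float(grid[0])
                continue
            if lls.max() - lls.min() < 1e-6:
                warnings.warn(
                    f"likelihood flat in {name}; returning boundary value",
                    UserWarning,
                    stacklevel=3,
                )
                pagel[name] = float(grid[0])
                continue
            best = float(grid[int(np.argmax(lls))])
            res = optimize.minimize_scalar(
                nll,
                bounds=(max(lo, best - _GRID_STEP), min(hi, best + _GRID_STEP)),
                args=(name,),
                method="bounded",
                options={"xatol": 1e-4},
            )
            pagel[name] = float(res.x) if res.fun <= nll(best, name) else best
        return pagel

    # -- API ---------------------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.n_features_in_ = X.shape[1]
        pagel = {"lambda": float(self.lam), "kappa": float(self.kappa),
                 "delta": float(self.delta)}
        for name, (lo, hi) in PAGEL_BOUNDS.items():
            if name not in set(self.estimate) and not lo <= pagel[name] <= hi:
                raise ValueError(f"{name}={pagel[name]} outside [{lo}, {hi}]")
        pagel = self._profile(y, X, pagel)
        V = self._covariance_for(pagel, len(y))
        out = self._gls(y, X, V)
        self.pagel_ = pagel
        self.coef_ = out["beta"]
        self.se_ = out["se"]
        self.tvalues_ = out["tvals"]
        self.pvalues_ = out["pvals"]
        self.sigma2_ = out["sigma2"]
        self.rss_ = out["rss"]
        self.tss_ = out["tss"]
        self.r2_ = out["r2"]
        self.fvalue_ = out["fval"]
        self.f_pvalue_ = out["f_pvalue"]
        self.df_ = (out["df1"], out["df2"])
        self.loglik_ = out["loglik"]
        self.resid_ = out["resid"]
        self.phylo_resid_ = out["phylo_resid"]
        self.n_ = len(y)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_


# ---------------------------------------------------------------------------
# fit container and functional wrappers
# ---------------------------------------------------------------------------


@dataclass
class PGLSFit:
    """Snapshot of one fitted PGLS model."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    sigma2: float
    r2: float
    fvalue: float
    f_pvalue: float
    df1: int
    df2: int
    n: int
    loglik: float
    rss: float
    tss: float
    pagel: dict
    resid: np.ndarray
    phylo_resid: np.ndarray
    breeds: list[str] = field(default_factory=list)
    spec: ModelSpec | None = None

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.coef,
                "se": self.se,
                "t": self.tvalues,
                "p": self.pvalues,
            },
            index=self.terms,
        )

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coef": [float(v) for v in self.coef],
            "se": [float(v) for v in self.se],
            "t": [float(v) for v in self.tvalues],
            "p": [float(v) for v in self.pvalues],
            "sigma2": float(self.sigma2),
            "r2": float(self.r2),
            "f": float(self.fvalue),
            "f_p": float(self.f_pvalue),
            "df": [int(self.df1), int(self.df2)],
            "n": int(self.n),
            "loglik": float(self.loglik),
            "pagel": {k: float(v) for k, v in self.pagel.items()},
        }


def _snapshot(est: PGLSRegressor, terms=None, breeds=None, spec=None) -> PGLSFit:
    k = len(est.coef_)
    return PGLSFit(
        terms=list(terms) if terms is not None else [f"x{i}" for i in range(k)],
        coef=est.coef_, se=est.se_, tvalues=est.tvalues_, pvalues=est.pvalues_,
        sigma2=est.sigma2_, r2=est.r2_, fvalue=est.fvalue_, f_pvalue=est.f_pvalue_,
        df1=est.df_[0], df2=est.df_[1], n=est.n_, loglik=est.loglik_,
        rss=est.rss_, tss=est.tss_, pagel=dict(est.pagel_),
        resid=est.resid_, phylo_resid=est.phylo_resid_,
        breeds=list(breeds) if breeds is not None else [], spec=spec,
    )


def fit_pgls(y, X, V, terms=None) -> PGLSFit:
    """GLS fit of y on X under residual covariance V (thin wrapper)."""
    est = PGLSRegressor(covariance=V).fit(np.asarray(X, float), np.asarray(y, float))
    return _snapshot(est, terms=terms)


def estimate_pagel(
    y,
    X,
    tree,
    which=("lambda",),
    lam: float = 1.0,
    kappa: float = 1.0,
    delta: float = 1.0,
    taxon_order=None,
    terms=None,
) -> tuple[dict, PGLSFit]:
    """Profile-ML estimate of the requested Pagel parameters plus the fit."""
    if not which:
        raise ValueError("which must name at least one of lambda/kappa/delta")
    est = PGLSRegressor(
        tree=tree, lam=lam, kappa=kappa, delta=delta,
        estimate=tuple(which), taxon_order=taxon_order,
    ).fit(np.asarray(X, float), np.asarray(y, float))
    return dict(est.pagel_), _snapshot(est, terms=terms)


def fit_trait_model(
    traits: pd.DataFrame,
    tree,
    trait: str,
    lam=0.0,
    kappa=1.0,
    delta=1.0,
    estimate: tuple = (),
    include_interaction: bool | None = None,
) -> PGLSFit:
    """Fit one trait's ANCOVA on the breeds shared by the table and tree.

    Breeds missing from the tree, or with missing trait values, are dropped
    with a warning; breeds with a cancer mortality rate of exactly zero are
    dropped from the CMR model because its log transform is undefined.
    """
    spec = TRAIT_SPECS[trait]
    if include_interaction is not None:
        spec = ModelSpec(
            spec.trait, spec.response_column, spec.response_transform,
            spec.weight_transform, include_interaction,
        )
    df = traits.copy()
    if trait == "cmr" and "cmr" not in df.columns:
        df = add_cmr_column(df)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    off_tree = sorted(set(df["breed"].astype(str)) - tips)
    if off_tree:
        warnings.warn(
            f"{len(off_tree)} breed(s) absent from the tree dropped: "
            + ", ".join(off_tree[:5]) + ("..." if len(off_tree) > 5 else ""),
            UserWarning,
            stacklevel=2,
        )
        df = df[df["breed"].astype(str).isin(tips)]
    df = df.dropna(subset=[spec.response_column, "weight_kg"])
    if trait == "cmr":
        zeros = df["cmr"] == 0
        if zeros.any():
            warnings.warn(
                f"{int(zeros.sum())} breed(s) with zero cancer mortality rate "
                "excluded (log undefined)",
                UserWarning,
                stacklevel=2,
            )
            df = df[~zeros]
    df = df.reset_index(drop=True)
    y = transform_response(spec, df)
    X, terms = design_matrix(spec, df)
    breeds = df["breed"].astype(str).tolist()
    est = PGLSRegressor(
        tree=tree, lam=lam, kappa=kappa, delta=delta,
        estimate=tuple(estimate), taxon_order=breeds,
    ).fit(X, y)
    return _snapshot(est, terms=terms, breeds=breeds, spec=spec)


def anova_interaction(fit_full: PGLSFit, fit_reduced: PGLSFit):
    """Partial F test of the terms the full model adds to the reduced one.

    Both fits must use the same data and covariance; the reduced model's
    terms must nest within the full model's.
    """
    if fit_full.n != fit_reduced.n:
        raise ValueError("models fitted to different numbers of observations")
    if not set(fit_reduced.terms) <= set(fit_full.terms):
        raise ValueError("models are not nested")
    df1 = (fit_reduced.df2) - (fit_full.df2)
    if df1 < 0:
        raise ValueError("full model has fewer parameters than the reduced model")
    df2 = fit_full.df2
    if df1 == 0:
        return 0.0, 0, df2, 1.0
    num = (fit_reduced.rss - fit_full.rss) / df1
    den = fit_full.rss / df2
    fval = max(num / den, 0.0)
    p = float(stats.f.sf(fval, df1, df2))
    return float(fval), int(df1), int(df2), p


def predict(fit: PGLSFit, spec: ModelSpec, weight_kg: float, breed_age: str) -> float:
    """Predict the trait on its original scale for one weight and breed age."""
    if breed_age not in ("ancient", "modern"):
        raise ValueError(f"unknown factor level {breed_age!r}")
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    w = float(_FORWARD[spec.weight_transform](weight_kg))
    ind = 1.0 if breed_age == "ancient" else 0.0
    coef = dict(zip(fit.terms, fit.coef))
    eta = coef["intercept"] + coef["weight"] * w + coef.get("ancient", 0.0) * ind
    if "weight:ancient" in coef:
        eta += coef["weight:ancient"] * w * ind
    return float(_BACKWARD[spec.response_transform](eta))


# ---------------------------------------------------------------------------
# residual diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JarqueBeraResult:
    jb: float
    p: float
    n: int
    skewness: float
    kurtosis: float


def jarque_bera(residuals) -> JarqueBeraResult:
    """Jarque-Bera normality test from moment skewness S and kurtosis K:

        JB = n/6 * (S^2 + (K - 3)^2 / 4),  p = P[chi2(2) > JB].

    Moment definitions with no small-sample correction.
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if n < 8:
        raise ValueError(f"need at least 8 residuals, got {n}")
    c = r - r.mean()
    m2 = float(np.mean(c**2))
    if m2 == 0:
        raise ValueError("constant residuals: moments undefined")
    S = float(np.mean(c**3)) / m2**1.5
    K = float(np.mean(c**4)) / m2**2
    jb = n / 6.0 * (S**2 + (K - 3.0) ** 2 / 4.0)
    p = float(stats.chi2.sf(jb, 2))
    return JarqueBeraResult(jb=float(jb), p=p, n=n, skewness=S, kurtosis=K)
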