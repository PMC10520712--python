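"""Maximum-likelihood spatial panel models with fixed effects.

Four model families over a balanced region-year panel with weight matrix W
(row-standardized, no islands, for the spatial families):

* FE   — non-spatial least squares on within-transformed data,
* SLM  — spatial lag:    y = rho*W y + X beta + mu + v + eps,
* SEM  — spatial error:  y = X beta + u,  u = lambda*W u + eps,
* SDM  — spatial Durbin: y = rho*W y + X beta + W X theta + mu + v + eps,

each estimated by concentrated maximum likelihood after demeaning out the
individual (mu_i) and/or time (v_t) fixed effects.  The spatial parameter
is found by bounded scalar optimization on the admissible interval
(1/omega_min + delta, 1/omega_max - delta), with the Jacobian term
evaluated from the pre-computed eigenvalues omega of W as
sum_k ln(1 - rho*omega_k).

Naive demeaned ML is inconsistent in short panels: time demeaning loses
one effective period and cross-section demeaning one effective region,
which biases the variance and — through the Jacobian — the spatial
parameter itself.  With ``bias_correct`` (default on for two-way effects)
the likelihood is the orthonormal-transformation one: effective dimensions
(n-1) and/or (T-1), and for cross-section demeaning of a row-standardized
W (where the constant vector is an eigenvector with eigenvalue 1) the
log-determinant drops one unit eigenvalue, ln|I - rho*W| - ln(1 - rho).
Standard errors come from the analytic information matrix evaluated on the
transformed problem.

The module also provides the LR test for nested fits, a Swamy-Arora
random-effects estimator for the non-spatial model, and the Hausman
fixed-vs-random test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import helmert

from .weights import SpatialWeights, rho_interval, spectrum

FAMILIES = ("FE", "SLM", "SEM", "SDM")
EFFECTS = ("none", "individual", "time", "twoway")
BOUNDARY_INSET = 1e-5
BOUNDARY_FLAG_TOL = 1e-4


@dataclass
class ModelSpec:
    """What to fit: family, fixed-effects mode, variables, log transform."""

    family: str
    y_var: str
    x_vars: list[str]
    effects: str = "twoway"
    log_transform: bool = False
    bias_correct: bool | None = None  # None -> on iff effects == 'twoway'

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.effects not in EFFECTS:
            raise ValueError(f"effects must be one of {EFFECTS}")
        if not self.x_vars:
            raise ValueError("at least one regressor required")


@dataclass
class SpatialFitResult:
    family: str
    effects: str
    rho: float | None
    lam: float | None
    beta: pd.Series
    theta: pd.Series | None
    sigma2: float
    loglik: float
    vcov: pd.DataFrame
    r2_within: float
    r2_naive: float
    fe_individual: pd.Series
    fe_time: pd.Series
    n: int
    T: int
    y_var: str = ""
    x_vars: list[str] = field(default_factory=list)
    rho_interval: tuple[float, float] | None = None
    boundary: bool = False
    bias_corrected: bool = False

    @property
    def spatial_param(self) -> float | None:
        return self.rho if self.rho is not None else self.lam

    def coef_table(self) -> pd.DataFrame:
        """Estimate / SE / t / p rows for every estimated parameter."""
        names = [n for n in self.vcov.index if n != "sigma2"]
        est = []
        for name in names:
            if name == "rho":
                est.append(self.rho)
            elif name == "lambda":
                est.append(self.lam)
            elif name.startswith("W."):
                est.append(self.theta[name[2:]])
            else:
                est.append(self.beta[name])
        est = np.asarray(est, dtype=float)
        se = np.sqrt(np.diag(self.vcov.loc[names, names].to_numpy()))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / se
        p = 2 * stats.norm.sf(np.abs(t))
        return pd.DataFrame({"estimate": est, "se": se, "t": t, "p": p}, index=names)


@dataclass
class TestResult:
    name: str
    statistic: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# panel plumbing


def panel_arrays(
    panel: pd.DataFrame, y_var: str, x_vars: list[str], region_order: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, list]:
    """Pivot a tidy balanced panel into y (n, T) and X (n, T, k) arrays."""
    cols = [y_var] + list(x_vars)
    missing = [c for c in cols if c not in panel.columns]
    if missing:
        raise KeyError(f"variables absent from panel: {missing}")
    years = sorted(panel["year"].unique())
    wide = panel.pivot_table(index="region", columns="year", values=cols, aggfunc="first")
    if wide.isna().any().any():
        raise ValueError("unbalanced panel: some region-year cells are missing")
    if set(panel["region"]) != set(region_order):
        raise ValueError("panel regions do not match weight-matrix region order")
    wide = wide.loc[list(region_order)]
    y = wide[y_var].loc[:, years].to_numpy(dtype=float)
    x = np.stack([wide[v].loc[:, years].to_numpy(dtype=float) for v in x_vars], axis=2)
    return y, x, years


def within_transform(arr: np.ndarray, effects: str) -> np.ndarray:
    """Demean an (n, T) or (n, T, k) array over regions and/or years.

    individual: subtract each region's time mean; time: subtract each
    year's cross-section mean; twoway: subtract both and add back the
    grand mean.  ``none`` is the identity.
    """
    if effects not in EFFECTS:
        raise ValueError(f"effects must be one of {EFFECTS}")
    a = np.asarray(arr, dtype=float)
    if effects == "none":
        return a.copy()
    out = a.copy()
    if effects in ("individual", "twoway"):
        out = out - a.mean(axis=1, keepdims=True)
    if effects in ("time", "twoway"):
        out = out - a.mean(axis=0, keepdims=True)
    if effects == "twoway":
        out = out + a.mean(axis=(0, 1), keepdims=True)
    return out


def _effective_dims(effects: str, n: int, T: int, corrected: bool) -> tuple[int, int, int]:
    """(n_eff, T_eff, drop_unit_root) for the (transformation) likelihood."""
    if not corrected:
        return n, T, 0
    n_eff = n - 1 if effects in ("time", "twoway") else n
    T_eff = T - 1 if effects in ("individual", "twoway") else T
    c = 1 if effects in ("time", "twoway") else 0
    return n_eff, T_eff, c


def _recover_fe(u: np.ndarray, effects: str, region_order, years) -> tuple[pd.Series, pd.Series, float]:
    """Fixed effects (and grand intercept) from raw-scale residual means."""
    n, T = u.shape
    grand = float(u.mean()) if effects == "twoway" else 0.0
    mu = np.zeros(n)
    v = np.zeros(T)
    if effects in ("individual", "twoway"):
        mu = u.mean(axis=1) - grand
    if effects in ("time", "twoway"):
        v = u.mean(axis=0) - grand
    return (
        pd.Series(mu, index=list(region_order), name="fe_individual"),
        pd.Series(v, index=list(years), name="fe_time"),
        grand,
    )


def _corr2(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1] ** 2)


def _logdet_term(par: float, omega: np.ndarray, c: int) -> float:
    """ln|I - par*W| from eigenvalues, minus c copies of ln(1 - par)."""
    return float(np.log(1.0 - par * omega).sum() - c * np.log(1.0 - par))


# ---------------------------------------------------------------------------
# estimation


def fit(
    spec: ModelSpec,
    panel: pd.DataFrame,
    w: SpatialWeights | None = None,
    rho_fixed: float | None = None,
    theta_zero: bool = False,
) -> SpatialFitResult:
    """Fit one model family by (concentrated) maximum likelihood.

    ``rho_fixed`` pins the spatial parameter instead of optimizing (used
    for restricted fits and reduction tests); ``theta_zero`` drops the
    W*X block from an SDM, collapsing it to the SLM likelihood.
    """
    spatial = spec.family != "FE"
    if spatial:
        if w is None:
            raise ValueError("spatial families need a weight matrix")
        if not w.standardized:
            raise ValueError("weight matrix must be row-standardized for model fitting")
        if w.islands:
            raise ValueError(f"weight matrix has islands: {w.islands}")
    if w is not None:
        region_order = w.region_order
    else:
        region_order = tuple(sorted(panel["region"].unique()))

    y, x, years = panel_arrays(panel, spec.y_var, spec.x_vars, region_order)
    if spec.log_transform:
        for j, v in enumerate([spec.y_var] + list(spec.x_vars)):
            arr = y if j == 0 else x[:, :, j - 1]
            if (arr <= 0).any():
                raise ValueError(f"log transform requires strictly positive {v!r}")
        y = np.log(y)
        x = np.log(x)
    n, T = y.shape
    k = x.shape[2]

    # without demeaning an explicit intercept is needed; W*const is collinear
    # with it under row standardization, so the constant never enters the
    # spatial-lag (theta) block
    add_const = spec.effects == "none"
    xb = np.concatenate([x, np.ones((n, T, 1))], axis=2) if add_const else x
    kb = xb.shape[2]

    bias_correct = spec.bias_correct if spec.bias_correct is not None else spec.effects == "twoway"
    n_eff, T_eff, c_adj = _effective_dims(spec.effects, n, T, bias_correct)
    N_eff = n_eff * T_eff

    wm = w.matrix if w is not None else None
    wy = wm @ y if spatial else None
    wx = np.einsum("ij,jtk->itk", wm, x) if spatial else None
    wxb = np.einsum("ij,jtk->itk", wm, xb) if spatial else None

    yd = within_transform(y, spec.effects)
    xbd = within_transform(xb, spec.effects)
    wyd = within_transform(wy, spec.effects) if spatial else None
    wxd = within_transform(wx, spec.effects) if spatial else None
    wxbd = within_transform(wxb, spec.effects) if spatial else None

    nT = n * T
    yv = yd.ravel()
    xv = xbd.reshape(nT, kb)

    use_wx = spec.family == "SDM" and not theta_zero
    zv = np.hstack([xv, wxd.reshape(nT, k)]) if use_wx else xv

    beta_names = list(spec.x_vars) + (["const"] if add_const else [])
    theta_names = [f"W.{v}" for v in spec.x_vars]

    if spec.family == "FE":
        delta, *_ = np.linalg.lstsq(zv, yv, rcond=None)
        resid = yv - zv @ delta
        sigma2 = float(resid @ resid / N_eff)
        loglik = -0.5 * N_eff * (np.log(2 * np.pi * sigma2) + 1)
        p = zv.shape[1]
        names = beta_names + ["sigma2"]
        vc = np.zeros((p + 1, p + 1))
        vc[:p, :p] = sigma2 * np.linalg.inv(zv.T @ zv)
        vc[p, p] = 2 * sigma2**2 / N_eff
        beta = pd.Series(delta, index=beta_names, name="beta")
        u = y - np.einsum("itk,k->it", xb, delta)
        mu, v, grand = _recover_fe(u, spec.effects, region_order, years)
        fitted_within = zv @ delta
        fitted = np.einsum("itk,k->it", xb, delta) + mu.to_numpy()[:, None] + v.to_numpy()[None, :] + grand
        return SpatialFitResult(
            family="FE", effects=spec.effects, rho=None, lam=None, beta=beta, theta=None,
            sigma2=sigma2, loglik=float(loglik),
            vcov=pd.DataFrame(vc, index=names, columns=names),
            r2_within=_corr2(fitted_within, yv), r2_naive=_corr2(fitted, y),
            fe_individual=mu, fe_time=v, n=n, T=T, y_var=spec.y_var, x_vars=list(spec.x_vars),
            bias_corrected=bias_correct,
        )

    omega = spectrum(w)
    lo, hi = rho_interval(w)
    lo_b, hi_b = lo + BOUNDARY_INSET, hi - BOUNDARY_INSET

    # cross-section orthonormal transform (drops the constant direction) for
    # the information matrix of corrected fits with time demeaning
    if c_adj:
        h = helmert(n)  # (n-1, n), rows orthonormal and orthogonal to 1
        w_star = h @ wm @ h.T
    else:
        h = np.eye(n)
        w_star = wm

    if spec.family in ("SLM", "SDM"):
        # concentrated likelihood over rho via the two auxiliary regressions
        ztz_inv = np.linalg.pinv(zv.T @ zv)
        b0 = ztz_inv @ (zv.T @ yv)
        b1 = ztz_inv @ (zv.T @ wyd.ravel())
        e0 = yv - zv @ b0
        e1 = wyd.ravel() - zv @ b1
        unidentified = float(e1 @ e1) <= 1e-16 * max(float(wyd.ravel() @ wyd.ravel()), 1e-300)

        def nll(rho: float) -> float:
            e = e0 - rho * e1
            s2 = max(e @ e / N_eff, 1e-300)
            return 0.5 * N_eff * np.log(s2) - T_eff * _logdet_term(rho, omega, c_adj)

        if rho_fixed is not None:
            rho = float(rho_fixed)
        elif unidentified:
            warnings.warn(
                "spatial lag has no residual variation; rho unidentified, set to 0",
                stacklevel=2,
            )
            rho = 0.0
        else:
            res = optimize.minimize_scalar(nll, bounds=(lo_b, hi_b), method="bounded",
                                           options={"xatol": 1e-10})
            if not res.success:
                raise RuntimeError("concentrated-likelihood optimization failed to converge")
            rho = float(res.x)
        boundary = min(rho - lo, hi - rho) < BOUNDARY_FLAG_TOL
        if boundary and rho_fixed is None:
            warnings.warn(f"spatial parameter at interval boundary: rho={rho:.6f}", stacklevel=2)

        delta = b0 - rho * b1
        e = e0 - rho * e1
        sigma2 = float(e @ e / N_eff)
        loglik = (
            -0.5 * N_eff * (np.log(2 * np.pi * max(sigma2, 1e-300)) + 1)
            + T_eff * _logdet_term(rho, omega, c_adj)
        )

        # analytic information matrix over (delta, rho, sigma2) on the
        # transformed problem
        p = zv.shape[1]
        g_star = w_star @ np.linalg.inv(np.eye(w_star.shape[0]) - rho * w_star)
        zt = zv.reshape(n, T, p)
        zt_star = np.einsum("mi,itp->mtp", h, zt)
        gzd = np.einsum("mj,jtp,p->mt", g_star, zt_star, delta)
        info = np.zeros((p + 2, p + 2))
        info[:p, :p] = zv.T @ zv / sigma2
        cross = np.einsum("mtp,mt->p", zt_star, gzd) / sigma2
        info[:p, -2] = cross
        info[-2, :p] = cross
        info[-2, -2] = T_eff * (np.trace(g_star @ g_star) + np.trace(g_star.T @ g_star)) + (
            gzd**2
        ).sum() / sigma2
        info[-2, -1] = info[-1, -2] = T_eff * np.trace(g_star) / sigma2
        info[-1, -1] = N_eff / (2 * sigma2**2)
        vc = np.linalg.pinv(info)
        names = (beta_names + theta_names if use_wx else beta_names) + ["rho", "sigma2"]

        beta = pd.Series(delta[:kb], index=beta_names, name="beta")
        theta = (
            pd.Series(delta[kb:], index=list(spec.x_vars), name="theta") if use_wx else None
        )
        u = y - rho * wy - _linear_raw(xb, wx, delta, kb, use_wx)
        mu, v, grand = _recover_fe(u, spec.effects, region_order, years)
        fitted_within = rho * wyd.ravel() + zv @ delta
        fitted = (
            rho * wy + _linear_raw(xb, wx, delta, kb, use_wx)
            + mu.to_numpy()[:, None] + v.to_numpy()[None, :] + grand
        )
        theta_full = (
            pd.Series(np.zeros(k), index=list(spec.x_vars), name="theta")
            if spec.family == "SDM" and theta_zero
            else theta
        )
        return SpatialFitResult(
            family=spec.family, effects=spec.effects, rho=rho, lam=None, beta=beta,
            theta=theta_full, sigma2=sigma2, loglik=float(loglik),
            vcov=pd.DataFrame(vc, index=names, columns=names),
            r2_within=_corr2(fitted_within, yv), r2_naive=_corr2(fitted, y),
            fe_individual=mu, fe_time=v, n=n, T=T, y_var=spec.y_var, x_vars=list(spec.x_vars),
            rho_interval=(lo, hi), boundary=bool(boundary),
            bias_corrected=bias_correct,
        )

    # SEM: concentrated likelihood over lambda with spatially filtered data
    wxv = wxbd.reshape(nT, kb)
    wyv = wyd.ravel()

    def sem_fit(lam: float):
        yl = yv - lam * wyv
        xl = xv - lam * wxv
        b, *_ = np.linalg.lstsq(xl, yl, rcond=None)
        e = yl - xl @ b
        return b, e

    def nll_sem(lam: float) -> float:
        _, e = sem_fit(lam)
        s2 = max(e @ e / N_eff, 1e-300)
        return 0.5 * N_eff * np.log(s2) - T_eff * _logdet_term(lam, omega, c_adj)

    if rho_fixed is not None:
        lam = float(rho_fixed)
    else:
        res = optimize.minimize_scalar(nll_sem, bounds=(lo_b, hi_b), method="bounded",
                                       options={"xatol": 1e-10})
        if not res.success:
            raise RuntimeError("concentrated-likelihood optimization failed to converge")
        lam = float(res.x)
    boundary = min(lam - lo, hi - lam) < BOUNDARY_FLAG_TOL
    if boundary and rho_fixed is None:
        warnings.warn(f"spatial parameter at interval boundary: lambda={lam:.6f}", stacklevel=2)
    b, e = sem_fit(lam)
    sigma2 = float(e @ e / N_eff)
    loglik = (
        -0.5 * N_eff * (np.log(2 * np.pi * max(sigma2, 1e-300)) + 1)
        + T_eff * _logdet_term(lam, omega, c_adj)
    )

    g_star = w_star @ np.linalg.inv(np.eye(w_star.shape[0]) - lam * w_star)
    xl = xv - lam * wxv
    info = np.zeros((kb + 2, kb + 2))
    info[:kb, :kb] = xl.T @ xl / sigma2
    info[-2, -2] = T_eff * (np.trace(g_star @ g_star) + np.trace(g_star.T @ g_star))
    info[-2, -1] = info[-1, -2] = T_eff * np.trace(g_star) / sigma2
    info[-1, -1] = N_eff / (2 * sigma2**2)
    vc = np.linalg.pinv(info)
    names = beta_names + ["lambda", "sigma2"]
    beta = pd.Series(b, index=beta_names, name="beta")
    u = y - np.einsum("itk,k->it", xb, b)
    mu, v, grand = _recover_fe(u, spec.effects, region_order, years)
    fitted_within = xv @ b
    fitted = np.einsum("itk,k->it", xb, b) + mu.to_numpy()[:, None] + v.to_numpy()[None, :] + grand
    return SpatialFitResult(
        family="SEM", effects=spec.effects, rho=None, lam=lam, beta=beta, theta=None,
        sigma2=sigma2, loglik=float(loglik),
        vcov=pd.DataFrame(vc, index=names, columns=names),
        r2_within=_corr2(fitted_within, yv), r2_naive=_corr2(fitted, y),
        fe_individual=mu, fe_time=v, n=n, T=T, y_var=spec.y_var, x_vars=list(spec.x_vars),
        rho_interval=(lo, hi), boundary=bool(boundary),
        bias_corrected=bias_correct,
    )


def _linear_raw(xb: np.ndarray, wx: np.ndarray | None, delta: np.ndarray, kb: int,
                use_wx: bool) -> np.ndarray:
    """X beta (+ WX theta) on the raw (un-demeaned) scale."""
    out = np.einsum("itk,k->it", xb, delta[:kb])
    if use_wx:
        out = out + np.einsum("itk,k->it", wx, delta[kb:])
    return out


# ---------------------------------------------------------------------------
# specification tests

_NESTS = {
    ("SDM", "SLM"), ("SDM", "SEM"), ("SDM", "FE"),
    ("SLM", "FE"), ("SEM", "FE"),
}


def lr_test(full: SpatialFitResult, restricted: SpatialFitResult, df: int | None = None,
            name: str | None = None) -> TestResult:
    """Likelihood-ratio test of a restricted model against a nesting one.

    ``df`` defaults to the number of dropped parameters where that is
    unambiguous (SDM vs SLM: k spatial-lag coefficients; SLM/SEM vs FE: 1);
    SDM-vs-SEM (the common-factor restriction) and fixed-effects
    comparisons must state df explicitly.  The statistic is clipped at 0.
    """
    same_family = full.family == restricted.family
    if not same_family and (full.family, restricted.family) not in _NESTS:
        raise ValueError(f"{restricted.family} is not nested in {full.family}")
    if df is None:
        if (full.family, restricted.family) == ("SDM", "SLM"):
            df = len(full.x_vars)
        elif (full.family, restricted.family) in (("SLM", "FE"), ("SEM", "FE")):
            df = 1
        else:
            raise ValueError("df must be given for this model pair")
    stat = max(0.0, 2.0 * (full.loglik - restricted.loglik))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    if name is None:
        name = f"LR_{full.family}_vs_{restricted.family}"
    return TestResult(name=name, statistic=float(stat), df=int(df), p=p)


@dataclass
class RandomEffectsFit:
    """Swamy-Arora feasible-GLS random-effects fit of the non-spatial model."""

    beta: pd.Series  # slopes only (intercept kept separately)
    intercept: float
    vcov: pd.DataFrame  # over slopes
    sigma2_e: float
    sigma2_u: float
    theta_gls: float
    n: int
    T: int


def fit_random_effects(panel: pd.DataFrame, y_var: str, x_vars: list[str],
                       log_transform: bool = False) -> RandomEffectsFit:
    """One-way (individual) error-components GLS with Swamy-Arora variances."""
    region_order = tuple(sorted(panel["region"].unique()))
    y, x, _ = panel_arrays(panel, y_var, x_vars, region_order)
    if log_transform:
        if (y <= 0).any() or (x <= 0).any():
            raise ValueError("log transform requires strictly positive data")
        y, x = np.log(y), np.log(x)
    n, T = y.shape
    k = x.shape[2]

    # within step
    yw = (y - y.mean(axis=1, keepdims=True)).ravel()
    xw = (x - x.mean(axis=1, keepdims=True)).reshape(n * T, k)
    bw, *_ = np.linalg.lstsq(xw, yw, rcond=None)
    rss_w = float(((yw - xw @ bw) ** 2).sum())
    sigma2_e = rss_w / (n * T - n - k)

    # between step (group means, with intercept)
    yb = y.mean(axis=1)
    xg = np.column_stack([np.ones(n), x.mean(axis=1)])
    bb, *_ = np.linalg.lstsq(xg, yb, rcond=None)
    rss_b = float(((yb - xg @ bb) ** 2).sum())
    dof_b = n - k - 1
    sigma2_between = rss_b / dof_b if dof_b > 0 else rss_b / max(n - k, 1)
    sigma2_u = max(0.0, sigma2_between - sigma2_e / T)

    theta = 1.0 - np.sqrt(sigma2_e / (sigma2_e + T * sigma2_u))
    yt = (y - theta * y.mean(axis=1, keepdims=True)).ravel()
    xt = np.concatenate(
        [np.full((n, T, 1), 1.0 - theta), x - theta * x.mean(axis=1, keepdims=True)], axis=2
    ).reshape(n * T, k + 1)
    b, *_ = np.linalg.lstsq(xt, yt, rcond=None)
    vcov_full = sigma2_e * np.linalg.inv(xt.T @ xt)
    names = list(x_vars)
    return RandomEffectsFit(
        beta=pd.Series(b[1:], index=names, name="beta"),
        intercept=float(b[0]),
        vcov=pd.DataFrame(vcov_full[1:, 1:], index=names, columns=names),
        sigma2_e=float(sigma2_e), sigma2_u=float(sigma2_u), theta_gls=float(theta),
        n=n, T=T,
    )


def hausman_test(fe_fit: SpatialFitResult, re_fit: RandomEffectsFit) -> TestResult:
    """Hausman test on the slope coefficients shared by FE and RE fits.

    H = (b_FE - b_RE)' [V_FE - V_RE]^{-1} (b_FE - b_RE); a variance
    difference that is not positive definite is inverted by pseudo-inverse
    with a warning.
    """
    common = [v for v in fe_fit.beta.index if v in re_fit.beta.index]
    if not common:
        raise ValueError("no common parameters between FE and RE fits")
    diff = fe_fit.beta[common].to_numpy() - re_fit.beta[common].to_numpy()
    v_fe = fe_fit.vcov.loc[common, common].to_numpy()
    v_re = re_fit.vcov.loc[common, common].to_numpy()
    dv = v_fe - v_re
    eig = np.linalg.eigvalsh((dv + dv.T) / 2)
    if eig.min() < -1e-12 * max(1.0, abs(eig.max())):
        warnings.warn("V_FE - V_RE not positive definite; using pseudo-inverse", stacklevel=2)
    inv = np.linalg.pinv(dv)
    stat = float(max(0.0, diff @ inv @ diff))
    df = len(common)
    return TestResult(name="Hausman", statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)))
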