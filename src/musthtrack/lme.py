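"""Linear mixed-effects models of log daily speed / log daily range.

Model: for individual i on day t,

    y_it = x_it' beta + z_it' b_i + e_it,     b_i ~ N(0, G)

with fixed effects musth x {age, age^2, NDVI, NDVI^2, slope, slope^2,
VRM, VRM^2, distance-to-water, distance-to-water^2, protected}, a
per-individual random intercept and NDVI slope (G is 2x2), and residuals
that are AR1 within individual with correlation phi^Δdays across calendar
gaps and state-specific variances sigma^2 (non-musth) and (delta*sigma)^2
(musth).

The marginal Gaussian likelihood is maximised numerically over the
variance parameters with beta profiled out by GLS and sigma^2 profiled
analytically; ML is used for likelihood-ratio tests between nested fixed
structures and REML for the reported estimates. Backward selection drops
the least significant droppable term (respecting marginality) until all
remaining terms have LRT p < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

MAIN_TERMS = ["age", "age2", "ndvi", "ndvi2", "slope", "slope2",
              "vrm", "vrm2", "dist_water", "dist_water2", "protected"]
_QUAD = {"age2": "age", "ndvi2": "ndvi", "slope2": "slope",
         "vrm2": "vrm", "dist_water2": "dist_water"}

RESPONSES = {"speed": "mean_speed_kmh", "mcp": "mcp95_km2"}


@dataclass
class LmeDesign:
    """Stacked design matrices sorted by (individual, date)."""

    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    Z: np.ndarray                 # random-effect design (intercept [, ndvi])
    groups: np.ndarray            # integer group index per row
    group_ids: list[str]
    day: np.ndarray               # integer day number per row (AR1 lags)
    musth: np.ndarray             # 0/1 per row
    response: str = "speed"

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    def subset_columns(self, cols: list[str]) -> "LmeDesign":
        idx = [self.colnames.index(c) for c in cols]
        return LmeDesign(y=self.y, X=self.X[:, idx], colnames=list(cols),
                         Z=self.Z, groups=self.groups, group_ids=self.group_ids,
                         day=self.day, musth=self.musth, response=self.response)

    def subset_groups(self, which: list[int]) -> "LmeDesign":
        """Stack the chosen groups (repeats become distinct individuals)."""
        rows, groups, ids = [], [], []
        for k, g in enumerate(which):
            sel = np.flatnonzero(self.groups == g)
            rows.append(sel)
            groups.append(np.full(len(sel), k))
            ids.append(f"{self.group_ids[g]}#{k}")
        rows = np.concatenate(rows)
        return LmeDesign(y=self.y[rows], X=self.X[rows], colnames=self.colnames,
                         Z=self.Z[rows], groups=np.concatenate(groups),
                         group_ids=ids, day=self.day[rows],
                         musth=self.musth[rows], response=self.response)


@dataclass
class LmeFit:
    beta: pd.Series
    se: pd.Series
    G: np.ndarray                  # random-effects covariance (response units)
    phi: float                     # AR1 parameter
    delta: float                   # musth residual-SD ratio
    sigma: float                   # non-musth residual SD
    loglik: float
    method: str                    # "ML" or "REML"
    converged: bool
    design: LmeDesign = field(repr=False, default=None)
    theta: np.ndarray = field(repr=False, default=None)

    @property
    def state_variance_ratio(self) -> float:
        return self.delta ** 2


def build_design(daily: pd.DataFrame, response: str = "speed",
                 random_slope: bool = True) -> LmeDesign:
    """Assemble response and design matrices from a labelled daily table.

    Expects standardized covariates, age centred on 35, a 0/1 ``musth``
    column (excluded-label days removed upstream), and the response
    strictly positive (it is log-transformed here). Rows with any missing
    covariate are dropped. Rows are sorted by (individual, date) so that
    AR1 lags are well defined; non-consecutive days decay as phi^Δdays.
    """
    ycol = RESPONSES.get(response, response)
    need = ["individual_id", "date", ycol, "musth", "age"] + \
        ["ndvi", "slope", "vrm", "dist_water", "protected"]
    df = daily[need].dropna().copy()
    df = df.sort_values(["individual_id", "date"], kind="mergesort")
    y = np.log(df[ycol].to_numpy(float))
    musth = df["musth"].to_numpy(float)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df)), "musth": musth}
    for t in MAIN_TERMS:
        base = _QUAD.get(t)
        v = df[base].to_numpy(float) ** 2 if base else df[t].to_numpy(float)
        cols[t] = v
    for t in MAIN_TERMS:
        cols[f"musth:{t}"] = musth * cols[t]
    X = np.column_stack(list(cols.values()))
    Zcols = [np.ones(len(df))]
    if random_slope:
        Zcols.append(df["ndvi"].to_numpy(float))
    Z = np.column_stack(Zcols)
    ids = df["individual_id"].astype(str).to_numpy()
    group_ids = list(dict.fromkeys(ids))
    gidx = np.array([group_ids.index(i) for i in ids])
    day = pd.to_datetime(df["date"]).map(pd.Timestamp.toordinal).to_numpy(int)
    return LmeDesign(y=y, X=X, colnames=list(cols), Z=Z, groups=gidx,
                     group_ids=group_ids, day=day, musth=musth,
                     response=response)


# ---------------------------------------------------------------------------
# likelihood machinery

def _unpack(theta: np.ndarray, q: int, ar1: bool, het: bool):
    k = 0
    if q == 2:
        L = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
        k = 3
    else:
        L = np.array([[np.exp(theta[0])]])
        k = 1
    A = L @ L.T                      # G / sigma^2
    phi = np.tanh(theta[k]) if ar1 else 0.0
    k += ar1
    delta = np.exp(theta[k]) if het else 1.0
    return A, phi, delta


def _profile(design: LmeDesign, A, phi, delta, reml: bool):
    """Profiled beta/sigma^2 and the pieces of the (restricted) loglik."""
    p = design.X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    for g in range(design.n_groups):
        sel = design.groups == g
        Xg, yg, Zg = design.X[sel], design.y[sel], design.Z[sel]
        dday = np.abs(np.subtract.outer(design.day[sel], design.day[sel]))
        w = np.where(design.musth[sel] > 0, delta, 1.0)
        C = np.outer(w, w) * np.power(float(phi), dday.astype(int))
        V = Zg @ A @ Zg.T + C
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
        logdet += 2.0 * np.sum(np.log(np.diag(cf[0])))
        Xs = linalg.cho_solve(cf, Xg, check_finite=False)
        ys = linalg.cho_solve(cf, yg, check_finite=False)
        XtVX += Xg.T @ Xs
        XtVy += Xg.T @ ys
        ytVy += yg @ ys
    beta = np.linalg.solve(XtVX, XtVy)
    rss = float(ytVy - beta @ XtVy)
    n = len(design.y)
    dof = n - p if reml else n
    sigma2 = max(rss / dof, 1e-300)
    ll = -0.5 * (dof * np.log(2.0 * np.pi * sigma2) + logdet + dof)
    if reml:
        sign, ld = np.linalg.slogdet(XtVX)
        ll -= 0.5 * ld
    return beta, sigma2, ll, XtVX


def _theta0(q: int, ar1: bool, het: bool) -> np.ndarray:
    parts = [np.log(0.5)] if q == 1 else [np.log(0.5), 0.0, np.log(0.2)]
    if ar1:
        parts.append(np.arctanh(0.2))
    if het:
        parts.append(0.0)
    return np.array(parts)


def fit_lme(design: LmeDesign, method: str = "ML", ar1: bool = True,
            het: bool = True, theta0: np.ndarray | None = None) -> LmeFit:
    """Maximise the (restricted) marginal likelihood.

    ``ar1=False`` fixes phi = 0 and ``het=False`` fixes delta = 1, which
    is how the within-group correlation and variance-weighting LRT
    diagnostics are produced.
    """
    if design.n_groups < 2:
        raise ValueError("need at least 2 individuals")
    reml = method.upper() == "REML"
    q = design.Z.shape[1]

    def nll(theta):
        A, phi, delta = _unpack(theta, q, ar1, het)
        try:
            _, _, ll, _ = _profile(design, A, phi, delta, reml)
        except linalg.LinAlgError:
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    t0 = theta0 if theta0 is not None else _theta0(q, ar1, het)
    res = optimize.minimize(nll, t0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8,
                                     "maxiter": 4000, "maxfev": 4000})
    res2 = optimize.minimize(nll, res.x, method="L-BFGS-B")
    if res2.fun <= res.fun:
        res = res2
    A, phi, delta = _unpack(res.x, q, ar1, het)
    beta, sigma2, ll, XtVX = _profile(design, A, phi, delta, reml)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtVX)))
    return LmeFit(beta=pd.Series(beta, index=design.colnames),
                  se=pd.Series(se, index=design.colnames),
                  G=sigma2 * A, phi=float(phi), delta=float(delta),
                  sigma=float(np.sqrt(sigma2)), loglik=float(ll),
                  method="REML" if reml else "ML",
                  converged=bool(res.success or res.fun < 1e11),
                  design=design, theta=res.x)


def lrt(full: LmeFit, reduced: LmeFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits: (chi2, df, p)."""
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("LRTs on fixed terms require ML fits")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = len(full.beta) - len(reduced.beta)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _droppable(cols: list[str]) -> list[str]:
    """Terms whose removal respects marginality."""
    out = []
    for c in cols:
        if c == "intercept":
            continue
        needed = False
        for other in cols:
            if other == c:
                continue
            if other.startswith("musth:") and c in ("musth", other.split(":", 1)[1]):
                needed = True
            if _QUAD.get(other) == c:  # quadratic keeps its linear term
                needed = True
        if not needed:
            out.append(c)
    return out


@dataclass
class SelectionResult:
    fit: LmeFit                 # final REML fit
    ml_fit: LmeFit              # final ML fit
    table: pd.DataFrame         # per-step LRT trace


def select_model(design: LmeDesign, alpha: float = 0.05,
                 ar1: bool = True, het: bool = True) -> SelectionResult:
    """Backward selection by single-term-deletion LRTs (ML), one term per
    step (largest p first); the final model is refit by REML."""
    cols = list(design.colnames)
    current = fit_lme(design.subset_columns(cols), "ML", ar1, het)
    trace = []
    step = 0
    while True:
        step += 1
        best = None
        for c in _droppable(cols):
            cand_cols = [k for k in cols if k != c]
            cand = fit_lme(design.subset_columns(cand_cols), "ML", ar1, het,
                           theta0=current.theta)
            chi2, df, p = lrt(current, cand)
            trace.append({"step": step, "term": c, "chi2": chi2,
                          "df": df, "p": p, "dropped": False})
            if best is None or p > best[2]:
                best = (c, cand, p, chi2, df)
        if best is None or best[2] < alpha:
            break
        cols = [k for k in cols if k != best[0]]
        current = best[1]
        for t in trace:
            if t["step"] == step and t["term"] == best[0]:
                t["dropped"] = True
    final = fit_lme(design.subset_columns(cols), "REML", ar1, het,
                    theta0=current.theta)
    return SelectionResult(fit=final, ml_fit=current,
                           table=pd.DataFrame(trace))


# ---------------------------------------------------------------------------
# effect ratios

@dataclass
class EffectRatio:
    age: float
    ratio: float
    lo: float
    hi: float


def _musth_contrast(beta: pd.Series, age: float) -> float:
    """Log musth/non-musth contrast at centred age and mean covariates.

    Standardized covariates sit at 0 and protected at 0, so only the
    musth main effect and the musth x age terms survive.
    """
    a = age - 35.0
    lc = 0.0
    if "musth" in beta.index:
        lc += beta["musth"]
    if "musth:age" in beta.index:
        lc += beta["musth:age"] * a
    if "musth:age2" in beta.index:
        lc += beta["musth:age2"] * a * a
    return float(lc)


def effect_ratio(fit: LmeFit, age: float, n_boot: int = 1000,
                 seed: int = 0, level: float = 0.95,
                 refit: str = "gls") -> EffectRatio:
    """Musth/non-musth response ratio at a given age with bootstrap CI.

    The CI resamples individuals with replacement. ``refit="gls"``
    re-estimates beta by GLS with the variance parameters held at the
    full-data estimates (fast); ``refit="full"`` re-maximises the
    likelihood per resample.
    """
    point = float(np.exp(_musth_contrast(fit.beta, age)))
    design = fit.design
    if n_boot <= 0 or design is None:
        return EffectRatio(age=age, ratio=point, lo=np.nan, hi=np.nan)
    rng = np.random.default_rng(seed)
    q = design.Z.shape[1]
    A = fit.G / fit.sigma ** 2
    reml = fit.method == "REML"
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, design.n_groups, size=design.n_groups)
        d = design.subset_groups(list(pick))
        if refit == "full":
            bf = fit_lme(d, fit.method, theta0=fit.theta)
            beta = bf.beta
        else:
            beta_v, _, _, _ = _profile(d, A, fit.phi, fit.delta, reml)
            beta = pd.Series(beta_v, index=d.colnames)
        ratios[b] = np.exp(_musth_contrast(beta, age))
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(ratios, [a, 1.0 - a])
    return EffectRatio(age=age, ratio=point, lo=float(lo), hi=float(hi))


def ratio_curve(fit: LmeFit, ages: np.ndarray, n_boot: int = 1000,
                seed: int = 0) -> pd.DataFrame:
    rows = [effect_ratio(fit, float(a), n_boot=n_boot, seed=seed)
            for a in ages]
    return pd.DataFrame({"age": [r.age for r in rows],
                         "ratio": [r.ratio for r in rows],
                         "lo": [r.lo for r in rows],
                         "hi": [r.hi for r in rows]})
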