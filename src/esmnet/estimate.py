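"""Multilevel lagged regression and group-level temporal affect networks.

For each of the six affect items, the outcome at beep t is regressed on
all six person-mean-centered items at beep t-1 plus a linear time
covariate:

    y_t = b0 + sum_k b_k x^(k)_{t-1} + b_time * t + (random effects) + e_t

with a random intercept at the family (twin-pair) level, a random
intercept plus random slopes for time and all six lagged predictors at the
person level (diagonal random-effects covariance), and residuals following
a continuous AR(1) correlation over each person's analysis rows
(phi^dt, dt in hours).  Estimation is by maximum likelihood so that AIC
comparisons across rungs with identical fixed effects are coherent.

The marginal likelihood is computed exactly per family block: the AR(1)
correlation matrix of a Gaussian Markov process has a closed-form
tridiagonal inverse, and the low-rank random-effects part is folded in by
the Woodbury identity, so each evaluation costs O(rows) per family.  The
residual scale and the fixed effects are profiled out.

When a rung fails to converge, a ladder of simplifications is walked:
drop the AR(1) correlation, drop the random slopes, drop the family
intercept, and finally a pooled regression with cluster-robust errors.
When the full model converges its AIC is also compared against the next
rung and the better-fitting model is reported.

The fixed-effect b-coefficients form the directed network: W[j, k] is the
effect of node k at t-1 on node j at t.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

from .simulate import NODES, N_NODES
from .preprocess import LAG_COLS

FIXED_NAMES = ["intercept", *LAG_COLS, "time"]
RE_NAMES = ["family_intercept", "person_intercept",
            *[f"slope_{c}" for c in LAG_COLS], "slope_time"]

RUNG_NAMES = ("full", "no_ar1", "no_slopes", "no_family", "pooled")


class EstimationError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Specification of one outcome's multilevel lagged model."""

    outcome: str
    ar1: bool = True
    random_slopes: bool = True
    family_intercept: bool = True
    person_intercept: bool = True
    #: scheduled beeps, used to rescale the beep-number time covariate to
    #: [0, 1] for conditioning; coefficients are reported per beep
    scheduled_beeps: int = 60
    phi_max: float = 0.95
    max_iter: int = 200
    ftol: float = 1e-10
    #: when the full model converges, also fit the next rung and report
    #: the better AIC
    aic_select: bool = True

    def __post_init__(self):
        if self.outcome not in NODES:
            raise ValueError(f"unknown outcome {self.outcome!r}")


@dataclass
class FitResult:
    """Fixed effects, variance components and fit statistics of one model."""

    outcome: str
    coef: pd.Series
    se: pd.Series
    pvalues: pd.Series
    varcomps: dict
    sigma: float
    phi: float
    loglik: float
    aic: float
    n_params: int
    rung: str
    converged: bool
    n_rows: int
    n_persons: int
    resid_diagnostics: dict


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------

def _design_arrays(design: pd.DataFrame, spec: ModelSpec):
    """Fixed-effect matrix, outcome vector and grouping structures."""
    y = design[f"y_{spec.outcome}"].to_numpy(dtype=float)
    time_scaled = design["time"].to_numpy(dtype=float) / spec.scheduled_beeps
    X = np.column_stack([
        np.ones(len(design)),
        design[LAG_COLS].to_numpy(dtype=float),
        time_scaled,
    ])
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("lag design contains missing cells")
    _check_singular(X)
    return X, y, time_scaled


def _check_singular(X):
    sd = X[:, 1:].std(axis=0)
    for name, s in zip(FIXED_NAMES[1:], sd):
        if s < 1e-10:
            raise EstimationError(f"constant predictor column: {name}")
    corr = np.corrcoef(X[:, 1:], rowvar=False)
    off = np.abs(corr - np.eye(corr.shape[0]))
    j, k = np.unravel_index(np.argmax(off), off.shape)
    if off[j, k] > 1.0 - 1e-10:
        raise EstimationError(
            f"singular design: columns {FIXED_NAMES[1 + j]!r} and "
            f"{FIXED_NAMES[1 + k]!r} are collinear"
        )


class _FamilyBlock:
    """Per-family pieces of the marginal likelihood."""

    __slots__ = ("X", "y", "Z", "re_kind", "gaps_hr", "n")

    def __init__(self, X, y, Z, re_kind, gaps_hr):
        self.X, self.y, self.Z = X, y, Z
        self.re_kind = re_kind      # index into RE sd vector per Z column
        self.gaps_hr = gaps_hr      # NaN at each person's first row
        self.n = len(y)


def _build_blocks(design, X, y, time_scaled, spec: ModelSpec):
    """Group rows by family; build random-effect design Z per family.

    Z columns: family intercept (if enabled), then per person an intercept
    and, if enabled, slopes for the six lagged predictors and time.
    """
    df = design.reset_index(drop=True)
    order = np.lexsort((df["beep_number"].to_numpy(),
                        df["person_id"].to_numpy(),
                        df["family_id"].to_numpy()))
    X, y, time_scaled = X[order], y[order], time_scaled[order]
    fam = df["family_id"].to_numpy()[order]
    person = df["person_id"].to_numpy()[order]
    tmin = df["time_min"].to_numpy(dtype=float)[order]
    lags = df[LAG_COLS].to_numpy(dtype=float)[order]

    blocks = []
    for f in pd.unique(fam):
        sel = fam == f
        Xf, yf = X[sel], y[sel]
        pf, tf = person[sel], tmin[sel]
        lf, tsf = lags[sel], time_scaled[sel]
        cols, kinds = [], []
        if spec.family_intercept:
            cols.append(np.ones(sel.sum()))
            kinds.append(0)
        gaps = np.full(sel.sum(), np.nan)
        for p in pd.unique(pf):
            mask = (pf == p).astype(float)
            if spec.person_intercept:
                cols.append(mask)
                kinds.append(1)
            if spec.random_slopes:
                for i in range(N_NODES):
                    cols.append(mask * lf[:, i])
                    kinds.append(2 + i)
                cols.append(mask * tsf)
                kinds.append(2 + N_NODES)
            rows = np.flatnonzero(pf == p)
            gaps[rows[1:]] = np.diff(tf[rows]) / 60.0   # hours
        Z = np.column_stack(cols) if cols else np.zeros((sel.sum(), 0))
        blocks.append(_FamilyBlock(Xf, yf, Z, np.array(kinds, dtype=int), gaps))
    return blocks


# ---------------------------------------------------------------------------
# Profiled marginal likelihood
# ---------------------------------------------------------------------------

def _tridiag_inverse_pieces(gaps_hr, phi):
    """Closed-form inverse and log-determinant of the continuous-AR(1)
    correlation matrix of one chain.

    ``r_i = phi^dt_i`` links row i to row i-1; NaN gaps (first row of a
    person) break the chain (r = 0).  Returns (main diagonal, upper/lower
    diagonal, logdet R).
    """
    n = len(gaps_hr)
    r = np.zeros(n)
    if phi > 0.0:
        r[1:] = np.where(np.isnan(gaps_hr[1:]), 0.0,
                         phi ** np.nan_to_num(gaps_hr[1:], nan=0.0))
    r = np.clip(r, 0.0, 0.999999)
    denom = 1.0 - r ** 2
    ratio = r[1:] ** 2 / denom[1:]
    # (R^-1)_{ii} = 1 + r_i^2/(1-r_i^2) + r_{i+1}^2/(1-r_{i+1}^2)
    diag = np.ones(n)
    diag[1:] += ratio
    diag[:-1] += ratio
    off = -r[1:] / denom[1:]
    logdet = float(np.sum(np.log(denom[1:])))
    return diag, off, logdet


class _ProfiledML:
    """Profiled ML objective over (log RE sd ratios, transformed phi).

    Family blocks are padded to a common size and the whole likelihood is
    evaluated with batched array operations.
    """

    def __init__(self, blocks, spec: ModelSpec):
        self.blocks = blocks
        self.spec = spec
        self.re_kinds = sorted({k for b in blocks for k in b.re_kind})
        self.n_re = len(self.re_kinds)
        self.n = sum(b.n for b in blocks)
        self.p = blocks[0].X.shape[1]
        self._stack(blocks)

    def _stack(self, blocks):
        F = len(blocks)
        nmax = max(b.n for b in blocks)
        mmax = max(b.Z.shape[1] for b in blocks)
        p = self.p
        self.Xb = np.zeros((F, nmax, p))
        self.yb = np.zeros((F, nmax))
        self.Zb = np.zeros((F, nmax, mmax))
        self.kindb = np.full((F, mmax), -1, dtype=int)
        self.gapb = np.full((F, nmax), np.nan)
        self.maskb = np.zeros((F, nmax))
        for i, b in enumerate(blocks):
            self.Xb[i, :b.n] = b.X
            self.yb[i, :b.n] = b.y
            self.Zb[i, :b.n, :b.Z.shape[1]] = b.Z
            self.kindb[i, :len(b.re_kind)] = b.re_kind
            self.gapb[i, :b.n] = b.gaps_hr
            self.maskb[i, :b.n] = 1.0
        self.mmax = mmax
        self.eye_m = np.eye(mmax)
        self.ZbT = np.ascontiguousarray(self.Zb.transpose(0, 2, 1))
        self.Xflat = self.Xb.reshape(-1, p)
        self.yflat = self.yb.reshape(-1)
        self.gap_valid = ~np.isnan(self.gapb)
        self.gap0 = np.nan_to_num(self.gapb, nan=0.0)
        # products reused verbatim on every phi = 0 evaluation
        self._c0 = {
            "XtX": self.Xflat.T @ self.Xflat,
            "Xty": self.Xflat.T @ self.yflat,
            "yty": float(self.yflat @ self.yflat),
            "ZtZ": self.ZbT @ self.Zb,
            "ZtX": self.ZbT @ self.Xb,
            "Zty": (self.ZbT @ self.yb[..., None])[..., 0],
        }

    # -- parameter packing ---------------------------------------------
    def n_params(self):
        return self.n_re + (1 if self.spec.ar1 else 0)

    def unpack(self, u):
        g = np.exp(u[:self.n_re])            # sd ratios per RE kind
        phi = 0.0
        if self.spec.ar1:
            phi = self.spec.phi_max / (1.0 + np.exp(-u[self.n_re]))
        return g, phi

    def initial(self):
        u = np.empty(self.n_params())
        for i, k in enumerate(self.re_kinds):
            u[i] = np.log(0.7) if k <= 1 else np.log(0.1)
        if self.spec.ar1:
            u[self.n_re] = -1.4   # phi ~ 0.2 * phi_max
        return u

    # -- likelihood ------------------------------------------------------
    def _assemble(self, u):
        g, phi = self.unpack(u)
        # per-block column scales; padded columns get 0 (inert under I + ...)
        gmap = np.zeros(max(self.re_kinds, default=0) + 2)
        for k, gi in zip(self.re_kinds, g):
            gmap[k] = gi
        gz = np.where(self.kindb >= 0, gmap[self.kindb], 0.0)   # F x m

        if self.spec.ar1 and phi > 0.0:
            valid = self.gap_valid
            r = np.where(valid, phi ** self.gap0, 0.0)
            r = np.clip(r, 0.0, 0.999999)
            denom = 1.0 - r ** 2
            ratio = np.where(valid, r ** 2 / denom, 0.0)
            diag = self.maskb.copy()
            diag[:, 1:] += ratio[:, 1:]
            diag[:, :-1] += ratio[:, 1:]
            off = -r[:, 1:] / denom[:, 1:]
            logdet = float(np.sum(np.log(denom[:, 1:][valid[:, 1:]])))

            def rinv(M):
                out = diag[..., None] * M
                out[:, :-1] += off[..., None] * M[:, 1:]
                out[:, 1:] += off[..., None] * M[:, :-1]
                return out

            RiX = rinv(self.Xb)
            Riy = rinv(self.yb[..., None])[..., 0]
            RiXf = RiX.reshape(-1, self.p)
            Riyf = Riy.reshape(-1)
            XtRiX = self.Xflat.T @ RiXf
            XtRiy = self.Xflat.T @ Riyf
            ytRiy = float(self.yflat @ Riyf)
            ZtRiZ = self.ZbT @ rinv(self.Zb)
            ZtRiX = self.ZbT @ RiX
            ZtRiy = (self.ZbT @ Riy[..., None])[..., 0]
        else:
            c = self._c0
            logdet = 0.0
            XtRiX, XtRiy, ytRiy = c["XtX"], c["Xty"], c["yty"]
            ZtRiZ, ZtRiX, ZtRiy = c["ZtZ"], c["ZtX"], c["Zty"]

        if self.mmax:
            M = ZtRiZ * gz[:, None, :] * gz[:, :, None] + self.eye_m
            try:
                L = np.linalg.cholesky(M)
            except np.linalg.LinAlgError:
                return None
            logdet += 2.0 * float(np.sum(np.log(
                np.diagonal(L, axis1=1, axis2=2))))
            W1 = ZtRiX * gz[:, :, None]            # F x m x p
            w2 = ZtRiy * gz                        # F x m
            rhs = np.concatenate([W1, w2[:, :, None]], axis=2)
            sol = np.linalg.solve(M, rhs)
            sol1 = sol[:, :, :-1].reshape(-1, self.p)
            sol2 = sol[:, :, -1]
            W1f = W1.reshape(-1, self.p)
            XtVX = XtRiX - W1f.T @ sol1
            XtVy = XtRiy - sol2.reshape(-1) @ W1f
            ytVy = ytRiy - float(w2.reshape(-1) @ sol2.reshape(-1))
        else:
            XtVX, XtVy, ytVy = XtRiX, XtRiy, ytRiy
        return XtVX, XtVy, ytVy, logdet

    def nll(self, u):
        parts = self._assemble(u)
        if parts is None:
            return 1e12
        XtVX, XtVy, ytVy, logdet = parts
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return 1e12
        qform = ytVy - beta @ XtVy
        if not np.isfinite(qform) or qform <= 0:
            return 1e12
        sigma2 = qform / self.n
        nll = 0.5 * (self.n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet)
        return float(nll)

    def finalize(self, u):
        parts = self._assemble(u)
        if parts is None:
            raise np.linalg.LinAlgError("likelihood assembly failed at the optimum")
        XtVX, XtVy, ytVy, logdet = parts
        beta = np.linalg.solve(XtVX, XtVy)
        sigma2 = (ytVy - beta @ XtVy) / self.n
        cov = sigma2 * np.linalg.inv(XtVX)
        se = np.sqrt(np.diag(cov))
        g, phi = self.unpack(u)
        sigma = float(np.sqrt(sigma2))
        varcomps = {RE_NAMES_BY_KIND[k]: float((gi * sigma) ** 2)
                    for k, gi in zip(self.re_kinds, g)}
        loglik = -self.nll(u)
        return beta, se, sigma, phi, varcomps, loglik


RE_NAMES_BY_KIND = {0: "family_intercept", 1: "person_intercept",
                    **{2 + i: f"slope_{LAG_COLS[i]}" for i in range(N_NODES)},
                    2 + N_NODES: "slope_time"}


# ---------------------------------------------------------------------------
# Fitting with the convergence ladder
# ---------------------------------------------------------------------------

def _ladder(spec: ModelSpec):
    """Ordered fallback simplifications ending in a guaranteed fit."""
    rungs = []
    s = spec
    rungs.append(("full", s))
    if s.ar1:
        s = replace(s, ar1=False)
        rungs.append(("no_ar1", s))
    if s.random_slopes:
        s = replace(s, random_slopes=False)
        rungs.append(("no_slopes", s))
    if s.family_intercept:
        s = replace(s, family_intercept=False)
        rungs.append(("no_family", s))
    rungs.append(("pooled", replace(s, person_intercept=False)))
    # keep canonical rung names even if the ladder starts lower
    if not (spec.ar1 and spec.random_slopes and spec.family_intercept):
        rungs[0] = (_rung_name(spec), spec)
    return rungs


def _rung_name(spec):
    if spec.ar1:
        return "full"
    if spec.random_slopes:
        return "no_ar1"
    if spec.family_intercept:
        return "no_slopes"
    if spec.person_intercept:
        return "no_family"
    return "pooled"


def _resid_diagnostics(resid):
    resid = np.asarray(resid, dtype=float)
    std = (resid - resid.mean()) / resid.std()
    qq = np.sort(std)
    theo = stats.norm.ppf((np.arange(len(qq)) + 0.5) / len(qq))
    return {
        "qq_correlation": float(np.corrcoef(qq, theo)[0, 1]),
        "skewness": float(stats.skew(std)),
        "excess_kurtosis": float(stats.kurtosis(std)),
    }


def _fit_pooled(design, spec):
    """Final rung: pooled regression with person-cluster-robust errors."""
    X, y, _ = _design_arrays(design, spec)
    model = sm.OLS(y, X)
    res = model.fit(cov_type="cluster",
                    cov_kwds={"groups": design["person_id"].to_numpy()})
    coef = pd.Series(res.params, index=FIXED_NAMES)
    se = pd.Series(res.bse, index=FIXED_NAMES)
    z = coef / se
    p = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=FIXED_NAMES)
    k = len(coef) + 1
    return FitResult(
        outcome=spec.outcome,
        coef=_rescale_time(coef, spec), se=_rescale_time(se, spec), pvalues=p,
        varcomps={},
        sigma=float(np.sqrt(res.scale)),
        phi=0.0,
        loglik=float(res.llf),
        aic=float(2 * k - 2 * res.llf),
        n_params=k,
        rung="pooled",
        converged=True,
        n_rows=len(design),
        n_persons=design["person_id"].nunique(),
        resid_diagnostics=_resid_diagnostics(res.resid),
    )


def _rescale_time(s: pd.Series, spec) -> pd.Series:
    # the time covariate enters scaled to [0, 1]; report it per beep
    out = s.copy()
    out["time"] = out["time"] / spec.scheduled_beeps
    return out


def _fit_ml_rung(design, spec: ModelSpec, rung_name, warm_u=None):
    X, y, time_scaled = _design_arrays(design, spec)
    blocks = _build_blocks(design, X, y, time_scaled, spec)
    prob = _ProfiledML(blocks, spec)
    if prob.n <= prob.p + prob.n_params():
        raise EstimationError("fewer rows than parameters")
    if prob.n_params() == 0:
        u_opt = np.empty(0)
        success = True
    else:
        u0 = prob.initial() if warm_u is None else warm_u
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                prob.nll, u0, method="L-BFGS-B",
                bounds=[(-8.0, 3.0)] * prob.n_re
                       + ([(-12.0, 8.0)] if spec.ar1 else []),
                options={"maxiter": spec.max_iter, "ftol": spec.ftol},
            )
        u_opt, success = res.x, bool(res.success)
    beta, se, sigma, phi, varcomps, loglik = prob.finalize(u_opt)
    converged = success and np.all(np.isfinite(se)) and np.all(se > 0)
    coef = pd.Series(beta, index=FIXED_NAMES)
    se = pd.Series(se, index=FIXED_NAMES)
    z = coef / se
    p = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=FIXED_NAMES)
    k = prob.p + prob.n_params() + 1   # + residual sigma
    # marginal residuals for the normality diagnostic
    resid = y - X @ beta
    return FitResult(
        outcome=spec.outcome,
        coef=_rescale_time(coef, spec), se=_rescale_time(se, spec), pvalues=p,
        varcomps=varcomps,
        sigma=sigma, phi=phi,
        loglik=loglik,
        aic=float(2 * k - 2 * loglik),
        n_params=k,
        rung=rung_name,
        converged=converged,
        n_rows=len(design),
        n_persons=design["person_id"].nunique(),
        resid_diagnostics=_resid_diagnostics(resid),
    ), u_opt


def fit_lagged_model(design: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one outcome's multilevel lagged model, walking the convergence
    ladder on failure.

    ``design`` is a lag design restricted to one group (see
    :func:`esmnet.preprocess.build_lag_pairs`).
    """
    if design["person_id"].nunique() < 2:
        raise EstimationError("need at least two persons")
    if design["family_id"].nunique() < 2:
        raise EstimationError("need at least two families")
    rungs = _ladder(spec)
    last_error = None
    for i, (name, rung_spec) in enumerate(rungs[:-1]):
        try:
            fit, u_opt = _fit_ml_rung(design, rung_spec, name)
        except np.linalg.LinAlgError as exc:   # numerical failure: descend
            last_error = exc
            continue
        except (EstimationError, ValueError):  # invalid input: do not descend
            raise
        except Exception as exc:               # other numerical failure
            last_error = exc
            continue
        if not fit.converged:
            continue
        if spec.aic_select and i + 1 < len(rungs) - 1:
            next_name, next_spec = rungs[i + 1]
            try:
                warm = _warm_start(u_opt, rung_spec, next_spec)
                alt, _ = _fit_ml_rung(design, next_spec, next_name, warm_u=warm)
                if alt.converged and alt.aic < fit.aic:
                    fit = alt
            except Exception:
                pass
        return fit
    if last_error is not None:
        warnings.warn(f"ladder descended to pooled fit: {last_error}")
    return _fit_pooled(design, rungs[-1][1])


def _warm_start(u_opt, old_spec, new_spec):
    """Map a fitted parameter vector onto the next rung's packing."""
    old_kinds = _active_kinds(old_spec)
    new_kinds = _active_kinds(new_spec)
    u = []
    for k in new_kinds:
        u.append(u_opt[old_kinds.index(k)] if k in old_kinds else np.log(0.1))
    if new_spec.ar1:
        u.append(u_opt[len(old_kinds)] if old_spec.ar1 else -1.4)
    return np.asarray(u)


def _active_kinds(spec):
    kinds = []
    if spec.family_intercept:
        kinds.append(0)
    if spec.person_intercept:
        kinds.append(1)
    if spec.random_slopes:
        kinds.extend(range(2, 2 + N_NODES + 1))
    return kinds


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

@dataclass
class AffectNetwork:
    """Directed 6x6 temporal network of lagged fixed effects.

    ``weights[j, k]`` is the effect of node k at t-1 on node j at t
    (the diagonal holds autoregressions).
    """

    nodes: tuple
    weights: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    group_label: str = ""
    n_persons: int = 0
    n_rows: int = 0
    tier: str = "full"
    alpha: float | None = None
    unfiltered: np.ndarray | None = None
    side_table: pd.DataFrame | None = None
    fits: list = field(default_factory=list)

    def edge_list(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = []
        for j in range(len(self.nodes)):
            for k in range(len(self.nodes)):
                rows.append({
                    "from": self.nodes[k], "to": self.nodes[j],
                    "b": self.weights[j, k], "se": self.se[j, k],
                    "p": self.pvalues[j, k],
                    "significant": bool(self.pvalues[j, k] < alpha),
                })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps({
            "nodes": list(self.nodes),
            "group": self.group_label,
            "tier": self.tier,
            "n_persons": int(self.n_persons),
            "n_rows": int(self.n_rows),
            "alpha": self.alpha,
            "weights": np.asarray(self.weights).tolist(),
            "se": np.asarray(self.se).tolist(),
            "pvalues": np.asarray(self.pvalues).tolist(),
        }, indent=2)

    def to_dot(self, alpha: float = 0.05) -> str:
        """DOT export: solid edges for positive weights, dashed for
        negative; only edges significant at ``alpha``."""
        lines = [f'digraph "{self.group_label or "network"}" {{']
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for j in range(len(self.nodes)):
            for k in range(len(self.nodes)):
                w, p = self.weights[j, k], self.pvalues[j, k]
                if w == 0 or p >= alpha:
                    continue
                style = "solid" if w > 0 else "dashed"
                color = "darkgreen" if w > 0 else "red"
                lines.append(
                    f'  "{self.nodes[k]}" -> "{self.nodes[j]}" '
                    f'[style={style}, color={color}, label="{w:.3f}"];'
                )
        lines.append("}")
        return "\n".join(lines)


def estimate_group_network(
    design: pd.DataFrame,
    group_label: str = "",
    persons=None,
    spec: ModelSpec | None = None,
    tier: str = "full",
) -> AffectNetwork:
    """Estimate one group's directed temporal network.

    Runs one lagged model per outcome (``tier='full'``) or the two-stage
    per-person estimator (``tier='fast'``); assembles fixed-effect
    matrices with W[j, k] = effect of k on j.
    """
    if persons is not None:
        design = design[design["person_id"].isin(set(persons))]
    if len(design) == 0:
        raise EstimationError(f"no rows for group {group_label!r}")
    if tier == "fast":
        return fast_group_network(design, group_label=group_label)
    if tier != "full":
        raise ValueError("tier must be 'full' or 'fast'")

    W = np.zeros((N_NODES, N_NODES))
    SE = np.zeros((N_NODES, N_NODES))
    P = np.ones((N_NODES, N_NODES))
    fits, side = [], []
    for j, outcome in enumerate(NODES):
        s = replace(spec, outcome=outcome) if spec is not None else ModelSpec(outcome)
        try:
            fit = fit_lagged_model(design, s)
        except Exception as exc:
            raise EstimationError(f"fit failed for outcome {outcome!r}: {exc}") from exc
        for k, col in enumerate(LAG_COLS):
            W[j, k] = fit.coef[col]
            SE[j, k] = fit.se[col]
            P[j, k] = fit.pvalues[col]
        fits.append(fit)
        side.append({
            "outcome": outcome, "rung": fit.rung,
            "time_coef": fit.coef["time"], "time_p": fit.pvalues["time"],
            "sigma": fit.sigma, "phi": fit.phi,
            "loglik": fit.loglik, "aic": fit.aic,
            **fit.varcomps,
        })
    return AffectNetwork(
        nodes=NODES, weights=W, se=SE, pvalues=P,
        group_label=group_label,
        n_persons=design["person_id"].nunique(),
        n_rows=len(design),
        tier="full",
        side_table=pd.DataFrame(side),
        fits=fits,
    )


def significant_subnetwork(network: AffectNetwork, alpha: float = 0.05) -> AffectNetwork:
    """Zero all weights with p >= alpha; the unfiltered weights are kept."""
    W = np.where(network.pvalues < alpha, network.weights, 0.0)
    return replace(
        network,
        weights=W,
        alpha=alpha,
        unfiltered=network.weights.copy(),
    )


# ---------------------------------------------------------------------------
# Fast (two-stage) estimator
# ---------------------------------------------------------------------------

def person_coefficient_matrices(design: pd.DataFrame, min_rows: int = 12):
    """First stage: per-person OLS of every outcome on the six centered
    lagged predictors plus time.  Returns {person_id: 6x8 coefficient
    array} (rows = outcomes; columns = intercept, 6 lags, time); persons
    with fewer than ``min_rows`` rows are skipped."""
    out = {}
    for person, rows in design.groupby("person_id"):
        if len(rows) < min_rows:
            continue
        X = np.column_stack([
            np.ones(len(rows)),
            rows[LAG_COLS].to_numpy(dtype=float),
            rows["time"].to_numpy(dtype=float) / 60.0,
        ])
        Y = rows[[f"y_{n}" for n in NODES]].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        out[person] = coef.T          # 6 outcomes x 8 coefficients
    return out


def fast_group_network(design=None, group_label: str = "",
                       person_coefs=None, persons=None,
                       min_rows: int = 12) -> AffectNetwork:
    """Second stage: average per-person coefficient matrices within the
    group; SEs are the between-person standard errors of the mean and
    p-values use a t reference with n_persons - 1 df."""
    if person_coefs is None:
        if design is None:
            raise ValueError("provide a design or precomputed person_coefs")
        if persons is not None:
            design = design[design["person_id"].isin(set(persons))]
        person_coefs = person_coefficient_matrices(design, min_rows=min_rows)
    elif persons is not None:
        person_coefs = {p: person_coefs[p] for p in persons if p in person_coefs}
    if len(person_coefs) < 2:
        raise EstimationError("fast tier needs at least two usable persons")
    stack = np.stack(list(person_coefs.values()))   # n x 6 x 8
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=stack.shape[0] - 1)
    lag_slice = slice(1, 1 + N_NODES)
    return AffectNetwork(
        nodes=NODES,
        weights=mean[:, lag_slice].copy(),
        se=se[:, lag_slice].copy(),
        pvalues=p[:, lag_slice].copy(),
        group_label=group_label,
        n_persons=stack.shape[0],
        n_rows=0 if design is None else len(design),
        tier="fast",
    )
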