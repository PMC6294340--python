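"""Weighted mixed-effects Cox models with locale random effects.

The model is a Cox proportional-hazards regression with linear predictor

    eta_i = x_i' beta + b_E[loc(i)] + b_GxE[loc(i)] * prs_i

where ``b_E ~ N(0, sigma2_E I)`` are locale random intercepts (the latent
environmental field E) and ``b_GxE ~ N(0, sigma2_GxE I)`` are locale random
slopes on the standardized polygenic score (the GxE field). Observations
carry inverse-probability-of-sampling weights (case-cohort design) and may
be stratified (separate baseline hazards, e.g. by duration of residence).
Ties are handled by the Breslow approximation.

Estimation: for fixed variance components theta = (sigma2_E, sigma2_GxE)
the (beta, b) mode maximizes the weighted penalized partial likelihood by
Newton-Raphson; theta itself maximizes the Laplace-approximate integrated
partial likelihood

    l_int(theta) = l_pen(beta_hat, b_hat; theta)
                   - 1/2 log det K(theta) + 1/2 log det Q(theta)

with K the random-effect block of the penalized information at the mode and
Q = diag(1/sigma2) the penalty precision.  Posterior means of the random
effects at theta_hat (the BLUPs) drive the hazard-ratio risk maps, and the
between-locale heterogeneity is summarized by the median hazard ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "CoxData",
    "InnerFit",
    "SpatialCoxFit",
    "MedianHRSummary",
    "model_spec",
    "weighted_partial_loglik",
    "fit_inner",
    "fit_fixed_only",
    "fit_variance_components",
    "lrt_random_effects",
    "median_hazard_ratio",
    "urban_rural_contrast",
    "export_risk_map",
]

DEFAULT_COVARIATES = ("sex", "pc1", "pc2", "pc3", "famhx", "prs", "log_density")
#: urban vs rural population densities (persons/km^2) used for the
#: conventional urbanicity contrast
URBAN_DENSITY = 5220.0
RURAL_DENSITY = 55.0


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed terms and which locale random terms enter the model."""

    fixed: tuple[str, ...]
    random_intercept: bool = False
    random_slope: bool = False
    prs_col: str = "prs"
    strata_col: str | None = None
    ties: str = "breslow"

    @property
    def n_random_terms(self) -> int:
        return int(self.random_intercept) + int(self.random_slope)


def model_spec(
    model: int,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    prs_col: str = "prs",
    strata_col: str | None = "res_stratum",
    interaction_with: tuple[str, ...] = ("sex", "pc1", "pc2", "pc3", "famhx"),
) -> ModelSpec:
    """The three nested model layouts.

    Model 1: fixed effects only. Model 2: + locale random intercept (E).
    Model 3: + locale random PRS slope (GxE) and all pairwise PRS x
    covariate fixed interactions (full interaction model).
    """
    if model == 1:
        return ModelSpec(tuple(covariates), False, False, prs_col, strata_col)
    if model == 2:
        return ModelSpec(tuple(covariates), True, False, prs_col, strata_col)
    if model == 3:
        inter = tuple(f"{prs_col}:{c}" for c in interaction_with if c in covariates)
        return ModelSpec(tuple(covariates) + inter, True, True, prs_col, strata_col)
    raise ValueError("model must be 1, 2, or 3")


class CoxData:
    """Survival records prepared for the partial-likelihood kernel.

    Rows are grouped by stratum and sorted by descending event/censoring
    time so that risk sets are prefixes. Interaction terms named 'a:b' are
    materialized as products of the named columns.
    """

    def __init__(self, records: pd.DataFrame, spec: ModelSpec,
                 time_col: str = "event_age", event_col: str = "case",
                 weight_col: str = "weight", locale_col: str = "locale_id"):
        n = len(records)
        self.spec = spec
        self.subject_id = (
            records["subject_id"].to_numpy()
            if "subject_id" in records.columns else np.asarray(records.index)
        )
        time = records[time_col].to_numpy(dtype=float)
        if np.any(~np.isfinite(time)) or np.any(time <= 0):
            bad = records.index[~np.isfinite(time) | (time <= 0)].tolist()
            raise ValueError(f"event/censoring time must be positive and finite; rows {bad[:10]}")
        event = records[event_col].to_numpy(dtype=float)
        if not np.isin(event, [0.0, 1.0]).all():
            raise ValueError("event indicator must be 0/1")
        if weight_col in records.columns:
            weight = records[weight_col].to_numpy(dtype=float)
            if np.any(weight < 1.0 - 1e-12):
                raise ValueError("weights must be >= 1 (inverse sampling probabilities)")
        else:
            weight = np.ones(n)

        cols = []
        for name in spec.fixed:
            if ":" in name:
                a, b = name.split(":", 1)
                cols.append(records[a].to_numpy(dtype=float) * records[b].to_numpy(dtype=float))
            else:
                cols.append(records[name].to_numpy(dtype=float))
        X = np.column_stack(cols) if cols else np.empty((n, 0))
        if not np.isfinite(X).all():
            raise ValueError("non-finite covariate values")

        if spec.strata_col and spec.strata_col in records.columns:
            strat_labels, strat = np.unique(records[spec.strata_col], return_inverse=True)
        else:
            strat_labels, strat = np.array(["_all"]), np.zeros(n, dtype=int)

        if locale_col in records.columns:
            self.locale_ids, loc = np.unique(records[locale_col], return_inverse=True)
        else:
            self.locale_ids, loc = np.array([0]), np.zeros(n, dtype=int)

        prs = (
            records[spec.prs_col].to_numpy(dtype=float)
            if spec.prs_col in records.columns else np.zeros(n)
        )

        # sort by (stratum, -time); stable so input order breaks exact ties
        order = np.lexsort((-time, strat))
        self.order = order
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.weight = weight[order]
        self.X = X[order]
        self.strat = strat[order]
        self.loc = loc[order]
        self.prs = prs[order]
        self.strat_labels = strat_labels
        self.n, self.p = X.shape
        self.q = len(self.locale_ids)
        self.n_events = int(self.event.sum())

        # per-stratum slices (contiguous after the sort)
        self.stratum_slices = []
        starts = np.flatnonzero(np.r_[True, np.diff(self.strat) != 0])
        ends = np.r_[starts[1:], n]
        for s, e in zip(starts, ends):
            self.stratum_slices.append(slice(int(s), int(e)))

    def dim(self) -> tuple[int, int, int]:
        qE = self.q if self.spec.random_intercept else 0
        qG = self.q if self.spec.random_slope else 0
        return self.p, qE, qG


def _stratum_parts(t, ev, w, r, loc, prs, X, q, order, need_E, need_G):
    """Breslow partial-likelihood pieces for one stratum (descending time).

    Returns (value, event_sums, per-event-group arrays) as needed for the
    requested derivative ``order`` (0 = value, 1 = +gradient, 2 = +Hessian).
    """
    n, p = X.shape
    # group by distinct time (descending): boundaries where time changes
    new_group = np.r_[True, np.diff(t) != 0]
    gid = np.cumsum(new_group) - 1
    n_groups = gid[-1] + 1
    group_end = np.r_[np.flatnonzero(new_group)[1:] - 1, n - 1]

    d = np.bincount(gid[ev], weights=w[ev], minlength=n_groups)  # Breslow tie mass
    ev_groups = np.flatnonzero(d > 0)
    m = len(ev_groups)
    if m == 0:
        return None  # all-censored stratum contributes 0

    cs0 = np.cumsum(r)
    S0 = cs0[group_end[ev_groups]]
    out = {"d": d[ev_groups], "S0": S0, "ev_groups": ev_groups,
           "group_end": group_end, "gid": gid}
    if order == 0:
        return out

    rX = r[:, None] * X
    cs1x = np.cumsum(rX, axis=0)
    out["S1x"] = cs1x[group_end[ev_groups]]

    if need_E or need_G:
        snapE = np.zeros((m, q))
        snapG = np.zeros((m, q)) if need_G else None
        snapG2 = np.zeros((m, q)) if (order == 2 and need_G) else None
        snapXE = np.zeros((m, q, p)) if (order == 2 and need_E and p) else None
        snapXG = np.zeros((m, q, p)) if (order == 2 and need_G and p) else None
        pos = 0
        accE = np.zeros(q)
        accG = np.zeros(q)
        accG2 = np.zeros(q)
        accXE = np.zeros((q, p))
        accXG = np.zeros((q, p))
        for k, g in enumerate(ev_groups):
            end = group_end[g] + 1
            if end > pos:
                sl = slice(pos, end)
                lc = loc[sl]
                rr = r[sl]
                accE += np.bincount(lc, weights=rr, minlength=q)
                if need_G:
                    rp = rr * prs[sl]
                    accG += np.bincount(lc, weights=rp, minlength=q)
                    if snapG2 is not None:
                        accG2 += np.bincount(lc, weights=rp * prs[sl], minlength=q)
                if snapXE is not None or snapXG is not None:
                    for j in range(p):
                        if snapXE is not None:
                            accXE[:, j] += np.bincount(lc, weights=rr * X[sl, j], minlength=q)
                        if snapXG is not None:
                            accXG[:, j] += np.bincount(lc, weights=rr * prs[sl] * X[sl, j], minlength=q)
                pos = end
            snapE[k] = accE
            if need_G:
                snapG[k] = accG
            if snapG2 is not None:
                snapG2[k] = accG2
            if snapXE is not None:
                snapXE[k] = accXE
            if snapXG is not None:
                snapXG[k] = accXG
        out.update(snapE=snapE, snapG=snapG, snapG2=snapG2, snapXE=snapXE, snapXG=snapXG)

    if order == 2 and p:
        # running X'WX over the risk-set prefix at each event group
        S2xx = np.zeros((m, p, p))
        acc = np.zeros((p, p))
        pos = 0
        for k, g in enumerate(ev_groups):
            end = group_end[g] + 1
            if end > pos:
                Xs = X[pos:end]
                acc = acc + Xs.T @ (r[pos:end, None] * Xs)
                pos = end
            S2xx[k] = acc
        out["S2xx"] = S2xx
    return out


def weighted_partial_loglik(
    data: CoxData,
    beta: np.ndarray,
    b_E: np.ndarray | None = None,
    b_GxE: np.ndarray | None = None,
    order: int = 2,
):
    """Weighted Breslow partial log-likelihood, gradient, and information.

    The gradient and information (negative Hessian) are over the packed
    parameter vector [beta, b_E?, b_GxE?] in that order; random-effect
    blocks are present only when the model spec includes them.  Gradient
    and Hessian are consistent with the value (finite-difference checked in
    the test suite).  All-censored strata contribute zero.
    """
    p, qE, qG = data.dim()
    q = data.q
    beta = np.asarray(beta, dtype=float)
    bE = np.zeros(q) if b_E is None else np.asarray(b_E, dtype=float)
    bG = np.zeros(q) if b_GxE is None else np.asarray(b_GxE, dtype=float)
    need_E, need_G = qE > 0, qG > 0

    eta = data.X @ beta if p else np.zeros(data.n)
    if need_E:
        eta = eta + bE[data.loc]
    if need_G:
        eta = eta + bG[data.loc] * data.prs
    if not np.isfinite(eta).all():
        bad = int(np.flatnonzero(~np.isfinite(eta))[0])
        raise FloatingPointError(
            f"non-finite linear predictor for subject {data.subject_id[bad]}"
        )

    dim = p + qE + qG
    value = 0.0
    grad = np.zeros(dim) if order >= 1 else None
    hess = np.zeros((dim, dim)) if order >= 2 else None

    for sl in data.stratum_slices:
        t, ev, w = data.time[sl], data.event[sl], data.weight[sl]
        X, loc, prs = data.X[sl], data.loc[sl], data.prs[sl]
        e = eta[sl]
        shift = e.max() if len(e) else 0.0  # loglik is shift-invariant per stratum
        r = w * np.exp(e - shift)
        parts = _stratum_parts(t, ev, w, r, loc, prs, X, q, order, need_E, need_G)
        if parts is None:
            continue
        d, S0 = parts["d"], parts["S0"]
        value += float(np.sum(w[ev] * (e[ev] - shift)) - np.sum(d * np.log(S0)))
        if order == 0:
            continue

        dS0 = d / S0
        # observed part of the score
        if p:
            grad[:p] += w[ev] @ X[ev] - dS0 @ parts["S1x"]
        if need_E:
            obsE = np.bincount(loc[ev], weights=w[ev], minlength=q)
            grad[p:p + q] += obsE - dS0 @ parts["snapE"]
        if need_G:
            obsG = np.bincount(loc[ev], weights=w[ev] * prs[ev], minlength=q)
            grad[p + qE:] += obsG - dS0 @ parts["snapG"]
        if order == 1:
            continue

        # information = sum_g d_g [S2/S0 - u u']
        m = len(d)
        U = np.empty((m, dim))
        if p:
            U[:, :p] = parts["S1x"] / S0[:, None]
        if need_E:
            U[:, p:p + q] = parts["snapE"] / S0[:, None]
        if need_G:
            U[:, p + qE:] = parts["snapG"] / S0[:, None]
        hess -= (U * d[:, None]).T @ U
        if p:
            hess[:p, :p] += np.einsum("g,gij->ij", dS0, parts["S2xx"])
        if need_E:
            iE = np.arange(p, p + q)
            hess[iE, iE] += dS0 @ parts["snapE"]
            if p:
                blk = np.einsum("g,gqj->qj", dS0, parts["snapXE"])
                hess[:p, p:p + q] += blk.T
                hess[p:p + q, :p] += blk
        if need_G:
            iG = np.arange(p + qE, dim)
            hess[iG, iG] += dS0 @ parts["snapG2"]
            if p:
                blkG = np.einsum("g,gqj->qj", dS0, parts["snapXG"])
                hess[:p, p + qE:] += blkG.T
                hess[p + qE:, :p] += blkG
            if need_E:
                cross = dS0 @ parts["snapG"]
                hess[np.arange(p, p + q), iG] += cross
                hess[iG, np.arange(p, p + q)] += cross

    if order == 0:
        return value
    if order == 1:
        return value, grad
    return value, grad, hess


@dataclass
class InnerFit:
    beta: np.ndarray
    b_E: np.ndarray
    b_GxE: np.ndarray
    loglik: float  # unpenalized partial loglik at the mode
    loglik_pen: float
    info_pen: np.ndarray  # penalized information at the mode (packed)
    converged: bool
    n_iter: int


def _unpack(data: CoxData, x):
    p, qE, qG = data.dim()
    beta = x[:p]
    bE = x[p:p + qE] if qE else np.zeros(data.q)
    bG = x[p + qE:] if qG else np.zeros(data.q)
    return beta, bE, bG


def fit_inner(
    data: CoxData,
    theta: tuple[float, float],
    beta0: np.ndarray | None = None,
    b0: np.ndarray | None = None,
    max_iter: int = 50,
    rel_tol: float = 1e-8,
    grad_tol: float = 1e-6,
) -> InnerFit:
    """Penalized-mode (beta, b) estimates at fixed variance components.

    Newton-Raphson with step halving on the penalized partial
    log-likelihood; converged when the relative change in the objective is
    below ``rel_tol`` or the gradient sup-norm is below ``grad_tol``.
    Non-convergence within ``max_iter`` returns a flagged partial result.
    As theta -> 0 the penalty forces b -> 0 and beta to the
    fixed-effects-only Cox solution; a locale with no events gets a
    negative but finite (shrunken) intercept BLUP.
    """
    p, qE, qG = data.dim()
    s2E, s2G = theta
    if (qE and s2E < 0) or (qG and s2G < 0):
        raise ValueError("variance components must be non-negative")
    dim = p + qE + qG
    x = np.zeros(dim)
    if beta0 is not None:
        x[:p] = beta0
    if b0 is not None and len(b0) == qE + qG:
        x[p:] = b0

    prec = np.zeros(dim)
    if qE:
        prec[p:p + qE] = 1.0 / s2E
    if qG:
        prec[p + qE:] = 1.0 / s2G

    def pen_value_grad_hess(xv):
        beta, bE, bG = _unpack(data, xv)
        v, g, h = weighted_partial_loglik(data, beta, bE, bG, order=2)
        vp = v - 0.5 * float(np.sum(prec * xv**2))
        gp = g - prec * xv
        hp = h + np.diag(prec)
        return v, vp, gp, hp

    v, vp, gp, hp = pen_value_grad_hess(x)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hp, gp)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(hp + 1e-8 * np.eye(dim), gp)
        # step halving on the penalized objective
        lam, accepted = 1.0, False
        for _ in range(30):
            x_new = x + lam * step
            beta, bE, bG = _unpack(data, x_new)
            v_new = weighted_partial_loglik(data, beta, bE, bG, order=0)
            vp_new = v_new - 0.5 * float(np.sum(prec * x_new**2))
            if np.isfinite(vp_new) and vp_new >= vp - 1e-12:
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            break
        x = x_new
        rel = abs(vp_new - vp) / (abs(vp) + 1e-10)
        v, vp, gp, hp = pen_value_grad_hess(x)
        if rel < rel_tol or np.max(np.abs(gp)) < grad_tol:
            converged = True
            break
    if not converged:
        logger.warning("inner Newton did not converge in %d iterations", max_iter)
    beta, bE, bG = _unpack(data, x)
    return InnerFit(beta, bE, bG, v, vp, hp, converged, it)


def fit_fixed_only(data: CoxData, **kw) -> InnerFit:
    """Plain weighted stratified Cox fit (no random effects)."""
    if data.dim()[1] or data.dim()[2]:
        raise ValueError("spec includes random terms; use fit_inner/fit_variance_components")
    return fit_inner(data, (0.0, 0.0), **kw)


@dataclass
class MedianHRSummary:
    mhr: float
    method: str


def median_hazard_ratio(blups: np.ndarray, sigma2: float | None = None) -> dict[str, MedianHRSummary]:
    """Between-locale heterogeneity on the hazard-ratio scale.

    ``pairwise_empirical``: median over all unordered locale pairs (i, j)
    of exp(|b_i - b_j|).  ``closed_form`` (when sigma2 given): the value
    this median takes for Gaussian effects, exp(sqrt(2 sigma2) * z_0.75).
    Both are >= 1 by construction.
    """
    b = np.asarray(blups, dtype=float)
    if len(b) < 2:
        raise ValueError("median hazard ratio needs at least 2 locales")
    diffs = np.abs(b[:, None] - b[None, :])[np.triu_indices(len(b), 1)]
    out = {
        "pairwise_empirical": MedianHRSummary(
            float(np.exp(np.median(diffs))), "pairwise_empirical"
        )
    }
    if sigma2 is not None:
        z75 = stats.norm.ppf(0.75)
        out["closed_form"] = MedianHRSummary(
            float(np.exp(math.sqrt(2.0 * max(sigma2, 0.0)) * z75)), "closed_form"
        )
    return out


@dataclass
class SpatialCoxFit:
    spec: ModelSpec
    beta: pd.Series
    se: pd.Series
    robust_se: pd.Series | None
    sigma2_E: float
    sigma2_GxE: float
    blup_E: pd.Series
    blup_GxE: pd.Series
    loglik_integrated: float
    loglik_penalized: float
    loglik_fixed: float  # max partial loglik of the no-random-effects fit
    converged: bool
    n_iter: int
    boundary_E: bool = False
    boundary_GxE: bool = False
    n_outer_evals: int = 0

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.beta)

    def median_hr(self) -> dict:
        """Median hazard ratios for the fitted random components."""
        out = {}
        if self.spec.random_intercept:
            out["E"] = median_hazard_ratio(self.blup_E.to_numpy(), self.sigma2_E)
        if self.spec.random_slope:
            out["GxE"] = median_hazard_ratio(self.blup_GxE.to_numpy(), self.sigma2_GxE)
        return out


def _integrated_loglik(data: CoxData, theta, inner: InnerFit) -> float:
    """Laplace-approximate integrated partial log-likelihood at the mode."""
    p, qE, qG = data.dim()
    if qE + qG == 0:
        return inner.loglik
    K = inner.info_pen[p:, p:]
    sign, logdetK = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    logdetQ = 0.0
    if qE:
        logdetQ += -qE * math.log(theta[0])
    if qG:
        logdetQ += -qG * math.log(theta[1])
    return inner.loglik_pen - 0.5 * logdetK + 0.5 * logdetQ


def _reml_correction(data: CoxData, inner: InnerFit) -> float:
    """REML-type correction: profile the fixed effects out as well."""
    p = data.dim()[0]
    if p == 0:
        return 0.0
    Ifull = inner.info_pen
    Kbb = Ifull[p:, p:]
    # Schur complement: information for beta after accounting for b
    if Kbb.size:
        S = Ifull[:p, :p] - Ifull[:p, p:] @ np.linalg.solve(Kbb, Ifull[p:, :p])
    else:
        S = Ifull[:p, :p]
    sign, ld = np.linalg.slogdet(S)
    return -0.5 * ld if sign > 0 else -np.inf


def _robust_se(data: CoxData, inner: InnerFit) -> np.ndarray | None:
    """Sandwich SEs for the fixed effects (score residuals, weights as
    sampling weights; random effects held fixed as offsets)."""
    p = data.dim()[0]
    if p == 0:
        return None
    eta = data.X @ inner.beta
    if data.spec.random_intercept:
        eta = eta + inner.b_E[data.loc]
    if data.spec.random_slope:
        eta = eta + inner.b_GxE[data.loc] * data.prs
    B = np.zeros((p, p))
    for sl in data.stratum_slices:
        t, ev, w, X = data.time[sl], data.event[sl], data.weight[sl], data.X[sl]
        e = eta[sl]
        shift = e.max() if len(e) else 0.0
        r = w * np.exp(e - shift)
        parts = _stratum_parts(t, ev, w, r, data.loc[sl], data.prs[sl], X,
                               data.q, 1, False, False)
        if parts is None:
            continue
        d, S0, S1x = parts["d"], parts["S0"], parts["S1x"]
        gid, ev_groups = parts["gid"], parts["ev_groups"]
        xbar = S1x / S0[:, None]
        dl = d / S0
        # suffix sums over event groups: rows are in descending time order,
        # so event times t_g <= t_i correspond to group indices >= gid_i
        suf_dl = np.cumsum(dl[::-1])[::-1]
        suf_dlx = np.cumsum((dl[:, None] * xbar)[::-1], axis=0)[::-1]
        k0 = np.searchsorted(ev_groups, gid, side="left")
        at_risk = k0 < len(ev_groups)
        expeta = np.exp(e - shift)
        U = np.zeros((len(t), p))
        U[at_risk] = expeta[at_risk, None] * suf_dlx[k0[at_risk]] \
            - (expeta[at_risk] * suf_dl[k0[at_risk]])[:, None] * X[at_risk]
        k_ev = np.searchsorted(ev_groups, gid[ev])
        U[ev] += X[ev] - xbar[k_ev]
        Uw = w[:, None] * U
        B += Uw.T @ Uw
    A = inner.info_pen[:p, :p]
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return None
    V = Ainv @ B @ Ainv
    return np.sqrt(np.clip(np.diag(V), 0, None))


def fit_variance_components(
    records: pd.DataFrame,
    spec: ModelSpec,
    theta_bounds: tuple[float, float] = (1e-8, 10.0),
    objective: str = "ml",
    outer_xtol: float = 5e-3,
    inner_kw: dict | None = None,
    robust: bool = True,
    **data_kw,
) -> SpatialCoxFit:
    """Maximize the Laplace-approximate integrated partial likelihood over
    the variance components, then report BLUPs at the optimum.

    The outer optimizer is derivative-free and bounded (Brent for one
    variance component, Powell for two), searching on the log10 scale over
    ``theta_bounds``. ``objective`` is 'ml' (default) or 'reml' (adds a
    fixed-effect profile correction). A component estimated at the lower
    bound is reported as exactly 0 with a boundary flag.
    """
    data = CoxData(records, spec, **data_kw)
    p, qE, qG = data.dim()
    if (qE or qG) and data.q < 2:
        raise ValueError("random locale effects need at least 2 locales")
    if data.n_events == 0:
        raise ValueError("no events in the data")
    inner_kw = inner_kw or {}

    # fixed-effects-only reference (also the reduced model for LRTs)
    spec_fixed = ModelSpec(spec.fixed, False, False, spec.prs_col, spec.strata_col)
    data_fixed = CoxData(records, spec_fixed, **data_kw)
    fit0 = fit_inner(data_fixed, (0.0, 0.0), **inner_kw)

    if qE + qG == 0:
        se = np.sqrt(np.diag(np.linalg.inv(fit0.info_pen))) if p else np.empty(0)
        rse = _robust_se(data_fixed, fit0) if robust else None
        names = list(spec.fixed)
        return SpatialCoxFit(
            spec=spec, beta=pd.Series(fit0.beta, index=names),
            se=pd.Series(se, index=names),
            robust_se=pd.Series(rse, index=names) if rse is not None else None,
            sigma2_E=0.0, sigma2_GxE=0.0,
            blup_E=pd.Series(dtype=float), blup_GxE=pd.Series(dtype=float),
            loglik_integrated=fit0.loglik, loglik_penalized=fit0.loglik_pen,
            loglik_fixed=fit0.loglik, converged=fit0.converged, n_iter=fit0.n_iter,
        )

    lo, hi = math.log10(theta_bounds[0]), math.log10(theta_bounds[1])
    state = {"x": None, "evals": 0, "best": (-np.inf, None, None)}

    def theta_from(u):
        uE = u[0] if qE else None
        uG = u[-1] if qG else None
        return (10.0 ** uE if qE else 0.0, 10.0 ** uG if qG else 0.0)

    def negobj(u):
        u = np.atleast_1d(u)
        th = theta_from(u)
        beta0 = state["x"][:p] if state["x"] is not None else fit0.beta
        b0 = state["x"][p:] if state["x"] is not None else None
        inner = fit_inner(data, th, beta0=beta0, b0=b0, **inner_kw)
        state["x"] = np.concatenate(
            [inner.beta]
            + ([inner.b_E] if qE else [])
            + ([inner.b_GxE] if qG else [])
        )
        ll = _integrated_loglik(data, th, inner)
        if objective == "reml":
            ll += _reml_correction(data, inner)
        state["evals"] += 1
        if ll > state["best"][0]:
            state["best"] = (ll, th, inner)
        return -ll if np.isfinite(ll) else 1e30

    n_vc = int(qE > 0) + int(qG > 0)
    if n_vc == 1:
        res = optimize.minimize_scalar(
            lambda u: negobj([u]), bounds=(lo, hi), method="bounded",
            options={"xatol": outer_xtol},
        )
        u_hat = np.array([res.x])
    else:
        res = optimize.minimize(
            negobj, x0=np.array([-1.0, -1.0]), method="Powell",
            bounds=[(lo, hi)] * 2, options={"xtol": outer_xtol, "ftol": 1e-7},
        )
        u_hat = np.atleast_1d(res.x)

    ll_best, th_hat, inner = state["best"]
    # refit at the best theta to make the reported mode consistent
    inner = fit_inner(data, th_hat, beta0=inner.beta,
                      b0=np.concatenate(([inner.b_E] if qE else []) + ([inner.b_GxE] if qG else []))
                      if qE + qG else None, **inner_kw)
    ll_best = _integrated_loglik(data, th_hat, inner)
    if objective == "reml":
        ll_best += _reml_correction(data, inner)

    s2E = th_hat[0] if qE else 0.0
    s2G = th_hat[1] if qG else 0.0
    boundary_E = bool(qE and s2E <= theta_bounds[0] * 10 ** (2 * outer_xtol))
    boundary_GxE = bool(qG and s2G <= theta_bounds[0] * 10 ** (2 * outer_xtol))
    if boundary_E:
        s2E = 0.0
    if boundary_GxE:
        s2G = 0.0

    try:
        cov = np.linalg.inv(inner.info_pen)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    rse = _robust_se(data, inner) if robust else None
    names = list(spec.fixed)
    lid = data.locale_ids
    return SpatialCoxFit(
        spec=spec,
        beta=pd.Series(inner.beta, index=names),
        se=pd.Series(se, index=names),
        robust_se=pd.Series(rse, index=names) if rse is not None else None,
        sigma2_E=float(s2E), sigma2_GxE=float(s2G),
        blup_E=pd.Series(inner.b_E, index=lid) if qE else pd.Series(dtype=float),
        blup_GxE=pd.Series(inner.b_GxE, index=lid) if qG else pd.Series(dtype=float),
        loglik_integrated=float(ll_best), loglik_penalized=float(inner.loglik_pen),
        loglik_fixed=float(fit0.loglik),
        converged=bool(inner.converged), n_iter=inner.n_iter,
        boundary_E=boundary_E, boundary_GxE=boundary_GxE,
        n_outer_evals=state["evals"],
    )


def lrt_random_effects(fit_full: SpatialCoxFit, fit_reduced: SpatialCoxFit):
    """Likelihood-ratio test of added variance components.

    statistic = 2 (l_int_full - l_int_reduced); df = number of added
    variance components; p from chi2_df.  The plain chi-square reference is
    conservative at the boundary sigma2 = 0 (a 50:50 mixture would halve
    the p-value); identical fits give statistic 0, p = 1.
    """
    full_terms = {
        t for t, on in (("E", fit_full.spec.random_intercept),
                        ("GxE", fit_full.spec.random_slope)) if on
    }
    red_terms = {
        t for t, on in (("E", fit_reduced.spec.random_intercept),
                        ("GxE", fit_reduced.spec.random_slope)) if on
    }
    if not red_terms <= full_terms:
        raise ValueError("reduced model's random terms are not nested in the full model's")
    df = len(full_terms) - len(red_terms)
    stat = 2.0 * (fit_full.loglik_integrated - fit_reduced.loglik_integrated)
    stat = max(stat, 0.0)
    if df == 0:
        return stat, 0, 1.0
    p = float(stats.chi2.sf(stat, df))
    if stat == 0.0:
        p = 1.0
    return float(stat), df, p


def urban_rural_contrast(fit: SpatialCoxFit, density_col: str = "log_density"):
    """Urbanicity hazard ratio: the density coefficient contrasted between
    5220 and 55 persons/km^2 (the conventional urban/rural categories)."""
    if density_col not in fit.beta.index:
        raise KeyError(f"{density_col} is not a fixed term of this fit")
    delta = math.log(URBAN_DENSITY) - math.log(RURAL_DENSITY)
    b = float(fit.beta[density_col])
    se = float(fit.se[density_col])
    hr = math.exp(b * delta)
    return {
        "hr": hr,
        "ci_low": math.exp((b - 1.96 * se) * delta),
        "ci_high": math.exp((b + 1.96 * se) * delta),
    }


def _decile_bins(values: np.ndarray) -> np.ndarray:
    """Decile bin (1..10) per value; ranks, ties averaged then floored."""
    order = np.argsort(np.argsort(values, kind="stable"), kind="stable")
    n = len(values)
    return np.minimum((order * 10) // n + 1, 10)


def export_risk_map(fit: SpatialCoxFit, locale_map, n_hist_bins: int = 20) -> dict:
    """GeoJSON risk map: per-locale hazard ratios exp(BLUP) with decile bins.

    Locales present in the map but absent from the fit get null properties
    (logged). Histogram summaries of the HR distributions (the map's
    companion panels) are embedded in the metadata.
    """
    from .tessellation import locale_map_to_geojson

    props: dict[int, dict] = {}
    have_E = len(fit.blup_E) > 0
    have_G = len(fit.blup_GxE) > 0
    ids = [loc.id for loc in locale_map.locales]
    missing = [i for i in ids if have_E and i not in fit.blup_E.index]
    if missing:
        logger.warning("%d locale(s) in map have no fitted BLUP; null properties", len(missing))
    if have_E:
        present = [i for i in ids if i in fit.blup_E.index]
        hrE = np.exp(fit.blup_E.loc[present].to_numpy())
        binsE = _decile_bins(hrE)
        for i, h, bn in zip(present, hrE, binsE):
            props.setdefault(i, {})["hr_E"] = float(h)
            props[i]["hr_E_decile"] = int(bn)
    if have_G:
        present = [i for i in ids if i in fit.blup_GxE.index]
        hrG = np.exp(fit.blup_GxE.loc[present].to_numpy())
        binsG = _decile_bins(hrG)
        for i, h, bn in zip(present, hrG, binsG):
            props.setdefault(i, {})["hr_GxE"] = float(h)
            props[i]["hr_GxE_decile"] = int(bn)
    for i in ids:
        props.setdefault(i, {}).setdefault("hr_E", None)
        props[i].setdefault("hr_GxE", None)

    gj = locale_map_to_geojson(locale_map, extra_properties=props)
    hists = {}
    if have_E:
        counts, edges = np.histogram(np.exp(fit.blup_E.to_numpy()), bins=n_hist_bins)
        hists["hr_E"] = {"counts": counts.tolist(), "edges": edges.tolist()}
    if have_G:
        counts, edges = np.histogram(np.exp(fit.blup_GxE.to_numpy()), bins=n_hist_bins)
        hists["hr_GxE"] = {"counts": counts.tolist(), "edges": edges.tolist()}
    gj["metadata"]["hr_histograms"] = hists
    gj["metadata"]["sigma2_E"] = fit.sigma2_E
    gj["metadata"]["sigma2_GxE"] = fit.sigma2_GxE
    return gj
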