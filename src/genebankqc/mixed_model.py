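"""REML fitting of the additive accession x year model.

The model is

    y_ij = mu + g_i + a_j + e_ij,        e_ij ~ N(0, sigma2_e_j)

with year-specific error variances.  Three role configurations are used by
the curation pipeline:

* accessions random / years fixed  - year means and per-year error
  variances for the CV screen;
* accessions fixed / years random  - studentized-residual outlier test and
  BLUEs (adjusted accession means on the trait scale);
* both random                      - variance components for heritability.

The engine is self-contained (no external mixed-model library).  The large
accession factor is absorbed: Henderson's coefficient matrix is reduced by
a Schur complement on the accession block, whose diagonal structure makes
memory and time linear in the number of records and quadratic only in the
number of years (<= ~70).  Variance parameters are driven to the REML
optimum by EM fixed-point updates (monotone in the restricted likelihood)
and finished with an L-BFGS polish on the log-variance scale using
analytic gradients.

Years with fewer than ``min_records_per_year_variance`` records share a
pooled residual variance; a single-record year cannot support its own
variance estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse
from scipy.sparse import csgraph

from .exceptions import (DegreesOfFreedomError, EstimabilityError,
                         InsufficientDataError)

__all__ = ["FitSpec", "FitResult", "VarianceParams", "fit_mixed_model",
           "reml_criterion"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class FitSpec:
    """Roles and numerical settings for one model fit."""

    accession_role: str = "random"        # "fixed" | "random"
    year_role: str = "fixed"              # "fixed" | "random"
    heteroscedastic: bool = True          # year-specific vs pooled sigma2_e
    min_records_per_year_variance: int = 5
    convergence_tol: float = 1e-8
    max_iter: int = 500
    polish: bool = True                   # quasi-Newton finish after EM

    def __post_init__(self) -> None:
        for role in (self.accession_role, self.year_role):
            if role not in ("fixed", "random"):
                raise ValueError(f"role must be 'fixed' or 'random', got {role!r}")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


@dataclass
class VarianceParams:
    """Explicit variance parameters for evaluating the REML criterion."""

    sigma2_e_by_year: Mapping[int, float] | float
    sigma2_g: float | None = None
    sigma2_y: float | None = None


@dataclass
class FitResult:
    """Converged (or best-effort) REML fit of the additive model."""

    spec: FitSpec
    mu_hat: float
    accession_effects: pd.Series       # BLUEs if fixed, BLUPs if random
    year_effects: pd.Series            # marginal means if fixed, BLUPs if random
    sigma2_g: float | None
    sigma2_y: float | None
    sigma2_e_by_year: pd.Series
    residuals: pd.Series               # aligned to the input record index
    leverages: pd.Series               # h_r = w_r m_r' C^-1 m_r, same alignment
    effective_df_by_year: pd.Series    # n_group - sum(h) mapped to years
    reml_loglik: float
    converged: bool
    n_iter: int
    standard_errors: dict = field(default_factory=dict)
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_records(self) -> int:
        return len(self.residuals)


# ---------------------------------------------------------------------------
# internal design representation


class _Design:
    """Index arrays and bookkeeping for one (records, spec) pair."""

    def __init__(self, records: pd.DataFrame, spec: FitSpec):
        if len(records) == 0:
            raise InsufficientDataError("no records")
        self.spec = spec
        self.index = records.index
        self.y = records["value"].to_numpy(float)
        if not np.isfinite(self.y).all():
            raise ValueError("non-finite phenotype values")

        acc = pd.Categorical(records["accession_id"],
                             categories=sorted(records["accession_id"].unique()))
        yr = pd.Categorical(records["year"],
                            categories=sorted(records["year"].unique()))
        self.acc_levels = np.asarray(acc.categories)
        self.year_levels = np.asarray(yr.categories)
        self.acc_idx = acc.codes.astype(np.int64)
        self.year_idx = yr.codes.astype(np.int64)
        self.q = len(self.acc_levels)
        self.m = len(self.year_levels)
        self.n = len(self.y)
        if self.q < 2:
            raise InsufficientDataError("need >= 2 distinct accessions")

        # residual-variance groups: big years own, small years pooled
        year_counts = np.bincount(self.year_idx, minlength=self.m)
        if spec.heteroscedastic:
            big = year_counts >= spec.min_records_per_year_variance
            group_of_year = np.full(self.m, -1, int)
            group_of_year[big] = np.arange(int(big.sum()))
            if (~big).any():
                group_of_year[~big] = int(big.sum())
                self.n_groups = int(big.sum()) + 1
            else:
                self.n_groups = int(big.sum())
            if self.n_groups == 0:    # all years tiny -> one pooled group
                group_of_year[:] = 0
                self.n_groups = 1
        else:
            group_of_year = np.zeros(self.m, int)
            self.n_groups = 1
        self.group_of_year = group_of_year
        self.group_idx = group_of_year[self.year_idx]
        self.group_sizes = np.bincount(self.group_idx, minlength=self.n_groups)

        # b-block layout (non-absorbed columns)
        self.acc_random = spec.accession_role == "random"
        self.year_random = spec.year_role == "random"
        self.has_intercept = self.acc_random and self.year_random
        both_fixed = not self.acc_random and not self.year_random
        if both_fixed:
            # reference constraint: drop the last year's deviation
            self.year_cols = self.m - 1
            self.year_col_of_year = np.where(
                np.arange(self.m) < self.m - 1, np.arange(self.m), -1)
        else:
            self.year_cols = self.m
            self.year_col_of_year = np.arange(self.m)
        self.b = int(self.has_intercept) + self.year_cols
        self.year_col_idx = self.year_col_of_year[self.year_idx]

        self.n_fixed = (
            (0 if self.acc_random else self.q)
            + (0 if self.year_random else self.year_cols)
            + (1 if self.has_intercept else 0)
        )
        if both_fixed:
            self._check_connected()
        if self.n <= self.n_fixed:
            raise DegreesOfFreedomError(
                f"{self.n} records cannot support {self.n_fixed} fixed-effect "
                "parameters"
            )
        self.var_y = float(np.var(self.y, ddof=1)) if self.n > 1 else 1.0
        self.var_floor = 1e-8 * max(self.var_y, 1e-12)

    def _check_connected(self) -> None:
        inc = sparse.coo_matrix(
            (np.ones(self.n), (self.acc_idx, self.year_idx)),
            shape=(self.q, self.m),
        ).tocsr()
        graph = sparse.bmat([[None, inc], [inc.T, None]], format="csr")
        n_comp, labels = csgraph.connected_components(graph, directed=False)
        if n_comp > 1:
            groups = [
                list(self.acc_levels[labels[: self.q] == c])[:5]
                for c in range(n_comp)
            ]
            raise EstimabilityError(
                f"design is disconnected into {n_comp} components with both "
                f"factors fixed; sample accessions per component: {groups}"
            )


@dataclass
class _State:
    """All quantities of one generalized-least-squares solve."""

    theta: np.ndarray           # [group variances..., (sigma2_g), (sigma2_y)]
    alpha: np.ndarray           # absorbed accession solutions
    beta: np.ndarray            # b-block solutions
    resid: np.ndarray
    h: np.ndarray               # per-record leverages
    loglik: float
    grad: np.ndarray            # d loglik / d log(theta)
    se_alpha: np.ndarray
    se_beta: np.ndarray
    sum_h_group: np.ndarray
    sse_group: np.ndarray
    tr_cgg: float
    tr_cyy: float


def _unpack(design: _Design, theta: np.ndarray):
    g = design.n_groups
    s2e_group = theta[:g]
    pos = g
    sigma2_g = sigma2_y = None
    if design.acc_random:
        sigma2_g = theta[pos]
        pos += 1
    if design.year_random:
        sigma2_y = theta[pos]
    return s2e_group, sigma2_g, sigma2_y


def _solve(design: _Design, theta: np.ndarray) -> _State:
    d = design
    s2e_group, sigma2_g, sigma2_y = _unpack(d, theta)
    w = 1.0 / s2e_group[d.group_idx]
    wy = w * d.y

    # accession block diagonal
    sw_acc = np.bincount(d.acc_idx, weights=w, minlength=d.q)
    diag_d = sw_acc + (1.0 / sigma2_g if d.acc_random else 0.0)
    r_a = np.bincount(d.acc_idx, weights=wy, minlength=d.q)

    # b block: optional intercept row 0, then year columns
    b = d.b
    off = 1 if d.has_intercept else 0
    U = np.zeros((b, d.q))
    F = np.zeros((b, b))
    r_b = np.zeros(b)
    has_col = d.year_col_idx >= 0
    rows = off + d.year_col_idx[has_col]
    # cross products with the accession block
    np.add.at(U, (rows, d.acc_idx[has_col]), w[has_col])
    sw_yearcol = np.bincount(d.year_col_idx[has_col], weights=w[has_col],
                             minlength=d.year_cols)
    swy_yearcol = np.bincount(d.year_col_idx[has_col], weights=wy[has_col],
                              minlength=d.year_cols)
    F[off:, off:][np.diag_indices(d.year_cols)] = sw_yearcol
    r_b[off:] = swy_yearcol
    if d.has_intercept:
        U[0] = sw_acc
        F[0, 0] = w.sum()
        F[0, off:] = sw_yearcol
        F[off:, 0] = sw_yearcol
        r_b[0] = wy.sum()
    if d.year_random:
        F[off:, off:][np.diag_indices(d.year_cols)] += 1.0 / sigma2_y

    T = U / diag_d                       # (b, q)
    S = F - T @ U.T
    S = 0.5 * (S + S.T)
    try:
        cf = linalg.cho_factor(S, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular mixed-model equations; condition estimate "
            f"{np.linalg.cond(S):.3g}"
        ) from exc
    beta = linalg.cho_solve(cf, r_b - T @ r_a, check_finite=False)
    alpha = (r_a - U.T @ beta) / diag_d

    fitted = alpha[d.acc_idx]
    fitted = fitted + np.where(
        has_col, beta[off + np.clip(d.year_col_idx, 0, None)], 0.0)
    if d.has_intercept:
        fitted = fitted + beta[0]
    resid = d.y - fitted

    ypy = float(wy @ d.y - alpha @ r_a - beta @ r_b)
    logdet_d = float(np.log(diag_d).sum())
    logdet_s = 2.0 * float(np.log(np.diag(cf[0])).sum())
    loglik = -0.5 * (
        float(np.log(s2e_group[d.group_idx]).sum())
        + (d.q * np.log(sigma2_g) if d.acc_random else 0.0)
        + (d.m * np.log(sigma2_y) if d.year_random else 0.0)
        + logdet_d + logdet_s + ypy + (d.n - d.n_fixed) * _LOG2PI
    )

    # leverages h_r = w_r [1/d_i + (v_r - t_i)' S^-1 (v_r - t_i)]
    K = linalg.cho_solve(cf, np.eye(b), check_finite=False)
    M = K @ T                            # (b, q)
    tkt = np.einsum("bq,bq->q", T, M)
    i = d.acc_idx
    diag_k = np.diag(K)
    c = np.clip(d.year_col_idx, 0, None)
    if d.has_intercept:
        vkv = K[0, 0] + 2.0 * K[0, off + c] + diag_k[off + c]
        vkt = M[0, i] + M[off + c, i]
    else:
        vkv = np.where(has_col, diag_k[off + c], 0.0)
        vkt = np.where(has_col, M[off + c, i], 0.0)
    quad = vkv - 2.0 * vkt + tkt[i]
    h = w * (1.0 / diag_d[i] + quad)

    sum_h_group = np.bincount(d.group_idx, weights=h, minlength=d.n_groups)
    sse_group = np.bincount(d.group_idx, weights=resid**2, minlength=d.n_groups)

    tr_cgg = float((1.0 / diag_d + tkt).sum()) if d.acc_random else 0.0
    tr_cyy = float(diag_k[off:].sum()) if d.year_random else 0.0

    # gradient on the log-variance scale
    grad = np.empty_like(theta)
    grad[: d.n_groups] = -0.5 * (
        (d.group_sizes - sum_h_group) - sse_group / s2e_group
    )
    pos = d.n_groups
    if d.acc_random:
        gg = float(alpha @ alpha)
        grad[pos] = -0.5 * ((d.q - tr_cgg / sigma2_g) - gg / sigma2_g)
        pos += 1
    if d.year_random:
        a_blup = beta[off:]
        aa = float(a_blup @ a_blup)
        grad[pos] = -0.5 * ((d.m - tr_cyy / sigma2_y) - aa / sigma2_y)

    se_alpha = np.sqrt(1.0 / diag_d + tkt)
    se_beta = np.sqrt(np.clip(diag_k, 0.0, None))
    return _State(theta, alpha, beta, resid, h, loglik, grad,
                  se_alpha, se_beta, sum_h_group, sse_group, tr_cgg, tr_cyy)


def _em_update(design: _Design, state: _State) -> np.ndarray:
    """One EM step for all variance parameters (monotone in REML loglik)."""
    d = design
    theta = state.theta.copy()
    s2e_group, sigma2_g, sigma2_y = _unpack(d, theta)
    new_e = (state.sse_group + s2e_group * state.sum_h_group) / d.group_sizes
    theta[: d.n_groups] = np.maximum(new_e, d.var_floor)
    pos = d.n_groups
    if d.acc_random:
        gg = float(state.alpha @ state.alpha)
        theta[pos] = max((gg + state.tr_cgg) / d.q, d.var_floor)
        pos += 1
    if d.year_random:
        off = 1 if d.has_intercept else 0
        aa = float(state.beta[off:] @ state.beta[off:])
        theta[pos] = max((aa + state.tr_cyy) / d.m, d.var_floor)
    return theta


def _anderson_update(design: _Design, state: _State) -> np.ndarray:
    """One step of the classic REML fixed-point iteration.

    sigma2 <- quadratic form / trace-adjusted count for every component;
    not monotone in general (unlike EM) but contracts much faster near the
    optimum, where it is used as a final refinement.
    """
    d = design
    theta = state.theta.copy()
    s2e_group, sigma2_g, sigma2_y = _unpack(d, theta)
    denom = d.group_sizes - state.sum_h_group
    ok = denom > 1e-12
    theta[: d.n_groups][ok] = np.maximum(
        state.sse_group[ok] / denom[ok], d.var_floor)
    pos = d.n_groups
    if d.acc_random:
        gg = float(state.alpha @ state.alpha)
        denom_g = d.q - state.tr_cgg / sigma2_g
        if denom_g > 1e-12:
            theta[pos] = max(gg / denom_g, d.var_floor)
        pos += 1
    if d.year_random:
        off = 1 if d.has_intercept else 0
        aa = float(state.beta[off:] @ state.beta[off:])
        denom_y = d.m - state.tr_cyy / sigma2_y
        if denom_y > 1e-12:
            theta[pos] = max(aa / denom_y, d.var_floor)
    return theta


def _initial_theta(design: _Design) -> np.ndarray:
    d = design
    n_rand = int(d.acc_random) + int(d.year_random)
    base = max(d.var_y, d.var_floor)
    resid0 = base / (1 + n_rand)
    theta = [resid0] * d.n_groups
    if d.acc_random:
        theta.append(resid0)
    if d.year_random:
        theta.append(resid0)
    return np.maximum(np.asarray(theta, float), d.var_floor)


def fit_mixed_model(records: pd.DataFrame, spec: FitSpec | None = None
                    ) -> FitResult:
    """Fit the additive model by REML for the roles given in ``spec``.

    ``records`` needs columns ``accession_id``, ``year``, ``value``;
    replicated checks simply appear as extra residual draws within their
    year.  The fit is deterministic: no random initialization, levels
    processed in sorted order.
    """
    spec = spec or FitSpec()
    design = _Design(records, spec)
    theta = _initial_theta(design)

    trace = []
    state = _solve(design, theta)
    trace.append(state.loglik)
    converged = False
    n_iter = 0
    for n_iter in range(1, spec.max_iter + 1):
        theta = _em_update(design, state)
        new_state = _solve(design, theta)
        rel = abs(new_state.loglik - state.loglik) / (abs(state.loglik) + 1.0)
        state = new_state
        trace.append(state.loglik)
        if rel < spec.convergence_tol:
            converged = True
            break

    if spec.polish and len(theta) > 0:
        lo = np.log(design.var_floor)
        hi = np.log(max(design.var_y, design.var_floor) * 1e6)

        def negloglik(eta: np.ndarray):
            st = _solve(design, np.exp(np.clip(eta, lo, hi)))
            return -st.loglik, -st.grad

        res = optimize.minimize(
            negloglik, np.log(theta), jac=True, method="L-BFGS-B",
            bounds=[(lo, hi)] * len(theta),
            options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-10},
        )
        polished = np.exp(res.x)
        polished_state = _solve(design, polished)
        if polished_state.loglik >= state.loglik:
            theta, state = polished, polished_state
            trace.append(state.loglik)
            converged = converged or res.success
        # Score-based fixed-point refinement: contracts on the parameters
        # where the likelihood is too flat for loglik-based stopping (the
        # score still resolves the optimum).  Kept only if the score norm
        # improves; ascent of the recorded trace is preserved.
        best_theta, best_state = theta, state
        cur_theta, cur_state = theta, state
        for _ in range(50):
            if np.abs(cur_state.grad).max() < 1e-11:
                break
            cur_theta = _anderson_update(design, cur_state)
            cur_state = _solve(design, cur_theta)
            if (np.abs(cur_state.grad).max() < np.abs(best_state.grad).max()
                    and cur_state.loglik >= best_state.loglik - 1e-9):
                best_theta, best_state = cur_theta, cur_state
        if best_state is not state:
            theta, state = best_theta, best_state
            trace.append(state.loglik)

    if not converged:
        warnings.warn(
            f"REML did not converge in {spec.max_iter} EM iterations "
            f"(last loglik {state.loglik:.6f})", stacklevel=2)

    return _build_result(design, state, converged, n_iter, np.asarray(trace))


def _build_result(design: _Design, state: _State, converged: bool,
                  n_iter: int, trace: np.ndarray) -> FitResult:
    d = design
    spec = d.spec
    s2e_group, sigma2_g, sigma2_y = _unpack(d, state.theta)
    off = 1 if d.has_intercept else 0

    acc_eff = pd.Series(state.alpha, index=d.acc_levels)
    if d.year_cols == d.m:
        year_eff = pd.Series(state.beta[off:], index=d.year_levels)
        year_se = pd.Series(state.se_beta[off:], index=d.year_levels)
    else:  # both fixed, reference constraint: last year's deviation is 0
        vals = np.append(state.beta[off:], 0.0)
        year_eff = pd.Series(vals, index=d.year_levels)
        year_se = pd.Series(np.append(state.se_beta[off:], 0.0),
                            index=d.year_levels)

    if d.has_intercept:
        mu_hat = float(state.beta[0])
    elif not d.acc_random:   # accession cell means carry the scale
        mu_hat = float(np.mean(state.alpha))
    else:                    # years fixed carry the scale
        mu_hat = float(np.mean(year_eff))

    s2e_by_year = pd.Series(s2e_group[d.group_of_year], index=d.year_levels)
    df_group = d.group_sizes - state.sum_h_group
    df_by_year = pd.Series(df_group[d.group_of_year], index=d.year_levels)

    ses = {
        "accession": pd.Series(state.se_alpha, index=d.acc_levels),
        "year": year_se,
    }
    if d.has_intercept:
        ses["mu"] = float(state.se_beta[0])

    return FitResult(
        spec=spec,
        mu_hat=mu_hat,
        accession_effects=acc_eff,
        year_effects=year_eff,
        sigma2_g=float(sigma2_g) if sigma2_g is not None else None,
        sigma2_y=float(sigma2_y) if sigma2_y is not None else None,
        sigma2_e_by_year=s2e_by_year,
        residuals=pd.Series(state.resid, index=d.index),
        leverages=pd.Series(state.h, index=d.index),
        effective_df_by_year=df_by_year,
        reml_loglik=float(state.loglik),
        converged=converged,
        n_iter=n_iter,
        standard_errors=ses,
        loglik_trace=trace,
    )


def reml_criterion(records: pd.DataFrame, params: VarianceParams,
                   spec: FitSpec | None = None) -> float:
    """Restricted log-likelihood at explicit variance parameters.

    Fixed effects are profiled out.  Exposed separately from the fitter so
    ascent and parameterization comparisons can be verified directly.
    """
    spec = spec or FitSpec()
    design = _Design(records, spec)
    g = design.n_groups
    if np.isscalar(params.sigma2_e_by_year):
        s2e_group = np.full(g, float(params.sigma2_e_by_year))
    else:
        mapping = dict(params.sigma2_e_by_year)
        s2e_group = np.empty(g)
        for j, year in enumerate(design.year_levels):
            s2e_group[design.group_of_year[j]] = float(mapping[year])
    theta = list(s2e_group)
    if design.acc_random:
        if params.sigma2_g is None:
            raise ValueError("sigma2_g required when accessions are random")
        theta.append(float(params.sigma2_g))
    if design.year_random:
        if params.sigma2_y is None:
            raise ValueError("sigma2_y required when years are random")
        theta.append(float(params.sigma2_y))
    theta = np.asarray(theta, float)
    if (theta <= 0).any():
        raise ValueError("all variances must be > 0")
    return float(_solve(design, theta).loglik)
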