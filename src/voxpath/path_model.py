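"""Recursive observed-variable path model with permutation-null p-values,
jackknife stability certification and two-group invariance testing.

The model is a DAG of regressions among standardized observed variables plus
free covariances among the exogenous block. Residuals are mutually
uncorrelated, so equation-wise least squares on the correlation matrix is the
maximum-likelihood fit; the chi-square statistic compares the sample
covariance with the model-implied covariance in the usual RAM form
``(I - A)^-1 S (I - A)^-T``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "PathModelSpec",
    "PathFit",
    "InvarianceResult",
    "ConvergenceError",
    "build_path_spec",
    "fit_path_model",
    "implied_covariance",
    "ml_chisquare",
    "permutation_pvalues",
    "jackknife_stability",
    "invariance_test",
]

EXOGENOUS_VARS = ("age", "height_cm", "weight_kg", "ratio")
RANGE_VARS = ("speech_range_st", "singing_range_st")
F0_VARS = ("speech_f0_st", "singing_f0_st")
VTL_VARS = ("speech_vtl_cm", "singing_vtl_cm")
OUTCOME_VARS = ("attract_speech", "attract_singing")
FINAL_VAR = "soi_total"


class ConvergenceError(RuntimeError):
    """Raised when the constrained invariance fit fails to converge."""


@dataclass(frozen=True)
class PathModelSpec:
    """Variables, directed regressions and exogenous covariances of a
    recursive path model."""

    variables: tuple[str, ...]
    roles: Mapping[str, str]  # variable -> exogenous|mediator|outcome|final
    regressions: tuple[tuple[str, str], ...]  # (predictor, response)
    covariances: tuple[tuple[str, str], ...]  # undirected exogenous pairs
    mediator_basis: str = "f0"
    groups: str | None = None

    def __post_init__(self) -> None:
        known = set(self.variables)
        for pred, resp in self.regressions:
            if pred not in known or resp not in known:
                raise ValueError(f"regression {pred}->{resp} uses unknown variable")
        for a, b in self.covariances:
            if a not in known or b not in known:
                raise ValueError(f"covariance {a}~~{b} uses unknown variable")
        if self._has_cycle():
            raise ValueError("regression graph is not acyclic")

    def _has_cycle(self) -> bool:
        succ: dict[str, list[str]] = {v: [] for v in self.variables}
        for pred, resp in self.regressions:
            succ[pred].append(resp)
        state: dict[str, int] = {}

        def visit(v: str) -> bool:
            state[v] = 1
            for w in succ[v]:
                s = state.get(w, 0)
                if s == 1 or (s == 0 and visit(w)):
                    return True
            state[v] = 2
            return False

        return any(state.get(v, 0) == 0 and visit(v) for v in self.variables)

    @property
    def param_names(self) -> tuple[str, ...]:
        reg = tuple(f"{resp}~{pred}" for pred, resp in self.regressions)
        cov = tuple(f"{a}~~{b}" for a, b in self.covariances)
        return reg + cov

    @property
    def n_parameters(self) -> int:
        return len(self.regressions) + len(self.covariances)

    @property
    def exogenous(self) -> tuple[str, ...]:
        return tuple(v for v in self.variables if self.roles[v] == "exogenous")

    @property
    def endogenous(self) -> tuple[str, ...]:
        return tuple(v for v in self.variables if self.roles[v] != "exogenous")


@dataclass(frozen=True)
class PathFit:
    """Standardized estimates and inference for a fitted path model."""

    param_names: tuple[str, ...]
    estimates: dict[str, float]
    analytic_p: dict[str, float]
    residual_variances: dict[str, float]
    chi_square: float
    df: int
    n: int
    permutation_p: dict[str, float] | None = None
    stable: dict[str, bool] | None = None


@dataclass(frozen=True)
class InvarianceResult:
    chi2_configural: float
    chi2_invariant: float
    chi2_diff: float
    df_diff: int
    p: float
    n_per_group: dict[str, int]


def build_path_spec(mediator_basis: str = "f0", ratio_kind: str = "wsr") -> PathModelSpec:
    """Default spec: 4 exogenous variables, 4 acoustic mediators, 2
    attractiveness outcomes and the sociosexuality total.

    Mediators are regressed on every exogenous variable (16 edges), each
    attractiveness score on all mediators and all exogenous variables
    (16 edges), and the sociosexuality total on the mediators and both
    attractiveness scores (6 edges): 38 regressions plus the 6 exogenous
    covariances.
    """
    basis = mediator_basis.lower()
    if basis not in ("f0", "vtl"):
        raise ValueError(f"mediator_basis must be 'f0' or 'vtl', got {mediator_basis!r}")
    if ratio_kind.lower() not in ("wsr", "whr"):
        raise ValueError(f"ratio_kind must be 'wsr' or 'whr', got {ratio_kind!r}")
    level = F0_VARS if basis == "f0" else VTL_VARS
    mediators = level + RANGE_VARS
    variables = EXOGENOUS_VARS + mediators + OUTCOME_VARS + (FINAL_VAR,)
    roles = {v: "exogenous" for v in EXOGENOUS_VARS}
    roles.update({v: "mediator" for v in mediators})
    roles.update({v: "outcome" for v in OUTCOME_VARS})
    roles[FINAL_VAR] = "final"

    regressions: list[tuple[str, str]] = []
    for m in mediators:
        regressions.extend((x, m) for x in EXOGENOUS_VARS)
    for out in OUTCOME_VARS:
        regressions.extend((m, out) for m in mediators)
        regressions.extend((x, out) for x in EXOGENOUS_VARS)
    regressions.extend((m, FINAL_VAR) for m in mediators)
    regressions.extend((out, FINAL_VAR) for out in OUTCOME_VARS)

    covariances = [
        (a, b) for i, a in enumerate(EXOGENOUS_VARS) for b in EXOGENOUS_VARS[i + 1 :]
    ]
    return PathModelSpec(
        variables=variables,
        roles=roles,
        regressions=tuple(regressions),
        covariances=tuple(covariances),
        mediator_basis=basis,
    )


# ---------------------------------------------------------------------------
# compiled spec: index arrays for fast (batched) fitting


@dataclass(frozen=True)
class _Compiled:
    var_index: dict[str, int]
    exog_idx: np.ndarray
    endog_idx: np.ndarray
    # equations grouped by identical predictor sets: (pred_idx, resp_idx, slot[k, m])
    eq_groups: tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]
    equations: tuple[tuple[int, np.ndarray, np.ndarray], ...]  # per-response
    cov_i: np.ndarray
    cov_j: np.ndarray
    cov_slots: np.ndarray
    n_params: int


def _compile(spec: PathModelSpec) -> _Compiled:
    idx = {v: i for i, v in enumerate(spec.variables)}
    slots = {name: s for s, name in enumerate(spec.param_names)}
    by_resp: dict[str, list[str]] = {}
    for pred, resp in spec.regressions:
        by_resp.setdefault(resp, []).append(pred)
    equations = []
    grouped: dict[tuple[int, ...], list[int]] = {}
    for resp, preds in by_resp.items():
        p_idx = np.array([idx[p] for p in preds])
        s_idx = np.array([slots[f"{resp}~{p}"] for p in preds])
        equations.append((idx[resp], p_idx, s_idx))
        grouped.setdefault(tuple(p_idx), []).append(idx[resp])
    eq_groups = []
    eq_by_resp = {r: (p, s) for r, p, s in equations}
    for preds, resps in grouped.items():
        pred_arr = np.array(preds)
        resp_arr = np.array(resps)
        slot = np.empty((len(preds), len(resps)), dtype=int)
        for j, r in enumerate(resps):
            slot[:, j] = eq_by_resp[r][1]
        eq_groups.append((pred_arr, resp_arr, slot))
    cov_i = np.array([idx[a] for a, _ in spec.covariances], dtype=int)
    cov_j = np.array([idx[b] for _, b in spec.covariances], dtype=int)
    cov_slots = np.array([slots[f"{a}~~{b}"] for a, b in spec.covariances], dtype=int)
    return _Compiled(
        var_index=idx,
        exog_idx=np.array([idx[v] for v in spec.exogenous], dtype=int),
        endog_idx=np.array([idx[v] for v in spec.endogenous], dtype=int),
        eq_groups=tuple(eq_groups),
        equations=tuple(equations),
        cov_i=cov_i,
        cov_j=cov_j,
        cov_slots=cov_slots,
        n_params=spec.n_parameters,
    )


def _estimates_from_corr(R: np.ndarray, comp: _Compiled) -> np.ndarray:
    """Parameter estimates from (a batch of) correlation matrices.

    ``R`` has shape (..., p, p); returns (..., n_params). Regression
    coefficients solve the normal equations of each equation's predictor
    block; covariance parameters are read off directly.
    """
    out = np.empty(R.shape[:-2] + (comp.n_params,))
    for pred, resp, slot in comp.eq_groups:
        Rxx = R[..., pred[:, None], pred[None, :]]
        Rxy = R[..., pred[:, None], resp[None, :]]
        out[..., slot] = np.linalg.solve(Rxx, Rxy)
    out[..., comp.cov_slots] = R[..., comp.cov_i, comp.cov_j]
    return out


def _residual_variances(R: np.ndarray, est: np.ndarray, comp: _Compiled) -> np.ndarray:
    """Residual variance per endogenous variable, in comp.endog_idx order."""
    endog_pos = {v: k for k, v in enumerate(comp.endog_idx.tolist())}
    psi = np.empty(R.shape[:-2] + (len(comp.endog_idx),))
    for resp, p_idx, s_idx in comp.equations:
        b = est[..., s_idx]
        rxy = R[..., p_idx, resp]
        psi[..., endog_pos[resp]] = R[..., resp, resp] - np.sum(b * rxy, axis=-1)
    return psi


def _implied_sigma(
    est: np.ndarray, psi: np.ndarray, S_exog: np.ndarray, comp: _Compiled, p: int
) -> np.ndarray:
    A = np.zeros((p, p))
    for resp, p_idx, s_idx in comp.equations:
        A[resp, p_idx] = est[s_idx]
    S = np.zeros((p, p))
    S[np.ix_(comp.exog_idx, comp.exog_idx)] = S_exog
    S[comp.endog_idx, comp.endog_idx] = psi
    ImA = np.eye(p) - A
    M = np.linalg.solve(ImA, S)
    sigma = np.linalg.solve(ImA, M.T).T
    return (sigma + sigma.T) / 2.0


def _analytic_pvalues(R: np.ndarray, n: int, comp: _Compiled, est: np.ndarray) -> np.ndarray:
    """Two-sided p-values: t test per OLS coefficient, Pearson t test per
    covariance (correlation) parameter. Operates on one correlation matrix."""
    p_out = np.empty(comp.n_params)
    for resp, p_idx, s_idx in comp.equations:
        k = len(p_idx)
        Rxx = R[np.ix_(p_idx, p_idx)]
        rxy = R[p_idx, resp]
        b = est[s_idx]
        dof = n - k - 1
        if dof < 1:
            raise ValueError(f"not enough observations for equation with {k} predictors")
        sigma2 = max(R[resp, resp] - float(b @ rxy), 0.0) * (n - 1) / dof
        cov_b = sigma2 * np.linalg.inv(Rxx) / (n - 1)
        se = np.sqrt(np.maximum(np.diag(cov_b), 1e-300))
        t = b / se
        p_out[s_idx] = 2.0 * sps.t.sf(np.abs(t), dof)
    r = est[comp.cov_slots]
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p_out[comp.cov_slots] = 2.0 * sps.t.sf(np.abs(t), n - 2)
    return np.minimum(p_out, 1.0)


def _prepare_data(data: pd.DataFrame, spec: PathModelSpec) -> np.ndarray:
    missing = [v for v in spec.variables if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks model variables: {missing}")
    X = data[list(spec.variables)].dropna().to_numpy(dtype=float)
    largest = max(len(p) for _, p, _ in _compile(spec).equations)
    if len(X) <= largest + 2:
        raise ValueError(f"n = {len(X)} too small for equations with {largest} predictors")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [v for v, s in zip(spec.variables, sd) if s == 0]
        raise ValueError(f"constant variables: {bad}")
    return (X - X.mean(axis=0)) / sd


def fit_path_model(data: pd.DataFrame, spec: PathModelSpec) -> PathFit:
    """Fit the model on complete cases: z-score, estimate each equation by
    least squares on the correlation matrix, read exogenous covariances off
    as sample correlations, and compute the ML chi-square against the
    implied covariance."""
    Z = _prepare_data(data, spec)
    n, p = Z.shape
    comp = _compile(spec)
    R = (Z.T @ Z) / (n - 1)
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > 1e10:
        raise ValueError(f"rank-deficient design (condition number {cond:.3g})")
    est = _estimates_from_corr(R, comp)
    psi = _residual_variances(R, est, comp)
    sigma = _implied_sigma(est, psi, R[np.ix_(comp.exog_idx, comp.exog_idx)], comp, p)
    chi2 = ml_chisquare(R, sigma, n)
    # free parameters: structural + every variance (exogenous + residual)
    df = p * (p + 1) // 2 - (comp.n_params + p)
    names = spec.param_names
    return PathFit(
        param_names=names,
        estimates=dict(zip(names, est.tolist())),
        analytic_p=dict(zip(names, _analytic_pvalues(R, n, comp, est).tolist())),
        residual_variances={
            spec.variables[v]: float(psi[k]) for k, v in enumerate(comp.endog_idx.tolist())
        },
        chi_square=chi2,
        df=df,
        n=n,
    )


def implied_covariance(params: Mapping[str, float], spec: PathModelSpec) -> np.ndarray:
    """Model-implied covariance for explicit parameter values.

    ``params`` maps ``"y~x"`` to regression coefficients, ``"a~~b"`` to
    exogenous covariances and ``"v~~v"`` to variances (exogenous variance or
    residual variance; missing variances default to 1).
    """
    idx = {v: i for i, v in enumerate(spec.variables)}
    p = len(spec.variables)
    A = np.zeros((p, p))
    S = np.zeros((p, p))
    known = set(spec.param_names) | {f"{v}~~{v}" for v in spec.variables}
    for name in params:
        if name not in known:
            raise ValueError(f"unknown parameter {name!r} for this spec")
    for pred, resp in spec.regressions:
        A[idx[resp], idx[pred]] = params.get(f"{resp}~{pred}", 0.0)
    for a, b in spec.covariances:
        S[idx[a], idx[b]] = S[idx[b], idx[a]] = params.get(f"{a}~~{b}", 0.0)
    for v in spec.variables:
        S[idx[v], idx[v]] = params.get(f"{v}~~{v}", 1.0)
    ImA = np.eye(p) - A
    M = np.linalg.solve(ImA, S)
    sigma = np.linalg.solve(ImA, M.T).T
    return (sigma + sigma.T) / 2.0


def ml_chisquare(
    sample_cov: np.ndarray, implied_cov: np.ndarray, n: int, p_vars: int | None = None
) -> float:
    """Maximum-likelihood discrepancy chi-square.

    (n - 1) * [log|Sigma| + tr(S Sigma^-1) - log|S| - p]; exactly 0 when the
    matrices coincide. Both matrices must be symmetric positive definite.
    """
    S = np.asarray(sample_cov, dtype=float)
    Sig = np.asarray(implied_cov, dtype=float)
    if S.shape != Sig.shape or S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("sample and implied covariance must be square matrices of equal size")
    p = p_vars if p_vars is not None else S.shape[0]
    try:
        Ls = np.linalg.cholesky(S)
        Lsig = np.linalg.cholesky(Sig)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance matrices must be positive definite") from err
    logdet_S = 2.0 * float(np.sum(np.log(np.diag(Ls))))
    logdet_sig = 2.0 * float(np.sum(np.log(np.diag(Lsig))))
    inv_sig_S = np.linalg.solve(Sig, S)
    f_ml = logdet_sig + float(np.trace(inv_sig_S)) - logdet_S - p
    return (n - 1) * max(f_ml, 0.0)


def permutation_pvalues(
    data: pd.DataFrame,
    spec: PathModelSpec,
    B: int = 10_000,
    seed: int | np.random.Generator | None = None,
    scheme: str = "columns",
    chunk_size: int = 2_000,
) -> dict[str, float]:
    """Monte-Carlo null p-values from model fits on randomized datasets.

    With ``scheme="columns"`` (default) every variable's column is permuted
    independently, destroying all dependencies while preserving marginals;
    ``scheme="joint"`` permutes the endogenous block's rows with one shared
    permutation per replicate, keeping within-block structure intact. The
    two-sided p-value uses the add-one correction (1 + #exceedances)/(B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if scheme not in ("columns", "joint"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = _prepare_data(data, spec)
    n, p = Z.shape
    comp = _compile(spec)
    observed = np.abs(_estimates_from_corr((Z.T @ Z) / (n - 1), comp))
    counts = np.zeros(comp.n_params, dtype=np.int64)
    failures = 0
    done = 0
    while done < B:
        b = min(chunk_size, B - done)
        Zp = np.empty((b, n, p))
        if scheme == "columns":
            for j in range(p):
                idx = rng.permuted(np.broadcast_to(np.arange(n), (b, n)), axis=1)
                Zp[:, :, j] = Z[idx, j]
        else:
            exog = sorted(comp.exog_idx.tolist())
            endog = sorted(comp.endog_idx.tolist())
            Zp[:, :, exog] = Z[:, exog]
            idx = rng.permuted(np.broadcast_to(np.arange(n), (b, n)), axis=1)
            for j in endog:
                Zp[:, :, j] = Z[idx, j]
        Rb = np.einsum("bnp,bnq->bpq", Zp, Zp) / (n - 1)
        try:
            est = _estimates_from_corr(Rb, comp)
            counts += np.sum(np.abs(est) >= observed[None, :], axis=0)
        except np.linalg.LinAlgError:
            for k in range(b):
                try:
                    est_k = _estimates_from_corr(Rb[k], comp)
                    counts += (np.abs(est_k) >= observed).astype(np.int64)
                except np.linalg.LinAlgError:
                    failures += 1
        done += b
    if failures > 0.01 * B:
        raise RuntimeError(f"{failures}/{B} permutation refits failed (> 1%)")
    pvals = (1.0 + counts) / (B + 1.0)
    return dict(zip(spec.param_names, pvals.tolist()))


def jackknife_stability(
    data: pd.DataFrame, spec: PathModelSpec, alpha: float = 0.05
) -> dict[str, bool]:
    """Leave-one-out stability: a parameter is stable iff its analytic
    p-value is below ``alpha`` in the full sample and in every
    leave-one-out refit. A refit failure marks all parameters unstable for
    that subsample."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    Z0 = _prepare_data(data, spec)
    n = len(Z0)
    if n < 10:
        raise ValueError(f"jackknife needs n >= 10, got {n}")
    comp = _compile(spec)

    def _p_of(Z: np.ndarray) -> np.ndarray:
        m = len(Z)
        Zs = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
        R = (Zs.T @ Zs) / (m - 1)
        est = _estimates_from_corr(R, comp)
        return _analytic_pvalues(R, m, comp, est)

    stable = _p_of(Z0) < alpha
    for i in range(n):
        if not stable.any():
            break
        sub = np.delete(Z0, i, axis=0)
        try:
            stable &= _p_of(sub) < alpha
        except (np.linalg.LinAlgError, ValueError):
            stable[:] = False
    return dict(zip(spec.param_names, stable.tolist()))


# ---------------------------------------------------------------------------
# two-group invariance


def _group_corr(data: pd.DataFrame, spec: PathModelSpec, group_var: str):
    if group_var not in data.columns:
        raise ValueError(f"grouping variable {group_var!r} not in data")
    levels = sorted(data[group_var].dropna().unique().tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, found {levels}")
    out = {}
    for lev in levels:
        sub = data.loc[data[group_var] == lev]
        Z = _prepare_data(sub, spec)
        out[lev] = ((Z.T @ Z) / (len(Z) - 1), len(Z))
    return out


def invariance_test(
    data: pd.DataFrame,
    group_var: str,
    spec: PathModelSpec,
    tol: float = 1e-10,
) -> InvarianceResult:
    """Chi-square difference between the configural model (spec fitted freely
    per group) and the path-invariant model (all structural parameters equal
    across groups), with df equal to the number of constrained parameters.

    Both models are fitted to the same within-group correlation matrices, so
    the invariant chi-square can never drop below the configural one.
    """
    comp = _compile(spec)
    groups = _group_corr(data, spec, group_var)
    levels = list(groups)
    p = len(spec.variables)
    n_exog = len(comp.exog_idx)
    n_endog = len(comp.endog_idx)
    n_struct = comp.n_params

    chi2_conf = 0.0
    start_struct = np.zeros(n_struct)
    start_psi = []
    for lev in levels:
        R, n = groups[lev]
        est = _estimates_from_corr(R, comp)
        psi = _residual_variances(R, est, comp)
        sigma = _implied_sigma(est, psi, R[np.ix_(comp.exog_idx, comp.exog_idx)], comp, p)
        chi2_conf += ml_chisquare(R, sigma, n)
        start_struct += est / len(levels)
        start_psi.append(np.maximum(psi, 1e-4))

    n_cov = len(comp.cov_slots)
    reg_slots = np.setdiff1d(np.arange(n_struct), comp.cov_slots)

    # theta layout: [regressions, exog correlations, per-group log exog var,
    #                per-group log residual var]
    def unpack(theta):
        struct = np.empty(n_struct)
        struct[reg_slots] = theta[: len(reg_slots)]
        struct[comp.cov_slots] = theta[len(reg_slots) : len(reg_slots) + n_cov]
        off = len(reg_slots) + n_cov
        pieces = []
        for g in range(2):
            ev = np.exp(theta[off : off + n_exog])
            off += n_exog
            rv = np.exp(theta[off : off + n_endog])
            off += n_endog
            pieces.append((ev, rv))
        return struct, pieces

    cov_rel = comp.cov_i, comp.cov_j  # positions within full variable order

    def objective(theta):
        struct, pieces = unpack(theta)
        total = 0.0
        for g, lev in enumerate(levels):
            R, n = groups[lev]
            ev, rv = pieces[g]
            # exogenous block: shared correlations, group-specific variances
            C = np.eye(n_exog)
            pos = {v: k for k, v in enumerate(comp.exog_idx.tolist())}
            for s, i, j in zip(comp.cov_slots, cov_rel[0], cov_rel[1]):
                C[pos[i], pos[j]] = C[pos[j], pos[i]] = struct[s]
            D = np.sqrt(ev)
            S_exog = C * np.outer(D, D)
            sigma = _implied_sigma(struct, rv, S_exog, comp, p)
            try:
                total += ml_chisquare(R, sigma, n)
            except ValueError:
                return 1e12
        return total

    theta0 = np.concatenate(
        [
            start_struct[reg_slots],
            np.clip(start_struct[comp.cov_slots], -0.98, 0.98),
            np.concatenate([np.zeros(n_exog), np.log(start_psi[0])]),
            np.concatenate([np.zeros(n_exog), np.log(start_psi[1])]),
        ]
    )
    bounds = (
        [(-10.0, 10.0)] * len(reg_slots)
        + [(-0.999, 0.999)] * n_cov
        + [(-8.0, 8.0)] * (2 * (n_exog + n_endog))
    )
    res = optimize.minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 2000, "maxfun": 200_000, "ftol": tol, "gtol": 1e-8},
    )
    if not np.isfinite(res.fun) or res.fun >= 1e11:
        raise ConvergenceError(f"constrained invariance fit failed: {res.message}")
    chi2_inv = float(res.fun)
    diff = max(chi2_inv - chi2_conf, 0.0)
    df_diff = n_struct
    return InvarianceResult(
        chi2_configural=chi2_conf,
        chi2_invariant=max(chi2_inv, chi2_conf),
        chi2_diff=diff,
        df_diff=df_diff,
        p=float(sps.chi2.sf(diff, df_diff)),
        n_per_group={str(lev): groups[lev][1] for lev in levels},
    )
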