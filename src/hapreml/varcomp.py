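"""REML estimation of variance-component mixed models.

The model is

    y = X b + sum_r Z_r u_r + sum_g W g + e,   g ~ MVN(0, K_g s2_g),
    u_r ~ MVN(0, I s2_r),                      e ~ MVN(0, I s2_e),

with X the fixed-effect design (intercept always included), Z_r incidence
matrices of iid non-genetic random effects, and each genetic effect g
correlated through a relationship matrix K_g.  Repeated-measures designs
add a permanent-environment effect: an iid individual-level effect over the
record-level design.

Estimation maximizes the restricted likelihood by average-information (AI)
updates with an EM fallback and step-halving; variances are constrained to
be non-negative, with proposals projected onto the boundary at zero.  The
boundary projection is what makes the mixture chi-squared null distribution
of downstream likelihood-ratio tests correct.

Two fast paths exist and must agree with the general dense path (asserted
by the test suite): an eigendecomposition path for a single genetic
component without iid effects, and a Woodbury low-rank path when every
genetic component carries a low-rank factorisation (regional GRMs do).

The restricted log-likelihood convention, used identically by every path:

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y + (n - p) log 2 pi ].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize, minimize_scalar

from .geno_io import PhenotypeTable, RelationshipMatrix

__all__ = [
    "ModelSpec",
    "VarianceModelFit",
    "reml_fit",
    "restricted_loglik_at",
    "RemlError",
]

log = logging.getLogger(__name__)

MAX_ITER = 200
LOGLIK_TOL = 1e-6
PARAM_TOL = 1e-6


class RemlError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Declarative mixed-model description against a phenotype table."""

    response: str
    fixed_effects: list[str] = field(default_factory=list)
    iid_random_effects: list[str] = field(default_factory=list)
    genetic_components: list[tuple[RelationshipMatrix | None, str]] = field(
        default_factory=list
    )
    repeated: bool = False

    def __post_init__(self) -> None:
        labels = [lab for _, lab in self.genetic_components]
        if len(set(labels)) != len(labels):
            raise ValueError("genetic component labels must be unique")


@dataclass
class VarianceModelFit:
    """REML estimates, restricted log-likelihood and convergence record."""

    variance_estimates: dict[str, float]
    fixed_estimates: pd.Series
    restricted_loglik: float
    converged: bool
    n_iterations: int
    blups: dict[str, np.ndarray] = field(default_factory=dict)
    residuals: np.ndarray | None = None
    iteration_log: list[float] = field(default_factory=list)
    dropped_fixed: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# design assembly

@dataclass
class _Structure:
    """One random term at record level: cov = Z K Z' (K = I when None)."""

    label: str
    Z: np.ndarray              # (n_records, q) incidence
    K: np.ndarray | None       # (q, q) correlation, or None for iid
    loadings: np.ndarray | None  # (n_records, r) with cov = L L'

    def cov(self) -> np.ndarray:
        if self.K is None:
            return self.Z @ self.Z.T
        return self.Z @ self.K @ self.Z.T


@dataclass
class _Problem:
    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    structures: list[_Structure]
    dropped_fixed: list[str]
    record_ids: np.ndarray


def _design_matrix(
    df: pd.DataFrame, fixed_effects: list[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for name in fixed_effects:
        if name not in df.columns:
            raise ValueError(f"fixed-effect column {name!r} absent")
        col = df[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy())
                names.append(c)
    X = np.column_stack(cols)
    # pivoted QR to drop aliased columns
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    dropped = [names[j] for j in piv[rank:]]
    if dropped:
        log.info("dropped aliased fixed-effect columns: %s", dropped)
    return X[:, keep], [names[j] for j in keep], dropped


def _incidence(labels: np.ndarray, levels: np.ndarray) -> np.ndarray:
    lut = {v: j for j, v in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for i, v in enumerate(labels):
        Z[i, lut[v]] = 1.0
    return Z


def _assemble(
    spec: ModelSpec,
    phenotypes: PhenotypeTable,
    matrices: dict[str, RelationshipMatrix] | None = None,
) -> _Problem:
    df = phenotypes.records
    y = df[spec.response].to_numpy(dtype=float)
    X, x_names, dropped = _design_matrix(df, spec.fixed_effects)
    ids = df[phenotypes.id_column].to_numpy()

    structures: list[_Structure] = []
    for matrix, label in spec.genetic_components:
        if matrix is None:
            if matrices is None or label not in matrices:
                raise ValueError(f"no matrix supplied for component {label!r}")
            matrix = matrices[label]
        panel = {v: j for j, v in enumerate(matrix.individual_ids)}
        missing = [i for i in ids if i not in panel]
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped individual(s) absent from GRM "
                f"{label!r}, e.g. {missing[0]!r}"
            )
        rows = np.array([panel[i] for i in ids], dtype=np.intp)
        Z = np.zeros((len(ids), matrix.n_individuals))
        Z[np.arange(len(ids)), rows] = 1.0
        loadings = (
            matrix.loadings[rows] if matrix.loadings is not None else None
        )
        structures.append(_Structure(label, Z, matrix.values, loadings))

    for name in spec.iid_random_effects:
        if name not in df.columns:
            raise ValueError(f"random-effect column {name!r} absent")
        levels = pd.unique(df[name])
        Z = _incidence(df[name].to_numpy(), levels)
        structures.append(_Structure(name, Z, None, Z))

    if spec.repeated:
        levels = pd.unique(ids)
        Z = _incidence(ids, levels)
        structures.append(_Structure("pe", Z, None, Z))

    return _Problem(y, X, x_names, structures, dropped, ids)


# ---------------------------------------------------------------------------
# canonical restricted log-likelihood (dense)

def _loglik_dense(
    y: np.ndarray, X: np.ndarray, covs: list[np.ndarray], theta: np.ndarray
) -> tuple[float, dict]:
    """Exact restricted log-likelihood; theta = (structures..., residual)."""
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for t, C in zip(theta[:-1], covs):
        V += t * C
    try:
        cf = sla.cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise RemlError(f"singular V at theta={theta}") from exc
    logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_y = sla.cho_solve(cf, y)
    Vi_X = sla.cho_solve(cf, X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise RemlError("X' V^-1 X not positive definite")
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    ypy = float(y @ Py)
    ll = -0.5 * (logdet_v + logdet_x + ypy + (n - p) * np.log(2.0 * np.pi))
    return ll, {"cf": cf, "beta": beta, "Py": Py, "Vi_X": Vi_X, "XtViX": XtViX}


def restricted_loglik_at(
    spec: ModelSpec,
    phenotypes: PhenotypeTable,
    variances: dict[str, float],
    matrices: dict[str, RelationshipMatrix] | None = None,
) -> float:
    """Exact restricted log-likelihood at a supplied variance point.

    ``variances`` maps every structure label (and ``"residual"``) to a
    non-negative value; no optimization is performed.
    """
    prob = _assemble(spec, phenotypes, matrices)
    labels = [s.label for s in prob.structures] + ["residual"]
    theta = np.array([float(variances[lab]) for lab in labels])
    if np.any(theta < 0):
        raise ValueError("variances must be non-negative")
    if np.all(theta == 0):
        raise ValueError("all variances zero")
    covs = [s.cov() for s in prob.structures]
    ll, _ = _loglik_dense(prob.y, prob.X, covs, theta)
    return ll


# ---------------------------------------------------------------------------
# general dense AI-REML

def _ai_reml_dense(
    y: np.ndarray, X: np.ndarray, covs: list[np.ndarray]
) -> tuple[np.ndarray, float, bool, int, list[float], list[str]]:
    """AI-REML with EM fallback and boundary projection.

    Correlated components (e.g. SNP and haplotype GRMs of one block) can
    create two boundary corners; when the first run pins a component at 0,
    the iteration is restarted once per pinned component from an interior
    point and the best converged point wins.
    """
    vary = float(np.var(y, ddof=1))
    k = len(covs)
    start = np.full(k + 1, vary / (k + 1))
    theta, ll, conv, it, hist, msgs = _ai_iterate(y, X, covs, start)
    pinned = np.flatnonzero(theta[:-1] == 0.0)
    for i in pinned:
        alt = theta.copy()
        alt[i] = 0.3 * vary
        alt[-1] = max(alt[-1], 0.1 * vary)
        t2, ll2, c2, it2, h2, m2 = _ai_iterate(y, X, covs, alt)
        if ll2 > ll + 1e-10:
            theta, ll, conv, it, hist, msgs = t2, ll2, c2, it2, h2, m2
    return theta, ll, conv, it, hist, msgs


def _ai_iterate(
    y: np.ndarray, X: np.ndarray, covs: list[np.ndarray], start: np.ndarray
) -> tuple[np.ndarray, float, bool, int, list[float], list[str]]:
    n, p = X.shape
    messages: list[str] = []
    vary = float(np.var(y, ddof=1))
    theta = start.copy()
    floor = 1e-10 * vary

    ll, aux = _loglik_dense(y, X, covs, theta)
    history = [ll]
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        cf, Py, Vi_X, XtViX = aux["cf"], aux["Py"], aux["Vi_X"], aux["XtViX"]
        Vi = sla.cho_solve(cf, np.eye(n))
        P = Vi - Vi_X @ np.linalg.solve(XtViX, Vi_X.T)
        all_covs = covs + [np.eye(n)]
        t_vecs = [C @ Py for C in all_covs]
        score = np.array(
            [
                -0.5 * (np.sum(P * C) - Py @ t)
                for C, t in zip(all_covs, t_vecs)
            ]
        )
        AI = 0.5 * np.array([[ti @ P @ tj for tj in t_vecs] for ti in t_vecs])
        # active set: keep boundary components with non-positive score at 0
        free = ~((theta <= 0.0) & (score <= 0.0))
        free[-1] = True
        try:
            cond = np.linalg.cond(AI[np.ix_(free, free)])
            if cond > 1e12:
                msg = (
                    "average-information matrix near-singular: components "
                    "may be aliased (likelihood flat)"
                )
                if msg not in messages:
                    messages.append(msg)
            delta = np.zeros_like(theta)
            delta[free] = np.linalg.solve(AI[np.ix_(free, free)], score[free])
        except np.linalg.LinAlgError:
            delta = None

        def em_step() -> np.ndarray:
            upd = theta.copy()
            for i, (C, t) in enumerate(zip(all_covs, t_vecs)):
                upd[i] = theta[i] + (theta[i] ** 2 / n) * (Py @ t - np.sum(P * C))
            return upd

        proposals = []
        if delta is not None:
            step = 1.0
            for _ in range(6):
                proposals.append(theta + step * delta)
                step *= 0.5
        proposals.append(em_step())

        best = None
        for prop in proposals:
            cand = np.maximum(prop, 0.0)
            cand[-1] = max(cand[-1], floor)
            try:
                cll, caux = _loglik_dense(y, X, covs, cand)
            except RemlError:
                continue
            if best is None or cll > best[0]:
                best = (cll, cand, caux)
            if cll >= ll - 1e-12:
                break
        if best is None:
            messages.append("no admissible update found; stopping")
            break
        new_ll, new_theta, aux = best
        d_ll = new_ll - ll
        d_par = np.max(np.abs(new_theta - theta)) / max(theta.sum(), floor)
        theta, ll = new_theta, new_ll
        history.append(ll)
        if abs(d_ll) < LOGLIK_TOL and d_par < PARAM_TOL:
            converged = True
            break
    return theta, ll, converged, it, history, messages


# ---------------------------------------------------------------------------
# fast path: single genetic component, eigendecomposition

def _fit_single_eig(
    y: np.ndarray, X: np.ndarray, K: np.ndarray
) -> tuple[np.ndarray, float, bool, int]:
    n, p = X.shape
    lam, Q = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    yt, Xt = Q.T @ y, Q.T @ X

    def neg_profile(u: float) -> float:
        gamma = u / (1.0 - u)
        v0 = 1.0 + gamma * lam
        w = 1.0 / v0
        XtWX = Xt.T @ (Xt * w[:, None])
        XtWy = Xt.T @ (yt * w)
        beta = np.linalg.solve(XtWX, XtWy)
        r = yt - Xt @ beta
        ypy0 = float(r @ (r * w))
        sigma = ypy0 / (n - p)
        sign, logdet_x = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            np.sum(np.log(v0)) + logdet_x
            + (n - p) * np.log(sigma) + (n - p)
            + (n - p) * np.log(2.0 * np.pi)
        )
        return -ll

    res = minimize_scalar(neg_profile, bounds=(0.0, 1.0 - 1e-9), method="bounded",
                          options={"xatol": 1e-10})
    candidates = [(neg_profile(0.0), 0.0), (res.fun, float(res.x))]
    fneg, u = min(candidates, key=lambda t: t[0])
    gamma = u / (1.0 - u)
    v0 = 1.0 + gamma * lam
    w = 1.0 / v0
    XtWX = Xt.T @ (Xt * w[:, None])
    beta = np.linalg.solve(XtWX, Xt.T @ (yt * w))
    r = yt - Xt @ beta
    sigma_e = float(r @ (r * w)) / (n - p)
    theta = np.array([gamma * sigma_e, sigma_e])
    return theta, -fneg, True, int(getattr(res, "nit", 0) or 0)


# ---------------------------------------------------------------------------
# fast path: low-rank genetic components (Woodbury, profiled residual)

def _fit_lowrank(
    y: np.ndarray, X: np.ndarray, load_list: list[np.ndarray]
) -> tuple[np.ndarray, float, bool, int]:
    n, p = X.shape
    L = np.hstack(load_list)
    ranks = [l.shape[1] for l in load_list]
    edges = np.cumsum([0] + ranks)
    G = L.T @ L
    Lty = L.T @ y
    LtX = L.T @ X
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def pieces(gam: np.ndarray):
        scale = np.concatenate(
            [np.full(r, np.sqrt(g)) for r, g in zip(ranks, gam)]
        )
        A = np.eye(L.shape[1]) + (scale[:, None] * G) * scale[None, :]
        cf = sla.cho_factor(A, lower=True)
        logdet0 = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Uy = scale * Lty
        UX = scale[:, None] * LtX
        AiUy = sla.cho_solve(cf, Uy)
        AiUX = sla.cho_solve(cf, UX)
        yV0y = yty - Uy @ AiUy
        XV0X = XtX - UX.T @ AiUX
        XV0y = Xty - UX.T @ AiUy
        beta = np.linalg.solve(XV0X, XV0y)
        ypy0 = yV0y - XV0y @ beta
        sign, logdet_x = np.linalg.slogdet(XV0X)
        return logdet0, logdet_x, float(ypy0), beta

    def neg_profile(gam: np.ndarray) -> float:
        logdet0, logdet_x, ypy0, _ = pieces(np.asarray(gam))
        if ypy0 <= 0:
            return np.inf
        sigma = ypy0 / (n - p)
        return 0.5 * (
            logdet0 + logdet_x + (n - p) * np.log(sigma) + (n - p)
            + (n - p) * np.log(2.0 * np.pi)
        )

    # multi-start: correlated components create boundary corners, and a
    # single quasi-Newton run can converge to the worse one
    kc = len(ranks)
    starts = [np.full(kc, 0.1)]
    if kc > 1:
        for i in range(kc):
            s = np.full(kc, 1e-3)
            s[i] = 0.3
            starts.append(s)
    best = None
    nit = 0
    for x0 in starts:
        res = minimize(
            neg_profile, x0, method="L-BFGS-B",
            bounds=[(0.0, None)] * kc,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        nit += int(res.nit)
        if best is None or res.fun < best.fun:
            best = res
    gam = np.maximum(best.x, 0.0)
    _, _, ypy0, _ = pieces(gam)
    sigma_e = ypy0 / (n - p)
    theta = np.concatenate([gam * sigma_e, [sigma_e]])
    return theta, -best.fun, bool(best.success), nit


# ---------------------------------------------------------------------------
# public fit

def reml_fit(
    spec: ModelSpec,
    phenotypes: PhenotypeTable,
    matrices: dict[str, RelationshipMatrix] | None = None,
    compute_blups: bool = True,
    force_general: bool = False,
) -> VarianceModelFit:
    """Fit a variance-component mixed model by REML.

    Chooses the fastest exact path for the problem structure; paths agree
    in restricted log-likelihood to optimizer tolerance.  Boundary variance
    estimates are returned as exact zeros.  Non-convergence within the
    iteration cap is flagged on the result, never silent.
    """
    prob = _assemble(spec, phenotypes, matrices)
    y, X = prob.y, prob.X
    if y.std() == 0:
        raise ValueError("response has zero variance")
    n, p = X.shape
    labels = [s.label for s in prob.structures]
    history: list[float] = []
    messages: list[str] = []

    if not prob.structures:
        # fixed effects + residual only: closed form
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        sigma = float(r @ r) / (n - p)
        theta = np.array([sigma])
        ll, aux = _loglik_dense(y, X, [], theta)
        converged, n_iter = True, 0
    elif (
        not force_general
        and all(s.loadings is not None for s in prob.structures)
        and sum(s.loadings.shape[1] for s in prob.structures) < max(n // 2, 2)
    ):
        loads = [s.loadings for s in prob.structures]
        theta, ll, converged, n_iter = _fit_lowrank(y, X, loads)
        if compute_blups:
            covs = [s.cov() for s in prob.structures]
            ll, aux = _loglik_dense(
                y, X, covs,
                np.maximum(theta, [0.0] * len(covs) + [1e-12 * y.var()]),
            )
        else:
            aux = None
    elif (
        not force_general
        and len(prob.structures) == 1
        and prob.structures[0].K is not None
        and prob.structures[0].Z.shape[0] == prob.structures[0].Z.shape[1]
        and np.array_equal(prob.structures[0].Z, np.eye(n))
    ):
        K = prob.structures[0].K
        theta, ll, converged, n_iter = _fit_single_eig(y, X, K)
        ll, aux = _loglik_dense(y, X, [K], theta)
    else:
        covs = [s.cov() for s in prob.structures]
        theta, ll, converged, n_iter, history, messages = _ai_reml_dense(y, X, covs)
        _, aux = _loglik_dense(y, X, covs, theta)

    variance_estimates = dict(zip(labels + ["residual"], map(float, theta)))
    blups: dict[str, np.ndarray] = {}
    residuals = None
    fixed = pd.Series(dtype=float)
    if aux is not None:
        fixed = pd.Series(aux["beta"], index=prob.x_names)
        if compute_blups:
            Py = aux["Py"]
            fitted_random = np.zeros(n)
            for s, t in zip(prob.structures, theta[:-1]):
                if s.K is None:
                    u = t * (s.Z.T @ Py)
                else:
                    u = t * (s.K @ (s.Z.T @ Py))
                blups[s.label] = u
                fitted_random += s.Z @ u
            residuals = y - X @ aux["beta"] - fitted_random
            blups["_record_ids"] = prob.record_ids

    if not converged:
        messages.append(f"REML did not converge within {MAX_ITER} iterations")

    return VarianceModelFit(
        variance_estimates=variance_estimates,
        fixed_estimates=fixed,
        restricted_loglik=float(ll),
        converged=bool(converged),
        n_iterations=n_iter,
        blups=blups,
        residuals=residuals,
        iteration_log=history,
        dropped_fixed=prob.dropped_fixed,
        messages=messages,
    )
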