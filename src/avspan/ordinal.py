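"""Cumulative-link (mixed) ordinal regression.

The proportional-odds model treats an ordinal response Y with categories
1..K through K-1 strictly increasing thresholds theta_k and a shared linear
predictor eta = x'beta on the logit scale::

    P(Y <= k | x) = logistic(theta_k - eta)

Mixed models add participant-level random effects b_j ~ N(0, Sigma) to eta
(random intercept, optionally a random trial-order slope).  The marginal
likelihood integrates b_j out per participant; here via a Laplace
approximation (inner Newton for the per-participant mode plus a
log-determinant correction), with adaptive Gauss-Hermite quadrature
available for random-intercept-only models.  Thresholds are kept monotone
by parameterizing the first threshold freely and the increments on the log
scale.  Model comparison uses AIC and chi-squared likelihood-ratio tests;
effects are reported as odds ratios, with OR^k giving the multiplicative
odds change over a k-unit covariate change.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "OrdinalFit",
    "fit_clm",
    "fit_clmm",
    "fit_model",
    "lr_test",
    "odds_ratio",
    "compose_odds_ratio",
]


class OrdinalModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# model specification and design matrices

#: columns always expanded as unordered categoricals (treatment coding)
DEFAULT_CATEGORICAL = ("Condition", "Sequence")


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effect term list plus an optional participant random term.

    ``terms`` are tuples of variable names; a tuple of length > 1 is an
    interaction (elementwise product of the expanded pieces).  ``random``
    is ``()`` for none, ``("1",)`` for a random intercept, or
    ``("1", "<var>")`` for correlated intercept + slope, grouped by
    ``group``.
    """

    response: str
    terms: tuple[tuple[str, ...], ...]
    random: tuple[str, ...] = ()
    group: str = "Participant"

    def formula(self) -> str:
        parts = ["1"]
        if self.random:
            parts.append(f"({' + '.join(self.random)}|{self.group})")
        parts.extend(":".join(t) for t in self.terms)
        return f"{self.response} ~ " + " + ".join(parts)

    def with_terms(self, terms) -> "ModelSpec":
        return ModelSpec(self.response, tuple(tuple(t) for t in terms), self.random, self.group)

    def add_term(self, term: Sequence[str]) -> "ModelSpec":
        return self.with_terms(self.terms + (tuple(term),))

    def drop_term(self, term: Sequence[str]) -> "ModelSpec":
        term = tuple(term)
        return self.with_terms(t for t in self.terms if t != term)

    def with_random(self, random: Sequence[str]) -> "ModelSpec":
        return ModelSpec(self.response, self.terms, tuple(random), self.group)


_RANDOM_RE = re.compile(r"\(([^|]+)\|([^)]+)\)")


def parse_formula(formula: str) -> ModelSpec:
    """Parse the small formula grammar.

    Example: ``"per_digit ~ 1 + (1 + Order|Participant) + Order +
    Condition + Condition:PercSoundSupport"``.  Bracketed factor lists
    distribute over interactions: ``Condition:[A + B]`` expands to
    ``Condition:A + Condition:B``.
    """
    if "~" not in formula:
        raise OrdinalModelError("formula needs a '~'")
    lhs, rhs = formula.split("~", 1)
    response = lhs.strip()
    random: tuple[str, ...] = ()
    group = "Participant"
    m = _RANDOM_RE.search(rhs)
    if m:
        random = tuple(p.strip() for p in m.group(1).split("+"))
        group = m.group(2).strip()
        rhs = rhs[: m.start()] + rhs[m.end():]
    # split on '+' only at bracket depth 0
    chunks: list[str] = []
    depth, cur = 0, []
    for ch in rhs:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        if ch == "+" and depth == 0:
            chunks.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    chunks.append("".join(cur))
    terms: list[tuple[str, ...]] = []
    for raw in chunks:
        raw = raw.strip()
        if not raw or raw == "1":
            continue
        pieces = [p.strip() for p in raw.split(":")]
        expanded: list[list[str]] = [[]]
        for p in pieces:
            if p.startswith("[") and p.endswith("]"):
                opts = [o.strip() for o in p[1:-1].split("+")]
            else:
                opts = [p]
            expanded = [e + [o] for e in expanded for o in opts]
        terms.extend(tuple(e) for e in expanded)
    return ModelSpec(response, tuple(terms), random, group)


def _expand_variable(
    data: pd.DataFrame, name: str, categorical: Sequence[str]
) -> list[tuple[str, np.ndarray]]:
    if name not in data.columns:
        raise OrdinalModelError(f"variable {name!r} not in data")
    col = data[name]
    is_cat = (
        name in categorical
        or col.dtype == object
        or isinstance(col.dtype, pd.CategoricalDtype)
        or col.dtype == bool
    )
    if not is_cat:
        return [(name, col.to_numpy(float))]
    levels = sorted(pd.unique(col.astype(str)))
    arr = col.astype(str).to_numpy()
    # first level is the reference
    return [(f"{name}[{lev}]", (arr == lev).astype(float)) for lev in levels[1:]]


def build_design(
    data: pd.DataFrame,
    terms: Sequence[Sequence[str]],
    categorical: Sequence[str] = DEFAULT_CATEGORICAL,
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded fixed-effect design matrix (no intercept column)."""
    names: list[str] = []
    cols: list[np.ndarray] = []
    for term in terms:
        pieces = [_expand_variable(data, v, categorical) for v in term]
        for combo in itertools.product(*pieces):
            names.append(":".join(n for n, _ in combo))
            out = combo[0][1].copy()
            for _, arr in combo[1:]:
                out = out * arr
            cols.append(out)
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return X, names


# ---------------------------------------------------------------------------
# fit container


@dataclass
class OrdinalFit:
    thresholds: np.ndarray
    coefficients: dict[str, float]
    loglik: float
    n_params: int
    aic: float
    converged: bool
    method: str
    n_obs: int
    response_levels: np.ndarray
    spec: ModelSpec | None = None
    re_names: tuple[str, ...] = ()
    re_covariance: np.ndarray | None = None
    vcov_coef: np.ndarray | None = None
    coef_names: tuple[str, ...] = ()
    boundary: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def re_sd(self) -> np.ndarray | None:
        if self.re_covariance is None:
            return None
        return np.sqrt(np.diag(self.re_covariance))

    def wald(self) -> pd.DataFrame:
        """Coefficient table with Wald z statistics and p-values."""
        if self.vcov_coef is None:
            raise OrdinalModelError("fit was run without standard errors")
        beta = np.array([self.coefficients[n] for n in self.coef_names])
        se = np.sqrt(np.clip(np.diag(self.vcov_coef), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"coef": beta, "se": se, "z": z, "p": p, "OR": np.exp(beta)},
            index=list(self.coef_names),
        )

    def wald_p(self, term: str) -> float:
        return float(self.wald().loc[term, "p"])

    def to_dict(self) -> dict:
        return {
            "formula": self.spec.formula() if self.spec else None,
            "method": self.method,
            "thresholds": self.thresholds.tolist(),
            "coefficients": self.coefficients,
            "odds_ratios": {k: float(np.exp(v)) for k, v in self.coefficients.items()},
            "re_names": list(self.re_names),
            "re_covariance": None
            if self.re_covariance is None
            else self.re_covariance.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


# ---------------------------------------------------------------------------
# proportional-odds likelihood kernel

_EPS = 1e-300


def _encode_response(y: pd.Series | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels = np.unique(np.asarray(y))
    if len(levels) < 2:
        raise OrdinalModelError("response needs at least 2 observed categories")
    codes = np.searchsorted(levels, np.asarray(y))
    return codes.astype(np.int64), levels


def _zeta_to_theta(zeta: np.ndarray) -> np.ndarray:
    theta = np.empty_like(zeta)
    theta[0] = zeta[0]
    if len(zeta) > 1:
        theta[1:] = zeta[0] + np.cumsum(np.exp(zeta[1:]))
    return theta


def _theta_to_zeta(theta: np.ndarray) -> np.ndarray:
    zeta = np.empty_like(theta)
    zeta[0] = theta[0]
    if len(theta) > 1:
        zeta[1:] = np.log(np.maximum(np.diff(theta), 1e-6))
    return zeta


def _po_parts(theta: np.ndarray, eta: np.ndarray, codes: np.ndarray):
    """Per-observation loglik and first/second derivatives w.r.t. eta."""
    K = len(theta) + 1
    hi = codes
    lo = codes - 1
    a = np.where(hi <= K - 2, theta[np.minimum(hi, K - 2)] - eta, np.inf)
    b = np.where(lo >= 0, theta[np.maximum(lo, 0)] - eta, -np.inf)
    Fa, Fb = special.expit(a), special.expit(b)
    fa = np.where(np.isfinite(a), Fa * (1 - Fa), 0.0)
    fb = np.where(np.isfinite(b), Fb * (1 - Fb), 0.0)
    pi = np.maximum(Fa - Fb, _EPS)
    ll = np.log(pi)
    u = -(fa - fb) / pi  # d ll / d eta
    # f'(x) = f(x) (1 - 2 F(x))
    dfa = np.where(np.isfinite(a), fa * (1 - 2 * Fa), 0.0)
    dfb = np.where(np.isfinite(b), fb * (1 - 2 * Fb), 0.0)
    w = -((dfa - dfb) / pi - ((fa - fb) / pi) ** 2)  # -d2 ll / d eta2 >= 0
    return ll, u, np.maximum(w, 0.0), (fa, fb, pi)


def _po_loglik_grad(
    params: np.ndarray, X: np.ndarray, codes: np.ndarray, K: int
) -> tuple[float, np.ndarray]:
    """Negative loglik and gradient in the (zeta, beta) parameterization."""
    zeta, beta = params[: K - 1], params[K - 1:]
    theta = _zeta_to_theta(zeta)
    eta = X @ beta if X.shape[1] else np.zeros(len(codes))
    ll, u, _, (fa, fb, pi) = _po_parts(theta, eta, codes)
    g_theta = np.zeros(K - 1)
    hi, lo = codes, codes - 1
    np.add.at(g_theta, np.minimum(hi, K - 2), np.where(hi <= K - 2, fa / pi, 0.0))
    np.add.at(g_theta, np.maximum(lo, 0), np.where(lo >= 0, -fb / pi, 0.0))
    g_beta = X.T @ u if X.shape[1] else np.empty(0)
    # chain rule theta -> zeta
    g_zeta = np.empty(K - 1)
    rev = np.cumsum(g_theta[::-1])[::-1]
    g_zeta[0] = rev[0]
    if K > 2:
        g_zeta[1:] = np.exp(zeta[1:]) * rev[1:]
    return -float(np.sum(ll)), -np.concatenate([g_zeta, g_beta])


def _numeric_hessian(fun, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    p = len(x)
    H = np.zeros((p, p))
    f0 = fun(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = steps[i]
            ej = np.zeros(p); ej[j] = steps[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


def _start_values(codes: np.ndarray, K: int, p: int) -> np.ndarray:
    freq = np.bincount(codes, minlength=K) / len(codes)
    cum = np.clip(np.cumsum(freq)[:-1], 1e-4, 1 - 1e-4)
    theta0 = special.logit(cum)
    return np.concatenate([_theta_to_zeta(theta0), np.zeros(p)])


# ---------------------------------------------------------------------------
# CLM (no random effects)


def fit_clm(
    spec: ModelSpec | str,
    data: pd.DataFrame,
    *,
    categorical: Sequence[str] = DEFAULT_CATEGORICAL,
    se: bool = True,
    gtol: float = 1e-9,
    max_iter: int = 200,
) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit (fixed effects only).

    Quasi-Newton optimization with analytic gradients followed by Newton
    polishing; ``converged`` reflects the gradient max-norm at the optimum.
    """
    if isinstance(spec, str):
        spec = parse_formula(spec)
    if spec.random:
        raise OrdinalModelError("spec has random terms; use fit_clmm")
    codes, levels = _encode_response(data[spec.response])
    K = len(levels)
    X, names = build_design(data, spec.terms, categorical)
    x0 = _start_values(codes, K, X.shape[1])
    res = optimize.minimize(
        _po_loglik_grad,
        x0,
        args=(X, codes, K),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter * 10, "ftol": 1e-14, "gtol": 1e-12},
    )
    x = res.x
    # Newton polish to drive the gradient toward machine precision
    for _ in range(25):
        f, g = _po_loglik_grad(x, X, codes, K)
        if np.max(np.abs(g)) < gtol:
            break
        H = _grad_jacobian(lambda p: _po_loglik_grad(p, X, codes, K)[1], x)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(len(x)), g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(30):
            f_new, _ = _po_loglik_grad(x - t * step, X, codes, K)
            if f_new <= f:
                break
            t /= 2
        x = x - t * step
    f, g = _po_loglik_grad(x, X, codes, K)
    converged = bool(np.max(np.abs(g)) < 1e-6)
    zeta, beta = x[: K - 1], x[K - 1:]
    theta = _zeta_to_theta(zeta)
    vcov_coef = None
    if se:
        H = _numeric_hessian(lambda p: _po_loglik_grad(p, X, codes, K)[0], x)
        vcov = np.linalg.pinv(H)
        vcov_coef = vcov[K - 1:, K - 1:]
    n_params = len(x)
    ll = -f
    return OrdinalFit(
        thresholds=theta,
        coefficients=dict(zip(names, map(float, beta))),
        loglik=ll,
        n_params=n_params,
        aic=-2 * ll + 2 * n_params,
        converged=converged,
        method="clm",
        n_obs=len(codes),
        response_levels=levels,
        spec=spec,
        vcov_coef=vcov_coef,
        coef_names=tuple(names),
        diagnostics={"grad_maxnorm": float(np.max(np.abs(g)))},
    )


def _grad_jacobian(grad_fun, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Forward-difference Jacobian of a gradient (i.e. a Hessian estimate)."""
    p = len(x)
    g0 = grad_fun(x)
    H = np.zeros((p, p))
    for i in range(p):
        xi = x.copy()
        h = eps * max(1.0, abs(x[i]))
        xi[i] += h
        H[:, i] = (grad_fun(xi) - g0) / h
    return (H + H.T) / 2


def predict_category_probs(fit: OrdinalFit, data: pd.DataFrame,
                           categorical: Sequence[str] = DEFAULT_CATEGORICAL) -> np.ndarray:
    """Fixed-effect category probabilities (random effects at zero)."""
    X, names = build_design(data, fit.spec.terms, categorical)
    beta = np.array([fit.coefficients[n] for n in names])
    eta = X @ beta if X.shape[1] else np.zeros(len(data))
    theta = fit.thresholds
    cum = special.expit(theta[None, :] - eta[:, None])
    cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
    return np.diff(cum, axis=1)


# ---------------------------------------------------------------------------
# CLMM: Laplace / adaptive Gauss-Hermite marginal likelihood


class _MarginalLoglik:
    """Callable negative marginal loglik over packed (zeta, beta, psi).

    Random effects live in standardized v-space, b_j = L v_j with L the
    Cholesky factor of Sigma; psi holds log-diagonal entries and the free
    subdiagonal.  Per-group modes are found by damped Newton (vectorized
    across groups) and cached as warm starts between calls.
    """

    def __init__(self, X, codes, K, group_idx, n_groups, Zr, method="laplace", agq_nodes=15):
        self.X, self.codes, self.K = X, codes, K
        self.gi, self.G = group_idx, n_groups
        self.Zr = Zr  # (n, q) raw random design
        self.q = Zr.shape[1]
        self.method = method
        if method == "agq" and self.q != 1:
            raise OrdinalModelError("adaptive quadrature supports random intercepts only")
        self.nodes, self.weights = np.polynomial.hermite.hermgauss(agq_nodes)
        self.v = np.zeros((n_groups, self.q))
        self.n_psi = 1 if self.q == 1 else 3

    def _unpack(self, params):
        K, p = self.K, self.X.shape[1]
        zeta = params[: K - 1]
        beta = params[K - 1: K - 1 + p]
        psi = params[K - 1 + p:]
        if self.q == 1:
            L = np.array([[np.exp(psi[0])]])
        else:
            L = np.array([[np.exp(psi[0]), 0.0], [psi[2], np.exp(psi[1])]])
        return _zeta_to_theta(zeta), beta, L

    def _group_sum(self, x):
        return np.bincount(self.gi, weights=x, minlength=self.G)

    def _inner_mode(self, theta, eta_fixed, ZL):
        """Damped Newton for all group modes simultaneously."""
        v = self.v.copy()
        q = self.q

        def g_value(v):
            eta = eta_fixed + np.einsum("nq,nq->n", ZL, v[self.gi])
            ll, u, w, _ = _po_parts(theta, eta, self.codes)
            gv = self._group_sum(ll) - 0.5 * np.sum(v * v, axis=1)
            return gv, u, w

        gv, u, w = g_value(v)
        for _ in range(100):
            grad = np.stack(
                [self._group_sum(u * ZL[:, l]) for l in range(q)], axis=1
            ) - v
            # 1e-10 target; the scale guard stops once roundoff in the
            # per-group loglik sums dominates the residual gradient
            tol = max(1e-10, 1e-14 * float(np.max(np.abs(gv), initial=1.0)))
            if np.max(np.abs(grad)) < tol:
                break
            A = np.empty((self.G, q, q))
            for l in range(q):
                for m in range(l, q):
                    A[:, l, m] = A[:, m, l] = self._group_sum(w * ZL[:, l] * ZL[:, m])
            H = A + np.eye(q)[None]
            if q == 1:
                step = grad / H[:, 0, :]
            else:
                det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2
                step = np.empty_like(grad)
                step[:, 0] = (H[:, 1, 1] * grad[:, 0] - H[:, 0, 1] * grad[:, 1]) / det
                step[:, 1] = (H[:, 0, 0] * grad[:, 1] - H[:, 0, 1] * grad[:, 0]) / det
            t = np.ones(self.G)
            for _ in range(20):
                v_new = v + t[:, None] * step
                gv_new, u_new, w_new = g_value(v_new)
                worse = gv_new < gv - 1e-12
                if not np.any(worse):
                    break
                t[worse] /= 2
            if np.max(np.abs(t[:, None] * step)) < 1e-12:
                v, gv, u, w = v_new, gv_new, u_new, w_new
                break
            v, gv, u, w = v_new, gv_new, u_new, w_new
        self.v = v
        return v, u, w, gv

    def __call__(self, params) -> float:
        theta, beta, L = self._unpack(params)
        eta_fixed = self.X @ beta if self.X.shape[1] else np.zeros(len(self.codes))
        ZL = self.Zr @ L
        v, u, w, gv = self._inner_mode(theta, eta_fixed, ZL)
        q = self.q
        A = np.empty((self.G, q, q))
        for l in range(q):
            for m in range(l, q):
                A[:, l, m] = A[:, m, l] = self._group_sum(w * ZL[:, l] * ZL[:, m])
        H = A + np.eye(q)[None]
        if self.method == "laplace" or q > 1:
            if q == 1:
                logdet = np.log(H[:, 0, 0])
            else:
                logdet = np.log(H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2)
            return -float(np.sum(gv - 0.5 * logdet))
        # adaptive Gauss-Hermite around the mode, q == 1
        s = 1.0 / np.sqrt(H[:, 0, 0])  # (G,)
        ll_nodes = np.empty((len(self.nodes), self.G))
        for m, (z, wt) in enumerate(zip(self.nodes, self.weights)):
            vm = v + np.sqrt(2.0) * s[:, None] * z
            eta = eta_fixed + ZL[:, 0] * vm[self.gi, 0]
            ll, _, _, _ = _po_parts(theta, eta, self.codes)
            g = self._group_sum(ll) - 0.5 * vm[:, 0] ** 2
            ll_nodes[m] = np.log(wt) + z**2 + g
        group_ll = special.logsumexp(ll_nodes, axis=0) + np.log(
            np.sqrt(2.0) * s
        ) - 0.5 * np.log(2 * np.pi)
        return -float(np.sum(group_ll))


def fit_clmm(
    spec: ModelSpec | str,
    data: pd.DataFrame,
    *,
    categorical: Sequence[str] = DEFAULT_CATEGORICAL,
    method: str = "laplace",
    agq_nodes: int = 15,
    se: bool = True,
    max_iter: int = 200,
    start: OrdinalFit | None = None,
) -> OrdinalFit:
    """Cumulative-link mixed model with participant-level random effects.

    ``method`` is ``"laplace"`` (default) or ``"agq"`` (adaptive
    Gauss-Hermite, random-intercept models only).  A variance estimate
    pinned at the zero boundary is reported via ``boundary``, not raised.
    """
    if isinstance(spec, str):
        spec = parse_formula(spec)
    if not spec.random:
        raise OrdinalModelError("spec has no random terms; use fit_clm")
    if spec.random[0] != "1" or len(spec.random) > 2:
        raise OrdinalModelError("random structure must be (1|g) or (1 + var|g)")
    codes, levels = _encode_response(data[spec.response])
    K = len(levels)
    X, names = build_design(data, spec.terms, categorical)
    groups, group_levels = pd.factorize(data[spec.group], sort=True)
    q = len(spec.random)
    Zr = np.ones((len(codes), q))
    if q == 2:
        Zr[:, 1] = data[spec.random[1]].to_numpy(float)
    problem = _MarginalLoglik(X, codes, K, groups, len(group_levels), Zr,
                              method=method, agq_nodes=agq_nodes)
    if start is not None and start.coef_names == tuple(names):
        x_fixed = np.concatenate(
            [_theta_to_zeta(start.thresholds),
             [start.coefficients[n] for n in names]]
        )
    else:
        clm0 = fit_clm(spec.with_random(()), data, categorical=categorical, se=False)
        x_fixed = np.concatenate(
            [_theta_to_zeta(clm0.thresholds),
             [clm0.coefficients[n] for n in names]]
        )
    if q == 1:
        psi0 = np.array([np.log(0.3)])
    else:
        scale1 = max(np.std(Zr[:, 1]), 1e-8)
        psi0 = np.array([np.log(0.3), np.log(0.1 / scale1), 0.0])
    x0 = np.concatenate([x_fixed, psi0])
    n_fixed = len(x_fixed)
    bounds = [(None, None)] * n_fixed + [(-12.0, 5.0)] * (1 if q == 1 else 2)
    if q == 2:
        bounds.append((None, None))
    res = optimize.minimize(
        problem,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-10, "eps": 1e-6},
    )
    x = res.x
    nll = problem(x)
    theta, beta, L = problem._unpack(x)
    Sigma = L @ L.T
    boundary = bool(np.any(np.exp(x[n_fixed:][:1 if q == 1 else 2]) < 1e-4))
    vcov_coef = None
    if se:
        H = _numeric_hessian(problem, x, eps=1e-4)
        vcov = np.linalg.pinv(H)
        vcov_coef = vcov[K - 1: K - 1 + X.shape[1], K - 1: K - 1 + X.shape[1]]
    n_params = len(x)
    ll = -nll
    re_names = ("(Intercept)",) if q == 1 else ("(Intercept)", spec.random[1])
    return OrdinalFit(
        thresholds=theta,
        coefficients=dict(zip(names, map(float, beta))),
        loglik=ll,
        n_params=n_params,
        aic=-2 * ll + 2 * n_params,
        converged=bool(res.success),
        method=f"clmm-{method}",
        n_obs=len(codes),
        response_levels=levels,
        spec=spec,
        re_names=re_names,
        re_covariance=Sigma,
        vcov_coef=vcov_coef,
        coef_names=tuple(names),
        boundary=boundary,
        diagnostics={"opt_message": str(res.message), "n_groups": len(group_levels)},
    )


def fit_model(spec: ModelSpec | str, data: pd.DataFrame, **kwargs) -> OrdinalFit:
    """Dispatch to :func:`fit_clm` or :func:`fit_clmm` based on the spec."""
    if isinstance(spec, str):
        spec = parse_formula(spec)
    if spec.random:
        return fit_clmm(spec, data, **kwargs)
    kwargs.pop("method", None)
    kwargs.pop("start", None)
    return fit_clm(spec, data, **kwargs)


# ---------------------------------------------------------------------------
# response binning
#
# By default every distinct observed score value is its own ordered
# category.  Fixed-width alternatives coarsen the two fractional scores:
# PerDigit to the nearest 1/5 (its natural resolution for five-digit
# answers) and Distraction into 0.2-wide bins over [-1, 1]; Levenshtein is
# already integer-valued.


def bin_per_digit(values: np.ndarray | pd.Series) -> np.ndarray:
    """PerDigit binned to the nearest fifth: categories 0, 1, ..., 5."""
    v = np.asarray(values, float)
    return np.clip(np.round(v * 5), 0, 5).astype(int)


def bin_distraction(values: np.ndarray | pd.Series) -> np.ndarray:
    """Distraction binned into ten 0.2-wide categories over [-1, 1]."""
    v = np.asarray(values, float)
    return np.clip(np.floor((v + 1.0) / 0.2), 0, 9).astype(int)


# ---------------------------------------------------------------------------
# comparison and effect calculus


def lr_test(fit_small: OrdinalFit, fit_big: OrdinalFit) -> float:
    """Chi-squared likelihood-ratio p-value for nested fits."""
    df = fit_big.n_params - fit_small.n_params
    if df < 0:
        raise OrdinalModelError("fit_big must have more parameters than fit_small")
    if (
        fit_small.spec is not None
        and fit_big.spec is not None
        and fit_small.spec.random == fit_big.spec.random
        and not set(fit_small.spec.terms) <= set(fit_big.spec.terms)
    ):
        raise OrdinalModelError("models are not nested")
    if df == 0:
        return 1.0
    dev = max(2.0 * (fit_big.loglik - fit_small.loglik), 0.0)
    return float(stats.chi2.sf(dev, df))


def odds_ratio(fit: OrdinalFit, term: str, k_units: float = 1.0) -> float:
    """exp(coefficient)^k: multiplicative odds change over k covariate units."""
    if term not in fit.coefficients:
        raise OrdinalModelError(f"term {term!r} not in fit")
    return float(np.exp(fit.coefficients[term]) ** k_units)


def compose_odds_ratio(fit: OrdinalFit, settings: Mapping[str, float]) -> float:
    """Product of per-term OR factors raised to their variable settings.

    For a predictor configuration involving main effects and interactions,
    ``settings`` maps coefficient names to the numeric value each takes
    (indicator terms take 0/1); the result is
    ``prod_t OR(t)^settings[t]``, i.e. exp of the linear predictor offset.
    """
    total = 0.0
    for term, value in settings.items():
        if term not in fit.coefficients:
            raise OrdinalModelError(f"term {term!r} not in fit")
        total += fit.coefficients[term] * value
    return float(np.exp(total))
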