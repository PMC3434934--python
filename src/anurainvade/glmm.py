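"""Binomial logit mixed models with a Laplace-approximated likelihood.

The establishment model is a Bernoulli GLMM: logit P(success) =
x'beta + u_family + u_genus + u_species + u_location, with the three
taxonomic intercepts nested (genus within family, species within genus,
encoded by composite keys so label reuse across families is safe) and
the introduction location crossed.  No overdispersion parameter exists:
the Bernoulli variance is determined by the mean.

Fitting maximizes the Laplace approximation to the marginal likelihood:

  l(beta, theta) = l_cond(u*) - u*' D^-1 u* / 2 - log|D| / 2 - log|H| / 2

where u* is the conditional mode found by an inner penalized IRLS
(Newton) solve, D = diag of per-term variances, and H = Z'WZ + D^-1 is
the negative Hessian at the mode.  The outer problem is quasi-Newton
(L-BFGS-B with finite-difference gradients) over the fixed effects and
the per-term log-SDs; optimizing on the log-SD scale keeps variances
non-negative by construction.  Starting values are fixed (beta = 0,
log-SD = log 0.5) so fits are deterministic.

Wald standard errors for the fixed effects come from the observed
information with the random effects profiled at their modes,
I(beta) = X'WX - X'WZ H^-1 Z'WX, the quantity mixed-model software
conventionally reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special

from .dataset import FACTORS

__all__ = ["RandomStructure", "FitResult", "fit_glmm", "aicc",
           "predict_probability", "build_design", "build_random_terms",
           "LaplaceGLMM", "ConvergenceWarning"]

_LOG_SD_START = np.log(0.5)
_LOG_SD_BOUNDS = (-8.0, 4.0)
_INNER_TOL = 1e-8
_MAX_INNER = 100
_SEPARATION_LIMIT = 15.0


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class RandomStructure:
    """Random-intercept layout: an ordered nesting chain plus crossed terms.

    ``nested=("family", "genus", "species")`` yields intercepts for
    family, genus-within-family and species-within-genus; ``crossed``
    terms (location) get one intercept per level.
    """

    nested: tuple[str, ...] = ("family", "genus", "species")
    crossed: tuple[str, ...] = ("location",)

    @property
    def labels(self) -> tuple[str, ...]:
        nested = tuple(":".join(self.nested[: i + 1]) for i in range(len(self.nested)))
        return nested + tuple(self.crossed)

    @property
    def n_terms(self) -> int:
        return len(self.nested) + len(self.crossed)


@dataclass
class RandomTerm:
    label: str
    codes: np.ndarray  # (n,) int level index per row
    n_levels: int


def build_random_terms(table: pd.DataFrame, rs: RandomStructure) -> list[RandomTerm]:
    """Integer-coded random-effect design, nesting via composite keys."""
    terms: list[RandomTerm] = []
    for depth in range(len(rs.nested)):
        cols = list(rs.nested[: depth + 1])
        key = table[cols].astype(str).agg(":".join, axis=1)
        codes, levels = pd.factorize(key, sort=True)
        terms.append(RandomTerm(":".join(cols), codes.astype(np.intp), len(levels)))
    for col in rs.crossed:
        codes, levels = pd.factorize(table[col].astype(str), sort=True)
        terms.append(RandomTerm(col, codes.astype(np.intp), len(levels)))
    return terms


def build_design(table: pd.DataFrame, factors) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix: intercept plus one column per numeric
    factor and dummy columns (reference level dropped) per categorical.

    ``factors`` may mix column names and 1-10 integer codes; columns are
    ordered by factor code for determinism.  For intentionality the
    reference level is "intentional"; other string factors use their
    first sorted level as reference.
    """
    names = []
    for f in factors:
        names.append(FACTORS[f] if isinstance(f, (int, np.integer)) else str(f))
    unknown = [f for f in names if f not in FACTORS.values()]
    if unknown:
        raise KeyError(f"unknown factor(s): {unknown}")
    names = sorted(set(names), key=lambda f: [k for k, v in FACTORS.items() if v == f][0])

    cols: list[np.ndarray] = [np.ones(len(table))]
    labels: list[str] = ["(Intercept)"]
    for f in names:
        col = table[f]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            ref = "intentional" if f == "intentionality" else levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                labels.append(f"{f}[{lev}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            labels.append(f)
    return np.column_stack(cols), labels


@dataclass
class FitResult:
    """One fitted model: coefficients, variance components, AICc."""

    model_spec: tuple[str, ...]
    coef: pd.Series
    se: pd.Series
    variance_components: pd.DataFrame  # term, variance, sd
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    n_outer_iter: int = 0

    @property
    def spec_code(self) -> str:
        """Factor-code label, e.g. '4+6+7+8+10'; 'intercept_only' for the null model."""
        codes = sorted(
            k for k, v in FACTORS.items() if v in self.model_spec
        )
        return "+".join(str(c) for c in codes) if codes else "intercept_only"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.coef, "se": self.se})


class LaplaceGLMM:
    """Laplace-approximated Bernoulli-logit likelihood for one row set.

    Holds the data and random-effect coding; :meth:`loglik` evaluates
    the approximate marginal log-likelihood at given fixed effects and
    per-term SDs (the quantity the outer optimizer maximizes).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, terms: list[RandomTerm]):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.terms = terms
        self.n, self.p = self.X.shape
        self.offsets = np.cumsum([0] + [t.n_levels for t in terms])
        self.q = int(self.offsets[-1])
        self._u = np.zeros(self.q)  # warm start across evaluations

    # ----- random-effect linear algebra on integer codes ------------------

    def _Zu(self, u: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n)
        for t, off in zip(self.terms, self.offsets):
            out += u[off + t.codes]
        return out

    def _Zt(self, v: np.ndarray) -> np.ndarray:
        out = np.empty(self.q)
        for t, off in zip(self.terms, self.offsets):
            out[off:off + t.n_levels] = np.bincount(t.codes, weights=v,
                                                    minlength=t.n_levels)
        return out

    def _ZtWZ(self, w: np.ndarray) -> np.ndarray:
        H = np.zeros((self.q, self.q))
        T = len(self.terms)
        for a in range(T):
            ta, oa = self.terms[a], self.offsets[a]
            diag = np.bincount(ta.codes, weights=w, minlength=ta.n_levels)
            idx = np.arange(oa, oa + ta.n_levels)
            H[idx, idx] += diag
            for b in range(a + 1, T):
                tb, ob = self.terms[b], self.offsets[b]
                M = np.bincount(ta.codes * tb.n_levels + tb.codes, weights=w,
                                minlength=ta.n_levels * tb.n_levels
                                ).reshape(ta.n_levels, tb.n_levels)
                H[oa:oa + ta.n_levels, ob:ob + tb.n_levels] = M
                H[ob:ob + tb.n_levels, oa:oa + ta.n_levels] = M.T
        return H

    def _var_vec(self, sds: np.ndarray) -> np.ndarray:
        var = np.empty(self.q)
        for t, off, sd in zip(self.terms, self.offsets, sds):
            var[off:off + t.n_levels] = max(float(sd) ** 2, 1e-12)
        return var

    # ----- likelihood pieces ----------------------------------------------

    @staticmethod
    def _cond_loglik(y: np.ndarray, eta: np.ndarray) -> float:
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def _pirls(self, eta_fix: np.ndarray, var_vec: np.ndarray):
        """Newton solve for the conditional mode of u; returns
        (u, chol(H), w) at convergence."""
        u = self._u.copy()

        def penalized(u_):
            eta = eta_fix + self._Zu(u_)
            return self._cond_loglik(self.y, eta) - 0.5 * float(np.sum(u_ ** 2 / var_vec))

        pll = penalized(u)
        chol = None
        for _ in range(_MAX_INNER):
            eta = eta_fix + self._Zu(u)
            mu = special.expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            g = self._Zt(self.y - mu) - u / var_vec
            H = self._ZtWZ(w)
            H[np.diag_indices_from(H)] += 1.0 / var_vec
            chol = linalg.cho_factor(H, lower=True, check_finite=False)
            if np.max(np.abs(g)) < _INNER_TOL:
                break
            step = linalg.cho_solve(chol, g, check_finite=False)
            # step-halving keeps the penalized objective monotone
            for _ in range(30):
                u_new = u + step
                pll_new = penalized(u_new)
                if pll_new >= pll - 1e-12:
                    break
                step *= 0.5
            u, pll = u_new, pll_new
        self._u = u
        return u, chol, pll

    def loglik(self, beta: np.ndarray, sds: np.ndarray) -> float:
        """Laplace marginal log-likelihood at (beta, per-term SDs)."""
        beta = np.asarray(beta, dtype=float)
        sds = np.asarray(sds, dtype=float)
        eta_fix = self.X @ beta
        if self.q == 0:
            return self._cond_loglik(self.y, eta_fix)
        var_vec = self._var_vec(sds)
        u, chol, pll = self._pirls(eta_fix, var_vec)
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        logdet_D = float(np.sum(np.log(var_vec)))
        return pll - 0.5 * logdet_D - 0.5 * logdet_H

    # ----- Wald information ----------------------------------------------

    def fixed_information(self, beta: np.ndarray, sds: np.ndarray) -> np.ndarray:
        """Observed information for beta with u profiled at its mode."""
        eta_fix = self.X @ beta
        if self.q == 0:
            mu = special.expit(eta_fix)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            return (self.X * w[:, None]).T @ self.X
        var_vec = self._var_vec(np.asarray(sds, dtype=float))
        u, chol, _ = self._pirls(eta_fix, var_vec)
        mu = special.expit(eta_fix + self._Zu(u))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        XtWX = (self.X * w[:, None]).T @ self.X
        XtWZ = np.empty((self.p, self.q))
        for j in range(self.p):
            XtWZ[j] = self._Zt(w * self.X[:, j])
        HinvZtWX = linalg.cho_solve(chol, XtWZ.T, check_finite=False)
        return XtWX - XtWZ @ HinvZtWX


def aicc(loglik: float, k: int, n: int) -> float:
    """Second-order AIC: -2*loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_glmm(
    table: pd.DataFrame,
    factors=(),
    rs: RandomStructure | None = RandomStructure(),
    fixed_sds: dict[str, float] | None = None,
    max_outer: int = 200,
) -> FitResult:
    """Fit one candidate model on the analysis table.

    Parameters
    ----------
    table : analysis table with ``outcome``, factor columns, and the
        grouping columns for the random structure.
    factors : factor subset (column names or 1-10 codes); empty for the
        intercept-only model.
    rs : random structure, or None for a plain (no random effect) logit
        fit solved by Newton-IRLS.
    fixed_sds : per-term SDs to pin instead of estimating (term label ->
        SD); an SD of 0 removes that term's contribution, so pinning
        every term at 0 reduces the fit to an ordinary logit GLM.
    """
    X, labels = build_design(table, factors)
    y = table["outcome"].to_numpy(dtype=float)
    n, p = X.shape
    terms = build_random_terms(table, rs) if rs is not None else []
    prob = LaplaceGLMM(X, y, terms)

    fixed_sds = dict(fixed_sds or {})
    unknown = set(fixed_sds) - {t.label for t in terms}
    if unknown:
        raise KeyError(f"fixed_sds names unknown term(s): {sorted(unknown)}")
    free_idx = [i for i, t in enumerate(terms) if t.label not in fixed_sds]
    n_free = len(free_idx)

    k = p + n_free
    if n <= k + 1:
        raise ValueError(f"n={n} too small for k={k} parameters")

    def unpack(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta = params[:p]
        sds = np.empty(len(terms))
        for i, t in enumerate(terms):
            sds[i] = fixed_sds.get(t.label, np.nan)
        sds[free_idx] = np.exp(params[p:])
        return beta, sds

    def nll(params: np.ndarray) -> float:
        beta, sds = unpack(params)
        return -prob.loglik(beta, sds)

    x0 = np.concatenate([np.zeros(p), np.full(n_free, _LOG_SD_START)])
    bounds = [(None, None)] * p + [_LOG_SD_BOUNDS] * n_free
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_outer, "ftol": 1e-11, "gtol": 1e-6, "maxfun": 100000},
    )
    beta, sds = unpack(res.x)

    # Polish the no-random-effect case to full Newton accuracy so it agrees
    # with an IRLS GLM to ~1e-10.
    if not terms or all(s <= 1e-6 for s in sds):
        beta = _newton_glm(X, y, beta)
        res.x[:p] = beta

    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success or grad_norm < 1e-2)
    if not converged:
        warnings.warn(
            f"model {factors} did not converge ({res.message})", ConvergenceWarning,
            stacklevel=2,
        )
    if np.any(np.abs(beta) > _SEPARATION_LIMIT):
        warnings.warn(
            f"possible complete separation in model {factors}: "
            f"max |coef| = {np.max(np.abs(beta)):.1f}", ConvergenceWarning,
            stacklevel=2,
        )

    loglik = prob.loglik(beta, sds)
    info = prob.fixed_information(beta, sds)
    try:
        cov = linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except linalg.LinAlgError:  # pragma: no cover - singular information
        se = np.full(p, np.nan)

    vc = pd.DataFrame({
        "term": [t.label for t in terms],
        "variance": [float(s) ** 2 for s in sds],
        "sd": [float(s) for s in sds],
    })
    spec = tuple(lbl for lbl in
                 sorted({FACTORS[f] if isinstance(f, (int, np.integer)) else str(f)
                         for f in factors},
                        key=lambda f: [c for c, v in FACTORS.items() if v == f][0]))
    return FitResult(
        model_spec=spec,
        coef=pd.Series(beta, index=labels),
        se=pd.Series(se, index=labels),
        variance_components=vc,
        loglik=float(loglik),
        k=k,
        n=n,
        aicc=aicc(float(loglik), k, n),
        converged=converged,
        n_outer_iter=int(res.nit),
    )


def _newton_glm(X: np.ndarray, y: np.ndarray, beta0: np.ndarray,
                tol: float = 1e-12, max_iter: int = 100) -> np.ndarray:
    """Plain logit GLM by Newton-IRLS (used when all variances are zero)."""
    beta = beta0.copy()
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        g = X.T @ (y - mu)
        if np.max(np.abs(g)) < tol:
            break
        H = (X * w[:, None]).T @ X
        beta = beta + linalg.solve(H, g, assume_a="pos")
    return beta


def predict_probability(fit: FitResult, covariates: dict,
                        at_random_modes_or_zero: bool = False) -> float:
    """Population-level establishment probability for one covariate set.

    Random effects are set to zero (the population level); covariates
    maps factor name -> value, with intentionality given as its level
    string.  Every fitted factor must be supplied.
    """
    eta = float(fit.coef["(Intercept)"])
    for f in fit.model_spec:
        if f not in covariates:
            raise KeyError(f"missing covariate {f!r}")
        value = covariates[f]
        if f in fit.coef.index:
            eta += float(fit.coef[f]) * float(value)
        else:  # categorical: find the dummy for this level (reference -> 0)
            label = f"{f}[{value}]"
            dummies = [c for c in fit.coef.index if c.startswith(f"{f}[")]
            if not dummies:
                raise KeyError(f"missing covariate column for {f!r}")
            if label in fit.coef.index:
                eta += float(fit.coef[label])
    return float(special.expit(eta))
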