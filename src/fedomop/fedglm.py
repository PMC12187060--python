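"""Exact federated GLM fitting by summed IRLS sufficient statistics.

Iteratively reweighted least squares solves, at each iteration,

    (XᵀWX) β_{t+1} = XᵀWz,      W = diag(w_i),  z the working response,

and both XᵀWX and XᵀWz are plain sums over rows.  Rows partitioned across
sites therefore contribute additively: each site returns only its p×p
information matrix, length-p score vector, deviance and row count, the
client sums them, solves, and broadcasts the new β.  The federated fit is
*algebraically identical* to pooling the data — not an approximation — which
is the property this module exists to deliver and which the test-suite
verifies against an independent reference implementation.

Families: binomial with logit link (μ = 1/(1+e^{-Xβ}), w = μ(1-μ),
z = Xβ + (y-μ)/w, deviance = -2Σ[y log μ + (1-y) log(1-μ)]) and gaussian
with identity link (w = 1, z = y, deviance = RSS), for which IRLS collapses
to the normal equations in one step.

Inference is Wald: SE = √diag((ΣXᵀWX)⁻¹) at convergence, OR = e^β with
CI e^{β ± z₀.₉₇₅·SE}, p = 2(1-Φ(|β/SE|)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .errors import DataError, RankDeficiencyError, UsageError

__all__ = [
    "FAMILIES",
    "GLMSpec",
    "GLMResult",
    "parse_formula",
    "irls_local_contribution",
    "pooled_glm_fit",
    "fed_fit",
]

FAMILIES = ("binomial_logit", "gaussian_identity")

#: clamp for fitted probabilities; keeps the working weights finite without
#: perturbing any well-separated fit
_MU_EPS = 1e-10


@dataclass(frozen=True)
class GLMSpec:
    """What to fit: outcome, additive predictors, family, stopping rule."""

    outcome: str
    predictors: tuple[str, ...]
    family: str = "binomial_logit"
    tolerance: float = 1e-8
    max_iterations: int = 25

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise UsageError(f"unknown family '{self.family}'; choose from {FAMILIES}")
        if self.tolerance <= 0:
            raise UsageError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise UsageError("max_iterations must be >= 1")

    @property
    def term_names(self) -> tuple[str, ...]:
        return ("(Intercept)",) + tuple(self.predictors)


def parse_formula(text: str) -> tuple[str, tuple[str, ...]]:
    """Parse ``outcome ~ pred1 + pred2 + ...`` (additive terms, implicit
    intercept; ``outcome ~ 1`` is intercept-only)."""
    if text.count("~") != 1:
        raise UsageError(f"formula must contain exactly one '~': {text!r}")
    lhs, rhs = (side.strip() for side in text.split("~"))
    if not lhs:
        raise UsageError("formula lacks an outcome")
    terms = [t.strip() for t in rhs.split("+") if t.strip()]
    if not terms:
        raise UsageError("formula lacks a right-hand side (use '1' for intercept-only)")
    predictors = tuple(t for t in terms if t != "1")
    return lhs, predictors


@dataclass
class GLMResult:
    """Fit summary: coefficients with Wald inference.

    ``odds_ratios``/CI bounds are populated for the binomial family only.
    """

    term_names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    deviance: float
    iterations: int
    converged: bool
    n_total: int
    family: str
    odds_ratios: Optional[np.ndarray] = None
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        out = {
            "schema_version": 1,
            "family": self.family,
            "n_total": int(self.n_total),
            "deviance": float(self.deviance),
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
            "terms": [],
        }
        for i, name in enumerate(self.term_names):
            term = {
                "name": name,
                "coefficient": float(self.coefficients[i]),
                "standard_error": float(self.standard_errors[i]),
                "p_value": float(self.p_values[i]),
            }
            if self.odds_ratios is not None:
                term["odds_ratio"] = float(self.odds_ratios[i])
                term["ci_low"] = float(self.ci_low[i])
                term["ci_high"] = float(self.ci_high[i])
            out["terms"].append(term)
        return out


def irls_local_contribution(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, family: str = "binomial_logit"
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """One partition's IRLS sufficient statistics at the current β.

    Returns ``(XᵀWX, XᵀWz, deviance, n)``.  These are the only quantities a
    site ever discloses per iteration, and they sum exactly across any
    partition of the rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    beta = np.asarray(beta, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[1] != beta.shape[0]:
        raise UsageError("X, y and beta have inconsistent shapes")

    eta = X @ beta
    if family == "binomial_logit":
        if not np.all((y == 0) | (y == 1)):
            raise DataError("binomial outcome must be coded 0/1")
        mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        deviance = -2.0 * float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))
    elif family == "gaussian_identity":
        w = np.ones_like(y)
        z = y
        deviance = float(np.sum((y - eta) ** 2))
    else:
        raise UsageError(f"unknown family '{family}'")

    info = X.T @ (w[:, None] * X)
    score = X.T @ (w * z)
    return info, score, deviance, int(X.shape[0])


def _solve_information(info: np.ndarray, score: np.ndarray, term_names) -> np.ndarray:
    """Solve info·β = score, raising a named rank-deficiency error when the
    summed information matrix is singular."""
    _check_rank(info, term_names)
    return np.linalg.solve(info, score)


def _check_rank(info: np.ndarray, term_names) -> None:
    s = np.linalg.svd(info, compute_uv=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-12:
        u, s_full, vt = np.linalg.svd(info)
        null = vt[s_full / max(s_full[0], 1e-300) < 1e-12]
        involved = sorted(
            {term_names[j] for v in null for j in np.nonzero(np.abs(v) > 1e-8)[0]}
        )
        raise RankDeficiencyError(involved or list(term_names))


def _irls(
    contribution: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray, float, int]],
    p: int,
    spec: GLMSpec,
) -> tuple[np.ndarray, np.ndarray, float, int, int, bool]:
    """Shared client-side IRLS loop.

    ``contribution(beta)`` returns already-summed (info, score, deviance, n);
    for a pooled fit that is one local computation, for a federated fit the
    elementwise sum of the site payloads.  Both therefore walk the same
    arithmetic path, which is what makes single-site federation bit-for-bit
    equal to pooling.

    Stops when |dev_t - dev_{t-1}| / (|dev_t| + 0.1) < tolerance.
    """
    beta = np.zeros(p)
    dev_prev: Optional[float] = None
    deviance = 0.0
    iterations = 0
    converged = False
    info = np.zeros((p, p))
    n_total = 0
    for _ in range(spec.max_iterations + 1):
        info, score, deviance, n_total = contribution(beta)
        if dev_prev is not None and abs(deviance - dev_prev) / (abs(deviance) + 0.1) < spec.tolerance:
            converged = True
            break
        dev_prev = deviance
        if iterations >= spec.max_iterations:
            break
        beta_new = _solve_information(info, score, spec.term_names)
        if not np.array_equal(beta_new, beta):
            iterations += 1
        beta = beta_new
    return beta, info, deviance, n_total, iterations, converged


def _summarize(
    beta: np.ndarray,
    info: np.ndarray,
    deviance: float,
    n_total: int,
    iterations: int,
    converged: bool,
    spec: GLMSpec,
) -> GLMResult:
    _check_rank(info, spec.term_names)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    zval = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p_values = 2.0 * norm.sf(np.abs(zval))
    result = GLMResult(
        term_names=spec.term_names,
        coefficients=beta,
        standard_errors=se,
        p_values=p_values,
        deviance=float(deviance),
        iterations=iterations,
        converged=converged,
        n_total=n_total,
        family=spec.family,
    )
    if spec.family == "binomial_logit":
        zcrit = norm.ppf(0.975)
        result.odds_ratios = np.exp(beta)
        result.ci_low = np.exp(beta - zcrit * se)
        result.ci_high = np.exp(beta + zcrit * se)
    return result


def pooled_glm_fit(X: np.ndarray, y: np.ndarray, spec: GLMSpec) -> GLMResult:
    """Fit on physically concatenated data — the single-site scenario.

    Runs the identical IRLS loop as :func:`fed_fit` with a single local
    contribution, so it doubles as the in-repo oracle for the federated path.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    p = len(spec.term_names)
    if X.shape[1] != p:
        raise UsageError(
            f"design matrix has {X.shape[1]} columns but the spec names {p} terms "
            "(including the intercept)"
        )

    def contribution(beta: np.ndarray):
        return irls_local_contribution(X, y, beta, spec.family)

    return _summarize(*_irls(contribution, p, spec), spec=spec)


def fed_fit(sites: Sequence, symbol: str, spec: GLMSpec) -> GLMResult:
    """Fit across sites, exchanging only aggregate payloads.

    Each iteration requests every site's (XᵀWX, XᵀWz, deviance, n) at the
    current β — computed by :func:`irls_local_contribution` against the
    server-held ``symbol`` table, behind each site's disclosure checks — sums
    them elementwise in site order, and solves for the next β.
    """
    # local import: federation builds on this module's payload contract
    from .federation import ModelRequest, site_aggregate

    if not sites:
        raise UsageError("fed_fit needs at least one site")
    p = len(spec.term_names)

    def contribution(beta: np.ndarray):
        info = np.zeros((p, p))
        score = np.zeros(p)
        deviance = 0.0
        n_total = 0
        for site in sites:
            payload = site_aggregate(site, ModelRequest(symbol=symbol, spec=spec, beta=beta))
            info = info + payload.info_matrix
            score = score + payload.score_vector
            deviance = deviance + payload.deviance
            n_total += payload.n_obs
        return info, score, deviance, n_total

    return _summarize(*_irls(contribution, p, spec), spec=spec)
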