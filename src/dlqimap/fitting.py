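"""Maximum-likelihood estimation of the per-domain proportional-odds models.

The log-likelihood of the cumulative-logit model (see :mod:`dlqimap.olr` for
the sign convention) is maximized on the unconstrained parameterization
``(a1, log(a2 - a1), slopes)`` so the threshold ordering a1 < a2 holds by
construction.  Optimization is quasi-Newton (L-BFGS-B with analytic
gradients) started from the empirical cumulative logits with zero slopes,
followed by a few Newton polish steps using a finite-difference Hessian, so
fits are deterministic and sharp (gradient max-norm target 1e-8).  Standard
errors come from the inverse observed information at the optimum.

Model comparisons follow the likelihood-ratio recipe: twice the absolute
difference in maximized log-likelihoods referred to the chi-square
distribution with df equal to the difference in the number of free slope
terms.  The proportional-odds assumption is checked with the test for
parallelism: the same likelihood-ratio construction against a generalized
cumulative model that allows a separate slope vector per threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, log_expit

from .instruments import EQ5D_DOMAINS
from .io import AGE_COL, DLQI_COLS, EQ5D_COLS, SEX_COL, dlqi_item_matrix
from .olr import DomainModel

GRADIENT_TOL = 1e-8

#: Named covariate sets.  ``none`` (intercept-only) is mostly useful for
#: closed-form checks and null models.
COVARIATE_SETS = {
    "none": (),
    "age_sex": (AGE_COL, SEX_COL),
    "dlqi": DLQI_COLS,
    "age_sex_dlqi": (AGE_COL, SEX_COL) + DLQI_COLS,
}


class DegenerateOutcomeError(ValueError):
    """All subjects fall in a single outcome category; nothing to fit."""


class NonConvergenceError(RuntimeError):
    """The optimizer failed to reach the gradient tolerance."""


class NotComputableError(ValueError):
    """A test's preconditions are not met (e.g. empty top category)."""


class DegenerateThresholdWarning(UserWarning):
    """A threshold is non-estimable because a category is (nearly) empty."""


class ParallelismReliabilityWarning(UserWarning):
    """Few top-category subjects make the parallelism test unreliable."""


@dataclass
class FitResult:
    """Outcome of one proportional-odds fit.

    ``params`` holds the natural parameters ``(a1, a2, slopes...)`` and
    ``covariance`` the matching inverse observed information (None when the
    fit was degenerate).  ``neg2_loglik`` is -2 x the maximized
    log-likelihood and is always >= 0.
    """

    model: DomainModel
    neg2_loglik: float
    params: np.ndarray
    param_names: list[str]
    covariance: Optional[np.ndarray]
    se: Optional[np.ndarray]
    n_used: int
    converged: bool
    iterations: int
    domain: str
    covariate_set: str
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class LrTestResult:
    """A likelihood-ratio comparison."""

    chi_square: float
    df: int
    p_value: float
    warning: Optional[str] = None


# ---------------------------------------------------------------------------
# Likelihood and gradients
# ---------------------------------------------------------------------------


def _po_nll_grad(a1, a2, b, X, masks):
    """Negative log-likelihood and gradient in natural parameters.

    ``masks`` is the (m1, m2, m3) triple of boolean outcome masks.  Requires
    a2 > a1.  Returns (nll, d/da1, d/da2, d/db).
    """
    m1, m2, m3 = masks
    Z = X @ b if X.shape[1] else np.zeros(X.shape[0])
    eta1 = a1 - Z
    eta2 = a2 - Z
    c1 = expit(eta1)
    c2 = expit(eta2)
    logp1 = log_expit(eta1)
    logp3 = log_expit(-eta2)
    # log p2 = log(sigma(eta2) - sigma(eta1)), stable because eta2-eta1 = a2-a1 > 0
    with np.errstate(divide="ignore"):
        logp2 = log_expit(eta2) + log_expit(-eta1) + np.log(-np.expm1(eta1 - eta2))
    nll = -(logp1[m1].sum() + logp2[m2].sum() + logp3[m3].sum())

    g_a1 = np.zeros_like(Z)
    g_a2 = np.zeros_like(Z)
    g_Z = np.zeros_like(Z)
    # y = 1: log sigma(eta1)
    g_a1[m1] = 1.0 - c1[m1]
    g_Z[m1] = -(1.0 - c1[m1])
    # y = 2: log(c2 - c1)
    p2 = np.exp(logp2)
    w2 = 1.0 / np.maximum(p2, 1e-300)
    d1 = c1 * (1.0 - c1)
    d2 = c2 * (1.0 - c2)
    g_a1[m2] = -d1[m2] * w2[m2]
    g_a2[m2] = d2[m2] * w2[m2]
    g_Z[m2] = (d1[m2] - d2[m2]) * w2[m2]
    # y = 3: log(1 - c2)
    g_a2[m3] = -c2[m3]
    g_Z[m3] = c2[m3]

    grad_b = -(X.T @ g_Z) if X.shape[1] else np.zeros(0)
    return nll, -g_a1.sum(), -g_a2.sum(), grad_b


def _po_objective(theta, X, masks):
    """Objective in the unconstrained (a1, log-gap, slopes) parameterization."""
    a1 = theta[0]
    gap = np.exp(theta[1])
    nll, ga1, ga2, gb = _po_nll_grad(a1, a1 + gap, theta[2:], X, masks)
    grad = np.concatenate(([ga1 + ga2, ga2 * gap], gb))
    return nll, grad


def _binary_nll_grad(a, b, X, m_low):
    """Cumulative-logit likelihood with a single threshold (two categories).

    ``m_low`` marks subjects in the lower category; P(low) = sigma(a - Z).
    """
    Z = X @ b if X.shape[1] else np.zeros(X.shape[0])
    eta = a - Z
    c = expit(eta)
    nll = -(log_expit(eta)[m_low].sum() + log_expit(-eta)[~m_low].sum())
    g = np.where(m_low, 1.0 - c, -c)  # d loglik / d a
    grad_b = X.T @ g if X.shape[1] else np.zeros(0)  # d loglik/db = -g*x summed
    return nll, -g.sum(), grad_b


def _fd_gradient_hessian(grad_fn, x, eps=1e-5):
    """Symmetrized finite-difference Hessian of a function given its gradient."""
    p = len(x)
    H = np.empty((p, p))
    for j in range(p):
        h = eps * max(1.0, abs(x[j]))
        xp = x.copy()
        xp[j] += h
        xm = x.copy()
        xm[j] -= h
        H[:, j] = (grad_fn(xp) - grad_fn(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def _minimize_with_polish(fun_grad, x0, max_newton=10, gtol=GRADIENT_TOL):
    """L-BFGS-B followed by Newton polish steps on a smooth objective.

    Returns (x, nll, grad, n_iter).  Newton steps use a finite-difference
    Hessian of the analytic gradient and are halved until they do not
    increase the objective.
    """
    res = optimize.minimize(
        fun_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10, "maxcor": 25},
    )
    x, (nll, grad) = res.x, fun_grad(res.x)
    iters = res.nit
    for _ in range(max_newton):
        if np.max(np.abs(grad)) <= gtol:
            break
        H = _fd_gradient_hessian(lambda v: fun_grad(v)[1], x)
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -grad, rcond=None)[0]
        scale = 1.0
        for _ in range(30):
            x_new = x + scale * step
            nll_new, grad_new = fun_grad(x_new)
            if np.isfinite(nll_new) and nll_new <= nll + 1e-12:
                break
            scale *= 0.5
        else:
            break
        x, nll, grad = x_new, nll_new, grad_new
        iters += 1
    return x, nll, grad, iters


# ---------------------------------------------------------------------------
# Data extraction
# ---------------------------------------------------------------------------


def _design(cohort: pd.DataFrame, covariate_set: str) -> tuple[np.ndarray, list[str]]:
    try:
        cols = COVARIATE_SETS[covariate_set]
    except KeyError:
        raise ValueError(
            f"unknown covariate set {covariate_set!r}; choose from {sorted(COVARIATE_SETS)}"
        ) from None
    n = len(cohort)
    if not cols:
        return np.empty((n, 0)), []
    parts = []
    for c in cols:
        if c in DLQI_COLS:
            parts.append(cohort[c].to_numpy(dtype=float, na_value=0.0))
        else:
            parts.append(cohort[c].to_numpy(dtype=float))
    return np.column_stack(parts), list(cols)


def _complete_cases(cohort: pd.DataFrame, domain: str, covariate_set: str) -> pd.DataFrame:
    """Rows usable for fitting: outcome present, age/sex present when used.

    Missing DLQI items are scored zero by the instrument rule, so they never
    exclude a subject here.
    """
    ycol = EQ5D_COLS[domain]
    if ycol not in cohort.columns:
        raise ValueError(f"cohort has no observed column for domain {domain!r}")
    keep = cohort[ycol].notna()
    for c in COVARIATE_SETS[covariate_set]:
        if c not in DLQI_COLS:
            keep &= cohort[c].notna()
    return cohort.loc[keep]


def _build_domain_model(
    domain: str, a1: float, a2: float, b: np.ndarray, colnames: list[str],
    se: Optional[np.ndarray],
) -> DomainModel:
    """Place the fitted slopes into the full 12-covariate layout.

    Covariates absent from the fitted set get coefficient 0 (and no SE)."""
    b_full = {name: 0.0 for name in (AGE_COL, SEX_COL) + DLQI_COLS}
    se_full = {name: None for name in b_full}
    for j, name in enumerate(colnames):
        b_full[name] = float(b[j])
        if se is not None:
            se_full[name] = float(se[2 + j])
    return DomainModel(
        domain=domain,
        a1=a1,
        a2=a2,
        b_age=b_full[AGE_COL],
        b_sex=b_full[SEX_COL],
        b_items=tuple(b_full[c] for c in DLQI_COLS),
        se_a1=None if se is None else float(se[0]),
        se_a2=None if se is None or not np.isfinite(a2) else float(se[1]),
        se_b_age=se_full[AGE_COL],
        se_b_sex=se_full[SEX_COL],
        se_b_items=tuple(se_full[c] for c in DLQI_COLS)
        if se is not None
        else None,
    )


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------


def fit_proportional_odds(
    cohort: pd.DataFrame,
    domain: str,
    covariate_set: str = "age_sex_dlqi",
    gtol: float = GRADIENT_TOL,
) -> FitResult:
    """Fit one EQ-5D domain by maximum likelihood.

    Deterministic given the data: empirical-cumulative-logit start, no random
    initialization.  Raises :class:`DegenerateOutcomeError` when all subjects
    share one category and :class:`NonConvergenceError` on separation (the
    likelihood keeps improving without the gradient vanishing).  When an
    extreme category is empty the corresponding threshold is non-estimable:
    the fit degrades to a two-category cumulative model, the threshold is
    reported infinite and a :class:`DegenerateThresholdWarning` is issued.
    """
    if domain not in EQ5D_DOMAINS:
        raise ValueError(f"unknown EQ-5D domain {domain!r}")
    data = _complete_cases(cohort, domain, covariate_set)
    y = data[EQ5D_COLS[domain]].to_numpy(dtype=float).astype(int)
    X, colnames = _design(data, covariate_set)
    n = len(y)
    counts = np.array([(y == k).sum() for k in (1, 2, 3)])
    if (counts > 0).sum() <= 1:
        raise DegenerateOutcomeError(
            f"{domain}: all {n} subjects in one outcome category (counts={counts.tolist()})"
        )

    # Column scaling for optimizer conditioning; undone on the way out.
    scale = X.std(axis=0) if X.shape[1] else np.empty(0)
    scale[scale == 0] = 1.0
    Xs = X / scale if X.shape[1] else X

    fit_warnings: list[str] = []
    if counts[2] == 0 or counts[0] == 0 or counts[1] == 0:
        return _fit_degenerate(
            domain, covariate_set, y, Xs, scale, colnames, counts, n, gtol, fit_warnings
        )

    masks = (y == 1, y == 2, y == 3)
    cum = np.cumsum(counts) / n
    a1_0 = float(np.log(cum[0] / (1 - cum[0])))
    a2_0 = float(np.log(cum[1] / (1 - cum[1])))
    theta0 = np.concatenate(([a1_0, np.log(max(a2_0 - a1_0, 1e-2))], np.zeros(X.shape[1])))

    theta, nll, grad, iters = _minimize_with_polish(
        lambda t: _po_objective(t, Xs, masks), theta0, gtol=gtol
    )
    converged = bool(np.max(np.abs(grad)) <= max(gtol, 1e-6))
    if not converged:
        raise NonConvergenceError(
            f"{domain}: optimizer stalled with gradient max-norm "
            f"{np.max(np.abs(grad)):.3e} (possible separation; "
            f"category counts {counts.tolist()})"
        )

    a1 = theta[0]
    a2 = a1 + np.exp(theta[1])
    b_scaled = theta[2:]
    b = b_scaled / scale if X.shape[1] else b_scaled

    # Observed information in natural (a1, a2, b_scaled) space, then transform.
    def natural_grad(p):
        nll_, ga1, ga2, gb = _po_nll_grad(p[0], p[1], p[2:], Xs, masks)
        return np.concatenate(([ga1, ga2], gb))

    x_nat = np.concatenate(([a1, a2], b_scaled))
    H = _fd_gradient_hessian(natural_grad, x_nat)
    cov_scaled = np.linalg.pinv(H)
    J = np.diag(np.concatenate(([1.0, 1.0], 1.0 / scale))) if X.shape[1] else np.eye(2)
    cov = J @ cov_scaled @ J
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    model = _build_domain_model(domain, float(a1), float(a2), b, colnames, se)
    return FitResult(
        model=model,
        neg2_loglik=2.0 * nll,
        params=np.concatenate(([a1, a2], b)),
        param_names=["a1", "a2"] + colnames,
        covariance=cov,
        se=se,
        n_used=n,
        converged=converged,
        iterations=iters,
        domain=domain,
        covariate_set=covariate_set,
        warnings=fit_warnings,
    )


def _fit_degenerate(
    domain, covariate_set, y, Xs, scale, colnames, counts, n, gtol, fit_warnings
):
    """Two-category fallback when an outcome category is empty."""
    if counts[2] == 0:
        msg = (
            f"{domain}: no level-3 responses; threshold a2 non-estimable "
            "(reported as +inf)"
        )
        m_low = y == 1
        a_name = "a1"
    elif counts[0] == 0:
        msg = (
            f"{domain}: no level-1 responses; threshold a1 non-estimable "
            "(reported as -inf)"
        )
        m_low = y == 2
        a_name = "a2"
    else:
        msg = (
            f"{domain}: no level-2 responses; threshold gap non-estimable "
            "(single threshold fitted between levels 1 and 3)"
        )
        m_low = y == 1
        a_name = "mid"
    warnings.warn(msg, DegenerateThresholdWarning, stacklevel=3)
    fit_warnings.append(msg)

    def obj(theta):
        nll, ga, gb = _binary_nll_grad(theta[0], theta[1:], Xs, m_low)
        return nll, np.concatenate(([ga], gb))

    p_low = m_low.mean()
    a0 = float(np.log(p_low / (1 - p_low)))
    theta0 = np.concatenate(([a0], np.zeros(Xs.shape[1])))
    theta, nll, grad, iters = _minimize_with_polish(obj, theta0, gtol=gtol)
    converged = bool(np.max(np.abs(grad)) <= max(gtol, 1e-6))
    a = float(theta[0])
    b = theta[1:] / scale if Xs.shape[1] else theta[1:]

    def natural_grad(p):
        nll_, ga, gb = _binary_nll_grad(p[0], p[1:], Xs, m_low)
        return np.concatenate(([ga], gb))

    H = _fd_gradient_hessian(natural_grad, theta)
    cov_small = np.linalg.pinv(H)
    # Embed into (a1, a2, b) layout; the missing threshold has no SE.
    p = Xs.shape[1]
    cov = np.full((p + 2, p + 2), np.nan)
    se = np.full(p + 2, np.nan)
    se_small = np.sqrt(np.clip(np.diag(cov_small), 0.0, None))
    a_idx = 1 if a_name == "a2" else 0
    se[a_idx] = se_small[0]
    se[2:] = se_small[1:] / scale if p else se_small[1:]

    if a_name == "a1":
        a1, a2 = a, np.inf
    elif a_name == "a2":
        a1, a2 = -np.inf, a
    else:  # no level-2 responses: both thresholds collapse onto one cut point
        a1, a2 = a, a + 1e-6
    model = _build_domain_model(domain, a1, a2, b, colnames, se)
    return FitResult(
        model=model,
        neg2_loglik=2.0 * nll,
        params=np.concatenate(([a1, a2], b)),
        param_names=["a1", "a2"] + colnames,
        covariance=cov,
        se=se,
        n_used=n,
        converged=converged,
        iterations=iters,
        domain=domain,
        covariate_set=covariate_set,
        warnings=fit_warnings,
    )


def neg2_loglik(model: DomainModel, cohort: pd.DataFrame, domain: str) -> float:
    """-2 x log-likelihood of a given model on observed domain responses.

    Agrees with ``FitResult.neg2_loglik`` when evaluated at the fitted
    optimum.  An observed outcome assigned probability zero yields +inf with
    a warning.
    """
    data = _complete_cases(cohort, domain, "age_sex_dlqi")
    y = data[EQ5D_COLS[domain]].to_numpy(dtype=float).astype(int)
    age = data[AGE_COL].to_numpy(dtype=float)
    sex = data[SEX_COL].to_numpy(dtype=float)
    items = dlqi_item_matrix(data)
    Z = model.b_age * age + model.b_sex * sex + items @ np.asarray(model.b_items)
    from .olr import cumulative_probabilities

    p1, p2, p3 = cumulative_probabilities(model.a1, model.a2, Z)
    probs = np.choose(y - 1, [p1, p2, p3])
    if np.any(probs <= 0):
        warnings.warn(
            f"{domain}: observed outcome with probability 0 under the model; "
            "-2LL is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return float(-2.0 * np.log(probs).sum())


def lr_test(reduced: FitResult, full: FitResult) -> LrTestResult:
    """Likelihood-ratio test of nested covariate sets on the same data.

    chi-square = |(-2LL reduced) - (-2LL full)|, df = difference in free
    slope terms, p from the chi-square upper tail.
    """
    n_red = len(COVARIATE_SETS[reduced.covariate_set])
    n_full = len(COVARIATE_SETS[full.covariate_set])
    nested = set(COVARIATE_SETS[reduced.covariate_set]) <= set(
        COVARIATE_SETS[full.covariate_set]
    )
    if not nested or n_red == n_full:
        raise ValueError(
            f"covariate set {reduced.covariate_set!r} is not strictly nested in "
            f"{full.covariate_set!r}"
        )
    if reduced.domain != full.domain:
        raise ValueError("fits compare different domains")
    if reduced.n_used != full.n_used:
        raise ValueError(
            "fits used different numbers of subjects; restrict to common "
            "complete cases before fitting"
        )
    chi = abs(reduced.neg2_loglik - full.neg2_loglik)
    df = n_full - n_red
    return LrTestResult(chi_square=chi, df=df, p_value=float(stats.chi2.sf(chi, df)))


# ---------------------------------------------------------------------------
# Test for parallelism (proportional-odds assumption)
# ---------------------------------------------------------------------------


def _gen_nll_grad(theta, X, masks):
    """Generalized cumulative model: separate slope vector per threshold.

    theta = (a1, a2, b1, b2) with p slopes each.  Cumulative probabilities
    may cross inside the covariate hull; category-2 probabilities are floored
    at 1e-12 during the search (the optimum, started from the parallel fit,
    stays in the valid region for well-posed data).
    """
    m1, m2, m3 = masks
    p = X.shape[1]
    a1, a2 = theta[0], theta[1]
    b1 = theta[2 : 2 + p]
    b2 = theta[2 + p :]
    eta1 = a1 - X @ b1
    eta2 = a2 - X @ b2
    c1 = expit(eta1)
    c2 = expit(eta2)
    logp1 = log_expit(eta1)
    logp3 = log_expit(-eta2)
    d = eta2 - eta1
    with np.errstate(divide="ignore", invalid="ignore"):
        logp2 = np.where(
            d > 0,
            log_expit(eta2) + log_expit(-eta1) + np.log(-np.expm1(-np.abs(d))),
            -np.inf,
        )
    logp2 = np.maximum(logp2, np.log(1e-12))
    nll = -(logp1[m1].sum() + logp2[m2].sum() + logp3[m3].sum())

    p2 = np.exp(logp2)
    w2 = 1.0 / p2
    d1 = c1 * (1.0 - c1)
    d2 = c2 * (1.0 - c2)

    g_a1 = np.zeros_like(eta1)
    g_a2 = np.zeros_like(eta1)
    g_Z1 = np.zeros_like(eta1)
    g_Z2 = np.zeros_like(eta1)
    g_a1[m1] = 1.0 - c1[m1]
    g_Z1[m1] = -(1.0 - c1[m1])
    g_a1[m2] = -d1[m2] * w2[m2]
    g_Z1[m2] = d1[m2] * w2[m2]
    g_a2[m2] = d2[m2] * w2[m2]
    g_Z2[m2] = -d2[m2] * w2[m2]
    g_a2[m3] = -c2[m3]
    g_Z2[m3] = c2[m3]

    grad = np.concatenate(
        ([-g_a1.sum(), -g_a2.sum()], -(X.T @ g_Z1), -(X.T @ g_Z2))
    )
    return nll, grad


def test_parallelism(
    cohort: pd.DataFrame,
    domain: str,
    covariate_set: str = "age_sex_dlqi",
    top_category_floor: int = 30,
    po_fit: Optional[FitResult] = None,
) -> LrTestResult:
    """Likelihood-ratio test of the proportional-odds assumption.

    Compares the proportional-odds fit against a generalized cumulative model
    with a separate slope vector per threshold; df = number of slope
    parameters.  When the top-category count falls below
    ``top_category_floor`` the result carries an explicit reliability warning
    (the sub-model splitting {1,2} from {3} is then unstable).

    Pass ``po_fit`` to reuse an existing proportional-odds fit on the same
    cohort/domain/covariates.
    """
    data = _complete_cases(cohort, domain, covariate_set)
    y = data[EQ5D_COLS[domain]].to_numpy(dtype=float).astype(int)
    n_top = int((y == 3).sum())
    if n_top == 0:
        raise NotComputableError(
            f"{domain}: no level-3 responses; parallelism test not computable"
        )
    if po_fit is None:
        po_fit = fit_proportional_odds(cohort, domain, covariate_set)
    elif po_fit.domain != domain or po_fit.covariate_set != covariate_set:
        raise ValueError("po_fit does not match the requested domain/covariates")

    X, _ = _design(data, covariate_set)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale
    masks = (y == 1, y == 2, y == 3)
    p = X.shape[1]

    b_scaled = po_fit.params[2:] * scale
    theta0 = np.concatenate(
        ([po_fit.params[0], po_fit.params[1]], b_scaled, b_scaled)
    )
    theta, nll, grad, _ = _minimize_with_polish(
        lambda t: _gen_nll_grad(t, Xs, masks), theta0, gtol=1e-6
    )
    neg2_gen = 2.0 * nll
    chi = max(po_fit.neg2_loglik - neg2_gen, 0.0)
    p_value = float(stats.chi2.sf(chi, p))

    warning = None
    if n_top < top_category_floor:
        warning = (
            f"only {n_top} subjects in the top outcome category "
            f"(< {top_category_floor}); parallelism test unreliable"
        )
        warnings.warn(warning, ParallelismReliabilityWarning, stacklevel=2)
    # Post-fit crossing check: cumulative curves must not cross in-sample.
    eta1 = theta[0] - Xs @ theta[2 : 2 + p]
    eta2 = theta[1] - Xs @ theta[2 + p :]
    if np.any(eta2 <= eta1):
        msg = "generalized model's cumulative probabilities cross inside the data"
        warnings.warn(msg, UserWarning, stacklevel=2)
        warning = msg if warning is None else warning + "; " + msg
    return LrTestResult(chi_square=chi, df=p, p_value=p_value, warning=warning)


# ---------------------------------------------------------------------------
# Item-domain association screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationTable:
    """Spearman rank correlations of each DLQI item with each EQ-5D domain.

    ``statistic`` and ``p_value`` are 10 x 5 DataFrames (rows dlqi1..dlqi10,
    columns in canonical domain order); constant columns yield NaN entries.
    ``method`` records the chosen association statistic.
    """

    statistic: pd.DataFrame
    p_value: pd.DataFrame
    method: str = "spearman"


def item_domain_association(cohort: pd.DataFrame) -> AssociationTable:
    """Rank-based association screen between DLQI items and EQ-5D domains.

    Complete cases only (all five domains observed); missing DLQI items are
    scored zero per the instrument rule.  Two-sided p-values, no
    multiple-testing adjustment.
    """
    cols = [EQ5D_COLS[d] for d in EQ5D_DOMAINS]
    keep = cohort[cols].notna().all(axis=1)
    data = cohort.loc[keep]
    items = dlqi_item_matrix(data)
    rho = pd.DataFrame(index=list(DLQI_COLS), columns=list(EQ5D_DOMAINS), dtype=float)
    pval = rho.copy()
    for j, d in enumerate(EQ5D_DOMAINS):
        y = data[cols[j]].to_numpy(dtype=float)
        for i, item_col in enumerate(DLQI_COLS):
            x = items[:, i]
            if np.all(x == x[0]) or np.all(y == y[0]):
                rho.loc[item_col, d] = np.nan
                pval.loc[item_col, d] = np.nan
                continue
            res = stats.spearmanr(x, y)
            rho.loc[item_col, d] = res.statistic
            pval.loc[item_col, d] = res.pvalue
    return AssociationTable(statistic=rho, p_value=pval)
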