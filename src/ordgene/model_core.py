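"""Cumulative-link (proportional-odds) ordinal regression for a single covariate.

The model
---------
For an ordered response ``Y`` taking values ``0, ..., k`` (``k + 1`` levels,
e.g. control plus increasing neuropathological grades) and a scalar covariate
``x`` (log-scale expression of one gene), the cumulative-link model with the
proportional-odds assumption is

.. math::

    P(Y \\le i \\mid x) = F(\\alpha_i - \\beta x), \\qquad i = 1, \\dots, k,

where ``F`` is the link CDF (standard Gaussian for the probit link, the
default), the ``k`` intercepts ``alpha_1 < ... < alpha_k`` are the latent
category boundaries, and the single slope ``beta`` is shared across all
boundaries.  Equivalently, a latent variable ``z* = beta * x + eps`` with
``eps ~ N(0, 1)`` is thresholded at the ``alpha_i``.  Under this sign
convention ``beta > 0`` means the expected grade rises with expression.

Parameters are estimated by direct maximum likelihood (quasi-Newton with an
analytic gradient, followed by Newton polishing), standard errors come from
the inverse observed information, and each parameter gets a two-tailed Wald
z-test against zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit, ndtr, ndtri

_log = logging.getLogger(__name__)

_SQRT_2PI = np.sqrt(2.0 * np.pi)

__all__ = [
    "InvalidParameterError",
    "LinkSpec",
    "LINKS",
    "get_link",
    "OrdinalPhenotype",
    "CumulativeLinkFit",
    "cumulative_probability",
    "negative_log_likelihood",
    "fit_cumulative_link",
]


class InvalidParameterError(ValueError):
    """Model parameters violate their constraints (e.g. unordered intercepts)."""


def _probit_pdf(x):
    return np.exp(-0.5 * np.square(x)) / _SQRT_2PI


def _logit_pdf(x):
    p = expit(x)
    return p * (1.0 - p)


def _logit_ppf(q):
    q = np.asarray(q, dtype=float)
    return np.log(q) - np.log1p(-q)


@dataclass(frozen=True)
class LinkSpec:
    """A cumulative-link specification: a strictly increasing CDF on (0, 1)."""

    name: str
    cdf: Callable
    pdf: Callable
    ppf: Callable


LINKS = {
    "probit": LinkSpec("probit", ndtr, _probit_pdf, ndtri),
    "logit": LinkSpec("logit", expit, _logit_pdf, _logit_ppf),
}


def get_link(link) -> LinkSpec:
    """Resolve a link given by name (``"probit"``/``"logit"``) or as a LinkSpec."""
    if isinstance(link, LinkSpec):
        return link
    try:
        return LINKS[link]
    except KeyError:
        raise ValueError(f"unknown link {link!r}; available: {sorted(LINKS)}") from None


@dataclass
class OrdinalPhenotype:
    """Per-sample ordered category labels coded as integers ``0..k``.

    Parameters
    ----------
    sample_ids : sequence of str
        One identifier per sample.
    grades : array-like of int
        Integer category per sample, coded ``0..k``.
    level_labels : sequence of str, optional
        Ordered display names for the ``k + 1`` levels.  If omitted, generic
        names are generated from the observed maximum grade.
    """

    sample_ids: Sequence[str]
    grades: np.ndarray
    level_labels: Sequence[str] | None = None

    def __post_init__(self):
        grades = np.asarray(self.grades)
        if grades.ndim != 1:
            raise ValueError("grades must be one-dimensional")
        if grades.size and not np.all(np.equal(np.mod(grades, 1), 0)):
            raise ValueError("grades must be integers")
        grades = grades.astype(int)
        if len(self.sample_ids) != grades.size:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {grades.size} grades"
            )
        if grades.size and grades.min() < 0:
            raise ValueError("grades must be non-negative")
        if np.unique(grades).size < 2:
            raise ValueError("at least 2 distinct ordinal levels are required")
        if self.level_labels is None:
            self.level_labels = [f"level_{i}" for i in range(grades.max() + 1)]
        if grades.size and grades.max() >= len(self.level_labels):
            raise ValueError(
                f"grade {grades.max()} out of range for "
                f"{len(self.level_labels)} level labels"
            )
        self.grades = grades
        self.sample_ids = list(self.sample_ids)

    @property
    def n_levels(self) -> int:
        return len(self.level_labels)

    @property
    def k(self) -> int:
        """Number of category boundaries (``n_levels - 1``)."""
        return self.n_levels - 1

    def level_counts(self) -> np.ndarray:
        return np.bincount(self.grades, minlength=self.n_levels)


@dataclass
class CumulativeLinkFit:
    """MLE of the cumulative-link model for one gene.

    ``z_values`` / ``p_values`` are ordered as ``(alpha_1, ..., alpha_k, beta)``;
    ``p_values[-1]`` is the slope test.
    """

    alphas: np.ndarray
    beta: float
    se_alphas: np.ndarray
    se_beta: float
    z_values: np.ndarray
    p_values: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    separated: bool = False
    link: str = "probit"
    message: str = ""

    @property
    def k(self) -> int:
        return len(self.alphas)

    @property
    def params(self) -> np.ndarray:
        return np.append(self.alphas, self.beta)

    @property
    def p_slope(self) -> float:
        return float(self.p_values[-1])

    @property
    def p_max(self) -> float:
        return float(np.max(self.p_values))


def _check_alphas(alphas: np.ndarray) -> np.ndarray:
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    if alphas.size > 1 and np.any(np.diff(alphas) <= 0):
        raise InvalidParameterError(
            f"intercepts must be strictly increasing, got {alphas}"
        )
    return alphas


def cumulative_probability(alphas, beta, x, level_index, link="probit"):
    """``P(Y <= level_index | x) = F(alpha_i - beta * x)``.

    ``level_index`` is 1-based (``1..k``); it indexes the category boundary,
    so the returned probability is non-decreasing in ``level_index``.
    """
    alphas = _check_alphas(alphas)
    lk = get_link(link)
    if not 1 <= level_index <= alphas.size:
        raise ValueError(f"level_index must be in 1..{alphas.size}, got {level_index}")
    x = np.asarray(x, dtype=float)
    return lk.cdf(alphas[level_index - 1] - beta * x)


def _category_probabilities(alphas, beta, x, lk: LinkSpec) -> np.ndarray:
    """n x (k+1) matrix of P(Y = j | x_i)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    eta = alphas[None, :] - beta * x[:, None]
    cdf = lk.cdf(eta)
    n = x.size
    upper = np.hstack([cdf, np.ones((n, 1))])
    lower = np.hstack([np.zeros((n, 1)), cdf])
    return upper - lower


def negative_log_likelihood(params, x_vector, grades, link="probit") -> float:
    """Exact negative log-likelihood ``-sum_i log P(Y = y_i | x_i)``.

    ``params`` is the flat vector ``(alpha_1, ..., alpha_k, beta)``.  Returns
    ``+inf`` (not an exception) when any observed category has probability
    exactly zero at the given parameters.
    """
    params = np.asarray(params, dtype=float)
    alphas = _check_alphas(params[:-1])
    beta = float(params[-1])
    lk = get_link(link)
    x = np.asarray(x_vector, dtype=float)
    y = np.asarray(grades, dtype=int)
    probs = _category_probabilities(alphas, beta, x, lk)
    p_obs = probs[np.arange(y.size), y]
    if np.any(p_obs <= 0.0):
        return float("inf")
    return float(-np.sum(np.log(p_obs)))


# ---------------------------------------------------------------------------
# MLE internals
# ---------------------------------------------------------------------------

_CLIP = 1e-300


def _make_nll_grad_natural(x, y, k, lk: LinkSpec, clip=1e-12):
    """Build a clipped NLL+gradient evaluator in (alpha_1..alpha_k, beta).

    Index structures depending only on the data are precomputed once; the
    returned callable is what the per-gene optimizer iterates on.
    """
    n = x.size
    idx_u = np.flatnonzero(y != k)  # samples whose upper boundary is alpha_{y+1}
    idx_l = np.flatnonzero(y != 0)  # samples whose lower boundary is alpha_y
    a_u = y[idx_u]          # alpha index (0-based) of the upper boundary
    a_l = y[idx_l] - 1      # alpha index of the lower boundary
    x_u = x[idx_u]
    x_l = x[idx_l]

    def nll_grad(alphas, beta):
        eta_u = alphas[a_u] - beta * x_u
        eta_l = alphas[a_l] - beta * x_l
        cdf_u = np.ones(n)
        cdf_u[idx_u] = lk.cdf(eta_u)
        cdf_l = np.zeros(n)
        cdf_l[idx_l] = lk.cdf(eta_l)
        p = np.maximum(cdf_u - cdf_l, clip)
        nll = -np.sum(np.log(p))
        pdf_u = np.zeros(n)
        pdf_u[idx_u] = lk.pdf(eta_u)
        pdf_l = np.zeros(n)
        pdf_l[idx_l] = lk.pdf(eta_l)
        inv_p = 1.0 / p
        grad = np.empty(k + 1)
        grad[:k] = np.bincount(a_l, weights=pdf_l[idx_l] * inv_p[idx_l],
                               minlength=k) - np.bincount(
            a_u, weights=pdf_u[idx_u] * inv_p[idx_u], minlength=k
        )
        grad[k] = np.sum(x * (pdf_u - pdf_l) * inv_p)
        return nll, grad

    return nll_grad


def _nll_grad_natural(alphas, beta, x, y, k, lk: LinkSpec, clip=1e-12):
    """Clipped NLL and analytic gradient in (alpha_1..alpha_k, beta)."""
    return _make_nll_grad_natural(x, y, k, lk, clip)(np.asarray(alphas, float), beta)


def _theta_to_natural(theta, k):
    """theta = (alpha_1, log gap_2..log gap_k, beta) -> (alphas, beta)."""
    alphas = np.empty(k)
    alphas[0] = theta[0]
    if k > 1:
        alphas[1:] = theta[0] + np.cumsum(np.exp(theta[1:k]))
    return alphas, float(theta[k])


def _objective(theta, nll_grad, k):
    alphas, beta = _theta_to_natural(theta, k)
    nll, g_nat = nll_grad(alphas, beta)
    g = np.empty(k + 1)
    g[0] = np.sum(g_nat[:k])
    for m in range(1, k):
        g[m] = np.exp(theta[m]) * np.sum(g_nat[m:k])
    g[k] = g_nat[k]
    return nll, g


def _initial_theta(y, k, lk: LinkSpec):
    n = y.size
    cum = np.cumsum(np.bincount(y, minlength=k + 1))[:k] / n
    cum = np.clip(cum, 0.5 / n, 1 - 0.5 / n)
    alphas = lk.ppf(cum)
    gaps = np.maximum(np.diff(alphas), 1e-3)
    theta = np.empty(k + 1)
    theta[0] = alphas[0]
    theta[1:k] = np.log(gaps)
    theta[k] = 0.0
    return theta


def _hessian_fd(fun_grad, point, step=1e-5):
    """Central finite-difference Hessian from an analytic gradient."""
    m = point.size
    hess = np.empty((m, m))
    for j in range(m):
        h = step * max(1.0, abs(point[j]))
        up = point.copy()
        dn = point.copy()
        up[j] += h
        dn[j] -= h
        _, g_up = fun_grad(up)
        _, g_dn = fun_grad(dn)
        hess[:, j] = (g_up - g_dn) / (2 * h)
    return 0.5 * (hess + hess.T)


def fit_cumulative_link(
    x_vector,
    grades,
    link="probit",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> CumulativeLinkFit:
    """Maximum-likelihood fit of the cumulative-link model for one gene.

    Parameters
    ----------
    x_vector : array-like of float
        Covariate (expression) per sample; must not be constant.
    grades : array-like of int
        Ordinal response per sample.  Observed levels are recoded to a
        contiguous ``0..k`` internally (unobserved boundary intercepts are not
        identifiable).
    link : str or LinkSpec
        ``"probit"`` (default) or ``"logit"``.
    tol : float
        Convergence tolerance on the gradient infinity norm.
    max_iter : int
        Iteration cap for the quasi-Newton stage.

    Returns
    -------
    CumulativeLinkFit
        With Wald ``z`` and two-tailed normal ``p`` per parameter.  On
        non-convergence ``converged=False``; on (quasi-)separation the fit is
        flagged ``separated=True`` and all p-values are set to the
        conservative value 1.
    """
    x = np.asarray(x_vector, dtype=float)
    y_raw = np.asarray(grades, dtype=int)
    if x.ndim != 1 or x.size != y_raw.size:
        raise ValueError("x_vector and grades must be 1-D and equal length")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite covariate values")
    levels = np.unique(y_raw)
    if levels.size < 2:
        raise ValueError("need at least 2 observed ordinal levels")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: the slope is not identifiable")
    # recode observed levels to contiguous 0..k
    y = np.searchsorted(levels, y_raw)
    k = levels.size - 1
    lk = get_link(link)
    n = x.size

    nll_grad = _make_nll_grad_natural(x, y, k, lk)
    fun_grad = lambda th: _objective(th, nll_grad, k)
    theta0 = _initial_theta(y, k, lk)
    res = optimize.minimize(
        fun_grad,
        theta0,
        jac=True,
        method="BFGS",
        options={"gtol": tol, "maxiter": max_iter},
    )
    theta = res.x
    nll, grad = fun_grad(theta)
    # Newton polish: BFGS often stops at ~1e-6; a few damped Newton steps on
    # the unconstrained parameterization reliably reach the requested tol.
    for _ in range(30):
        if np.max(np.abs(grad)) < tol:
            break
        hess = _hessian_fd(fun_grad, theta)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ls in range(30):
            cand = theta - scale * step
            nll_c, grad_c = fun_grad(cand)
            if nll_c <= nll + 1e-12:
                theta, nll, grad = cand, nll_c, grad_c
                break
            scale *= 0.5
        else:
            break
    converged = bool(np.max(np.abs(grad)) < max(tol, 1e-7))

    alphas, beta = _theta_to_natural(theta, k)

    # observed information in the natural parameterization
    def nat_fun_grad(p):
        return nll_grad(p[:k], p[k])

    natural = np.append(alphas, beta)
    info = _hessian_fd(nat_fun_grad, natural)
    separated = False
    se = np.full(k + 1, np.nan)
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if np.all(np.isfinite(diag)) and np.all(diag > 0):
            se = np.sqrt(diag)
        else:
            separated = True
    except np.linalg.LinAlgError:
        separated = True
    # quasi-separation: slope diverging on the standardized covariate scale
    if abs(beta) * np.std(x) > 25:
        separated = True

    with np.errstate(invalid="ignore", divide="ignore"):
        z = natural / se
    p = 2.0 * ndtr(-np.abs(z))
    if separated:
        p = np.ones(k + 1)
        _log.debug("separation flagged: |beta|=%.3g, p set to 1", abs(beta))
    if not converged:
        _log.debug("non-convergence: grad inf-norm %.3g", np.max(np.abs(grad)))

    return CumulativeLinkFit(
        alphas=alphas,
        beta=beta,
        se_alphas=se[:k],
        se_beta=float(se[k]),
        z_values=z,
        p_values=p,
        loglik=float(-negative_log_likelihood(natural, x, y, lk)),
        converged=converged,
        n_obs=n,
        separated=separated,
        link=lk.name,
        message=str(res.message),
    )
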