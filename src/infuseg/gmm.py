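"""Two-component Gaussian mixture over normalized intensities, fitted by EM.

The intensity histogram inside the operator's bounding box is modelled as a
mixture of a darker background class and a brighter foreground (infusate)
class::

    p(x) = (1 - alpha) * N(x; mu0, sigma0) + alpha * N(x; mu1, sigma1)

where ``alpha`` is the prior probability that a voxel is foreground.
Expectation-Maximization alternates posterior class responsibilities
(E-step) with closed-form maximum-likelihood parameter updates (M-step),
monitoring the negative log-likelihood until its relative change drops
below a tolerance. All densities are evaluated in log-space so the fit is
robust to extreme intensities that would underflow a direct density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .image_model import BinaryMask

__all__ = [
    "GMMParameters",
    "FitResult",
    "ClassCollapseError",
    "DEFAULT_INIT",
    "SIGMA_FLOOR",
    "ALPHA_EPS",
    "normal_pdf",
    "normal_logpdf",
    "mixture_density",
    "e_step",
    "m_step",
    "negative_log_likelihood",
    "fit_em",
    "classify",
]

# Numerical guards (normalized-intensity units). The variance floor prevents
# a component collapsing onto a single value with a singular likelihood; the
# alpha clamp keeps both mixture terms alive in log-space.
SIGMA_FLOOR = 1e-4
ALPHA_EPS = 1e-6

# Initial parameter values: background near the dark end, foreground near
# the bright end, both with broad spread, equal priors.
DEFAULT_INIT_TUPLE = (0.5, 0.2, 0.2, 0.8, 0.2)  # alpha, mu0, sigma0, mu1, sigma1


class ClassCollapseError(RuntimeError):
    """Raised when one mixture component absorbs all responsibility."""


@dataclass(frozen=True)
class GMMParameters:
    """The five mixture parameters.

    ``alpha`` is the foreground mixing proportion; ``mu0``/``sigma0`` the
    background mean and standard deviation, ``mu1``/``sigma1`` the
    foreground ones. After fitting, components are relabelled so that
    ``mu1 >= mu0`` (foreground is the brighter class).
    """

    alpha: float
    mu0: float
    sigma0: float
    mu1: float
    sigma1: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ValueError("sigmas must be strictly positive")
        for name in ("alpha", "mu0", "sigma0", "mu1", "sigma1"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} is not finite: {v}")

    def relabeled(self) -> "GMMParameters":
        """Swap components (and flip alpha) if the foreground is the darker one."""
        if self.mu1 >= self.mu0:
            return self
        return GMMParameters(1.0 - self.alpha, self.mu1, self.sigma1, self.mu0, self.sigma0)


DEFAULT_INIT = GMMParameters(*DEFAULT_INIT_TUPLE)


@dataclass
class FitResult:
    params: GMMParameters
    nll_trace: List[float]
    iterations: int
    converged: bool
    collapsed: bool = False

    @property
    def final_nll(self) -> float:
        return self.nll_trace[-1]


def normal_pdf(x, mu: float, sigma: float):
    """Univariate Normal density N(x; mu, sigma)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    x = np.asarray(x, dtype=np.float64)
    z = (x - mu) / sigma
    out = np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))
    return out if out.ndim else float(out)


def normal_logpdf(x, mu: float, sigma: float):
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    x = np.asarray(x, dtype=np.float64)
    z = (x - mu) / sigma
    return -0.5 * z * z - math.log(sigma) - 0.5 * math.log(2.0 * math.pi)


def _log_terms(x: np.ndarray, params: GMMParameters) -> Tuple[np.ndarray, np.ndarray]:
    """Log of the two weighted mixture terms: background, foreground."""
    a = min(max(params.alpha, ALPHA_EPS), 1.0 - ALPHA_EPS)
    log_bg = math.log1p(-a) + normal_logpdf(x, params.mu0, params.sigma0)
    log_fg = math.log(a) + normal_logpdf(x, params.mu1, params.sigma1)
    return log_bg, log_fg


def mixture_density(x, params: GMMParameters):
    """Mixture density (1-alpha) N(x; mu0, sigma0) + alpha N(x; mu1, sigma1)."""
    x_arr = np.asarray(x, dtype=np.float64)
    log_bg, log_fg = _log_terms(x_arr, params)
    out = np.exp(logsumexp(np.stack([log_bg, log_fg]), axis=0))
    return out if out.ndim else float(out)


def e_step(values: np.ndarray, params: GMMParameters) -> np.ndarray:
    """Posterior foreground responsibilities r = alpha N1 / (alpha N1 + (1-alpha) N0).

    Computed in log-space so that an underflowing mixture density never
    produces a division by zero.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("e_step requires at least one value")
    log_bg, log_fg = _log_terms(values, params)
    log_mix = np.logaddexp(log_bg, log_fg)
    return np.exp(log_fg - log_mix)


def m_step(values: np.ndarray, responsibilities: np.ndarray) -> GMMParameters:
    """Maximum-likelihood parameter update from soft class memberships.

    Weighted means and population (maximum-likelihood) weighted variances,
    with the sigma floor and alpha clamp applied.
    """
    x = np.asarray(values, dtype=np.float64)
    r = np.asarray(responsibilities, dtype=np.float64)
    if x.shape != r.shape:
        raise ValueError("values and responsibilities must have the same length")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("responsibilities must lie in [0, 1]")
    n = x.size
    w_fg = r.sum()
    w_bg = n - w_fg
    if w_fg <= 0 or w_bg <= 0:
        raise ClassCollapseError(
            f"a class has zero total responsibility (fg weight={w_fg}, bg weight={w_bg})"
        )
    alpha = min(max(w_fg / n, ALPHA_EPS), 1.0 - ALPHA_EPS)
    mu1 = float((r * x).sum() / w_fg)
    mu0 = float(((1.0 - r) * x).sum() / w_bg)
    sigma1 = max(math.sqrt(float((r * (x - mu1) ** 2).sum() / w_fg)), SIGMA_FLOOR)
    sigma0 = max(math.sqrt(float(((1.0 - r) * (x - mu0) ** 2).sum() / w_bg)), SIGMA_FLOOR)
    return GMMParameters(alpha, mu0, sigma0, mu1, sigma1)


def negative_log_likelihood(values: np.ndarray, params: GMMParameters) -> float:
    """-sum_i log p(x_i) under the mixture, evaluated in log-space."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("negative_log_likelihood requires at least one value")
    log_bg, log_fg = _log_terms(values, params)
    return float(-np.logaddexp(log_bg, log_fg).sum())


def fit_em(
    values: Sequence[float],
    init: GMMParameters = DEFAULT_INIT,
    rel_tol: float = 1e-3,
    max_iter: int = 500,
) -> FitResult:
    """Fit the two-class mixture by EM from fixed starting values.

    Iteration stops when the relative change in negative log-likelihood
    between successive iterations falls below ``rel_tol`` (default 0.1%),
    or after ``max_iter`` iterations (``converged=False``). If a class
    collapses during fitting the result is returned with the last valid
    parameters and ``collapsed=True`` rather than raising.

    After convergence the components are relabelled so that the foreground
    (``mu1``) is the brighter class.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 10:
        raise ValueError(f"need at least 10 values to fit, got {x.size}")
    if float(np.ptp(x)) == 0.0:
        raise ValueError("values have zero spread; mixture fit is degenerate")

    params = init
    nll_trace = [negative_log_likelihood(x, params)]
    converged = False
    collapsed = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        r = e_step(x, params)
        try:
            params = m_step(x, r)
        except ClassCollapseError:
            collapsed = True
            break
        nll = negative_log_likelihood(x, params)
        nll_trace.append(nll)
        prev = nll_trace[-2]
        denom = abs(prev) if prev != 0 else 1.0
        if abs(nll - prev) / denom < rel_tol:
            converged = True
            break
        # sigma pinned at the floor with near-total absorption: flag collapse
        if params.alpha >= 1.0 - 10 * ALPHA_EPS or params.alpha <= 10 * ALPHA_EPS:
            collapsed = True
            converged = True
            break

    return FitResult(
        params=params.relabeled(),
        nll_trace=nll_trace,
        iterations=iterations,
        converged=converged,
        collapsed=collapsed,
    )


def classify(
    values: Sequence[float],
    index_map: np.ndarray,
    params: GMMParameters,
    grid_shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    posterior: bool = True,
) -> BinaryMask:
    """Assign each boxed voxel to foreground or background.

    A voxel is foreground iff the weighted foreground density exceeds the
    weighted background density, ``alpha N(x; mu1, sigma1) > (1-alpha)
    N(x; mu0, sigma0)`` — the Bayes rule under the fitted mixture. Ties go
    to background (conservative distribution volume). Voxels outside the
    bounding box are background by construction. With ``posterior=False``
    the raw, unweighted likelihoods are compared instead.
    """
    x = np.asarray(values, dtype=np.float64)
    log_bg, log_fg = _log_terms(x, params)
    if not posterior:
        log_bg = normal_logpdf(x, params.mu0, params.sigma0)
        log_fg = normal_logpdf(x, params.mu1, params.sigma1)
    fg = log_fg > log_bg
    mask = np.zeros(grid_shape, dtype=bool)
    idx = np.asarray(index_map)
    mask[idx[fg, 0], idx[fg, 1], idx[fg, 2]] = True
    return BinaryMask(mask, spacing)
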