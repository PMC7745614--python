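"""Sample-specific expected squared prediction error for PCR.

For a sample at score position ``u`` in the calibration basis, the expected
squared prediction error of an A-component PCR decomposes exactly as

    E(ŷ - y)² = σ² + [ σ²/N + σ² Σ_{a<=A} u_a² ] + [ -Σ_{m>A} u_m g_m ]²

i.e. random error + estimation-variance contribution + squared
omitted-component bias.  The variance term is σ² times the score-space
leverage, so it grows as the sample moves away from the calibration centroid;
the bias term is sample specific and sign carrying, caused by truncating the
component expansion at A.

Plug-in practice:

- σ² is estimated by the MSEC of a deliberately large model (default 50
  components, capped below the retained rank), large enough that components
  beyond it carry no systematic information;
- the bias sum uses fitted coefficients ``g_hat`` only for components whose
  univariate score-response slope passes a t-test (two-sided, default
  significance level 0.01), and only up to a component limit (default 15), to
  keep pure estimation noise from far components out of the sum.  Components
  at or below A always contribute to the *prediction* regardless of the mask —
  gating applies only to the bias estimate.

For ordinary least squares on full-rank data the same quantity is
σ²(1 + 1/N + xᵀ(XᵀX)⁻¹x); the PCR formula with A = M and an empty bias range
reduces to it through the identity Σ_m u_m² = xᵀ(XᵀX)⁻¹x.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DegreesOfFreedomError,
    DimensionError,
    RankError,
    ValidationError,
)
from .pcr import PCRModel, fit_pcr
from .preprocess import _as_spectra

__all__ = [
    "ErrorBreakdown",
    "estimate_sigma2",
    "significant_components",
    "variance_contribution",
    "bias_contribution",
    "expected_squared_error",
    "ols_expected_squared_error",
    "calibrate_uncertainty",
]

logger = logging.getLogger(__name__)


@dataclass
class ErrorBreakdown:
    """Per-sample decomposition of the expected squared prediction error.

    ``total = sigma2 + variance_term + bias_signed**2`` holds exactly.
    """

    sigma2: float
    variance_term: float
    bias_signed: float
    total: float


def estimate_sigma2(X, y, A_noise: int = 50) -> float:
    """Random-error variance estimate: MSEC of an ``A_noise``-component model.

    ``A_noise`` is capped at the retained rank minus one (with a logged
    warning) when the spectra have lower rank than requested.
    """
    X = _as_spectra(X)
    N = X.n_samples
    A_noise = int(A_noise)
    if A_noise < 1:
        raise ValidationError("A_noise must be a positive integer")
    if N - A_noise - 1 <= 0:
        raise DegreesOfFreedomError(
            f"A_noise={A_noise} leaves no residual degrees of freedom at N={N}"
        )
    model = fit_pcr(X, y, A=1)
    cap = model.M - 1
    if cap < 1:
        raise RankError("spectra rank too low to estimate the random error")
    A_used = min(A_noise, cap)
    if A_used < A_noise:
        logger.warning(
            "A_noise=%d exceeds retained rank %d; using %d components",
            A_noise, model.M, A_used,
        )
    from .validation import msec  # local import to avoid a cycle

    return msec(model, X, y, A=A_used, denominator="components")


def significant_components(
    model: PCRModel, y, alpha: float = 0.01, m_max: int = 15
) -> np.ndarray:
    """t-test mask over components for use in the bias sum.

    For each component ``m <= m_max``, the centered response is regressed on
    score column ``m`` alone (the slope equals ``g_hat[m]`` by orthonormality)
    and the slope is tested against zero with a two-sided t-test on ``N - 2``
    degrees of freedom.  Components beyond ``m_max`` are False.
    """
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must be in (0, 1]")
    m_max = int(m_max)
    if m_max > model.M:
        raise DimensionError(f"m_max={m_max} exceeds the retained rank {model.M}")
    if model.N < 4:
        raise ValidationError("need at least 4 calibration samples for the t-test")
    yc = np.asarray(y, dtype=float).ravel() - model.y_mean
    mask = np.zeros(model.M, dtype=bool)
    if not np.any(np.abs(yc) > 0):
        return mask
    total = float(yc @ yc)
    g = model.g_hat[:m_max]
    rss = np.maximum(total - g**2, 0.0)
    dof = model.N - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = g / np.sqrt(rss / dof)
    # zero residual with a nonzero slope: infinite t, always significant
    t = np.where((rss <= 1e-14 * max(total, 1.0)) & (g != 0), np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    mask[:m_max] = p < alpha
    return mask


def variance_contribution(u, A: int, sigma2: float, N: int) -> float:
    """Estimation-variance term σ²/N + σ² Σ_{a<=A} u_a²."""
    u = np.asarray(u, dtype=float).ravel()
    if not sigma2 > 0:
        raise ValidationError("sigma2 must be positive")
    A = int(A)
    if A > u.shape[0]:
        raise RankError(f"A={A} exceeds score vector length {u.shape[0]}")
    return float(sigma2 / N + sigma2 * np.sum(u[:A] ** 2))


def bias_contribution(u, model: PCRModel) -> float:
    """Signed omitted-component bias -Σ u_m g_hat_m over significant m in (A, m_max]."""
    if model.significance_mask is None or model.m_max_bias is None:
        raise ConfigurationError(
            "model carries no significance mask; run significant_components "
            "(or calibrate_uncertainty) first"
        )
    u = np.asarray(u, dtype=float).ravel()
    m_hi = min(int(model.m_max_bias), model.M, u.shape[0])
    A = model.A
    if A >= m_hi:
        return 0.0
    sel = model.significance_mask[A:m_hi]
    return float(-(u[A:m_hi][sel] @ model.g_hat[A:m_hi][sel]))


def expected_squared_error(u, model: PCRModel) -> ErrorBreakdown:
    """Assemble the full per-sample error breakdown at score position ``u``."""
    if model.sigma2_hat is None:
        raise ConfigurationError(
            "model carries no sigma2_hat; run estimate_sigma2 "
            "(or calibrate_uncertainty) first"
        )
    var_term = variance_contribution(u, model.A, model.sigma2_hat, model.N)
    bias = bias_contribution(u, model)
    return ErrorBreakdown(
        sigma2=float(model.sigma2_hat),
        variance_term=var_term,
        bias_signed=bias,
        total=float(model.sigma2_hat + var_term + bias**2),
    )


def ols_expected_squared_error(x, X, sigma2: float, N: int | None = None) -> float:
    """OLS reference formula σ²(1 + 1/N + xᵀ(XᵀX)⁻¹x) on centered data.

    ``X`` is the centered calibration matrix (full column rank, K < N) and
    ``x`` a sample centered by the calibration means.
    """
    X = _as_spectra(X).values
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != X.shape[1]:
        raise DimensionError(f"x has length {x.shape[0]}, X has {X.shape[1]} columns")
    if not sigma2 > 0:
        raise ValidationError("sigma2 must be positive")
    N = X.shape[0] if N is None else int(N)
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < X.shape[1]:
        raise RankError(
            "X^T X is singular (collinear channels); use the PCR score-space formula"
        )
    quad = float(x @ np.linalg.solve(XtX, x))
    return float(sigma2 * (1.0 + 1.0 / N + quad))


def calibrate_uncertainty(
    model: PCRModel,
    X,
    y,
    alpha: float = 0.01,
    m_max_bias: int = 15,
    a_noise: int = 50,
) -> PCRModel:
    """Attach σ² estimate, significance mask and bias range to a fitted model.

    Returns a new :class:`PCRModel`; the input model is left untouched.
    """
    m_max = min(int(m_max_bias), model.M)
    sigma2 = estimate_sigma2(X, y, A_noise=a_noise)
    mask = significant_components(model, y, alpha=alpha, m_max=m_max)
    return dataclasses.replace(
        model, sigma2_hat=sigma2, significance_mask=mask, m_max_bias=m_max
    )
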