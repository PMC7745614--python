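"""Bias diagnostics: least-squares-effect line, Loess tendency, agreement report.

Two diagnostics relate estimated to observed prediction behaviour:

- The *least-squares effect*: even with exactly known model parameters, the
  expected prediction conditioned on the reference value shrinks toward the
  mean, E(ŷ | y) - ȳ = slope · (y - ȳ) with slope = bᵀ Σ_xy / Σ_y.  Low
  reference values are overestimated and high ones underestimated.  With
  plug-in sample moments from the calibration set the slope equals the R² of
  the fit.

- A Loess tendency smoother (locally weighted polynomial regression, tricube
  weights, default span 0.5 and degree 2, no robustness iterations) that reads
  the average relation between a per-sample estimate (abscissa) and the
  observed counterpart out of a noisy scatter, plus a one-number summary: the
  straight-line slope of the Loess curve over the central 90% of the abscissa
  (the edge 5% on each side is dropped to avoid boundary-leverage artifacts —
  a repository convention).  For a well-calibrated bias estimate that slope is
  ~1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .pcr import PCRModel

__all__ = [
    "ShrinkageLine",
    "SmootherFit",
    "AgreementReport",
    "least_squares_effect_line",
    "shrinkage_line_from_model",
    "loess_fit",
    "agreement_report",
]


@dataclass
class ShrinkageLine:
    """Least-squares-effect line in centered coordinates: ŷ - ȳ = slope (y - ȳ)."""

    slope: float

    def evaluate(self, y_centered):
        return self.slope * np.asarray(y_centered, dtype=float)


@dataclass
class SmootherFit:
    """A Loess fit evaluated at sorted input abscissae."""

    eval_points: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int
    included_mask: np.ndarray


@dataclass
class AgreementReport:
    """Summary of estimated-vs-observed agreement for a prediction set."""

    mean_diff: float  # mean(observed - estimated)
    var_true: float
    var_estimated: float
    loess_slope: float  # NaN when the abscissa is degenerate
    slope_available: bool
    n: int
    loess: SmootherFit


def least_squares_effect_line(b, cov_xy, var_y: float) -> ShrinkageLine:
    """Shrinkage line slope bᵀ·cov_xy / var_y.

    ``b`` may be a coefficient vector or a fitted :class:`PCRModel`, in which
    case the score-space coefficients of its first A components are used and
    ``cov_xy`` must be given in score space.
    """
    if not var_y > 0:
        raise ValidationError("var_y must be positive")
    if isinstance(b, PCRModel):
        b = b.g_hat[: b.A]
    b = np.asarray(b, dtype=float).ravel()
    cov_xy = np.asarray(cov_xy, dtype=float).ravel()
    if b.shape != cov_xy.shape:
        raise ValidationError(
            f"b has length {b.shape[0]}, cov_xy has length {cov_xy.shape[0]}"
        )
    return ShrinkageLine(slope=float(b @ cov_xy / var_y))


def shrinkage_line_from_model(model: PCRModel, y) -> ShrinkageLine:
    """Plug-in shrinkage line from calibration sample moments, in score space.

    cov(u_a, y) = g_hat_a / (N-1) by score orthonormality, so the slope reduces
    to Σ_{a<=A} g_hat_a² / ||y_centered||², the R² of the A-component fit.
    """
    yc = np.asarray(y, dtype=float).ravel() - model.y_mean
    denom = float(yc @ yc)
    if not denom > 0:
        raise ValidationError("response has zero variance")
    cov = model.g_hat[: model.A] / (model.N - 1)
    return least_squares_effect_line(model.g_hat[: model.A], cov, denom / (model.N - 1))


def _tricube(r: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.clip(r, 0.0, 1.0) ** 3, 0.0, None) ** 3
    return w


def loess_fit(
    x,
    y,
    span: float = 0.5,
    degree: int = 2,
    included_mask=None,
) -> SmootherFit:
    """Locally weighted polynomial regression with tricube weights.

    At every evaluation point (the sorted input abscissae, included or not) a
    weighted polynomial of the given degree is fitted over the
    ``ceil(span * n_included)`` nearest *included* points, with tricube weights
    on distance scaled by the neighbourhood radius.  No robustness iterations.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError("x and y must have the same length")
    if not 0 < span <= 1:
        raise ValidationError("span must be a fraction in (0, 1]")
    degree = int(degree)
    if included_mask is None:
        included_mask = np.ones(x.shape[0], dtype=bool)
    else:
        included_mask = np.asarray(included_mask, dtype=bool).ravel()
        if included_mask.shape != x.shape:
            raise ValidationError("included_mask must match the input length")
    xin, yin = x[included_mask], y[included_mask]
    n_in = xin.shape[0]
    if n_in < degree + 2:
        raise ValidationError(
            f"need at least degree + 2 = {degree + 2} included points, got {n_in}"
        )
    q = math.ceil(span * n_in)
    if q < degree + 1:
        raise ValidationError(
            f"span * n_included = {q} is below degree + 1 = {degree + 1}"
        )

    order = np.argsort(x, kind="stable")
    eval_points = x[order]
    fitted = np.empty_like(eval_points)
    for i, x0 in enumerate(eval_points):
        d = np.abs(xin - x0)
        if q < n_in:
            nbr = np.argpartition(d, q - 1)[:q]
        else:
            nbr = np.arange(n_in)
        dmax = d[nbr].max()
        w = _tricube(d[nbr] / dmax) if dmax > 0 else np.ones(nbr.shape[0])
        if np.count_nonzero(w) < degree + 1:
            w = np.ones(nbr.shape[0])  # degenerate window: fall back to unweighted
        z = (xin[nbr] - x0) / (dmax if dmax > 0 else 1.0)
        V = np.vander(z, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(V * sw[:, None], yin[nbr] * sw, rcond=None)
        fitted[i] = coef[0]
    return SmootherFit(
        eval_points=eval_points,
        fitted=fitted,
        span=float(span),
        degree=degree,
        included_mask=included_mask,
    )


def agreement_report(
    estimated,
    observed,
    span: float = 0.5,
    degree: int = 2,
    included_mask=None,
) -> AgreementReport:
    """Estimated-vs-observed agreement summary.

    Returns the mean difference observed - estimated, the variance of each
    vector, the Loess tendency of observed on estimated, and the straight-line
    slope of the Loess curve over the central 90% of the abscissa.  A constant
    abscissa yields ``loess_slope = NaN`` with ``slope_available = False``
    rather than an exception.
    """
    estimated = np.asarray(estimated, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if estimated.shape != observed.shape:
        raise ValidationError("estimated and observed must have the same length")
    n = estimated.shape[0]
    if n < 10:
        raise ValidationError(f"need at least 10 samples, got {n}")
    fit = loess_fit(estimated, observed, span=span, degree=degree, included_mask=included_mask)
    lo, hi = np.percentile(estimated, [5.0, 95.0])
    sel = (fit.eval_points >= lo) & (fit.eval_points <= hi)
    xs = fit.eval_points[sel]
    if xs.size >= 2 and np.ptp(xs) > 0:
        slope = float(np.polyfit(xs, fit.fitted[sel], 1)[0])
        available = True
    else:
        slope, available = float("nan"), False
    return AgreementReport(
        mean_diff=float(np.mean(observed - estimated)),
        var_true=float(np.var(observed, ddof=1)),
        var_estimated=float(np.var(estimated, ddof=1)),
        loess_slope=slope,
        slope_available=available,
        n=n,
        loess=fit,
    )
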