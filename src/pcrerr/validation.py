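"""Average-error measures as functions of model complexity.

Three standard summaries of a PCR calibration:

- MSEC, mean squared error of calibration: the fitted residual sum of squares
  divided by a degrees-of-freedom denominator.  The textbook denominator is
  ``N - K - 1`` (one per predictor channel), but for a PCR model with ``A``
  components the fit uses only ``A`` directions, so the default here divides by
  ``N - A - 1``; the channel-based convention remains selectable.  The
  component-based convention is also the one that keeps the large-``A`` MSEC a
  coherent estimator of the random-error variance.
- MSECV, mean squared error of leave-one-out cross-validation: each fold
  refits centering, SVD and coefficients from scratch on the remaining N - 1
  samples (no shortcut formulae), predicts the held-out sample, and the
  squared errors are averaged with denominator N (no d.o.f. correction).
- MSEP, mean squared error of prediction on an independent test set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DegreesOfFreedomError, RankError, ValidationError
from .pcr import PCRModel, fit_pcr, predict_many, project
from .preprocess import SpectraMatrix, _as_spectra

__all__ = ["ValidationCurves", "msec", "loocv_curve", "msep", "validation_curves"]


@dataclass
class ValidationCurves:
    """MSEC/MSECV (and optionally MSEP) indexed by number of components."""

    components: np.ndarray
    msec: np.ndarray
    msecv: np.ndarray
    msep: np.ndarray | None = None

    def argmin_msecv(self) -> int:
        """Number of components at the MSECV minimum."""
        return int(self.components[int(np.argmin(self.msecv))])


def _sse_by_A(model: PCRModel, y: np.ndarray, A_values: Sequence[int]) -> np.ndarray:
    """Residual sum of squares for each A, via score orthonormality."""
    yc = np.asarray(y, dtype=float).ravel() - model.y_mean
    total = float(yc @ yc)
    cum = np.concatenate([[0.0], np.cumsum(model.g_hat**2)])
    sse = np.array([max(total - cum[A], 0.0) for A in A_values])
    return sse


def msec(model: PCRModel, X, y, A: int | None = None, denominator: str = "components") -> float:
    """Mean squared error of calibration for the model's fit to its own data.

    ``denominator="components"`` divides by ``N - A - 1`` (default);
    ``"channels"`` divides by ``N - K - 1``.
    """
    A = model.A if A is None else int(A)
    if not 1 <= A <= model.M:
        raise RankError(f"A={A} outside the retained rank range 1..{model.M}")
    if denominator == "components":
        dof = model.N - A - 1
    elif denominator == "channels":
        dof = model.N - model.K - 1
    else:
        raise ValidationError(f"unknown denominator convention {denominator!r}")
    if dof <= 0:
        raise DegreesOfFreedomError(
            f"nonpositive degrees of freedom ({dof}) for N={model.N} with "
            f"denominator convention {denominator!r}"
        )
    sse = _sse_by_A(model, y, [A])[0]
    return float(sse / dof)


def loocv_curve(X, y, A_values: Sequence[int]) -> ValidationCurves:
    """Leave-one-out cross-validation across model complexities.

    Every fold refits centering + SVD + coefficients on the N - 1 remaining
    samples and predicts the held-out sample at each requested A.  Component
    ordering within a fold follows that fold's singular values.
    """
    X = _as_spectra(X)
    y = np.asarray(y, dtype=float).ravel()
    N = X.n_samples
    A_values = [int(a) for a in A_values]
    if len(A_values) == 0:
        raise ValidationError("A_values is empty")
    A_max = max(A_values)
    if A_max > min(N - 2, X.n_channels):
        raise RankError(
            f"max A={A_max} too large for N={N} samples and {X.n_channels} channels"
        )

    sq_err = np.zeros((N, len(A_values)))
    idx = np.arange(N)
    for n in range(N):
        keep = idx != n
        sub = SpectraMatrix(X.values[keep], X.wavelengths)
        model_n = fit_pcr(sub, y[keep], A=1)
        if A_max > model_n.M:
            raise RankError(
                f"fold {n}: A={A_max} exceeds the fold's retained rank {model_n.M}"
            )
        u = project(model_n, X.values[n])
        cum = model_n.y_mean + np.cumsum(u * model_n.g_hat)
        preds = cum[np.array(A_values) - 1]
        sq_err[n] = (preds - y[n]) ** 2

    msecv = sq_err.mean(axis=0)
    full = fit_pcr(X, y, A=1)
    if A_max > full.M:
        raise RankError(f"A={A_max} exceeds the retained rank {full.M}")
    sse = _sse_by_A(full, y, A_values)
    dof = np.array([full.N - A - 1 for A in A_values], dtype=float)
    if np.any(dof <= 0):
        raise DegreesOfFreedomError("N - A - 1 <= 0 for some requested A")
    return ValidationCurves(
        components=np.array(A_values), msec=sse / dof, msecv=msecv
    )


def msep(model: PCRModel, X_test, y_test, A: int | None = None) -> float:
    """Mean squared error of prediction on an independent test set."""
    y_test = np.asarray(y_test, dtype=float).ravel()
    if y_test.size == 0:
        raise ValidationError("test set is empty")
    X_test = _as_spectra(X_test)
    if X_test.n_samples != y_test.shape[0]:
        raise ValidationError(
            f"X_test has {X_test.n_samples} rows, y_test has {y_test.shape[0]} entries"
        )
    preds = predict_many(model, X_test, A=A)
    return float(np.mean((preds - y_test) ** 2))


def validation_curves(X, y, A_values: Sequence[int], X_test=None, y_test=None) -> ValidationCurves:
    """MSEC + MSECV curves, with an MSEP curve when a test set is supplied."""
    curves = loocv_curve(X, y, A_values)
    if X_test is not None and y_test is not None:
        model = fit_pcr(X, y, A=1)
        curves.msep = np.array([msep(model, X_test, y_test, A=A) for A in A_values])
    return curves
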