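"""SVD-based principal component regression: fitting, projection, prediction.

The calibration model is ``y = 1 g0 + X b + e`` with highly collinear spectral
columns in ``X``.  PCR replaces ``X`` by its singular value decomposition
``X = U S P^T`` (computed after column mean-centering) and regresses the
centered response on the first ``A`` orthonormal score columns of ``U``:

    y_centered = U_A g_A + f

Because the score columns are orthonormal, the least-squares coefficients are
simply ``g_m = u_m^T y_centered``; they are estimated for *all* retained
components at fit time because the omitted-component bias formula needs the
coefficients beyond ``A``.

A new sample ``x`` is centered by the calibration means and projected onto
``P S^{-1}`` to obtain its score vector ``u``; the prediction uses the first
``A`` entries of ``u`` and adds the calibration mean of ``y`` back.

Sign convention: each loading column's largest-magnitude element is made
positive (ties broken by the lowest channel index); scores and coefficients
flip accordingly.  This makes fitted models bitwise reproducible across
platforms and lets a simulator place ground truth in the same basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, RankError, ValidationError
from .preprocess import SpectraMatrix, _as_spectra

__all__ = [
    "PCRModel",
    "fit_pcr",
    "project",
    "transform",
    "predict",
    "predict_many",
    "leverage",
    "spectral_residual",
]

#: relative singular-value tolerance below which components are discarded
RANK_RTOL = 1e-10


def svd_sign_fix(loadings: np.ndarray, *others: np.ndarray):
    """Flip column signs so each loading column's largest-|.| entry is positive.

    ``others`` are matrices whose columns pair with the loading columns (scores)
    and are flipped in step.  Ties in magnitude are broken by the lowest row
    index (``np.argmax`` returns the first maximum).
    """
    flips = np.ones(loadings.shape[1])
    for m in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, m])))
        if loadings[j, m] < 0:
            flips[m] = -1.0
    loadings = loadings * flips
    flipped = [o * flips for o in others]
    return (loadings, *flipped)


@dataclass
class PCRModel:
    """A fitted PCR calibration.

    Fields follow the decomposition ``X_centered = U S P^T``:

    - ``loadings``: P, (n_channels, M), orthonormal columns
    - ``singular_values``: diagonal of S, descending and positive
    - ``cal_scores``: U, (n_cal, M), orthonormal columns
    - ``g_hat``: score-space coefficients for all M components
    - ``A``: number of components used for prediction
    - ``sigma2_hat``, ``significance_mask``, ``m_max_bias``: optional state
      attached by the uncertainty module (random-error estimate, t-test mask
      for the bias sum, upper component limit of the bias sum)
    """

    x_mean: np.ndarray
    y_mean: float
    loadings: np.ndarray
    singular_values: np.ndarray
    cal_scores: np.ndarray
    g_hat: np.ndarray
    A: int
    N: int
    K: int
    M: int
    sigma2_hat: float | None = None
    significance_mask: np.ndarray | None = None
    m_max_bias: int | None = None
    wavelengths: np.ndarray | None = field(default=None, repr=False)


def fit_pcr(X, y, A: int) -> PCRModel:
    """Fit a PCR model with ``A`` prediction components.

    Centers ``X`` and ``y`` by their calibration means, computes the SVD of the
    centered spectra, retains every component whose singular value exceeds
    ``RANK_RTOL`` times the largest, and estimates score-space coefficients for
    all retained components.
    """
    X = _as_spectra(X)
    y = np.asarray(y, dtype=float).ravel()
    N, K = X.values.shape
    if y.shape[0] != N:
        raise DimensionError(f"y has {y.shape[0]} entries, X has {N} rows")
    if not np.all(np.isfinite(y)):
        raise ValidationError("y contains non-finite entries")
    if N < 2:
        raise ValidationError(f"need at least 2 calibration samples, got {N}")

    x_mean = X.values.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X.values - x_mean
    yc = y - y_mean

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s.size == 0 or s[0] <= 0.0:
        raise RankError("centered calibration spectra have rank zero")
    M = int(np.sum(s > RANK_RTOL * s[0]))
    M = min(M, N - 1)  # centering removes one degree of freedom
    U, s, P = U[:, :M], s[:M], Vt[:M].T
    P, U = svd_sign_fix(P, U)
    g_hat = U.T @ yc

    A = int(A)
    if not 1 <= A <= M:
        raise RankError(f"A={A} outside the retained rank range 1..{M}")
    return PCRModel(
        x_mean=x_mean,
        y_mean=y_mean,
        loadings=P,
        singular_values=s,
        cal_scores=U,
        g_hat=g_hat,
        A=A,
        N=N,
        K=K,
        M=M,
        wavelengths=X.wavelengths.copy(),
    )


def _check_x(model: PCRModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.K:
        raise DimensionError(f"x has length {x.shape[0]}, model expects {model.K}")
    return x


def project(model: PCRModel, x) -> np.ndarray:
    """Project a new sample onto the calibration score basis: u = (x - x̄) P S⁻¹."""
    x = _check_x(model, x)
    return ((x - model.x_mean) @ model.loadings) / model.singular_values


def transform(model: PCRModel, X) -> np.ndarray:
    """Row-wise :func:`project`: returns an (n_samples, M) score matrix."""
    X = _as_spectra(X)
    if X.n_channels != model.K:
        raise DimensionError(f"X has {X.n_channels} channels, model expects {model.K}")
    return ((X.values - model.x_mean) @ model.loadings) / model.singular_values


def predict(model: PCRModel, x, A: int | None = None) -> float:
    """Predict the reference value of one sample: ŷ = ȳ + Σ_{a<=A} u_a g_a."""
    A = model.A if A is None else int(A)
    if not 1 <= A <= model.M:
        raise RankError(f"A={A} outside the retained rank range 1..{model.M}")
    u = project(model, x)
    return float(model.y_mean + u[:A] @ model.g_hat[:A])


def predict_many(model: PCRModel, X, A: int | None = None) -> np.ndarray:
    """Row-wise :func:`predict`."""
    A = model.A if A is None else int(A)
    if not 1 <= A <= model.M:
        raise RankError(f"A={A} outside the retained rank range 1..{model.M}")
    U = transform(model, X)
    return model.y_mean + U[:, :A] @ model.g_hat[:A]


def leverage(u, A: int, N: int) -> float:
    """Score-space leverage 1/N + Σ_{a<=A} u_a² — distance from the centroid."""
    u = np.asarray(u, dtype=float).ravel()
    if A > u.shape[0]:
        raise RankError(f"A={A} exceeds score vector length {u.shape[0]}")
    return float(1.0 / N + np.sum(u[:A] ** 2))


def spectral_residual(model: PCRModel, x, A: int | None = None) -> float:
    """Squared norm of the part of ``x - x̄`` outside the first A loadings.

    Large values flag samples whose spectra are not spanned by the calibration
    subspace, i.e. samples for which the calibration may not be representative.
    """
    A = model.A if A is None else int(A)
    if not 1 <= A <= model.M:
        raise RankError(f"A={A} outside the retained rank range 1..{model.M}")
    x = _check_x(model, x)
    xc = x - model.x_mean
    u = (xc @ model.loadings) / model.singular_values
    recon = (u[:A] * model.singular_values[:A]) @ model.loadings[:, :A].T
    return float(np.sum((xc - recon) ** 2))
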