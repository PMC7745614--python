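"""Spectral preprocessing: Savitzky-Golay derivative filtering and mean-centering.

Derivative spectra are the standard input to NIR calibration models: taking the
second derivative of absorbance with respect to the wavelength axis removes
additive baseline offsets and linear baseline drift while sharpening overlapping
bands.  The filter fits a low-order polynomial in a sliding window and returns
the derivative of that polynomial; it is exact on polynomials up to the fitting
order.

Edge policy: only the valid interior region is returned (``K - window + 1``
channels).  No polynomial extrapolation is fabricated at the edges, so every
retained channel is produced by the same full-window filter.  The trimmed
wavelength axis is carried along so that calibration and prediction spectra
stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import DimensionError, ValidationError

__all__ = ["SpectraMatrix", "savgol_derivative", "center_columns"]


@dataclass
class SpectraMatrix:
    """A set of spectra: rows are samples, columns are wavelength channels.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_channels)
        Absorbance (or derivative) readings.  Must be finite.
    wavelengths : ndarray of shape (n_channels,)
        Strictly increasing channel labels in nm.
    """

    values: np.ndarray
    wavelengths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.wavelengths is None:
            self.wavelengths = np.arange(self.values.shape[1], dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        if self.wavelengths.shape[0] != self.values.shape[1]:
            raise DimensionError(
                f"wavelength axis has {self.wavelengths.shape[0]} entries, "
                f"spectra have {self.values.shape[1]} channels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("spectra contain non-finite entries")
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def _as_spectra(X) -> SpectraMatrix:
    return X if isinstance(X, SpectraMatrix) else SpectraMatrix(np.asarray(X, dtype=float))


def savgol_derivative(
    X, window: int = 21, polyorder: int = 2, deriv: int = 2
) -> SpectraMatrix:
    """Savitzky-Golay derivative filter applied row-wise.

    The derivative is taken per unit channel-index step (``delta=1``); a uniform
    physical channel spacing only rescales all channels by a constant, which the
    downstream regression absorbs.

    Returns a :class:`SpectraMatrix` restricted to the valid interior region,
    i.e. ``n_channels - window + 1`` channels, with the wavelength axis trimmed
    to match.
    """
    X = _as_spectra(X)
    if window % 2 == 0 or window < 3:
        raise ValidationError(f"window must be an odd integer >= 3, got {window}")
    if not (deriv <= polyorder < window):
        raise ValidationError(
            f"need deriv <= polyorder < window, got deriv={deriv}, "
            f"polyorder={polyorder}, window={window}"
        )
    if X.n_channels < window:
        raise ValidationError(
            f"spectra have {X.n_channels} channels, fewer than window={window}"
        )
    filtered = savgol_filter(X.values, window, polyorder, deriv=deriv, delta=1.0, axis=1)
    half = (window - 1) // 2
    sl = slice(half, X.n_channels - half)
    return SpectraMatrix(filtered[:, sl], X.wavelengths[sl])


def center_columns(X, means: np.ndarray | None = None):
    """Subtract column means (calibration mode) or supplied means (prediction mode).

    Returns ``(centered, means_used)``.  When ``means`` is None the column means
    of ``X`` are used and returned so they can be re-applied to prediction data.
    """
    X = _as_spectra(X)
    if means is None:
        means = X.values.mean(axis=0)
    else:
        means = np.asarray(means, dtype=float).ravel()
        if means.shape[0] != X.n_channels:
            raise DimensionError(
                f"means has length {means.shape[0]}, spectra have "
                f"{X.n_channels} channels"
            )
    return SpectraMatrix(X.values - means, X.wavelengths), means
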