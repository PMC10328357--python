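"""Spectral preprocessing before the latent-variable fit.

The stack is: per-spectrum Standard Normal Variate (SNV) to correct
multiplicative scatter and baseline shifts, a per-spectrum median filter for
de-noising, then mean centering of both the spectral columns and the
temperature response.  Centering constants are estimated on the calibration
set only and replayed unchanged on test spectra, so held-out predictions never
see held-out statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter as _ndi_median
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateSpectrumError, ValidationError
from .spectra import SpectralMatrix

__all__ = [
    "snv",
    "median_filter",
    "PreprocessState",
    "SpectralPreprocessor",
    "fit_preprocess",
    "apply_preprocess",
]

_SD_TOL = 1e-12


def snv(x: np.ndarray) -> np.ndarray:
    """Standard Normal Variate: centre a spectrum and scale to unit sample sd.

    Uses the n-1 denominator conventional in chemometrics.  Raises
    :class:`DegenerateSpectrumError` for (near-)constant input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("snv expects a 1-D vector of length >= 2")
    sd = x.std(ddof=1)
    if sd <= _SD_TOL:
        raise DegenerateSpectrumError("zero-variance spectrum cannot be SNV-normalised")
    return (x - x.mean()) / sd


def median_filter(x: np.ndarray, window: int) -> np.ndarray:
    """Running median with nearest-value (edge replication) padding."""
    x = np.asarray(x, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"median-filter window must be odd and >= 1, got {window}")
    if window > x.size:
        raise ValidationError(f"window {window} exceeds vector length {x.size}")
    if window == 1:
        return x.copy()
    return _ndi_median(x, size=window, mode="nearest")


@dataclass
class PreprocessState:
    """Frozen calibration statistics replayed on test spectra."""

    column_means: np.ndarray
    y_mean: float
    filter_window: int
    use_snv: bool = True

    def __post_init__(self) -> None:
        self.column_means = np.asarray(self.column_means, dtype=float)
        if self.filter_window < 1 or self.filter_window % 2 == 0:
            raise ValidationError("filter_window must be odd and >= 1")


def _row_transform(values: np.ndarray, window: int, use_snv: bool, meta=None) -> np.ndarray:
    out = np.empty_like(values, dtype=float)
    for i, row in enumerate(values):
        try:
            r = snv(row) if use_snv else np.asarray(row, dtype=float)
        except DegenerateSpectrumError as exc:
            sid = None
            if meta is not None and i < len(meta):
                sid = meta[i].get("sample_id")
            raise DegenerateSpectrumError(
                f"degenerate spectrum in row {i}" + (f" (sample {sid})" if sid else "")
            ) from exc
        out[i] = median_filter(r, window)
    return out


class SpectralPreprocessor(TransformerMixin, BaseEstimator):
    """SNV + median filter + calibration-mean centering as a sklearn transformer.

    Parameters
    ----------
    window : int
        Odd median-filter width in grid points.  The default of 5 removes
        1-2-point noise spikes without flattening diagnostic bands, which are
        several points wide at the ~5.6 cm^-1 grid spacing.
    snv : bool
        Apply the SNV scatter correction (disable for ablation experiments).
    """

    def __init__(self, window: int = 5, snv: bool = True):
        self.window = window
        self.snv = snv

    def fit(self, X, y=None):
        values, meta = _as_values(X)
        if values.shape[0] < 1:
            raise ValidationError("cannot fit preprocessing on an empty matrix")
        processed = _row_transform(values, self.window, self.snv, meta)
        self.column_means_ = processed.mean(axis=0)
        self.y_mean_ = float(np.mean(y)) if y is not None else 0.0
        self.n_features_in_ = values.shape[1]
        return self

    def transform(self, X):
        values, meta = _as_values(X)
        if values.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"grid mismatch: {values.shape[1]} points, expected {self.n_features_in_}"
            )
        return _row_transform(values, self.window, self.snv, meta) - self.column_means_

    @property
    def state_(self) -> PreprocessState:
        return PreprocessState(self.column_means_.copy(), self.y_mean_, self.window, self.snv)


def _as_values(X):
    if isinstance(X, SpectralMatrix):
        return X.values, X.sample_meta
    return np.atleast_2d(np.asarray(X, dtype=float)), None


def fit_preprocess(X, y, window: int = 5, use_snv: bool = True):
    """Fit the stack on a calibration matrix; returns (Xp, yp, state)."""
    y = np.asarray(y, dtype=float)
    values, _ = _as_values(X)
    if len(y) != values.shape[0]:
        raise ValidationError("y length must match the number of calibration spectra")
    pre = SpectralPreprocessor(window=window, snv=use_snv).fit(X, y)
    return pre.transform(X), y - pre.y_mean_, pre.state_


def apply_preprocess(X, state: PreprocessState) -> np.ndarray:
    """Replay stored calibration preprocessing on new spectra (no re-estimation)."""
    values, meta = _as_values(X)
    if values.shape[1] != len(state.column_means):
        raise ValidationError(
            f"grid mismatch: {values.shape[1]} points, expected {len(state.column_means)}"
        )
    return _row_transform(values, state.filter_window, state.use_snv, meta) - state.column_means
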