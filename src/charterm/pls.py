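"""PLS1 latent-variable regression for spectral temperature calibration.

The fit is the classical single-response NIPALS scheme: per factor the weight
direction is the covariance of the (deflated) spectra with the (deflated)
temperature, scores are the projections, and both blocks are deflated before
the next factor is extracted.  Factor count is chosen by leave-one-out
cross-validation with an AIC penalty; variable relevance is summarised by VIP
(Variable Importance for Projection) profiles whose peaks mark the diagnostic
bands.

The estimator :class:`TemperaturePLS` bundles the preprocessing stack
(SNV -> median filter -> mean centering) with the latent-variable fit behind a
scikit-learn fit/predict interface; the module-level functions expose the same
steps individually.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import RankDeficiencyError, ValidationError
from .preprocess import PreprocessState, SpectralPreprocessor, apply_preprocess
from .spectra import SpectralMatrix

__all__ = [
    "PLSModel",
    "CVResult",
    "VIPProfile",
    "TemperaturePLS",
    "fit_pls1",
    "predict",
    "loo_cv",
    "aic",
    "select_n_factors",
    "vip",
    "diagnostic_bands",
]

_TOL = 1e-12


def _nipals(X: np.ndarray, y: np.ndarray, n_factors: int, strict: bool = True):
    """Extract up to ``n_factors`` PLS1 factors by iterative deflation.

    Returns (W, P, q, T).  With ``strict`` the requested count must be
    achievable; otherwise extraction stops silently when the residual
    covariance vanishes (rank exhausted), returning fewer factors.
    """
    Xd = np.array(X, dtype=float)
    yd = np.array(y, dtype=float)
    n, p = Xd.shape
    scale = max(float(np.linalg.norm(X)) * float(np.linalg.norm(y)), 1.0)
    W, P, Q, T = [], [], [], []
    for _ in range(n_factors):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= _TOL * scale:
            break
        w = w / nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _TOL:
            break
        pload = Xd.T @ t / tt
        qload = float(yd @ t / tt)
        Xd -= np.outer(t, pload)
        yd -= qload * t
        W.append(w)
        P.append(pload)
        Q.append(qload)
        T.append(t)
    if strict and len(W) < n_factors:
        raise RankDeficiencyError(
            f"requested {n_factors} factors but only {len(W)} are achievable"
        )
    f = len(W)
    W = np.column_stack(W) if f else np.zeros((p, 0))
    P = np.column_stack(P) if f else np.zeros((p, 0))
    T = np.column_stack(T) if f else np.zeros((n, 0))
    return W, P, np.asarray(Q, dtype=float), T


def _scores_for(W: np.ndarray, P: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Latent scores of new (preprocessed, centered) rows by sequential deflation."""
    Xd = np.array(X, dtype=float)
    F = W.shape[1]
    T = np.empty((Xd.shape[0], F))
    for f in range(F):
        t = Xd @ W[:, f]
        T[:, f] = t
        Xd -= np.outer(t, P[:, f])
    return T


@dataclass
class PLSModel:
    """Fitted PLS1 decomposition plus the preprocessing state it was trained with."""

    n_factors: int
    weights: np.ndarray      # p x F, unit-norm columns
    x_loadings: np.ndarray   # p x F
    y_loadings: np.ndarray   # F
    scores: np.ndarray       # n x F (training)
    preprocess_state: PreprocessState | None = None
    grid: np.ndarray | None = None
    taxon: str = "custom"

    @property
    def regression_vector(self) -> np.ndarray:
        """Equivalent single regression vector b with yhat = Xp @ b."""
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        if W.shape[1] == 0:
            return np.zeros(W.shape[0])
        return W @ np.linalg.solve(P.T @ W, q)

    def to_dict(self) -> dict:
        d = {
            "format": "charterm-pls/1",
            "taxon": self.taxon,
            "n_factors": int(self.n_factors),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
        }
        if self.grid is not None:
            d["grid"] = np.asarray(self.grid).tolist()
        if self.preprocess_state is not None:
            s = self.preprocess_state
            d["preprocess"] = {
                "column_means": s.column_means.tolist(),
                "y_mean": s.y_mean,
                "filter_window": s.filter_window,
                "use_snv": s.use_snv,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        if d.get("format") != "charterm-pls/1":
            raise ValidationError("unrecognised model serialization format")
        state = None
        if "preprocess" in d:
            s = d["preprocess"]
            state = PreprocessState(
                np.asarray(s["column_means"]), s["y_mean"], s["filter_window"], s["use_snv"]
            )
        W = np.asarray(d["weights"], dtype=float)
        return cls(
            n_factors=int(d["n_factors"]),
            weights=W,
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            scores=np.zeros((0, W.shape[1])),
            preprocess_state=state,
            grid=np.asarray(d["grid"], dtype=float) if "grid" in d else None,
            taxon=d.get("taxon", "custom"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_pls1(Xp: np.ndarray, yp: np.ndarray, n_factors: int) -> PLSModel:
    """Fit PLS1 on an already preprocessed, centered block.

    Raises :class:`RankDeficiencyError` (naming the achievable maximum) when
    more factors are requested than the data support, and
    :class:`ValidationError` for a zero-variance response.
    """
    Xp = np.atleast_2d(np.asarray(Xp, dtype=float))
    yp = np.asarray(yp, dtype=float)
    n, p = Xp.shape
    if n < 2:
        raise ValidationError("PLS needs at least 2 samples")
    if len(yp) != n:
        raise ValidationError("y length must match the number of rows")
    if np.ptp(yp) <= 0:
        raise ValidationError("response has zero variance")
    if n_factors < 1 or n_factors > min(n - 1, p):
        raise RankDeficiencyError(
            f"n_factors must be in [1, {min(n - 1, p)}], got {n_factors}"
        )
    W, P, q, T = _nipals(Xp, yp, n_factors, strict=True)
    return PLSModel(n_factors, W, P, q, T)


def predict(model: PLSModel, X_raw) -> np.ndarray:
    """Predict temperatures (degC) from raw spectra on the model grid.

    Applies the stored preprocessing, accumulates q-weighted latent scores and
    adds back the calibration mean temperature.  Predictions are deliberately
    not clipped to the calibration range: genuine extrapolation beyond 600 degC
    is reported as-is.
    """
    if model.preprocess_state is None:
        raise ValidationError("model carries no preprocessing state; use predict_centered")
    values = X_raw.values if isinstance(X_raw, SpectralMatrix) else np.atleast_2d(X_raw)
    if values.shape[1] != len(model.preprocess_state.column_means):
        raise ValidationError("grid mismatch between model and spectra")
    Xp = apply_preprocess(values, model.preprocess_state)
    T = _scores_for(model.weights, model.x_loadings, Xp)
    return T @ model.y_loadings + model.preprocess_state.y_mean


def predict_centered(model: PLSModel, Xp: np.ndarray) -> np.ndarray:
    """Predict the centered response from an already preprocessed block."""
    T = _scores_for(model.weights, model.x_loadings, np.atleast_2d(Xp))
    return T @ model.y_loadings


def aic(rmsecv: float, n: int, n_factors: int) -> float:
    """Akaike criterion for factor selection: n*ln(MSE_cv) + 2*(F+1).

    The +1 counts the intercept (the centered-response mean).  A zero RMSECV
    is degenerate and returns -inf so that the perfect model is always chosen.
    """
    if rmsecv < 0:
        raise ValidationError("rmsecv must be nonnegative")
    if rmsecv == 0:
        return -math.inf
    return n * math.log(rmsecv**2) + 2 * (n_factors + 1)


def select_n_factors(aics) -> int:
    """Smallest factor count attaining the minimum AIC (parsimony tie-break)."""
    aics = list(aics)
    if not aics:
        raise ValidationError("empty AIC sequence")
    return int(np.argmin(aics)) + 1


@dataclass
class CVResult:
    """Leave-one-out cross-validation summary over factor counts 1..F_max."""

    per_factor_rmsecv: np.ndarray
    per_factor_aic: np.ndarray
    chosen_factors: int
    predicted: np.ndarray   # held-out predictions at the chosen factor count
    observed: np.ndarray
    r2: float
    p_value: float


def _cv_r2(predicted: np.ndarray, observed: np.ndarray, mode: str = "pearson"):
    """Cross-validated r^2 with its significance.

    ``pearson`` squares the Pearson correlation of predicted vs observed and
    tests it with the two-sided t-test on n-2 df; ``ss`` uses 1 - SSE/SST
    (may be negative) with the same correlation-based p-value.
    """
    r, p = stats.pearsonr(predicted, observed)
    if mode == "pearson":
        return float(r**2), float(p)
    sse = float(np.sum((observed - predicted) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    return 1.0 - sse / sst, float(p)


def loo_cv(
    X,
    y,
    f_max: int,
    window: int = 5,
    use_snv: bool = True,
    r2_mode: str = "pearson",
) -> CVResult:
    """Leave-one-out CV with full per-fold refit of preprocessing and PLS.

    For every left-out sample the SNV/median-filter/centering statistics and
    the latent factors are re-estimated on the remaining n-1 samples only, so
    no held-out information leaks into the fold model.  When a fold's data
    support fewer than ``f_max`` factors, predictions for the missing factor
    counts repeat the deepest achievable model (an uninformative fold falls
    back to the training-fold mean).
    """
    values = X.values if isinstance(X, SpectralMatrix) else np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, dtype=float)
    n = values.shape[0]
    if n < 3:
        raise ValidationError("leave-one-out CV needs at least 3 samples")
    if not 1 <= f_max <= n - 2:
        raise ValidationError(f"f_max must be in [1, {n - 2}], got {f_max}")
    preds = np.zeros((n, f_max))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xtr, ytr = values[keep], y[keep]
        pre = SpectralPreprocessor(window=window, snv=use_snv).fit(Xtr, ytr)
        Xp = pre.transform(Xtr)
        yp = ytr - pre.y_mean_
        W, P, q, _ = _nipals(Xp, yp, f_max, strict=False)
        xte = pre.transform(values[i : i + 1])
        t = _scores_for(W, P, xte)[0]
        cum = pre.y_mean_ + np.cumsum(t * q) if len(q) else np.array([])
        for f in range(f_max):
            preds[i, f] = cum[min(f, len(cum) - 1)] if len(cum) else pre.y_mean_
    errs = preds - y[:, None]
    rmsecv = np.sqrt(np.mean(errs**2, axis=0))
    aics = np.array([aic(rmsecv[f], n, f + 1) for f in range(f_max)])
    chosen = select_n_factors(aics)
    r2, p = _cv_r2(preds[:, chosen - 1], y, r2_mode)
    return CVResult(rmsecv, aics, chosen, preds[:, chosen - 1].copy(), y.copy(), r2, p)


@dataclass
class VIPProfile:
    """Per-wavenumber Variable Importance for Projection, mean-square one."""

    values: np.ndarray
    grid: np.ndarray | None = None
    taxon: str = "custom"


def vip(model: PLSModel) -> VIPProfile:
    """VIP_j = sqrt(p * sum_f SS_f w_jf^2 / sum_f SS_f) with SS_f = q_f^2 t_f't_f.

    Weight columns are unit-norm by construction, so sum_j VIP_j^2 = p.
    """
    W, q, T = model.weights, model.y_loadings, model.scores
    p = W.shape[0]
    ss = q**2 * np.einsum("ij,ij->j", T, T)
    total = float(ss.sum())
    if total <= 0:
        raise ValidationError("model explains no response variance; VIP undefined")
    wn2 = (W / np.linalg.norm(W, axis=0)) ** 2
    vals = np.sqrt(p * (wn2 @ ss) / total)
    return VIPProfile(vals, model.grid, model.taxon)


def diagnostic_bands(
    profile: VIPProfile | np.ndarray,
    grid: np.ndarray | None = None,
    threshold: float = 1.0,
    min_separation: float = 30.0,
) -> list[float]:
    """Wavenumbers of local VIP maxima above ``threshold``.

    Peaks are reported greedily from the highest VIP down, discarding any peak
    within ``min_separation`` cm^-1 of one already accepted.  Each reported
    position is refined to the baseline-subtracted VIP centroid of the +-3
    samples around the maximum, which undoes most of the sample-quantisation
    and median-filter flattening of peak tops.  Bands closer together than the
    band width itself are not individually resolvable and only the dominant
    one is reported.
    """
    if isinstance(profile, VIPProfile):
        vals = profile.values
        grid = profile.grid if grid is None else grid
    else:
        vals = np.asarray(profile, dtype=float)
    if grid is None:
        raise ValidationError("a wavenumber grid is required to report bands")
    grid = np.asarray(grid, dtype=float)
    v = vals
    # plateau-aware local maxima: the median filter flattens peak tops, so a
    # run of equal values higher than both flanks counts as one peak at its
    # midpoint; a trace flat everywhere has no maxima.
    peaks, _ = signal.find_peaks(v, height=threshold)

    def _refine(i: int, half: int = 3) -> float:
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        w = v[lo:hi] - v[lo:hi].min()
        if w.sum() <= 0:
            return float(grid[i])
        return float((grid[lo:hi] * w).sum() / w.sum())

    idx = sorted(peaks.tolist(), key=lambda i: -v[i])
    kept: list[float] = []
    for i in idx:
        pos = _refine(i)
        if all(abs(pos - k) >= min_separation for k in kept):
            kept.append(pos)
    return kept


class TemperaturePLS(RegressorMixin, BaseEstimator):
    """Charring-temperature calibration: preprocessing + PLS1 in one estimator.

    Parameters
    ----------
    n_factors : int or "aic"
        Latent factor count; ``"aic"`` picks it by leave-one-out CV with the
        AIC penalty (ties resolved toward fewer factors).
    f_max : int
        Largest factor count screened by CV.
    window : int
        Median-filter width (odd, grid points).
    snv : bool
        Apply the SNV scatter correction.
    r2_mode : {"pearson", "ss"}
        Definition of the cross-validated r^2 reported in ``cv_``.

    Attributes (after fit)
    ----------------------
    weights_, x_loadings_, y_loadings_, x_scores_ : the PLS1 decomposition
    n_factors_ : the factor count actually used
    cv_ : :class:`CVResult` (present when factor selection ran)
    model_ : the underlying :class:`PLSModel` with preprocessing state
    """

    def __init__(
        self,
        n_factors: int | str = "aic",
        f_max: int = 4,
        window: int = 5,
        snv: bool = True,
        r2_mode: str = "pearson",
    ):
        self.n_factors = n_factors
        self.f_max = f_max
        self.window = window
        self.snv = snv
        self.r2_mode = r2_mode

    def fit(self, X, y):
        values = X.values if isinstance(X, SpectralMatrix) else np.atleast_2d(np.asarray(X, float))
        grid = X.grid if isinstance(X, SpectralMatrix) else None
        y = np.asarray(y, dtype=float)
        if values.shape[0] != len(y):
            raise ValidationError("X and y disagree on the number of samples")
        if self.n_factors == "aic":
            self.cv_ = loo_cv(values, y, self.f_max, self.window, self.snv, self.r2_mode)
            chosen = self.cv_.chosen_factors
        else:
            chosen = int(self.n_factors)
        pre = SpectralPreprocessor(window=self.window, snv=self.snv).fit(values, y)
        Xp = pre.transform(values)
        core = fit_pls1(Xp, y - pre.y_mean_, chosen)
        core.preprocess_state = pre.state_
        core.grid = grid
        self.model_ = core
        self.weights_ = core.weights
        self.x_loadings_ = core.x_loadings
        self.y_loadings_ = core.y_loadings
        self.x_scores_ = core.scores
        self.n_factors_ = chosen
        self.n_features_in_ = values.shape[1]
        return self

    def predict(self, X):
        return predict(self.model_, X)

    def vip(self) -> VIPProfile:
        return vip(self.model_)

    def diagnostic_bands(self, threshold: float = 1.0, min_separation: float = 30.0):
        if self.model_.grid is None:
            raise ValidationError("fit on a SpectralMatrix to report band positions")
        return diagnostic_bands(self.vip(), threshold=threshold, min_separation=min_separation)
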