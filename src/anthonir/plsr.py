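"""NIPALS partial least squares regression (PLS1) with full leave-one-out
cross-validation, calibration diagnostics, Hotelling T^2 outlier detection
and jack-knife ("uncertainty test") wavenumber selection.

The estimator follows the scikit-learn protocol (``fit``/``predict``/
``get_params``) so it composes with sklearn pipelines and model selection,
but the factor extraction is authored here: classic NIPALS for a single
response, operating on column-centered X and centered y with no variance
scaling — the convention for derivative spectra. For one response NIPALS is
non-iterative: per factor

    w = X'y / ||X'y||,   t = X w,   p = X't / t't,   q = y't / t't,

followed by deflation ``X <- X - t p'``, ``y <- y - q t``.  The regression
vector on the original (pretreated) wavenumber axis is
``b = W (P'W)^{-1} q``.

Model quality is summarized by RMSEC, RMSECV, their ratio, R^2 of
calibration and validation, and RSD_PLSR = 100 * RMSECV / mean(y_cal)
(percent of the average calibration concentration; the range midpoint is
available as an alternative denominator).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "NIPALSPLSRegression",
    "PLSRModel",
    "CVResult",
    "ModelMetrics",
    "fit_plsr",
    "loo_cv",
    "select_n_factors",
    "compute_metrics",
    "hotelling_outliers",
    "uncertainty_test",
    "significant_regions",
    "save_model",
    "load_model",
]


class RankDeficiencyWarning(UserWarning):
    """Requested more PLS factors than the data support."""


class NIPALSPLSRegression(RegressorMixin, BaseEstimator):
    """PLS1 regression fitted by NIPALS with deflation.

    Parameters
    ----------
    n_components : int
        Number of latent factors to extract. If the residual X rank is
        exhausted earlier, extraction stops with a warning and
        ``n_components_`` records the achieved count.

    Attributes
    ----------
    x_mean_ : ndarray (n_features,)
    y_mean_ : float
    x_weights_ : ndarray (n_features, n_components_)   -- W
    x_loadings_ : ndarray (n_features, n_components_)  -- P
    y_loadings_ : ndarray (n_components_,)             -- q
    x_scores_ : ndarray (n_samples, n_components_)     -- T
    coef_ : ndarray (n_features,)
        Regression vector b on the original (centered) axis.
    wavenumbers_ : ndarray or None
        Grid the model was trained on, when supplied.
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, y, wavenumbers=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x wavenumbers)")
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if y.shape[0] != n:
            raise ValueError("X and y sample counts differ")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite (no missing values)")
        if np.ptp(y) == 0:
            raise ValueError("y has zero variance")
        max_rank = min(n - 1, p)
        if not 1 <= self.n_components <= max_rank:
            raise ValueError(
                f"n_components must be in 1..min(n-1, p)={max_rank}, "
                f"got {self.n_components}"
            )

        x_mean = X.mean(axis=0)
        y_mean = float(y.mean())
        Xc = X - x_mean  # fresh array; deflation below is destructive
        yc = y - y_mean
        # tolerance relative to the initial data scale
        x_scale = np.linalg.norm(Xc)
        eps = 1e-12 * max(x_scale, 1e-300)

        W, P, Q, T = [], [], [], []
        for _ in range(self.n_components):
            w = Xc.T @ yc
            nw = np.linalg.norm(w)
            if nw <= eps:
                warnings.warn(
                    f"residual rank exhausted after {len(W)} factors "
                    f"(requested {self.n_components})",
                    RankDeficiencyWarning,
                )
                break
            w /= nw
            t = Xc @ w
            tt = float(t @ t)
            if tt <= eps**2:
                warnings.warn(
                    f"degenerate score after {len(W)} factors",
                    RankDeficiencyWarning,
                )
                break
            pl = Xc.T @ t / tt
            ql = float(yc @ t / tt)
            Xc -= np.outer(t, pl)
            yc = yc - ql * t
            W.append(w)
            P.append(pl)
            Q.append(ql)
            T.append(t)

        if not W:
            raise ValueError("no PLS factor could be extracted (X'y is zero)")
        self.n_components_ = len(W)
        self.x_weights_ = np.column_stack(W)
        self.x_loadings_ = np.column_stack(P)
        self.y_loadings_ = np.asarray(Q)
        self.x_scores_ = np.column_stack(T)
        self.x_mean_ = x_mean
        self.y_mean_ = y_mean
        self.coef_ = self.coefficients()
        self.n_features_in_ = p
        self.wavenumbers_ = None if wavenumbers is None else np.asarray(
            wavenumbers, dtype=float
        )
        return self

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression vector using the first ``n_components`` factors."""
        k = self.n_components_ if n_components is None else n_components
        if not 1 <= k <= self.n_components_:
            raise ValueError(f"n_components must be in 1..{self.n_components_}")
        W = self.x_weights_[:, :k]
        P = self.x_loadings_[:, :k]
        q = self.y_loadings_[:k]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.x_mean_.shape[0]:
            raise ValueError(
                f"grid mismatch: model has {self.x_mean_.shape[0]} wavenumbers, "
                f"input has {X.shape[1]}"
            )
        b = self.coef_ if n_components is None else self.coefficients(n_components)
        return self.y_mean_ + (X - self.x_mean_) @ b

    def to_dict(self) -> dict:
        return {
            "n_components": int(self.n_components_),
            "x_mean": self.x_mean_.tolist(),
            "y_mean": self.y_mean_,
            "x_weights": self.x_weights_.tolist(),
            "x_loadings": self.x_loadings_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "coef": self.coef_.tolist(),
            "wavenumbers": None
            if self.wavenumbers_ is None
            else self.wavenumbers_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NIPALSPLSRegression":
        m = cls(n_components=d["n_components"])
        m.n_components_ = d["n_components"]
        m.x_mean_ = np.asarray(d["x_mean"], dtype=float)
        m.y_mean_ = float(d["y_mean"])
        m.x_weights_ = np.asarray(d["x_weights"], dtype=float)
        m.x_loadings_ = np.asarray(d["x_loadings"], dtype=float)
        m.y_loadings_ = np.asarray(d["y_loadings"], dtype=float)
        m.coef_ = np.asarray(d["coef"], dtype=float)
        m.x_scores_ = np.empty((0, m.n_components_))
        m.n_features_in_ = m.x_mean_.shape[0]
        m.wavenumbers_ = (
            None if d.get("wavenumbers") is None
            else np.asarray(d["wavenumbers"], dtype=float)
        )
        return m


#: Alias used in type annotations and the public API.
PLSRModel = NIPALSPLSRegression


def fit_plsr(X, y, n_factors: int = 3, wavenumbers=None) -> NIPALSPLSRegression:
    """Fit a NIPALS PLS1 model (thin functional wrapper)."""
    return NIPALSPLSRegression(n_components=n_factors).fit(X, y, wavenumbers)


@dataclass
class CVResult:
    """Leave-one-out cross-validation summary.

    ``rmsecv[k-1]`` and ``predictions[:, k-1]`` correspond to models with
    ``k`` factors; centering is recomputed inside every fold.
    """

    rmsecv: np.ndarray
    predictions: np.ndarray
    max_factors: int

    def best_n_factors(self, rel_tol: float = 0.02) -> int:
        return select_n_factors(self.rmsecv, rel_tol=rel_tol)


def loo_cv(X, y, max_factors: int) -> CVResult:
    """Full (leave-one-out) cross-validation of the NIPALS PLS1 model.

    For each left-out sample the model is refitted on the remainder with
    per-fold recentering; RMSECV(k) is the root mean square of the held-out
    prediction errors using k factors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    kmax = min(max_factors, n - 2, X.shape[1])
    preds = np.empty((n, kmax))
    for i in range(n):
        keep = np.arange(n) != i
        if np.ptp(y[keep]) == 0:
            # constant reference in the fold: the model is its mean
            preds[i, :] = y[keep].mean()
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RankDeficiencyWarning)
                m = NIPALSPLSRegression(n_components=kmax).fit(X[keep], y[keep])
        except ValueError as exc:
            raise ValueError(f"cross-validation fold {i} failed: {exc}") from exc
        for k in range(1, kmax + 1):
            kk = min(k, m.n_components_)
            preds[i, k - 1] = m.predict(X[i], n_components=kk)[0]
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    return CVResult(rmsecv=rmsecv, predictions=preds, max_factors=kmax)


def select_n_factors(rmsecv: np.ndarray, rel_tol: float = 0.02) -> int:
    """Parsimonious factor count: smallest k with RMSECV within
    ``rel_tol`` (relative) of the global minimum."""
    rmsecv = np.asarray(rmsecv, dtype=float)
    lo = rmsecv.min()
    return int(np.flatnonzero(rmsecv <= (1.0 + rel_tol) * lo)[0] + 1)


@dataclass
class ModelMetrics:
    """Calibration quality summary in reference units."""

    rmsec: float
    rmsecv: float
    ratio: float          # RMSECV / RMSEC
    r2_cal: float
    r2_val: float
    rsd_plsr_percent: float
    n_factors: int
    outlier_ids: tuple = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outlier_ids"] = list(self.outlier_ids)
        return d


def compute_metrics(
    y,
    yhat_cal,
    yhat_cv,
    n_factors: int,
    outlier_ids: Sequence = (),
    rsd_denominator: str = "mean",
) -> ModelMetrics:
    """Assemble RMSEC/RMSECV/R^2/RSD_PLSR from calibration and CV predictions.

    ``rsd_denominator``: "mean" (average calibration concentration, the
    default reading of "average concentration range") or "midrange"
    ((min+max)/2 of the calibration references).
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat_cal = np.asarray(yhat_cal, dtype=float).ravel()
    yhat_cv = np.asarray(yhat_cv, dtype=float).ravel()
    if not (y.shape == yhat_cal.shape == yhat_cv.shape):
        raise ValueError("y, yhat_cal and yhat_cv must be aligned")
    rmsec = float(np.sqrt(np.mean((y - yhat_cal) ** 2)))
    rmsecv = float(np.sqrt(np.mean((y - yhat_cv) ** 2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("reference values have zero variance")
    r2_cal = 1.0 - float(np.sum((y - yhat_cal) ** 2)) / sst
    r2_val = 1.0 - float(np.sum((y - yhat_cv) ** 2)) / sst
    if rsd_denominator == "mean":
        denom = float(y.mean())
    elif rsd_denominator == "midrange":
        denom = float((y.min() + y.max()) / 2.0)
    else:
        raise ValueError("rsd_denominator must be 'mean' or 'midrange'")
    if denom == 0:
        raise ValueError("zero mean reference; RSD_PLSR undefined")
    return ModelMetrics(
        rmsec=rmsec,
        rmsecv=rmsecv,
        ratio=rmsecv / rmsec if rmsec > 0 else np.inf if rmsecv > 0 else 0.0,
        r2_cal=r2_cal,
        r2_val=r2_val,
        rsd_plsr_percent=100.0 * rmsecv / denom,
        n_factors=n_factors,
        outlier_ids=tuple(outlier_ids),
    )


@dataclass
class HotellingResult:
    t2: np.ndarray
    threshold: float
    flags: np.ndarray  # boolean


def hotelling_outliers(
    model: NIPALSPLSRegression, alpha: float = 0.05
) -> HotellingResult:
    """Hotelling T^2 in PLS score space with the F-distribution limit.

    T^2_i = sum_k t_ik^2 / var(t_k) (sample variance); the threshold is
    k(n-1)/(n-k) * F(1-alpha; k, n-k). Samples above it are flagged.
    """
    T = model.x_scores_
    n, k = T.shape
    if n == 0:
        raise ValueError("model has no stored scores")
    if k >= n:
        raise ValueError("need more samples than factors for the F limit")
    var = T.var(axis=0, ddof=1)
    if np.any(var == 0):
        t2 = np.zeros(n)
        nz = var > 0
        if nz.any():
            t2 = np.sum(T[:, nz] ** 2 / var[nz], axis=1)
    else:
        t2 = np.sum(T**2 / var, axis=1)
    thr = k * (n - 1) / (n - k) * stats.f.ppf(1.0 - alpha, k, n - k)
    return HotellingResult(t2=t2, threshold=float(thr), flags=t2 > thr)


@dataclass
class UncertaintyResult:
    significant: np.ndarray       # boolean mask per wavenumber
    t_statistic: np.ndarray
    coef: np.ndarray
    jackknife_variance: np.ndarray
    t_critical: float


def uncertainty_test(
    X, y, n_factors: int, alpha: float = 0.05
) -> UncertaintyResult:
    """Martens-style jack-knife significance of PLS regression coefficients.

    For each leave-one-out segment s the perturbation is
    ``d_js = b_j - b_j^(s)``; the jack-knife variance estimate is
    ``v_j = sum_s d_js^2 * (n-1)/n`` and variable j is significant when
    ``|b_j| / sqrt(v_j)`` exceeds the two-sided t quantile at level alpha
    with n-1 degrees of freedom. ``v_j = 0`` is defined, not an error:
    significant iff ``b_j != 0``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    full = NIPALSPLSRegression(n_components=n_factors).fit(X, y)
    b = full.coefficients(min(n_factors, full.n_components_))
    D = np.empty((n, X.shape[1]))
    for i in range(n):
        keep = np.arange(n) != i
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RankDeficiencyWarning)
            m = NIPALSPLSRegression(n_components=n_factors).fit(X[keep], y[keep])
        D[i] = b - m.coefficients(min(n_factors, m.n_components_))
    v = np.sum(D**2, axis=0) * (n - 1) / n
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.abs(b) / np.sqrt(v)
    sig = np.where(v > 0, tstat > tcrit, b != 0)
    return UncertaintyResult(
        significant=sig.astype(bool),
        t_statistic=tstat,
        coef=b,
        jackknife_variance=v,
        t_critical=tcrit,
    )


def significant_regions(mask, wavenumbers) -> list[tuple[float, float]]:
    """Maximal runs of consecutive significant grid points as closed
    (low, high) cm^-1 intervals."""
    mask = np.asarray(mask, dtype=bool)
    wn = np.asarray(wavenumbers, dtype=float)
    if mask.shape != wn.shape:
        raise ValueError("mask and grid are not aligned")
    regions = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            chunk = wn[start:i]
            regions.append((float(chunk.min()), float(chunk.max())))
            start = None
    if start is not None:
        chunk = wn[start:]
        regions.append((float(chunk.min()), float(chunk.max())))
    return regions


def save_model(model: NIPALSPLSRegression, path, recipe=None) -> None:
    """Serialize a fitted model (grid, centering, factors, coefficients)
    plus an optional recipe descriptor to a JSON artifact."""
    doc = model.to_dict()
    if recipe is not None:
        doc["recipe"] = recipe.to_config()
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> tuple[NIPALSPLSRegression, dict | None]:
    with open(path) as fh:
        doc = json.load(fh)
    recipe = doc.pop("recipe", None)
    return NIPALSPLSRegression.from_dict(doc), recipe
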