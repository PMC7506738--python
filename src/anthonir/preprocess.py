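"""Spectral pretreatment operators and named pretreatment recipes.

Each operator is a scikit-learn transformer acting row-wise on a
``(n_spectra, n_points)`` matrix, so recipes compose as ordinary sklearn
pipelines.  The closed operator set is: second-order detrending, Savitzky-
Golay smoothing derivatives (5/7/9-point window, polynomial order 2,
derivative order 1 or 2), standard normal variate (SNV), maximum
normalization, and wavenumber-region selection.

Two named recipes reproduce the pretreatments behind the best-performing
TAC calibration models:

* ``RECIPE_PHDIFF`` (pH-differential reference): detrend(order 2) ->
  1st derivative (7-point SG, poly 2) -> SNV.
* ``RECIPE_HPLC`` (HPLC sum-parameter reference): max-normalization ->
  1st derivative (7-point SG, poly 2) -> SNV -> restriction to the
  meaningful wavenumber regions of the HPLC model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .bands import HPLC_MODEL_REGIONS
from .spectra_io import SpectrumSet, region_mask

__all__ = [
    "DegenerateSpectrumError",
    "SNV",
    "Detrend",
    "SavitzkyGolayDerivative",
    "MaxNormalize",
    "RegionSelector",
    "PretreatmentRecipe",
    "RECIPE_PHDIFF",
    "RECIPE_HPLC",
    "snv",
    "detrend",
    "sg_derivative",
    "max_normalize",
    "apply_recipe",
    "recipe_from_config",
]

_SG_WINDOWS = (5, 7, 9)


class DegenerateSpectrumError(ValueError):
    """A spectrum has no dispersion (or is all zero) where the operator needs it."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("expected a spectrum vector or (n_spectra, n_points) matrix")
    return X


class SNV(TransformerMixin, BaseEstimator):
    """Standard normal variate: per-spectrum centering and unit-sd scaling.

    Uses the sample (n-1 denominator) standard deviation. Constant spectra
    have no dispersion and raise :class:`DegenerateSpectrumError`.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if X.shape[1] < 2:
            raise ValueError("SNV needs spectra of length >= 2")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=self.ddof, keepdims=True)
        # a spectrum annihilated by earlier operators (e.g. detrend +
        # derivative on a pure polynomial baseline) leaves only float
        # round-off; treat dispersion below 1e-12 of unit scale as zero
        tol = 1e-12 * np.maximum(1.0, np.max(np.abs(X), axis=1))
        zero = np.flatnonzero(sd.ravel() <= tol)
        if zero.size:
            raise DegenerateSpectrumError(
                f"constant spectrum (zero dispersion) at row {zero[0]}",
                row=int(zero[0]),
            )
        return (X - mu) / sd

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


class Detrend(TransformerMixin, BaseEstimator):
    """Subtract each spectrum's least-squares polynomial baseline.

    The fit is in the grid coordinate; because the grid is affine in the
    point index, the degree-``order`` polynomial subspace (and hence the
    projection) is identical whether parameterized by wavenumber or by
    index, so no grid is required. The residual is orthogonal to the
    polynomial basis, which makes the operator an idempotent linear
    projection.
    """

    def __init__(self, order: int = 2):
        self.order = order

    def _basis(self, n: int) -> np.ndarray:
        if n <= self.order + 1:
            raise ValueError(f"need more than order+1={self.order + 1} points")
        t = np.linspace(-1.0, 1.0, n)
        q, _ = np.linalg.qr(np.vander(t, self.order + 1, increasing=True))
        return q

    def fit(self, X, y=None):
        X = _as_matrix(X)
        self.n_features_in_ = X.shape[1]
        self._q = self._basis(X.shape[1])
        return self

    def transform(self, X):
        X = _as_matrix(X)
        q = getattr(self, "_q", None)
        if q is None or q.shape[0] != X.shape[1]:
            q = self._basis(X.shape[1])
        return X - (X @ q) @ q.T

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


class SavitzkyGolayDerivative(TransformerMixin, BaseEstimator):
    """Savitzky-Golay smoothing derivative of order 1 or 2.

    Parameters
    ----------
    window : {5, 7, 9}
        Number of smoothing points (odd, > polynomial order).
    polyorder : int
        Local polynomial order (default 2).
    deriv : {1, 2}
        Derivative order; must not exceed ``polyorder``.
    spacing : float
        Signed grid step in cm^-1 (negative on a descending grid). Output
        is scaled to per-cm^-1 units via 1/spacing**deriv unless
        ``per_index`` is set.
    per_index : bool
        If True, report derivatives per point index (vendor-style),
        ignoring the grid spacing.

    Edge points are produced by re-fitting the boundary-window polynomial
    and evaluating its derivative there, so output length equals input
    length and the filter reproduces polynomials of degree <= ``polyorder``
    exactly.
    """

    def __init__(
        self,
        window: int = 7,
        polyorder: int = 2,
        deriv: int = 1,
        spacing: float = -4.0,
        per_index: bool = False,
    ):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv
        self.spacing = spacing
        self.per_index = per_index

    def _validate(self):
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("SG window must be odd and exceed the polynomial order")
        if not 1 <= self.deriv <= self.polyorder:
            raise ValueError("derivative order must be in 1..polyorder")
        if self.spacing == 0:
            raise ValueError("spacing must be nonzero")

    def fit(self, X, y=None):
        self._validate()
        X = _as_matrix(X)
        if X.shape[1] < self.window:
            raise ValueError("spectrum shorter than the SG window")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        self._validate()
        X = _as_matrix(X)
        delta = 1.0 if self.per_index else abs(self.spacing)
        out = savgol_filter(
            X, self.window, self.polyorder, deriv=self.deriv,
            delta=delta, axis=-1, mode="interp",
        )
        if not self.per_index and self.spacing < 0 and self.deriv % 2 == 1:
            out = -out
        return out

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


class MaxNormalize(TransformerMixin, BaseEstimator):
    """Scale each spectrum by its maximum absolute value."""

    def fit(self, X, y=None):
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        m = np.max(np.abs(X), axis=1, keepdims=True)
        zero = np.flatnonzero(m.ravel() == 0)
        if zero.size:
            raise DegenerateSpectrumError(
                f"all-zero spectrum at row {zero[0]}", row=int(zero[0])
            )
        return X / m

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


class RegionSelector(TransformerMixin, BaseEstimator):
    """Keep only the columns whose wavenumbers fall in the given regions.

    ``regions`` are closed (low, high) intervals in cm^-1; ``wavenumbers``
    is the grid the input columns are aligned to.
    """

    def __init__(self, regions: Sequence[tuple[float, float]], wavenumbers=None):
        self.regions = regions
        self.wavenumbers = wavenumbers

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if self.wavenumbers is None:
            raise ValueError("RegionSelector needs the wavenumber grid")
        wn = np.asarray(self.wavenumbers, dtype=float)
        if wn.size != X.shape[1]:
            raise ValueError("grid length does not match number of columns")
        mask = region_mask(wn, self.regions)
        if not mask.any():
            raise ValueError("no grid points inside the requested regions")
        self.n_features_in_ = X.shape[1]
        self.support_ = np.flatnonzero(mask)
        self.wavenumbers_ = wn[self.support_]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        return X[:, self.support_]

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


# -- functional wrappers ----------------------------------------------------

def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate of a single spectrum (sample sd, n-1)."""
    return SNV().fit_transform(np.asarray(x, dtype=float)[None, :])[0]


def detrend(x: np.ndarray, order: int = 2) -> np.ndarray:
    return Detrend(order=order).fit_transform(np.asarray(x, dtype=float)[None, :])[0]


def sg_derivative(
    x: np.ndarray,
    window: int = 7,
    polyorder: int = 2,
    deriv: int = 1,
    spacing: float = -4.0,
    per_index: bool = False,
) -> np.ndarray:
    op = SavitzkyGolayDerivative(window, polyorder, deriv, spacing, per_index)
    return op.fit_transform(np.asarray(x, dtype=float)[None, :])[0]


def max_normalize(x: np.ndarray) -> np.ndarray:
    return MaxNormalize().fit_transform(np.asarray(x, dtype=float)[None, :])[0]


# -- recipes ----------------------------------------------------------------

_OPERATOR_NAMES = {"detrend", "sg_derivative", "snv", "max_normalize", "region_select"}


@dataclass(frozen=True)
class PretreatmentRecipe:
    """Ordered list of pretreatment operator descriptors.

    Each step is ``(name, params)`` with ``name`` from the closed operator
    set. Recipes are declarative so they can round-trip through YAML config
    files and be rebuilt against any concrete grid.
    """

    steps: tuple[tuple[str, dict], ...] = ()
    name: str = "custom"

    def __post_init__(self):
        steps = tuple((n, dict(p)) for n, p in self.steps)
        object.__setattr__(self, "steps", steps)
        for op, params in steps:
            if op not in _OPERATOR_NAMES:
                raise ValueError(f"unknown operator {op!r}")
            if op == "sg_derivative":
                w = params.get("window", 7)
                if w not in _SG_WINDOWS:
                    raise ValueError(f"SG window must be one of {_SG_WINDOWS}")
                if params.get("deriv", 1) > params.get("polyorder", 2):
                    raise ValueError("derivative order exceeds polynomial order")

    def build(self, wavenumbers: np.ndarray) -> list[tuple[str, BaseEstimator]]:
        """Instantiate the transformers for a concrete grid.

        Returns (name, transformer) pairs; a ``region_select`` step narrows
        the grid seen by any later step.
        """
        wn = np.asarray(wavenumbers, dtype=float)
        spacing = float(wn[1] - wn[0]) if wn.size > 1 else 1.0
        out: list[tuple[str, BaseEstimator]] = []
        for op, params in self.steps:
            if op == "snv":
                out.append((op, SNV(**params)))
            elif op == "detrend":
                out.append((op, Detrend(**params)))
            elif op == "max_normalize":
                out.append((op, MaxNormalize(**params)))
            elif op == "sg_derivative":
                kw = dict(params)
                kw.setdefault("spacing", spacing)
                out.append((op, SavitzkyGolayDerivative(**kw)))
            elif op == "region_select":
                sel = RegionSelector(params["regions"], wavenumbers=wn)
                sel.fit(np.empty((1, wn.size)))
                wn = sel.wavenumbers_
                out.append((op, sel))
        return out

    def to_config(self) -> dict:
        return {
            "name": self.name,
            "steps": [{"op": op, **params} for op, params in self.steps],
        }


RECIPE_PHDIFF = PretreatmentRecipe(
    steps=(
        ("detrend", {"order": 2}),
        ("sg_derivative", {"window": 7, "polyorder": 2, "deriv": 1}),
        ("snv", {}),
    ),
    name="phdiff",
)

RECIPE_HPLC = PretreatmentRecipe(
    steps=(
        ("max_normalize", {}),
        ("sg_derivative", {"window": 7, "polyorder": 2, "deriv": 1}),
        ("snv", {}),
        ("region_select", {"regions": HPLC_MODEL_REGIONS}),
    ),
    name="hplc",
)

_BUILTIN_RECIPES = {"phdiff": RECIPE_PHDIFF, "hplc": RECIPE_HPLC}


def recipe_from_config(config: dict | str) -> PretreatmentRecipe:
    """Build a recipe from a YAML string or parsed mapping.

    A bare string (or ``{"name": ...}`` with no steps) refers to a built-in
    recipe by name; otherwise ``steps`` is a list of ``{op: ..., **params}``
    mappings applied in order.
    """
    if isinstance(config, str):
        parsed = yaml.safe_load(config)
        if isinstance(parsed, str):
            return _BUILTIN_RECIPES[parsed]
        config = parsed
    if "steps" not in config:
        return _BUILTIN_RECIPES[config["name"]]
    steps = []
    for step in config["steps"]:
        step = dict(step)
        op = step.pop("op")
        if op == "region_select" and "regions" in step:
            step["regions"] = [tuple(r) for r in step["regions"]]
        steps.append((op, step))
    return PretreatmentRecipe(steps=tuple(steps), name=config.get("name", "custom"))


def apply_recipe(s: SpectrumSet, recipe: PretreatmentRecipe) -> SpectrumSet:
    """Apply a pretreatment recipe to an averaged absorbance SpectrumSet.

    Operators run per sample in the listed order; a region-selection step
    narrows the grid for all subsequent steps. Operator failures are
    re-raised with the offending sample id attached.
    """
    if s.mode != "absorbance":
        raise ValueError("recipes apply to absorbance spectra; convert first")
    if len(s.samples) != len(s.sample_ids):
        raise ValueError("average replicates before applying a recipe")
    X = s.matrix().copy()
    wn = s.wavenumbers
    for op, transformer in recipe.build(wn):
        try:
            X = transformer.fit_transform(X)
        except DegenerateSpectrumError as exc:
            sid = s.sample_ids[exc.row] if exc.row is not None else "?"
            raise DegenerateSpectrumError(
                f"{op} failed for sample {sid!r}: {exc}", row=exc.row
            ) from exc
        if isinstance(transformer, RegionSelector):
            wn = transformer.wavenumbers_
    return SpectrumSet(
        wavenumbers=wn,
        sample_ids=s.sample_ids,
        replicate_ids=s.replicate_ids,
        intensities=X,
        mode="absorbance",
        metadata={**s.metadata, "recipe": recipe.name},
    )
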