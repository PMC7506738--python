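"""Containers and I/O for replicate NIR spectra on a fixed wavenumber grid.

A :class:`SpectrumSet` holds one or more replicate intensity vectors per
sample, all aligned to a single strictly monotone wavenumber grid.  The
instrument convention is followed: the default grid runs descending from
10,000 to 4000 cm^-1 at 4 cm^-1 point spacing (1501 points).  Spectra start
life as diffuse reflectance ``R`` and are converted to pseudo-absorbance
``A = log10(1/R)`` before any chemometric treatment; replicate averaging
happens after that nonlinear transform.

Region specifications are always closed ``(low, high)`` intervals in cm^-1,
independent of the grid storage order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSet",
    "default_grid",
    "read_spectra",
    "write_spectra",
    "read_reference_table",
    "reflectance_to_absorbance",
    "average_replicates",
    "restrict_to_regions",
]

_GRID_RTOL = 1e-9


def default_grid() -> np.ndarray:
    """Descending 10,000 -> 4000 cm^-1 grid at 4 cm^-1 spacing (1501 pts)."""
    return np.arange(10_000.0, 4000.0 - 2.0, -4.0)


@dataclass(frozen=True)
class SpectrumSet:
    """Replicate spectra for a set of samples on a common wavenumber grid.

    Attributes
    ----------
    wavenumbers : ndarray, shape (n_points,)
        Strictly monotone grid with constant spacing, cm^-1.
    sample_ids : ndarray of str, shape (n_spectra,)
        Sample identifier of each spectrum row (repeated across replicates).
    replicate_ids : ndarray of int, shape (n_spectra,)
        Replicate index of each row within its sample.
    intensities : ndarray, shape (n_spectra, n_points)
        Reflectance or absorbance values, one row per replicate spectrum.
    mode : {"reflectance", "absorbance"}
    metadata : dict
        Free-form instrument annotations.
    """

    wavenumbers: np.ndarray
    sample_ids: np.ndarray
    replicate_ids: np.ndarray
    intensities: np.ndarray
    mode: str = "reflectance"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        sids = np.asarray(self.sample_ids, dtype=object)
        rids = np.asarray(self.replicate_ids, dtype=int)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "sample_ids", sids)
        object.__setattr__(self, "replicate_ids", rids)

        if self.mode not in ("reflectance", "absorbance"):
            raise ValueError(f"mode must be reflectance or absorbance, got {self.mode!r}")
        if wn.ndim != 1 or wn.size < 2:
            raise ValueError("wavenumber grid must be 1-D with at least 2 points")
        steps = np.diff(wn)
        if not (np.all(steps > 0) or np.all(steps < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")
        # the grid must be a (possibly region-restricted) subset of a
        # regular lattice: every step an integer multiple of the base step
        base = np.abs(steps).min()
        ratio = np.abs(steps) / base
        if not np.allclose(ratio, np.round(ratio), rtol=_GRID_RTOL, atol=1e-6):
            raise ValueError("wavenumber grid spacing is not constant")
        if inten.ndim != 2 or inten.shape[1] != wn.size:
            raise ValueError(
                f"intensities must be (n_spectra, {wn.size}), got {inten.shape}"
            )
        if sids.shape != (inten.shape[0],) or rids.shape != (inten.shape[0],):
            raise ValueError("sample_ids/replicate_ids must match intensity rows")
        if not np.all(np.isfinite(inten)):
            bad = np.argwhere(~np.isfinite(inten))[0]
            raise ValueError(
                f"non-finite intensity for sample {sids[bad[0]]!r} "
                f"replicate {rids[bad[0]]}"
            )
        if self.mode == "reflectance" and np.any(inten <= 0):
            bad = np.argwhere(inten <= 0)[0]
            raise ValueError(
                f"nonpositive reflectance for sample {sids[bad[0]]!r} "
                f"replicate {rids[bad[0]]}"
            )

    # -- basic introspection ------------------------------------------------

    @property
    def samples(self) -> list[str]:
        """Ordered unique sample identifiers (first-appearance order)."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(s, None)
        return list(seen)

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    @property
    def spacing(self) -> float:
        """Grid point spacing in cm^-1 (absolute value)."""
        return float(abs(self.wavenumbers[1] - self.wavenumbers[0]))

    def replicates(self, sample_id: str) -> np.ndarray:
        """Intensity block (n_replicates, n_points) for one sample."""
        m = self.sample_ids == sample_id
        if not m.any():
            raise KeyError(sample_id)
        return self.intensities[m]

    def matrix(self) -> np.ndarray:
        """(n_samples, n_points) matrix; requires one spectrum per sample."""
        if len(self.samples) != len(self.sample_ids):
            raise ValueError("multiple replicates per sample; average first")
        return self.intensities

    # -- transforms ---------------------------------------------------------

    def to_absorbance(self) -> "SpectrumSet":
        """Convert reflectance to pseudo-absorbance a = -log10(r)."""
        if self.mode == "absorbance":
            return self
        if np.any(self.intensities <= 0):
            raise ValueError("reflectance must be strictly positive")
        return replace(
            self, intensities=-np.log10(self.intensities), mode="absorbance"
        )

    def average_replicates(self) -> "SpectrumSet":
        """Reduce each sample's replicates to their pointwise mean spectrum."""
        order = self.samples
        means = np.vstack([self.replicates(s).mean(axis=0) for s in order])
        return replace(
            self,
            sample_ids=np.asarray(order, dtype=object),
            replicate_ids=np.zeros(len(order), dtype=int),
            intensities=means,
        )

    def restrict_to_regions(
        self, regions: Sequence[tuple[float, float]]
    ) -> tuple["SpectrumSet", np.ndarray]:
        """Keep only grid points inside any closed (low, high) interval.

        Returns the restricted set and the retained-point index map into the
        original grid. Original point order is preserved.
        """
        mask = region_mask(self.wavenumbers, regions)
        if not mask.any():
            raise ValueError("no grid points fall inside the requested regions")
        idx = np.flatnonzero(mask)
        restricted = SpectrumSet(
            wavenumbers=self.wavenumbers[idx],
            sample_ids=self.sample_ids,
            replicate_ids=self.replicate_ids,
            intensities=self.intensities[:, idx],
            mode=self.mode,
            metadata=dict(self.metadata),
        )
        return restricted, idx

    # -- tabular form -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: sample_id, replicate, then one column per wavenumber."""
        df = pd.DataFrame(self.intensities, columns=[f"{w:g}" for w in self.wavenumbers])
        df.insert(0, "replicate", self.replicate_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def region_mask(
    wavenumbers: np.ndarray, regions: Iterable[tuple[float, float]]
) -> np.ndarray:
    """Boolean mask of grid points inside any closed (low, high) interval."""
    wn = np.asarray(wavenumbers, dtype=float)
    mask = np.zeros(wn.shape, dtype=bool)
    for low, high in regions:
        if low > high:
            raise ValueError(f"malformed region ({low}, {high}): low > high")
        mask |= (wn >= low) & (wn <= high)
    return mask


def read_spectra(
    path,
    *,
    mode: str = "reflectance",
    sep: str = ",",
    grid: np.ndarray | None = None,
) -> SpectrumSet:
    """Read a wide-layout delimited spectra table into a :class:`SpectrumSet`.

    The expected layout has a ``sample_id`` column, a ``replicate`` column
    and one numeric column per grid wavenumber (header row = wavenumbers in
    cm^-1). If ``grid`` is given, the file's grid must match it.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = {"sample_id", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError("spectra table needs 'sample_id' and 'replicate' columns")
    wn_cols = [c for c in df.columns if c not in required]
    try:
        wn = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavenumber header: {exc}") from None
    values = df[wn_cols].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("non-numeric intensity cells in spectra table")
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        if wn.shape != grid.shape or not np.allclose(wn, grid, rtol=1e-9):
            raise ValueError("file grid does not match the supplied grid")
    return SpectrumSet(
        wavenumbers=wn,
        sample_ids=df["sample_id"].to_numpy(dtype=object),
        replicate_ids=df["replicate"].to_numpy(dtype=int),
        intensities=values.astype(float),
        mode=mode,
    )


def write_spectra(s: SpectrumSet, path, *, sep: str = ",") -> None:
    """Write the wide-layout delimited table read back by :func:`read_spectra`."""
    # 17 significant digits round-trips IEEE doubles exactly
    s.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_reference_table(path, *, sep: str = ",") -> pd.DataFrame:
    """Read a reference TAC table (sample_id, tac_mg_per_kg, method, rsd_percent).

    Uncensored TAC values must be nonnegative and sample ids unique within
    each method tag.
    """
    df = pd.read_csv(path, sep=sep)
    if not {"sample_id", "tac_mg_per_kg"}.issubset(df.columns):
        raise ValueError("reference table needs sample_id and tac_mg_per_kg columns")
    if "method" not in df.columns:
        df["method"] = "ph_differential"
    if "censored" not in df.columns:
        df["censored"] = df["tac_mg_per_kg"].isna()
    ok = ~df["censored"]
    if (df.loc[ok, "tac_mg_per_kg"] < 0).any():
        raise ValueError("negative TAC in reference table")
    if df.groupby("method")["sample_id"].apply(lambda s: s.duplicated().any()).any():
        raise ValueError("duplicate sample ids within a method tag")
    return df


# Thin functional wrappers (module-level surface over the container methods).

def reflectance_to_absorbance(s: SpectrumSet) -> SpectrumSet:
    """a = -log10(r), elementwise; grid unchanged, mode set to absorbance."""
    if s.mode != "reflectance":
        raise ValueError("input set is not in reflectance mode")
    return s.to_absorbance()


def average_replicates(s: SpectrumSet) -> SpectrumSet:
    return s.average_replicates()


def restrict_to_regions(
    s: SpectrumSet, regions: Sequence[tuple[float, float]]
) -> tuple[SpectrumSet, np.ndarray]:
    return s.restrict_to_regions(regions)
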