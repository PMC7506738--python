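"""Wet-chemistry reference quantification arithmetic for anthocyanins.

Covers the photometric pH-differential assay (AOAC-style, cyanidin-3-O-
glucoside equivalents), the HPLC sum parameter over the three quantified
cyanidin glycosides, calibration-curve linearity with DIN 32645
calibration-curve detection/quantitation limits, Fisher's F-test for
comparing method variances, and repeatability relative standard deviations.

The pH-differential TAC in the measured dilution is

    TAC [mg/L] = A * MW * DF * 1000 / (eps * l)

with the differential absorbance
``A = (A520 - A700)_pH1.0 - (A520 - A700)_pH4.5``, molecular weight
MW = 449.2 g/mol of cyanidin-3-glucoside, dilution factor DF (30 in the
standard workflow), molar extinction coefficient eps = 26,900 L/(mol cm)
and path length l in cm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PhDiffMeasurement",
    "CalibrationCurve",
    "HplcSum",
    "FTestResult",
    "tac_ph_differential",
    "extract_to_fresh_weight",
    "hplc_sum_parameter",
    "fit_calibration",
    "lod_loq_din32645",
    "f_test_variances",
    "repeatability_rsd",
    "rsd_percent",
]

MW_CYANIDIN_3_GLUCOSIDE = 449.2     # g/mol
EPSILON_CYANIDIN_3_GLUCOSIDE = 26_900.0  # L mol^-1 cm^-1


@dataclass(frozen=True)
class PhDiffMeasurement:
    """Absorbance quadruple and constants feeding the pH-differential formula."""

    a520_ph1: float
    a700_ph1: float
    a520_ph45: float
    a700_ph45: float
    dilution_factor: float = 30.0
    molecular_weight: float = MW_CYANIDIN_3_GLUCOSIDE
    epsilon: float = EPSILON_CYANIDIN_3_GLUCOSIDE
    path_length_cm: float = 1.0

    def __post_init__(self):
        for name in ("dilution_factor", "molecular_weight", "epsilon", "path_length_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def differential_absorbance(self) -> float:
        return (self.a520_ph1 - self.a700_ph1) - (self.a520_ph45 - self.a700_ph45)


def tac_ph_differential(m: PhDiffMeasurement) -> float:
    """Total monomeric anthocyanin content, mg/L cyanidin-3-glucoside
    equivalents, in the solution as measured.

    A negative differential absorbance is physically meaningless but
    arithmetically defined; it is returned as-is with a warning.
    """
    a = m.differential_absorbance
    if a < 0:
        warnings.warn(
            "negative differential absorbance; TAC returned as-is", UserWarning
        )
    return a * m.molecular_weight * m.dilution_factor * 1000.0 / (
        m.epsilon * m.path_length_cm
    )


def extract_to_fresh_weight(
    tac_extract_mg_per_l: float,
    sample_mass_g: float = 1.0,
    extract_volume_ml: float = 10.0,
    extra_dilution: float = 10.0,
) -> float:
    """Convert an extract concentration (mg/L) to mg per kg fresh fruit.

    mg/L x mL / g is ug/g, i.e. mg/kg, so the chain is
    ``tac * extra_dilution * extract_volume_ml / sample_mass_g``.
    Defaults mirror the extraction workflow: 1 g berry homogenized into
    10 g (~10 mL) solvent, then diluted 1:10 before photometry (the
    photometric dilution factor lives inside the pH-differential formula).
    """
    if sample_mass_g <= 0:
        raise ValueError("sample mass must be positive")
    if extract_volume_ml <= 0 or extra_dilution <= 0:
        raise ValueError("volumes and dilution factors must be positive")
    return tac_extract_mg_per_l * extra_dilution * extract_volume_ml / sample_mass_g


@dataclass(frozen=True)
class HplcSum:
    """HPLC sum-parameter TAC with the censoring status of its inputs."""

    tac_mg_per_kg: float | None
    status: str  # "quantified" | "partial" | "below_loq"


def hplc_sum_parameter(
    c_glucoside: float | None,
    c_sambubioside: float | None,
    c_sambubioside_glucoside: float | None,
    loq: float | Sequence[float] | None = None,
) -> HplcSum:
    """Sum the three quantified cyanidin glycosides into the TAC parameter.

    ``None`` marks an analyte reported below its limit of quantitation;
    a numeric value below the corresponding ``loq`` is censored likewise.
    Censored analytes contribute 0 and the record is flagged "partial";
    with all three censored no numeric TAC is reported ("below_loq").
    """
    values = [c_glucoside, c_sambubioside, c_sambubioside_glucoside]
    if loq is None:
        loqs = [None, None, None]
    elif np.isscalar(loq):
        loqs = [float(loq)] * 3
    else:
        loqs = list(loq)
        if len(loqs) != 3:
            raise ValueError("need one LOQ per analyte")
    total = 0.0
    n_censored = 0
    for v, q in zip(values, loqs):
        if v is not None and v < 0:
            raise ValueError("negative analyte concentration")
        if v is None or (q is not None and v < q):
            n_censored += 1
            continue
        total += v
    if n_censored == 3:
        return HplcSum(tac_mg_per_kg=None, status="below_loq")
    status = "partial" if n_censored else "quantified"
    return HplcSum(tac_mg_per_kg=total, status=status)


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordinary least-squares calibration line response = slope*conc + intercept."""

    concentrations: tuple
    responses: tuple
    slope: float
    intercept: float
    residual_sd: float  # n-2 denominator
    r_squared: float

    @property
    def n(self) -> int:
        return len(self.concentrations)


def fit_calibration(concentrations, responses) -> CalibrationCurve:
    """Fit the calibration line; concentrations must be strictly increasing."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need >= 3 aligned calibration points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return CalibrationCurve(
        concentrations=tuple(x),
        responses=tuple(y),
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=float(np.sqrt(sse / (x.size - 2))),
        r_squared=1.0 - sse / sst if sst > 0 else 1.0,
    )


def lod_loq_din32645(
    curve: CalibrationCurve,
    alpha: float = 0.01,
    k_loq: float = 3.0,
    m: int = 1,
) -> tuple[float, float]:
    """Detection and quantitation limits from the calibration-curve method
    of DIN 32645.

    s_x0 = residual_sd / slope;
    LOD = s_x0 * t(1-alpha; n-2) * sqrt(1/m + 1/n + xbar^2/Sxx);
    LOQ = k_loq * LOD (quick-estimate convention). ``m`` is the number of
    replicate measurements of the future analysis sample.
    """
    if curve.slope == 0:
        raise ValueError("zero calibration slope; limits undefined")
    x = np.asarray(curve.concentrations, dtype=float)
    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    s_x0 = curve.residual_sd / abs(curve.slope)
    t_q = stats.t.ppf(1.0 - alpha, n - 2)
    lod = s_x0 * t_q * np.sqrt(1.0 / m + 1.0 / n + x.mean() ** 2 / sxx)
    return float(lod), float(k_loq * lod)


@dataclass(frozen=True)
class FTestResult:
    statistic: float
    critical_value: float
    comparable: bool
    df_num: int
    df_den: int
    alpha: float


def f_test_variances(y1, y2, alpha: float = 0.05) -> FTestResult:
    """Fisher's F-test on two method variances (two-sided, larger/smaller).

    ``comparable`` is True when F does not exceed the critical value, i.e.
    the variances are statistically indistinguishable at level ``alpha``.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.size < 2 or y2.size < 2:
        raise ValueError("each group needs at least 2 values")
    v1 = y1.var(ddof=1)
    v2 = y2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("both groups have zero variance; F undefined")
    if v1 >= v2:
        f, dfn, dfd = v1 / v2, y1.size - 1, y2.size - 1
    else:
        f, dfn, dfd = v2 / v1, y2.size - 1, y1.size - 1
    crit = stats.f.ppf(1.0 - alpha / 2.0, dfn, dfd)
    return FTestResult(
        statistic=float(f),
        critical_value=float(crit),
        comparable=bool(f <= crit),
        df_num=int(dfn),
        df_den=int(dfd),
        alpha=alpha,
    )


def rsd_percent(values) -> float:
    """Relative standard deviation, 100*sd/mean (sample sd)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mu = v.mean()
    if mu == 0:
        raise ValueError("zero mean; RSD undefined")
    return float(100.0 * v.std(ddof=1) / mu)


def repeatability_rsd(values_by_day: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Intra-day and inter-day repeatability RSDs in percent.

    Intra-day: RSD within a single day's replicates, averaged over days
    when several are supplied. Inter-day: RSD over all measurements pooled
    across days.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_day]
    if not groups or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 values per day")
    intraday = float(np.mean([rsd_percent(g) for g in groups]))
    interday = rsd_percent(np.concatenate(groups))
    return intraday, interday
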