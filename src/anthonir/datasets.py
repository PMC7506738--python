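"""Published elderberry reference tables bundled as loadable datasets.

Total anthocyanin content (TAC, mg per kg fresh fruit) of 27 wild elderberry
samples (``S`` ids) and 7 additional control samples (``R`` ids), quantified
by the two wet-chemistry reference methods:

* ``ph_differential`` — photometric pH-differential assay, cyanidin-3-O-
  glucoside equivalents;
* ``hplc_sum`` — sum of cyanidin-3-O-glucoside, cyanidin-3-O-sambubioside
  and cyanidin-3-O-sambubioside-5-O-glucoside quantified by
  UHPLC-MWD-UHR-TOF-MS. R-sample values fell below the limit of
  quantitation and are censored (NaN with ``censored=True``).

These tables are the printed inputs for method comparison and for pinning
the calibration ranges; the NIR spectra themselves were never deposited.
"""

from __future__ import annotations

import io

import pandas as pd

_PHDIFF_CSV = """\
sample_id,tac_mg_per_kg,rsd_percent
S1,2428.68,18.5
S3,3885.30,12.9
S6,1716.63,26.8
S7,3121.65,33.9
S9,3264.08,30.1
S10,1191.33,19.2
S11,4342.01,23.7
S12,898.39,24.1
S13,2034.47,12.9
S14,1190.72,18.9
S15,2879.10,17.4
S16,1452.55,28.3
S17,3443.98,33.4
S18,1820.62,33.1
S19,1089.76,21.2
S20,876.83,23.7
S21,632.87,24.1
S22,1330.89,12.9
S23,1132.08,11.5
S24,656.74,12.9
S25,624.12,11.5
S26,1099.06,12.7
S27,1218.08,12.2
S28,1447.48,4.2
S29,1380.31,20.0
S30,1908.79,15.5
S31,1851.28,11.9
R1,168.10,25.8
R2,121.07,33.9
R3,235.73,30.1
R4,276.64,13.2
R5,172.00,20.7
R6,206.23,25.1
R7,240.74,17.9
"""

_HPLC_CSV = """\
sample_id,tac_mg_per_kg,rsd_percent
S1,4491.57,2
S3,6866.07,4
S6,2421.38,3
S7,5718.50,5
S9,5563.06,6
S10,2388.63,4
S11,8311.39,3
S12,1154.70,6
S13,2824.30,5
S14,1560.03,1
S15,4277.62,3
S16,2136.57,6
S17,4211.50,5
S18,2644.24,5
S19,1366.76,4
S20,1196.72,5
S21,823.35,1
S22,1710.49,2
S23,1399.16,3
S24,783.02,1
S25,499.43,6
S26,997.69,5
S27,674.17,2
S28,1025.82,1
S29,1581.02,1
S30,1289.57,2
S31,776.00,4
R1,,
R2,,
R3,,
R4,,
R5,,
R6,,
R7,,
"""


def load_reference_table(method: str = "ph_differential") -> pd.DataFrame:
    """Load a published TAC reference table.

    Parameters
    ----------
    method : {"ph_differential", "hplc_sum"}
        Which reference method's table to load.

    Returns
    -------
    pandas.DataFrame
        Columns ``sample_id``, ``tac_mg_per_kg``, ``rsd_percent``,
        ``method``, ``censored``. HPLC control (R) samples are below the
        limit of quantitation: ``tac_mg_per_kg`` is NaN and ``censored``
        is True.
    """
    if method == "ph_differential":
        df = pd.read_csv(io.StringIO(_PHDIFF_CSV))
    elif method == "hplc_sum":
        df = pd.read_csv(io.StringIO(_HPLC_CSV))
    else:
        raise ValueError(f"unknown reference method: {method!r}")
    df["method"] = method
    df["censored"] = df["tac_mg_per_kg"].isna()
    return df


def load_study_samples(method: str = "ph_differential") -> pd.DataFrame:
    """Reference table restricted to the 27 wild (S) elderberry samples."""
    df = load_reference_table(method)
    return df[df["sample_id"].str.startswith("S")].reset_index(drop=True)
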