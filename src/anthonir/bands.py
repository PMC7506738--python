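"""NIR band assignments for cyanidin-3-O-glucoside and model region lists.

The band table lists first-overtone and binary-combination transitions of
cyanidin-3-O-glucoside obtained from anharmonic (VPT2-level) quantum-chemical
calculation.  Notation: ``2`` marks a first overtone, ``+`` a combination
transition, ``v`` a stretching mode, ``d`` a deformation mode, ``as``/``s``
antisymmetric/symmetric.  Centers are in cm^-1; the calculation yields no
bandwidths or reliable relative intensities, so those are modelling choices
(see :mod:`anthonir.synthdata`).

The two region lists are the wavenumber windows found meaningful for
predicting total anthocyanin content by PLSR against each reference method
(jack-knife uncertainty-test selection), given as closed ``(low, high)``
intervals in cm^-1.
"""

from __future__ import annotations

# (center cm^-1, assignment)
CYANIDIN_GLUCOSIDE_BANDS: list[tuple[float, str]] = [
    (6990.7, "vOH + vOH"),
    (6958.1, "vOH + vOH"),
    (6840.3, "2vOH"),
    (6802.7, "2vOH"),
    (6821.4, "2vOH"),
    (6782.7, "2vOH"),
    (6773.5, "2vOH"),
    (6701.6, "2vOH"),
    (6588.1, "2vOH"),
    (6576.4, "2vOH"),
    (6219.2, "vCH + vOH"),
    (6173.8, "vCH + vOH"),
    (6108.6, "vCH + vOH"),
    (6013.0, "(vasCH2, vCH) + vOH"),
    (5414.1, "vCH + vCH"),
    (5324.9, "2(vsCH2, vCH)"),
    (5289.9, "(vasCH2, vCH) + vsCH2"),
    (5220.8, "2vCH"),
    (5074.2, "dring + vOH"),
    (5024.2, "dring + vOH"),
    (4896.3, "dCOH + vOH"),
    (4875.2, "dCOH + vOH"),
    (4839.0, "dCOH + vOH"),
    (4787.7, "dCOH + vOH"),
    (4729.9, "dring, dCOH + vOH"),
    (4680.9, "dring, dCOH + vOH"),
    (4650.1, "dring + vOH"),
    (4606.8, "dring + vOH"),
    (4585.3, "dCH + vOH"),
    (4495.7, "dCH + vOH"),
    (4287.6, "dring + vCH"),
    (4190.1, "(dring, dCOH) + vCH"),
    (4084.3, "(dring, dCOH) + vCH"),
]

#: Water matrix bands dominating fresh-fruit NIR spectra: the O-H stretching
#: first overtone near 6900 cm^-1 and the O-H stretching + deformation
#: combination near 5188 cm^-1.
WATER_BANDS: list[tuple[float, str]] = [
    (6900.0, "2vOH (water)"),
    (5188.0, "vOH + dOH (water)"),
]

#: Meaningful regions for the PLSR model calibrated against the HPLC
#: (UHPLC-MWD-UHR-TOF-MS) sum-parameter reference.
HPLC_MODEL_REGIONS: list[tuple[float, float]] = [
    (4188.0, 4516.0),
    (4704.0, 4716.0),
    (4772.0, 4924.0),
    (4976.0, 5076.0),
    (5188.0, 5276.0),
    (5812.0, 5900.0),
    (6416.0, 6432.0),
    (7100.0, 7208.0),
    (8956.0, 8968.0),
]

#: Meaningful regions for the PLSR model calibrated against the
#: pH-differential reference.
PHDIFF_MODEL_REGIONS: list[tuple[float, float]] = [
    (4256.0, 4296.0),
    (4336.0, 4408.0),
    (4972.0, 5160.0),
    (5204.0, 5344.0),
    (7072.0, 7216.0),
    (8712.0, 8752.0),
    (8792.0, 8804.0),
]
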