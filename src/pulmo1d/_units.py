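"""Exact unit-conversion constants.

All solver-internal computation is SI (m, s, kg, Pa).  Public interfaces use
the field's customary units: pressures in mmHg, flows in mL/s, lengths in cm,
moduli in kPa.  Conversions happen once, at the interface.
"""

MMHG_TO_PA = 133.322387415
PA_TO_MMHG = 1.0 / MMHG_TO_PA
KPA_TO_PA = 1000.0
KPA_TO_MMHG = KPA_TO_PA * PA_TO_MMHG
CM_TO_M = 1.0e-2
CM2_TO_M2 = 1.0e-4
ML_TO_M3 = 1.0e-6
M3_TO_ML = 1.0e6
G_PER_ML_TO_KG_PER_M3 = 1000.0
CM2S_TO_M2S = 1.0e-4
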