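"""Bundled reference measurements for a family of hypertrophy models.

These small tables describe a healthy control heart and thirty derived
hypertrophy models (eccentric, asymmetric-concentric and symmetric-concentric
at +10%..+100% LV mass): imaging-derived LV tissue volume / mass / height-
indexed mass with the image-based LVH flag, and the three voltage-criterion
values measured on the corresponding simulated ECGs.  They are used by the
worked examples and by validation tests of the mass-bookkeeping and
criterion-metric operations.  The reference subject's height is 1.92 m.

Known internal inconsistencies of the source tables (kept verbatim): the
asymmetric-concentric rows at +70%..+100% print masses that do not equal
volume x density while their indices follow volume / height^2.7 without the
density factor, and the eccentric precision/F footer does not match the
printed values.  The validation tests document rather than hide these.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "REFERENCE_HEIGHT_M",
    "reference_mass_table",
    "reference_criteria_table",
]

REFERENCE_HEIGHT_M = 1.92

_MASS_CSV = """model,growth_type,level,tissue_volume_ml,mass_g,mass_index,hypertrophy
Healthy,none,0.0,211.88,223.11,38.34,False
E 10%,eccentric,0.1,234.79,247.23,42.48,False
E 20%,eccentric,0.2,257.11,270.74,46.52,False
E 30%,eccentric,0.3,277.18,291.87,50.15,False
E 40%,eccentric,0.4,298.48,314.30,54.00,True
E 50%,eccentric,0.5,319.78,336.73,57.86,True
E 60%,eccentric,0.6,342.38,360.53,61.95,True
E 70%,eccentric,0.7,361.01,380.15,65.32,True
E 80%,eccentric,0.8,382.60,402.88,69.23,True
E 90%,eccentric,0.9,400.70,421.93,72.50,True
E 100%,eccentric,1.0,421.94,444.30,76.34,True
AC 10%,concentric_asymmetric,0.1,238.89,251.55,43.22,False
AC 20%,concentric_asymmetric,0.2,255.48,269.02,46.22,False
AC 30%,concentric_asymmetric,0.3,268.89,283.14,48.65,False
AC 40%,concentric_asymmetric,0.4,284.22,299.28,51.42,True
AC 50%,concentric_asymmetric,0.5,308.77,325.13,55.87,True
AC 60%,concentric_asymmetric,0.6,336.32,354.15,60.85,True
AC 70%,concentric_asymmetric,0.7,373.18,448.32,64.12,True
AC 80%,concentric_asymmetric,0.8,405.73,487.41,69.71,True
AC 90%,concentric_asymmetric,0.9,440.82,529.57,75.74,True
AC 100%,concentric_asymmetric,1.0,451.71,542.66,77.62,True
SC 10%,concentric_symmetric,0.1,235.29,247.76,42.57,False
SC 20%,concentric_symmetric,0.2,255.77,269.33,46.28,False
SC 30%,concentric_symmetric,0.3,274.98,289.56,49.75,False
SC 40%,concentric_symmetric,0.4,297.00,312.75,53.74,True
SC 50%,concentric_symmetric,0.5,317.35,334.16,57.42,True
SC 60%,concentric_symmetric,0.6,341.80,359.91,61.84,True
SC 70%,concentric_symmetric,0.7,360.31,379.41,65.19,True
SC 80%,concentric_symmetric,0.8,381.41,401.62,69.01,True
SC 90%,concentric_symmetric,0.9,405.67,427.17,73.40,True
SC 100%,concentric_symmetric,1.0,424.53,447.03,76.81,True
"""

# criterion values (mV) on the simulated ECGs plus the image-based truth star
_CRITERIA_CSV = """model,growth_type,level,truth,sokolow,cornell,peguero
Healthy,none,0.0,False,2.91,1.31,1.93
E 10%,eccentric,0.1,False,3.16,1.61,2.22
E 20%,eccentric,0.2,False,3.37,1.68,2.28
E 30%,eccentric,0.3,False,3.57,1.82,2.47
E 40%,eccentric,0.4,True,3.74,1.97,2.57
E 50%,eccentric,0.5,True,3.95,2.01,2.60
E 60%,eccentric,0.6,True,4.27,2.18,2.86
E 70%,eccentric,0.7,True,4.38,2.42,2.92
E 80%,eccentric,0.8,True,4.57,2.46,3.05
E 90%,eccentric,0.9,True,4.74,2.67,3.08
E 100%,eccentric,1.0,True,4.87,2.85,3.31
AC 10%,concentric_asymmetric,0.1,False,3.03,1.40,2.05
AC 20%,concentric_asymmetric,0.2,False,3.05,1.33,2.18
AC 30%,concentric_asymmetric,0.3,False,3.14,1.35,2.19
AC 40%,concentric_asymmetric,0.4,True,3.27,1.31,2.13
AC 50%,concentric_asymmetric,0.5,True,3.39,1.22,2.11
AC 60%,concentric_asymmetric,0.6,True,3.26,0.64,2.06
AC 70%,concentric_asymmetric,0.7,True,3.17,0.63,2.31
AC 80%,concentric_asymmetric,0.8,True,3.16,0.75,2.18
AC 90%,concentric_asymmetric,0.9,True,3.15,0.49,2.30
AC 100%,concentric_asymmetric,1.0,True,3.09,0.45,2.49
SC 10%,concentric_symmetric,0.1,False,3.2,0.76,1.79
SC 20%,concentric_symmetric,0.2,False,3.49,1.04,2.13
SC 30%,concentric_symmetric,0.3,False,3.36,0.78,2.02
SC 40%,concentric_symmetric,0.4,True,3.51,0.69,2.32
SC 50%,concentric_symmetric,0.5,True,3.42,0.92,2.43
SC 60%,concentric_symmetric,0.6,True,3.63,0.69,2.35
SC 70%,concentric_symmetric,0.7,True,3.5,0.72,2.46
SC 80%,concentric_symmetric,0.8,True,3.46,0.71,2.46
SC 90%,concentric_symmetric,0.9,True,3.43,0.64,2.44
SC 100%,concentric_symmetric,1.0,True,3.43,0.92,2.52
"""


def reference_mass_table() -> pd.DataFrame:
    """31 models: tissue volume (ml), mass (g), mass index (g m^-2.7), flag."""
    return pd.read_csv(io.StringIO(_MASS_CSV))


def reference_criteria_table() -> pd.DataFrame:
    """31 models: voltage-criterion values (mV) and the image-based truth flag."""
    return pd.read_csv(io.StringIO(_CRITERIA_CSV))
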