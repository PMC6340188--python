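"""Static reference table of fetal flow distributions across methods.

Literature values of mean indexed flow (mL/min per kg fetal body weight)
and the same values expressed as a percentage of combined ventricular
output (%CVO), for the major fetal vessels and shunts, as measured with
different modalities in human, mouse and sheep fetuses.  The
``sheep_4d_flow`` row is the one this package's default phantom network
is anchored to.

Vessel abbreviations: MPA main pulmonary artery, AAo ascending aorta,
SVC superior vena cava, DA ductus arteriosus, PBF pulmonary blood flow
(LPA+RPA), DAo descending aorta, UV umbilical vein, FO foramen ovale,
IVCd/IVCp distal/proximal inferior vena cava, DV ductus venosus.
"""

from __future__ import annotations

import pandas as pd

VESSELS = ["MPA", "AAo", "SVC", "DA", "PBF", "DAo", "UV", "FO", "IVCd", "IVCp", "DV"]

# mean indexed flow, mL/min per kg; None where not measured
_MEAN_FLOW = {
    #                 CVO  MPA  AAo  SVC   DA PBF  DAo   UV   FO IVCd IVCp   DV
    "human_2d_pc": [465, 261, 191, 137, 187, 74, 252, 134, 135, None, None, None],
    "mouse_ultrasound": [1020, 550, 470, 210, 340, 210, 410, 130, 270, None, 290, 90],
    "sheep_microspheres": [450, 300, 137, 108, 260, 36, 305, 180, 115, 125, 305, 100],
    "sheep_2d_pc": [517, 266, 236, 121, 200, 89, 352, 213, 164, None, None, 105],
    "sheep_4d_flow": [546, 284, 245, 181, 265, 38, 333, 197, 174, 117, 357, 144],
}

# the same rows as printed integer %CVO
_PCT_CVO = {
    "human_2d_pc": [56, 41, 29, 40, 15, 54, 29, 29, None, None, None],
    "mouse_ultrasound": [52, 48, 23, 36, 21, 42, 14, 31, None, 30, 10],
    "sheep_microspheres": [67, 30, 24, 58, 8, 68, 40, 26, 28, 68, 22],
    "sheep_2d_pc": [51, 46, 23, 39, 17, 68, 41, 32, None, None, 20],
    "sheep_4d_flow": [52, 45, 33, 48, 7, 61, 36, 32, 21, 65, 26],
}


def reference_mean_flows() -> pd.DataFrame:
    """Mean indexed flows (mL/min per kg) by method; columns CVO + vessels."""
    return pd.DataFrame.from_dict(_MEAN_FLOW, orient="index", columns=["CVO"] + VESSELS).astype(
        "float64"
    )


def reference_pct_cvo() -> pd.DataFrame:
    """Printed integer %CVO by method; columns are vessels."""
    return pd.DataFrame.from_dict(_PCT_CVO, orient="index", columns=VESSELS).astype("Float64")


def sheep_4d_flows() -> dict[str, float]:
    """Indexed mean flows (mL/min per kg) of the sheep 4D-flow cohort."""
    row = _MEAN_FLOW["sheep_4d_flow"]
    out = {"CVO": float(row[0])}
    out.update({v: float(x) for v, x in zip(VESSELS, row[1:])})
    return out
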