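"""Reference ROI measurements of a pelvis-phantom scatter-correction
experiment, used to validate the image-quality metric arithmetic.

Ten circular ROIs (six in the muscle-equivalent background, one each in
adipose, bladder, uterus and rectum) with mean CT numbers from the
registered planning CT, the scatter-corrected CBCT and the uncorrected raw
CBCT of the same phantom.  Feeding the corrected/raw columns against the CT
column through :func:`cbctsc.metrics.rmse` and :func:`cbctsc.metrics.snu`
reproduces the study-level summary values (corrected RMSE 9.3 HU, raw
RMSE 509.6 HU, corrected muscle SNU 16 HU, raw muscle SNU 107 HU).
"""

from __future__ import annotations

#: ROI name -> (registered CT, corrected CBCT, raw CBCT) mean HU
REFERENCE_PHANTOM_ROI_MEANS: dict[str, tuple[float, float, float]] = {
    "muscle_1": (134.0, 140.0, -384.0),
    "muscle_2": (127.0, 126.0, -441.0),
    "muscle_3": (134.0, 142.0, -353.0),
    "muscle_4": (125.0, 138.0, -334.0),
    "muscle_5": (121.0, 129.0, -435.0),
    "muscle_6": (131.0, 139.0, -375.0),
    "adipose": (-112.0, -108.0, -128.0),
    "bladder": (191.0, 205.0, -340.0),
    "uterus": (196.0, 181.0, -416.0),
    "rectum": (199.0, 199.0, -380.0),
}

MUSCLE_ROIS = tuple(f"muscle_{i}" for i in range(1, 7))

#: Printed per-ROI HU errors (corrected, raw) of the same experiment.  Two
#: corrected entries differ by 1 HU from subtracting the rounded means
#: above (the study rounded means and errors independently); the error
#: columns are the authoritative inputs for the RMSE summary.
REFERENCE_PHANTOM_HU_ERRORS: dict[str, tuple[float, float]] = {
    "muscle_1": (6.0, -518.0),
    "muscle_2": (-1.0, -569.0),
    "muscle_3": (8.0, -487.0),
    "muscle_4": (13.0, -459.0),
    "muscle_5": (9.0, -556.0),
    "muscle_6": (9.0, -505.0),
    "adipose": (4.0, -16.0),
    "bladder": (14.0, -532.0),
    "uterus": (-15.0, -612.0),
    "rectum": (0.0, -579.0),
}


def reference_columns() -> tuple[list[float], list[float], list[float]]:
    """(registered CT, corrected, raw) mean vectors in catalog order."""
    ct = [v[0] for v in REFERENCE_PHANTOM_ROI_MEANS.values()]
    corrected = [v[1] for v in REFERENCE_PHANTOM_ROI_MEANS.values()]
    raw = [v[2] for v in REFERENCE_PHANTOM_ROI_MEANS.values()]
    return ct, corrected, raw
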