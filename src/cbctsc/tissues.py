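"""Tissue classes and HU threshold windows.

Four tissue classes are distinguished by HU windowing of a high-quality
planning CT: air, adipose (fat), muscle and bone.  Voxels whose CT number
falls between windows ("gap" voxels, e.g. many soft-tissue materials around
100-190 HU) are treated as air for labelling purposes but flagged as
unclassified so that downstream steps can exclude them.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np


class TissueClass(IntEnum):
    AIR = 0
    FAT = 1
    MUSCLE = 2
    BONE = 3


#: Default HU windows per class: closed intervals except bone, which is
#: open-ended above its lower bound (strictly > 190 HU).
DEFAULT_HU_WINDOWS: dict[TissueClass, tuple[float, float]] = {
    TissueClass.AIR: (-1024.0, -500.0),
    TissueClass.FAT: (-125.0, -60.0),
    TissueClass.MUSCLE: (15.0, 85.0),
    TissueClass.BONE: (190.0, np.inf),
}


def validate_windows(windows: dict[TissueClass, tuple[float, float]]) -> None:
    for cls, (lo, hi) in windows.items():
        if not lo < hi:
            raise ValueError(f"window for {cls.name} is empty: [{lo}, {hi}]")
    spans = sorted(windows.values())
    for (_, hi_a), (lo_b, _) in zip(spans, spans[1:]):
        if lo_b < hi_a:
            raise ValueError("HU windows must be pairwise disjoint")


def in_window(
    hu: np.ndarray | float, cls: TissueClass, windows=None
) -> np.ndarray | bool:
    """Window membership test.  Bone uses a strict lower bound (> 190 HU)."""
    windows = DEFAULT_HU_WINDOWS if windows is None else windows
    lo, hi = windows[cls]
    hu = np.asarray(hu)
    if cls is TissueClass.BONE:
        return (hu > lo) & (hu <= hi) if np.isfinite(hi) else hu > lo
    return (hu >= lo) & (hu <= hi)


def classify_hu(hu: float, windows=None) -> TissueClass | None:
    """Class of a single HU value, or ``None`` for gap-class values."""
    windows = DEFAULT_HU_WINDOWS if windows is None else windows
    for cls in TissueClass:
        if bool(in_window(hu, cls, windows)):
            return cls
    return None
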