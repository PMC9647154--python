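"""ROI statistics and image-quality metrics (RMSE, SNU, CNR).

Given per-ROI mean CT numbers of a test image and a reference image, the
overall accuracy is

    RMSE = sqrt( (1/n) * sum_i (HU_test_i - HU_ref_i)^2 )        [HU]

the spatial nonuniformity of one tissue across its ROIs is

    SNU = max_i HU_i - min_i HU_i                                [HU]

and the contrast-to-noise ratio between a target ROI r and a background b is

    CNR = |HU_r - HU_b| / sigma_r

with sigma_r the standard deviation inside the target ROI (sample std,
n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import ROISpec
from .volume import VoxelVolume


@dataclass
class ROIStats:
    name: str
    mean: float
    std: float
    range: tuple[float, float]
    n_voxels: int


@dataclass
class MetricsReport:
    roi_stats: list[ROIStats]
    rmse_hu: float
    snu_hu: dict[str, float]  # per tissue with >= 2 ROIs
    cnr: float | None


def _roi_values(volume: VoxelVolume, roi: ROISpec, mode: str) -> np.ndarray:
    if mode == "sphere":
        m = roi.mask(volume)
    elif mode == "disc":
        # circle on the axial slice nearest the ROI centre (as drawn on 2D views)
        iz = int(round((roi.center[0] - volume.origin[0]) / volume.spacing[0]))
        iz = min(max(iz, 0), volume.shape[0] - 1)
        _, y, x = volume.world_grid()
        d2 = (y[0] - roi.center[1]) ** 2 + (x[0] - roi.center[2]) ** 2
        m = np.zeros(volume.shape, dtype=bool)
        m[iz] = d2 <= roi.radius**2
    else:
        raise ValueError(f"unknown ROI mode {mode!r}")
    vals = volume.data[m]
    if vals.size == 0:
        raise ValueError(f"ROI {roi.name!r} contains no voxels")
    return vals


def roi_stats(
    volume: VoxelVolume, rois: list[ROISpec], mode: str = "sphere"
) -> list[ROIStats]:
    """Sample mean, sample std (n-1) and value range per ROI."""
    out = []
    for roi in rois:
        vals = _roi_values(volume, roi, mode)
        std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out.append(
            ROIStats(roi.name, float(vals.mean()), std,
                     (float(vals.min()), float(vals.max())), int(vals.size))
        )
    return out


def rmse(test_means, ref_means) -> float:
    """Root-mean-square error between paired per-ROI means (HU)."""
    t = np.asarray(test_means, dtype=float)
    r = np.asarray(ref_means, dtype=float)
    if t.shape != r.shape or t.ndim != 1 or t.size < 1:
        raise ValueError("need two equal-length 1D mean vectors, n >= 1")
    return float(np.sqrt(np.mean((t - r) ** 2)))


def snu(same_tissue_means) -> float:
    """Spatial nonuniformity: max - min of same-tissue ROI means (HU)."""
    m = np.asarray(same_tissue_means, dtype=float)
    if m.size < 2:
        raise ValueError("SNU needs at least two ROIs of the same tissue")
    return float(m.max() - m.min())


def cnr(
    volume: VoxelVolume,
    target: ROISpec,
    background: ROISpec | list[ROISpec],
    mode: str = "sphere",
) -> float:
    """Contrast-to-noise ratio |mean_t - mean_b| / std_t.

    ``background`` may be one ROI or a list whose voxels are pooled.
    """
    tv = _roi_values(volume, target, mode)
    bgs = background if isinstance(background, list) else [background]
    bv = np.concatenate([_roi_values(volume, b, mode) for b in bgs])
    sigma = float(tv.std(ddof=1))
    if sigma == 0.0:
        raise ValueError("target ROI has zero standard deviation")
    return float(abs(tv.mean() - bv.mean()) / sigma)


def metrics_report(
    volume: VoxelVolume,
    reference: VoxelVolume,
    rois: list[ROISpec],
    cnr_target: str | None = None,
    mode: str = "sphere",
) -> MetricsReport:
    """Full report: per-ROI stats, RMSE vs reference, per-tissue SNU, CNR.

    CNR uses ``cnr_target`` (ROI name) against the pooled background-role
    ROIs; omitted if no target is named.
    """
    stats = roi_stats(volume, rois, mode)
    ref_stats = roi_stats(reference, rois, mode)
    rmse_hu = rmse([s.mean for s in stats], [s.mean for s in ref_stats])
    by_tissue: dict[str, list[float]] = {}
    for roi, s in zip(rois, stats):
        by_tissue.setdefault(roi.tissue_class, []).append(s.mean)
    snu_hu = {t: snu(m) for t, m in by_tissue.items() if len(m) >= 2}
    cnr_val = None
    if cnr_target is not None:
        target = next(r for r in rois if r.name == cnr_target)
        background = [r for r in rois if r.role == "background"
                      and r.tissue_class == "muscle"]
        cnr_val = cnr(volume, target, background, mode)
    return MetricsReport(stats, rmse_hu, snu_hu, cnr_val)
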