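"""Hybrid-domain CBCT scatter correction using a planning-CT prior.

The correction runs in six steps:

1.  Reference tissue attenuation coefficients (air/fat/muscle/bone) are read
    off the planning CT: per tissue window, the histogram mode in HU is
    converted to a LAC via ``mu = HU/1000*mu_w + mu_w``.
2.  A single empirical uniform scatter level ``s_bar`` is subtracted from
    the raw projections in the intensity domain (chosen so that 90% of the
    object pixels are larger; a soft-cut keeps the result positive) and a
    first-pass volume ``CBCT_c`` is reconstructed with FDK.
3.  The volume is segmented into the four tissue classes by HU windowing
    (by default the windows are applied to the prior and the labels are
    transferred rigidly) and a piecewise-constant template ``CBCT_t`` is
    built by filling each class with its reference LAC.
4.  The scatter ratio ``r = CBCT_t / CBCT_c`` is computed and a binary mask
    ``f`` keeps only trustworthy samples: ``f = 0`` where ``|r|`` or the
    in-plane gradient ``|grad r|`` exceeds its 80th-percentile threshold,
    where the voxel class is uncertain, outside the body, or inside the
    applicator.
5.  The sparsely sampled ratio is spread into a smooth field by masked
    normalised convolution per axial slice: ``r_f = (r*f)**w / (f**w)``
    with a 2D Gaussian ``w``.
6.  The corrected volume is ``CBCT_fc = CBCT_c * r_f``; finally the rigid
    applicator model replaces the blooming applicator footprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy import ndimage

from .fdk import DEFAULT_MU_W, ReconGrid, fdk_reconstruct, hu_to_lac, lac_to_hu
from .projector import INTENSITY, ProjectionStack, to_line_integral
from .tissues import DEFAULT_HU_WINDOWS, TissueClass, in_window, validate_windows
from .volume import VoxelVolume, resample_to

log = logging.getLogger(__name__)

#: Label used for applicator voxels in template label volumes (tissue
#: classes occupy 0..3).
APPLICATOR_CLASS = 4


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: smallest value with at least q*n below-or-equal."""
    v = np.sort(np.asarray(values).ravel())
    if v.size == 0:
        raise ValueError("empty sample")
    rank = int(np.ceil(q * v.size))
    rank = min(max(rank, 1), v.size)
    return float(v[rank - 1])


# ---------------------------------------------------------------------------
# Step 1: reference LACs from the prior


@dataclass
class TissueLACTable:
    """Reference per-class LACs (1/mm) plus the HU windows that defined them."""

    mu_air: float
    mu_fat: float
    mu_muscle: float
    mu_bone: float
    mu_w: float = DEFAULT_MU_W
    hu_windows: dict = field(default_factory=lambda: dict(DEFAULT_HU_WINDOWS))

    def __post_init__(self) -> None:
        if not self.mu_air < self.mu_fat < self.mu_muscle < self.mu_bone:
            raise ValueError(
                "tissue LACs must be ordered air < fat < muscle < bone, got "
                f"{self.mu_air}, {self.mu_fat}, {self.mu_muscle}, {self.mu_bone}"
            )
        validate_windows(self.hu_windows)

    def lac_of(self, cls: TissueClass) -> float:
        return {
            TissueClass.AIR: self.mu_air,
            TissueClass.FAT: self.mu_fat,
            TissueClass.MUSCLE: self.mu_muscle,
            TissueClass.BONE: self.mu_bone,
        }[cls]


def _window_mode_hu(values: np.ndarray, lo: float, hi: float) -> float:
    """Histogram mode at 1-HU binning; ties break toward the window centre."""
    if not np.isfinite(hi):
        hi = float(values.max())
    edges = np.arange(np.floor(lo), np.ceil(hi) + 1.0 + 1e-9)
    counts, _ = np.histogram(values, bins=edges)
    centres = (edges[:-1] + edges[1:]) / 2.0
    best = counts.max()
    cand = centres[counts == best]
    window_centre = (lo + hi) / 2.0
    return float(cand[np.argmin(np.abs(cand - window_centre))])


def extract_tissue_lacs(
    prior_hu: VoxelVolume,
    hu_windows: dict | None = None,
    mu_w: float = DEFAULT_MU_W,
    min_class_voxels: int = 100,
) -> TissueLACTable:
    """Per-class histogram mode of the prior, converted to LAC.

    Negative LACs (possible if the air mode drifts slightly below -1000 HU)
    are clamped to zero.
    """
    windows = dict(DEFAULT_HU_WINDOWS) if hu_windows is None else dict(hu_windows)
    validate_windows(windows)
    mus = {}
    for cls in TissueClass:
        sel = in_window(prior_hu.data, cls, windows)
        vals = prior_hu.data[sel]
        if vals.size < min_class_voxels:
            raise ValueError(
                f"only {vals.size} voxels in the {cls.name} window "
                f"(need >= {min_class_voxels}); prior does not cover this class"
            )
        mode_hu = _window_mode_hu(vals, *windows[cls])
        mus[cls] = max(mode_hu / 1000.0 * mu_w + mu_w, 0.0)
    return TissueLACTable(
        mus[TissueClass.AIR], mus[TissueClass.FAT],
        mus[TissueClass.MUSCLE], mus[TissueClass.BONE],
        mu_w=mu_w, hu_windows=windows,
    )


# ---------------------------------------------------------------------------
# Step 2: uniform scatter subtraction and first-pass reconstruction


@dataclass
class UniformScatterEstimate:
    """One global scatter constant per scan (intensity units).

    ``s_bar`` is the value actually subtracted; ``s_bar_percentile`` the raw
    percentile-rule value before the linear-regime guard (they coincide when
    the guard is off or inactive).
    """

    s_bar: float
    percentile_rule: float = 0.90  # fraction of object pixels larger than s_bar
    object_mask_rule: float = 0.90  # object pixels have I < rule * I0
    s_bar_percentile: float | None = None

    def __post_init__(self) -> None:
        if self.s_bar < 0:
            raise ValueError("s_bar must be >= 0")
        if self.s_bar_percentile is None:
            self.s_bar_percentile = self.s_bar


def estimate_uniform_scatter(
    stack: ProjectionStack,
    percentile_rule: float = 0.90,
    object_mask_rule: float = 0.90,
) -> UniformScatterEstimate:
    """Empirical uniform scatter: the intensity that ``percentile_rule`` of
    all object pixels (pooled over views) exceed."""
    if stack.domain != INTENSITY:
        raise ValueError("estimate_uniform_scatter expects an intensity stack")
    obj = stack.data[stack.data < object_mask_rule * stack.geometry.I0]
    if obj.size < 0.01 * stack.data.size:
        raise ValueError(
            "fewer than 1% of pixels qualify as object; cannot estimate scatter"
        )
    s_bar = nearest_rank_percentile(obj, 1.0 - percentile_rule)
    return UniformScatterEstimate(s_bar, percentile_rule, object_mask_rule)


def soft_cut_subtract(
    stack: ProjectionStack, s_bar: float, eps: float = 0.05
) -> ProjectionStack:
    """Subtract ``s_bar`` with a C1 positivity-preserving soft cut.

    Where ``I - s_bar >= eps*I`` the subtraction is plain; below that the
    output rolls off as ``eps*I*exp((I - s_bar - eps*I)/(eps*I))``, which
    matches value and slope at the switch and stays positive.
    """
    if stack.domain != INTENSITY:
        raise ValueError("soft_cut_subtract expects an intensity stack")
    if not 0.0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    I = stack.data
    lin = I - s_bar
    knee = eps * I
    with np.errstate(under="ignore"):
        soft = knee * np.exp((lin - knee) / knee)
    # the exponential underflows to 0.0 for I << s_bar; keep strictly positive
    out = np.where(lin >= knee, lin, np.maximum(soft, np.finfo(float).tiny))
    return dc_replace(stack, data=out)


def first_pass_reconstruct(
    stack: ProjectionStack,
    grid: ReconGrid | None = None,
    filter_name: str = "ramlak",
    percentile_rule: float = 0.90,
    object_mask_rule: float = 0.90,
    softcut_eps: float = 0.05,
    floor_frac: float = 1e-4,
    linear_guard: bool = True,
) -> tuple[VoxelVolume, UniformScatterEstimate]:
    """Uniform-scatter-corrected first-pass FDK volume ``CBCT_c`` (1/mm).

    With ``linear_guard`` (default), the subtracted constant is additionally
    capped at ``(1 - eps) * min(object intensity)`` so that every object
    pixel stays in the soft-cut's plain-subtraction branch.  Beyond that
    point the exponential roll-off compresses the darkest projections
    towards zero and the reconstruction inherits sharp overshoot artifacts
    in the most attenuated regions, which the smooth-ratio stages downstream
    cannot repair; a slightly smaller constant only leaves a little more of
    the (smooth) scatter floor for the image-domain stages to absorb.
    """
    est = estimate_uniform_scatter(stack, percentile_rule, object_mask_rule)
    s_bar = est.s_bar
    if linear_guard:
        obj_min = float(
            stack.data[stack.data < object_mask_rule * stack.geometry.I0].min()
        )
        cap = (1.0 - softcut_eps) * obj_min
        if cap < s_bar:
            log.info(
                "  linear-regime guard active: s_bar %.4g -> %.4g", s_bar, cap
            )
            est = UniformScatterEstimate(
                cap, percentile_rule, object_mask_rule, s_bar_percentile=s_bar
            )
    pc = to_line_integral(
        soft_cut_subtract(stack, est.s_bar, softcut_eps), floor_frac=floor_frac
    )
    return fdk_reconstruct(pc, grid, filter_name), est


# ---------------------------------------------------------------------------
# Step 3: segmentation and template


def segment_tissues(
    hu: VoxelVolume, hu_windows: dict | None = None
) -> tuple[VoxelVolume, VoxelVolume]:
    """Window-threshold segmentation into the four tissue classes.

    Returns (label volume with TissueClass codes, confidence volume).  Gap
    voxels whose HU falls between windows are labelled air but flagged
    unconfident; they are excluded from ratio sampling downstream.
    """
    windows = dict(DEFAULT_HU_WINDOWS) if hu_windows is None else dict(hu_windows)
    validate_windows(windows)
    labels = np.full(hu.shape, int(TissueClass.AIR), dtype=np.int8)
    confident = np.zeros(hu.shape, dtype=bool)
    for cls in TissueClass:
        sel = in_window(hu.data, cls, windows)
        labels[sel] = int(cls)
        confident |= sel
    return hu.copy_with(labels, unit="label"), hu.copy_with(confident, unit="mask")


def build_template(
    labels: VoxelVolume,
    table: TissueLACTable,
    applicator_lac: float | None = None,
) -> VoxelVolume:
    """Piecewise-constant template ``CBCT_t``: each class filled with its LAC.

    ``labels`` may contain the four TissueClass codes plus
    :data:`APPLICATOR_CLASS`; any other code raises.
    """
    lab = labels.data
    known = {int(c) for c in TissueClass} | {APPLICATOR_CLASS}
    present = set(np.unique(lab).tolist())
    if not present <= known:
        raise ValueError(f"unknown labels {sorted(present - known)}")
    out = np.zeros(labels.shape)
    for cls in TissueClass:
        out[lab == int(cls)] = table.lac_of(cls)
    if APPLICATOR_CLASS in present:
        if applicator_lac is None:
            raise ValueError("labels contain applicator voxels but no applicator_lac given")
        out[lab == APPLICATOR_CLASS] = applicator_lac
    return labels.copy_with(out, unit="1/mm")


# ---------------------------------------------------------------------------
# Steps 4-5: scatter ratio, mask, local filtration


@dataclass
class ScatterRatioField:
    r: VoxelVolume
    eps_floor: float
    n_floored: int = 0


@dataclass
class MaskField:
    f: VoxelVolume  # binary sampling mask
    r_max: float
    G_max: float
    percentile: float = 0.80


@dataclass
class FiltrationParams:
    """2D Gaussian smoothing of the masked ratio (per axial slice)."""

    sigma_mm: float = 12.0
    kernel_radius_sigmas: float = 3.0
    denom_floor: float = 1e-6
    fallback: str = "global_mean"  # or "identity" (ratio 1 where unsupported)

    def __post_init__(self) -> None:
        if self.sigma_mm <= 0:
            raise ValueError("sigma_mm must be positive")
        if self.fallback not in ("global_mean", "identity"):
            raise ValueError(f"unknown fallback {self.fallback!r}")


def compute_scatter_ratio(
    cbct_t: VoxelVolume,
    cbct_c: VoxelVolume,
    eps_floor: float = 1e-4,
    presmooth_mm: float = 0.0,
) -> ScatterRatioField:
    """r = CBCT_t / max(CBCT_c, eps_floor); finite everywhere.

    ``presmooth_mm`` optionally applies an isotropic Gaussian to the
    denominator first: the ratio is meant to sample the low-frequency error
    of the first pass, and a noisy denominator both inflates the spread that
    the mask percentiles see and biases the ratio upward (Jensen).  The
    corrected volume itself is always built from the unsmoothed first pass.
    """
    if not cbct_t.same_grid_as(cbct_c):
        raise ValueError("template and first-pass volumes must share a grid")
    den = cbct_c.data
    if presmooth_mm > 0:
        den = ndimage.gaussian_filter(
            den, [presmooth_mm / s for s in cbct_c.spacing], mode="nearest"
        )
    floored = den < eps_floor
    n = int(np.count_nonzero(floored))
    if n:
        log.debug("compute_scatter_ratio: %d voxels floored at %g", n, eps_floor)
    r = cbct_t.data / np.maximum(den, eps_floor)
    return ScatterRatioField(cbct_c.copy_with(r, unit=""), eps_floor, n)


def _inplane_gradient_magnitude(r: np.ndarray, spacing) -> np.ndarray:
    """Central-difference 2D gradient magnitude per axial slice."""
    gy = np.gradient(r, spacing[1], axis=1)
    gx = np.gradient(r, spacing[2], axis=2)
    return np.sqrt(gy * gy + gx * gx)


def build_mask(
    ratio: ScatterRatioField,
    confident: VoxelVolume,
    body_mask: VoxelVolume,
    percentile: float = 0.80,
    percentile_over: str = "candidates",
) -> MaskField:
    """Binary sampling mask for the scatter ratio.

    Thresholds: ``r_max`` and ``G_max`` are the (nearest-rank) ``percentile``
    of ``|r|`` and of the in-plane gradient magnitude, computed separately
    over the candidate sample set (confidently classified voxels inside the
    body) so that the selection rejects the worst 20% of actual candidates;
    the ratio is meaningless at gap-class voxels (whose template value is
    the air LAC) and would otherwise dominate the percentiles.  Ties at
    exactly the threshold are kept.  Besides the two threshold tests, ``f``
    is zero at unconfident (gap-class or applicator) voxels and outside the
    body.
    """
    r = ratio.r.data
    body = body_mask.data.astype(bool)
    if not np.any(body):
        raise ValueError("body mask is empty")
    if percentile_over == "body":
        pool = body
    elif percentile_over == "candidates":
        pool = body & confident.data.astype(bool)
        if not np.any(pool):
            raise ValueError("no confidently classified voxels inside the body")
    else:
        raise ValueError(f"unknown percentile_over {percentile_over!r}")
    grad = _inplane_gradient_magnitude(r, ratio.r.spacing)
    r_max = nearest_rank_percentile(np.abs(r[pool]), percentile)
    g_max = nearest_rank_percentile(grad[pool], percentile)
    f = (
        (np.abs(r) <= r_max)
        & (grad <= g_max)
        & confident.data.astype(bool)
        & body
    )
    return MaskField(ratio.r.copy_with(f, unit="mask"), r_max, g_max, percentile)


def local_filtration(
    ratio: ScatterRatioField,
    mask: MaskField,
    params: FiltrationParams | None = None,
) -> VoxelVolume:
    """Masked normalised convolution: r_f = (r*f)**w / (f**w), per axial slice.

    Where the local weight sum falls below ``denom_floor`` the fallback
    applies (global mean of sampled r, or ratio 1).  The Gaussian kernel is
    truncated at ``kernel_radius_sigmas`` and zero-padded at slice borders,
    which the normalisation cancels exactly.
    """
    params = FiltrationParams() if params is None else params
    r = ratio.r.data
    f = mask.f.data.astype(float)
    if not np.any(f > 0):
        raise ValueError("sampling mask is identically zero")
    sy = params.sigma_mm / ratio.r.spacing[1]
    sx = params.sigma_mm / ratio.r.spacing[2]
    num = np.empty_like(r)
    den = np.empty_like(r)
    for iz in range(r.shape[0]):
        num[iz] = ndimage.gaussian_filter(
            r[iz] * f[iz], (sy, sx), mode="constant", cval=0.0,
            truncate=params.kernel_radius_sigmas,
        )
        den[iz] = ndimage.gaussian_filter(
            f[iz], (sy, sx), mode="constant", cval=0.0,
            truncate=params.kernel_radius_sigmas,
        )
    good = den >= params.denom_floor
    fallback = float(r[f > 0].mean()) if params.fallback == "global_mean" else 1.0
    rf = np.full_like(r, fallback)
    rf[good] = num[good] / den[good]
    return ratio.r.copy_with(rf, unit="")


# ---------------------------------------------------------------------------
# Step 6: apply the ratio; applicator substitution


def apply_ratio(
    cbct_c: VoxelVolume, r_f: VoxelVolume, mu_w: float = DEFAULT_MU_W
) -> tuple[VoxelVolume, VoxelVolume]:
    """CBCT_fc = CBCT_c * r_f; returns (LAC volume, HU view)."""
    if not cbct_c.same_grid_as(r_f):
        raise ValueError("first-pass volume and ratio field must share a grid")
    fc = cbct_c.copy_with(cbct_c.data * r_f.data, unit="1/mm")
    return fc, lac_to_hu(fc, mu_w)


def estimate_rigid_transform(
    moving_points: np.ndarray, fixed_points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid (R, t) mapping moving -> fixed via centroids + principal axes.

    Axis signs are disambiguated against the fixed axes (suitable for the
    small rotations of a rigidly held applicator); no scaling.
    """

    def _axes(pts, centre):
        q = pts - centre
        _, _, vt = np.linalg.svd(q, full_matrices=False)
        return vt  # rows: principal axes, descending variance

    cm = moving_points.mean(axis=0)
    cf = fixed_points.mean(axis=0)
    am = _axes(moving_points, cm)
    af = _axes(fixed_points, cf)
    # flip moving axes to agree with the fixed ones
    for i in range(3):
        if np.dot(am[i], af[i]) < 0:
            am[i] = -am[i]
    R = af.T @ am
    # project onto SO(3)
    u, _, vt = np.linalg.svd(R)
    R = u @ vt
    if np.linalg.det(R) < 0:
        u[:, -1] = -u[:, -1]
        R = u @ vt
    t = cf - R @ cm
    return R, t


def substitute_applicator(
    cbct_fc_hu: VoxelVolume,
    applicator_model_hu: VoxelVolume,
    threshold_hu: float = 1000.0,
    transform: tuple[np.ndarray, np.ndarray] | str | None = None,
) -> VoxelVolume:
    """Replace the applicator footprint with the rigid applicator model.

    ``transform`` maps model world coordinates to CBCT world coordinates;
    ``None`` estimates it from the two thresholded point clouds (centroid +
    principal axes), ``"identity"`` skips estimation.  Voxels above the
    threshold in the corrected volume but outside the transformed model are
    filled with the median HU of a thin ring around the footprint (they are
    blooming/streak, not applicator metal).
    """
    cbct_mask = cbct_fc_hu.data > threshold_hu
    model_mask = applicator_model_hu.data > threshold_hu
    if not np.any(cbct_mask) or not np.any(model_mask):
        raise ValueError("no voxels above the applicator threshold in one input")

    def _world_points(vol, mask):
        idx = np.argwhere(mask).astype(float)
        return idx * np.asarray(vol.spacing) + np.asarray(vol.origin)

    if transform is None:
        R, t = estimate_rigid_transform(
            _world_points(applicator_model_hu, model_mask),
            _world_points(cbct_fc_hu, cbct_mask),
        )
    elif transform == "identity":
        R, t = np.eye(3), np.zeros(3)
    else:
        R, t = transform

    # sample the transformed model on the CBCT grid (inverse mapping)
    zz, yy, xx = cbct_fc_hu.world_grid()
    pts = np.stack(np.broadcast_arrays(zz, yy, xx), axis=-1).reshape(-1, 3)
    inv = (pts - t) @ R  # R^-1 = R^T applied from the right
    frac = (inv - np.asarray(applicator_model_hu.origin)) / np.asarray(
        applicator_model_hu.spacing
    )
    model_vals = ndimage.map_coordinates(
        applicator_model_hu.data.astype(float), frac.T, order=1,
        mode="constant", cval=applicator_model_hu.data.min(),
    ).reshape(cbct_fc_hu.shape)
    model_in = model_vals > threshold_hu

    out = cbct_fc_hu.copy_with(cbct_fc_hu.data.copy())
    residual = cbct_mask & ~model_in
    if np.any(residual):
        ring = ndimage.binary_dilation(cbct_mask, iterations=2) & ~cbct_mask
        fill = float(np.median(cbct_fc_hu.data[ring])) if np.any(ring) else 0.0
        out.data[residual] = fill
    out.data[model_in] = model_vals[model_in]
    return out


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class CorrectionConfig:
    """Tunable parameters of the six-step correction."""

    mu_w: float = DEFAULT_MU_W
    hu_windows: dict = field(default_factory=lambda: dict(DEFAULT_HU_WINDOWS))
    min_class_voxels: int = 100
    percentile_rule: float = 0.90
    object_mask_rule: float = 0.90
    softcut_eps: float = 0.05
    floor_frac: float = 1e-4
    recon_grid: ReconGrid = field(default_factory=ReconGrid)
    filter_name: str = "ramlak"
    segmentation_source: str = "prior"  # or "cbct"
    eps_floor: float = 1e-4
    ratio_presmooth_mm: float = 0.0
    mask_percentile: float = 0.80
    filtration: FiltrationParams = field(default_factory=FiltrationParams)
    applicator_threshold_hu: float = 1000.0
    applicator_hu: float = 2500.0


@dataclass
class CorrectionResult:
    """Final corrected volume plus every intermediate, for inspection."""

    cbct_fc: VoxelVolume
    cbct_fc_hu: VoxelVolume
    cbct_c: VoxelVolume
    scatter_estimate: UniformScatterEstimate
    lac_table: TissueLACTable
    labels: VoxelVolume
    confident: VoxelVolume
    body_mask: VoxelVolume
    cbct_t: VoxelVolume
    ratio: ScatterRatioField
    mask: MaskField
    r_f: VoxelVolume
    final_hu: VoxelVolume  # after applicator substitution (== cbct_fc_hu if none)


def correct_cbct(
    raw_stack: ProjectionStack,
    prior_hu: VoxelVolume,
    config: CorrectionConfig | None = None,
    applicator_model_hu: VoxelVolume | None = None,
) -> CorrectionResult:
    """Run the full six-step correction on a raw intensity stack."""
    cfg = CorrectionConfig() if config is None else config

    log.info("step 1: reference LACs from the prior")
    table = extract_tissue_lacs(
        prior_hu, cfg.hu_windows, cfg.mu_w, cfg.min_class_voxels
    )
    log.info(
        "  mu_air=%.5f mu_fat=%.5f mu_muscle=%.5f mu_bone=%.5f (1/mm)",
        table.mu_air, table.mu_fat, table.mu_muscle, table.mu_bone,
    )

    log.info("step 2: uniform scatter subtraction + first-pass FDK")
    cbct_c, est = first_pass_reconstruct(
        raw_stack, cfg.recon_grid, cfg.filter_name,
        cfg.percentile_rule, cfg.object_mask_rule, cfg.softcut_eps, cfg.floor_frac,
    )
    log.info("  s_bar = %.4g (I0 = %.4g)", est.s_bar, raw_stack.geometry.I0)

    log.info("step 3: segmentation (%s) + template", cfg.segmentation_source)
    if cfg.segmentation_source == "prior":
        lab_src, conf_src = segment_tissues(prior_hu, cfg.hu_windows)
        labels = resample_to(lab_src, cbct_c, order=0, cval=int(TissueClass.AIR))
        confident = resample_to(conf_src, cbct_c, order=0, cval=1.0)
        labels.data = labels.data.astype(np.int8)
        confident.data = confident.data.astype(bool)
    elif cfg.segmentation_source == "cbct":
        labels, confident = segment_tissues(lac_to_hu(cbct_c, cfg.mu_w), cfg.hu_windows)
    else:
        raise ValueError(f"unknown segmentation_source {cfg.segmentation_source!r}")
    cbct_c_hu = lac_to_hu(cbct_c, cfg.mu_w)
    applicator_mask = cbct_c_hu.data > cfg.applicator_threshold_hu
    labels.data[applicator_mask] = APPLICATOR_CLASS
    applicator_lac = cfg.applicator_hu / 1000.0 * cfg.mu_w + cfg.mu_w
    cbct_t = build_template(labels, table, applicator_lac)

    log.info("step 4: scatter ratio + sampling mask")
    ratio = compute_scatter_ratio(cbct_t, cbct_c, cfg.eps_floor, cfg.ratio_presmooth_mm)
    body = (labels.data != int(TissueClass.AIR)) | (~confident.data)
    body_vol = labels.copy_with(body, unit="mask")
    sampling_conf = labels.copy_with(
        confident.data & ~applicator_mask, unit="mask"
    )
    mask = build_mask(ratio, sampling_conf, body_vol, cfg.mask_percentile)
    log.info("  r_max = %.3f, G_max = %.3g, f=1 fraction of body = %.2f",
             mask.r_max, mask.G_max,
             float(mask.f.data[body].mean()))

    log.info("step 5: local filtration (sigma %.1f mm)", cfg.filtration.sigma_mm)
    r_f = local_filtration(ratio, mask, cfg.filtration)

    log.info("step 6: apply ratio")
    cbct_fc, cbct_fc_hu = apply_ratio(cbct_c, r_f, cfg.mu_w)
    final_hu = cbct_fc_hu
    if applicator_model_hu is not None:
        if np.any(cbct_fc_hu.data > cfg.applicator_threshold_hu):
            log.info("  applicator substitution")
            final_hu = substitute_applicator(
                cbct_fc_hu, applicator_model_hu, cfg.applicator_threshold_hu
            )
        else:
            log.warning(
                "no voxels above %(thr).0f HU in the corrected volume; "
                "applicator substitution skipped",
                {"thr": cfg.applicator_threshold_hu},
            )
    return CorrectionResult(
        cbct_fc=cbct_fc, cbct_fc_hu=cbct_fc_hu, cbct_c=cbct_c,
        scatter_estimate=est, lac_table=table, labels=labels,
        confident=confident, body_mask=body_vol, cbct_t=cbct_t,
        ratio=ratio, mask=mask, r_f=r_f, final_hu=final_hu,
    )
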