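"""Cone-beam forward projection and raw-data simulation.

Geometry: circular full-scan trajectory around the z axis.  At view angle
beta (degrees) the source sits at world position
``(z, y, x) = (0, SAD*sin(beta), SAD*cos(beta))`` and a flat detector,
centred on the source-isocenter line at distance SDD from the source, spans
the in-plane direction u = (-sin(beta), cos(beta)) (in x/y) and the axial
direction v = +z.  Detector pixels are centre-addressed with pixel (0, 0)
at the most negative (v, u) corner.

Raw data simulation follows Beer-Lambert: line integrals p of the linear
attenuation coefficient are converted to intensities I = I0*exp(-p), a
spatially smooth additive scatter field is layered on top, and scaled
Poisson noise models finite photon statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._kernels import forward_view
from .volume import VoxelVolume

log = logging.getLogger(__name__)

INTENSITY = "intensity"
LINE_INTEGRAL = "line_integral"


@dataclass
class ConeBeamGeometry:
    """Circular cone-beam scan geometry (OBI-like desk-scale defaults)."""

    source_axis_distance: float = 1000.0  # mm
    source_detector_distance: float = 1500.0  # mm
    detector_pixels: tuple[int, int] = (384, 192)  # (nu, nv)
    pixel_pitch: float = 1.552  # mm, square pixels
    view_angles_deg: np.ndarray = field(
        default_factory=lambda: np.arange(360, dtype=float)
    )
    I0: float = 1.0  # unattenuated detector intensity (arbitrary units)

    def __post_init__(self) -> None:
        self.view_angles_deg = np.asarray(self.view_angles_deg, dtype=float)
        if not 0 < self.source_axis_distance < self.source_detector_distance:
            raise ValueError("require SDD > SAD > 0")
        if self.I0 <= 0:
            raise ValueError("I0 must be positive")
        if self.view_angles_deg.size < 2:
            raise ValueError("need at least two view angles")
        d = np.diff(self.view_angles_deg)
        if np.any(d <= 0):
            raise ValueError("view angles must be strictly increasing")
        step = float(np.median(d))
        span = float(self.view_angles_deg[-1] - self.view_angles_deg[0])
        if span < 360.0 - step - 1e-9:
            raise ValueError("only full 360-degree circular scans are supported")

    @property
    def n_views(self) -> int:
        return int(self.view_angles_deg.size)

    def detector_axes(self, beta_deg: float):
        """(source, pixel(0,0) position, u step, v step) world vectors."""
        b = np.deg2rad(beta_deg)
        sad, sdd = self.source_axis_distance, self.source_detector_distance
        src = np.array([0.0, sad * np.sin(b), sad * np.cos(b)])
        ray = np.array([0.0, -np.sin(b), -np.cos(b)])  # central ray direction
        e_u = np.array([0.0, np.cos(b), -np.sin(b)])
        e_v = np.array([1.0, 0.0, 0.0])
        nu, nv = self.detector_pixels
        du = dv = self.pixel_pitch
        center = src + sdd * ray
        det00 = center - (nu - 1) / 2.0 * du * e_u - (nv - 1) / 2.0 * dv * e_v
        return src, det00, du * e_u, dv * e_v

    def detector_u_coords(self) -> np.ndarray:
        nu = self.detector_pixels[0]
        return (np.arange(nu) - (nu - 1) / 2.0) * self.pixel_pitch

    def detector_v_coords(self) -> np.ndarray:
        nv = self.detector_pixels[1]
        return (np.arange(nv) - (nv - 1) / 2.0) * self.pixel_pitch


@dataclass
class ProjectionStack:
    """Per-view detector arrays plus the geometry that produced them."""

    domain: str  # "intensity" | "line_integral"
    data: np.ndarray  # (n_views, nv, nu)
    geometry: ConeBeamGeometry
    scatter_truth: np.ndarray | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.domain not in (INTENSITY, LINE_INTEGRAL):
            raise ValueError(f"unknown projection domain {self.domain!r}")
        nu, nv = self.geometry.detector_pixels
        expected = (self.geometry.n_views, nv, nu)
        if self.data.shape != expected:
            raise ValueError(f"data shape {self.data.shape} != geometry {expected}")
        if self.domain == INTENSITY and np.any(self.data <= 0):
            raise ValueError("intensity data must be strictly positive")


def _support_extent(vol: VoxelVolume, threshold: float = 1e-8):
    """(max in-plane radius, max |z| edge) of non-negligible attenuation."""
    mask = np.abs(vol.data) > threshold
    if not mask.any():
        return 0.0, 0.0
    zc, yc, xc = vol.world_coords()
    inplane = mask.any(axis=0)
    iy, ix = np.nonzero(inplane)
    r = np.sqrt(yc[iy] ** 2 + xc[ix] ** 2).max() + 0.5 * float(np.hypot(*vol.spacing[1:]))
    iz = np.nonzero(mask.any(axis=(1, 2)))[0]
    z = max(abs(zc[iz.min()]), abs(zc[iz.max()])) + 0.5 * vol.spacing[0]
    return float(r), float(z)


def check_fov(vol: VoxelVolume, geometry: ConeBeamGeometry) -> None:
    """Raise if the attenuating support can project outside the detector.

    The support is bounded by a cylinder (max in-plane radius around the
    rotation axis, max |z|); for a full circular scan the worst-case
    detector coordinates of such a cylinder have closed forms.
    """
    r, z = _support_extent(vol)
    sad, sdd = geometry.source_axis_distance, geometry.source_detector_distance
    if r >= sad:
        raise ValueError("object support reaches the source orbit")
    # max |u| over the orbit for a point at radius r occurs where the point's
    # ray grazes the circle of radius r: cos(phi) = r/SAD
    u_max = sdd * r * np.sqrt(1.0 - (r / sad) ** 2) / (sad - r**2 / sad)
    v_max = sdd * z / (sad - r)
    nu, nv = geometry.detector_pixels
    half_u = nu * geometry.pixel_pitch / 2.0
    half_v = nv * geometry.pixel_pitch / 2.0
    if u_max > half_u or v_max > half_v:
        raise ValueError(
            "volume extends beyond the reconstructible field of view "
            f"(|u|max {u_max:.1f}/{half_u:.1f} mm, "
            f"|v|max {v_max:.1f}/{half_v:.1f} mm); truncated scans "
            "are not supported"
        )


def forward_project(
    vol: VoxelVolume,
    geometry: ConeBeamGeometry,
    step_mm: float | None = None,
) -> ProjectionStack:
    """Cone-beam line integrals of a LAC volume (units 1/mm).

    ``step_mm`` is the ray-marching step (default: half the smallest voxel
    side, a good accuracy/runtime balance for piecewise-smooth volumes).
    """
    check_fov(vol, geometry)
    if step_mm is None:
        step_mm = 0.5 * min(vol.spacing)
    nu, nv = geometry.detector_pixels
    data = np.empty((geometry.n_views, nv, nu))
    voldata = np.ascontiguousarray(vol.data, dtype=np.float64)
    oz, oy, ox = vol.origin
    sz, sy, sx = vol.spacing
    for i, beta in enumerate(geometry.view_angles_deg):
        src, det00, ustep, vstep = geometry.detector_axes(beta)
        forward_view(
            voldata, oz, oy, ox, sz, sy, sx,
            src, det00, ustep, vstep, data[i], step_mm,
        )
    np.maximum(data, 0.0, out=data)
    return ProjectionStack(LINE_INTEGRAL, data, geometry)


def to_intensity(stack: ProjectionStack, I0: float | None = None) -> ProjectionStack:
    """Beer-Lambert conversion p -> I = I0*exp(-p)."""
    if stack.domain != LINE_INTEGRAL:
        raise ValueError("to_intensity expects a line-integral stack")
    I0 = stack.geometry.I0 if I0 is None else float(I0)
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    return replace(stack, domain=INTENSITY, data=I0 * np.exp(-stack.data))


def to_line_integral(
    stack: ProjectionStack,
    I0: float | None = None,
    floor_frac: float = 1e-4,
) -> ProjectionStack:
    """Beer-Lambert conversion I -> p = -ln(I/I0).

    Intensities below ``floor_frac*I0`` are clamped before the log and
    negative line integrals (I > I0, possible for scatter-contaminated air
    pixels) are clipped to zero; both events are counted in ``info``.
    """
    if stack.domain != INTENSITY:
        raise ValueError("to_line_integral expects an intensity stack")
    I0 = stack.geometry.I0 if I0 is None else float(I0)
    floor = floor_frac * I0
    n_floored = int(np.count_nonzero(stack.data < floor))
    p = -np.log(np.maximum(stack.data, floor) / I0)
    n_negative = int(np.count_nonzero(p < 0))
    if n_floored or n_negative:
        log.debug(
            "to_line_integral: %d pixels floored, %d negative integrals clipped",
            n_floored, n_negative,
        )
    np.maximum(p, 0.0, out=p)
    info = dict(stack.info)
    info.update(n_floored=n_floored, n_negative_clipped=n_negative)
    return replace(stack, domain=LINE_INTEGRAL, data=p, info=info)


def simulate_scatter(
    stack: ProjectionStack,
    spr: float = 0.06,
    blur_sigma_mm: float = 150.0,
    plateau_frac: float = 0.9,
) -> ProjectionStack:
    """Add a smooth additive scatter field per view:

        S = spr * ((1 - plateau_frac) * Gaussian2D(blur_sigma) ** I
                   + plateau_frac * mean(I))

    Scatter point-spread functions at a flat-panel detector combine a broad
    blurred component with an even broader, nearly flat plateau.  The
    plateau is modelled at the scan level (``mean(I)`` over the whole
    stack): this is the regime in which a single empirical constant per scan
    removes the bulk of the scatter, which is the premise of the uniform
    subtraction step and the behaviour clinical full-fan data exhibits.
    Both components are constant-preserving, so a flat field with spr=1
    gets exactly doubled.  The injected field is kept in ``scatter_truth``.
    """
    if stack.domain != INTENSITY:
        raise ValueError("simulate_scatter expects an intensity stack")
    if spr < 0:
        raise ValueError("scatter-to-primary ratio must be >= 0")
    if not 0.0 <= plateau_frac <= 1.0:
        raise ValueError("plateau_frac must lie in [0, 1]")
    sigma_px = blur_sigma_mm / stack.geometry.pixel_pitch
    plateau = plateau_frac * float(stack.data.mean())
    scatter = np.empty_like(stack.data)
    for i in range(stack.data.shape[0]):
        blurred = ndimage.gaussian_filter(stack.data[i], sigma_px, mode="nearest")
        scatter[i] = spr * ((1.0 - plateau_frac) * blurred + plateau)
    return replace(stack, data=stack.data + scatter, scatter_truth=scatter)


def add_noise(
    stack: ProjectionStack,
    photons_per_I0: float,
    seed: int,
) -> ProjectionStack:
    """Scaled-Poisson detector noise; at least one photon per pixel."""
    if stack.domain != INTENSITY:
        raise ValueError("add_noise expects an intensity stack")
    if photons_per_I0 <= 0:
        raise ValueError("photons_per_I0 must be positive")
    rng = np.random.default_rng(seed)
    I0 = stack.geometry.I0
    counts = rng.poisson(stack.data / I0 * photons_per_I0)
    counts = np.maximum(counts, 1)
    return replace(stack, data=counts * (I0 / photons_per_I0))
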