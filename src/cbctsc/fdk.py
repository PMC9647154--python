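"""Feldkamp-Davis-Kress reconstruction and HU/LAC conversion.

The FDK pipeline: per-view cosine weighting (flat detector), frequency-domain
ramp filtering along detector rows (Ram-Lak, optional Hann apodisation,
zero-padded to the next power of two to avoid circular-convolution bias) and
distance-weighted voxel-driven backprojection over the full circular scan.

HU and linear attenuation coefficient are related affinely through the water
coefficient mu_w:  mu = HU/1000 * mu_w + mu_w,  so HU 0 maps to water and
HU -1000 to vacuum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import backproject_view
from .projector import LINE_INTEGRAL, ConeBeamGeometry, ProjectionStack
from .volume import VoxelVolume, centered_grid

#: Default water LAC in 1/mm (~0.2 cm^-1, reasonable at CBCT effective energies).
DEFAULT_MU_W = 0.020


@dataclass
class ReconGrid:
    """Reconstruction grid; origin ``None`` centres the grid on the isocenter."""

    shape: tuple[int, int, int] = (64, 192, 192)  # (nz, ny, nx)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    origin: tuple[float, float, float] | None = None

    def resolve_origin(self) -> tuple[float, float, float]:
        if self.origin is not None:
            return tuple(float(o) for o in self.origin)
        return centered_grid(self.shape, self.voxel_size)[1]

    def empty_volume(self, unit: str = "1/mm") -> VoxelVolume:
        return VoxelVolume(
            np.zeros(self.shape), self.voxel_size, self.resolve_origin(), unit
        )


def _ramp_kernel(n_pad: int, ds: float) -> np.ndarray:
    """Band-limited spatial-domain ramp impulse response (length n_pad)."""
    h = np.zeros(n_pad)
    h[0] = 1.0 / (4.0 * ds * ds)
    k = np.arange(1, n_pad // 2 + 1)
    odd = k[k % 2 == 1]
    vals = -1.0 / (np.pi * odd * ds) ** 2
    h[odd] = vals
    h[-odd] = vals  # symmetric wrap-around layout for circular convolution
    return h


def filter_projections(
    proj: np.ndarray,
    geometry: ConeBeamGeometry,
    filter_name: str = "ramlak",
) -> np.ndarray:
    """Cosine-weight and ramp-filter a (n_views, nv, nu) line-integral array."""
    sad, sdd = geometry.source_axis_distance, geometry.source_detector_distance
    mag = sad / sdd
    u = geometry.detector_u_coords() * mag  # rescaled to the isocenter plane
    v = geometry.detector_v_coords() * mag
    ds = geometry.pixel_pitch * mag
    weight = sad / np.sqrt(sad**2 + u[None, :] ** 2 + v[:, None] ** 2)
    nu = proj.shape[2]
    n_pad = 1 << int(np.ceil(np.log2(2 * nu)))
    H = np.fft.rfft(_ramp_kernel(n_pad, ds))
    if filter_name == "hann":
        freq = np.arange(H.size) / n_pad  # cycles per sample, 0..0.5
        H = H * 0.5 * (1.0 + np.cos(2.0 * np.pi * freq))
    elif filter_name != "ramlak":
        raise ValueError(f"unknown filter {filter_name!r}")
    out = np.empty_like(proj, dtype=np.float64)
    for i in range(proj.shape[0]):
        rw = proj[i] * weight
        spec = np.fft.rfft(rw, n=n_pad, axis=1)
        filt = np.fft.irfft(spec * H[None, :], n=n_pad, axis=1)[:, :nu]
        out[i] = 0.5 * ds * filt
    return out


def fdk_reconstruct(
    stack: ProjectionStack,
    grid: ReconGrid | None = None,
    filter_name: str = "ramlak",
) -> VoxelVolume:
    """Reconstruct a LAC volume (1/mm) from a full-scan line-integral stack."""
    if stack.domain != LINE_INTEGRAL:
        raise ValueError("fdk_reconstruct expects a line-integral stack; "
                         "convert intensities with to_line_integral first")
    grid = ReconGrid() if grid is None else grid
    geom = stack.geometry
    q = filter_projections(stack.data, geom, filter_name)
    vol = grid.empty_volume()
    out = vol.data
    oz, oy, ox = vol.origin
    sz, sy, sx = vol.spacing
    angles = np.deg2rad(geom.view_angles_deg)
    # per-view angular increment (wrap-aware for the closing view)
    d = np.diff(angles)
    dbeta = np.empty_like(angles)
    dbeta[:-1] = d
    dbeta[-1] = 2.0 * np.pi - (angles[-1] - angles[0])
    u0 = float(geom.detector_u_coords()[0])
    v0 = float(geom.detector_v_coords()[0])
    for i, beta in enumerate(angles):
        backproject_view(
            out, oz, oy, ox, sz, sy, sx,
            np.ascontiguousarray(q[i]),
            float(np.cos(beta)), float(np.sin(beta)),
            geom.source_axis_distance, geom.source_detector_distance,
            geom.pixel_pitch, geom.pixel_pitch, u0, v0,
            float(dbeta[i]),
        )
    return vol


def lac_to_hu(vol: VoxelVolume, mu_w: float = DEFAULT_MU_W) -> VoxelVolume:
    """mu -> HU = 1000*(mu - mu_w)/mu_w (exact inverse of :func:`hu_to_lac`)."""
    if mu_w <= 0:
        raise ValueError("mu_w must be positive")
    return vol.copy_with((vol.data - mu_w) / mu_w * 1000.0, unit="HU")


def hu_to_lac(vol: VoxelVolume, mu_w: float = DEFAULT_MU_W) -> VoxelVolume:
    """HU -> mu = HU/1000*mu_w + mu_w."""
    if mu_w <= 0:
        raise ValueError("mu_w must be positive")
    return vol.copy_with(vol.data / 1000.0 * mu_w + mu_w, unit="1/mm")
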