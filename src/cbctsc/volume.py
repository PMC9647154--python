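"""Voxel volume container.

All physical coordinates in this package are expressed in millimetres and
ordered ``(z, y, x)`` to match numpy array axis order: axis 0 is the slice
(cranio-caudal) axis and axes 1-2 span the axial plane.  Voxels are
centre-addressed: the world position of index ``i`` along an axis is
``origin + i * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoxelVolume:
    """A 3D scalar grid (HU, linear attenuation coefficient, or dose).

    Parameters
    ----------
    data:
        Array of shape ``(nz, ny, nx)``.
    spacing:
        Voxel size in mm, ``(dz, dy, dx)``.
    origin:
        World position in mm of voxel ``(0, 0, 0)``, ``(z0, y0, x0)``.
    unit:
        Free-text unit tag (``"HU"``, ``"1/mm"``, ``"Gy"``, ``"label"``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    unit: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centres (1D arrays z, y, x)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )  # type: ignore[return-value]

    def world_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (open meshgrid)."""
        z, y, x = self.world_coords()
        return z[:, None, None], y[None, :, None], x[None, None, :]

    def index_of(self, point_mm: tuple[float, float, float]) -> np.ndarray:
        """Fractional voxel index of a world point."""
        return (np.asarray(point_mm, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )

    def same_grid_as(self, other: "VoxelVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy_with(self, data: np.ndarray, unit: str | None = None) -> "VoxelVolume":
        return VoxelVolume(
            data, self.spacing, self.origin, self.unit if unit is None else unit
        )


def centered_grid(
    shape: tuple[int, int, int], spacing: tuple[float, float, float]
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Return ``(spacing, origin)`` for a grid centred on the world origin."""
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    return tuple(float(s) for s in spacing), origin  # type: ignore[return-value]


def make_centered_volume(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    fill: float = 0.0,
    dtype=np.float64,
    unit: str = "",
) -> VoxelVolume:
    spacing, origin = centered_grid(shape, spacing)
    return VoxelVolume(np.full(shape, fill, dtype=dtype), spacing, origin, unit)


def resample_to(
    src: VoxelVolume,
    target: VoxelVolume,
    order: int = 1,
    cval: float = 0.0,
) -> VoxelVolume:
    """Resample ``src`` onto the grid of ``target`` (identity world mapping).

    ``order=0`` gives nearest-neighbour (for label volumes), ``order=1``
    trilinear.  Voxels outside ``src`` get ``cval``.
    """
    from scipy import ndimage

    if src.same_grid_as(target):
        return target.copy_with(src.data.copy(), unit=src.unit)
    coords = [
        (target.origin[a] + np.arange(target.shape[a]) * target.spacing[a] - src.origin[a])
        / src.spacing[a]
        for a in range(3)
    ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(
        src.data.astype(float) if order > 0 else src.data,
        np.stack([zz, yy, xx]),
        order=order,
        mode="constant",
        cval=cval,
    )
    return target.copy_with(out, unit=src.unit)
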