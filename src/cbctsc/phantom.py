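"""Seeded digital female-pelvis phantom.

Generates an analytic label/HU volume pair emulating a pelvis brachytherapy
phantom: an elliptical body cross-section (default 340 mm x 200 mm) with an
adipose shell, muscle-equivalent background, pelvic organs (bladder, uterus,
rectum, intestine), bilateral bone stand-ins and an optional high-HU tandem
applicator.  Structure HU statistics follow typical phantom materials:
organs around 190-200 HU, adipose near -112 HU, muscle-equivalent plastic
near 130 HU (deliberately *between* the muscle and bone threshold windows,
as such materials are in practice), a PMMA-like cortical-bone stand-in
(~120 HU) and a POM-like cancellous stand-in (~340 HU).

All geometry is analytic (ellipsoids, elliptic cylinders, capsule tubes), so
structure volumes are exact and segmentation/DVH behaviour is predictable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .tissues import DEFAULT_HU_WINDOWS, TissueClass, classify_hu
from .volume import VoxelVolume, make_centered_volume

AIR_HU = -1000.0
AIR_LABEL = 0
APPLICATOR_LABEL = 99


@dataclass
class Structure:
    """One analytic structure: an ellipsoid or a full-height elliptic cylinder.

    ``center`` and ``radii`` are (z, y, x) mm; for ``kind="ecyl"`` the z
    entries are ignored and the structure spans the whole grid height.
    """

    name: str
    kind: str  # "ellipsoid" | "ecyl"
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    mean_hu: float
    std_hu: float

    def mask(self, vol: VoxelVolume) -> np.ndarray:
        z, y, x = vol.world_grid()
        cz, cy, cx = self.center
        rz, ry, rx = self.radii
        q = ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2
        if self.kind == "ellipsoid":
            q = q + ((z - cz) / rz) ** 2
        elif self.kind != "ecyl":
            raise ValueError(f"unknown structure kind {self.kind!r}")
        return np.broadcast_to(q <= 1.0, vol.shape).copy()


def default_organ_set() -> list[Structure]:
    """Structure list in painting priority order (later entries override)."""
    return [
        Structure("adipose", "ecyl", (0, 0, 0), (0, 100.0, 170.0), -112.0, 10.0),
        Structure("muscle", "ecyl", (0, 0, 0), (0, 86.0, 156.0), 130.0, 9.0),
        Structure("intestine", "ellipsoid", (25.0, 20.0, 60.0), (28.0, 22.0, 30.0), 30.0, 9.0),
        Structure("bladder", "ellipsoid", (0.0, -45.0, 0.0), (28.0, 28.0, 35.0), 191.0, 10.0),
        Structure("rectum", "ellipsoid", (0.0, 45.0, 0.0), (45.0, 15.0, 18.0), 199.0, 10.0),
        Structure("uterus", "ellipsoid", (5.0, 0.0, 0.0), (32.0, 25.0, 28.0), 196.0, 15.0),
        Structure("cortical_bone_left", "ellipsoid", (0.0, 0.0, -110.0), (60.0, 35.0, 25.0), 120.0, 12.0),
        Structure("cortical_bone_right", "ellipsoid", (0.0, 0.0, 110.0), (60.0, 35.0, 25.0), 120.0, 12.0),
        Structure("cancellous_bone_left", "ellipsoid", (0.0, 0.0, -110.0), (52.0, 27.0, 17.0), 340.0, 12.0),
        Structure("cancellous_bone_right", "ellipsoid", (0.0, 0.0, 110.0), (52.0, 27.0, 17.0), 340.0, 12.0),
    ]


@dataclass
class PhantomSpec:
    """Parameters of the digital pelvis phantom.

    ``grid_shape``/``voxel_size`` are (z, y, x); the body is the first
    (lowest-priority) structure of ``organ_set`` and must fit inside the
    grid.  ``texture_scale`` rescales every structure's texture std (0 gives
    noiseless piecewise-constant ground truth).
    """

    grid_shape: tuple[int, int, int] = (96, 192, 256)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    organ_set: list[Structure] = field(default_factory=default_organ_set)
    texture_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if not self.organ_set:
            raise ValueError("organ_set must contain at least the body outline")
        body = self.organ_set[0]
        half = [n * s / 2.0 for n, s in zip(self.grid_shape, self.voxel_size)]
        if body.radii[1] > half[1] or body.radii[2] > half[2]:
            raise ValueError("body ellipse does not fit inside the grid")
        for s in self.organ_set:
            cls = classify_hu(s.mean_hu, DEFAULT_HU_WINDOWS)
            # gap-class structures (cls None) are allowed by design; a mean
            # inside two windows is impossible since windows are disjoint.
            del cls


@dataclass
class ApplicatorSpec:
    """Rigid high-HU tandem applicator along a polyline channel.

    ``channel_polyline`` is an ordered list of (z, y, x) mm points; the tube
    is the union of capsules around consecutive segments.
    """

    channel_polyline: tuple[tuple[float, float, float], ...] = (
        (-60.0, 0.0, 0.0),
        (30.0, 0.0, 0.0),
    )
    radius: float = 3.0
    hu_value: float = 2500.0

    def __post_init__(self) -> None:
        if len(self.channel_polyline) < 2:
            raise ValueError("channel_polyline needs at least two points")
        if self.hu_value <= DEFAULT_HU_WINDOWS[TissueClass.BONE][0]:
            raise ValueError("applicator HU must sit clearly above the bone threshold")

    def mask(self, vol: VoxelVolume) -> np.ndarray:
        z, y, x = vol.world_grid()
        pts = [np.asarray(p, dtype=float) for p in self.channel_polyline]
        d2min = np.full(vol.shape, np.inf)
        for a, b in zip(pts, pts[1:]):
            ab = b - a
            denom = float(ab @ ab)
            # clamp projection parameter to the segment -> capsule distance
            t = ((z - a[0]) * ab[0] + (y - a[1]) * ab[1] + (x - a[2]) * ab[2]) / denom
            t = np.clip(t, 0.0, 1.0)
            d2 = (
                (z - (a[0] + t * ab[0])) ** 2
                + (y - (a[1] + t * ab[1])) ** 2
                + (x - (a[2] + t * ab[2])) ** 2
            )
            d2min = np.minimum(d2min, d2)
        return d2min <= self.radius**2

    def length(self) -> float:
        pts = [np.asarray(p, dtype=float) for p in self.channel_polyline]
        return float(sum(np.linalg.norm(b - a) for a, b in zip(pts, pts[1:])))


@dataclass
class ROISpec:
    """A spherical region of interest entirely inside one structure."""

    name: str
    center: tuple[float, float, float]  # (z, y, x) mm
    radius: float
    tissue_class: str
    role: str  # "target" | "background"

    def mask(self, vol: VoxelVolume) -> np.ndarray:
        z, y, x = vol.world_grid()
        cz, cy, cx = self.center
        d2 = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2
        return d2 <= self.radius**2


# name, center (z,y,x), radius mm, structure containing it, role
DEFAULT_ROI_LAYOUT: list[tuple[str, tuple[float, float, float], float, str, str]] = [
    ("muscle_1", (0.0, 40.0, -80.0), 6.0, "muscle", "background"),
    ("muscle_2", (-20.0, 40.0, 80.0), 6.0, "muscle", "background"),
    ("muscle_3", (10.0, -40.0, -80.0), 6.0, "muscle", "background"),
    ("muscle_4", (-30.0, -40.0, 80.0), 6.0, "muscle", "background"),
    ("muscle_5", (-30.0, 70.0, 0.0), 6.0, "muscle", "background"),
    ("muscle_6", (30.0, -70.0, 25.0), 6.0, "muscle", "background"),
    ("adipose", (0.0, -92.0, 0.0), 5.0, "adipose", "background"),
    ("bladder", (0.0, -50.0, 0.0), 8.0, "bladder", "target"),
    ("uterus", (5.0, 8.0, 12.0), 6.0, "uterus", "target"),
    ("rectum", (0.0, 45.0, 0.0), 7.0, "rectum", "target"),
]


def structure_labels(spec: PhantomSpec) -> dict[str, int]:
    """Integer label per structure; 0 is air, 99 the applicator."""
    return {s.name: i + 1 for i, s in enumerate(spec.organ_set)}


def make_pelvis_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, VoxelVolume]:
    """Build (label volume, ground-truth HU volume) from a phantom spec.

    Later structures in ``organ_set`` override earlier ones (declared
    priority order).  Outside the body everything is air at -1000 HU.  The
    HU texture is seeded Gaussian noise with each structure's own std.
    """
    spec.validate()
    labels = make_centered_volume(spec.grid_shape, spec.voxel_size, fill=AIR_LABEL, dtype=np.int16, unit="label")
    hu = make_centered_volume(spec.grid_shape, spec.voxel_size, fill=AIR_HU, unit="HU")
    name_to_label = structure_labels(spec)
    body_mask = spec.organ_set[0].mask(labels)
    rng = np.random.default_rng(spec.seed)
    for s in spec.organ_set:
        m = s.mask(labels)
        if np.any(m & ~body_mask):
            raise ValueError(f"structure {s.name!r} extends outside the body outline")
        labels.data[m] = name_to_label[s.name]
        vals = np.full(int(m.sum()), s.mean_hu)
        std = s.std_hu * spec.texture_scale
        if std > 0:
            vals = vals + rng.normal(0.0, std, size=vals.size)
        hu.data[m] = vals
    return labels, hu


def make_planning_ct(hu: VoxelVolume, noise_std: float, seed: int) -> VoxelVolume:
    """Emulate a high-quality planning-CT prior: ground truth + i.i.d. noise."""
    if noise_std < 0:
        raise ValueError("noise_std must be >= 0")
    out = hu.data.astype(float)
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_std, size=out.shape)
    return hu.copy_with(out)


def insert_applicator(
    labels: VoxelVolume, hu: VoxelVolume, spec: ApplicatorSpec
) -> tuple[VoxelVolume, VoxelVolume]:
    """Paint the applicator tube into copies of the label and HU volumes."""
    if spec.radius < min(hu.spacing):
        raise ValueError("applicator radius must be at least one voxel")
    m = spec.mask(hu)
    if np.any(labels.data[m] == AIR_LABEL):
        raise ValueError("applicator channel leaves the body")
    labels_out = labels.copy_with(labels.data.copy())
    hu_out = hu.copy_with(hu.data.copy())
    labels_out.data[m] = APPLICATOR_LABEL
    hu_out.data[m] = spec.hu_value
    return labels_out, hu_out


def applicator_scan(spec: ApplicatorSpec, like: VoxelVolume) -> VoxelVolume:
    """Emulate a dedicated CT scan of the applicator alone (air background)."""
    out = like.copy_with(np.full(like.shape, AIR_HU), unit="HU")
    out.data[spec.mask(like)] = spec.hu_value
    return out


def roi_catalog(
    labels: VoxelVolume,
    spec: PhantomSpec,
    layout: list[tuple[str, tuple[float, float, float], float, str, str]] | None = None,
) -> list[ROISpec]:
    """Build the 10-ROI catalog (six muscle, adipose, bladder, uterus, rectum).

    Each ROI must be entirely inside its declared structure; impure or empty
    ROIs raise, so layout errors surface immediately.
    """
    layout = DEFAULT_ROI_LAYOUT if layout is None else layout
    name_to_label = structure_labels(spec)
    rois = []
    for name, center, radius, struct, role in layout:
        if struct not in name_to_label:
            raise ValueError(f"ROI {name!r} references absent structure {struct!r}")
        roi = ROISpec(name, center, radius, struct, role)
        m = roi.mask(labels)
        if not np.any(m):
            raise ValueError(f"ROI {name!r} contains no voxels")
        got = np.unique(labels.data[m])
        if got.size != 1 or got[0] != name_to_label[struct]:
            raise ValueError(
                f"ROI {name!r} is not pure {struct!r}: labels {got.tolist()}"
            )
        rois.append(roi)
    return rois


def rois_to_json(rois: list[ROISpec], path) -> None:
    with open(path, "w") as f:
        json.dump([asdict(r) for r in rois], f, indent=1)


def rois_from_json(path) -> list[ROISpec]:
    with open(path) as f:
        raw = json.load(f)
    return [
        ROISpec(r["name"], tuple(r["center"]), r["radius"], r["tissue_class"], r["role"])
        for r in raw
    ]
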