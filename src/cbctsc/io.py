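"""Reading and writing volumes and projection stacks.

Volumes go through SimpleITK (MetaImage ``.mha`` and NIfTI ``.nii.gz``) with
spacing and origin preserved in the header; array axis order (z, y, x) maps
to ITK's (x, y, z) metadata convention.  Projection stacks are stored as a
``.npy`` array next to a JSON sidecar carrying the geometry, domain tag and
I0 (plus the scatter ground truth, when present, as a second ``.npy``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .projector import ConeBeamGeometry, ProjectionStack
from .volume import VoxelVolume

VOLUME_SUFFIXES = (".mha", ".nii.gz", ".nii")


def _check_volume_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in VOLUME_SUFFIXES):
        raise ValueError(
            f"unsupported volume format {path.name!r}; use one of {VOLUME_SUFFIXES}"
        )


def write_volume(vol: VoxelVolume, path) -> None:
    path = Path(path)
    _check_volume_path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data))
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(tuple(reversed(vol.origin)))
    sitk.WriteImage(img, str(path), useCompression=path.name.endswith(".nii.gz"))


def read_volume(path, unit: str = "") -> VoxelVolume:
    path = Path(path)
    _check_volume_path(path)
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)
    return VoxelVolume(
        data,
        tuple(reversed(img.GetSpacing())),
        tuple(reversed(img.GetOrigin())),
        unit,
    )


def write_projections(stack: ProjectionStack, basepath) -> None:
    """Write ``<basepath>.npy`` (+ ``_scatter.npy``) and ``<basepath>.json``."""
    base = Path(basepath)
    np.save(base.with_suffix(".npy"), stack.data)
    g = stack.geometry
    sidecar = {
        "domain": stack.domain,
        "source_axis_distance": g.source_axis_distance,
        "source_detector_distance": g.source_detector_distance,
        "detector_pixels": list(g.detector_pixels),
        "pixel_pitch": g.pixel_pitch,
        "view_angles_deg": g.view_angles_deg.tolist(),
        "I0": g.I0,
        "has_scatter_truth": stack.scatter_truth is not None,
    }
    if stack.scatter_truth is not None:
        np.save(base.parent / (base.stem + "_scatter.npy"), stack.scatter_truth)
    with open(base.with_suffix(".json"), "w") as f:
        json.dump(sidecar, f, indent=1)


def read_projections(basepath, expect_domain: str | None = None) -> ProjectionStack:
    base = Path(basepath)
    with open(base.with_suffix(".json")) as f:
        sidecar = json.load(f)
    required = {
        "domain", "source_axis_distance", "source_detector_distance",
        "detector_pixels", "pixel_pitch", "view_angles_deg", "I0",
    }
    missing = required - sidecar.keys()
    if missing:
        raise ValueError(f"corrupted sidecar: missing {sorted(missing)}")
    if expect_domain is not None and sidecar["domain"] != expect_domain:
        raise ValueError(
            f"projection stack is in the {sidecar['domain']!r} domain, "
            f"expected {expect_domain!r}"
        )
    geom = ConeBeamGeometry(
        sidecar["source_axis_distance"],
        sidecar["source_detector_distance"],
        tuple(sidecar["detector_pixels"]),
        sidecar["pixel_pitch"],
        np.asarray(sidecar["view_angles_deg"]),
        sidecar["I0"],
    )
    data = np.load(base.with_suffix(".npy"))
    scatter = None
    if sidecar.get("has_scatter_truth"):
        scatter = np.load(base.parent / (base.stem + "_scatter.npy"))
    return ProjectionStack(sidecar["domain"], data, geom, scatter)
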