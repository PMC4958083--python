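"""Manual cylindrical VOIs, PET sampling, and Dice overlap evaluation.

The manual workflow places cylindrical red-marrow VOIs (default 1.9 cm
diameter, 2 cm height — five axial slices on the 4 mm PET grid) in each
vertebral body; any mask, manual or automatic, is mapped onto the
coregistered PET volume by taking the arithmetic mean of the PET voxels
under it.  Agreement between automatic and manual VOIs is quantified by the
Dice similarity coefficient DSC = 2|A ∩ M| / (|A| + |M|).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataError, EmptyRegionError, GridError, UndefinedDSCError
from .imaging import BinaryMask, ImageVolume

__all__ = [
    "BinaryMask",
    "CylinderSpec",
    "make_cylinder_voi",
    "mean_concentration",
    "dice",
    "dice_per_segment",
]


@dataclass
class CylinderSpec:
    """A z-axis-aligned cylindrical VOI in physical coordinates (mm)."""

    center: tuple[float, float, float]
    diameter: float = 19.0
    height: float = 20.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.height <= 0:
            raise DataError("cylinder diameter and height must be > 0")
        self.center = tuple(float(c) for c in self.center)


def make_cylinder_voi(spec: CylinderSpec, geometry: ImageVolume | BinaryMask) -> BinaryMask:
    """Rasterise a cylinder on a volume's grid by voxel-centre inclusion.

    A voxel belongs to the VOI iff its centre lies within the cylinder:
    in-plane distance <= radius and axial distance <= height/2.  A cylinder
    whose bounding box misses the grid extent entirely raises
    :class:`EmptyRegionError`; a cylinder that intersects the grid but
    captures no voxel centre yields a valid empty mask.
    """
    cx, cy, cz = spec.center
    r = spec.diameter / 2.0
    hz = spec.height / 2.0
    # grid extent check (voxel-centre span per axis)
    for ax, (c, half) in enumerate([(cx, r), (cy, r), (cz, hz)]):
        centers = geometry.voxel_centers(ax)
        if c + half < centers[0] - geometry.spacing[ax] / 2 or c - half > centers[-1] + geometry.spacing[ax] / 2:
            raise EmptyRegionError("cylinder does not intersect the volume extent")
    x = geometry.voxel_centers(0)[:, None, None]
    y = geometry.voxel_centers(1)[None, :, None]
    z = geometry.voxel_centers(2)[None, None, :]
    support = ((x - cx) ** 2 + (y - cy) ** 2 <= r**2) & (np.abs(z - cz) <= hz)
    return BinaryMask(
        support=support, spacing=geometry.spacing, origin=geometry.origin, label="cylinder"
    )


def mean_concentration(mask: BinaryMask, pet: ImageVolume) -> float:
    """Mean PET activity concentration (Bq/mL) of the voxels under a mask."""
    if not mask.same_geometry(pet):
        raise GridError("mask and PET volume are on different grids")
    if not mask.support.any():
        raise EmptyRegionError("cannot average over an empty mask")
    return float(pet.voxels[mask.support].mean())


def dice(a: BinaryMask, m: BinaryMask) -> float:
    """Dice similarity coefficient 2|A ∩ M| / (|A| + |M|) by voxel counts."""
    if not a.same_geometry(m):
        raise GridError("masks are on different grids")
    na, nm = a.voxel_count, m.voxel_count
    if na + nm == 0:
        raise UndefinedDSCError("DSC is undefined for two empty masks")
    inter = int((a.support & m.support).sum())
    return 2.0 * inter / (na + nm)


def dice_per_segment(
    auto: BinaryMask, manual: Sequence[BinaryMask]
) -> tuple[float, list[float]]:
    """DSC of an automatic mask against a set of per-segment manual VOIs.

    Returns the default union DSC (automatic mask vs the union of all manual
    VOIs) together with the per-segment DSC list, since either convention is
    defensible when segments are scored separately.
    """
    if not manual:
        raise EmptyRegionError("need at least one manual VOI")
    union = np.zeros(auto.shape, dtype=bool)
    per = []
    for m in manual:
        if not m.same_geometry(auto):
            raise GridError("manual VOI grid differs from the automatic mask grid")
        union |= m.support
        per.append(dice(auto, m))
    union_mask = BinaryMask(support=union, spacing=auto.spacing, origin=auto.origin, label="manual-union")
    return dice(auto, union_mask), per
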