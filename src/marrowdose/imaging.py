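"""Image data model, NIfTI I/O with JSON sidecars, and trilinear rebinning.

Volumes are stored as 3D arrays indexed ``(x, y, z)`` with axial slices
``voxels[:, :, k]``.  Voxel ``(i, j, k)`` is centred at the physical point
``origin + index * spacing`` (mm); the affine written to NIfTI is the
corresponding diagonal scaling plus translation.

CT volumes carry Hounsfield units; PET volumes carry activity concentration
in Bq/mL together with the acquisition time in hours post injection.  Study
metadata that has no standard NIfTI home (modality, acquisition time,
injected activity, patient weight) travels in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DataError, GridError, ShapeError

__all__ = [
    "ImageVolume",
    "StudyMeta",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_study_meta",
    "write_study_meta",
    "rebin_trilinear",
]

_MODALITIES = ("CT", "PET")


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    voxels:
        3D float array, indexed (x, y, z).  HU for CT, Bq/mL for PET.
    spacing:
        Voxel pitch (dx, dy, dz) in mm, all > 0.
    origin:
        Physical coordinate (mm) of the centre of voxel (0, 0, 0).
    modality:
        "CT" or "PET".
    time_post_injection_h:
        Acquisition time in hours post injection (PET only; None for CT).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"
    time_post_injection_h: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ShapeError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ShapeError(f"degenerate grid shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise DataError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise DataError("voxel values must all be finite")
        if self.modality not in _MODALITIES:
            raise DataError(f"modality must be one of {_MODALITIES}, got {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mL(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent covered by the grid (shape * spacing) per axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def same_geometry(self, other: "ImageVolume | BinaryMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class BinaryMask:
    """A boolean region on an :class:`ImageVolume` geometry.

    Holds the contours of the delineation pipeline: the loose initialisation
    region c1, the outer bone contour c2 and the eroded intraosseous region
    c3, as well as manual cylindrical VOIs.
    """

    support: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=bool)
        if self.support.ndim != 3:
            raise ShapeError(f"mask must be 3D, got ndim={self.support.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise DataError(f"spacing must be positive, got {self.spacing}")

    @classmethod
    def like(cls, vol: ImageVolume, support: np.ndarray, label: str = "") -> "BinaryMask":
        support = np.asarray(support, dtype=bool)
        if support.shape != vol.shape:
            raise GridError(f"mask shape {support.shape} != volume shape {vol.shape}")
        return cls(support=support, spacing=vol.spacing, origin=vol.origin, label=label)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.support.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.support.sum())

    @property
    def volume_mL(self) -> float:
        dx, dy, dz = self.spacing
        return self.voxel_count * dx * dy * dz / 1000.0

    def same_geometry(self, other: "BinaryMask | ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def voxel_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]


@dataclass
class StudyMeta:
    """Per-study acquisition metadata from the JSON sidecar."""

    injected_activity_MBq: float
    patient_weight_kg: float
    scan_times_h: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.injected_activity_MBq <= 0:
            raise DataError("injected activity must be > 0 MBq")
        if self.patient_weight_kg <= 0:
            raise DataError("patient weight must be > 0 kg")
        self.scan_times_h = tuple(float(t) for t in self.scan_times_h)
        t = np.asarray(self.scan_times_h)
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise DataError("scan times must be non-negative and strictly increasing")


def _affine(vol: ImageVolume | BinaryMask) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vol.spacing
    aff[:3, 3] = vol.origin
    return aff


def write_volume(vol: ImageVolume | BinaryMask, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a volume or mask as NIfTI-1; optionally write the JSON sidecar."""
    if isinstance(vol, BinaryMask):
        data = vol.support.astype(np.uint8)
        img = nib.Nifti1Image(data, _affine(vol))
    else:
        img = nib.Nifti1Image(vol.voxels.astype(np.float32), _affine(vol))
        img.header["descrip"] = vol.modality.encode()
    nib.save(img, str(path))
    if sidecar is not None and isinstance(vol, ImageVolume):
        payload: dict = {"modality": vol.modality}
        if vol.time_post_injection_h is not None:
            payload["time_post_injection_h"] = vol.time_post_injection_h
        Path(sidecar).write_text(json.dumps(payload, indent=1))


def read_volume(path: str | Path, sidecar: str | Path | None = None) -> ImageVolume:
    """Read a NIfTI volume; modality/time come from the sidecar when given.

    Raises
    ------
    ShapeError
        if the stored image is not 3D.
    DataError
        if the header carries no usable (positive) voxel spacing.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3D image, got shape {data.shape}")
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise DataError(f"{path}: header has no valid voxel spacing ({spacing})")
    origin = tuple(float(v) for v in aff[:3, 3])

    modality = "CT"
    time_h: float | None = None
    descrip = bytes(img.header["descrip"]).rstrip(b"\x00").decode(errors="ignore")
    if descrip in _MODALITIES:
        modality = descrip
    if sidecar is not None:
        meta = json.loads(Path(sidecar).read_text())
        modality = meta.get("modality", modality)
        time_h = meta.get("time_post_injection_h", None)
    return ImageVolume(
        voxels=data,
        spacing=spacing,
        origin=origin,
        modality=modality,
        time_post_injection_h=time_h,
    )


def read_mask(path: str | Path, label: str = "") -> BinaryMask:
    """Read a {0,1} NIfTI file as a BinaryMask."""
    vol = read_volume(path)
    return BinaryMask(support=vol.voxels > 0.5, spacing=vol.spacing, origin=vol.origin, label=label)


def write_study_meta(meta: StudyMeta, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "injected_activity_MBq": meta.injected_activity_MBq,
                "patient_weight_kg": meta.patient_weight_kg,
                "scan_times_h": list(meta.scan_times_h),
            },
            indent=1,
        )
    )


def read_study_meta(path: str | Path) -> StudyMeta:
    d = json.loads(Path(path).read_text())
    return StudyMeta(
        injected_activity_MBq=float(d["injected_activity_MBq"]),
        patient_weight_kg=float(d["patient_weight_kg"]),
        scan_times_h=tuple(d.get("scan_times_h", ())),
    )


def rebin_trilinear(
    vol: ImageVolume,
    target_spacing: Sequence[float],
    target_shape: Sequence[int] | None = None,
) -> ImageVolume:
    """Resample a volume onto a coarser/finer grid by trilinear interpolation.

    By default the output grid is anchored at the input origin with
    ``dims = ceil(extent / target_spacing)``, so the physical extent is
    preserved to within one target voxel per border.  Passing
    ``target_shape`` pins the output matrix instead (e.g. the actual PET
    grid, so masks drawn on the output lie voxel-for-voxel on PET).  Output
    values are the trilinear interpolant of the input evaluated at output
    voxel centres; queries beyond the input sample support clamp to the
    edge value.

    This is the rebinning used to bring the native low-dose CT grid
    (1.17 x 1.17 x 5.00 mm) onto the 4 mm isotropic PET grid.
    """
    target = tuple(float(s) for s in target_spacing)
    if len(target) != 3 or any(s <= 0 for s in target):
        raise DataError(f"target spacing must be three positive values, got {target}")
    extent = vol.extent_mm
    if any(s > e for s, e in zip(target, extent)):
        raise ShapeError(
            f"target spacing {target} coarser than the volume extent {extent}: degenerate grid"
        )
    if target_shape is not None:
        out_shape = tuple(int(n) for n in target_shape)
        if any(n < 1 for n in out_shape):
            raise ShapeError(f"degenerate target shape {out_shape}")
    else:
        out_shape = tuple(int(np.ceil(e / s - 1e-9)) for e, s in zip(extent, target))
    # output centre j maps to fractional input index j * target / spacing
    axes = [np.arange(n) * t / s for n, t, s in zip(out_shape, target, vol.spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(vol.voxels, np.stack(coords), order=1, mode="nearest")
    return ImageVolume(
        voxels=out,
        spacing=target,
        origin=vol.origin,
        modality=vol.modality,
        time_post_injection_h=vol.time_post_injection_h,
    )
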