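"""Synthetic coregistered CT/PET lumbar-spine phantom.

Emulates the acquisition geometry of a hybrid PET/CT study: a low-dose CT
on a native 1.17 x 1.17 x 5.00 mm grid showing a stack of vertebral bodies
(cylinders with a cortical shell around a trabecular interior, separated by
intervertebral gaps, in a soft-tissue background), and a matched series of
4 mm isotropic PET volumes in which the intraosseous (marrow) compartment
clears mono-exponentially with a configurable effective half-life while the
background carries a small fraction of the marrow uptake.

Vertebrae are analytic cylinders rather than anatomical meshes: every
pipeline operator (active contour, erosion, Dice, TAC extraction) is
geometry-agnostic, and simple shapes give closed-form volumes to test
against.  The cortical shell is a lateral ring only (no endplates), matching
the strictly in-plane contour and erosion operators.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .dosimetry import ZR89_HALF_LIFE_H
from .errors import DataError, EmptyRegionError
from .imaging import BinaryMask, ImageVolume, StudyMeta, write_study_meta, write_volume

__all__ = [
    "PhantomSpec",
    "generate_ct",
    "generate_pet_series",
    "write_phantom",
    "pet_truth_masks",
    "marrow_concentration",
    "manual_cylinder_centers_mm",
]

CT_SPACING = (1.17, 1.17, 5.0)
PET_SPACING = (4.0, 4.0, 4.0)


@dataclass
class PhantomSpec:
    """Geometry, contrast and kinetics of the synthetic study.

    Defaults follow the imaged study conditions: five lumbar vertebrae,
    scans at 1, 24, 48, 96 and 144 h post injection, marrow clearing with a
    73 h effective half-life (shorter than the 78.41 h Zr-89 physical
    half-life), low-dose-CT noise of 20 HU, 5 % PET multiplicative noise and
    a 7 mm reconstruction point-spread blur.  Vertebral-body dimensions
    (48 mm diameter, 30 mm height, 10 mm disc gap, 4 mm cortical shell) are
    plausible adult lumbar values.
    """

    n_vertebrae: int = 5
    body_radius_mm: float = 24.0
    body_height_mm: float = 30.0
    gap_mm: float = 10.0
    shell_thickness_mm: float = 4.0
    hu_background: float = 40.0
    hu_cortical: float = 400.0
    hu_trabecular: float = 120.0
    ct_noise_hu: float = 20.0
    pet_noise_frac: float = 0.05
    marrow_C0_Bq_per_mL: float = 5000.0
    background_uptake_frac: float = 0.05
    effective_half_life_h: float = 73.0
    scan_times_h: tuple[float, ...] = (1.0, 24.0, 48.0, 96.0, 144.0)
    psf_fwhm_mm: float = 7.0
    injected_activity_MBq: float = 37.1
    patient_weight_kg: float = 73.7
    inplane_margin_mm: float = 24.0
    axial_margin_mm: float = 23.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.hu_cortical > self.hu_trabecular > self.hu_background):
            raise DataError(
                "need hu_cortical > hu_trabecular > hu_background for segmentable contrast"
            )
        if self.effective_half_life_h <= 0 or self.effective_half_life_h > ZR89_HALF_LIFE_H:
            raise DataError(
                "effective half-life must be positive and no longer than the physical half-life"
            )
        if self.n_vertebrae < 1 or self.body_radius_mm <= 0 or self.body_height_mm <= 0:
            raise DataError("phantom geometry must be positive")
        if self.shell_thickness_mm <= 0 or self.shell_thickness_mm >= self.body_radius_mm:
            raise DataError("cortical shell must be thinner than the body radius")
        self.scan_times_h = tuple(float(t) for t in self.scan_times_h)

    # -- analytic geometry -------------------------------------------------

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        xy = 2.0 * (self.body_radius_mm + self.inplane_margin_mm)
        z = (
            self.n_vertebrae * self.body_height_mm
            + (self.n_vertebrae - 1) * self.gap_mm
            + 2.0 * self.axial_margin_mm
        )
        return (xy, xy, z)

    @property
    def center_xy_mm(self) -> tuple[float, float]:
        return (self.fov_mm[0] / 2.0, self.fov_mm[1] / 2.0)

    def vertebra_z_span(self, i: int) -> tuple[float, float]:
        """Axial [lo, hi] extent (mm) of vertebral body ``i``."""
        lo = self.axial_margin_mm + i * (self.body_height_mm + self.gap_mm)
        return lo, lo + self.body_height_mm

    def vertebra_centroids_mm(self) -> list[tuple[float, float, float]]:
        cx, cy = self.center_xy_mm
        out = []
        for i in range(self.n_vertebrae):
            lo, hi = self.vertebra_z_span(i)
            out.append((cx, cy, (lo + hi) / 2.0))
        return out

    def lv_box_mm(self) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
        """A tight physical box around the whole vertebral stack (input for c1)."""
        cx, cy = self.center_xy_mm
        r = self.body_radius_mm
        z0 = self.vertebra_z_span(0)[0]
        z1 = self.vertebra_z_span(self.n_vertebrae - 1)[1]
        return ((cx - r, cy - r, z0), (cx + r, cy + r, z1))

    def interior_volume_mL(self) -> float:
        """Closed-form intraosseous volume of the whole stack (mL)."""
        r_in = self.body_radius_mm - self.shell_thickness_mm
        return self.n_vertebrae * math.pi * r_in**2 * self.body_height_mm / 1000.0


def manual_cylinder_centers_mm(
    spec: PhantomSpec, snap_to_slice_mm: float | None = PET_SPACING[2]
) -> list[tuple[float, float, float]]:
    """Stand-in for the radiologist: cylinder centres at vertebral-body centroids.

    Circular ROIs are drawn on displayed axial slices, so the axial centre is
    snapped to the nearest PET slice centre by default.
    """
    centers = []
    for cx, cy, cz in spec.vertebra_centroids_mm():
        if snap_to_slice_mm:
            cz = round(cz / snap_to_slice_mm) * snap_to_slice_mm
        centers.append((cx, cy, cz))
    return centers


def _grid_shape(fov: Sequence[float], spacing: Sequence[float]) -> tuple[int, int, int]:
    return tuple(int(np.ceil(f / s - 1e-9)) for f, s in zip(fov, spacing))  # type: ignore[return-value]


def _rasterize(spec: PhantomSpec, spacing: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """(whole_vertebra, intraosseous) boolean grids on an arbitrary spacing."""
    shape = _grid_shape(spec.fov_mm, spacing)
    x = np.arange(shape[0]) * spacing[0]
    y = np.arange(shape[1]) * spacing[1]
    z = np.arange(shape[2]) * spacing[2]
    cx, cy = spec.center_xy_mm
    r2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
    in_disk = r2 <= spec.body_radius_mm**2
    in_core = r2 <= (spec.body_radius_mm - spec.shell_thickness_mm) ** 2
    in_body_z = np.zeros(shape[2], dtype=bool)
    for i in range(spec.n_vertebrae):
        lo, hi = spec.vertebra_z_span(i)
        in_body_z |= (z >= lo) & (z <= hi)
    whole = in_disk[:, :, None] & in_body_z[None, None, :]
    core = in_core[:, :, None] & in_body_z[None, None, :]
    return whole, core


def generate_ct(spec: PhantomSpec) -> tuple[ImageVolume, dict[str, BinaryMask]]:
    """Native-grid low-dose CT plus ground-truth masks.

    Voxels inside the cortical ring take ``hu_cortical``, the trabecular
    interior ``hu_trabecular``, everything else ``hu_background``; seeded
    additive Gaussian noise of sd ``ct_noise_hu`` is applied on top.
    Returns the CT and ``{"whole_vertebra": ..., "intraosseous": ...}``
    truth masks on the same grid.
    """
    whole, core = _rasterize(spec, CT_SPACING)
    hu = np.full(whole.shape, spec.hu_background, dtype=float)
    hu[whole] = spec.hu_cortical
    hu[core] = spec.hu_trabecular
    if spec.ct_noise_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.ct_noise_hu, size=hu.shape)
    ct = ImageVolume(voxels=hu, spacing=CT_SPACING, modality="CT")
    truth = {
        "whole_vertebra": BinaryMask.like(ct, whole, label="truth-whole-vertebra"),
        "intraosseous": BinaryMask.like(ct, core, label="truth-intraosseous"),
    }
    return ct, truth


def pet_truth_masks(spec: PhantomSpec) -> dict[str, BinaryMask]:
    """Ground-truth masks rasterised analytically on the 4 mm PET grid."""
    whole, core = _rasterize(spec, PET_SPACING)
    return {
        "whole_vertebra": BinaryMask(support=whole, spacing=PET_SPACING, label="truth-whole-vertebra"),
        "intraosseous": BinaryMask(support=core, spacing=PET_SPACING, label="truth-intraosseous"),
    }


def marrow_concentration(spec: PhantomSpec, t_h: float) -> float:
    """Generator marrow concentration C(t) = C0 * 2^(-t / T_eff), Bq/mL."""
    return spec.marrow_C0_Bq_per_mL * 2.0 ** (-t_h / spec.effective_half_life_h)


def generate_pet_series(
    spec: PhantomSpec, truth: dict[str, BinaryMask] | None = None
) -> list[ImageVolume]:
    """One 4 mm isotropic PET volume per scan time.

    Marrow voxels take the mono-exponential concentration
    ``C(t) = C0 * 2^(-t/T_eff)``; all other voxels take
    ``background_uptake_frac * C(t)``.  A Gaussian blur of
    ``psf_fwhm_mm`` emulates reconstruction resolution, then seeded
    multiplicative Gaussian noise of fractional sd ``pet_noise_frac``.
    """
    if truth is not None and not truth["intraosseous"].support.any():
        raise EmptyRegionError("truth intraosseous mask is empty")
    marrow = pet_truth_masks(spec)["intraosseous"].support
    if not marrow.any():
        raise EmptyRegionError("phantom geometry yields no marrow voxels on the PET grid")
    rng = np.random.default_rng(spec.seed + 1)
    sigma_vox = [spec.psf_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / s for s in PET_SPACING]
    series: list[ImageVolume] = []
    for t in spec.scan_times_h:
        c = marrow_concentration(spec, t)
        img = np.full(marrow.shape, spec.background_uptake_frac * c, dtype=float)
        img[marrow] = c
        if spec.psf_fwhm_mm > 0:
            img = ndimage.gaussian_filter(img, sigma=sigma_vox)
        if spec.pet_noise_frac > 0:
            img = img * (1.0 + rng.normal(0.0, spec.pet_noise_frac, size=img.shape))
            img = np.clip(img, 0.0, None)
        series.append(
            ImageVolume(voxels=img, spacing=PET_SPACING, modality="PET", time_post_injection_h=t)
        )
    return series


def write_phantom(spec: PhantomSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write CT + sidecar, the PET series + sidecars, truth masks and the spec.

    Produces the standard layout consumed by the imaging module and the CLI.
    Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ct, truth = generate_ct(spec)
    pets = generate_pet_series(spec, truth)
    paths: dict[str, Path] = {}

    paths["ct"] = out / "ct.nii.gz"
    write_volume(ct, paths["ct"], sidecar=out / "ct.json")
    for name, mask in truth.items():
        paths[f"truth_{name}"] = out / f"truth_{name}.nii.gz"
        write_volume(mask, paths[f"truth_{name}"])
    for name, mask in pet_truth_masks(spec).items():
        paths[f"truth_{name}_pet"] = out / f"truth_{name}_pet.nii.gz"
        write_volume(mask, paths[f"truth_{name}_pet"])
    for i, pet in enumerate(pets):
        p = out / f"pet_{i:02d}.nii.gz"
        write_volume(pet, p, sidecar=out / f"pet_{i:02d}.json")
        paths[f"pet_{i:02d}"] = p
    meta = StudyMeta(
        injected_activity_MBq=spec.injected_activity_MBq,
        patient_weight_kg=spec.patient_weight_kg,
        scan_times_h=spec.scan_times_h,
    )
    paths["study"] = out / "study.json"
    write_study_meta(meta, paths["study"])
    paths["spec"] = out / "phantom_spec.json"
    Path(paths["spec"]).write_text(json.dumps(asdict(spec), indent=1))
    return paths
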