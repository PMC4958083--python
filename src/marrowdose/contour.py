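"""Automatic lumbar-vertebra delineation on rebinned low-dose CT.

The pipeline follows three nested contours per axial slice:

1. c1 — a loose region: a user-supplied box around the vertebral column,
   dilated by ~1 cm, rasterised on the rebinned CT grid.
2. c2 — the outer bone contour, found per slice by a region-based
   (Chan–Vese) active contour with an additional distance-regularisation
   term that keeps the level-set function close to a signed distance
   function, which stabilises evolution across weak boundaries.
3. c3 — the intraosseous region, obtained by in-plane morphological
   erosion of c2 with a cross-shaped element of radius 1, 2 or 3 pixels,
   removing the cortical shell.

The level-set energy minimised per slice is

    E(phi) = mu_reg * R(phi) + mu_length * L(phi)
             + lambda_in  * int_{phi>0} (I - c_in)^2
             + lambda_out * int_{phi<0} (I - c_out)^2

with R(phi) = int 1/2 (|grad phi| - 1)^2 the distance-regularisation term,
L(phi) the smoothed contour length, and c_in/c_out the region means under
the smoothed Heaviside weighting, recomputed every iteration.  Gradient
descent uses the smoothed Dirac delta of width ``epsilon``; the inside
region is {phi > 0}.  Evolution is strictly 2D, applied slice by slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import DataError, EmptyRegionError, ShapeError
from .imaging import BinaryMask, ImageVolume

__all__ = [
    "ContourParams",
    "LevelSetState",
    "DelineationResult",
    "make_initial_region",
    "evolve_slice",
    "find_outer_bone",
    "erode_to_intraosseous",
    "delineate",
]


@dataclass
class ContourParams:
    """Tunable weights of the regularised Chan–Vese evolution.

    ``n_iter`` defaults to 30 fixed iterations with no convergence test;
    an optional early stop on the mean |dphi| per iteration is available via
    ``early_stop_tol`` but off by default.  Intensities are normalised to
    [0, 1] over the working window before evolution (``normalize``), which
    makes the data-term weights scale-free and the result invariant to
    affine intensity changes of the slice.
    """

    n_iter: int = 30
    mu_length: float = 0.1
    lambda_in: float = 1.0
    lambda_out: float = 1.0
    dt: float = 1.0  # ~pixels of contour travel per iteration (speed-normalised)
    mu_reg: float = 0.2  # keep mu_reg * dt <= 0.25 for stability
    epsilon: float = 1.5  # Heaviside/Dirac smoothing width, pixels
    normalize: bool = True
    early_stop_tol: float | None = None
    min_contrast: float = 50.0  # HU; slices whose converged region contrast
    # (c_in - c_out, in original intensity units) falls below this carry no
    # bone and contribute nothing when slices are stacked in find_outer_bone

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise DataError("n_iter must be >= 1")
        if self.lambda_in <= 0 or self.lambda_out <= 0 or self.dt <= 0 or self.epsilon <= 0:
            raise DataError("lambda_in, lambda_out, dt and epsilon must be > 0")
        if self.mu_length < 0 or self.mu_reg < 0:
            raise DataError("mu_length and mu_reg must be >= 0")


@dataclass
class LevelSetState:
    """Diagnostics of one slice evolution."""

    phi: np.ndarray
    c_in: float
    c_out: float
    iteration: int
    degenerate: bool = False
    polarity_flipped: bool = False
    contrast: float = 0.0  # |c_in - c_out| in original intensity units


@dataclass
class DelineationResult:
    """Nested contours of a full delineation run: c3[k] <= c2 <= c1."""

    c1_region: BinaryMask
    c2_outer_bone: BinaryMask
    c3_intraosseous: dict[int, BinaryMask]
    slice_diagnostics: list[dict] = field(default_factory=list)


def _heaviside(phi: np.ndarray, eps: float) -> np.ndarray:
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(phi / eps))


def _dirac(phi: np.ndarray, eps: float) -> np.ndarray:
    return eps / (np.pi * (phi * phi + eps * eps))


def _curvature(phi: np.ndarray) -> np.ndarray:
    """div(grad phi / |grad phi|) with central differences."""
    g0 = np.gradient(phi, axis=0)
    g1 = np.gradient(phi, axis=1)
    norm = np.sqrt(g0 * g0 + g1 * g1) + 1e-10
    return np.gradient(g0 / norm, axis=0) + np.gradient(g1 / norm, axis=1)


def _signed_distance(region: np.ndarray) -> np.ndarray:
    """Signed distance to the region boundary, positive inside."""
    inside = ndimage.distance_transform_edt(region)
    outside = ndimage.distance_transform_edt(~region)
    return inside - outside


def make_initial_region(
    vol: ImageVolume,
    lv_box: Sequence[Sequence[float]],
    margin_mm: float = 10.0,
) -> BinaryMask:
    """Rasterise the loose initialisation region c1.

    ``lv_box`` is a physical-space box ``((x0, y0, z0), (x1, y1, z1))`` in mm
    around the lumbar-vertebra stack.  The box is rasterised by voxel-centre
    inclusion and then dilated by ``ceil(margin / spacing)`` voxels per axis
    (default margin ~1 cm), yielding the coarse CT region CT1.
    """
    lo = np.minimum(lv_box[0], lv_box[1]).astype(float)
    hi = np.maximum(lv_box[0], lv_box[1]).astype(float)
    inside = np.ones(vol.shape, dtype=bool)
    for ax in range(3):
        c = vol.voxel_centers(ax)
        sel = (c >= lo[ax]) & (c <= hi[ax])
        shape = [1, 1, 1]
        shape[ax] = -1
        inside &= sel.reshape(shape)
    if not inside.any():
        raise EmptyRegionError("lv_box does not intersect the volume")
    if margin_mm > 0:
        radii = [int(np.ceil(margin_mm / s)) for s in vol.spacing]
        struct = np.ones(tuple(2 * r + 1 for r in radii), dtype=bool)
        inside = ndimage.binary_dilation(inside, structure=struct)
    return BinaryMask.like(vol, inside, label="c1")


def evolve_slice(
    slice_img: np.ndarray,
    init: np.ndarray,
    params: ContourParams | None = None,
    return_state: bool = False,
):
    """Evolve the regularised Chan–Vese contour on one 2D slice.

    Runs ``params.n_iter`` gradient-descent steps of the energy described in
    the module docstring, starting from the signed distance function of
    ``init`` (positive inside), and returns the final inside region
    ``{phi > 0}``.  On a constant slice the data term has no gradient
    (c_in == c_out): the initial region is returned unchanged with a
    degenerate-convergence warning.  If the converged inside region is
    darker than the outside (a polarity flip on unusual initialisations)
    the complement is returned with a warning.
    """
    params = params or ContourParams()
    img = np.asarray(slice_img, dtype=float)
    init = np.asarray(init, dtype=bool)
    if img.ndim != 2 or init.shape != img.shape:
        raise ShapeError("slice and init must be 2D arrays of identical shape")
    if not np.all(np.isfinite(img)):
        raise DataError("slice intensities must be finite")
    if not init.any() or init.all():
        raise EmptyRegionError("init region must be non-empty and not the whole slice")

    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        warnings.warn("degenerate slice: constant intensity, contour cannot evolve", stacklevel=2)
        if return_state:
            return init.copy(), LevelSetState(
                phi=_signed_distance(init), c_in=lo, c_out=lo, iteration=0, degenerate=True
            )
        return init.copy()
    work = (img - lo) / (hi - lo) if params.normalize else img

    phi = _signed_distance(init)
    eps = params.epsilon
    c_in = c_out = 0.0
    it = 0
    for it in range(1, params.n_iter + 1):
        h = _heaviside(phi, eps)
        w_in = h.sum()
        w_out = (1.0 - h).sum()
        c_in = float((work * h).sum() / max(w_in, 1e-12))
        c_out = float((work * (1.0 - h)).sum() / max(w_out, 1e-12))
        curv = _curvature(phi)
        data = -params.lambda_in * (work - c_in) ** 2 + params.lambda_out * (work - c_out) ** 2
        force = _dirac(phi, eps) * (params.mu_length * curv + data)
        # normalise to unit maximum speed so dt is contour travel in pixels
        # per iteration, independent of the data-term magnitude
        force /= np.abs(force).max() + 1e-12
        dphi = params.dt * (force + params.mu_reg * (ndimage.laplace(phi) - curv))
        phi += dphi
        if params.early_stop_tol is not None and float(np.abs(dphi).mean()) < params.early_stop_tol:
            break

    region = phi > 0
    flipped = False
    if region.any() and (~region).any():
        mean_in = float(img[region].mean())
        mean_out = float(img[~region].mean())
        if mean_in < mean_out:
            warnings.warn("contour polarity flipped: returning the bright complement", stacklevel=2)
            region = ~region
            flipped = True
    if return_state:
        scale = (hi - lo) if params.normalize else 1.0
        return region, LevelSetState(
            phi=phi,
            c_in=c_in,
            c_out=c_out,
            iteration=it,
            polarity_flipped=flipped,
            contrast=abs(c_in - c_out) * scale,
        )
    return region


def find_outer_bone(
    vol: ImageVolume,
    c1: BinaryMask,
    params: ContourParams | None = None,
    diagnostics: list[dict] | None = None,
) -> BinaryMask:
    """Find the outer bone contour c2 within the loose region c1.

    Applies :func:`evolve_slice` independently to every axial slice that
    intersects c1, on a window cropped to the in-plane bounding box of c1
    (padded by 3 px), and intersects each slice result with c1 so that
    voxels outside the loose region are never included.  Results are stacked
    into a 3D mask on the volume's (rebinned) grid.
    """
    params = params or ContourParams()
    if not vol.same_geometry(c1):
        raise ShapeError("c1 must share the volume's grid")
    if not c1.support.any():
        raise EmptyRegionError("c1 is empty")
    out = np.zeros(vol.shape, dtype=bool)
    pad = 3
    for k in range(vol.shape[2]):
        sl = c1.support[:, :, k]
        if not sl.any():
            continue
        xs, ys = np.nonzero(sl)
        x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, vol.shape[0])
        y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, vol.shape[1])
        img = vol.voxels[x0:x1, y0:y1, k]
        init = sl[x0:x1, y0:y1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            region, state = evolve_slice(img, init, params, return_state=True)
        # slices without bone-level contrast (intervertebral gaps, margins)
        # carry no vertebra: they contribute nothing to c2
        included = not state.degenerate and state.contrast >= params.min_contrast
        if included:
            out[x0:x1, y0:y1, k] = region
        if diagnostics is not None:
            diagnostics.append(
                {
                    "slice": k,
                    "iterations": state.iteration,
                    "c_in": state.c_in,
                    "c_out": state.c_out,
                    "contrast": state.contrast,
                    "degenerate": state.degenerate,
                    "polarity_flipped": state.polarity_flipped,
                    "included": included,
                }
            )
    out &= c1.support
    return BinaryMask(support=out, spacing=vol.spacing, origin=vol.origin, label="c2")


def _cross_element(radius: int) -> np.ndarray:
    """Cross-shaped 2D structuring element: radius steps vertically and horizontally."""
    size = 2 * radius + 1
    el = np.zeros((size, size), dtype=bool)
    el[radius, :] = True
    el[:, radius] = True
    return el


def erode_to_intraosseous(c2: BinaryMask, kernel_px: int, element: str = "cross") -> BinaryMask:
    """In-plane erosion of the outer bone contour to the intraosseous region.

    Per axial slice, binary erosion by a structuring element of radius
    ``kernel_px``: a cross (``kernel_px`` steps vertically and horizontally,
    the default) or a full square (``element="square"``).  Removing a
    three-pixel layer excludes the cortical shell, leaving only the
    intraosseous (marrow) volume; an empty result is valid.
    """
    if kernel_px < 0:
        raise DataError("kernel_px must be >= 0")
    if kernel_px == 0:
        return BinaryMask(
            support=c2.support.copy(), spacing=c2.spacing, origin=c2.origin,
            label=f"c3_k{kernel_px}",
        )
    if element == "cross":
        el2d = _cross_element(kernel_px)
    elif element == "square":
        el2d = np.ones((2 * kernel_px + 1,) * 2, dtype=bool)
    else:
        raise DataError(f"unknown structuring element {element!r}")
    struct = el2d[:, :, None]  # in-plane only: z extent 1
    eroded = ndimage.binary_erosion(c2.support, structure=struct, border_value=0)
    return BinaryMask(
        support=eroded, spacing=c2.spacing, origin=c2.origin, label=f"c3_k{kernel_px}"
    )


def delineate(
    vol: ImageVolume,
    lv_box: Sequence[Sequence[float]],
    params: ContourParams | None = None,
    kernels: Sequence[int] = (1, 2, 3),
    margin_mm: float = 10.0,
    element: str = "cross",
) -> DelineationResult:
    """Full automatic pipeline: c1 (loose box) -> c2 (bone contour) -> c3 (erosions)."""
    params = params or ContourParams()
    c1 = make_initial_region(vol, lv_box, margin_mm=margin_mm)
    diags: list[dict] = []
    c2 = find_outer_bone(vol, c1, params, diagnostics=diags)
    c3 = {k: erode_to_intraosseous(c2, k, element=element) for k in kernels}
    return DelineationResult(
        c1_region=c1, c2_outer_bone=c2, c3_intraosseous=c3, slice_diagnostics=diags
    )
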