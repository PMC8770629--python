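"""NIfTI I/O, axial slice extraction and the slice preprocessing chain.

Coordinate conventions (documented once, here):

* ``Volume3D.voxels`` is indexed ``[row, col, slice]``; slice index 0 is the
  inferior-most axial slice.
* ``Slice2D.pixels`` is indexed ``[row, col]`` with row 0 at the top of the
  image.  Display follows the radiological convention by default: the
  patient's left appears on the right of the image.  Left/right assignment
  for bilateral structures is handled in :mod:`temporalis.quantify` relative
  to the image midline, with the patient-side interpretation configurable
  there.

Preprocessing follows the usual MRI chain for 2D segmentation: bias-field
correction, Z-score intensity normalisation, resampling to isotropic 1 mm
pixels, and center crop/pad to a fixed 256 px grid.  Bias correction here
divides out a least-squares exponentiated-polynomial surface fitted to the
log-intensities; it accepts pre-corrected input (``bias_degree=0`` disables
it), so images corrected upstream by a dedicated tool such as N4 pass
through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class Volume3D:
    """A 3D intensity grid with physical voxel spacing in mm."""

    voxels: np.ndarray  # [row, col, slice]
    spacing: tuple[float, float, float]  # (row, col, slice) mm

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.voxels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]


@dataclass
class Slice2D:
    """A 2D intensity image with physical pixel spacing — the unit of segmentation."""

    pixels: np.ndarray  # [row, col]
    spacing: tuple[float, float]  # (row, col) mm
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D array, got shape {self.pixels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("slice contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Per-pixel muscle labels {0, 1} aligned to a Slice2D."""

    labels: np.ndarray  # [row, col], values in {0, 1}
    spacing: tuple[float, float]  # (row, col) mm

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2D array, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, got {uniq}")
        self.labels = arr.astype(np.uint8)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.spacing[0] * self.spacing[1])


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_volume(path, volume: Volume3D) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), str(path))


def load_volume(path, spacing_override: tuple[float, float, float] | None = None) -> Volume3D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    spacing = spacing_override or tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(voxels=data, spacing=spacing)


def save_slice(path, sl: Slice2D) -> None:
    affine = np.diag([sl.spacing[0], sl.spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(sl.pixels[:, :, None].astype(np.float32), affine), str(path))


def load_slice(path, spacing_override: tuple[float, float] | None = None) -> Slice2D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError(f"{path}: expected a single-slice image, got shape {data.shape}")
        data = data[:, :, 0]
    spacing = spacing_override or tuple(float(z) for z in img.header.get_zooms()[:2])
    return Slice2D(pixels=data, spacing=spacing, provenance=str(path))


def save_mask(path, mask: BinaryMask) -> None:
    affine = np.diag([mask.spacing[0], mask.spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(mask.labels[:, :, None].astype(np.uint8), affine), str(path))


def load_mask(path, spacing_override: tuple[float, float] | None = None) -> BinaryMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        data = data[:, :, 0]
    spacing = spacing_override or tuple(float(z) for z in img.header.get_zooms()[:2])
    return BinaryMask(labels=(data > 0.5).astype(np.uint8), spacing=spacing)


def save_mask_png(path, mask: BinaryMask) -> None:
    """8-bit PNG export (255 = muscle). Spacing is not stored in PNG."""
    import imageio.v3 as iio

    iio.imwrite(str(path), (mask.labels * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# Slice extraction


def extract_axial_slice(volume: Volume3D, fraction: float) -> Slice2D:
    """Extract the axial slice at a craniocaudal fraction of the volume.

    ``fraction`` is the relative craniocaudal level: 0 selects the
    inferior-most slice, 1 the superior-most; the slice index is
    ``round(fraction * (n_slices - 1))``.  In-plane spacing carries over.
    """
    if volume.n_slices == 0:
        raise ValueError("cannot extract a slice from an empty volume")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    idx = int(round(fraction * (volume.n_slices - 1)))
    return Slice2D(
        pixels=volume.voxels[:, :, idx].copy(),
        spacing=(volume.spacing[0], volume.spacing[1]),
        provenance=f"slice {idx}/{volume.n_slices - 1}",
    )


# ---------------------------------------------------------------------------
# Bias-field correction


def _poly_design(shape: tuple[int, int], degree: int) -> np.ndarray:
    """Design matrix of 2D monomials x^i y^j (i + j <= degree) on [-1, 1]^2."""
    ny, nx = shape
    y = np.linspace(-1.0, 1.0, ny)
    x = np.linspace(-1.0, 1.0, nx)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    cols = [
        (xx**i * yy**j).ravel()
        for total in range(degree + 1)
        for i in range(total + 1)
        for j in [total - i]
    ]
    return np.stack(cols, axis=1)


def correct_bias_field(sl: Slice2D, degree: int) -> Slice2D:
    """Divide out a smooth multiplicative bias surface.

    The field is estimated on the dominant-tissue intensity band: among
    non-background pixels, those within a multiplicative window
    [0.6, 1.4] of the median intensity (mostly one tissue class, so their
    log-intensity variation is bias rather than anatomy, in the spirit of
    white-stripe-style tissue-band normalisation).  A degree-``degree``
    polynomial is fitted
    to those log-intensities by least squares and the whole image is
    divided by the exponentiated fit, re-centred to unit geometric mean
    over the fitted pixels (the global scale is arbitrary and removed by
    Z-scoring anyway).  Fitting on a band rather than on every pixel keeps
    genuine anatomical contrast — e.g. a bright skull rim, itself a smooth
    radial pattern — out of the estimated field.  ``degree=0`` is the
    identity, so images already corrected upstream pass through unchanged.
    """
    if degree < 0:
        raise ValueError("bias degree must be >= 0")
    if degree == 0:
        return sl
    px = sl.pixels
    pos = px > max(px.max(), 0) * 1e-3
    if pos.sum() < 16:
        raise ValueError("too few positive pixels to fit a bias surface")
    med = np.median(px[pos])
    band = pos & (px >= 0.6 * med) & (px <= 1.4 * med)
    if band.sum() < 16:
        band = pos
    design = _poly_design(px.shape, degree)
    logi = np.log(px[band])
    coef, *_ = np.linalg.lstsq(design[band.ravel()], logi, rcond=None)
    surface = (design @ coef).reshape(px.shape)
    surface -= surface[band].mean()
    corrected = px / np.exp(surface)
    return Slice2D(pixels=corrected, spacing=sl.spacing, provenance=sl.provenance)


# ---------------------------------------------------------------------------
# Preprocessing chain


def zscore(sl: Slice2D) -> Slice2D:
    sd = sl.pixels.std()
    if sd == 0:
        raise ValueError(f"cannot Z-score a constant image (provenance: {sl.provenance!r})")
    return Slice2D(
        pixels=(sl.pixels - sl.pixels.mean()) / sd,
        spacing=sl.spacing,
        provenance=sl.provenance,
    )


def _resample(arr: np.ndarray, spacing, target_spacing: float, order: int) -> np.ndarray:
    factors = (spacing[0] / target_spacing, spacing[1] / target_spacing)
    if factors == (1.0, 1.0):
        return arr
    return ndimage.zoom(arr, factors, order=order, mode="nearest", grid_mode=True)


def _crop_or_pad(arr: np.ndarray, size: int, fill: float = 0.0) -> np.ndarray:
    out = np.full((size, size), fill, dtype=arr.dtype)
    ny, nx = arr.shape
    # source / destination windows for a centred placement
    sy0 = max((ny - size) // 2, 0)
    sx0 = max((nx - size) // 2, 0)
    dy0 = max((size - ny) // 2, 0)
    dx0 = max((size - nx) // 2, 0)
    h = min(ny, size)
    w = min(nx, size)
    out[dy0 : dy0 + h, dx0 : dx0 + w] = arr[sy0 : sy0 + h, sx0 : sx0 + w]
    return out


def preprocess_slice(
    sl: Slice2D,
    bias_degree: int = 2,
    target_spacing_mm: float = 1.0,
    target_size_px: int = 256,
) -> Slice2D:
    """Full preprocessing chain: bias correction → Z-score → resample → crop/pad.

    The output grid is ``target_size_px²`` at isotropic ``target_spacing_mm``.
    Mean/SD are exactly 0/1 after the Z-score step; linear resampling and
    zero-padding perturb those moments slightly, which is expected.
    """
    corrected = correct_bias_field(sl, bias_degree)
    normed = zscore(corrected)
    res = _resample(normed.pixels, normed.spacing, target_spacing_mm, order=1)
    out = _crop_or_pad(res, target_size_px)
    return Slice2D(
        pixels=out,
        spacing=(target_spacing_mm, target_spacing_mm),
        provenance=sl.provenance,
    )


def preprocess_mask(
    mask: BinaryMask,
    target_spacing_mm: float = 1.0,
    target_size_px: int = 256,
) -> BinaryMask:
    """Geometric part of the chain for masks: nearest-neighbour, stays binary."""
    res = _resample(mask.labels.astype(np.float32), mask.spacing, target_spacing_mm, order=0)
    out = _crop_or_pad(res, target_size_px)
    return BinaryMask(labels=(out > 0.5).astype(np.uint8), spacing=(target_spacing_mm, target_spacing_mm))
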