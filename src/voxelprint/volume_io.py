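"""Loading, windowing and masking of volumetric scalar images.

Axis convention
---------------
Volumes are stored as ``voxels[row, column, slice]``: axis 0 runs along image
rows (physical y), axis 1 along image columns (physical x), axis 2 along the
slice direction (physical z, increasing with physical position).  ``spacing``
is always the physical pitch triple ``(dx, dy, dz)`` in millimetres, i.e.
``dx`` is the column pitch (axis 1), ``dy`` the row pitch (axis 0) and ``dz``
the inter-slice distance (axis 2).  One fixed, documented convention prevents
silent axis flips; no patient-orientation handling is attempted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import numpy as np

from .errors import DomainError, GeometryError, ParameterError, ReadError

__all__ = [
    "ImageVolume",
    "Mask",
    "WindowLevel",
    "read_volume",
    "write_volume",
    "read_mask",
    "apply_window_level",
    "compute_bounds",
    "crop_to_mask",
]

#: Relative spread of inter-slice distances accepted before a series is
#: rejected as non-uniform.  Real scanner series jitter slightly; the mean
#: distance is used as dz.
SLICE_SPACING_RTOL = 1e-3


@dataclass
class ImageVolume:
    """A 3D scalar field with physical spacing (scanner intensity units)."""

    voxels: np.ndarray
    spacing: Tuple[float, float, float]  # (dx, dy, dz) mm
    #: physical (x, y, z) position of the CENTRE of voxel (0, 0, 0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "row-column-slice"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise GeometryError(
                f"volume must be 3D with positive dimensions, got shape {self.voxels.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise DomainError("volume contains non-finite intensities")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def extent_mm(self) -> Tuple[float, float, float]:
        """Physical extent (x, y, z) treating voxels as cells."""
        nr, nc, ns = self.voxels.shape
        dx, dy, dz = self.spacing
        return (nc * dx, nr * dy, ns * dz)


@dataclass
class Mask:
    """Boolean voxel mask congruent with its :class:`ImageVolume`."""

    voxels: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise GeometryError(f"mask must be 3D, got shape {self.voxels.shape}")

    @property
    def shape(self):
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())

    def check_congruent(self, vol: ImageVolume) -> None:
        if self.voxels.shape != vol.voxels.shape:
            raise GeometryError(
                f"mask shape {self.voxels.shape} != volume shape {vol.voxels.shape}"
            )


@dataclass(frozen=True)
class WindowLevel:
    """Linear display mapping: the interval center ± width/2 → [0, 1]."""

    center: float
    width: float

    def __post_init__(self):
        if not self.width > 0:
            raise ParameterError(f"window width must be > 0, got {self.width}")


# ---------------------------------------------------------------------------
# reading / writing


def _read_dicom_series(path: Path) -> ImageVolume:
    import pydicom
    from pydicom.errors import InvalidDicomError

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix != ".png"
                   and p.name != "manifest.json")
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except (InvalidDicomError, OSError) as exc:
            raise ReadError(f"cannot read DICOM file {f.name}: {exc}") from exc
        datasets.append((f, ds))
    if len(datasets) < 2:
        raise ReadError(
            f"directory {path} holds {len(datasets)} DICOM slice(s); a series needs >= 2"
        )

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for _, ds in datasets}
    if len(uids) > 1:
        raise ReadError(f"directory {path} mixes {len(uids)} DICOM series")

    def z_of(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=lambda fd: z_of(fd[1]))

    shapes = {(int(ds.Rows), int(ds.Columns)) for _, ds in datasets}
    if len(shapes) > 1:
        raise GeometryError(f"in-plane dimensions differ across slices: {sorted(shapes)}")
    pixel_spacings = {tuple(float(v) for v in ds.PixelSpacing) for _, ds in datasets}
    if len(pixel_spacings) > 1:
        raise GeometryError(f"pixel spacing differs across slices: {sorted(pixel_spacings)}")

    zs = np.array([z_of(ds) for _, ds in datasets], dtype=float)
    steps = np.diff(zs)
    if np.any(steps <= 0):
        raise GeometryError("slice positions are not strictly increasing")
    spread = (steps.max() - steps.min()) / steps.mean()
    if spread > SLICE_SPACING_RTOL:
        raise GeometryError(
            f"non-uniform inter-slice spacing: steps range "
            f"{steps.min():.6g}-{steps.max():.6g} mm (relative spread {spread:.3g})"
        )
    dz = float(steps.mean())

    # PixelSpacing is (row pitch, column pitch) = (dy, dx)
    dy, dx = pixel_spacings.pop()

    slices = []
    for f, ds in datasets:
        try:
            arr = ds.pixel_array.astype(np.float64)
        except Exception as exc:  # corrupt pixel data
            raise ReadError(f"cannot decode pixel data in {f.name}: {exc}") from exc
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    voxels = np.stack(slices, axis=2)

    first = datasets[0][1]
    ipp = getattr(first, "ImagePositionPatient", (0.0, 0.0, zs[0]))
    origin = (float(ipp[0]), float(ipp[1]), float(ipp[2]))
    return ImageVolume(voxels=voxels, spacing=(dx, dy, dz), origin=origin)


def _read_nifti(path: Path) -> ImageVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ReadError(f"cannot read volume file {path.name}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise GeometryError(f"{path.name}: expected a 3D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    # data axes are (row, column, slice); zooms follow the data axes
    dy, dx, dz = (float(z) for z in zooms)
    return ImageVolume(voxels=data, spacing=(dx, dy, dz))


def read_volume(path: os.PathLike | str, format: str | None = None) -> ImageVolume:
    """Load a scalar volume from a DICOM series directory or a NIfTI file.

    ``format`` is ``"dicom_series"`` or ``"single_file"``; when omitted it is
    inferred from whether ``path`` is a directory.
    """
    path = Path(path)
    if not path.exists():
        raise ReadError(f"path does not exist: {path}")
    if format is None:
        format = "dicom_series" if path.is_dir() else "single_file"
    if format == "dicom_series":
        if not path.is_dir():
            raise ReadError(f"{path} is not a directory of DICOM slices")
        return _read_dicom_series(path)
    if format == "single_file":
        return _read_nifti(path)
    raise ParameterError(f"unknown format {format!r}")


def write_volume(vol: ImageVolume, path: os.PathLike | str) -> None:
    """Write an intermediate volume as NIfTI (lossless for float data)."""
    import nibabel as nib

    dx, dy, dz = vol.spacing
    affine = np.diag([dy, dx, dz, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float64), affine), str(path))


def read_mask(path: os.PathLike | str) -> Mask:
    """Load a mask from a NIfTI file or a directory of PNG slices.

    Any nonzero voxel/pixel is treated as true.  PNG stacks are read in
    lexicographic order along the slice axis.
    """
    path = Path(path)
    if not path.exists():
        raise ReadError(f"mask path does not exist: {path}")
    if path.is_dir():
        from PIL import Image

        pngs = sorted(path.glob("*.png"))
        if not pngs:
            raise ReadError(f"no PNG slices in mask directory {path}")
        planes = [np.array(Image.open(p).convert("L")) > 0 for p in pngs]
        shapes = {pl.shape for pl in planes}
        if len(shapes) > 1:
            raise GeometryError(f"mask PNG slices have mixed shapes: {sorted(shapes)}")
        return Mask(np.stack(planes, axis=2))
    vol = _read_nifti(path)
    return Mask(vol.voxels != 0)


# ---------------------------------------------------------------------------
# intensity operations


def apply_window_level(vol: ImageVolume, wl: WindowLevel) -> ImageVolume:
    """Rescale intensities so the window maps onto [0, 1], clamped outside.

    ``center - width/2`` maps to 0, ``center + width/2`` to 1; geometry is
    unchanged.  The mapping is monotone non-decreasing and idempotent for the
    full-range window of an already-normalised volume.
    """
    lo = wl.center - wl.width / 2.0
    out = np.clip((vol.voxels - lo) / wl.width, 0.0, 1.0)
    return ImageVolume(voxels=out, spacing=vol.spacing, origin=vol.origin,
                       axis_order=vol.axis_order)


def compute_bounds(vol: ImageVolume, mask: Mask) -> Tuple[float, float]:
    """Minimum and maximum intensity over the masked voxels only."""
    mask.check_congruent(vol)
    if mask.count() == 0:
        raise DomainError("mask selects no voxels; bounds are undefined")
    vals = vol.voxels[mask.voxels]
    return float(vals.min()), float(vals.max())


def crop_to_mask(vol: ImageVolume, mask: Mask, margin: int = 0):
    """Axis-aligned bounding-box crop of volume and mask around the mask.

    Replaces interactive cropping: the box is the tight bounding box of the
    true voxels, optionally grown by ``margin`` voxels per side.
    """
    mask.check_congruent(vol)
    if mask.count() == 0:
        raise DomainError("cannot crop to an empty mask")
    idx = np.nonzero(mask.voxels)
    slices = tuple(
        slice(max(int(i.min()) - margin, 0), min(int(i.max()) + 1 + margin, n))
        for i, n in zip(idx, mask.voxels.shape)
    )
    sub = vol.voxels[slices]
    dx, dy, dz = vol.spacing
    ox, oy, oz = vol.origin
    new_origin = (ox + slices[1].start * dx, oy + slices[0].start * dy,
                  oz + slices[2].start * dz)
    return (
        ImageVolume(voxels=sub, spacing=vol.spacing, origin=new_origin,
                    axis_order=vol.axis_order),
        Mask(mask.voxels[slices]),
    )
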