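"""Synthetic radiodensity phantoms with analytic ground truth.

Soft-tissue scans present smooth intensity gradients spanning hundreds to
thousands of distinct values on anisotropic grids (in-plane pitch around
1 mm, slice thickness 1–5 mm).  The phantoms emulate those features with
nested ellipsoids carrying base intensities, an optional radial or axial
gradient, and additive Gaussian noise, so every pipeline stage can be tested
against exact analytic region volumes (4/3·π·abc) and a known noise-free
intensity function — no patient data required.

Coordinates: voxel (i, j, k) = (row, column, slice) has its centre at
``((j+0.5)·dx, (i+0.5)·dy, (k+0.5)·dz)`` so that voxel cells tile the
physical extent exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Sequence, Tuple

import numpy as np

from .errors import GeometryWarning, OutputError, ParameterError
from .volume_io import ImageVolume, Mask

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "write_phantom_dicom",
    "gradient_sphere_spec",
    "nested_ellipsoids_spec",
    "two_blobs_spec",
    "PRESETS",
]


@dataclass(frozen=True)
class Ellipsoid:
    """One phantom layer: centre (mm, x/y/z), semi-axes (mm), base intensity."""

    center_mm: Tuple[float, float, float]
    semi_axes_mm: Tuple[float, float, float]
    base_intensity: float

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ParameterError(f"semi-axes must be > 0, got {self.semi_axes_mm}")

    @property
    def analytic_volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass
class PhantomSpec:
    """Recipe for one synthetic volume.

    Defaults emulate clinical anisotropy (0.8 × 0.8 mm in-plane, 3 mm
    slices).  ``gradient`` adds a smooth intensity ramp of ``gradient_span``
    units: "radial" ramps with normalised radius inside the first (outermost)
    ellipsoid, "axial" ramps along z across the volume.  Later ellipsoids in
    ``layers`` override earlier ones where they overlap (nesting).
    """

    shape: Tuple[int, int, int]  # (rows, cols, slices)
    spacing: Tuple[float, float, float] = (0.8, 0.8, 3.0)  # (dx, dy, dz) mm
    layers: List[Ellipsoid] = field(default_factory=list)
    gradient: str = "none"  # none | radial | axial
    gradient_span: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.gradient not in ("none", "radial", "axial"):
            raise ParameterError(f"unknown gradient {self.gradient!r}")
        if self.gradient_span < 0:
            raise ParameterError("gradient span must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise SD must be >= 0")
        if not self.layers:
            raise ParameterError("phantom needs at least one ellipsoid layer")


@dataclass
class GroundTruth:
    """Analytic reference values for a generated phantom."""

    analytic_volumes_mm3: List[float]  # one per ellipsoid layer
    intensity_fn: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    clipped: List[bool]  # per layer: True if the ellipsoid exceeds the grid


def _centres(shape, spacing):
    nr, nc, ns = shape
    dx, dy, dz = spacing
    y = (np.arange(nr) + 0.5) * dy
    x = (np.arange(nc) + 0.5) * dx
    z = (np.arange(ns) + 0.5) * dz
    return np.meshgrid(y, x, z, indexing="ij")


def generate_phantom(spec: PhantomSpec) -> Tuple[ImageVolume, Mask, GroundTruth]:
    """Deterministic phantom for a fixed seed: volume, mask and ground truth.

    The mask is the union of the ellipsoids; intensity = innermost layer's
    base + gradient + N(0, noise_sd²) noise.  The returned ground truth
    carries exact ellipsoid volumes and the noise-free intensity function.
    """
    yy, xx, zz = _centres(spec.shape, spec.spacing)
    extent = (spec.shape[1] * spec.spacing[0],
              spec.shape[0] * spec.spacing[1],
              spec.shape[2] * spec.spacing[2])

    clipped = []
    for e in spec.layers:
        cx, cy, cz = e.center_mm
        ax, ay, az = e.semi_axes_mm
        out = (cx - ax < 0 or cx + ax > extent[0]
               or cy - ay < 0 or cy + ay > extent[1]
               or cz - az < 0 or cz + az > extent[2])
        clipped.append(out)
        if out:
            warnings.warn(
                f"ellipsoid at {e.center_mm} with semi-axes {e.semi_axes_mm} "
                f"exceeds the volume extent {extent}; its analytic volume is "
                "larger than its voxelised volume", GeometryWarning)

    def noise_free(x, y, z):
        vals = np.zeros(np.broadcast(x, y, z).shape, dtype=np.float64)
        inside_any = np.zeros_like(vals, dtype=bool)
        for e in spec.layers:  # later layers override where nested
            cx, cy, cz = e.center_mm
            ax, ay, az = e.semi_axes_mm
            inside = (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
                      + ((z - cz) / az) ** 2) <= 1.0
            vals = np.where(inside, e.base_intensity, vals)
            inside_any |= inside
        if spec.gradient != "none" and spec.gradient_span > 0:
            if spec.gradient == "radial":
                e0 = spec.layers[0]
                cx, cy, cz = e0.center_mm
                ax, ay, az = e0.semi_axes_mm
                rho = np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
                              + ((z - cz) / az) ** 2)
                vals = vals + inside_any * spec.gradient_span * np.clip(rho, 0, 1)
            else:  # axial
                frac = z / extent[2]
                vals = vals + inside_any * spec.gradient_span * np.clip(frac, 0, 1)
        return vals

    mask_arr = np.zeros(spec.shape, dtype=bool)
    for e in spec.layers:
        cx, cy, cz = e.center_mm
        ax, ay, az = e.semi_axes_mm
        mask_arr |= (((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
                     + ((zz - cz) / az) ** 2) <= 1.0

    voxels = noise_free(xx, yy, zz)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        voxels = voxels + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    gt = GroundTruth(
        analytic_volumes_mm3=[e.analytic_volume_mm3 for e in spec.layers],
        intensity_fn=noise_free,
        clipped=clipped,
    )
    origin = (0.5 * spec.spacing[0], 0.5 * spec.spacing[1], 0.5 * spec.spacing[2])
    return (ImageVolume(voxels=voxels, spacing=spec.spacing, origin=origin),
            Mask(mask_arr), gt)


# ---------------------------------------------------------------------------
# presets


def gradient_sphere_spec(shape=(64, 64, 64), spacing=(0.15, 0.15, 0.15),
                         seed: int = 0, noise_sd: float = 50.0) -> PhantomSpec:
    """A sphere with a radial intensity ramp — the smooth soft-tissue analogue.

    The intensity spans 1000 scanner units over the radius (a soft-tissue-like
    wide range of distinct values); the default noise SD of 50 corresponds to
    an SNR of ~20 relative to that range, in line with clinical MR
    acquisitions.  The sphere fills ~85% of the grid.
    """
    extent = np.array([shape[1] * spacing[0], shape[0] * spacing[1],
                       shape[2] * spacing[2]])
    centre = tuple(extent / 2)
    r = 0.425 * float(extent.min())
    return PhantomSpec(
        shape=shape, spacing=spacing,
        layers=[Ellipsoid(centre, (r, r, r), base_intensity=100.0)],
        gradient="radial", gradient_span=1000.0, noise_sd=noise_sd, seed=seed,
    )


def nested_ellipsoids_spec(shape=(64, 64, 32), spacing=(0.8, 0.8, 1.0),
                           seed: int = 0, noise_sd: float = 10.0) -> PhantomSpec:
    """Three nested ellipsoids with distinct base intensities (organ-in-organ)."""
    extent = np.array([shape[1] * spacing[0], shape[0] * spacing[1],
                       shape[2] * spacing[2]])
    c = tuple(extent / 2)
    a = 0.45 * extent
    return PhantomSpec(
        shape=shape, spacing=spacing,
        layers=[
            Ellipsoid(c, tuple(a), base_intensity=200.0),
            Ellipsoid(c, tuple(0.6 * a), base_intensity=600.0),
            Ellipsoid(c, tuple(0.3 * a), base_intensity=1000.0),
        ],
        gradient="none", noise_sd=noise_sd, seed=seed,
    )


def two_blobs_spec(shape=(48, 96, 48), spacing=(0.5, 0.5, 0.5),
                   seed: int = 0, noise_sd: float = 0.0) -> PhantomSpec:
    """Two disjoint spheres of equal intensity — yields disconnected shells."""
    extent = np.array([shape[1] * spacing[0], shape[0] * spacing[1],
                       shape[2] * spacing[2]])
    r = 0.18 * float(extent[0])
    cy, cz = extent[1] / 2, extent[2] / 2
    return PhantomSpec(
        shape=shape, spacing=spacing,
        layers=[
            Ellipsoid((0.25 * extent[0], cy, cz), (r, r, r), base_intensity=500.0),
            Ellipsoid((0.75 * extent[0], cy, cz), (r, r, r), base_intensity=500.0),
        ],
        gradient="none", noise_sd=noise_sd, seed=seed,
    )


PRESETS = {
    "gradient-sphere": gradient_sphere_spec,
    "nested-ellipsoids": nested_ellipsoids_spec,
    "two-blobs": two_blobs_spec,
}


# ---------------------------------------------------------------------------
# DICOM export


def write_phantom_dicom(vol: ImageVolume, mask: Mask, dir) -> dict:
    """Write a minimal single-series DICOM slice stack plus a PNG mask stack.

    Intensities are stored as signed 16-bit integers with a fixed rescale
    slope/intercept recorded in the per-slice metadata (mirroring real CT/MR
    storage); ``read_volume`` round-trips geometry exactly and intensities to
    within the integer quantisation step.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid
    from PIL import Image

    mask.check_congruent(vol)
    dir = Path(dir)
    try:
        dir.mkdir(parents=True, exist_ok=True)
        (dir / "mask").mkdir(exist_ok=True)
    except OSError as exc:
        raise OutputError(f"cannot create phantom output directory {dir}: {exc}") from exc

    data = np.asarray(vol.voxels, dtype=np.float64)
    vmin, vmax = float(data.min()), float(data.max())
    span = max(vmax - vmin, 1e-12)
    slope = span / 30000.0
    intercept = vmin
    stored = np.round((data - intercept) / slope).astype(np.int16)

    dx, dy, dz = vol.spacing
    series_uid = generate_uid(entropy_srcs=["voxelprint-phantom-series"])
    study_uid = generate_uid(entropy_srcs=["voxelprint-phantom-study"])
    frame_uid = generate_uid(entropy_srcs=["voxelprint-phantom-frame"])
    files = []
    n_slices = vol.shape[2]
    for k in range(n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[f"voxelprint-phantom-slice-{k}"])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.PatientName = "SYNTHETIC^PHANTOM"
        ds.PatientID = "VOXELPRINT"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, float(k) * dz]
        ds.SliceThickness = dz
        ds.PixelSpacing = [dy, dx]  # (row pitch, column pitch)
        ds.Rows, ds.Columns = vol.shape[0], vol.shape[1]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.PixelData = np.ascontiguousarray(stored[:, :, k]).tobytes()
        name = f"slice_{k:04d}.dcm"
        ds.save_as(dir / name, enforce_file_format=True)
        files.append(name)

    mask_files = []
    for k in range(n_slices):
        name = f"mask_{k:04d}.png"
        Image.fromarray((mask.voxels[:, :, k] * 255).astype(np.uint8)).save(
            dir / "mask" / name)
        mask_files.append(name)

    manifest = {
        "kind": "phantom_dicom",
        "n_slices": n_slices,
        "spacing_mm": [dx, dy, dz],
        "rescale_slope": slope,
        "rescale_intercept": intercept,
        "dicom_files": files,
        "mask_files": mask_files,
    }
    (dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
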