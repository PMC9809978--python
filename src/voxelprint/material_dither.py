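"""Error-diffusion halftoning of color slices onto a printable material palette.

Each full-color slice is converted into a per-pixel material assignment over
K printable resins (K ≤ 6 for the target material-jetting printer).  The
quantiser picks the palette entry nearest the error-adjusted pixel color in
linear-RGB Euclidean distance; the residual is diffused to unprocessed
neighbours with the classic Floyd–Steinberg weights (7/16 ahead, 3/16
behind-below, 5/16 below, 1/16 ahead-below) in serpentine row order.
Because materials are mixed at the droplet level, local mean color is
preserved: a uniform region whose target lies in the palette's convex hull
dithers to material fractions reproducing that target.

All images handed to :func:`dither_slice` carry channels in linear-light RGB
plus alpha; alpha-0 pixels are "no material", receive no assignment, and
neither emit nor absorb diffused error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np
from numba import njit

from .errors import EmptyRegionError, GeometryError, OutputError, ParameterError
from .partition_lut import srgb_to_linear

__all__ = [
    "Material",
    "MaterialPalette",
    "MaterialSliceStack",
    "dither_slice",
    "material_fractions",
    "write_material_stack",
    "read_material_stack",
    "default_vero_palette",
    "NO_MATERIAL",
]

#: Sentinel index for pixels carrying no material (outside the anatomy mask).
NO_MATERIAL = -1

#: The target printer head carries at most six resins.
MAX_MATERIALS = 6


@dataclass(frozen=True)
class Material:
    """One printable resin: display color (sRGB RGBA in [0,1]) and clear flag."""

    name: str
    rgba: tuple
    clear: bool = False


@dataclass
class MaterialPalette:
    """An ordered set of 2–6 printable materials with pairwise distinct colors."""

    materials: List[Material]

    def __post_init__(self):
        k = len(self.materials)
        if k < 2:
            raise ParameterError(f"palette needs at least 2 materials, got {k}")
        if k > MAX_MATERIALS:
            raise ParameterError(
                f"palette has {k} materials; the printer is limited to {MAX_MATERIALS}")
        cols = [tuple(m.rgba[:3]) for m in self.materials]
        if len(set(cols)) != k:
            raise ParameterError("palette colors must be pairwise distinct")

    def __len__(self):
        return len(self.materials)

    @property
    def names(self) -> List[str]:
        return [m.name for m in self.materials]

    @property
    def srgb(self) -> np.ndarray:
        """(K, 4) sRGB RGBA array."""
        return np.array([m.rgba for m in self.materials], dtype=np.float64)

    @property
    def linear_rgb(self) -> np.ndarray:
        """(K, 3) linear-light RGB coordinates used by the quantiser."""
        return srgb_to_linear(self.srgb[:, :3])

    def to_config(self) -> list:
        return [
            {"name": m.name, "rgba": list(m.rgba), "clear": m.clear}
            for m in self.materials
        ]

    @classmethod
    def from_config(cls, entries: Sequence[dict]) -> "MaterialPalette":
        mats = []
        for e in entries:
            rgba = e["rgba"]
            if len(rgba) == 3:
                rgba = list(rgba) + [1.0]
            mats.append(Material(name=e["name"], rgba=tuple(float(v) for v in rgba),
                                 clear=bool(e.get("clear", False))))
        return cls(mats)


def default_vero_palette() -> MaterialPalette:
    """The shipped six-material palette: clear, white, black, yellow, cyan, magenta.

    Colors are nominal sRGB stand-ins for the vendor resins (the true
    measured colors are proprietary) and can be overridden per run.
    """
    return MaterialPalette([
        Material("clear", (0.88, 0.92, 0.95, 1.0), clear=True),
        Material("white", (1.0, 1.0, 1.0, 1.0)),
        Material("black", (0.0, 0.0, 0.0, 1.0)),
        Material("yellow", (1.0, 1.0, 0.0, 1.0)),
        Material("cyan", (0.0, 1.0, 1.0, 1.0)),
        Material("magenta", (1.0, 0.0, 1.0, 1.0)),
    ])


@dataclass
class MaterialSliceStack:
    """Per-layer, per-pixel material indices (the dithered print description)."""

    slices: List[np.ndarray]  # int16 rasters, NO_MATERIAL or [0, K)
    palette: MaterialPalette
    pitch_x_mm: float
    pitch_y_mm: float
    layer_mm: float
    z_positions_mm: np.ndarray

    def __post_init__(self):
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise GeometryError(f"material slices have mixed shapes: {sorted(shapes)}")
        k = len(self.palette)
        for s in self.slices:
            if s.max(initial=NO_MATERIAL) >= k:
                raise ParameterError("material index exceeds palette size")

    @property
    def n_layers(self) -> int:
        return len(self.slices)

    def as_array(self) -> np.ndarray:
        """(rows, cols, layers) integer array."""
        return np.stack(self.slices, axis=2)


# ---------------------------------------------------------------------------
# the error-diffusion kernel


@njit(cache=True)
def _fs_kernel(rgb, alive, pal, out):  # pragma: no cover - exercised via wrapper
    h, w = out.shape
    k = pal.shape[0]
    err = np.zeros((h, w, 3))
    for y in range(h):
        ltr = (y % 2) == 0
        step = 1 if ltr else -1
        for t in range(w):
            x = t if ltr else w - 1 - t
            if not alive[y, x]:
                continue
            v = np.empty(3)
            for c in range(3):
                e = err[y, x, c]
                if e > 1.0:
                    e = 1.0
                elif e < -1.0:
                    e = -1.0
                v[c] = rgb[y, x, c] + e
            best = 0
            bestd = 1e300
            for j in range(k):
                d = 0.0
                for c in range(3):
                    dc = v[c] - pal[j, c]
                    d += dc * dc
                if d < bestd:  # strict: ties keep the lowest index
                    bestd = d
                    best = j
            out[y, x] = best
            q0 = v[0] - pal[best, 0]
            q1 = v[1] - pal[best, 1]
            q2 = v[2] - pal[best, 2]
            xa = x + step  # ahead of the scan
            xb = x - step  # behind the scan
            if 0 <= xa < w and alive[y, xa]:
                err[y, xa, 0] += q0 * 0.4375
                err[y, xa, 1] += q1 * 0.4375
                err[y, xa, 2] += q2 * 0.4375
            if y + 1 < h:
                if 0 <= xb < w and alive[y + 1, xb]:
                    err[y + 1, xb, 0] += q0 * 0.1875
                    err[y + 1, xb, 1] += q1 * 0.1875
                    err[y + 1, xb, 2] += q2 * 0.1875
                if alive[y + 1, x]:
                    err[y + 1, x, 0] += q0 * 0.3125
                    err[y + 1, x, 1] += q1 * 0.3125
                    err[y + 1, x, 2] += q2 * 0.3125
                if 0 <= xa < w and alive[y + 1, xa]:
                    err[y + 1, xa, 0] += q0 * 0.0625
                    err[y + 1, xa, 1] += q1 * 0.0625
                    err[y + 1, xa, 2] += q2 * 0.0625


def dither_slice(img: np.ndarray, palette: MaterialPalette) -> np.ndarray:
    """Dither one RGBA raster (linear-RGB channels in [0,1]) onto the palette.

    Returns an int16 raster of palette indices; alpha-0 pixels get
    :data:`NO_MATERIAL`.  Deterministic: identical input, palette and scan
    order give bit-identical output.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 4:
        raise ParameterError(f"expected an (H, W, 4) RGBA raster, got shape {img.shape}")
    if img.min() < 0 or img.max() > 1:
        raise ParameterError("image channels must lie in [0, 1]")
    alive = img[:, :, 3] > 0
    out = np.full(img.shape[:2], NO_MATERIAL, dtype=np.int16)
    rgb = np.ascontiguousarray(img[:, :, :3])
    pal = np.ascontiguousarray(palette.linear_rgb)
    _fs_kernel(rgb, alive, pal, out)
    return out


def material_fractions(stack: MaterialSliceStack, region: np.ndarray) -> np.ndarray:
    """Per-material pixel fractions over the non-sentinel pixels of a region.

    ``region`` is a boolean array congruent with ``stack.as_array()``.
    The fractions sum to 1; a region with no material pixels raises
    :class:`EmptyRegionError`.
    """
    arr = stack.as_array()
    region = np.asarray(region, dtype=bool)
    if region.shape != arr.shape:
        raise GeometryError(
            f"region shape {region.shape} != stack shape {arr.shape}")
    vals = arr[region]
    vals = vals[vals != NO_MATERIAL]
    if vals.size == 0:
        raise EmptyRegionError("region contains no material pixels")
    counts = np.bincount(vals, minlength=len(stack.palette))
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# serialization


def _write_manifest(dir: Path, payload: dict) -> None:
    (dir / "manifest.json").write_text(json.dumps(payload, indent=2))


def write_material_stack(stack: MaterialSliceStack, dir, mode: str = "indexed_png",
                         compress_level: int = 0) -> dict:
    """Write the material stack as PNGs plus a JSON manifest.

    ``indexed_png``: one palette-indexed PNG per layer, sentinel stored as
    palette index K.  ``per_material_bitmaps``: K 1-bit PNGs per layer, one
    per material channel, pixel set where that material is deposited
    (droplet-deposition semantics).  PNGs default to stored (uncompressed)
    deflate so the print-file size is governed by raster dimensions, not by
    content; raise ``compress_level`` to shrink archives.  Returns the
    manifest dict.
    """
    from PIL import Image

    if mode not in ("indexed_png", "per_material_bitmaps"):
        raise ParameterError(f"unknown mode {mode!r}")
    dir = Path(dir)
    try:
        dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OutputError(f"cannot create output directory {dir}: {exc}") from exc

    k = len(stack.palette)
    files = []
    total = 0
    pal8 = np.clip(np.round(stack.palette.srgb[:, :3] * 255), 0, 255).astype(np.uint8)
    flat = np.zeros(768, dtype=np.uint8)
    flat[: 3 * k] = pal8.ravel()
    # sentinel entry K left black; the manifest records its index
    try:
        for i, s in enumerate(stack.slices):
            if mode == "indexed_png":
                arr = np.where(s == NO_MATERIAL, k, s).astype(np.uint8)
                im = Image.fromarray(arr, mode="P")
                im.putpalette(flat.tolist())
                name = f"layer_{i:04d}.png"
                im.save(dir / name, compress_level=compress_level)
                nbytes = (dir / name).stat().st_size
                files.append({"file": name, "bytes": nbytes})
                total += nbytes
            else:
                for j, mat in enumerate(stack.palette.materials):
                    bit = s == j
                    im = Image.fromarray(bit)
                    name = f"layer_{i:04d}_{mat.name}.png"
                    im.save(dir / name, compress_level=compress_level)
                    nbytes = (dir / name).stat().st_size
                    files.append({"file": name, "bytes": nbytes, "material": mat.name})
                    total += nbytes
    except OSError as exc:
        raise OutputError(f"failed writing material stack under {dir}: {exc}") from exc

    manifest = {
        "kind": "material_stack",
        "mode": mode,
        "palette": stack.palette.to_config(),
        "sentinel_index": k,
        "n_layers": stack.n_layers,
        "pitch_x_mm": stack.pitch_x_mm,
        "pitch_y_mm": stack.pitch_y_mm,
        "layer_mm": stack.layer_mm,
        "z_positions_mm": [float(z) for z in stack.z_positions_mm],
        "files": files,
        "total_bytes": total,
    }
    _write_manifest(dir, manifest)
    return manifest


def read_material_stack(dir) -> MaterialSliceStack:
    """Read back a stack written by :func:`write_material_stack` (either mode)."""
    from PIL import Image

    dir = Path(dir)
    manifest = json.loads((dir / "manifest.json").read_text())
    palette = MaterialPalette.from_config(manifest["palette"])
    k = len(palette)
    n_layers = manifest["n_layers"]
    slices = []
    if manifest["mode"] == "indexed_png":
        for i in range(n_layers):
            arr = np.array(Image.open(dir / f"layer_{i:04d}.png"), dtype=np.int16)
            arr[arr == manifest["sentinel_index"]] = NO_MATERIAL
            slices.append(arr)
    else:
        for i in range(n_layers):
            planes = []
            for mat in palette.materials:
                im = Image.open(dir / f"layer_{i:04d}_{mat.name}.png")
                planes.append(np.array(im, dtype=bool))
            s = np.full(planes[0].shape, NO_MATERIAL, dtype=np.int16)
            for j, p in enumerate(planes):
                s[p] = j
            slices.append(s)
    return MaterialSliceStack(
        slices=slices,
        palette=palette,
        pitch_x_mm=manifest["pitch_x_mm"],
        pitch_y_mm=manifest["pitch_y_mm"],
        layer_mm=manifest["layer_mm"],
        z_positions_mm=np.array(manifest["z_positions_mm"]),
    )
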