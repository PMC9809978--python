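"""Equal-width intensity partitioning and the intensity→color lookup table.

The masked intensity range ``[lo, hi]`` is split into N contiguous divisions
of equal width (half-open intervals, last one closed), and each division is
assigned a target color.  A transfer-function style LUT maps any in-range
intensity to RGBA; out-of-range intensities map to a fully transparent color,
the "no material" signal.  Optional gradient blending linearly interpolates
between neighbouring division colors in a band around each interior edge, in
linear-light RGB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DomainError, ParameterError

__all__ = [
    "Partition",
    "ColorLUT",
    "partition_range",
    "assign_division",
    "lut_color",
    "default_division_colors",
    "save_lut",
    "load_lut",
    "srgb_to_linear",
    "linear_to_srgb",
    "OUT_OF_RANGE",
]

#: Sentinel division index for intensities outside the partition bounds.
OUT_OF_RANGE = -1


# --- color space helpers ----------------------------------------------------

def srgb_to_linear(c):
    """sRGB [0,1] → linear-light RGB (IEC 61966-2-1 piecewise transfer)."""
    c = np.asarray(c, dtype=np.float64)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(c):
    c = np.asarray(c, dtype=np.float64)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * np.clip(c, 0, None) ** (1 / 2.4) - 0.055)


# --- partition ---------------------------------------------------------------

@dataclass(frozen=True)
class Partition:
    """N contiguous, equal-width intensity intervals spanning [lo, hi].

    ``edges`` has N+1 strictly increasing entries; interval i is
    ``[edges[i], edges[i+1])`` except the last, which is closed so hi belongs
    to division N-1.  Together the divisions tile the range with no overlap
    and no numerical gap.
    """

    n_divisions: int
    edges: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=np.float64)
        object.__setattr__(self, "edges", edges)
        if self.n_divisions < 1:
            raise ParameterError(f"need at least one division, got {self.n_divisions}")
        if edges.shape != (self.n_divisions + 1,):
            raise ParameterError(
                f"expected {self.n_divisions + 1} edges, got {edges.shape}")
        if not np.all(np.diff(edges) > 0):
            raise DomainError("partition edges must be strictly increasing")
        widths = np.diff(edges)
        # equal widths up to float representation of the edges themselves:
        # a narrow interval at a large offset cannot do better than a few
        # ulps of the offset
        atol = 8 * np.finfo(np.float64).eps * max(abs(edges[0]), abs(edges[-1]))
        if not np.allclose(widths, widths.mean(), rtol=1e-9, atol=atol):
            raise DomainError("division widths are not equal")

    @property
    def lo(self) -> float:
        return float(self.edges[0])

    @property
    def hi(self) -> float:
        return float(self.edges[-1])

    @property
    def width(self) -> float:
        """Common width of one division."""
        return (self.hi - self.lo) / self.n_divisions


def safe_range(lo: float, hi: float) -> tuple:
    """Widen a degenerate (constant-field) range so one division holds it.

    A constant masked volume has lo == hi; partitioning needs a nonzero
    width, so the upper bound is nudged up by a relative epsilon.  All
    voxels then land in division 0.
    """
    if hi > lo:
        return lo, hi
    pad = max(abs(lo), 1.0) * 1e-6
    return lo, lo + pad


def partition_range(lo: float, hi: float, n: int) -> Partition:
    """Evenly partition [lo, hi] into ``n`` divisions."""
    if n < 1:
        raise ParameterError(f"number of divisions must be >= 1, got {n}")
    if not hi > lo:
        raise DomainError(f"need hi > lo, got lo={lo}, hi={hi}")
    return Partition(n_divisions=n, edges=np.linspace(lo, hi, n + 1))


def assign_division(intensity, p: Partition):
    """Division index for each intensity; OUT_OF_RANGE outside [lo, hi].

    Vectorised: accepts a scalar or array and returns the same shape.
    ``edges[i] <= x < edges[i+1]``, with ``x == hi`` assigned to the last
    division.
    """
    x = np.asarray(intensity, dtype=np.float64)
    idx = np.searchsorted(p.edges, x, side="right") - 1
    idx = np.where(x == p.hi, p.n_divisions - 1, idx)
    idx = np.where((x < p.lo) | (x > p.hi), OUT_OF_RANGE, idx)
    idx = idx.astype(np.int64)
    if np.isscalar(intensity) or x.ndim == 0:
        return int(idx)
    return idx


# --- LUT ---------------------------------------------------------------------

# Nominal sRGB coordinates for the named target colors.  The printed resins'
# true colors are proprietary; these defaults are overridable per run.
NAMED_COLORS = {
    "cyan": (0.0, 1.0, 1.0, 1.0),
    "magenta": (1.0, 0.0, 1.0, 1.0),
    "yellow": (1.0, 1.0, 0.0, 1.0),
    "black": (0.0, 0.0, 0.0, 1.0),
    "white": (1.0, 1.0, 1.0, 1.0),
    "clear": (0.88, 0.92, 0.95, 1.0),
    "red": (1.0, 0.0, 0.0, 1.0),
    "orange": (1.0, 0.55, 0.0, 1.0),
    "green": (0.0, 0.8, 0.0, 1.0),
    "blue": (0.0, 0.0, 1.0, 1.0),
    "violet": (0.56, 0.0, 1.0, 1.0),
}

# Low→high intensity ramp used for the ten-division rendering: the six base
# materials plus blended targets reachable as material mixtures.
_RAMP_10 = ["black", "blue", "violet", "magenta", "red",
            "orange", "yellow", "green", "cyan", "white"]
_PALETTES = {
    1: ["white"],
    2: ["cyan", "magenta"],
    4: ["cyan", "magenta", "yellow", "black"],
    10: _RAMP_10,
}


def default_division_colors(n: int) -> np.ndarray:
    """Default N-division palette as an (N, 4) sRGB array.

    N ∈ {1, 2, 4, 10} use fixed named palettes; other N sample the
    ten-color ramp evenly.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if n in _PALETTES:
        names = _PALETTES[n]
    else:
        pick = np.linspace(0, len(_RAMP_10) - 1, n).round().astype(int)
        names = [_RAMP_10[i] for i in pick]
    return np.array([NAMED_COLORS[nm] for nm in names], dtype=np.float64)


@dataclass
class ColorLUT:
    """Intensity → RGBA transfer function over a :class:`Partition`.

    blend_mode "hard" gives each division its flat color.  "linear" blends
    the two neighbouring colors across a band of half-width
    ``blend_fraction * division_width`` centred on every interior edge
    (interpolation in linear-light RGB, alpha interpolated directly);
    ``blend_fraction = 0`` reproduces hard boundaries exactly.
    """

    partition: Partition
    division_colors: np.ndarray  # (N, 4) sRGB in [0, 1]
    blend_mode: str = "hard"
    blend_fraction: float = 0.25

    def __post_init__(self):
        cols = np.asarray(self.division_colors, dtype=np.float64)
        if cols.shape != (self.partition.n_divisions, 4):
            raise ParameterError(
                f"need {self.partition.n_divisions} RGBA colors, got shape {cols.shape}")
        if cols.min() < 0 or cols.max() > 1:
            raise ParameterError("color channels must lie in [0, 1]")
        if self.blend_mode not in ("hard", "linear"):
            raise ParameterError(f"unknown blend_mode {self.blend_mode!r}")
        if not 0.0 <= self.blend_fraction <= 0.5:
            raise ParameterError(
                f"blend_fraction must be in [0, 0.5], got {self.blend_fraction}")
        self.division_colors = cols

    def lookup(self, intensity) -> np.ndarray:
        """Vectorised RGBA lookup; out-of-range → transparent (alpha 0)."""
        x = np.asarray(intensity, dtype=np.float64)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        p = self.partition
        div = assign_division(x, p)
        out = np.zeros(x.shape + (4,), dtype=np.float64)
        ok = div != OUT_OF_RANGE
        out[ok] = self.division_colors[div[ok]]

        if self.blend_mode == "linear" and self.blend_fraction > 0 and p.n_divisions > 1:
            h = self.blend_fraction * p.width  # band half-width
            lin = srgb_to_linear(self.division_colors[:, :3])
            alpha = self.division_colors[:, 3]
            interior = p.edges[1:-1]
            # nearest interior edge for every in-range value
            xi = x[ok]
            di = div[ok]
            # band membership around edge j means j-1 and j are the blended pair
            j = np.clip(np.round((xi - p.lo) / p.width), 1, p.n_divisions - 1).astype(int)
            e = p.edges[j]
            inband = np.abs(xi - e) <= h
            if np.any(inband):
                t = (xi[inband] - (e[inband] - h)) / (2 * h)
                lo_c = lin[j[inband] - 1]
                hi_c = lin[j[inband]]
                rgb = linear_to_srgb(lo_c + t[:, None] * (hi_c - lo_c))
                a = alpha[j[inband] - 1] + t * (alpha[j[inband]] - alpha[j[inband] - 1])
                blended = np.concatenate([rgb, a[:, None]], axis=1)
                sub = out[ok]
                sub[inband] = blended
                out[ok] = sub
        out = np.clip(out, 0.0, 1.0)
        return out[0] if scalar else out


def lut_color(intensity: float, lut: ColorLUT) -> np.ndarray:
    """RGBA color of one intensity (scalar convenience wrapper)."""
    return lut.lookup(intensity)


# --- serialization -----------------------------------------------------------

def save_lut(lut: ColorLUT, path) -> None:
    """Write the LUT as a plain-text breakpoint table.

    One row per division: lower intensity breakpoint followed by R G B A.
    A final row repeats the last color at the upper bound so the table can be
    imported as a transfer function by common volume renderers.
    """
    lines = [
        "# voxelprint color lookup table",
        f"# n_divisions {lut.partition.n_divisions}",
        f"# blend_mode {lut.blend_mode}",
        f"# blend_fraction {lut.blend_fraction!r}",
        "# breakpoint R G B A",
    ]
    for i in range(lut.partition.n_divisions):
        e = float(lut.partition.edges[i])
        r, g, b, a = (float(v) for v in lut.division_colors[i])
        lines.append(f"{e!r} {r!r} {g!r} {b!r} {a!r}")
    r, g, b, a = (float(v) for v in lut.division_colors[-1])
    lines.append(f"{float(lut.partition.edges[-1])!r} {r!r} {g!r} {b!r} {a!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_lut(path) -> ColorLUT:
    """Read a LUT written by :func:`save_lut`."""
    meta = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2:
                meta[parts[0]] = parts[1]
            continue
        rows.append([float(v) for v in line.split()])
    if len(rows) < 2:
        raise ParameterError(f"LUT file {path} has no breakpoint rows")
    arr = np.asarray(rows, dtype=np.float64)
    edges = arr[:, 0]
    colors = arr[:-1, 1:5]
    part = Partition(n_divisions=len(edges) - 1, edges=edges)
    return ColorLUT(
        partition=part,
        division_colors=colors,
        blend_mode=meta.get("blend_mode", "hard"),
        blend_fraction=float(meta.get("blend_fraction", 0.0)),
    )
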