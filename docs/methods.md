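# Methods

## Pipeline model

`voxelprint` treats a medical image volume as a scalar field sampled on an
anisotropic grid and a 3D print as a second sampling of the same field on the
printer's native grid. The chain is:

    read → window/level → mask → bounds → equal-width partition → color LUT
    → reslice (trilinear) → colorize → PNG slice stack
    → multi-material error-diffusion dithering → material slice stack

and, for the audit, the conventional boundary-surface chain:

    read → mask → bounds → partition → per-division threshold label
    → per-division isosurface → STL per division → metrics

Key assumption: one volume in, one model out. No registration, bias-field
correction or multi-sequence fusion; masks arrive as files (or from the
phantom generator) and interactive cropping is replaced by an axis-aligned
bounding-box crop.

### Axis and coordinate conventions

Volumes are `voxels[row, column, slice]` with `spacing = (dx, dy, dz)` mm
(`dx` = column pitch, `dy` = row pitch, `dz` = inter-slice distance) and
`origin` at the centre of voxel (0, 0, 0). Slice index increases with
physical z. DICOM series are sorted by physical slice position; inter-slice
distances may jitter by a relative spread of ≤ 1e-3 (the mean is used as dz,
larger spread is a geometry error, which also catches missing slices).

### Window/level

`[center − width/2, center + width/2]` maps linearly onto [0, 1], clamped
outside. Working in a normalized domain decouples the downstream stages from
scanner units. Histogram equalisation beyond window/level is deliberately
not implemented.

### Partition and LUT

`partition_range(lo, hi, N)` places N+1 `linspace` edges; intervals are
half-open with the last closed, so the divisions tile [lo, hi] with no
overlap or gap (edge-width equality is validated up to a few ulps of the
edge magnitudes — a narrow interval at a large offset cannot represent
widths more equally than that). Intensities outside [lo, hi] map to a
sentinel and, through the LUT, to a fully transparent color (alpha 0 = "no
material").

Division colors default to named nominal sRGB palettes (2: cyan/magenta;
4: +yellow/black; 10: a black→blue→violet→magenta→red→orange→yellow→green→
cyan→white ramp — six base resins plus blended targets; other N sample that
ramp). Vendor resin colors are proprietary, so all palettes are overridable.
Gradient blending is linear interpolation in linear-light RGB (sRGB transfer
decoded first; alpha interpolated directly) across a band of half-width
`blend_fraction × division_width` centred on each interior edge. Default
`blend_fraction = 0.25`; 0 reproduces hard boundaries exactly, 0.5 makes the
transfer function continuous from division midpoint to midpoint.

### Reslicing and slicing

The output grid covers the masked bounding box with
`ceil(extent / pitch)` cells per axis; pitches derive from the printer
profile (defaults 600 DPI → 42.3 µm in x, 300 DPI → 84.7 µm in y, 27 µm
layers; the layer pitch is a print-mode parameter — quality modes reach
15 µm, draft 30 µm). Scalars are interpolated trilinearly (exact on affine
fields, preserves constants); the mask is resampled nearest-neighbour so it
stays binary; output cells in the sub-pitch `ceil` spill-over clamp to the
nearest source sample. The LUT is applied **after** reslicing: pointwise
colorizing of interpolated scalars keeps material identities crisp, whereas
interpolating RGBA across division boundaries would smear the colors the
dithering stage must reproduce.

Slice PNGs (8-bit RGBA, one per layer, zero-padded z-ordered names) are
written with stored (uncompressed) deflate blocks by default: the print file
is an interchange format consumed by the printer, and with a fixed-size
encoding its byte count is governed by raster dimensions and layer count
alone — independent of the number of divisions that colored the content.
Deflate-compressed sizes are content-dependent (up to ~2× across division
counts on smooth phantoms) and can be re-enabled per call for archival.

### Dithering

Floyd–Steinberg error diffusion over the material palette (K between 2 and
6): serpentine row order; per pixel the accumulated error is clamped to
[−1, 1] per channel (prevents runaway diffusion at mask boundaries), added
to the pixel, and the nearest palette entry in linear-RGB Euclidean distance
chosen (ties → lowest palette index, making the output fully deterministic);
the residual goes 7/16 to the pixel ahead, 3/16 behind-below, 5/16 below,
1/16 ahead-below — only to pixels that carry material. Alpha-0 pixels are
skipped entirely: they receive no assignment and neither emit nor absorb
error, and print as support.

Error diffusion preserves the local mean, so a uniform region whose target
color lies in the palette's convex hull dithers to material fractions whose
palette-weighted mean reproduces the target (measured ≤ 0.01 per channel on
128² regions). Per-material *fractions* are only uniquely determined when
the target's decomposition is unique — six palette colors in a
three-dimensional color space are affinely dependent, so e.g. a black/white
gray can legitimately be rendered as a cyan/magenta/yellow mixture. The
tests therefore check exact fraction recovery on two-material mixtures whose
mixing segment stays inside the endpoints' nearest-color cells, and
mean-color preservation for arbitrary hull mixtures. The clear resin
participates as an ordinary palette entry with a nominal pale color; optical
translucency is not modelled.

The material stack serialises either as palette-indexed PNGs (sentinel =
index K) or as K 1-bit per-layer deposition bitmaps; both round-trip
losslessly.

### Mesh workflow and audit

Each division's binary indicator is isosurfaced at level 0.5 with marching
cubes (standard tables — the accelerated flying-edges variant produces the
same surface), zero-padded so surfaces close at the volume border, each
division meshed independently with no face sharing. `run_comparison`
additionally Gaussian-smooths the indicator (σ = 1 voxel by default) before
isosurfacing, emulating the surface generation of clinical segmentation
exporters; this is what makes the workflow's pathology measurable. With raw
binary isosurfaces the surfaces of complementary labels coincide along
shared interfaces and the summed volume actually *over*-tiles the mask
slightly; with the exporter-style smoothing, ragged inter-division
boundaries erode from both sides and thin segments vanish, so the summed
enclosed volume falls monotonically as divisions are added (on the default
gradient-sphere phantom: ≈0.5% loss at N=2, ≈1% at N=4, ≈20–40% at N=10,
seed-dependent) while triangle counts and STL bytes grow several-fold.
`extract_mesh` itself defaults to σ = 0 (raw isosurface) so single voxels
and unsmoothed geometry remain meshable. Mesh *post*-processing (decimation,
mesh smoothing, booleans) is deliberately absent — it would confound the
audit.

Enclosed volume uses the divergence theorem (signed tetrahedra) after
vertex merging and degenerate-face removal. "Closed" means zero boundary
edges and consistent winding; non-manifold pinch edges shared by four faces
(two blobs of one division touching diagonally) are permitted — the signed
sum stays exact there, although strict two-manifold watertightness fails.
Disconnected shells are connected components under shared-edge face
adjacency (vertex-point contact does not merge shells), invariant to face
reordering and vertex renumbering. STL export is binary; bytes are measured
post-write. The volume-loss reference is the masked source volume (voxel
count × voxel volume).

## Synthetic phantoms

The generator emulates soft-tissue radiodensity volumes: nested ellipsoids
with base intensities (later layers override earlier where nested), an
optional radial or axial intensity ramp spanning a wide scalar range, and
additive Gaussian noise (seeded, bit-reproducible). Defaults follow clinical
acquisition: 0.8 × 0.8 mm in-plane, 3 mm slices for the generic spec; the
`gradient-sphere` preset uses a 1000-unit intensity span with noise SD 50
(SNR ≈ 20 over the full range, typical of MR) on a finer isotropic grid so
printer-scale reslicing stays tractable. Ground truth carries exact
ellipsoid volumes (4/3·π·abc) and the noise-free intensity function for
pointwise checks; ellipsoids exceeding the grid raise a warning and a
clipped flag. Gaussian (not Rician) noise is used — the pipeline is
noise-model agnostic and only boundary raggedness matters here.

What the phantoms do **not** emulate: anatomical texture and structure at
multiple scales, partial-volume and scanner point-spread effects, intensity
inhomogeneity, and non-convex organ topology. Passing tests therefore
demonstrate the pipeline's geometric and radiometric correctness and the
*mechanisms* of the mesh workflow's degradation, not the absolute loss
magnitudes any particular anatomy would show.

DICOM export writes a minimal single-series CT-style stack: signed 16-bit
pixels with a fixed rescale slope/intercept recorded per slice (slope =
intensity span / 30000), mirroring real CT/MR integer storage; round-trip
intensity error is bounded by half that quantisation step.

## Problem sizes and runtime choices

Default test/audit sizes: 64³ source phantoms for the comparison study
(≈ 9M printer voxels after reslicing) and a 128³ phantom (≈ 4.6M printer
voxels) for the end-to-end determinism run — large enough for stable
statistics, small enough to iterate quickly. The error-diffusion kernel is
JIT-compiled (numba) because the recurrence is inherently sequential per
pixel. All randomness flows from explicit seeds; repeated runs are
hash-identical.

## Known limitations

- Nominal sRGB stand-ins for resin colors; no ICC color management,
  ink-limiting or droplet-level printer calibration.
- No translucency/scattering model for the clear resin.
- No printer-vendor job files; the PNG stack is the interchange format.
- Patient orientation metadata is not interpreted; the fixed
  row/column/slice convention assumes a consistently acquired series.
- The audit's absolute loss numbers depend on the exporter-smoothing sigma
  and the phantom's noise; only the monotone trends are asserted.
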