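"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

import voxelprint as vp


@pytest.fixture(scope="session")
def vero_palette():
    return vp.default_vero_palette()


@pytest.fixture(scope="session")
def bw_palette():
    return vp.MaterialPalette([
        vp.Material("black", (0.0, 0.0, 0.0, 1.0)),
        vp.Material("white", (1.0, 1.0, 1.0, 1.0)),
    ])


@pytest.fixture(scope="session")
def small_gradient_sphere():
    """Noise-free radial-gradient sphere on a coarse isotropic grid."""
    spec = vp.gradient_sphere_spec(shape=(32, 32, 32), spacing=(0.3, 0.3, 0.3),
                                   seed=11, noise_sd=0.0)
    return vp.generate_phantom(spec)


def reference_floyd_steinberg(rgb, alpha, palette_linear):
    """Independent, straightforward trace of the error-diffusion recurrence.

    Serpentine scan; per pixel: clamp accumulated error to [-1, 1], add to
    the pixel, pick the nearest palette color (lowest index on ties),
    diffuse the residual with weights 7/16 (ahead), 3/16 (behind, next row),
    5/16 (below), 1/16 (ahead, next row) to unmasked pixels only.
    """
    h, w, _ = rgb.shape
    err = np.zeros((h, w, 3))
    out = np.full((h, w), -1, dtype=int)
    for y in range(h):
        step = 1 if y % 2 == 0 else -1
        xs = range(w) if step == 1 else range(w - 1, -1, -1)
        for x in xs:
            if alpha[y, x] <= 0:
                continue
            v = rgb[y, x] + np.clip(err[y, x], -1.0, 1.0)
            d = ((palette_linear - v) ** 2).sum(axis=1)
            j = int(np.argmin(d))  # argmin takes the first (lowest) index
            out[y, x] = j
            q = v - palette_linear[j]
            for dy, dx, wgt in ((0, step, 7 / 16), (1, -step, 3 / 16),
                                (1, 0, 5 / 16), (1, step, 1 / 16)):
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w and alpha[yy, xx] > 0:
                    err[yy, xx] += wgt * q
    return out


def uniform_rgba(shape, rgb, alpha=1.0):
    """Uniform linear-RGB image of the given (H, W)."""
    img = np.empty(shape + (4,), dtype=np.float64)
    img[:, :, :3] = np.asarray(rgb)
    img[:, :, 3] = alpha
    return img
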