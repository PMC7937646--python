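"""Deterministic lattice value noise for procedural textures.

Textures must be evaluable at arbitrary world coordinates (the renderer shades
ray hit points, not a pre-baked raster), so a hash-based lattice noise is used:
integer lattice corners are hashed to values in [0, 1) and interpolated with a
smoothstep, and octaves are summed with a per-octave amplitude gain that sets
the spectral falloff of the texture.
"""

from __future__ import annotations

import numpy as np

_U32 = np.uint32


def _hash01(ix: np.ndarray, iy: np.ndarray, seed: int) -> np.ndarray:
    """Hash integer lattice coordinates to floats in [0, 1)."""
    h = (
        ix.astype(_U32) * _U32(0x85EBCA6B)
        ^ iy.astype(_U32) * _U32(0xC2B2AE35)
        ^ _U32((seed * 0x27D4EB2F + 0x9E3779B9) & 0xFFFFFFFF)
    )
    h ^= h >> _U32(15)
    h *= _U32(0x2C1B3C6D)
    h ^= h >> _U32(12)
    h *= _U32(0x297A2D39)
    h ^= h >> _U32(15)
    return h.astype(np.float64) / 4294967296.0


def value_noise(x: np.ndarray, y: np.ndarray, seed: int = 0) -> np.ndarray:
    """Single-octave smoothed value noise in [0, 1], unit lattice period."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ix, iy = np.floor(x), np.floor(y)
    fx, fy = x - ix, y - iy
    ix = ix.astype(np.int64)
    iy = iy.astype(np.int64)
    ux = fx * fx * (3.0 - 2.0 * fx)
    uy = fy * fy * (3.0 - 2.0 * fy)
    v00 = _hash01(ix, iy, seed)
    v10 = _hash01(ix + 1, iy, seed)
    v01 = _hash01(ix, iy + 1, seed)
    v11 = _hash01(ix + 1, iy + 1, seed)
    return (
        v00 * (1 - ux) * (1 - uy)
        + v10 * ux * (1 - uy)
        + v01 * (1 - ux) * uy
        + v11 * ux * uy
    )


def fractal_noise(
    x: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    octaves: int = 5,
    base_scale: float = 1.0,
    gain: float = 0.5,
    anisotropy: float = 1.0,
) -> np.ndarray:
    """Multi-octave value noise, zero-mean-ish, roughly in [-1, 1].

    ``base_scale`` is the wavelength (in the units of x/y) of the lowest
    octave; ``gain`` the amplitude ratio between successive octaves (smaller
    gain -> steeper spectral falloff); ``anisotropy`` > 1 compresses the
    pattern along y (stripes elongated along y).
    """
    total = np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape)
    amp_sum = 0.0
    freq = 1.0 / base_scale
    amp = 1.0
    for k in range(octaves):
        total += amp * (value_noise(x * freq, y * freq * anisotropy, seed + 101 * k) - 0.5)
        amp_sum += amp
        freq *= 2.0
        amp *= gain
    return 2.0 * total / amp_sum
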