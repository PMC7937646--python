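"""Edge extraction via orientation tensors on matched derivative filters.

Gradients are computed with the 5-tap rotation-invariant prefilter/derivative
pair of Farid & Simoncelli; the local orientation tensor (Gaussian-averaged
outer product of the gradient) yields per-pixel energy (eigenvalue sum),
orientedness (normalized eigenvalue difference), and the dominant edge
orientation in [0, 180) degrees.  Edge pixels are those whose energy exceeds
the per-image 68th percentile and whose orientedness exceeds 0.8.

Orientations are expressed in the visual-field frame: 0 degrees = horizontal,
90 degrees = vertical, angles increasing counter-clockwise (+y up; image rows
increase downward, so the row-gradient sign is flipped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

__all__ = [
    "gradient_pair",
    "orientation_tensor",
    "TensorField",
    "EdgePixelSet",
    "select_edges",
    "orientation_histogram",
    "extract_orientations",
]

# Farid & Simoncelli 5-tap matched pair (prefilter p, derivative d1).
_PREFILTER = np.array([0.037659, 0.249153, 0.426375, 0.249153, 0.037659])
_DERIV = np.array([-0.109604, -0.276691, 0.0, 0.276691, 0.109604])
_BORDER = 2  # filter half-width; border pixels are invalid


def gradient_pair(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Matched-filter image gradients (gx along columns, gy along rows).

    Returns raw-array-axis gradients: ``gy`` is positive for intensity
    increasing with row index (downward in the raster).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError("gradient_pair needs a 2D image at least 16 px")
    gx = correlate1d(correlate1d(img, _DERIV, axis=1), _PREFILTER, axis=0)
    gy = correlate1d(correlate1d(img, _DERIV, axis=0), _PREFILTER, axis=1)
    return gx, gy


def _gaussian_kernel1d(sigma: float, size: int) -> np.ndarray:
    x = np.arange(size) - (size - 1) / 2.0
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


@dataclass
class TensorField:
    """Per-pixel orientation-tensor summaries."""

    energy: np.ndarray        # lambda1 + lambda2
    orientedness: np.ndarray  # (lambda1 - lambda2) / (lambda1 + lambda2)
    orientation_deg: np.ndarray  # edge orientation in [0, 180)
    valid: np.ndarray         # border-excluded mask


def orientation_tensor(
    gx: np.ndarray, gy: np.ndarray, sigma: float = 1.2, size: int = 5
) -> TensorField:
    """Locally averaged gradient outer-product tensor and its eigenstructure.

    The edge orientation is perpendicular to the dominant gradient direction,
    reported in the visual-field frame (+y up).
    """
    gy_up = -gy  # rows increase downward
    k = _gaussian_kernel1d(sigma, size)

    def smooth(a):
        return correlate1d(correlate1d(a, k, axis=0), k, axis=1)

    t11 = smooth(gx * gx)
    t12 = smooth(gx * gy_up)
    t22 = smooth(gy_up * gy_up)
    energy = t11 + t22
    diff = np.sqrt((t11 - t22) ** 2 + 4.0 * t12**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        orientedness = np.where(energy > 0, diff / energy, 0.0)
    grad_angle = 0.5 * np.arctan2(2.0 * t12, t11 - t22)
    orient = (np.degrees(grad_angle) + 90.0) % 180.0
    valid = np.zeros(energy.shape, bool)
    b = _BORDER + size // 2
    valid[b:-b, b:-b] = True
    return TensorField(energy, orientedness, orient, valid)


@dataclass
class EdgePixelSet:
    """Selected edge pixels of one or more patches."""

    orientations_deg: np.ndarray
    energies: np.ndarray
    orientedness: np.ndarray
    n_source_images: int = 1

    def __len__(self):
        return len(self.orientations_deg)

    @staticmethod
    def concatenate(sets: list["EdgePixelSet"]) -> "EdgePixelSet":
        return EdgePixelSet(
            np.concatenate([s.orientations_deg for s in sets]) if sets else np.zeros(0),
            np.concatenate([s.energies for s in sets]) if sets else np.zeros(0),
            np.concatenate([s.orientedness for s in sets]) if sets else np.zeros(0),
            sum(s.n_source_images for s in sets),
        )


def select_edges(
    field: TensorField,
    energy_percentile: float = 68.0,
    orientedness_min: float = 0.8,
    valid: np.ndarray | None = None,
) -> EdgePixelSet:
    """Edge pixels: energy strictly above the per-image percentile and
    orientedness strictly above the threshold (over valid pixels only)."""
    mask = field.valid if valid is None else (field.valid & valid)
    e = field.energy[mask]
    if e.size == 0:
        return EdgePixelSet(np.zeros(0), np.zeros(0), np.zeros(0))
    thresh = np.percentile(e, energy_percentile)
    keep = mask & (field.energy > thresh) & (field.orientedness > orientedness_min)
    return EdgePixelSet(
        field.orientation_deg[keep], field.energy[keep], field.orientedness[keep]
    )


def extract_orientations(patch, **kwargs) -> EdgePixelSet:
    """Full edge pipeline for one luminance patch (gradients -> tensor -> selection)."""
    img = patch.gray if hasattr(patch, "gray") else np.asarray(patch, float)
    valid = getattr(patch, "valid", None)
    gx, gy = gradient_pair(img)
    field = orientation_tensor(gx, gy)
    if valid is not None:
        from scipy.ndimage import binary_erosion

        valid = binary_erosion(valid, iterations=_BORDER + 2)
    return select_edges(field, valid=valid, **kwargs)


def orientation_histogram(edges, n_bins: int = 36):
    """Circular histogram over [0, 180), density integrating to 1 (per degree).

    Accepts an ``EdgePixelSet`` or an array of angles in degrees.
    Returns (density, bin_edges_deg).
    """
    angles = (
        edges.orientations_deg if isinstance(edges, EdgePixelSet) else np.asarray(edges)
    )
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    if angles.size == 0:
        raise ValueError("empty orientation set")
    a = np.mod(angles, 180.0)
    counts, edges_deg = np.histogram(a, bins=n_bins, range=(0.0, 180.0))
    density = counts / (counts.sum() * (180.0 / n_bins))
    return density, edges_deg
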