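"""Thin-lens eye models and projective geometry of an idealized spherical retina.

The eye is modeled as a thin lens focused at infinity: a sphere of radius ``r``
centered at ``c = (0, 0, -r)`` behind the optical center at the origin, with
focal length ``f = 2r``.  The conventional planar image lives on the plane
``z = -2r`` tangent to the back pole of the sphere.  A visual-field location is
addressed by eccentricity ``phi`` (angle from the optical axis) and polar angle
``chi`` (angle around the axis, counter-clockwise from +x with +y up).

Because the spherical image has no global 2D pixel coordinates, each patch is
approximated locally by the plane tangent to the sphere at its center; the
planar and tangent-plane images of the same scene are related by a homography
(both planes are imaged through the same center of projection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EyeModel",
    "HUMAN_EYE",
    "CAT_EYE",
    "VisualFieldCoord",
    "TangentPlane",
    "Homography",
    "plane_point",
    "sphere_point",
    "tangent_plane_at",
    "homography_for",
    "tangent_approx_error",
    "pixel_pitch_mm",
]


@dataclass(frozen=True)
class EyeModel:
    """Thin-lens equivalent eye focused at infinity (``f = 2r``).

    Parameters
    ----------
    species : str
        Label, e.g. ``"human"`` or ``"cat"``.
    focal_length_mm : float
        Focal length ``f``; the retinal sphere has radius ``r = f/2``.
    eye_height_m : float
        Height of the optical center above the ground plane.
    """

    species: str
    focal_length_mm: float
    eye_height_m: float

    @property
    def radius_mm(self) -> float:
        return self.focal_length_mm / 2.0

    @property
    def sphere_center_mm(self) -> np.ndarray:
        r = self.radius_mm
        return np.array([0.0, 0.0, -r])


#: Human eye: f = 16.67 mm (Emsley reduced eye), eye height 1.8 m.
HUMAN_EYE = EyeModel("human", 16.67, 1.8)
#: Cat eye: f = 12.5 mm, eye height 0.25 m.
CAT_EYE = EyeModel("cat", 12.5, 0.25)


@dataclass(frozen=True)
class VisualFieldCoord:
    """Visual-field location (eccentricity, polar angle), both in degrees.

    The center ``phi = 0`` is degenerate in ``chi``; the canonical form stores
    ``chi = 0`` there.
    """

    eccentricity_deg: float
    polar_angle_deg: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.eccentricity_deg < 90.0:
            raise ValueError(
                f"eccentricity must be in [0, 90), got {self.eccentricity_deg}"
            )
        chi = self.polar_angle_deg % 360.0
        if chi == 360.0:  # tiny negative inputs round up under fmod
            chi = 0.0
        if self.eccentricity_deg == 0.0:
            chi = 0.0
        object.__setattr__(self, "polar_angle_deg", chi)

    @property
    def phi_rad(self) -> float:
        return np.radians(self.eccentricity_deg)

    @property
    def chi_rad(self) -> float:
        return np.radians(self.polar_angle_deg)


@dataclass(frozen=True)
class TangentPlane:
    """Plane tangent to the retinal sphere at a visual-field location.

    ``basis`` rows span the plane: the first axis points along the local radial
    (increasing-eccentricity) direction, the second completes a right-handed
    frame with the inward normal.
    """

    tangent_point_mm: np.ndarray
    normal: np.ndarray  # outward unit normal (away from sphere center)
    basis: np.ndarray = field(repr=False)  # (2, 3), orthonormal rows

    def points(self, a, b) -> np.ndarray:
        """3D points at in-plane offsets ``(a, b)`` (mm) from the tangent point."""
        a = np.asarray(a, dtype=float)[..., None]
        b = np.asarray(b, dtype=float)[..., None]
        return self.tangent_point_mm + a * self.basis[0] + b * self.basis[1]


def pixel_pitch_mm(eye: EyeModel, scene_resolution_px: int, fov_deg: float) -> float:
    """Pixel pitch on the plane ``z = -2r`` for a square frame of the given FOV."""
    r = eye.radius_mm
    return 2.0 * (2.0 * r) * np.tan(np.radians(fov_deg / 2.0)) / scene_resolution_px


def plane_point(coord: VisualFieldCoord, eye: EyeModel) -> np.ndarray:
    """Image-plane point (mm) of a visual-field location on ``z = -2r``."""
    phi, chi = coord.phi_rad, coord.chi_rad
    f = 2.0 * eye.radius_mm
    return np.array(
        [f * np.tan(phi) * np.cos(chi), f * np.tan(phi) * np.sin(chi), -f]
    )


def sphere_point(coord: VisualFieldCoord, eye: EyeModel) -> np.ndarray:
    """Retinal-sphere point (mm) of a visual-field location.

    Lies on the sphere of radius ``r`` centered at ``(0, 0, -r)`` and on the ray
    through the origin and ``plane_point(coord)`` (the sphere passes through the
    center of projection, so the along-ray sphere intersection is closed-form).
    """
    phi, chi = coord.phi_rad, coord.chi_rad
    f = 2.0 * eye.radius_mm
    sc = np.sin(phi) * np.cos(phi)
    return np.array([f * sc * np.cos(chi), f * sc * np.sin(chi), -f * np.cos(phi) ** 2])


def tangent_plane_at(coord: VisualFieldCoord, eye: EyeModel) -> TangentPlane:
    """Tangent plane of the retinal sphere at a visual-field location."""
    phi, chi = coord.phi_rad, coord.chi_rad
    p_t = sphere_point(coord, eye)
    normal = (p_t - eye.sphere_center_mm) / eye.radius_mm
    # d(sphere_point)/d(phi), normalized: the local radial direction.
    e1 = np.array(
        [np.cos(2 * phi) * np.cos(chi), np.cos(2 * phi) * np.sin(chi), np.sin(2 * phi)]
    )
    e2 = np.cross(-normal, e1)  # right-handed with the inward normal
    return TangentPlane(p_t, normal, np.vstack([e1, e2]))


@dataclass(frozen=True)
class Homography:
    """3x3 projective map between planar-patch and tangent-patch pixel frames.

    ``matrix`` maps homogeneous *centered* patch coordinates (pixels, +y up,
    origin at the patch center) of the planar patch to those of the tangent
    patch.  Defined up to scale; normalized so ``matrix[2, 2] = 1``.
    """

    matrix: np.ndarray
    coord: VisualFieldCoord
    pixel_pitch_mm: float

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map centered planar-patch pixel coords (..., 2) to tangent coords."""
        xy = np.asarray(xy, dtype=float)
        h = np.concatenate([xy, np.ones(xy.shape[:-1] + (1,))], axis=-1)
        out = h @ self.matrix.T
        return out[..., :2] / out[..., 2:3]

    @property
    def inverse_matrix(self) -> np.ndarray:
        inv = np.linalg.inv(self.matrix)
        return inv / inv[2, 2]


def _patch_embeddings(coord: VisualFieldCoord, eye: EyeModel, pitch: float):
    """3D embeddings of the two 2D patch pixel frames.

    ``B`` embeds centered planar-patch pixels into the plane ``z = -2r``;
    ``A`` embeds centered tangent-patch pixels into the tangent plane.  Columns
    are (x-axis, y-axis, patch-center); a homogeneous pixel coordinate maps to
    the 3D point of that pixel.
    """
    p = plane_point(coord, eye)
    # Planar-patch in-plane axes: +x and +y of the image plane (visual field,
    # +y up); scaled to mm per pixel.
    bx = np.array([pitch, 0.0, 0.0])
    by = np.array([0.0, pitch, 0.0])
    B = np.column_stack([bx, by, p])
    tp = tangent_plane_at(coord, eye)
    A = np.column_stack([pitch * tp.basis[0], pitch * tp.basis[1], tp.tangent_point_mm])
    return A, B, tp


def homography_for(
    coord: VisualFieldCoord,
    eye: EyeModel,
    pixel_pitch_mm: float,
    patch_px: int | None = None,
) -> Homography:
    """Homography from planar-patch to tangent-patch centered pixel coordinates.

    Corresponding pixels lie on the same ray through the center of projection:
    ``A q' ∝ B q`` so ``H ∝ A⁻¹ B``.  ``patch_px`` is accepted for interface
    symmetry but the map itself is independent of patch size.
    """
    A, B, _ = _patch_embeddings(coord, eye, pixel_pitch_mm)
    H = np.linalg.solve(A, B)
    if abs(H[2, 2]) < 1e-15:
        raise np.linalg.LinAlgError("degenerate homography (H[2,2] ~ 0)")
    return Homography(H / H[2, 2], coord, pixel_pitch_mm)


def tangent_approx_error(
    coord: VisualFieldCoord,
    eye: EyeModel,
    patch_px: int = 128,
    scene_resolution_px: int = 5954,
    fov_deg: float = 120.0,
    pairing: str = "ray",
) -> float:
    """Maximal 3D distance (mm) between the tangent plane and the sphere.

    Enumerates the pixel centers of a ``patch_px`` x ``patch_px`` patch on the
    tangent plane (pixel pitch inherited from the full planar frame), pairs each
    tangent-plane point with the sphere either along the ray through the center
    of projection (``pairing="ray"``) or perpendicular to the tangent plane
    (``pairing="perpendicular"``), and returns the maximum pair distance.
    """
    pitch = pixel_pitch_mm(eye, scene_resolution_px, fov_deg)
    tp = tangent_plane_at(coord, eye)
    idx = (np.arange(patch_px) - (patch_px - 1) / 2.0) * pitch
    a, b = np.meshgrid(idx, idx)
    pts = tp.points(a, b)
    c = eye.sphere_center_mm
    if pairing == "ray":
        # Sphere passes through the origin, so along the ray x = t*p the
        # non-trivial intersection is t = 2 p.c / |p|^2.
        denom = np.einsum("...k,...k->...", pts, pts)
        t = 2.0 * (pts @ c) / denom
        if np.any(t <= 0):
            raise ValueError("ray misses the sphere: eccentricity too large")
        dist = np.abs(t - 1.0) * np.sqrt(denom)
    elif pairing == "perpendicular":
        dist = np.abs(np.linalg.norm(pts - c, axis=-1) - eye.radius_mm)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    return float(dist.max())
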