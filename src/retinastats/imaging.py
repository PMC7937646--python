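"""Pinhole rendering of visual-field image patches and the luminance pipeline.

Patches are rendered through an off-axis (asymmetric-frustum) pinhole camera:
a patch at visual-field position (phi, chi) covers the window
``[x - s/2, x + s/2] x [y - s/2, y + s/2]`` of the image plane ``z = -2r``,
where ``(x, y)`` is the plane point of the coordinate and ``s`` the patch size
in mm.  The frustum convention of OpenGL is used (front plane, no pinhole
inversion): polar angle chi = 90 degrees is the *upper* visual field.

The renderer is a vectorized CPU ray caster over analytic primitives (ground
plane, vertical cylinders, segment capsules) with Lambert-like shading from a
slanted overhead light.  Tangent-projection patches are obtained either by
warping a planar render through the patch homography (the production path) or
by casting rays directly through tangent-plane pixels (the oracle path).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from . import geometry as geom
from .geometry import EyeModel, Homography, VisualFieldCoord
from .noise import fractal_noise, value_noise
from .scene import GazeSpec, Pose, ScenePrimitives, apply_gaze

__all__ = [
    "ImagePatch",
    "render_patch",
    "render_tangent_patch_direct",
    "render_full_frame",
    "to_luminance",
    "normalize_mean",
    "warp_to_tangent",
    "capture_ensemble",
    "PatchEnsemble",
]

_EPS = 1e-6
_LIGHT = np.array([0.3, 0.9, 0.3]) / np.linalg.norm([0.3, 0.9, 0.3])


@dataclass
class ImagePatch:
    """Square image patch with imaging provenance.

    ``pixels`` is (H, W) grayscale or (H, W, 3) RGB, nonnegative.  ``valid``
    marks pixels with defined values (warping can map outside the source).
    """

    pixels: np.ndarray
    pixel_pitch_mm: float
    projection: str  # "planar" | "tangent"
    coord: VisualFieldCoord
    pose_index: int = -1
    strategy: str = ""
    species: str = ""
    valid: np.ndarray | None = None

    @property
    def patch_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def gray(self) -> np.ndarray:
        if self.pixels.ndim == 2:
            return self.pixels
        raise ValueError("patch is RGB; call to_luminance first")


# ---------------------------------------------------------------------------
# Shading


def _ground_albedo(scene: ScenePrimitives, x, z):
    g = scene.ground
    base = np.asarray(g.base_rgb)
    n = fractal_noise(x, z, seed=g.seed, octaves=g.octaves,
                      base_scale=g.noise_scale_m, gain=g.gain)
    val = 1.0 + g.noise_amp * n
    if g.stripe_amp > 0:
        th = np.radians(g.stripe_dir_deg)
        # Coordinate across the track direction; stripes run along the track.
        across = -x * np.sin(th) + z * np.cos(th)
        along = x * np.cos(th) + z * np.sin(th)
        val = val + g.stripe_amp * np.sin(2 * np.pi * across / g.stripe_period_m)
        if g.grass_amp > 0:
            # Grass strokes roughly perpendicular to the track: fine variation
            # along the track, coarse across it.
            grass = fractal_noise(
                along / g.grass_scale_m, across / (6.0 * g.grass_scale_m),
                seed=g.seed + 7, octaves=3, gain=0.6,
            )
            val = val + g.grass_amp * grass
    return base[None, :] * np.clip(val, 0.05, None)[..., None]


def _bark_albedo(scene: ScenePrimitives, trunk_idx, az_arc, y, shade):
    base = np.array([0.38, 0.30, 0.22])
    n = value_noise(az_arc / 0.03, y / 0.3, seed=scene.seed + 31 + trunk_idx)
    val = 1.0 + scene.bark_noise_amp * 2.0 * (n - 0.5)
    # Horizontal banding along the trunk.
    val = val + scene.bark_band_amp * np.sin(
        2 * np.pi * y / scene.bark_band_period_m + 2.1 * trunk_idx
    )
    return base[None, :] * np.clip(val * shade, 0.05, None)[..., None]


# ---------------------------------------------------------------------------
# Ray casting


def _cone_cull(origin, dirs, centers, radii):
    """Indices of primitives whose bounding sphere meets the ray cone."""
    axis = dirs.mean(axis=0)
    axis /= np.linalg.norm(axis)
    half = np.arccos(np.clip((dirs @ axis).min(), -1.0, 1.0))
    v = centers - origin
    dist = np.linalg.norm(v, axis=1)
    close = dist < 1.05 * radii + 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ang = np.arccos(np.clip((v @ axis) / np.where(dist == 0, 1, dist), -1, 1))
        ang_rad = np.arctan2(radii, dist)
    keep = close | (ang <= half + ang_rad + 0.05)
    return np.where(keep)[0]


def _cast_rays(scene: ScenePrimitives, origin: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Shade rays (n, 3, unit) from ``origin`` (m); returns RGB (n, 3)."""
    n_rays = dirs.shape[0]
    t_hit = np.full(n_rays, np.inf)
    rgb = np.tile(np.asarray(scene.sky_rgb), (n_rays, 1))
    ox, oy, oz = origin
    dx, dy, dz = dirs[:, 0], dirs[:, 1], dirs[:, 2]

    if scene.ground is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = -oy / dy
        hit = (dy < -1e-12) & (t > _EPS)
        if np.any(hit):
            hx = ox + t[hit] * dx[hit]
            hz = oz + t[hit] * dz[hit]
            alb = _ground_albedo(scene, hx, hz)
            shade = 0.35 + 0.65 * _LIGHT[1]  # ground normal is +y
            idx = np.where(hit)[0]
            t_hit[idx] = t[hit]
            rgb[idx] = alb * shade

    # Vertical cylinder trunks (no caps; y clipped to [0, height]),
    # cone-culled so only trunks near the patch frustum are intersected.
    if scene.n_trunks:
        centers = np.stack(
            [scene.trunk_x, scene.trunk_height / 2.0, scene.trunk_z], axis=1
        )
        radii = scene.trunk_radius + scene.trunk_height / 2.0
        trunk_idx = _cone_cull(origin, dirs, centers, radii)
    else:
        trunk_idx = np.zeros(0, dtype=int)
    for k in trunk_idx:
        cx, cz = scene.trunk_x[k], scene.trunk_z[k]
        R, H = scene.trunk_radius[k], scene.trunk_height[k]
        wx, wz = ox - cx, oz - cz
        a = dx * dx + dz * dz
        b = 2.0 * (wx * dx + wz * dz)
        c = wx * wx + wz * wz - R * R
        disc = b * b - 4 * a * c
        ok = (disc > 0) & (a > 1e-12)
        if not np.any(ok):
            continue
        sq = np.sqrt(np.where(ok, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-b - sq) / (2 * a)
            t2 = (-b + sq) / (2 * a)
        t = np.where(t1 > _EPS, t1, t2)
        y = oy + t * dy
        hit = ok & (t > _EPS) & (y >= 0) & (y <= H) & (t < t_hit)
        if not np.any(hit):
            continue
        idx = np.where(hit)[0]
        th = t[idx]
        hx = ox + th * dx[idx] - cx
        hz = oz + th * dz[idx] - cz
        nx, nz = hx / R, hz / R
        lam = np.clip(nx * _LIGHT[0] + nz * _LIGHT[2], 0.0, None)
        shade = 0.45 + 0.55 * lam
        az_arc = np.arctan2(hz, hx) * R
        alb = _bark_albedo(scene, k, az_arc, oy + th * dy[idx], scene.trunk_shade[k])
        t_hit[idx] = th
        rgb[idx] = alb * shade[:, None]

    # Segment clutter as thin capsules via ray-segment closest approach,
    # chunked over segments to bound temporary-array size.
    nseg = scene.n_segments
    if nseg:
        seg_d = scene.seg_p1 - scene.seg_p0
        seg_len = np.linalg.norm(seg_d, axis=1)
        seg_u = seg_d / np.where(seg_len[:, None] == 0, 1.0, seg_len[:, None])
        mid = 0.5 * (scene.seg_p0 + scene.seg_p1)
        seg_idx = _cone_cull(
            origin, dirs, mid, seg_len / 2.0 + scene.seg_width
        )
        for lo in range(0, len(seg_idx), 128):
            sub = seg_idx[lo : lo + 128]
            u = seg_u[sub]                         # (m, 3)
            L = seg_len[sub]
            w = scene.seg_p0[sub] - origin         # (m, 3)
            B = dirs @ u.T                         # (n, m) ray.segment cosines
            D = dirs @ w.T                         # (n, m) ray.offset
            E = np.einsum("mk,mk->m", w, u)[None, :]
            denom = np.clip(1.0 - B * B, 1e-9, None)
            s = np.clip((B * D - E) / denom, 0.0, L[None, :])
            t = D + s * B
            # Closest points and distance.
            px = w[None, :, 0] + s * u[None, :, 0] - t * dirs[:, 0:1]
            py = w[None, :, 1] + s * u[None, :, 1] - t * dirs[:, 1:2]
            pz = w[None, :, 2] + s * u[None, :, 2] - t * dirs[:, 2:3]
            dist2 = px * px + py * py + pz * pz
            r2 = (scene.seg_width[sub][None, :] / 2.0) ** 2
            hit = (dist2 < r2) & (t > _EPS)
            if not np.any(hit):
                continue
            t_masked = np.where(hit, t, np.inf)
            jbest = np.argmin(t_masked, axis=1)
            tbest = t_masked[np.arange(n_rays), jbest]
            upd = tbest < t_hit
            if np.any(upd):
                idx = np.where(upd)[0]
                t_hit[idx] = tbest[idx]
                alb = scene.seg_albedo[sub][jbest[idx]]
                rgb[idx] = 0.85 * alb[:, None] * np.ones(3)[None, :]

    # Aerial perspective: blend distant hits toward the sky color.
    fog = getattr(scene, "fog_length_m", 0.0)
    if fog:
        hit = np.isfinite(t_hit)
        frac = 1.0 - np.exp(-t_hit[hit] / fog)
        rgb[hit] = (1 - frac[:, None]) * rgb[hit] + frac[:, None] * np.asarray(
            scene.sky_rgb
        )
    return np.clip(rgb, 0.0, None)


def _camera_frame(heading_deg: float, elevation_deg: float):
    h = np.radians(heading_deg)
    e = np.radians(elevation_deg)
    forward = np.array([np.cos(e) * np.cos(h), np.sin(e), np.cos(e) * np.sin(h)])
    up = np.array([0.0, 1.0, 0.0])
    right = np.cross(forward, up)
    nr = np.linalg.norm(right)
    if nr < 1e-9:  # looking straight up/down: pick right from heading
        right = np.array([-np.sin(h), 0.0, np.cos(h)])
    else:
        right /= nr
    cam_up = np.cross(right, forward)
    return right, cam_up, forward


def _shade_plane_points(scene, pose, view, xs, ys, focal_mm):
    """Render image-plane window points (mm, mm on z=-2r) to RGB (H, W, 3)."""
    right, cam_up, forward = _camera_frame(*view)
    X, Y = np.meshgrid(xs, ys)
    d = (
        X[..., None] * right + Y[..., None] * cam_up + focal_mm * forward
    ).reshape(-1, 3)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    rgb = _cast_rays(scene, pose.position_m, d)
    return rgb.reshape(X.shape + (3,))


def render_patch(
    scene: ScenePrimitives,
    pose: Pose,
    view: tuple[float, float],
    coord: VisualFieldCoord,
    eye: EyeModel,
    scene_resolution_px: int,
    fov_deg: float = 120.0,
    patch_px: int = 128,
) -> ImagePatch:
    """Render a planar RGB patch at a visual-field position (off-axis frustum).

    ``view`` is (heading_deg, elevation_deg) of the gaze direction.  Pixel
    pitch is inherited from the full ``scene_resolution_px`` frame of the
    given field of view; rows run top (+y of the visual field) to bottom.
    """
    pitch = geom.pixel_pitch_mm(eye, scene_resolution_px, fov_deg)
    center = geom.plane_point(coord, eye)
    f = 2.0 * eye.radius_mm
    offs = (np.arange(patch_px) - (patch_px - 1) / 2.0) * pitch
    xs = center[0] + offs
    ys = center[1] - offs  # rows increase downward; +y is up
    rgb = _shade_plane_points(scene, pose, view, xs, ys, f)
    return ImagePatch(rgb, pitch, "planar", coord, pose.timestamp_index)


def render_full_frame(
    scene, pose, view, eye, scene_resolution_px, fov_deg=120.0
) -> ImagePatch:
    """Render the entire square frame (use small resolutions only)."""
    center = VisualFieldCoord(0.0)
    return render_patch(
        scene, pose, view, center, eye, scene_resolution_px, fov_deg,
        patch_px=scene_resolution_px,
    )


def render_tangent_patch_direct(
    scene: ScenePrimitives,
    pose: Pose,
    view: tuple[float, float],
    coord: VisualFieldCoord,
    eye: EyeModel,
    scene_resolution_px: int,
    fov_deg: float = 120.0,
    patch_px: int = 128,
) -> ImagePatch:
    """Oracle: ray-cast directly through tangent-plane pixels (no warping)."""
    pitch = geom.pixel_pitch_mm(eye, scene_resolution_px, fov_deg)
    tp = geom.tangent_plane_at(coord, eye)
    offs = (np.arange(patch_px) - (patch_px - 1) / 2.0) * pitch
    a, b = np.meshgrid(offs, -offs)  # rows top -> bottom along -e2
    pts = tp.points(a, b)  # (H, W, 3) in mm, z < 0
    # Frustum (front-plane) convention: image point (x, y, z) sees direction
    # (x, y, -z) in camera coordinates.
    d_cam = pts * np.array([1.0, 1.0, -1.0])
    right, cam_up, forward = _camera_frame(*view)
    R = np.stack([right, cam_up, forward], axis=1)  # cam -> world
    d = d_cam.reshape(-1, 3) @ R.T
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    rgb = _cast_rays(scene, pose.position_m, d).reshape(pts.shape)
    return ImagePatch(rgb, pitch, "tangent", coord, pose.timestamp_index)


# ---------------------------------------------------------------------------
# Luminance pipeline

#: Y row of the linear sRGB (D65) -> CIE XYZ matrix.
_Y_WEIGHTS = np.array([0.2126729, 0.7151522, 0.0721750])


def to_luminance(patch: ImagePatch) -> ImagePatch:
    """CIE Y luminance of a linear-RGB patch (XYZ transform, Y channel)."""
    px = patch.pixels
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("to_luminance expects an RGB patch")
    if px.min() < 0 or px.max() > 1 + 1e-9:
        warnings.warn("RGB values outside [0, 1]; clamping", stacklevel=2)
        px = np.clip(px, 0.0, 1.0)
    y = px @ (_Y_WEIGHTS / _Y_WEIGHTS.sum())
    return replace(patch, pixels=y)


def normalize_mean(patch: ImagePatch) -> ImagePatch:
    """Divide by the mean luminance over valid pixels (output mean = 1)."""
    px = patch.gray
    mask = patch.valid if patch.valid is not None else np.ones(px.shape, bool)
    m = px[mask].mean() if mask.any() else 0.0
    if m <= 0:
        raise ValueError("patch mean luminance is zero; cannot normalize")
    return replace(patch, pixels=px / m)


# ---------------------------------------------------------------------------
# Tangent warping


def _pix_to_centered(n: int) -> np.ndarray:
    c = (n - 1) / 2.0
    return np.array([[1.0, 0.0, -c], [0.0, -1.0, c], [0.0, 0.0, 1.0]])


def max_valid_warp_size(h: Homography, in_px: int) -> int:
    """Largest output size whose preimage under ``h`` fits in the source."""
    lo, hi = 0, in_px * 4
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _warp_corners_inside(h, in_px, mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def _warp_corners_inside(h: Homography, in_px: int, out_px: int) -> bool:
    half = (out_px - 1) / 2.0
    corners = np.array(
        [[-half, -half], [half, -half], [-half, half], [half, half],
         [0, -half], [0, half], [-half, 0], [half, 0]]
    )
    inv = np.linalg.inv(h.matrix)
    hom = np.concatenate([corners, np.ones((len(corners), 1))], axis=1) @ inv.T
    xy = hom[:, :2] / hom[:, 2:3]
    lim = (in_px - 1) / 2.0
    return bool(np.all(np.abs(xy) <= lim + 1e-9))


def warp_to_tangent(patch: ImagePatch, h: Homography, out_px: int) -> ImagePatch:
    """Warp a planar patch onto the tangent plane via the homography.

    Bilinear interpolation; output pixels whose preimage falls outside the
    source are marked invalid.  Raises if the requested output size exceeds
    the valid preimage region.
    """
    if patch.projection != "planar":
        raise ValueError("warp_to_tangent expects a planar patch")
    in_px = patch.patch_px
    if not _warp_corners_inside(h, in_px, out_px):
        raise ValueError(
            f"out_px={out_px} exceeds the valid preimage; "
            f"maximum valid size is {max_valid_warp_size(h, in_px)}"
        )
    C_in = _pix_to_centered(in_px)
    C_out = _pix_to_centered(out_px)
    # Output pixel -> centered tangent -> centered planar -> input pixel.
    M = np.linalg.inv(C_in) @ np.linalg.inv(h.matrix) @ C_out
    tf = ProjectiveTransform(matrix=M)
    gray = patch.pixels.ndim == 2
    img = patch.pixels if gray else patch.pixels
    out = warp(
        img, tf, output_shape=(out_px, out_px) if gray else (out_px, out_px, 3),
        order=1, mode="constant", cval=np.nan, preserve_range=True,
    )
    valid = ~np.isnan(out if gray else out[..., 0])
    out = np.nan_to_num(out, nan=0.0)
    return replace(patch, pixels=out, projection="tangent", valid=valid)


# ---------------------------------------------------------------------------
# Ensemble capture


@dataclass
class PatchEnsemble:
    """In-memory collection of luminance patches with a manifest."""

    patches: list
    manifest: "object"  # pandas.DataFrame

    def __len__(self):
        return len(self.patches)

    def select(self, **kv) -> list:
        """Patches whose manifest row matches all given column values."""
        m = self.manifest
        mask = np.ones(len(m), bool)
        for k, v in kv.items():
            mask &= (m[k] == v).to_numpy()
        return [self.patches[i] for i in np.where(mask)[0]]

    @classmethod
    def concatenate(cls, ensembles) -> "PatchEnsemble":
        """Pool several ensembles (e.g. from independent scenes) into one."""
        import pandas as pd

        ensembles = list(ensembles)
        if not ensembles:
            raise ValueError("need at least one ensemble")
        patches = [p for e in ensembles for p in e.patches]
        manifest = pd.concat([e.manifest for e in ensembles], ignore_index=True)
        return cls(patches, manifest)


def capture_ensemble(
    scene: ScenePrimitives,
    poses: list[Pose],
    gaze: GazeSpec,
    eye: EyeModel,
    grid: list[VisualFieldCoord],
    scene_resolution_px: int,
    fov_deg: float = 120.0,
    patch_px: int = 128,
    tangent_out_px: int | None = None,
    progress: bool = False,
) -> PatchEnsemble:
    """Render one planar luminance patch per (pose x grid position).

    If ``tangent_out_px`` is given, each planar patch also gets a
    tangent-projected twin via its homography.  Deterministic for fixed
    scene / trajectory / gaze seeds.
    """
    import pandas as pd

    if not grid:
        raise ValueError("visual-field grid is empty")
    rng = np.random.default_rng(gaze.seed)
    pitch = geom.pixel_pitch_mm(eye, scene_resolution_px, fov_deg)
    homs = {
        (c.eccentricity_deg, c.polar_angle_deg): geom.homography_for(c, eye, pitch)
        for c in grid
    } if tangent_out_px else {}
    patches, rows = [], []
    for pose in poses:
        view = apply_gaze(pose, gaze, rng)
        for c in grid:
            p = render_patch(
                scene, pose, view, c, eye, scene_resolution_px, fov_deg, patch_px
            )
            p = to_luminance(p)
            p.strategy = gaze.strategy
            p.species = eye.species
            patches.append(p)
            rows.append(
                dict(
                    pose_index=pose.timestamp_index, strategy=gaze.strategy,
                    species=eye.species, phi_deg=c.eccentricity_deg,
                    chi_deg=c.polar_angle_deg, projection="planar",
                    pixel_pitch_mm=pitch,
                )
            )
            if tangent_out_px:
                h = homs[(c.eccentricity_deg, c.polar_angle_deg)]
                tw = warp_to_tangent(p, h, tangent_out_px)
                patches.append(tw)
                rows.append(dict(rows[-1], projection="tangent"))
    return PatchEnsemble(patches, pd.DataFrame(rows))
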