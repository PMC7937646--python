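"""Procedural 3D scenes, avatar trajectories, and active gaze strategies.

The forest scene emulates a naturalistic wooded environment with analytic
primitives: a textured ground plane, vertical cylindrical trunks with bark
texture, and optional line-segment clutter (undergrowth).  A control scene of
randomly oriented 3D line segments isolates the purely projective component of
orientation statistics (the radial bias arises from perspective alone).

Trajectories are smooth correlated random walks sampled at a fixed 2 s
interval; gaze strategies map each locomotion pose to a viewing direction:

- ``straight``: gaze along the heading, zero elevation;
- ``down``: gaze along the heading, 30 degrees below horizontal;
- ``random``: heading and elevation offsets drawn i.i.d. from a standard
  normal in radians (SD = 1 rad = 57.30 degrees).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import EyeModel

__all__ = [
    "GroundParams",
    "ScenePrimitives",
    "Pose",
    "GazeSpec",
    "build_forest_scene",
    "build_random_edge_scene",
    "build_smooth_scene",
    "generate_trajectory",
    "apply_gaze",
    "RANDOM_GAZE_SD_DEG",
]

#: Standard-normal gaze offsets are drawn in radians; 1 rad = 57.30 degrees.
RANDOM_GAZE_SD_DEG = float(np.degrees(1.0))


@dataclass
class GroundParams:
    """Procedural ground-plane albedo parameters (units: meters)."""

    base_rgb: tuple = (0.30, 0.34, 0.22)
    noise_amp: float = 0.35
    noise_scale_m: float = 1.2
    octaves: int = 7
    gain: float = 0.55
    seed: int = 0
    # Track striping along a world direction plus perpendicular grass strokes;
    # lines parallel to the track converge to a vanishing point in perspective.
    stripe_amp: float = 0.0
    stripe_period_m: float = 0.5
    stripe_dir_deg: float = 0.0
    grass_amp: float = 0.0
    grass_scale_m: float = 0.25


@dataclass
class ScenePrimitives:
    """Analytic scene: ground plane (y = 0), vertical trunks, segment clutter."""

    seed: int
    ground: GroundParams | None
    # Trunks: arrays over n_trunks.
    trunk_x: np.ndarray = field(default_factory=lambda: np.zeros(0))
    trunk_z: np.ndarray = field(default_factory=lambda: np.zeros(0))
    trunk_radius: np.ndarray = field(default_factory=lambda: np.zeros(0))
    trunk_height: np.ndarray = field(default_factory=lambda: np.zeros(0))
    trunk_shade: np.ndarray = field(default_factory=lambda: np.zeros(0))
    # Clutter: line segments rendered as thin capsules.
    seg_p0: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    seg_p1: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    seg_width: np.ndarray = field(default_factory=lambda: np.zeros(0))
    seg_albedo: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sky_rgb: tuple = (0.78, 0.82, 0.88)
    bark_band_amp: float = 0.35
    bark_band_period_m: float = 0.6
    bark_noise_amp: float = 0.30
    #: Aerial-perspective attenuation length (m); 0 disables fog.
    fog_length_m: float = 120.0

    @property
    def n_trunks(self) -> int:
        return len(self.trunk_x)

    @property
    def n_segments(self) -> int:
        return len(self.seg_width)

    @property
    def segment_directions(self) -> np.ndarray:
        """Unit direction vectors of the clutter segments, shape (n, 3)."""
        d = self.seg_p1 - self.seg_p0
        n = np.linalg.norm(d, axis=1, keepdims=True)
        return d / np.where(n == 0, 1.0, n)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ScenePrimitives":
        d = dict(d)
        if d.get("ground") is not None:
            g = dict(d["ground"])
            g["base_rgb"] = tuple(g["base_rgb"])
            d["ground"] = GroundParams(**g)
        for k in (
            "trunk_x", "trunk_z", "trunk_radius", "trunk_height", "trunk_shade",
            "seg_p0", "seg_p1", "seg_width", "seg_albedo",
        ):
            d[k] = np.asarray(d[k], dtype=float)
        d["seg_p0"] = d["seg_p0"].reshape(-1, 3)
        d["seg_p1"] = d["seg_p1"].reshape(-1, 3)
        d["sky_rgb"] = tuple(d["sky_rgb"])
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "ScenePrimitives":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class Pose:
    """Avatar pose: eye position (m, y = eye height), ground-plane heading."""

    position_m: np.ndarray
    heading_deg: float
    timestamp_index: int


@dataclass(frozen=True)
class GazeSpec:
    """Active gaze strategy (``straight`` | ``down`` | ``random``)."""

    strategy: str
    elevation_offset_deg: float = -30.0
    random_sd_rad: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("straight", "down", "random"):
            raise ValueError(f"unknown gaze strategy {self.strategy!r}")


def build_forest_scene(
    seed: int,
    extent_m: float = 80.0,
    trunk_density_per_m2: float = 0.015,
    trunk_radius_range_m: tuple = (0.12, 0.40),
    trunk_height_range_m: tuple = (4.0, 14.0),
    branches_per_trunk: float = 8.0,
    log_density_per_m2: float = 0.003,
    n_clutter: int = 60,
    ground: GroundParams | None = None,
    track_striping: bool = True,
) -> ScenePrimitives:
    """Procedural forest: Poisson stand of vertical trunks over textured ground.

    Deterministic for a fixed seed.  Trunk count is Poisson with mean
    density * extent^2; positions are uniform over the square
    [-extent/2, extent/2]^2.  Sparse segment clutter stands in for undergrowth.
    """
    if extent_m <= 0:
        raise ValueError("extent_m must be positive")
    if trunk_density_per_m2 < 0:
        raise ValueError("trunk density must be nonnegative")
    rng = np.random.default_rng(seed)
    area = extent_m**2
    n = rng.poisson(trunk_density_per_m2 * area) if trunk_density_per_m2 > 0 else 0
    half = extent_m / 2.0
    tx = rng.uniform(-half, half, n)
    tz = rng.uniform(-half, half, n)
    tr = rng.uniform(*trunk_radius_range_m, n)
    th = rng.uniform(*trunk_height_range_m, n)
    shade = rng.uniform(0.7, 1.1, n)
    if ground is None:
        ground = GroundParams(seed=seed + 1)
        if track_striping:
            ground.stripe_amp = 0.22
            ground.grass_amp = 0.18
            ground.stripe_dir_deg = float(rng.uniform(0, 360))
    # Near-horizontal branches attached to the trunks (deadwood / limbs).
    p0s, p1s, sws, sas = [], [], [], []
    for k in range(n):
        nb = rng.poisson(branches_per_trunk)
        for _ in range(nb):
            hgt = rng.uniform(1.2, max(1.3, 0.8 * th[k]))
            az = rng.uniform(0, 2 * np.pi)
            tilt = rng.uniform(-0.12, 0.12)
            length = rng.uniform(1.0, 3.0)
            d = np.array(
                [np.cos(az) * np.cos(tilt), np.sin(tilt), np.sin(az) * np.cos(tilt)]
            )
            base = np.array([tx[k], hgt, tz[k]]) + d * tr[k]
            p0s.append(base)
            p1s.append(base + d * length)
            sws.append(rng.uniform(0.10, 0.25))
            sas.append(rng.uniform(0.12, 0.35))
    # Fallen logs: thick, nearly horizontal segments lying on the ground.
    n_logs = rng.poisson(log_density_per_m2 * area)
    for _ in range(n_logs):
        c = np.array([rng.uniform(-half, half), rng.uniform(0.1, 0.3),
                      rng.uniform(-half, half)])
        az = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(2.0, 6.0)
        d = np.array([np.cos(az), 0.0, np.sin(az)])
        p0s.append(c - 0.5 * length * d)
        p1s.append(c + 0.5 * length * d)
        sws.append(rng.uniform(0.2, 0.45))
        sas.append(rng.uniform(0.15, 0.4))
    # Undergrowth: short, low, randomly oriented-in-ground segments.
    for _ in range(n_clutter):
        c = np.array([rng.uniform(-half, half), rng.uniform(0.0, 0.6),
                      rng.uniform(-half, half)])
        az = rng.uniform(0, 2 * np.pi)
        tilt = rng.uniform(-0.4, 0.4)
        length = rng.uniform(0.3, 1.0)
        d = np.array(
            [np.cos(az) * np.cos(tilt), np.sin(tilt), np.sin(az) * np.cos(tilt)]
        )
        p0s.append(c)
        p1s.append(c + d * length)
        sws.append(rng.uniform(0.01, 0.04))
        sas.append(rng.uniform(0.15, 0.5))
    if p0s:
        p0 = np.array(p0s); p1 = np.array(p1s)
        sw = np.array(sws); sa = np.array(sas)
    else:
        p0 = np.zeros((0, 3)); p1 = np.zeros((0, 3))
        sw = np.zeros(0); sa = np.zeros(0)
    return ScenePrimitives(
        seed=seed, ground=ground,
        trunk_x=tx, trunk_z=tz, trunk_radius=tr, trunk_height=th, trunk_shade=shade,
        seg_p0=p0, seg_p1=p1, seg_width=sw, seg_albedo=sa,
    )


#: Vertical extent of the random-edge slab (meters relative to the ground
#: plane); symmetric enough about eye height that upper and lower visual
#: fields see comparable edge densities.
DEFAULT_EDGE_HEIGHT_RANGE_M = (-12.0, 15.0)


def build_random_edge_scene(
    seed: int,
    n_segments: int = 2000,
    box_half_extent_m: float = 25.0,
    height_range_m: tuple = DEFAULT_EDGE_HEIGHT_RANGE_M,
    length_range_m: tuple = (0.5, 2.0),
    width_m: float = 0.04,
) -> ScenePrimitives:
    """Control scene: line segments with i.i.d. uniform 3D orientations.

    No ground plane and no trunks; any orientation structure in rendered
    patches must come from the perspective projection, not the scene.  The
    vertical slab extends well above and below eye height so the upper and
    lower visual fields are sampled symmetrically.
    """
    if n_segments < 0:
        raise ValueError("n_segments must be nonnegative")
    rng = np.random.default_rng(seed)
    h = box_half_extent_m
    mid = np.stack(
        [
            rng.uniform(-h, h, n_segments),
            rng.uniform(*height_range_m, n_segments),
            rng.uniform(-h, h, n_segments),
        ],
        axis=1,
    )
    # Uniform directions on the sphere via normalized Gaussians.
    d = rng.standard_normal((n_segments, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    length = rng.uniform(*length_range_m, n_segments)
    p0 = mid - 0.5 * length[:, None] * d
    p1 = mid + 0.5 * length[:, None] * d
    albedo = rng.uniform(0.05, 0.45, n_segments)
    return ScenePrimitives(
        seed=seed, ground=None,
        seg_p0=p0, seg_p1=p1,
        seg_width=np.full(n_segments, width_m),
        seg_albedo=albedo,
        sky_rgb=(0.7, 0.7, 0.7),
    )


def build_smooth_scene(seed: int = 0) -> ScenePrimitives:
    """Smooth scene (low-frequency textured ground only) for warp oracles."""
    g = GroundParams(
        noise_amp=0.45, noise_scale_m=3.0, octaves=3, gain=0.5, seed=seed,
        stripe_amp=0.0, grass_amp=0.0,
    )
    return ScenePrimitives(seed=seed, ground=g)


def generate_trajectory(
    seed: int,
    n_poses: int,
    eye: EyeModel,
    speed_mps: float = 1.4,
    dt_s: float = 2.0,
    heading_sigma_deg: float = 15.0,
) -> list[Pose]:
    """Smooth correlated random walk at eye height, one pose every ``dt_s``.

    Heading increments are i.i.d. Normal(0, heading_sigma); consecutive
    positions are exactly ``speed * dt`` apart in the ground plane.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    rng = np.random.default_rng(seed)
    headings = np.cumsum(
        np.concatenate([[rng.uniform(0, 360)], rng.normal(0, heading_sigma_deg, n_poses - 1)])
    )
    step = speed_mps * dt_s
    hr = np.radians(headings)
    dx = np.cos(hr) * step
    dz = np.sin(hr) * step
    x = np.concatenate([[0.0], np.cumsum(dx[:-1])])
    z = np.concatenate([[0.0], np.cumsum(dz[:-1])])
    y = eye.eye_height_m
    return [
        Pose(np.array([x[i], y, z[i]]), float(headings[i] % 360.0), i)
        for i in range(n_poses)
    ]


def apply_gaze(
    pose: Pose, gaze: GazeSpec, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """Viewing direction (heading_deg, elevation_deg) for a pose.

    ``random`` draws heading and elevation offsets from Normal(0, sd) in
    radians from ``rng`` (required for that strategy).
    """
    if gaze.strategy == "straight":
        return (pose.heading_deg, 0.0)
    if gaze.strategy == "down":
        return (pose.heading_deg, gaze.elevation_offset_deg)
    if rng is None:
        rng = np.random.default_rng(gaze.seed)
    dh, de = np.degrees(rng.normal(0.0, gaze.random_sd_rad, 2))
    return (pose.heading_deg + float(dh), float(de))
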