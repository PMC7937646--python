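"""Orchestration: run configuration, visual-field grids, dataset generation,
per-position statistics, and strategy comparisons.

A run renders an ensemble of luminance patches (per pose x visual-field
position, optionally with tangent-projected twins), then aggregates
second-order (elliptical power-law spectrum fits, radial slopes) and
higher-order (edge orientation, von Mises) statistics per position, plus
cross-position summaries: circular correlations of spectral orientation and
edge mean against polar angle, paired planar-vs-tangent parameter deltas, and
per-position strategy tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import circular, edges, geometry as geom, imaging, scene as scene_mod, spectral
from .geometry import EyeModel, HUMAN_EYE, CAT_EYE, VisualFieldCoord
from .scene import GazeSpec

__all__ = [
    "RunConfig",
    "visual_field_grid",
    "run_generate",
    "run_generate_pooled",
    "run_stats",
    "compare_strategies",
    "eye_for_species",
    "save_ensemble",
    "load_ensemble",
]

#: Paper-scale defaults: 120-degree FOV at 5,954 px, 512-px capture patches,
#: 128-px analysis patches, eccentricities {0, 30, 50} x 8 polar angles,
#: 663 trajectory poses.
_DEFAULT_ECCS = (0.0, 30.0, 50.0)
_DEFAULT_CHIS = tuple(float(c) for c in range(0, 360, 45))


def eye_for_species(species: str) -> EyeModel:
    try:
        return {"human": HUMAN_EYE, "cat": CAT_EYE}[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}") from None


@dataclass
class RunConfig:
    """Configuration of a generation + analysis run (JSON round-trippable)."""

    species: str = "human"
    strategy: str = "straight"
    n_poses: int = 663
    scene_seed: int = 11
    trajectory_seed: int = 12
    gaze_seed: int = 13
    stats_seed: int = 14
    scene_resolution_px: int = 5954
    fov_deg: float = 120.0
    capture_patch_px: int = 512
    analysis_patch_px: int = 128
    eccentricities_deg: tuple = _DEFAULT_ECCS
    polar_angles_deg: tuple = _DEFAULT_CHIS
    projections: tuple = ("planar", "tangent")
    scene_kind: str = "forest"  # forest | random_edges | smooth
    b_mode: str = "divide"
    out_dir: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        d = json.loads(s)
        for k in ("eccentricities_deg", "polar_angles_deg", "projections"):
            d[k] = tuple(d[k])
        return cls(**d)

    @property
    def eye(self) -> EyeModel:
        return eye_for_species(self.species)

    @property
    def grid(self) -> list[VisualFieldCoord]:
        return visual_field_grid(self.eccentricities_deg, self.polar_angles_deg)


def visual_field_grid(eccentricities_deg, polar_angles_deg) -> list[VisualFieldCoord]:
    """Cartesian grid of visual-field coordinates, center collapsed.

    All eccentricity-0 entries are merged into the single degenerate center
    coordinate; ordering is eccentricity-ascending then polar-angle-ascending.
    """
    eccs = list(eccentricities_deg)
    chis = list(polar_angles_deg)
    if not eccs or not chis:
        raise ValueError("eccentricity and polar-angle lists must be nonempty")
    if len(set(eccs)) != len(eccs) or len(set(chis)) != len(chis):
        warnings.warn("duplicate grid values deduplicated", stacklevel=2)
        eccs, chis = sorted(set(eccs)), sorted(set(chis))
    out = []
    for phi in sorted(eccs):
        if phi == 0.0:
            out.append(VisualFieldCoord(0.0))
        else:
            for chi in sorted(chis):
                out.append(VisualFieldCoord(phi, chi))
    return out


def _build_scene(config: RunConfig, poses):
    # Size the scene to cover the trajectory plus a viewing margin, so long
    # walks never leave the populated region.
    xy = np.array([p.position_m[[0, 2]] for p in poses])
    if config.scene_kind == "forest":
        half = float(np.abs(xy).max()) + 80.0
        return scene_mod.build_forest_scene(config.scene_seed, extent_m=2 * half)
    if config.scene_kind == "random_edges":
        half = float(np.abs(xy).max()) + 60.0
        # Constant volumetric segment density (0.08 per m^3), so patch-level
        # edge counts do not depend on how large the slab must be to cover
        # the trajectory.
        lo, hi = scene_mod.DEFAULT_EDGE_HEIGHT_RANGE_M
        n = int(0.08 * (2.0 * half) ** 2 * (hi - lo))
        return scene_mod.build_random_edge_scene(
            config.scene_seed, n_segments=n, box_half_extent_m=half,
        )
    if config.scene_kind == "smooth":
        return scene_mod.build_smooth_scene(config.scene_seed)
    raise ValueError(f"unknown scene kind {config.scene_kind!r}")


def run_generate(config: RunConfig, scene=None) -> imaging.PatchEnsemble:
    """Build scene + trajectory + gaze and capture the patch ensemble."""
    eye = config.eye
    poses = scene_mod.generate_trajectory(config.trajectory_seed, config.n_poses, eye)
    if scene is None:
        scene = _build_scene(config, poses)
    gaze = GazeSpec(config.strategy, seed=config.gaze_seed)
    tangent = config.analysis_patch_px if "tangent" in config.projections else None
    ens = imaging.capture_ensemble(
        scene, poses, gaze, eye, config.grid,
        config.scene_resolution_px, config.fov_deg, config.capture_patch_px,
        tangent_out_px=tangent,
    )
    if config.out_dir:
        save_ensemble(ens, config.out_dir, config)
    return ens


def run_generate_pooled(config: RunConfig, n_scenes: int) -> imaging.PatchEnsemble:
    """Pool ensembles from ``n_scenes`` independent scene/trajectory draws.

    Patches captured along one walk through one scene re-view the same
    surfaces from nearby poses, so the effective sample size for ensemble
    statistics grows slowly with pose count.  Pooling a few short walks
    through independently seeded scenes decorrelates the ensemble at the
    same render cost.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be at least 1")
    parts = []
    for k in range(n_scenes):
        c = replace(
            config,
            scene_seed=config.scene_seed + 1000 * k,
            trajectory_seed=config.trajectory_seed + 1000 * k,
            gaze_seed=config.gaze_seed + 1000 * k,
            out_dir=None,
        )
        parts.append(run_generate(c))
    return imaging.PatchEnsemble.concatenate(parts)


def _central_crop(img: np.ndarray, size: int) -> np.ndarray:
    n = img.shape[0]
    if size > n:
        raise ValueError("analysis patch larger than capture patch")
    o = (n - size) // 2
    return img[o : o + size, o : o + size]


def analysis_patches(ensemble, config: RunConfig, projection: str, coord):
    """Central-crop analysis-size luminance patches for one grid position."""
    sel = ensemble.select(
        phi_deg=coord.eccentricity_deg, chi_deg=coord.polar_angle_deg,
        projection=projection,
    )
    return [_central_crop(p.gray, config.analysis_patch_px) for p in sel]


def position_statistics(
    ensemble, config: RunConfig, projection: str = "planar",
    keep_angles: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-position spectral and edge statistics for one projection.

    Returns a table (one row per grid position) and, when ``keep_angles``,
    a dict of raw edge-orientation samples keyed by (phi, chi).
    """
    win = spectral.radial_hamming_window(config.analysis_patch_px)
    rows, samples = [], {}
    for coord in config.grid:
        imgs = analysis_patches(ensemble, config, projection, coord)
        if not imgs:
            continue
        ps = spectral.mean_power_spectrum(imgs, win)
        fit = spectral.fit_elliptical_powerlaw(ps, b_mode=config.b_mode)
        prof = spectral.radial_average(ps)
        sets = [edges.extract_orientations(img) for img in imgs]
        eset = edges.EdgePixelSet.concatenate([s for s in sets if len(s)])
        # Image-orientation equivalent of the spectral ellipse angle.  In the
        # "divide" parametrization the fitted theta marks the spectral ridge,
        # which lies perpendicular to the dominant image orientation; the FFT
        # angle is additionally mirrored because the image row axis points
        # down while orientations are reported y-up.  Net map: 90 - theta.
        theta_edge = (
            (90.0 - fit.theta_deg) % 180.0 if config.b_mode == "divide"
            else (-fit.theta_deg) % 180.0
        )
        row = dict(
            phi_deg=coord.eccentricity_deg, chi_deg=coord.polar_angle_deg,
            projection=projection, n_images=len(imgs),
            A=fit.A, b=fit.b, beta=fit.beta, theta_deg=fit.theta_deg,
            theta_edge_deg=theta_edge, elongation=1.0 / fit.b,
            residual=fit.residual, isotropic=fit.isotropic, alpha=prof.alpha,
            n_edges=len(eset),
        )
        if len(eset) >= 10:
            vm = circular.fit_von_mises(eset.orientations_deg)
            row.update(mu_deg=vm.mu_deg, kappa=vm.kappa, kappa2=vm.kappa2)
        else:
            row.update(mu_deg=np.nan, kappa=np.nan, kappa2=np.nan)
            warnings.warn(
                f"position (phi={coord.eccentricity_deg}, chi={coord.polar_angle_deg})"
                " has too few edges; skipped von Mises fit", stacklevel=2,
            )
        rows.append(row)
        if keep_angles:
            samples[(coord.eccentricity_deg, coord.polar_angle_deg)] = (
                eset.orientations_deg
            )
    return pd.DataFrame(rows), samples


def radial_bias_summary(
    table: pd.DataFrame, phi_deg: float, stats_seed: int = 0,
    n_permutations: int = 9999,
) -> dict:
    """Circular correlation of fitted orientations against polar angle.

    Tests both the spectral ellipse orientation theta and the edge-histogram
    mean mu at one eccentricity ring.  Orientations are axial (period 180),
    and a radial bias predicts orientation = chi mod 180, so the polar angle
    is treated axially too: both variables are angle-doubled before the
    Jammalamadaka-SenGupta correlation.
    """
    ring = table[table.phi_deg == phi_deg].sort_values("chi_deg")
    out = {}
    for col, key in (("theta_edge_deg", "theta"), ("mu_deg", "mu")):
        vals = ring[col].to_numpy()
        ok = np.isfinite(vals)
        res = circular.circular_correlation(
            vals[ok], ring.chi_deg.to_numpy()[ok], a_axial=True, b_axial=True,
            seed=stats_seed, alternative="greater",
            n_permutations=n_permutations,
        )
        out[key] = res
    return out


def projection_contrast(planar: pd.DataFrame, tangent: pd.DataFrame) -> pd.DataFrame:
    """Paired per-position deltas of the spectral fit between projections."""
    keys = ["phi_deg", "chi_deg"]
    m = planar.merge(tangent, on=keys, suffixes=("_planar", "_tangent"))
    for par in ("A", "b", "beta", "theta_deg"):
        m[f"d_{par}"] = m[f"{par}_tangent"] - m[f"{par}_planar"]
    return m


def upper_lower_asymmetry(table: pd.DataFrame, param: str) -> pd.DataFrame:
    """Per-position |upper - lower| field asymmetry of a fitted parameter.

    Pairs each position at polar angle chi in (0, 180) with its mirror at
    360 - chi (reflection about the horizontal meridian).
    """
    t = table[table.phi_deg > 0]
    rows = []
    for (phi, chi), grp in t.groupby(["phi_deg", "chi_deg"]):
        if not 0 < chi < 180:
            continue
        mirror = t[(t.phi_deg == phi) & (t.chi_deg == (360 - chi) % 360)]
        if len(mirror) != 1:
            continue
        rows.append(dict(
            phi_deg=phi, chi_deg=chi,
            asymmetry=abs(grp[param].iloc[0] - mirror[param].iloc[0]),
        ))
    return pd.DataFrame(rows)


def run_stats(ensemble, config: RunConfig, keep_angles: bool = False):
    """Full per-position report for every configured projection."""
    tables, samples = [], {}
    for proj in config.projections:
        t, s = position_statistics(ensemble, config, proj, keep_angles=keep_angles)
        tables.append(t)
        samples[proj] = s
    report = pd.concat(tables, ignore_index=True)
    return (report, samples) if keep_angles else report


def compare_strategies(
    strategy_samples: dict, alpha_flag: float = 0.01
) -> pd.DataFrame:
    """Per-position Watson-Williams and pairwise Kuiper tests across strategies.

    ``strategy_samples`` maps strategy label -> {(phi, chi): orientation
    angles}.  Positions present in every strategy are compared; a position is
    flagged when every pairwise Kuiper p-value is below ``alpha_flag``.
    """
    names = sorted(strategy_samples)
    if len(names) < 2:
        raise ValueError("need at least two strategies")
    grids = [set(strategy_samples[n]) for n in names]
    common = set.intersection(*grids)
    if any(g != grids[0] for g in grids):
        raise ValueError("strategy reports use different grids")
    rows = []
    for pos in sorted(common):
        groups = [strategy_samples[n][pos] for n in names]
        if any(len(g) < 10 for g in groups):
            continue
        ww = circular.watson_williams(groups, axial=True)
        row = dict(phi_deg=pos[0], chi_deg=pos[1], ww_F=ww.F, ww_p=ww.p_value)
        kuiper_ps = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                kp = circular.kuiper_two_sample(groups[i], groups[j], axial=True)
                row[f"kuiper_p_{names[i]}_{names[j]}"] = kp.p_value
                kuiper_ps.append(kp.p_value)
        row["significant"] = bool(np.all(np.array(kuiper_ps) < alpha_flag))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Patch store (plain files: 16-bit PNGs + manifest.csv + config.json)


def save_ensemble(ensemble, out_dir: str, config: RunConfig | None = None) -> None:
    import os

    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    manifest = ensemble.manifest.copy()
    names = []
    for i, p in enumerate(ensemble.patches):
        name = f"patch_{i:06d}.png"
        arr = p.gray if p.pixels.ndim == 2 else p.pixels
        scale = arr.max() if arr.max() > 0 else 1.0
        iio.imwrite(
            os.path.join(out_dir, name),
            np.clip(arr / scale * 65535, 0, 65535).astype(np.uint16),
        )
        names.append(name)
    manifest["filename"] = names
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    if config is not None:
        with open(os.path.join(out_dir, "config.json"), "w") as fh:
            fh.write(config.to_json())


def load_ensemble(out_dir: str) -> imaging.PatchEnsemble:
    import os

    import imageio.v3 as iio

    manifest = pd.read_csv(os.path.join(out_dir, "manifest.csv"))
    patches = []
    for _, row in manifest.iterrows():
        arr = iio.imread(os.path.join(out_dir, row["filename"])).astype(float) / 65535
        patches.append(
            imaging.ImagePatch(
                arr, row["pixel_pitch_mm"], row["projection"],
                VisualFieldCoord(row["phi_deg"], row["chi_deg"]),
                int(row["pose_index"]), row["strategy"], row["species"],
            )
        )
    return imaging.PatchEnsemble(patches, manifest)
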