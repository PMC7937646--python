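"""Shared fixtures: small rendered ensembles reused across test modules.

Rendering is the expensive part of the suite, so every ensemble is built once
per session at a reduced problem size (1,024-px frames, 48-64 px patches, a
few pooled scenes) and shared between the unit, property, and acceptance
tests that need it.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from retinastats import pipeline as pl  # noqa: E402

CHIS = tuple(float(c) for c in range(0, 360, 45))


@pytest.fixture(scope="session")
def radial_run():
    """Random-edge ensemble at phi in {30, 50} plus its per-position table."""
    cfg = pl.RunConfig(
        n_poses=10, scene_resolution_px=1024, capture_patch_px=64,
        analysis_patch_px=64, projections=("planar",),
        eccentricities_deg=(30.0, 50.0), polar_angles_deg=CHIS,
        scene_kind="random_edges", strategy="straight",
    )
    ens = pl.run_generate_pooled(cfg, n_scenes=4)
    table, samples = pl.position_statistics(ens, cfg, "planar", keep_angles=True)
    return cfg, table, samples


@pytest.fixture(scope="session")
def cardinal_angles():
    """Edge orientations at the visual-field center of pooled forest walks."""
    cfg = pl.RunConfig(
        n_poses=16, scene_resolution_px=1024, capture_patch_px=64,
        analysis_patch_px=64, projections=("planar",),
        eccentricities_deg=(0.0,), polar_angles_deg=(0.0,),
        scene_kind="forest", strategy="straight",
    )
    ens = pl.run_generate_pooled(cfg, n_scenes=2)
    _, samples = pl.position_statistics(ens, cfg, "planar", keep_angles=True)
    return samples[(0.0, 0.0)]


@pytest.fixture(scope="session")
def strategy_samples():
    """Per-strategy edge-orientation samples on the phi=30 forest ring."""
    common = dict(
        n_poses=12, scene_resolution_px=1024, capture_patch_px=64,
        analysis_patch_px=64, projections=("planar",),
        eccentricities_deg=(30.0,), polar_angles_deg=CHIS,
        scene_kind="forest",
    )
    out = {}
    for strat in ("straight", "down"):
        cfg = pl.RunConfig(strategy=strat, **common)
        ens = pl.run_generate_pooled(cfg, n_scenes=3)
        _, s = pl.position_statistics(ens, cfg, "planar", keep_angles=True)
        out[strat] = s
    return out


@pytest.fixture(scope="session")
def projection_tables():
    """Planar and tangent per-position tables from one forest ensemble.

    The capture/analysis size ratio (224/48) leaves enough planar support for
    the tangent warp at phi=50 on all polar angles.
    """
    cfg = pl.RunConfig(
        n_poses=8, scene_resolution_px=1024, capture_patch_px=224,
        analysis_patch_px=48, projections=("planar", "tangent"),
        eccentricities_deg=(30.0, 50.0), polar_angles_deg=CHIS,
        scene_kind="forest", strategy="straight",
    )
    ens = pl.run_generate_pooled(cfg, n_scenes=2)
    tp, _ = pl.position_statistics(ens, cfg, "planar")
    tt, _ = pl.position_statistics(ens, cfg, "tangent")
    return cfg, tp, tt
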