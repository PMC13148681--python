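"""Shared fixtures: small synthetic scenes and tides built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from fjordcam import synthetic as syn


@pytest.fixture(scope="session")
def short_tide() -> syn.TideSeries:
    """Two-and-a-bit M2 cycles at 1-min sampling, no envelope, no noise."""
    return syn.generate_tide(
        duration_s=2 * syn.T_M2_H * 3600 + 7200, spring_neap_mod=0.0, seed=0
    )


@pytest.fixture(scope="session")
def small_scene(short_tide):
    """Sparse, well-separated scene without static structures.

    320x240 px, expected 20 particles/frame, radii 2-3 px, three 10-frame
    segments — small enough to quantify exhaustively.
    """
    cfg = syn.SceneConfig(
        width=320,
        height=240,
        total_hours=1.0,
        frames_per_segment=10,
        particle_density=20,
        radius_range=(2.0, 3.0),
        background_elements=(),
        seed=5,
    )
    segments, truth = syn.generate_scene(cfg, short_tide)
    return cfg, segments, truth


@pytest.fixture(scope="session")
def structured_scene(short_tide):
    """Scene with the static mooring line and reflector present."""
    cfg = syn.SceneConfig(
        width=320,
        height=240,
        total_hours=0.5,
        frames_per_segment=10,
        particle_density=30,
        seed=11,
    )
    segments, truth = syn.generate_scene(cfg, short_tide)
    return cfg, segments, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def margin_particle_image(
    shape: tuple[int, int],
    n: int = 150,
    grid: int = 32,
    margin: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Bright Gaussian discs kept ``margin`` px away from every multiple of
    ``grid`` in both axes, so interrogation-window borders never cut a
    particle. Used by the PIV shift oracles.
    """
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    h, w = shape
    for _ in range(n):
        r = int(rng.integers(margin, grid - margin) + rng.integers(0, h // grid) * grid)
        c = int(rng.integers(margin, grid - margin) + rng.integers(0, w // grid) * grid)
        if r + 5 >= h or c + 5 >= w or r < 5 or c < 5:
            continue
        yy, xx = np.mgrid[r - 4:r + 5, c - 4:c + 5]
        img[r - 4:r + 5, c - 4:c + 5] += 150 * np.exp(
            -((xx - c) ** 2 + (yy - r) ** 2) / 2.0
        )
    return img
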