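"""Shared fixtures: parametric hook fixtures and preset measurement tables."""

from __future__ import annotations

import numpy as np
import pytest

from hookmorph.synthetic import (HookShapeParams, build_hook_outline,
                                 generate_measurements, species_presets)


def random_shape_params(rng: np.random.Generator, resolution: tuple[int, int] = (400, 600),
                        posed: bool = True) -> HookShapeParams:
    """Draw hook-shape parameters from the validated fixture family.

    The family spans long-shaft, recurved-blade hooks with a pronounced
    heel knob — the configuration in which every zenith of the measurement
    scheme is an interior maximum of its search window.
    """
    pose = ((rng.uniform(0.0, 360.0), rng.uniform(-50.0, 50.0),
             rng.uniform(-50.0, 50.0)) if posed else (0.0, 0.0, 0.0))
    return HookShapeParams(
        shaft_length=rng.uniform(14.0, 18.0),
        shaft_width_proximal=rng.uniform(2.0, 2.8),
        shaft_width_distal=rng.uniform(1.3, 1.9),
        blade_inner_radius=rng.uniform(2.2, 3.2),
        blade_arc_degrees=rng.uniform(175.0, 205.0),
        point_taper_fraction=rng.uniform(0.25, 0.45),
        handle_length=rng.uniform(35.0, 65.0),
        heel_bulge_height=rng.uniform(2.6, 3.4),
        heel_bulge_position=rng.uniform(0.10, 0.16),
        resolution=int(rng.integers(*resolution)),
        rigid_pose=pose,
    )


@pytest.fixture(scope="session")
def default_hook():
    """Default parametric hook with brute-force ground truth."""
    outline, landmarks, measurements = build_hook_outline(HookShapeParams())
    return outline, landmarks, measurements


@pytest.fixture(scope="session")
def preset_table():
    """One synthetic measurement table at the published group sizes (8/4/5)."""
    return generate_measurements(species_presets(), seed=1)
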