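"""Shared fixtures: rendered synthetic runs reused across test modules.

The heavier fixtures (a 200-cell unbiased recovery run, a 100-cell biased
end-to-end run) are session-scoped so each is computed once.
"""

import numpy as np
import pytest

from neuriteguide import (
    CellRejected,
    RunConfig,
    analyze_cell,
    generate_scenes,
    render_scene,
    run_synthetic,
    segment_frame,
)
from neuriteguide.evaluation import recovery_table
from neuriteguide.synthetic import SyntheticCellSpec, _chord_angles, _make_waypoints


def measure_scene(scene):
    """Segment a scene and measure every accepted cell."""
    masks = segment_frame(scene.image)
    measured = []
    for k, mask in enumerate(masks):
        try:
            measured.append(analyze_cell(mask, cell_id=str(k), pixel_size_um=scene.image.pixel_size_um))
        except CellRejected:
            pass
    return measured


@pytest.fixture(scope="session")
def recovery_run():
    """200 unbiased synthetic cells, measured and matched to ground truth."""
    scenes = generate_scenes(200, 0.0, rng_seed=101, curl_sd_deg=3.0)
    results = [measure_scene(s) for s in scenes]
    table = recovery_table(scenes, results)
    return scenes, results, table


@pytest.fixture(scope="session")
def biased_run():
    """End-to-end pipeline run on 100 cells biased toward the gradient."""
    config = RunConfig(rng_seed=11)
    result, scenes = run_synthetic(config, 100, bias_kappa=2.0)
    return result, scenes


def make_single_cell(angle_deg=37.0, length_px=120.0, curl_sd_deg=4.0, center=(300.0, 310.0),
                     soma_radius=35.0, rng_seed=0, n_branches=0, branch_waypoints=()):
    """One hand-placed cell spec with ground-truth chord angles."""
    rng = np.random.default_rng(rng_seed)
    rad = np.deg2rad(angle_deg)
    rim = (center[0] + soma_radius * np.cos(rad), center[1] - soma_radius * np.sin(rad))
    waypoints = _make_waypoints(rim, angle_deg, length_px, curl_sd_deg, rng)
    ti, tt = _chord_angles(waypoints)
    return SyntheticCellSpec(
        soma_center=center,
        soma_radius_px=soma_radius,
        neurite_waypoints=waypoints,
        true_initiation_angle_deg=ti,
        true_terminal_angle_deg=tt,
        true_path_length_px=length_px,
        n_branches=n_branches,
        branch_waypoints=list(branch_waypoints),
    )


@pytest.fixture(scope="session")
def single_cell_scene():
    """A single curved cell at an oblique angle in a 600x600 frame."""
    cell = make_single_cell()
    return render_scene([cell], image_shape_px=(600, 600), noise_sd=0.02, rng_seed=9)
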