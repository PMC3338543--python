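"""Scoring pipeline output against synthetic ground truth.

Measured cells are matched to the generator's cell specs by nearest soma
centre within a scene; matched pairs yield circular angle errors, centroid
displacement, relative path-length error and direction-class agreement.
This is how the package quantifies its own accuracy, since no annotated
real micrographs exist.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import DEFAULT_RESTRICTION_ANGLE, classify_direction

__all__ = ["circular_difference_deg", "recovery_table", "recovery_summary"]


def circular_difference_deg(a, b):
    """Signed smallest difference a - b on the circle, in (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(d == -180.0, 180.0, d)


def recovery_table(
    scenes,
    results_per_scene,
    match_radius_px: float = 30.0,
    pixel_size_um: float = 0.371,
) -> pd.DataFrame:
    """Match measured cells to ground truth, one row per matched cell.

    ``results_per_scene`` is a sequence (parallel to ``scenes``) of lists
    of :class:`~neuriteguide.morphometry.CellMorphometry`.  A measured
    cell matches the nearest true soma centre if within
    ``match_radius_px``; unmatched measurements are dropped (they are
    segmentation artefacts, counted by the caller if needed).  Lengths
    are compared on the Euclidean geodesic (the ground-truth path length
    is a Euclidean arclength, so step counts would undercount diagonal
    paths by up to sqrt(2)).
    """
    rows = []
    for scene, measured in zip(scenes, results_per_scene):
        truth_centers = np.array([c.soma_center for c in scene.cells], dtype=float)
        for m in measured:
            cx, cy = m.soma_centroid_xy_px
            if len(truth_centers) == 0:
                continue
            d = np.hypot(truth_centers[:, 0] - cx, truth_centers[:, 1] - cy)
            j = int(np.argmin(d))
            if d[j] > match_radius_px:
                continue
            truth = scene.cells[j]
            rows.append(
                {
                    "centroid_error_px": float(d[j]),
                    "initiation_error_deg": float(
                        circular_difference_deg(
                            m.initiation_angle_deg, truth.true_initiation_angle_deg
                        )
                    ),
                    "terminal_error_deg": float(
                        circular_difference_deg(
                            m.terminal_angle_deg, truth.true_terminal_angle_deg
                        )
                    ),
                    "length_rel_error": float(
                        (m.neurite_length_um / pixel_size_um - truth.true_path_length_px)
                        / truth.true_path_length_px
                    ),
                    "true_initiation_angle_deg": truth.true_initiation_angle_deg,
                    "measured_initiation_angle_deg": m.initiation_angle_deg,
                    "n_branch_points": m.n_branch_points,
                    "true_n_branches": truth.n_branches,
                }
            )
    return pd.DataFrame(rows)


def recovery_summary(
    table: pd.DataFrame,
    angle_tol_deg: float = 10.0,
    centroid_tol_px: float = 3.0,
    length_tol: float = 0.10,
    restriction_deg: float = DEFAULT_RESTRICTION_ANGLE,
    boundary_margin_deg: float = 10.0,
) -> dict:
    """Aggregate recovery rates from a matched table.

    Direction-class agreement is evaluated only for cells whose true
    angle lies more than ``boundary_margin_deg`` from a sector boundary,
    where the class is unambiguous.
    """
    if len(table) == 0:
        raise ValueError("empty recovery table")
    init_ok = np.abs(table["initiation_error_deg"]) <= angle_tol_deg
    term_ok = np.abs(table["terminal_error_deg"]) <= angle_tol_deg
    cent_ok = table["centroid_error_px"] <= centroid_tol_px
    len_ok = np.abs(table["length_rel_error"]) <= length_tol

    boundaries = np.array(
        [180.0 - restriction_deg / 2.0, restriction_deg / 2.0]
    )
    true_abs = np.abs(table["true_initiation_angle_deg"].to_numpy())
    clear = np.min(np.abs(true_abs[:, None] - boundaries[None, :]), axis=1) > boundary_margin_deg
    agree = np.array(
        [
            classify_direction(m, restriction_deg) == classify_direction(t, restriction_deg)
            for m, t in zip(
                table["measured_initiation_angle_deg"], table["true_initiation_angle_deg"]
            )
        ]
    )
    return {
        "n_matched": int(len(table)),
        "initiation_within_tol": float(init_ok.mean()),
        "terminal_within_tol": float(term_ok.mean()),
        "centroid_within_tol": float(cent_ok.mean()),
        "length_within_tol": float(len_ok.mean()),
        "n_clear_of_boundary": int(clear.sum()),
        "class_agreement_clear": float(agree[clear].mean()) if clear.any() else float("nan"),
        "median_centroid_error_px": float(table["centroid_error_px"].median()),
        "median_abs_initiation_error_deg": float(np.abs(table["initiation_error_deg"]).median()),
    }
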