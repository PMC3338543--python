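"""Synthetic bright-field scenes with exact ground truth.

Real micrographs of neuron-like cells on protein gradients come with no
annotation, so this module is the test bed for the whole pipeline: it
generates linear-gradient geometry, populations of cells whose neurite
initiation angles follow a von Mises distribution centred on the
increasing-concentration direction (kappa = 0 giving the unbiased uniform
control), and renders them with the minimal bright-field intensity model
that makes edge detection well-posed — mid-gray background, dark cell
interiors, a thin bright halo at every cell boundary, additive Gaussian
noise.

Every generated quantity (soma centre, waypoints, initiation/terminal
angle by the same 45-px chord rule the measurement uses, path length,
branch count) is recorded in the scene, so downstream stages can be
scored against exact truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import draw, morphology

from ._angles import unit_vector, vector_angle_deg, wrap_deg
from .segmentation import DEFAULT_PIXEL_SIZE_UM, ImageFrame

__all__ = [
    "GradientSpec",
    "SyntheticCellSpec",
    "SyntheticScene",
    "PlacementError",
    "make_gradient_pair",
    "sample_population",
    "render_scene",
    "generate_scenes",
    "save_scene",
    "load_scene",
]

# Intensity model (normalized units). Bright-field imaging shows
# low-contrast cells; what matters here is only that interiors are darker
# than background and boundaries carry a bright halo so the Sobel stage
# sees a closed contour.
BACKGROUND_LEVEL = 0.5
INTERIOR_LEVEL = 0.22
HALO_LEVEL = 0.88
HALO_WIDTH_PX = 2
TUBE_RADIUS_PX = 2  # rendered neurite tubes are ~5 px wide

DEFAULT_SOMA_RADIUS_PX = 35
DEFAULT_NEURITE_LENGTH_RANGE = (100.0, 160.0)
MIN_LENGTH_WITH_BRANCHES = 130.0


class PlacementError(RuntimeError):
    """Raised when somata cannot be placed without overlap."""


@dataclass(frozen=True)
class GradientSpec:
    """A linear ramp of substrate-bound protein concentration.

    Concentration rises linearly from 0 at the shallow end to
    ``max_level`` over ``span_um`` micrometres along ``direction`` (an
    axis-aligned unit vector in (x, y); the canonical orientation is
    (-1, 0), increasing toward the left image edge).
    """

    span_um: float
    max_level: float = 1.0
    direction: tuple = (-1, 0)

    def __post_init__(self):
        if not self.span_um > 0:
            raise ValueError("span_um must be positive")
        if self.max_level < 0:
            raise ValueError("max_level must be non-negative")

    @property
    def slope(self) -> float:
        """Concentration change per micrometre."""
        return self.max_level / self.span_um

    def concentration(self, offset_um) -> np.ndarray | float:
        """Concentration at an offset (um) along ``direction`` from the low end."""
        c = self.max_level * np.asarray(offset_um, dtype=float) / self.span_um
        c = np.clip(c, 0.0, self.max_level)
        return float(c) if np.ndim(offset_um) == 0 else c


def make_gradient_pair(total_span_um: float, max_level: float = 1.0):
    """Split a linear profile at its first quartile into a steep and a shallow ramp.

    The left quarter of the profile climbs to ``max_level`` over a quarter
    of the span and the remaining three quarters over the rest, so the
    steep ramp's slope is exactly three times the shallow one's
    (592 um total gives the 148 um / 444 um pair).
    """
    if not total_span_um > 0:
        raise ValueError("total_span_um must be positive")
    if not max_level > 0:
        raise ValueError("max_level must be positive: a flat profile has no defined slope ratio")
    high = GradientSpec(span_um=total_span_um / 4.0, max_level=max_level)
    low = GradientSpec(span_um=3.0 * total_span_um / 4.0, max_level=max_level)
    return high, low


@dataclass
class SyntheticCellSpec:
    """Ground truth for one rendered cell."""

    soma_center: tuple  # (x, y) px
    soma_radius_px: float
    neurite_waypoints: list  # [(x, y), ...] from the soma rim to the tip
    true_initiation_angle_deg: float
    true_terminal_angle_deg: float
    true_path_length_px: float
    n_branches: int = 0
    branch_waypoints: list = field(default_factory=list)  # list of [(x, y), ...]

    def __post_init__(self):
        if self.neurite_waypoints:
            x0, y0 = self.neurite_waypoints[0]
            rim_err = abs(
                np.hypot(x0 - self.soma_center[0], y0 - self.soma_center[1]) - self.soma_radius_px
            )
            if rim_err > 0.51:
                raise ValueError(f"first waypoint is {rim_err:.2f} px off the soma rim")
        if self.true_path_length_px < 0:
            raise ValueError("true_path_length_px must be >= 0")
        for name in ("true_initiation_angle_deg", "true_terminal_angle_deg"):
            a = getattr(self, name)
            if not (-180.0 < a <= 180.0):
                raise ValueError(f"{name}={a} outside (-180, 180]")


@dataclass
class SyntheticScene:
    image: ImageFrame
    cells: list
    gradient: GradientSpec | None
    noise_sd: float
    rng_seed: int


def _resample_polyline(points: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Resample an (n, 2) polyline at equal arclength steps (endpoint kept)."""
    pts = np.asarray(points, dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return pts[:1]
    s = np.arange(0.0, total, step)
    s = np.append(s, total)
    return np.column_stack([np.interp(s, arc, pts[:, 0]), np.interp(s, arc, pts[:, 1])])


def _chord_angles(waypoints, chord_px: float = 45.0):
    """Initiation/terminal angles of a polyline by the 45-px chord rule.

    Uses the same definition as the measurement code: direction from the
    start to the point ``chord_px`` along the arc, and from the point
    ``chord_px`` before the end to the end.  Falls back to the full chord
    for polylines shorter than ``chord_px``.
    """
    dense = _resample_polyline(np.asarray(waypoints, dtype=float), step=1.0)
    n = len(dense)
    k = min(int(round(chord_px)), n - 1)
    initiation = vector_angle_deg(dense[0], dense[k])
    terminal = vector_angle_deg(dense[n - 1 - k], dense[n - 1])
    return initiation, terminal


def _make_waypoints(origin_xy, angle_deg, length_px, curl_sd_deg, rng, segment_px=45.0):
    """Piecewise-linear neurite: 45-px segments with a random turn between them."""
    pts = [np.asarray(origin_xy, dtype=float)]
    heading = float(angle_deg)
    remaining = float(length_px)
    while remaining > 1e-9:
        step = min(segment_px, remaining)
        dx, dy = unit_vector(heading)
        pts.append(pts[-1] + step * np.array([dx, dy]))
        remaining -= step
        if remaining > 0 and curl_sd_deg > 0:
            heading = wrap_deg(heading + rng.normal(0.0, curl_sd_deg))
    return [tuple(map(float, p)) for p in pts]


def sample_population(
    n_cells: int,
    bias_kappa: float,
    spec: GradientSpec | None = None,
    rng_seed: int = 0,
    *,
    image_shape_px: tuple = (1200, 1200),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    soma_radius_px: float = DEFAULT_SOMA_RADIUS_PX,
    neurite_length_range_px: tuple = DEFAULT_NEURITE_LENGTH_RANGE,
    curl_sd_deg: float = 3.0,
    n_branches: int = 0,
    min_center_distance_factor: float = 2.5,
    position_density: str = "uniform",
    max_retries: int = 1000,
) -> list[SyntheticCellSpec]:
    """Draw a population of synthetic cells with a tunable directional bias.

    Initiation angles follow a von Mises distribution centred on 180
    degrees (the increasing-concentration direction in canonical
    orientation) with concentration ``bias_kappa``; ``bias_kappa = 0`` is
    the uniform circular distribution.  Somata are placed by rejection
    sampling with a minimum centre distance of
    ``min_center_distance_factor`` soma radii, inside a margin wide enough
    that no rendered footprint can leave the frame regardless of neurite
    direction (so placement cannot bias the angle distribution).

    ``position_density="linear_concentration"`` places soma x positions
    with probability proportional to the local gradient concentration
    (requires ``spec``); the default is uniform.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if bias_kappa < 0:
        raise ValueError("bias_kappa must be >= 0")
    rng = np.random.default_rng(rng_seed)
    h, w = image_shape_px
    lo_len, hi_len = neurite_length_range_px
    if n_branches > 0:
        lo_len = max(lo_len, MIN_LENGTH_WITH_BRANCHES)
        hi_len = max(hi_len, lo_len)
    # symmetric margin: soma + longest neurite + tube/halo padding
    margin = soma_radius_px + hi_len + TUBE_RADIUS_PX + HALO_WIDTH_PX + 3
    if 2 * margin >= min(h, w):
        raise ValueError("image_shape_px too small for the requested cell geometry")
    min_dist = min_center_distance_factor * soma_radius_px

    span_px = None
    if position_density == "linear_concentration":
        if spec is None:
            raise ValueError("linear_concentration placement requires a GradientSpec")
        span_px = spec.span_um / pixel_size_um

    cells: list[SyntheticCellSpec] = []
    centers: list[np.ndarray] = []
    for _ in range(n_cells):
        angle = wrap_deg(np.degrees(rng.vonmises(np.pi, bias_kappa)))
        length = float(rng.uniform(lo_len, hi_len))
        placed = False
        for _attempt in range(max_retries):
            if span_px is None:
                cx = rng.uniform(margin, w - margin)
            else:
                # density proportional to concentration: highest at x = 0 (left edge)
                u = rng.uniform()
                cx = span_px * (1.0 - np.sqrt(1.0 - u))
                cx = min(max(cx, margin), w - margin)
            cy = rng.uniform(margin, h - margin)
            center = np.array([cx, cy])
            if min_dist <= 0 or all(np.hypot(*(center - c)) >= min_dist for c in centers):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {len(cells)} after {max_retries} retries"
            )
        centers.append(center)
        dx, dy = unit_vector(angle)
        rim = (center[0] + soma_radius_px * dx, center[1] + soma_radius_px * dy)
        waypoints = _make_waypoints(rim, angle, length, curl_sd_deg, rng)
        true_init, true_term = _chord_angles(waypoints)
        branches = []
        if n_branches > 0:
            dense = _resample_polyline(np.asarray(waypoints), step=1.0)
            fracs = np.linspace(0.30, 0.60, n_branches)
            for bi, frac in enumerate(fracs):
                attach = dense[int(frac * (len(dense) - 1))]
                side = 1.0 if bi % 2 == 0 else -1.0
                b_angle = wrap_deg(angle + side * rng.uniform(50.0, 70.0))
                bdx, bdy = unit_vector(b_angle)
                tip = (attach[0] + 50.0 * bdx, attach[1] + 50.0 * bdy)
                branches.append([tuple(map(float, attach)), tuple(map(float, tip))])
        cells.append(
            SyntheticCellSpec(
                soma_center=tuple(map(float, center)),
                soma_radius_px=float(soma_radius_px),
                neurite_waypoints=waypoints,
                true_initiation_angle_deg=float(true_init),
                true_terminal_angle_deg=float(true_term),
                true_path_length_px=length,
                n_branches=n_branches,
                branch_waypoints=branches,
            )
        )
    return cells


def _cell_extent(cell: SyntheticCellSpec):
    soma_pad = cell.soma_radius_px + HALO_WIDTH_PX + 1
    tube_pad = TUBE_RADIUS_PX + HALO_WIDTH_PX + 1
    pts = list(cell.neurite_waypoints)
    for br in cell.branch_waypoints:
        pts.extend(br)
    cx, cy = cell.soma_center
    xs = np.array([p[0] for p in pts] or [cx])
    ys = np.array([p[1] for p in pts] or [cy])
    return (
        min(xs.min() - tube_pad, cx - soma_pad),
        max(xs.max() + tube_pad, cx + soma_pad),
        min(ys.min() - tube_pad, cy - soma_pad),
        max(ys.max() + tube_pad, cy + soma_pad),
    )


def render_scene(
    cells: list,
    image_shape_px: tuple = (1200, 1200),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    noise_sd: float = 0.02,
    rng_seed: int = 0,
    gradient: GradientSpec | None = None,
) -> SyntheticScene:
    """Render cells into a bright-field-like frame (deterministic per seed).

    Somata are filled disks, neurites ~5-px-wide tubes along their
    waypoints; a 2-px bright halo surrounds every cell so edge detection
    sees a closed contour.  Gaussian noise of sd ``noise_sd`` is added to
    the whole frame.  A cell whose footprint would leave the frame raises
    a ValueError naming its index.
    """
    h, w = image_shape_px
    for i, cell in enumerate(cells):
        x0, x1, y0, y1 = _cell_extent(cell)
        if x0 < 0 or y0 < 0 or x1 > w - 1 or y1 > h - 1:
            raise ValueError(f"cell {i} footprint outside image bounds {image_shape_px}")

    interior = np.zeros((h, w), dtype=bool)
    tubes = np.zeros((h, w), dtype=bool)
    for cell in cells:
        rr, cc = draw.disk(
            (cell.soma_center[1], cell.soma_center[0]), cell.soma_radius_px, shape=(h, w)
        )
        interior[rr, cc] = True
        for line in [cell.neurite_waypoints] + list(cell.branch_waypoints):
            dense = _resample_polyline(np.asarray(line, dtype=float), step=0.5)
            rows = np.clip(np.rint(dense[:, 1]).astype(int), 0, h - 1)
            cols = np.clip(np.rint(dense[:, 0]).astype(int), 0, w - 1)
            tubes[rows, cols] = True
    if tubes.any():
        interior |= ndi.binary_dilation(tubes, structure=morphology.disk(TUBE_RADIUS_PX))
    halo = ndi.binary_dilation(interior, structure=morphology.disk(HALO_WIDTH_PX)) & ~interior

    img = np.full((h, w), BACKGROUND_LEVEL, dtype=np.float64)
    img[interior] = INTERIOR_LEVEL
    img[halo] = HALO_LEVEL
    rng = np.random.default_rng(rng_seed)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    frame = ImageFrame(
        pixels=img,
        pixel_size_um=pixel_size_um,
        gradient_toward_left=True,
        source_id=f"synthetic:seed={rng_seed}",
    )
    return SyntheticScene(
        image=frame, cells=list(cells), gradient=gradient, noise_sd=noise_sd, rng_seed=rng_seed
    )


def generate_scenes(
    n_cells: int,
    bias_kappa: float,
    rng_seed: int = 0,
    cells_per_scene: int = 8,
    gradient: GradientSpec | None = None,
    **population_kwargs,
) -> list[SyntheticScene]:
    """Convenience driver: split a population over as many frames as needed."""
    scenes = []
    remaining = n_cells
    chunk = 0
    while remaining > 0:
        n = min(cells_per_scene, remaining)
        seed = rng_seed + 7919 * chunk  # distinct, reproducible per-frame streams
        cells = sample_population(n, bias_kappa, gradient, rng_seed=seed, **population_kwargs)
        scenes.append(
            render_scene(
                cells,
                image_shape_px=population_kwargs.get("image_shape_px", (1200, 1200)),
                pixel_size_um=population_kwargs.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM),
                rng_seed=seed + 1,
                gradient=gradient,
            )
        )
        remaining -= n
        chunk += 1
    return scenes


def save_scene(scene: SyntheticScene, out_dir, stem: str = "scene"):
    """Write the frame as 16-bit TIFF plus a JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tiff_path = out / f"{stem}.tif"
    json_path = out / f"{stem}.truth.json"
    px = np.clip(scene.image.pixels, 0.0, 1.0)
    tifffile.imwrite(tiff_path, (px * 65535.0 + 0.5).astype(np.uint16))
    payload = {
        "rng_seed": scene.rng_seed,
        "noise_sd": scene.noise_sd,
        "pixel_size_um": scene.image.pixel_size_um,
        "gradient_toward_left": scene.image.gradient_toward_left,
        "image_shape_px": list(scene.image.shape),
        "gradient": asdict(scene.gradient) if scene.gradient else None,
        "cells": [asdict(c) for c in scene.cells],
    }
    json_path.write_text(json.dumps(payload, indent=1))
    return tiff_path, json_path


def load_scene(tiff_path, json_path=None) -> SyntheticScene:
    """Read a scene written by :func:`save_scene` back into memory."""
    tiff_path = Path(tiff_path)
    if json_path is None:
        json_path = tiff_path.with_suffix("").with_suffix(".truth.json")
        if not Path(json_path).exists():
            json_path = Path(str(tiff_path).replace(".tif", ".truth.json"))
    meta = json.loads(Path(json_path).read_text())
    px = tifffile.imread(tiff_path).astype(np.float64) / 65535.0
    frame = ImageFrame(
        pixels=px,
        pixel_size_um=meta["pixel_size_um"],
        gradient_toward_left=meta["gradient_toward_left"],
        source_id=str(tiff_path),
    )
    gradient = None
    if meta.get("gradient"):
        g = meta["gradient"]
        gradient = GradientSpec(g["span_um"], g["max_level"], tuple(g["direction"]))
    cells = [
        SyntheticCellSpec(
            soma_center=tuple(c["soma_center"]),
            soma_radius_px=c["soma_radius_px"],
            neurite_waypoints=[tuple(p) for p in c["neurite_waypoints"]],
            true_initiation_angle_deg=c["true_initiation_angle_deg"],
            true_terminal_angle_deg=c["true_terminal_angle_deg"],
            true_path_length_px=c["true_path_length_px"],
            n_branches=c["n_branches"],
            branch_waypoints=[[tuple(p) for p in br] for br in c["branch_waypoints"]],
        )
        for c in meta["cells"]
    ]
    return SyntheticScene(
        image=frame,
        cells=cells,
        gradient=gradient,
        noise_sd=meta["noise_sd"],
        rng_seed=meta["rng_seed"],
    )
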