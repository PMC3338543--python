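"""Batch orchestration: frames in, per-cell and per-condition tables out.

A raw micrograph holds the steep gradient in its left quarter (rising
left-to-right) and the shallow gradient in the remaining three quarters
(rising right-to-left).  :func:`split_and_orient` cuts the frame at the
configured fraction and horizontally flips the steep part, so that every
analyzed sub-frame is in canonical orientation: increasing concentration
toward the left edge, attraction at angles near +-180 degrees, soma x
position measured from the high-concentration edge (0 um).

:func:`process_frames` runs segmentation and per-cell morphometry with
full accounting (every candidate mask is either measured or tallied under
a rejection reason), and the summarizer refuses to mix rows produced
under different configurations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .morphometry import CellRejected, MorphometryConfig, analyze_cell
from .segmentation import (
    DEFAULT_PIXEL_SIZE_UM,
    ImageFrame,
    MIN_FRAME_DIM,
    SegmentationConfig,
    segment_frame,
)
from .stats import (
    DEFAULT_RESTRICTION_ANGLE,
    classify_direction,
    classify_turning,
    guidance_counts,
    restriction_sweep,
)

__all__ = [
    "RunConfig",
    "RunResult",
    "hflip_frame",
    "split_and_orient",
    "process_frames",
    "summarize",
    "run_directory",
    "run_synthetic",
    "write_outputs",
]


@dataclass
class RunConfig:
    """Frozen-per-run parameters; serialized into every output row."""

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    split_fraction: float = 0.25
    flip_high_slope: bool = True
    restriction_deg: float = DEFAULT_RESTRICTION_ANGLE
    sweep_restrictions: tuple = (60.0, 90.0, 120.0, 150.0, 180.0)
    rng_seed: int = 0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    input_dir: str = ""
    output_dir: str = ""

    def __post_init__(self):
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep_restrictions"] = list(self.sweep_restrictions)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    cells: pd.DataFrame
    accounting: pd.DataFrame
    summary: pd.DataFrame
    sweep: pd.DataFrame
    manifest: dict


def hflip_frame(frame: ImageFrame) -> ImageFrame:
    """Mirror a frame across its vertical axis (flips gradient orientation)."""
    return ImageFrame(
        pixels=np.ascontiguousarray(frame.pixels[:, ::-1]),
        pixel_size_um=frame.pixel_size_um,
        gradient_toward_left=not frame.gradient_toward_left,
        source_id=frame.source_id + "|hflip",
    )


def split_and_orient(frame: ImageFrame, config: RunConfig | None = None):
    """Cut a raw two-gradient frame into canonical steep/shallow sub-frames.

    The left ``split_fraction`` of columns is the steep gradient (rising
    rightward in the raw frame) and is horizontally flipped; the rest is
    the shallow gradient, already rising leftward.  Both sub-frames are
    returned with canonical orientation metadata.
    """
    if config is None:
        config = RunConfig()
    w = frame.shape[1]
    n_high = int(round(w * config.split_fraction))
    if n_high < MIN_FRAME_DIM or (w - n_high) < MIN_FRAME_DIM:
        raise ValueError(f"frame of width {w} too narrow to split at {config.split_fraction}")
    high_raw = ImageFrame(
        pixels=np.ascontiguousarray(frame.pixels[:, :n_high]),
        pixel_size_um=frame.pixel_size_um,
        gradient_toward_left=False,
        source_id=frame.source_id + ":high",
    )
    high = hflip_frame(high_raw) if config.flip_high_slope else high_raw
    low = ImageFrame(
        pixels=np.ascontiguousarray(frame.pixels[:, n_high:]),
        pixel_size_um=frame.pixel_size_um,
        gradient_toward_left=True,
        source_id=frame.source_id + ":low",
    )
    return high, low


def process_frames(
    frames,
    config: RunConfig | None = None,
    conditions=None,
) -> RunResult:
    """Segment and measure every frame; returns tables plus accounting.

    ``conditions`` optionally labels each frame (defaults to "default").
    Frames must already be in canonical orientation.
    """
    if config is None:
        config = RunConfig()
    frames = list(frames)
    if conditions is None:
        conditions = ["default"] * len(frames)
    chash = config.config_hash

    rows = []
    acct_rows = []
    for frame, condition in zip(frames, conditions):
        if not frame.gradient_toward_left:
            raise ValueError(
                f"frame {frame.source_id!r} not in canonical orientation; "
                "run split_and_orient or hflip_frame first"
            )
        masks = segment_frame(frame, config.segmentation)
        rejected: dict = {}
        n_ok = 0
        for k, mask in enumerate(masks):
            cell_id = f"{frame.source_id}#{k}"
            try:
                m = analyze_cell(
                    mask,
                    cell_id=cell_id,
                    pixel_size_um=frame.pixel_size_um,
                    config=config.morphometry,
                )
            except CellRejected as exc:
                rejected[exc.reason] = rejected.get(exc.reason, 0) + 1
                continue
            n_ok += 1
            rows.append(
                {
                    "cell_id": m.cell_id,
                    "source_id": frame.source_id,
                    "condition": condition,
                    "soma_x_px": m.soma_centroid_xy_px[0],
                    "soma_y_px": m.soma_centroid_xy_px[1],
                    "soma_x_um": m.soma_x_um,
                    "soma_area_px": m.soma_area_px,
                    "initiation_angle_deg": m.initiation_angle_deg,
                    "terminal_angle_deg": m.terminal_angle_deg,
                    "turning_angle_deg": m.turning_angle_deg,
                    "endpoint_angle_deg": m.endpoint_angle_deg,
                    "neurite_length_px": m.neurite_length_px,
                    "neurite_length_um": m.neurite_length_um,
                    "neurite_straight_um": m.neurite_straight_um,
                    "n_branch_points": m.n_branch_points,
                    "qc_flags": ";".join(m.qc_flags),
                    "config_hash": chash,
                }
            )
        acct = {
            "source_id": frame.source_id,
            "condition": condition,
            "n_candidate_masks": len(masks),
            "n_accepted": n_ok,
        }
        for reason, count in sorted(rejected.items()):
            acct[f"rejected_{reason}"] = count
        acct_rows.append(acct)

    cells = pd.DataFrame(rows)
    accounting = pd.DataFrame(acct_rows).fillna(0)
    summary = summarize(cells, config) if len(cells) else pd.DataFrame()
    sweep = (
        pd.concat(
            [
                restriction_sweep(
                    grp["endpoint_angle_deg"].to_numpy(),
                    config.sweep_restrictions,
                    condition=cond,
                )
                for cond, grp in cells.groupby("condition")
            ],
            ignore_index=True,
        )
        if len(cells)
        else pd.DataFrame()
    )
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": chash,
        "n_frames": len(frames),
        "n_cells_accepted": int(len(cells)),
        "accounting": accounting.to_dict(orient="records"),
    }
    return RunResult(cells=cells, accounting=accounting, summary=summary, sweep=sweep, manifest=manifest)


def summarize(cells: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-condition guidance tallies on each angle basis.

    Refuses tables mixing rows from different configurations (different
    ``config_hash`` values), since tallies would then be incomparable.
    """
    if config is None:
        config = RunConfig()
    if "config_hash" in cells.columns and cells["config_hash"].nunique() > 1:
        raise ValueError("refusing to summarize rows produced under different configs")
    out = []
    for cond, grp in cells.groupby("condition"):
        for basis, col in (
            ("endpoint", "endpoint_angle_deg"),
            ("initiation", "initiation_angle_deg"),
            ("terminal", "terminal_angle_deg"),
        ):
            gc = guidance_counts(
                grp[col].to_numpy(), config.restriction_deg, condition=cond, basis=basis
            )
            out.append(_counts_row(gc))
        turning = grp["turning_angle_deg"].to_numpy()
        classes = [classify_turning(t) for t in turning]
        n_att = sum(c.value == "attracted" for c in classes)
        n_rep = sum(c.value == "repulsed" for c in classes)
        n_neu = len(classes) - n_att - n_rep
        from .stats import GuidanceCounts, chi2_guidance

        if n_att + n_rep > 0:
            stat, p = chi2_guidance(n_att, n_rep)
        else:
            stat, p = float("nan"), float("nan")
        out.append(
            _counts_row(
                GuidanceCounts(n_att, n_neu, n_rep, stat, p, condition=cond, basis="turning")
            )
        )
    return pd.DataFrame(out)


def _counts_row(gc) -> dict:
    return {
        "condition": gc.condition,
        "basis": gc.basis,
        "restriction_deg": gc.restriction_deg,
        "n_attracted": gc.n_attracted,
        "n_neutral": gc.n_neutral,
        "n_repulsed": gc.n_repulsed,
        "chi2": gc.chi2_statistic,
        "p_value": gc.p_value,
        "ratio": gc.ratio,
        "ratio_defined": gc.ratio_defined,
    }


def run_directory(config: RunConfig) -> RunResult:
    """End-to-end run over a directory of raw two-gradient TIFF frames.

    Unreadable images are logged into the manifest and skipped; an empty
    input set is an error.
    """
    in_dir = Path(config.input_dir)
    paths = sorted(p for p in in_dir.glob("*.tif*") if not p.name.endswith(".truth.json"))
    if not paths:
        raise FileNotFoundError(f"no TIFF images in {in_dir}")
    frames, conditions, skipped = [], [], []
    for path in paths:
        try:
            px = tifffile.imread(path)
        except Exception as exc:  # unreadable file: log and continue
            skipped.append({"path": str(path), "error": str(exc)})
            continue
        raw = ImageFrame(
            pixels=px,
            pixel_size_um=config.pixel_size_um,
            gradient_toward_left=False,
            source_id=path.name,
        )
        high, low = split_and_orient(raw, config)
        frames.extend([high, low])
        conditions.extend(["high_slope", "low_slope"])
    if not frames:
        raise FileNotFoundError(f"no readable TIFF images in {in_dir}")
    result = process_frames(frames, config, conditions)
    result.manifest["skipped_images"] = skipped
    result.manifest["exit_ok"] = len(skipped) == 0
    return result


def run_synthetic(
    config: RunConfig,
    n_cells: int,
    bias_kappa: float,
    cells_per_scene: int = 8,
    condition: str = "synthetic",
    **population_kwargs,
):
    """Generate scenes and push them through the pipeline.

    Returns ``(result, scenes)`` so callers can score measurements
    against the attached ground truth.
    """
    from .synthetic import generate_scenes

    scenes = generate_scenes(
        n_cells,
        bias_kappa,
        rng_seed=config.rng_seed,
        cells_per_scene=cells_per_scene,
        **population_kwargs,
    )
    frames = [s.image for s in scenes]
    result = process_frames(frames, config, [condition] * len(frames))
    return result, scenes


def _atomic_write_csv(df: pd.DataFrame, path: Path):
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    os.replace(tmp, path)


def write_outputs(result: RunResult, out_dir) -> dict:
    """Write cells/summary/sweep/accounting CSVs and the JSON manifest atomically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("cells", result.cells),
        ("summary", result.summary),
        ("sweep", result.sweep),
        ("accounting", result.accounting),
    ):
        p = out / f"{name}.csv"
        _atomic_write_csv(df if len(df) else pd.DataFrame(), p)
        paths[name] = str(p)
    mpath = out / "manifest.json"
    tmp = mpath.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(result.manifest, indent=1, default=str))
    os.replace(tmp, mpath)
    paths["manifest"] = str(mpath)
    return paths
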