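"""Per-frame seaweed yield estimation, repeatability statistics, error budget.

The yield model is deliberately simple: the hanging kelp bundle is treated
as a flat, fronto-parallel sheet, so its surface area in m² is

    yield = (segmented pixel count) * (Z / f_h) * (Z / f_v)

with ``Z`` the single per-frame range from the central-crop disparity
median.  The first-order error budget combines the segmentation quality and
the range precision linearly:

    rel_yield_error = (1 - IoU) + 2 * rel_range_error

— area scales with the *square* of range, hence the factor two, and the
segmentation term enters linearly through the pixel count.  Linear addition
(rather than quadrature) is the package's deliberate, conservative choice
for these strongly coupled, non-independent error sources.

Per-frame yields are not mosaicked or overlap-corrected across frames;
each frame stands alone as an estimate of the sheet area it sees.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .camera_geometry import CameraModel, pixel_footprint_area
from .segmentation import (
    ClassicalParams,
    SegmentationMask,
    classical_segment,
    external_segmenter_hook,
    iou as mask_iou,
)
from .stereo_depth import RangeEstimate, SgmParams, compute_disparity, median_scene_distance

logger = logging.getLogger(__name__)

__all__ = [
    "YieldEstimate",
    "RepeatabilityReport",
    "estimate_yield",
    "repeatability_stats",
    "propagate_error",
    "run_pipeline",
    "load_manifest",
    "load_config",
    "DEFAULT_CONFIG",
]


class PipelineError(RuntimeError):
    pass


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "segmentation": {
        "method": "classical",  # classical | annotation | hook
        "classical": {
            "discriminant": "red-blue",
            "min_contrast": 12.0,
            "morphology_radius": 2,
            "min_component_px": 64,
        },
        "hook_command": None,
    },
    "sgm": {
        "block_size": 16,
        "disparity_range": [0, 48],
        "penalty_small": None,
        "penalty_large": None,
        "n_paths": 8,
        "uniqueness_ratio": 0.10,
        "do_left_right_check": False,
        "subpixel": True,
        "subpixel_method": "equiangular",
        "min_data_margin": 2.0,
    },
    "median_crop": [600, 400],
    # Assumed per-frame error budget inputs: segmentation model quality (IoU)
    # and relative range precision of the stationary-series spread.
    "error_budget": {"segmentation_iou": 0.9, "rel_range_error": 0.044},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Full run configuration: YAML file merged over the documented defaults."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _deep_merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def sgm_params_from_config(cfg: dict) -> SgmParams:
    s = cfg["sgm"]
    return SgmParams(
        block_size=int(s["block_size"]),
        disparity_range=tuple(int(x) for x in s["disparity_range"]),
        penalty_small=s.get("penalty_small"),
        penalty_large=s.get("penalty_large"),
        n_paths=int(s["n_paths"]),
        uniqueness_ratio=float(s["uniqueness_ratio"]),
        do_left_right_check=bool(s["do_left_right_check"]),
        subpixel=bool(s["subpixel"]),
        subpixel_method=s.get("subpixel_method", "equiangular"),
        min_data_margin=float(s.get("min_data_margin", 2.0)),
    )


@dataclass
class YieldEstimate:
    """One frame's seaweed surface area with its provenance and error bound."""

    frame_id: str
    seaweed_px: int
    range_m: float | None
    yield_m2: float | None
    rel_error: float | None
    flags: list[str] = field(default_factory=list)
    # flat-sheet, fronto-parallel assumption; single median range for all pixels
    assumption: str = "flat-sheet fronto-parallel, uniform median range"


@dataclass
class RepeatabilityReport:
    """Spread statistics of a per-frame scalar over a stationary series."""

    n_frames: int
    mean: float
    std: float  # sample standard deviation (ddof=1)
    half_range: float  # (max - min) / 2
    hist_counts: np.ndarray
    hist_edges: np.ndarray  # Freedman-Diaconis binning

    @property
    def rel_std(self) -> float:
        return self.std / self.mean if self.mean else float("nan")


def estimate_yield(
    mask: SegmentationMask, range_m: float | None, camera: CameraModel,
    rel_error: float | None = None,
) -> YieldEstimate:
    """Convert a segmented pixel count to m² at the frame's median range."""
    px = mask.area_px
    if range_m is None or (range_m is not None and range_m <= 0):
        return YieldEstimate(
            frame_id=mask.frame_id,
            seaweed_px=px,
            range_m=None,
            yield_m2=None,
            rel_error=None,
            flags=["range-unavailable"],
        )
    area = px * pixel_footprint_area(camera, range_m)
    return YieldEstimate(
        frame_id=mask.frame_id,
        seaweed_px=px,
        range_m=float(range_m),
        yield_m2=float(area),
        rel_error=rel_error,
    )


def repeatability_stats(series) -> RepeatabilityReport:
    """Mean, sample std, half-range and a histogram of a stationary series.

    For segmented-fraction series the values are fractions of total image
    area; any per-frame scalar (range in meters, yield in m²) works the same
    way.  Histogram bins follow the Freedman-Diaconis rule (falling back to
    a single bin for a constant series).
    """
    x = np.asarray(list(series), dtype=float)
    if x.size < 2:
        raise ValueError("repeatability needs at least 2 frames")
    counts, edges = np.histogram(x, bins="fd" if np.ptp(x) > 0 else 1)
    return RepeatabilityReport(
        n_frames=int(x.size),
        mean=float(x.mean()),
        std=float(x.std(ddof=1)),
        half_range=float(np.ptp(x) / 2.0),
        hist_counts=counts,
        hist_edges=edges,
    )


def propagate_error(iou: float, rel_range_error: float) -> float:
    """First-order relative yield error from IoU and range precision.

    ``(1 - IoU) + 2 * rel_range_error``: the pixel-count error is taken as
    the segmentation disagreement ``1 - IoU`` and the quadratic range
    dependence of the metric area contributes twice the relative range
    error.  Monotone non-increasing in IoU, non-decreasing in range error.
    """
    if not 0 < iou <= 1:
        raise ValueError(f"IoU must lie in (0, 1], got {iou}")
    if rel_range_error < 0:
        raise ValueError("relative range error must be >= 0")
    return (1.0 - iou) + 2.0 * rel_range_error


# ---------------------------------------------------------------------------
# Orchestration


def load_manifest(path: str | Path) -> tuple[CameraModel, list[dict], Path]:
    """Dataset manifest: camera block plus per-frame file entries.

    Schema: ``{"camera": {...}, "frames": [{"frame_id", "rgb", "left",
    "right", ["mask"]}]}``; paths are relative to the manifest location.
    """
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"manifest not found: {path}")
    with open(path) as fh:
        manifest = json.load(fh)
    try:
        camera = CameraModel.from_manifest_dict(manifest["camera"])
        frames = manifest["frames"]
    except KeyError as exc:
        raise PipelineError(f"manifest {path} missing required key: {exc}") from exc
    if not frames:
        raise PipelineError(f"manifest {path} lists no frames")
    return camera, frames, path.parent


def _load_gray(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))


def _segment_frame(
    entry: dict, root: Path, cfg: dict, camera: CameraModel
) -> SegmentationMask:
    method = cfg["segmentation"]["method"]
    fid = entry["frame_id"]
    if method == "classical":
        rgb = np.asarray(Image.open(root / entry["rgb"]).convert("RGB"))
        return classical_segment(
            rgb, ClassicalParams(**cfg["segmentation"]["classical"]), frame_id=fid
        )
    if method == "annotation":
        if "mask" not in entry:
            raise PipelineError(f"frame {fid}: annotation method needs a mask entry")
        arr = np.asarray(Image.open(root / entry["mask"]).convert("L"))
        return SegmentationMask(arr > 0, frame_id=fid, source="annotation")
    if method == "hook":
        command = cfg["segmentation"]["hook_command"]
        if not command:
            raise PipelineError("segmentation method 'hook' needs hook_command")
        return external_segmenter_hook(
            root / entry["rgb"], list(command), camera.image_size, frame_id=fid
        )
    raise PipelineError(f"unknown segmentation method {method!r}")


def run_pipeline(
    manifest_path: str | Path, config: dict | None = None
) -> tuple[list[YieldEstimate], pd.DataFrame, dict]:
    """Per-frame segment → disparity → median range → yield, fault-tolerant.

    A frame failing any stage is flagged and reported with empty results;
    the run continues.  Returns the estimates, a tidy table, and a run
    report (config echo, seed, per-stage timings, per-frame flags) that
    together make the run reproducible.
    """
    cfg = config if config is not None else load_config()
    camera, frames, root = load_manifest(manifest_path)
    sgm = sgm_params_from_config(cfg)
    crop = tuple(int(x) for x in cfg["median_crop"])
    budget = cfg["error_budget"]
    rel_error = propagate_error(
        float(budget["segmentation_iou"]), float(budget["rel_range_error"])
    )

    estimates: list[YieldEstimate] = []
    timings: list[dict] = []
    for entry in frames:
        fid = entry["frame_id"]
        t0 = time.perf_counter()
        try:
            mask = _segment_frame(entry, root, cfg, camera)
            t_seg = time.perf_counter()
            left = _load_gray(root / entry["left"])
            right = _load_gray(root / entry["right"])
            disp = compute_disparity(left, right, sgm)
            t_disp = time.perf_counter()
            rng: RangeEstimate = median_scene_distance(disp, camera, crop)
            est = estimate_yield(
                mask, rng.depth_m if rng.available else None, camera, rel_error
            )
            est.frame_id = fid
            if rng.crop_clipped:
                est.flags.append("clipped-crop")
            timings.append(
                {
                    "frame_id": fid,
                    "segment_s": round(t_seg - t0, 4),
                    "disparity_s": round(t_disp - t_seg, 4),
                }
            )
        except Exception as exc:  # per-frame fault isolation
            logger.warning("frame %s failed: %s", fid, exc)
            est = YieldEstimate(
                frame_id=fid,
                seaweed_px=0,
                range_m=None,
                yield_m2=None,
                rel_error=None,
                flags=[f"stage-error:{type(exc).__name__}"],
            )
        estimates.append(est)

    table = estimates_table(estimates)
    report = {
        "n_frames": len(frames),
        "n_flagged": int(sum(bool(e.flags) for e in estimates)),
        "config": cfg,
        "seed": cfg.get("seed", 0),
        "camera": camera.to_manifest_dict(),
        "timings": timings,
        "flags": {e.frame_id: e.flags for e in estimates if e.flags},
    }
    return estimates, table, report


def estimates_table(estimates: list[YieldEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame_id": [e.frame_id for e in estimates],
            "seaweed_px": [e.seaweed_px for e in estimates],
            "range_m": [e.range_m for e in estimates],
            "yield_m2": [e.yield_m2 for e in estimates],
            "rel_error": [e.rel_error for e in estimates],
            "flags": [";".join(e.flags) for e in estimates],
        }
    )


def write_outputs(
    table: pd.DataFrame, report: dict, out_dir: str | Path
) -> tuple[Path, Path]:
    """``yields.csv`` (fixed float formatting, hence byte-reproducible) + ``report.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "yields.csv"
    table.to_csv(csv_path, index=False, float_format="%.6f", lineterminator="\n")
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return csv_path, report_path
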