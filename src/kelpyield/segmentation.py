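"""Seaweed masks: polygon rasterization, IoU scoring, and segmenters.

Three ways to obtain a binary mask for a frame:

* rasterized ground-truth polygons (the annotation route; polygons drawn in
  an annotation tool, imported from CVAT XML 1.1 or a plain JSON schema);
* ``classical_segment`` — a deterministic thresholding/morphology pipeline
  that separates dark kelp blades from the bright open-water background;
* ``external_segmenter_hook`` — a contract for plugging in a trained
  semantic-segmentation model (e.g. an encoder-decoder CNN) as an external
  command mapping a frame file to a mask file.

Labeling policy mirrored from the field protocol: only seaweed on the
nearest line is foreground; plants on lines further back are negative class
(the synthetic generator applies the same rule through its foreground depth
cutoff).

Rasterization rule: a pixel counts as inside when its *center* lies inside
the polygon ring under the even-odd rule; pixel ``(i, j)`` covers
``[i, i+1) x [j, j+1)`` so its center is ``(i + 0.5, j + 0.5)``.  Masks from
multiple polygons are OR-ed together.
"""

from __future__ import annotations

import json
import logging
import subprocess
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationMask",
    "AnnotationPolygon",
    "rasterize_polygons",
    "iou",
    "classical_segment",
    "ClassicalParams",
    "external_segmenter_hook",
    "load_polygons_json",
    "load_polygons_cvat",
]


class AnnotationError(ValueError):
    pass


class SegmenterHookError(RuntimeError):
    """The external segmenter broke its contract for a frame."""


@dataclass
class SegmentationMask:
    values: np.ndarray  # (H, W) bool
    frame_id: str = ""
    source: str = "annotation"  # annotation | classical | external-model

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)

    @property
    def area_px(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class AnnotationPolygon:
    """Closed polygon ring in pixel coordinates (x, y), 0-based, top-left origin."""

    frame_id: str
    vertices: tuple[tuple[float, float], ...]
    label: str = "seaweed"

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise AnnotationError(
                f"frame {self.frame_id!r}: polygon needs >= 3 vertices, "
                f"got {len(self.vertices)}"
            )
        ring = ShapelyPolygon(self.vertices)
        if not ring.is_valid or ring.area == 0:
            raise AnnotationError(
                f"frame {self.frame_id!r}: polygon ring is degenerate or "
                "self-intersecting"
            )


def rasterize_polygons(
    polys: list[AnnotationPolygon], image_size: tuple[int, int]
) -> SegmentationMask:
    """Union of even-odd-filled polygons on a ``(width, height)`` raster."""
    width, height = image_size
    mask = np.zeros((height, width), dtype=bool)
    if not polys:
        return SegmentationMask(mask, source="annotation")
    cx, cy = np.meshgrid(np.arange(width) + 0.5, np.arange(height) + 0.5)
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    for poly in polys:
        path = MplPath(np.asarray(poly.vertices))  # implicitly closed ring
        # radius=-1e-9 keeps the test strictly-inside on the half-open
        # convention's far edges; centers of integer-aligned rectangles
        # never sit on an edge so the rule is exact there.
        inside = path.contains_points(centers, radius=-1e-9)
        mask |= inside.reshape(height, width)
    return SegmentationMask(mask, frame_id=polys[0].frame_id, source="annotation")


def iou(a: SegmentationMask | np.ndarray, b: SegmentationMask | np.ndarray) -> float:
    """Intersection over union of two binary masks.

    Defined as 1.0 when both masks are empty (perfect agreement on "nothing
    here") and 0.0 when exactly one is empty.
    """
    av = a.values if isinstance(a, SegmentationMask) else np.asarray(a, dtype=bool)
    bv = b.values if isinstance(b, SegmentationMask) else np.asarray(b, dtype=bool)
    if av.shape != bv.shape:
        raise ValueError(f"mask size mismatch: {av.shape} vs {bv.shape}")
    union = np.logical_or(av, bv).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(av, bv).sum() / union)


@dataclass(frozen=True)
class ClassicalParams:
    """Threshold/morphology segmenter settings.

    ``discriminant`` selects the per-pixel score that is thresholded:

    * ``"red-blue"`` (default): ``R - B``.  Kelp blades are brown
      (red-dominant), the veiling water light blue-green, so blades score
      high and water low at *any* haze level — attenuation only shrinks the
      gap, never flips the sign.
    * ``"luminance"``: mean channel intensity with dark polarity (blades are
      darker than open water).

    ``min_contrast`` guards against hallucinating structure in a frame of
    pure open water: if the Otsu split separates the two score classes by
    less than this many gray levels, the frame is declared empty.
    """

    discriminant: str = "red-blue"
    min_contrast: float = 12.0
    morphology_radius: int = 2
    min_component_px: int = 64


def _otsu_threshold(gray: np.ndarray) -> float:
    """Otsu's threshold on an 8-bit histogram (maximal between-class variance)."""
    hist = np.bincount(gray.ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * np.arange(256))
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return float(np.argmax(sigma_b))


def classical_segment(
    rgb_frame: np.ndarray,
    params: ClassicalParams | None = None,
    frame_id: str = "",
) -> SegmentationMask:
    """Deterministic kelp/water separation for haze-veiled frames.

    An Otsu threshold on the configured channel discriminant splits blade
    pixels from open water; morphological opening+closing removes speckle
    and bridges texture holes, and components below a minimum pixel area
    are discarded as floating-particle clutter.  May return an empty mask.
    """
    params = params or ClassicalParams()
    frame = np.asarray(rgb_frame)
    if params.discriminant == "red-blue" and frame.ndim == 3:
        score = frame[..., 0].astype(float) - frame[..., 2].astype(float)
        score = score + 128.0  # recentre the signed difference on the 8-bit scale
        fg_is_high = True
    elif params.discriminant in ("luminance", "red-blue"):
        score = frame.astype(float).mean(axis=2) if frame.ndim == 3 else frame.astype(float)
        fg_is_high = False
    else:
        raise ValueError(f"unknown discriminant {params.discriminant!r}")
    score_u8 = np.clip(np.rint(score), 0, 255).astype(np.uint8)

    def _empty() -> SegmentationMask:
        return SegmentationMask(
            np.zeros(score.shape, dtype=bool), frame_id=frame_id, source="classical"
        )

    if score_u8.max() - score_u8.min() < params.min_contrast:
        return _empty()
    thr = _otsu_threshold(score_u8)
    fg = score_u8 > thr if fg_is_high else score_u8 < thr
    fg_mean = score_u8[fg].mean() if fg.any() else 0.0
    bg_mean = score_u8[~fg].mean() if (~fg).any() else 0.0
    if abs(fg_mean - bg_mean) < params.min_contrast:
        return _empty()

    r = params.morphology_radius
    if r > 0:
        # square footprint: removes speckle and bridges holes while leaving
        # straight edges and right-angle corners untouched
        footprint = np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
        fg = ndimage.binary_opening(fg, structure=footprint)
        fg = ndimage.binary_closing(fg, structure=footprint)
    if params.min_component_px > 0:
        labels, n = ndimage.label(fg)
        if n:
            sizes = np.bincount(labels.ravel())
            keep = sizes >= params.min_component_px
            keep[0] = False
            fg = keep[labels]
    return SegmentationMask(fg, frame_id=frame_id, source="classical")


def external_segmenter_hook(
    frame_path: str | Path,
    command: list[str],
    expected_size: tuple[int, int],
    frame_id: str = "",
) -> SegmentationMask:
    """Run an external segmenter ``command frame.png mask.png`` and validate.

    The command receives the frame path and a target mask path as its last
    two arguments; it must write an 8-bit mask PNG (0 background, nonzero
    foreground) of exactly ``expected_size`` (width, height).  Violations
    raise :class:`SegmenterHookError` so the caller can flag the frame and
    continue the run.
    """
    frame_path = Path(frame_path)
    if not frame_path.exists():
        raise SegmenterHookError(f"frame file missing: {frame_path}")
    mask_path = frame_path.with_name(frame_path.stem + "_extmask.png")
    proc = subprocess.run(
        [*command, str(frame_path), str(mask_path)], capture_output=True, text=True
    )
    if proc.returncode != 0:
        raise SegmenterHookError(
            f"segmenter exited {proc.returncode} on {frame_path.name}: "
            f"{proc.stderr.strip()[:500]}"
        )
    if not mask_path.exists():
        raise SegmenterHookError(f"segmenter produced no mask for {frame_path.name}")
    arr = np.asarray(Image.open(mask_path))
    if arr.ndim != 2 or (arr.shape[1], arr.shape[0]) != tuple(expected_size):
        raise SegmenterHookError(
            f"mask for {frame_path.name} has shape {arr.shape}, "
            f"expected (h, w) = {expected_size[::-1]}"
        )
    return SegmentationMask(arr > 0, frame_id=frame_id, source="external-model")


# ---------------------------------------------------------------------------
# Annotation interchange


def load_polygons_json(path: str | Path) -> list[AnnotationPolygon]:
    """Plain JSON schema: ``[{"frame_id", "label", "vertices": [[x, y], ...]}]``."""
    with open(path) as fh:
        records = json.load(fh)
    return [
        AnnotationPolygon(
            frame_id=r["frame_id"],
            vertices=tuple((float(x), float(y)) for x, y in r["vertices"]),
            label=r.get("label", "seaweed"),
        )
        for r in records
    ]


def load_polygons_cvat(path: str | Path) -> list[AnnotationPolygon]:
    """Read-only import of the CVAT XML 1.1 polygon dialect.

    Only ``<image>/<polygon>`` elements are consumed; ``points`` is the
    semicolon-separated ``x,y`` list CVAT exports.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    polys: list[AnnotationPolygon] = []
    for image in root.iter("image"):
        frame_id = image.get("name", image.get("id", ""))
        for pg in image.iter("polygon"):
            pts = tuple(
                tuple(float(c) for c in pair.split(","))
                for pair in pg.get("points", "").split(";")
                if pair
            )
            polys.append(
                AnnotationPolygon(
                    frame_id=frame_id,
                    vertices=pts,
                    label=pg.get("label", "seaweed"),
                )
            )
    return polys
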