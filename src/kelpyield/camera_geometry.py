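"""Pinhole stereo camera model and triangulation.

The camera is an in-air pinhole model for a rectified, horizontally displaced
stereo pair: disparity is purely horizontal and depth follows ``Z = b * f / d``
with baseline ``b`` (meters), focal length ``f`` (pixels) and disparity ``d``
(pixels).  Refraction at the housing/water interface is ignored by
construction (the imaging design keeps both optical axes orthogonal to the
interfaces), and no lens distortion is modeled.

Pixel coordinates are 0-based with the origin at the top-left corner,
x rightward, y downward.  A pixel ``(i, j)`` covers the unit square
``[i, i+1) x [j, j+1)`` so its center sits at ``(i + 0.5, j + 0.5)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path


class GeometryError(ValueError):
    """Raised for geometrically invalid inputs (e.g. non-positive disparity)."""


@dataclass(frozen=True)
class CameraModel:
    """Calibrated stereo pinhole camera.

    Parameters
    ----------
    focal_px_h, focal_px_v
        Focal length in pixels along the horizontal and vertical image axes.
        Square pixels (``focal_px_h == focal_px_v``) are the default in
        manifests that give a single focal value.
    cx, cy
        Principal point in pixel coordinates.
    baseline_m
        Stereo baseline in meters (distance between the two optical centers).
    width, height
        Image size in pixels.
    """

    focal_px_h: float
    focal_px_v: float
    cx: float
    cy: float
    baseline_m: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.focal_px_h <= 0 or self.focal_px_v <= 0:
            raise GeometryError("focal length must be positive")
        if self.baseline_m <= 0:
            raise GeometryError("baseline must be positive")
        if self.width < 1 or self.height < 1:
            raise GeometryError("image size components must be >= 1")

    @property
    def image_size(self) -> tuple[int, int]:
        return (self.width, self.height)

    @property
    def vertical_fov_deg(self) -> float:
        """Full vertical field of view derived from the intrinsics."""
        return math.degrees(2.0 * math.atan(self.height / (2.0 * self.focal_px_v)))

    @classmethod
    def from_manifest_dict(cls, d: dict) -> "CameraModel":
        """Build from the manifest camera block.

        Recognized keys: ``focal_px_h``, ``focal_px_v`` (or a single
        ``focal_px`` for square pixels), ``cx``, ``cy``, ``baseline_m``,
        ``width``, ``height``.  Missing principal point defaults to the image
        center.
        """
        if "focal_px" in d and "focal_px_h" not in d:
            fh = fv = float(d["focal_px"])
        else:
            fh = float(d["focal_px_h"])
            fv = float(d.get("focal_px_v", fh))
        width = int(d["width"])
        height = int(d["height"])
        cx = float(d.get("cx", width / 2.0))
        cy = float(d.get("cy", height / 2.0))
        return cls(fh, fv, cx, cy, float(d["baseline_m"]), width, height)

    def to_manifest_dict(self) -> dict:
        return {
            "focal_px_h": self.focal_px_h,
            "focal_px_v": self.focal_px_v,
            "cx": self.cx,
            "cy": self.cy,
            "baseline_m": self.baseline_m,
            "width": self.width,
            "height": self.height,
        }

    @classmethod
    def from_manifest(cls, path: str | Path) -> "CameraModel":
        with open(path) as fh:
            manifest = json.load(fh)
        block = manifest.get("camera", manifest)
        return cls.from_manifest_dict(block)


def triangulate(camera: CameraModel, disparity_px: float) -> float:
    """Depth in meters from a horizontal disparity, ``Z = b * f / d``.

    Raises :class:`GeometryError` for non-positive disparity, which marks an
    unmatchable or invalid pixel rather than a physical depth.
    """
    if disparity_px <= 0:
        raise GeometryError(
            f"disparity must be positive, got {disparity_px!r} (invalid/unmatchable pixel)"
        )
    return camera.baseline_m * camera.focal_px_h / disparity_px


def disparity_for_depth(camera: CameraModel, depth_m: float) -> float:
    """Inverse of :func:`triangulate`: ``d = b * f / Z``."""
    if depth_m <= 0:
        raise GeometryError("depth must be positive")
    return camera.baseline_m * camera.focal_px_h / depth_m


def pixel_footprint(camera: CameraModel, depth_m: float) -> tuple[float, float]:
    """Metric extent ``(width_m, height_m)`` of one pixel at a given depth.

    By similar triangles a pixel of side 1 px subtends ``Z / f`` meters, so
    the footprint *area* grows as ``Z**2`` — the reason range precision enters
    the area error budget with a factor of two.
    """
    if depth_m <= 0:
        raise GeometryError("depth must be positive")
    return (depth_m / camera.focal_px_h, depth_m / camera.focal_px_v)


def pixel_footprint_area(camera: CameraModel, depth_m: float) -> float:
    """Metric area of one pixel at ``depth_m``, in square meters."""
    w, h = pixel_footprint(camera, depth_m)
    return w * h


def min_viewing_distance(vertical_fov_deg: float, object_extent_m: float) -> float:
    """Nearest fronto-parallel distance at which a centered object fits in frame.

    For a vertical field of view ``fov`` and an object of vertical extent
    ``E`` centered in the frame, the object just fits at
    ``E / (2 * tan(fov / 2))``.
    """
    if not 0 < vertical_fov_deg < 180:
        raise GeometryError("vertical FOV must lie strictly between 0 and 180 degrees")
    if object_extent_m < 0:
        raise GeometryError("object extent must be non-negative")
    return object_extent_m / (2.0 * math.tan(math.radians(vertical_fov_deg) / 2.0))
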