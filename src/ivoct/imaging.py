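"""Render A-lines into cross-sectional / longitudinal OCT images and files.

A cross-sectional frame is the single A-line rotated about the catheter
axis (the model is axisymmetric, so one depth profile defines the whole
frame); the longitudinal image stacks the per-frame radial profiles,
mirrored about the axis, in order of lens position.  Output is plain linear
8-bit grayscale; nearest-sample radial lookup keeps rendering bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import tifffile

from .optics import ALine

__all__ = [
    "CrossSectionImage",
    "LongitudinalImage",
    "render_cross_section",
    "stack_longitudinal",
    "write_image",
]

IMAGE_EXTENT_MM = 10.0  # cross-section spans 10 x 10 mm centred on the axis
MAX_RADIUS_MM = 5.0


@dataclass(frozen=True)
class CrossSectionImage:
    pixels: np.ndarray  # (size, size) uint8
    lens_z_mm: float | None = None
    frame_index: int | None = None


@dataclass(frozen=True)
class LongitudinalImage:
    pixels: np.ndarray  # (2 * n_radial, n_frames) uint8
    z_mm: np.ndarray | None = None  # column coordinates


def _full_radius_profile(aline: ALine) -> tuple[np.ndarray, np.ndarray]:
    """Grayscale vs radius on [0, 5] mm; inside the catheter renders black."""
    dr = float(aline.r[1] - aline.r[0])
    r_inner = np.arange(0.0, aline.r[0] - dr / 2, dr)
    r = np.concatenate([r_inner, aline.r])
    g = np.concatenate([np.zeros(r_inner.size, dtype=np.uint8), aline.G])
    keep = r <= MAX_RADIUS_MM + 1e-12
    return r[keep], g[keep]


def render_cross_section(
    aline: ALine,
    size: int = 512,
    lens_z_mm: float | None = None,
    frame_index: int | None = None,
) -> CrossSectionImage:
    """Rotate one A-line into a square cross-sectional frame.

    Pixel values come from a nearest-sample lookup of the grayscale profile
    at each pixel's radial distance; pixels beyond 5 mm are zero.  The
    result is exactly invariant under 90-degree rotations.
    """
    if size < 2:
        raise ValueError("image size must be at least 2 pixels")
    r_prof, g_prof = _full_radius_profile(aline)
    half = IMAGE_EXTENT_MM / 2.0
    coords = (np.arange(size) + 0.5) / size * IMAGE_EXTENT_MM - half
    rr = np.hypot(coords[:, None], coords[None, :])
    dr = r_prof[1] - r_prof[0]
    idx = np.rint((rr - r_prof[0]) / dr).astype(int)
    inside = (idx >= 0) & (idx < r_prof.size) & (rr <= MAX_RADIUS_MM)
    pixels = np.zeros((size, size), dtype=np.uint8)
    pixels[inside] = g_prof[np.clip(idx[inside], 0, r_prof.size - 1)]
    return CrossSectionImage(pixels=pixels, lens_z_mm=lens_z_mm, frame_index=frame_index)


def stack_longitudinal(
    frames: list[ALine], lens_z_mm: np.ndarray | list[float] | None = None
) -> LongitudinalImage:
    """Stack per-frame A-lines into a longitudinal cut image.

    Columns are ordered by increasing lens position; each column is the
    radial grayscale profile mirrored about the axis row.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    profiles = []
    ref_r = None
    for aline in frames:
        r, gprof = _full_radius_profile(aline)
        if ref_r is None:
            ref_r = r
        elif r.shape != ref_r.shape or not np.allclose(r, ref_r):
            raise ValueError("frames must share a common radial grid")
        profiles.append(gprof)
    cols = np.stack(profiles, axis=1)  # (n_radial, n_frames)
    z = None
    if lens_z_mm is not None:
        z = np.asarray(lens_z_mm, dtype=float)
        if z.size != cols.shape[1]:
            raise ValueError("lens_z_mm length must match the frame count")
        order = np.argsort(z, kind="stable")
        cols = cols[:, order]
        z = z[order]
    pixels = np.concatenate([cols[::-1, :], cols], axis=0).astype(np.uint8)
    return LongitudinalImage(pixels=pixels, z_mm=z)


def write_image(image, path: str, fmt: str | None = None) -> None:
    """Write an image as 8-bit grayscale PNG or TIFF (bit-exact round-trip)."""
    pixels = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    if pixels.dtype != np.uint8:
        raise ValueError("images must be 8-bit grayscale (uint8)")
    if fmt is None:
        lowered = path.lower()
        if lowered.endswith(".png"):
            fmt = "PNG"
        elif lowered.endswith((".tif", ".tiff")):
            fmt = "TIFF"
        else:
            raise ValueError(f"cannot infer image format from {path!r}")
    fmt = fmt.upper()
    if fmt == "PNG":
        iio.imwrite(path, pixels, extension=".png")
    elif fmt == "TIFF":
        tifffile.imwrite(path, pixels)
    else:
        raise ValueError(f"unsupported image format {fmt!r} (PNG or TIFF)")
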