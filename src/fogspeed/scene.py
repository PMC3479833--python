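"""Procedural road scenes with per-pixel depth.

The driving scenes used throughout the pipeline are a straight single-lane
road on a ground plane (asphalt centre, grass sides) under a homogeneous
grey sky.  Each frame carries an achromatic brightness channel (0-255, the
arithmetic mean of the R, G and B coordinates of a colour image) and a
per-pixel depth map in metres; sky pixels carry an infinite-depth sentinel
so that depth-dependent blending drives them exactly to the fog colour.

Geometry follows a pinhole camera at ``eye_height_m`` above the ground
plane, row 0 at the top of the image.  The focal length in pixels is fixed
at ``height_px`` (a vertical field of view of roughly 53 degrees), so the
depth of a ground pixel ``dr`` rows below the horizon is
``eye_height_m * height_px / dr``: strictly decreasing towards the bottom
of the image.

Surface texture is seeded value noise evaluated in world coordinates, so
its apparent wavelength shrinks with distance (perspective foreshortening)
and frames are bit-reproducible for a fixed spec.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "SceneSpec",
    "SceneFrame",
    "make_road_scene",
    "central_peripheral_split",
    "save_frame",
    "load_frame",
]

#: brightness of the untextured asphalt centre strip
ROAD_LEVEL = 96.0
#: brightness of the untextured grass shoulders
GRASS_LEVEL = 150.0
#: size of the wrap-around value-noise lattice
_LATTICE = 256


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a procedurally generated road scene.

    Attributes
    ----------
    width_px, height_px
        Frame dimensions in pixels.
    horizon_row
        Row index of the horizon; rows at or above it are sky.
    eye_height_m
        Camera height above the ground plane (metres).
    road_half_width_m
        Half-width of the asphalt strip (metres).
    texture_contrast
        Peak-to-mean relative amplitude of the surface texture, in [0, 1].
        Zero yields piecewise-constant road/grass levels.
    texture_scale_px
        Apparent texture wavelength, in pixels, at the reference depth
        (three quarters of the way down the below-horizon region).
    sky_brightness
        Uniform sky level, 0-255.  128 equals the fog colour, making the
        sky a fixed point of fog blending.
    seed
        Texture seed; identical specs produce bit-identical frames.
    """

    width_px: int
    height_px: int
    horizon_row: int
    eye_height_m: float = 0.8
    road_half_width_m: float = 2.0
    texture_contrast: float = 0.35
    texture_scale_px: int = 6
    sky_brightness: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("frame dimensions must be positive")
        if not (0 < self.horizon_row < self.height_px):
            raise ValueError("horizon_row must lie strictly inside the image")
        if not (0.0 <= self.texture_contrast <= 1.0):
            raise ValueError("texture_contrast must be in [0, 1]")
        if self.texture_scale_px <= 0:
            raise ValueError("texture_scale_px must be positive")
        if self.eye_height_m <= 0:
            raise ValueError("eye_height_m must be positive")
        if self.road_half_width_m <= 0:
            raise ValueError("road_half_width_m must be positive")
        if not (0 <= self.sky_brightness <= 255):
            raise ValueError("sky_brightness must be in [0, 255]")

    @property
    def focal_px(self) -> float:
        """Pinhole focal length in pixels (fixed convention: image height)."""
        return float(self.height_px)


@dataclass
class SceneFrame:
    """A rendered frame: achromatic brightness plus per-pixel depth.

    ``brightness`` is in [0, 255]; ``depth_m`` is positive with ``inf`` for
    sky.  Both arrays share a shape of ``(height_px, width_px)``.
    """

    brightness: np.ndarray
    depth_m: np.ndarray
    spec: SceneSpec = field(repr=False)

    def __post_init__(self) -> None:
        self.brightness = np.asarray(self.brightness, dtype=float)
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        if self.brightness.shape != self.depth_m.shape:
            raise ValueError("brightness and depth_m must have identical shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.brightness.shape


def _value_noise(rng: np.random.Generator, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Bilinear value noise in [-1, 1] on a seeded wrap-around lattice."""
    lattice = rng.uniform(-1.0, 1.0, size=(_LATTICE, _LATTICE))
    i0 = np.floor(u).astype(int)
    j0 = np.floor(v).astype(int)
    fu = u - i0
    fv = v - j0
    i0 %= _LATTICE
    j0 %= _LATTICE
    i1 = (i0 + 1) % _LATTICE
    j1 = (j0 + 1) % _LATTICE
    # smoothstep weights avoid lattice-aligned creases
    fu = fu * fu * (3.0 - 2.0 * fu)
    fv = fv * fv * (3.0 - 2.0 * fv)
    return (
        lattice[i0, j0] * (1 - fu) * (1 - fv)
        + lattice[i1, j0] * fu * (1 - fv)
        + lattice[i0, j1] * (1 - fu) * fv
        + lattice[i1, j1] * fu * fv
    )


def make_road_scene(spec: SceneSpec) -> SceneFrame:
    """Render a straight-road frame with its ground-plane depth map.

    Ground depth is obtained by back-projecting each below-horizon row
    through a pinhole at ``spec.eye_height_m``; texture is seeded value
    noise in world coordinates with peak-to-mean amplitude proportional to
    ``spec.texture_contrast``.  Deterministic for a fixed spec.
    """
    h, w = spec.height_px, spec.width_px
    f_px = spec.focal_px
    brightness = np.full((h, w), float(spec.sky_brightness))
    depth = np.full((h, w), np.inf)

    rows = np.arange(spec.horizon_row + 1, h)
    if rows.size:
        dr = rows - spec.horizon_row
        d_row = spec.eye_height_m * f_px / dr  # metres, strictly decreasing
        depth[rows, :] = d_row[:, None]

        cols = np.arange(w) - (w - 1) / 2.0
        x_m = cols[None, :] / f_px * d_row[:, None]  # lateral offset, metres
        road = np.abs(x_m) <= spec.road_half_width_m
        base = np.where(road, ROAD_LEVEL, GRASS_LEVEL)

        if spec.texture_contrast > 0.0:
            # texture wavelength in metres chosen so it spans
            # texture_scale_px pixels at a reference depth 3/4 down the
            # ground region; evaluating noise in world coordinates then
            # yields perspective foreshortening automatically.
            d_ref = d_row[int(round(0.75 * (d_row.size - 1)))]
            lam_m = spec.texture_scale_px * d_ref / f_px
            rng = np.random.default_rng(spec.seed)
            noise = _value_noise(rng, x_m / lam_m, d_row[:, None] / lam_m * np.ones_like(x_m))
            base = base * (1.0 + spec.texture_contrast * 0.5 * noise)

        brightness[rows, :] = np.clip(base, 0.0, 255.0)

    return SceneFrame(brightness=brightness, depth_m=depth, spec=spec)


def central_peripheral_split(
    frame: SceneFrame, central_halfwidth_deg: float, px_per_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split a frame into central and peripheral boolean masks.

    The central mask is the axis-aligned window of the given angular
    half-width around the image centre (clamped to the frame); the
    peripheral mask is its complement, so the two masks are disjoint and
    cover the frame.
    """
    if central_halfwidth_deg < 0 or px_per_deg <= 0:
        raise ValueError("half-width must be >= 0 and px_per_deg positive")
    h, w = frame.shape
    hw_px = int(round(central_halfwidth_deg * px_per_deg))
    if hw_px > max(h, w):
        raise ValueError("central half-width exceeds the frame")
    central = np.zeros((h, w), dtype=bool)
    r_lo, r_hi = max(0, h // 2 - hw_px), min(h, h // 2 + hw_px)
    c_lo, c_hi = max(0, w // 2 - hw_px), min(w, w // 2 + hw_px)
    central[r_lo:r_hi, c_lo:c_hi] = True
    return central, ~central


def save_frame(frame: SceneFrame, png_path: str | Path, depth_path: str | Path) -> None:
    """Write brightness as 8-bit grayscale PNG and depth as a CSV sidecar."""
    img = Image.fromarray(np.clip(np.rint(frame.brightness), 0, 255).astype(np.uint8), mode="L")
    img.save(png_path)
    with open(depth_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in frame.depth_m:
            writer.writerow(f"{v:.9g}" for v in row)


def load_frame(png_path: str | Path, depth_path: str | Path, spec: SceneSpec | None = None) -> SceneFrame:
    """Read a frame written by :func:`save_frame`.

    Brightness is quantised to 8 bits by the PNG round trip; depth is exact
    to the CSV's printed precision (``inf`` survives the round trip).
    """
    brightness = np.asarray(Image.open(png_path).convert("L"), dtype=float)
    depth = np.loadtxt(depth_path, delimiter=",", dtype=float)
    depth = np.atleast_2d(depth)
    if spec is None:
        h, w = brightness.shape
        spec = SceneSpec(width_px=w, height_px=h, horizon_row=max(1, h // 2))
    return SceneFrame(brightness=brightness, depth_m=depth, spec=spec)
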