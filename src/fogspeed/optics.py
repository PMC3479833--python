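"""Contrast reduction models, luminance calibration and contrast matching.

Three ways of degrading a scene's visibility are implemented, all as
per-pixel alpha blending of the scene with a grey fog colour,
``C_r = C_o * alpha + C_f * (1 - alpha)``:

* **fog** — distance-dependent, ``alpha = exp(-f * d)``: close objects
  stay visible, distant ones vanish into the fog.  Density ``f`` is an
  attenuation rate per metre; its meteorological visibility range (MVR,
  the distance at which a white object retains 5 % contrast) is
  ``ln(20) / f``.
* **anti-fog** — the reversed gradient, ``alpha = 1 - exp(-af * d)``:
  close objects are obscured and visibility improves with distance.
* **uniform** — distance-independent, ``alpha = 1 - opacity`` everywhere,
  the classic "dirty windshield" manipulation.

Global contrast is summarised as normalised RMS contrast, sigma/mu of the
pixel luminance after mapping brightness through a quadratic display
calibration.  Matching solvers find the uniform opacity or anti-fog
density whose global contrast equals that of a given fog condition, which
is how the conditions of the underlying experiments were equated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .scene import SceneFrame

__all__ = [
    "CalibrationCurve",
    "FogParams",
    "AntiFogParams",
    "UniformParams",
    "ContrastReport",
    "blend",
    "fog_alpha",
    "antifog_alpha",
    "apply_condition",
    "luminance_of",
    "rms_contrast",
    "mvr_from_density",
    "density_from_mvr",
    "match_uniform_opacity",
    "match_antifog_density",
]

#: contrast threshold defining the meteorological visibility range
MVR_CONTRAST_THRESHOLD = 0.05
#: solver tolerance on matched RMS contrast
MATCH_TOL = 1e-6
_MAX_BISECT = 200
#: anti-fog density solver bracket, per metre
AF_BRACKET = (1e-6, 1e3)


@dataclass(frozen=True)
class CalibrationCurve:
    """Quadratic map from display brightness (0-255) to luminance (cd/m2).

    ``L(b) = a2*b**2 + a1*b + a0``; the map must be non-negative and
    monotone non-decreasing over [0, 255], which is checked on
    construction (the fitted photometer curve of a real display is).
    """

    a2: float
    a1: float
    a0: float
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        # derivative 2*a2*b + a1 is linear: checking the endpoints suffices
        if min(self.a1, 2 * self.a2 * 255 + self.a1) < 0:
            raise ValueError("calibration must be monotone non-decreasing on [0, 255]")
        if self(0.0) < 0 or self(255.0) < 0:
            raise ValueError("calibration must be non-negative on [0, 255]")

    def __call__(self, brightness: np.ndarray | float) -> np.ndarray | float:
        b = np.asarray(brightness, dtype=float)
        out = self.a2 * b * b + self.a1 * b + self.a0
        return float(out) if np.isscalar(brightness) else out

    @classmethod
    def identity(cls) -> "CalibrationCurve":
        """Luminance numerically equal to brightness (unit-slope linear map)."""
        return cls(a2=0.0, a1=1.0, a0=0.0)


@dataclass(frozen=True)
class FogParams:
    """Distance-dependent contrast reduction: ``alpha = exp(-density_f * d)``."""

    density_f: float
    fog_brightness: float = 128.0

    def __post_init__(self) -> None:
        if self.density_f < 0:
            raise ValueError("fog density must be >= 0")


@dataclass(frozen=True)
class AntiFogParams:
    """Reversed gradient: ``alpha = 1 - exp(-density_af * d)``.

    ``density_af = 0`` is the degenerate fully-obscured scene (alpha = 0
    everywhere); the clear scene is recovered only in the ``af -> inf``
    limit.
    """

    density_af: float
    fog_brightness: float = 128.0

    def __post_init__(self) -> None:
        if self.density_af < 0:
            raise ValueError("anti-fog density must be >= 0")


@dataclass(frozen=True)
class UniformParams:
    """Distance-independent reduction through a translucent grey plane."""

    opacity: float
    fog_brightness: float = 128.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.opacity <= 1.0):
            raise ValueError("opacity must be in [0, 1]")


@dataclass(frozen=True)
class ContrastReport:
    """Global contrast summary of a frame (sigma/mu of pixel luminance)."""

    rms_contrast: float
    mean_luminance: float
    condition_label: str = ""


def blend(
    original_brightness: np.ndarray | float,
    fog_brightness: float,
    alpha: np.ndarray | float,
) -> np.ndarray | float:
    """Alpha-blend scene brightness with the fog colour.

    Returns ``C_o * alpha + C_f * (1 - alpha)``, which always lies within
    the closed interval bounded by the two inputs.
    """
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("alpha must be in [0, 1]")
    out = np.asarray(original_brightness, dtype=float) * a + fog_brightness * (1.0 - a)
    return float(out) if out.ndim == 0 else out


def fog_alpha(d: np.ndarray | float, params: FogParams) -> np.ndarray | float:
    """Fog blending factor ``exp(-f * d)``; 1 at d=0, 0 at infinite depth."""
    dd = np.asarray(d, dtype=float)
    if np.any(dd < 0):
        raise ValueError("distance must be >= 0")
    if params.density_f == 0.0:
        out = np.ones_like(dd)  # clear visibility, even at infinite depth
    else:
        out = np.exp(-params.density_f * dd)
    return float(out) if out.ndim == 0 else out


def antifog_alpha(d: np.ndarray | float, params: AntiFogParams) -> np.ndarray | float:
    """Anti-fog blending factor ``1 - exp(-af * d)``; 0 at d=0."""
    dd = np.asarray(d, dtype=float)
    if np.any(dd < 0):
        raise ValueError("distance must be >= 0")
    if params.density_af == 0.0:
        out = np.zeros_like(dd)  # degenerate: everything fully obscured
    else:
        out = -np.expm1(-params.density_af * dd)
    return float(out) if out.ndim == 0 else out


def apply_condition(
    frame: SceneFrame, condition: FogParams | AntiFogParams | UniformParams
) -> SceneFrame:
    """Apply a visibility condition per pixel; depth passes through unchanged."""
    if frame.brightness.shape != frame.depth_m.shape:
        raise ValueError("frame brightness/depth shape mismatch")
    if isinstance(condition, FogParams):
        alpha = fog_alpha(frame.depth_m, condition)
    elif isinstance(condition, AntiFogParams):
        alpha = antifog_alpha(frame.depth_m, condition)
    elif isinstance(condition, UniformParams):
        alpha = 1.0 - condition.opacity
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported condition type: {type(condition)!r}")
    blended = blend(frame.brightness, condition.fog_brightness, alpha)
    return SceneFrame(
        brightness=np.asarray(blended, dtype=float),
        depth_m=frame.depth_m.copy(),
        spec=frame.spec,
    )


def luminance_of(frame: SceneFrame, cal: CalibrationCurve) -> np.ndarray:
    """Map frame brightness to luminance (cd/m2) through the calibration."""
    return np.asarray(cal(frame.brightness), dtype=float)


def rms_contrast(
    frame: SceneFrame,
    cal: CalibrationCurve,
    mask: np.ndarray | None = None,
    label: str = "",
) -> ContrastReport:
    """Normalised RMS contrast sigma_L / mu_L over the frame (or a mask).

    Population standard deviation over all evaluated pixels; zero for a
    constant region.
    """
    lum = luminance_of(frame, cal)
    if mask is not None:
        lum = lum[mask]
    if lum.size == 0:
        raise ValueError("empty region")
    mu = float(lum.mean())
    if mu <= 0:
        raise ValueError("mean luminance must be positive for RMS contrast")
    return ContrastReport(
        rms_contrast=float(lum.std()) / mu, mean_luminance=mu, condition_label=label
    )


def mvr_from_density(f: float) -> float:
    """Meteorological visibility range ln(20)/f: depth where alpha hits 5 %."""
    if f <= 0:
        raise ValueError("fog density must be > 0")
    return math.log(1.0 / MVR_CONTRAST_THRESHOLD) / f


def density_from_mvr(mvr: float) -> float:
    """Fog density whose MVR is the given distance (exact inverse)."""
    if mvr <= 0:
        raise ValueError("MVR must be > 0")
    return math.log(1.0 / MVR_CONTRAST_THRESHOLD) / mvr


def _bisect_to_contrast(
    contrast_of: "callable",
    lo: float,
    hi: float,
    target: float,
    increasing: bool,
) -> float:
    """Bisection on a monotone parameter->contrast map, to MATCH_TOL on contrast."""
    for _ in range(_MAX_BISECT):
        mid = 0.5 * (lo + hi)
        c = contrast_of(mid)
        if abs(c - target) <= MATCH_TOL:
            return mid
        if (c < target) == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def match_uniform_opacity(
    frame: SceneFrame, cal: CalibrationCurve, target_rms: float, fog_brightness: float = 128.0
) -> float:
    """Opacity of the uniform plane whose global contrast equals ``target_rms``.

    The opacity -> contrast map is monotone decreasing (opacity 0 is the
    clear frame, opacity 1 a constant frame), so bisection converges;
    targets above the clear-frame contrast are infeasible.
    """
    clear = rms_contrast(frame, cal).rms_contrast
    if target_rms < 0:
        raise ValueError("target RMS contrast must be >= 0")
    if target_rms > clear + MATCH_TOL:
        raise ValueError(
            f"target contrast {target_rms:.6g} exceeds clear-frame contrast {clear:.6g}"
        )

    def contrast_of(op: float) -> float:
        cond = UniformParams(opacity=op, fog_brightness=fog_brightness)
        return rms_contrast(apply_condition(frame, cond), cal).rms_contrast

    if abs(target_rms - clear) <= MATCH_TOL:
        return 0.0
    return _bisect_to_contrast(contrast_of, 0.0, 1.0, target_rms, increasing=False)


def match_antifog_density(
    frame: SceneFrame, cal: CalibrationCurve, target_rms: float, fog_brightness: float = 128.0
) -> float:
    """Anti-fog density whose global contrast equals ``target_rms``.

    The af -> contrast map increases from 0 (af -> 0: fully obscured) to
    the clear-frame contrast (af -> inf); the solver brackets af in
    ``AF_BRACKET`` and reports infeasibility for targets beyond the upper
    bracket's contrast (e.g. the clear-frame contrast itself).
    """
    if target_rms < 0:
        raise ValueError("target RMS contrast must be >= 0")
    clear = rms_contrast(frame, cal).rms_contrast
    if target_rms >= clear - MATCH_TOL:
        raise ValueError(
            "the clear-frame contrast is attained only in the af -> inf limit; "
            f"target {target_rms:.6g} is infeasible at finite density"
        )

    def contrast_of(af: float) -> float:
        cond = AntiFogParams(density_af=af, fog_brightness=fog_brightness)
        return rms_contrast(apply_condition(frame, cond), cal).rms_contrast

    lo, hi = AF_BRACKET
    if target_rms <= contrast_of(lo):
        return lo
    if target_rms > contrast_of(hi) + MATCH_TOL:
        raise ValueError(
            "target contrast not reachable within the anti-fog density bracket "
            f"{AF_BRACKET}; the clear-frame contrast is attained only as af -> inf"
        )
    return _bisect_to_contrast(contrast_of, lo, hi, target_rms, increasing=True)


def match_fog_density(
    frame: SceneFrame, cal: CalibrationCurve, target_rms: float, fog_brightness: float = 128.0
) -> float:
    """Fog density whose global contrast equals ``target_rms`` (decreasing map)."""
    clear = rms_contrast(frame, cal).rms_contrast
    if not (0 <= target_rms <= clear + MATCH_TOL):
        raise ValueError("target contrast must lie in [0, clear-frame contrast]")

    def contrast_of(f: float) -> float:
        cond = FogParams(density_f=f, fog_brightness=fog_brightness)
        return rms_contrast(apply_condition(frame, cond), cal).rms_contrast

    if abs(target_rms - clear) <= MATCH_TOL:
        return 0.0
    return _bisect_to_contrast(contrast_of, 0.0, AF_BRACKET[1], target_rms, increasing=False)
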