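"""Generative synthetic observers for the speed-perception experiments.

An observer perceives a scene moving at ``v`` km/hr under condition ``c``
as ``g_c * v * exp(eps)`` with log-normal internal noise, where the
condition gain ``g_c`` (> 1: overestimation, < 1: underestimation)
captures the perceptual bias that the contrast manipulation induces.
From this single mechanism follow both tasks:

* **2IFC comparison** against a clear reference: responses are Bernoulli
  with an implied cumulative-Gaussian-in-log-speed psychometric function
  whose location is ``pse = reference * g_clear / g_c`` and whose slope is
  ``sqrt(2) * noise_sigma`` (two independent noisy intervals).
* **speed production**: the driver settles on the speed whose percept
  matches the remembered target, ``produced = (target / g_c) * exp(eps')``
  — overestimation makes them drive slower, and vice versa.

Gains can be set directly ("calibrated" mode, from measured PSEs) or
derived from the rendered scene's central/peripheral contrast profile
("mechanistic" mode): fog spares the near periphery and obscures the
centre of the visual field, so a peripheral/central relative-contrast
rule with positive exponent produces gain > 1 under fog and < 1 under
anti-fog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .optics import CalibrationCurve, rms_contrast
from .scene import SceneFrame, central_peripheral_split

__all__ = [
    "ObserverParams",
    "ContrastGainRule",
    "calibrated_gains",
    "gain_from_contrast",
    "perceive_speed",
    "respond_2ifc",
    "produce_speed",
]

CLEAR = "clear"


@dataclass(frozen=True)
class ObserverParams:
    """Condition-dependent perceived-speed gains plus internal noise.

    ``gains`` maps condition label -> multiplicative gain (1 = veridical;
    the clear condition defaults to 1 if absent).  ``noise_sigma`` is the
    per-interval log-speed noise; ``production_noise_sigma`` the log-speed
    variability of produced speeds.
    """

    gains: dict[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.15
    lapse: float = 0.02
    production_noise_sigma: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        gains = dict(self.gains)
        gains.setdefault(CLEAR, 1.0)
        object.__setattr__(self, "gains", gains)
        if any(g <= 0 for g in gains.values()):
            raise ValueError("all gains must be > 0")
        if self.noise_sigma < 0 or self.production_noise_sigma < 0:
            raise ValueError("noise parameters must be >= 0")
        if not (0.0 <= self.lapse <= 0.1):
            raise ValueError("lapse must be in [0, 0.1]")

    def gain(self, condition: str) -> float:
        try:
            return self.gains[condition]
        except KeyError:
            raise KeyError(f"unknown condition label: {condition!r}") from None


@dataclass(frozen=True)
class ContrastGainRule:
    """Peripheral/central relative-contrast gain rule.

    ``gain = (C_periph / C_central) ** exponent_kappa`` with each region's
    contrast normalised by the same region's clear-frame contrast.
    ``exponent_kappa = 0`` collapses every condition to veridical gain 1.
    ``px_per_deg`` converts the angular half-width of the central window
    into pixels for the split.
    """

    exponent_kappa: float = 1.0
    central_halfwidth_deg: float = 10.0
    px_per_deg: float = 4.0

    def __post_init__(self) -> None:
        if self.exponent_kappa < 0:
            raise ValueError("exponent_kappa must be >= 0")


def calibrated_gains(pse_clear: float, pse_by_condition: dict[str, float]) -> dict[str, float]:
    """Condition gains from measured PSEs: ``g_c = PSE_clear / PSE_c``.

    A condition matched at a lower test speed than clear (PSE below the
    clear PSE) is one that makes motion look faster, hence gain > 1.
    """
    if pse_clear <= 0 or any(p <= 0 for p in pse_by_condition.values()):
        raise ValueError("PSEs must be positive")
    gains = {c: pse_clear / p for c, p in pse_by_condition.items()}
    gains[CLEAR] = 1.0
    return gains


def gain_from_contrast(
    frame_clear: SceneFrame,
    frame_condition: SceneFrame,
    cal: CalibrationCurve,
    rule: ContrastGainRule,
) -> float:
    """Perceived-speed gain from the condition frame's contrast profile.

    Fog leaves the near periphery clearer than the image centre, giving a
    peripheral/central contrast ratio above 1 and hence gain > 1;
    anti-fog reverses the gradient (gain < 1); a uniform reduction
    attenuates both regions equally (gain 1).  A condition that wipes out
    central contrast entirely is flagged as an infinite-gain condition.
    """
    if frame_clear.shape != frame_condition.shape:
        raise ValueError("frames must share a scene spec")
    if rule.exponent_kappa == 0.0:
        return 1.0
    central, peripheral = central_peripheral_split(
        frame_clear, rule.central_halfwidth_deg, rule.px_per_deg
    )
    c_cen_clear = rms_contrast(frame_clear, cal, mask=central).rms_contrast
    c_per_clear = rms_contrast(frame_clear, cal, mask=peripheral).rms_contrast
    c_cen = rms_contrast(frame_condition, cal, mask=central).rms_contrast
    c_per = rms_contrast(frame_condition, cal, mask=peripheral).rms_contrast
    if c_cen_clear <= 0 or c_per_clear <= 0:
        raise ValueError("clear frame has zero contrast in a region; no gradient defined")
    if c_cen <= 0:
        warnings.warn("zero central contrast: infinite-gain condition")
        return float("inf")
    ratio = (c_per / c_per_clear) / (c_cen / c_cen_clear)
    return float(ratio**rule.exponent_kappa)


def perceive_speed(
    obs: ObserverParams, v: float, condition: str, rng: np.random.Generator
) -> float:
    """One noisy percept ``g_c * v * exp(eps)``; median over draws is g_c*v."""
    if v <= 0:
        raise ValueError("speed must be positive")
    g = obs.gain(condition)
    eps = rng.normal(0.0, obs.noise_sigma) if obs.noise_sigma > 0 else 0.0
    return g * v * float(np.exp(eps))


def respond_2ifc(
    obs: ObserverParams,
    reference_speed: float,
    test_speed: float,
    condition: str,
    rng: np.random.Generator,
    reference_condition: str = CLEAR,
) -> bool:
    """Simulate one 2IFC trial: is the test interval judged faster?

    With probability ``lapse`` the response is uniform at random;
    otherwise the two intervals' noisy percepts are compared.  The implied
    psychometric function is a cumulative Gaussian in log speed with
    location ``reference * g_ref / g_c`` and slope ``sqrt(2)*noise_sigma``.
    """
    if reference_speed <= 0 or test_speed <= 0:
        raise ValueError("speeds must be positive")
    if obs.lapse > 0 and rng.random() < obs.lapse:
        return bool(rng.random() < 0.5)
    p_test = perceive_speed(obs, test_speed, condition, rng)
    p_ref = perceive_speed(obs, reference_speed, reference_condition, rng)
    return bool(p_test > p_ref)


def produce_speed(
    obs: ObserverParams, target: float, condition: str, rng: np.random.Generator
) -> float:
    """Speed actually driven when trying to hold a remembered target.

    The driver equates the percept ``g_c * produced`` with the target, so
    ``produced = (target / g_c) * exp(eps')``: overestimation (g > 1)
    yields slower driving, underestimation faster.
    """
    if target <= 0:
        raise ValueError("target speed must be positive")
    g = obs.gain(condition)
    eps = (
        rng.normal(0.0, obs.production_noise_sigma)
        if obs.production_noise_sigma > 0
        else 0.0
    )
    return (target / g) * float(np.exp(eps))
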