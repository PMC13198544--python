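"""Stimulus and design generation for the three-dot colour/location task.

Each trial shows three coloured dots on an invisible circle around fixation.
Dot positions and hues are drawn uniformly on the circle, subject to a minimum
dot-centre distance (stated in degrees of visual angle and converted here to a
central-angle threshold on the stimulus circle) and a minimum hue separation on
the colour wheel.  Sampling is by rejection with a hard attempt cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from misbind.core import PROBE_CONDITIONS, Condition, circ_dist

__all__ = [
    "TaskGeometry",
    "StimulusArray",
    "DesignSpec",
    "min_location_sep_central_angle",
    "sample_stimulus_array",
    "make_design",
]

_MAX_REJECTION_ATTEMPTS = 10_000


@dataclass(frozen=True)
class TaskGeometry:
    """Display geometry of the dot array (degrees of visual angle / degrees).

    Defaults: dots of radius 0.7 dva on a circle of radius 6.5 dva, centres at
    least 1.4 dva apart, hues at least 5 deg apart on the colour wheel.
    """

    circle_radius_dva: float = 6.5
    dot_radius_dva: float = 0.7
    min_dot_distance_dva: float = 1.4
    min_hue_sep_deg: float = 5.0

    def __post_init__(self) -> None:
        if self.circle_radius_dva <= 0 or self.dot_radius_dva <= 0:
            raise ValueError("radii must be positive")
        if self.min_dot_distance_dva < 0 or self.min_hue_sep_deg < 0:
            raise ValueError("separations must be non-negative")
        if self.min_dot_distance_dva >= 2 * self.circle_radius_dva:
            raise ValueError(
                "min dot distance must be below the circle diameter"
            )


@dataclass(frozen=True)
class StimulusArray:
    """Colour and location angles (degrees) of the three studied dots."""

    colours: tuple[float, float, float]
    locations: tuple[float, float, float]
    presentation: str = "simultaneous"
    presentation_order: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.presentation not in ("simultaneous", "sequential"):
            raise ValueError(f"unknown presentation {self.presentation!r}")
        if self.presentation == "sequential":
            order = self.presentation_order
            if order is None or sorted(order) != [0, 1, 2]:
                raise ValueError("sequential arrays need a presentation order")


@dataclass(frozen=True)
class DesignSpec:
    """Counts and conditions of a simulated experiment."""

    n_subjects: int = 20
    trials_per_condition: int = 60
    presentation: str = "simultaneous"
    conditions: tuple[str, ...] = PROBE_CONDITIONS
    geometry: TaskGeometry = field(default_factory=TaskGeometry)

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.trials_per_condition <= 0:
            raise ValueError("counts must be positive")
        for c in self.conditions:
            Condition(c)  # validates


def min_location_sep_central_angle(geometry: TaskGeometry) -> float:
    """Minimum central angle (degrees) between dot centres on the circle.

    A chord of length ``d`` on a circle of radius ``r`` subtends a central
    angle of ``2 asin(d / 2r)``.
    """
    ratio = geometry.min_dot_distance_dva / (2.0 * geometry.circle_radius_dva)
    if ratio > 1.0:
        raise ValueError("impossible geometry: chord exceeds diameter")
    return math.degrees(2.0 * math.asin(ratio))


def _sample_separated_angles(
    rng: np.random.Generator, min_sep_deg: float, what: str
) -> tuple[float, float, float]:
    """Three uniform angles with pairwise circular separation >= min_sep_deg."""
    if 3.0 * min_sep_deg > 360.0:
        raise ValueError(
            f"infeasible {what} constraint: 3 x {min_sep_deg} deg > 360 deg"
        )
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        angles = rng.uniform(0.0, 360.0, size=3)
        d01 = abs(circ_dist(angles[0], angles[1]))
        d02 = abs(circ_dist(angles[0], angles[2]))
        d12 = abs(circ_dist(angles[1], angles[2]))
        if min(d01, d02, d12) >= min_sep_deg:
            return tuple(angles)
    raise ValueError(f"rejection sampling of {what} exceeded attempt cap")


def sample_stimulus_array(
    geometry: TaskGeometry,
    presentation: str = "simultaneous",
    rng: np.random.Generator | None = None,
) -> StimulusArray:
    """Draw one stimulus array satisfying the separation constraints."""
    rng = np.random.default_rng() if rng is None else rng
    loc_sep = min_location_sep_central_angle(geometry)
    locations = _sample_separated_angles(rng, loc_sep, "locations")
    colours = _sample_separated_angles(rng, geometry.min_hue_sep_deg, "hues")
    order = tuple(int(i) for i in rng.permutation(3)) if presentation == "sequential" else None
    return StimulusArray(colours, locations, presentation, order)


def make_design(
    spec: DesignSpec, rng: np.random.Generator | int | None = None
) -> list[tuple[int, Condition, StimulusArray]]:
    """Trial shells (subject, condition, stimuli) for a full design.

    Reproducible given an integer seed or a Generator; counts are exactly
    ``n_subjects * len(conditions) * trials_per_condition``.
    """
    rng = np.random.default_rng(rng)
    shells = []
    for subject in range(spec.n_subjects):
        for probe in spec.conditions:
            cond = Condition(probe)
            for _ in range(spec.trials_per_condition):
                stim = sample_stimulus_array(spec.geometry, spec.presentation, rng)
                shells.append((subject, cond, stim))
    return shells
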