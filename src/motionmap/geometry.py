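"""Stimulus geometry and circular (angular) arithmetic.

Angles are expressed in degrees of polar angle at the API surface. Position
index 0 sits at 12 o'clock and indices increase clockwise; positive velocity
denotes clockwise motion. Angular differences are always reduced to the
interval (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusGeometry",
    "wrap_angle",
    "angular_difference",
    "angular_error",
]


def wrap_angle(angle_deg):
    """Map angles (degrees) into [0, 360)."""
    return np.asarray(angle_deg, dtype=float) % 360.0


def angular_difference(a_deg, b_deg):
    """Signed circular difference ``a - b`` in degrees, reduced to (-180, 180]."""
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def angular_error(a_deg, b_deg):
    """Absolute circular difference in degrees, in [0, 180]."""
    return np.abs(angular_difference(a_deg, b_deg))


@dataclass(frozen=True)
class StimulusGeometry:
    """Circular layout of localizer positions and motion kinematics.

    Parameters
    ----------
    n_positions
        Number of equally spaced localizer positions on the circle.
    wedge_extent_deg
        Polar-angle extent of the wedge stimulus (metadata).
    inner_eccentricity_dva, outer_eccentricity_dva
        Eccentricity of the wedge's inner/outer edge in degrees of visual
        angle (metadata only; never used in computation).
    velocity_deg_s
        Signed angular velocity of smooth motion in degrees of polar angle
        per second. Positive = clockwise; 360 deg/s is one cycle per second.
    localizer_rate_hz
        Localizer onset rate (flashes per second).
    frame_rate_hz
        Display frame rate.
    """

    n_positions: int = 40
    wedge_extent_deg: float = 9.0
    inner_eccentricity_dva: float = 7.7
    outer_eccentricity_dva: float = 9.4
    velocity_deg_s: float = 360.0
    localizer_rate_hz: float = 5.0
    frame_rate_hz: float = 120.0

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if self.frame_rate_hz <= 0 or self.localizer_rate_hz <= 0:
            raise ValueError("rates must be positive")

    @property
    def spacing_deg(self) -> float:
        """Angular spacing between neighbouring positions (360 / n)."""
        return 360.0 / self.n_positions

    @property
    def position_angles(self) -> np.ndarray:
        """Angle of every position index, degrees in [0, 360)."""
        return np.arange(self.n_positions) * self.spacing_deg

    def angle_of(self, index) -> np.ndarray:
        """Angle (degrees) of a position index (or array of indices)."""
        return wrap_angle(np.asarray(index) * self.spacing_deg)

    def nearest_index(self, angle_deg) -> np.ndarray:
        """Index of the position nearest to an angle."""
        idx = np.rint(wrap_angle(angle_deg) / self.spacing_deg).astype(int)
        return idx % self.n_positions

    @property
    def step_per_frame_deg(self) -> float:
        """Angular step between successive display frames during motion."""
        return self.velocity_deg_s / self.frame_rate_hz

    @property
    def inter_position_interval_s(self) -> float:
        """Time for the moving stimulus to travel between adjacent positions."""
        return self.spacing_deg / abs(self.velocity_deg_s)

    @property
    def velocity_cycles_s(self) -> float:
        return self.velocity_deg_s / 360.0
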