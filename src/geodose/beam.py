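"""Treatment-machine beam geometry.

Gantry angles follow IEC 61217 for a head-first supine patient in DICOM LPS
coordinates: 0 deg puts the source anterior (-y), 90 deg at patient left (+x);
the gantry rotates in the axial plane about the superior-inferior (z) axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BeamGeometry:
    """Point-source projection geometry of the delivery machine.

    Parameters
    ----------
    sad : float
        Source-to-axis distance, mm (1000 for the machines modelled here).
    plane_distance : float
        Distance from isocenter to the fluence-encoding plane, mm, measured
        toward the source; must satisfy 0 < plane_distance < sad.
    angular_spacing : float
        Gantry sampling interval in degrees; must divide 360.
    isocenter : tuple of float
        (x, y, z) mm isocenter position in patient coordinates.
    """

    sad: float = 1000.0
    plane_distance: float = 300.0
    angular_spacing: float = 2.0
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0 < self.plane_distance < self.sad:
            raise ValueError("require 0 < plane_distance < sad")
        n = 360.0 / self.angular_spacing
        if abs(n - round(n)) > 1e-9:
            raise ValueError("angular_spacing must divide 360")
        object.__setattr__(self, "isocenter", tuple(float(v) for v in self.isocenter))

    @property
    def n_angles(self) -> int:
        return int(round(360.0 / self.angular_spacing))

    @property
    def magnification(self) -> float:
        """Lateral scale factor from the isocenter plane to the encoding plane."""
        return (self.sad - self.plane_distance) / self.sad

    def sampled_angles(self) -> np.ndarray:
        """The sampled gantry angles, deg, [0, 360)."""
        return np.arange(self.n_angles) * self.angular_spacing

    def source_direction(self, gantry_angle_deg: float) -> np.ndarray:
        """Unit vector from isocenter toward the source."""
        t = np.deg2rad(gantry_angle_deg)
        return np.array([np.sin(t), -np.cos(t), 0.0])

    def source_position(self, gantry_angle_deg: float) -> np.ndarray:
        return np.asarray(self.isocenter) + self.sad * self.source_direction(
            gantry_angle_deg
        )

    def fm_axes(self, gantry_angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
        """Unit vectors (u_hat, v_hat) of the fluence-map plane at this angle.

        u is the crossplane axis (leaf travel), v the inplane axis (+z,
        patient superior); both are perpendicular to the central axis.
        """
        t = np.deg2rad(gantry_angle_deg)
        u_hat = np.array([np.cos(t), np.sin(t), 0.0])
        v_hat = np.array([0.0, 0.0, 1.0])
        return u_hat, v_hat

    def nearest_angle_bin(self, gantry_angle_deg: float) -> int:
        """Index of the nearest sampled angle; exact midpoints round to the
        lower bin (circularly)."""
        a = float(gantry_angle_deg) % 360.0
        return int(np.ceil(a / self.angular_spacing - 0.5)) % self.n_angles
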