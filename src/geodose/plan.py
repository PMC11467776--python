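"""VMAT plan model: arcs of machine control points.

Leaf and jaw positions are stated in millimetres projected to the isocenter
plane, as DICOM RTPLAN records them. Bank A is the negative-x bank (its leaf
tip position is the lower edge of the opening), bank B the positive-x bank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ControlPoint:
    """One machine state of a dynamic arc.

    ``cumulative_weight`` is the cumulative meterset weight in [0, 1];
    a control point's MU share is its increment over the previous control
    point times the beam MU.
    """

    gantry_angle: float  # deg, [0, 360)
    mlc_a: np.ndarray  # (n_leaf_pairs,) mm, bank A leaf tip (lower x edge)
    mlc_b: np.ndarray  # (n_leaf_pairs,) mm, bank B leaf tip (upper x edge)
    cumulative_weight: float

    def __post_init__(self) -> None:
        self.mlc_a = np.asarray(self.mlc_a, dtype=float)
        self.mlc_b = np.asarray(self.mlc_b, dtype=float)
        if self.mlc_a.shape != self.mlc_b.shape:
            raise ValueError("MLC banks must have equal leaf counts")
        if np.any(self.mlc_a > self.mlc_b + 1e-9):
            raise ValueError("bank A leaf edge exceeds bank B edge (negative gap)")
        self.gantry_angle = float(self.gantry_angle) % 360.0
        self.cumulative_weight = float(self.cumulative_weight)


@dataclass
class Arc:
    """One treatment arc: its control points and shared machine settings."""

    control_points: list[ControlPoint]
    leaf_boundaries: np.ndarray  # (n_leaf_pairs + 1,) mm, y edges of leaf rows
    jaws_x: tuple[float, float]  # mm (x1, x2)
    jaws_y: tuple[float, float]  # mm (y1, y2)
    beam_mu: float  # monitor units delivered by this arc

    def __post_init__(self) -> None:
        self.leaf_boundaries = np.asarray(self.leaf_boundaries, dtype=float)
        if np.any(np.diff(self.leaf_boundaries) <= 0):
            raise ValueError("leaf row boundaries must be strictly increasing")
        if not self.control_points:
            raise ValueError("arc has no control points")
        n_rows = len(self.leaf_boundaries) - 1
        for cp in self.control_points:
            if cp.mlc_a.shape[0] != n_rows:
                raise ValueError("control point leaf count does not match boundaries")
        w = np.array([cp.cumulative_weight for cp in self.control_points])
        if np.any(np.diff(w) < -1e-9):
            raise ValueError("cumulative meterset weight must be non-decreasing")
        if w[0] < -1e-9 or w[-1] > 1 + 1e-9:
            raise ValueError("cumulative meterset weight must lie in [0, 1]")
        if self.beam_mu <= 0:
            raise ValueError("beam MU must be positive")
        self.jaws_x = (float(self.jaws_x[0]), float(self.jaws_x[1]))
        self.jaws_y = (float(self.jaws_y[0]), float(self.jaws_y[1]))
        if self.jaws_x[0] >= self.jaws_x[1] or self.jaws_y[0] >= self.jaws_y[1]:
            raise ValueError("jaw intervals must be non-empty")


@dataclass
class PlanModel:
    """A VMAT plan: one or more arcs sharing an isocenter."""

    arcs: list[Arc]
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    prescription_gy: float | None = None
    label: str = "plan"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.arcs:
            raise ValueError("plan has no arcs")
        self.isocenter = tuple(float(v) for v in self.isocenter)

    @property
    def total_mu(self) -> float:
        return float(sum(a.beam_mu for a in self.arcs))

    def scale_mu(self, factor: float) -> "PlanModel":
        """Return a copy with every arc's MU multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("MU scale factor must be positive")
        arcs = [
            Arc(
                control_points=[
                    ControlPoint(cp.gantry_angle, cp.mlc_a.copy(), cp.mlc_b.copy(),
                                 cp.cumulative_weight)
                    for cp in a.control_points
                ],
                leaf_boundaries=a.leaf_boundaries.copy(),
                jaws_x=a.jaws_x,
                jaws_y=a.jaws_y,
                beam_mu=a.beam_mu * factor,
            )
            for a in self.arcs
        ]
        return PlanModel(arcs=arcs, isocenter=self.isocenter,
                         prescription_gy=self.prescription_gy, label=self.label,
                         meta=dict(self.meta))
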