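"""Eye-exclusion laser gating for the side beam.

During whole-brain imaging the side sheet sweeps across the fish's eye.
To protect the eye (and the fish's vision during behavioural tasks), the
user draws an elliptic ROI on the lateral (y–z) projection of a stack;
this module converts that ellipse into per-plane laser-off intervals and
a boolean gate train aligned with the sheet sweep. Only the side beam is
gated — the front beam scans the narrow strip between the eyes and never
crosses them.

Gating is computed per plane from the plane's nominal z (planes are thin
relative to an eye), and boundary samples exactly on the ellipse count as
inside — safety-first rounding: when in doubt, the laser is off.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .waveform_synth import AnalogTrain, GateTrain, sheet_y_positions


@dataclass
class EllipseROI:
    """Elliptic exclusion region in the lateral (y–z) projection, in μm."""

    center_y: float
    center_z: float
    semi_y: float
    semi_z: float

    def __post_init__(self):
        if self.semi_y <= 0 or self.semi_z <= 0:
            raise ValueError("ellipse semi-axes must be positive")


@dataclass
class PlaneGate:
    """Laser-off interval for one Z plane; ``off_interval`` is None when
    the plane misses the ellipse."""

    z_plane: float
    off_interval: Optional[Tuple[float, float]]


def ellipse_chord(roi: EllipseROI, z: float) -> Optional[Tuple[float, float]]:
    """Horizontal chord [y_lo, y_hi] of the ellipse at axial position z.

    Empty (None) when |z − center_z| > semi_z; at the boundary the chord
    degenerates to the single point center_y (inclusive: counts as
    inside). Half-width w = semi_y * sqrt(1 − ((z − center_z)/semi_z)²).
    """
    u = (z - roi.center_z) / roi.semi_z
    if abs(u) > 1.0:
        return None
    w = roi.semi_y * math.sqrt(max(0.0, 1.0 - u * u))
    return (roi.center_y - w, roi.center_y + w)


def plane_gates(roi: EllipseROI, scan) -> list:
    """Per-plane off intervals for every plane of the scan program."""
    return [
        PlaneGate(z_plane=scan.plane_z(i), off_interval=ellipse_chord(roi, scan.plane_z(i)))
        for i in range(scan.n_planes)
    ]


def _roi_intersects_scan(roi: EllipseROI, scan) -> bool:
    z_lo, z_hi = scan.plane_z(0), scan.plane_z(scan.n_planes - 1)
    if roi.center_z + roi.semi_z < z_lo or roi.center_z - roi.semi_z > z_hi:
        return False
    if roi.center_y + roi.semi_y < scan.y_start or roi.center_y - roi.semi_y > scan.y_end:
        return False
    return True


def gates_for_volume(roi: Optional[EllipseROI], scan, sheet_command: AnalogTrain) -> GateTrain:
    """Boolean side-laser gate train for one volume.

    A sample is False (laser off) exactly when its plane's z and the
    beam's in-plane y position (decoded from the sheet command through
    the documented V→μm gain) fall inside the ellipse; True elsewhere.
    An ROI that lies entirely outside the scanned volume produces a
    warning and an all-on gate.
    """
    n = len(sheet_command.samples)
    gate = np.ones(n, dtype=bool)
    if roi is None:
        return GateTrain(gate, "gate_side", sheet_command.sample_rate)
    if not _roi_intersects_scan(roi, scan):
        warnings.warn(
            "eye-exclusion ROI lies entirely outside the scanned volume; "
            "side-beam gate left all-on",
            stacklevel=2,
        )
        return GateTrain(gate, "gate_side", sheet_command.sample_rate)
    y = sheet_y_positions(scan, sheet_command)
    for i in range(scan.n_planes):
        chord = ellipse_chord(roi, scan.plane_z(i))
        if chord is None:
            continue
        s0 = scan.plane_start_sample(i)
        s1 = scan.plane_start_sample(i + 1) if i + 1 < scan.n_planes else n
        seg = y[s0:s1]
        off = (seg >= chord[0]) & (seg <= chord[1])  # boundary counts as inside
        gate[s0:s1] = ~off
    return GateTrain(gate, "gate_side", sheet_command.sample_rate)
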