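"""Random-rotation simulation of arbitrary sensor mounting.

A sensor unit fixed to the body at an unknown orientation measures
``RV`` instead of ``V``, with ``R`` a proper rotation constant over the
window.  This module builds rotation matrices from yaw/pitch/roll Euler
angles as the product

    R = Rx(theta) @ Ry(phi) @ Rz(psi)

(elementary rotations about the x, then y, then z axes, composed in that
left-to-right order), draws the three angles independently and uniformly
from [0, 2*pi), and applies one matrix per unit to every block of a
segment -- all sensor types of a unit share the unit's orientation.

Uniform Euler angles do not sample the rotation group SO(3) uniformly
(they over-weight the poles); they are used here deliberately because
they are the stated simulation protocol this pipeline mirrors.
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

import numpy as np

from .core import Segment

__all__ = [
    "rotation_from_euler",
    "random_rotation",
    "is_rotation",
    "rotate_segment",
]


def rotation_from_euler(theta: float, phi: float, psi: float) -> np.ndarray:
    """Rotation matrix from yaw, pitch and roll angles (radians).

    Returns ``Rx(theta) @ Ry(phi) @ Rz(psi)`` where ``Rx``, ``Ry``, ``Rz``
    are the elementary rotations about the coordinate axes.
    """
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    cs, ss = np.cos(psi), np.sin(psi)
    rx = np.array([[1.0, 0.0, 0.0], [0.0, ct, -st], [0.0, st, ct]])
    ry = np.array([[cp, 0.0, sp], [0.0, 1.0, 0.0], [-sp, 0.0, cp]])
    rz = np.array([[cs, -ss, 0.0], [ss, cs, 0.0], [0.0, 0.0, 1.0]])
    return rx @ ry @ rz


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Draw a random proper rotation from three independent uniform
    [0, 2*pi) Euler angles."""
    theta, phi, psi = rng.uniform(0.0, 2.0 * np.pi, size=3)
    return rotation_from_euler(theta, phi, psi)


def is_rotation(m: np.ndarray, tol: float = 1e-10) -> bool:
    """True iff ``m`` is orthonormal with determinant +1, to ``tol``."""
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        return False
    ortho = np.max(np.abs(m.T @ m - np.eye(3))) < tol
    proper = abs(np.linalg.det(m) - 1.0) < tol
    return bool(ortho and proper)


def rotate_segment(
    segment: Segment, rotations: Mapping[str, np.ndarray]
) -> Segment:
    """Left-multiply every 3xL block of each unit by that unit's rotation.

    All sensor types within a unit are rotated by the same matrix; labels
    and segment bookkeeping are unchanged.  Raises ``KeyError`` when a
    unit present in the segment has no rotation.
    """
    blocks: Dict[Tuple[str, str], np.ndarray] = {}
    for (unit, sensor), block in segment.blocks.items():
        if unit not in rotations:
            raise KeyError(f"no rotation supplied for unit {unit!r}")
        blocks[(unit, sensor)] = np.asarray(rotations[unit]) @ block
    return Segment(
        subject_id=segment.subject_id,
        activity_id=segment.activity_id,
        blocks=blocks,
        length=segment.length,
        rate=segment.rate,
        segment_index=segment.segment_index,
    )
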