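"""SVD-based orientation-invariant transformation.

A segment's data matrix V (3xN) factors as V = U S W^T with U a 3x3
orthonormal matrix of principal directions, S the non-increasing
singular values and W (Nx3) orthonormal columns (compact SVD).  Rotating
the sensor replaces V by RV = (RU) S W^T: only the left factor absorbs
the mounting rotation, so S W^T = U^T V -- the data re-expressed in its
own principal axes -- is invariant to how the unit was oriented, up to
the signs of the rows.

When a unit houses several sensor types, their blocks share one physical
orientation, so one joint transform is computed: each sensor type is
first divided by its corpus-wide standard deviation (so no type
dominates the decomposition merely by its units of measure), the scaled
blocks are concatenated along the time axis, one compact SVD is taken,
and the transformed concatenation is split back per sensor.

The SVD leaves row signs undefined.  They are canonicalized
deterministically: each output row is flipped, if needed, so that its
entry of largest absolute value (earliest column on ties) is positive.
This makes the transform a function, which downstream moment features
(mean, skewness) require.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import yaml

from .core import Dataset, Segment

__all__ = [
    "SensorScales",
    "fit_sensor_scales",
    "fit_sensor_scales_from_segments",
    "svd_transform",
    "DegenerateSegmentWarning",
]


class DegenerateSegmentWarning(UserWarning):
    """A segment is (numerically) rank-deficient; its principal axes are
    not unique.  Noise in real recordings makes this a measure-zero event."""


@dataclass
class SensorScales:
    """Per-sensor-type pooled standard deviations used to equalize the
    contribution of each sensor type to the joint SVD."""

    scale: Dict[str, float]

    def __post_init__(self) -> None:
        for t, s in self.scale.items():
            if not s > 0:
                raise ValueError(f"scale for {t!r} must be positive, got {s}")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: float(v) for k, v in self.scale.items()}, fh)

    @classmethod
    def load(cls, path) -> "SensorScales":
        with open(path) as fh:
            return cls(scale={k: float(v) for k, v in yaml.safe_load(fh).items()})


def _pooled_std(values: np.ndarray, sensor_type: str) -> float:
    std = float(np.std(values))
    if not std > 0:
        raise ValueError(
            f"pooled variance of sensor type {sensor_type!r} is zero; "
            "cannot normalize"
        )
    return std


def fit_sensor_scales(dataset: Dataset) -> SensorScales:
    """Pooled standard deviation of every sample value (all axes, units
    and recordings) per sensor type over the corpus."""
    pooled: Dict[str, List[np.ndarray]] = {}
    for rec in dataset.recordings:
        for ch in rec.channels:
            pooled.setdefault(ch.sensor_type, []).append(ch.samples.ravel())
    return SensorScales(
        scale={
            t: _pooled_std(np.concatenate(chunks), t)
            for t, chunks in pooled.items()
        }
    )


def fit_sensor_scales_from_segments(segments: Iterable[Segment]) -> SensorScales:
    """As `fit_sensor_scales`, but pooling over a collection of segments
    (e.g. the training folds of a cross-validation split)."""
    pooled: Dict[str, List[np.ndarray]] = {}
    for seg in segments:
        for (_, sensor), block in seg.blocks.items():
            pooled.setdefault(sensor, []).append(block.ravel())
    return SensorScales(
        scale={
            t: _pooled_std(np.concatenate(chunks), t)
            for t, chunks in pooled.items()
        }
    )


def _canonicalize_row_signs(out: np.ndarray) -> np.ndarray:
    # flip each row so its largest-magnitude entry (earliest on ties) is >= 0
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


def svd_transform(
    unit_blocks: Sequence[np.ndarray],
    sensor_types: Sequence[str],
    scales: SensorScales,
) -> List[np.ndarray]:
    """Jointly transform all 3xL blocks of one unit into principal-axis
    coordinates.

    Each block is divided by its sensor type's scale, the scaled blocks
    are concatenated column-wise into ``Vbar`` (3 x S*L), a compact SVD
    ``Vbar = U S W^T`` is computed, and ``S W^T`` (equivalently
    ``U^T Vbar``) is sign-canonicalized per row and split back into S
    blocks of 3xL in input order.  Output stays in the normalized
    (unit-variance) sensor units.
    """
    if len(unit_blocks) != len(sensor_types):
        raise ValueError("one sensor type per block is required")
    blocks = [np.asarray(b, dtype=float) for b in unit_blocks]
    L = blocks[0].shape[1]
    for b in blocks:
        if b.shape != (3, L):
            raise ValueError("all blocks of a unit must be 3xL with equal L")
    scaled = [b / scales.scale[t] for b, t in zip(blocks, sensor_types)]
    vbar = np.hstack(scaled)
    u, s, wt = np.linalg.svd(vbar, full_matrices=False)
    if s[0] > 0 and s[-1] < 1e-12 * s[0]:
        warnings.warn(
            "rank-deficient segment: principal axes are not unique",
            DegenerateSegmentWarning,
            stacklevel=2,
        )
    out = s[:, np.newaxis] * wt  # = U^T Vbar up to floating-point round-off
    out = _canonicalize_row_signs(out)
    return [out[:, i * L : (i + 1) * L] for i in range(len(blocks))]
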