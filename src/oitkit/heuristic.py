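"""Heuristic orientation-invariant transformation (9 channels).

A tri-axial sequence v[n] (3xL) is mapped to nine scalar channels that
are unchanged when the whole sequence is pre-multiplied by any fixed
proper rotation:

    w1 = ||v[n]||                 norm of the sample
    w2 = ||dv[n]||                norm of the first difference
    w3 = ||ddv[n]||               norm of the second difference
    w4 = angle(v[n], v[n+1])
    w5 = angle(dv[n], dv[n+1])
    w6 = angle(ddv[n], ddv[n+1])
    w7 = angle(p[n], p[n+1]),  p[n] = v[n]  x v[n+1]
    w8 = angle(q[n], q[n+1]),  q[n] = dv[n] x dv[n+1]
    w9 = angle(r[n], r[n+1]),  r[n] = ddv[n] x ddv[n+1]

with dv[n] = v[n+1] - v[n] and ddv[n] = dv[n+1] - dv[n].  Norms are
invariant because rotations are isometries; angles are invariant because
a common rotation preserves inner products; and the cross-product
rotation axes p, q, r themselves co-rotate with the data, so the angles
between consecutive axes are invariant as well.  The axes p, q, r are
used unnormalized, since only their directions enter the angles.

The deepest stencil is w9[n], which reaches v[n..n+4]; all channels are
truncated to the common valid length L' = L - 4 so the output is a
rectangular 9 x L' matrix.  An angle whose operand is the zero vector is
set to 0 (it is undefined there), and the arccos argument is clipped to
[-1, 1] against floating-point round-off.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "HEURISTIC_CHANNEL_NAMES",
    "first_difference",
    "angle_between",
    "heuristic_transform",
    "euclidean_norm_transform",
    "truncate_channels",
]

HEURISTIC_CHANNEL_NAMES = ("w1", "w2", "w3", "w4", "w5", "w6", "w7", "w8", "w9")


class SegmentTooShortError(ValueError):
    """The window is shorter than the transform's stencil."""


def first_difference(seq: np.ndarray) -> np.ndarray:
    """Columnwise first difference: output column n is seq[:, n+1] - seq[:, n]."""
    seq = np.asarray(seq, dtype=float)
    if seq.shape[1] < 2:
        raise ValueError("need at least 2 columns to difference")
    return np.diff(seq, axis=1)


def _column_norms(seq: np.ndarray) -> np.ndarray:
    return np.linalg.norm(seq, axis=0)


def _column_angles(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle between paired columns of two 3xK arrays, in [0, pi].

    Zero columns on either side yield 0.
    """
    dots = np.einsum("ij,ij->j", a, b)
    denom = _column_norms(a) * _column_norms(b)
    out = np.zeros_like(denom)
    nz = denom > 0
    out[nz] = np.arccos(np.clip(dots[nz] / denom[nz], -1.0, 1.0))
    return out


def angle_between(u: np.ndarray, w: np.ndarray) -> float:
    """Angle in radians between two 3-vectors; 0 if either is the zero vector."""
    u = np.asarray(u, dtype=float).reshape(3, 1)
    w = np.asarray(w, dtype=float).reshape(3, 1)
    return float(_column_angles(u, w)[0])


def euclidean_norm_transform(block: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a 3xL block, as a 1xL matrix.

    The simplest proper orientation-invariant transform; equals channel
    w1 of `heuristic_transform` on the shared index range.
    """
    block = np.asarray(block, dtype=float)
    return _column_norms(block)[np.newaxis, :]


def heuristic_transform(block: np.ndarray) -> np.ndarray:
    """Apply the 9-channel heuristic transform to a 3xL block.

    Returns a 9 x (L - 4) array whose rows follow
    ``HEURISTIC_CHANNEL_NAMES``.  Requires L >= 5.
    """
    v = np.asarray(block, dtype=float)
    if v.ndim != 2 or v.shape[0] != 3:
        raise ValueError(f"block must be 3xL, got shape {v.shape}")
    L = v.shape[1]
    if L < 5:
        raise SegmentTooShortError(
            f"heuristic transform needs at least 5 samples, got {L}"
        )
    lp = L - 4
    dv = np.diff(v, axis=1)     # 3 x (L-1)
    ddv = np.diff(dv, axis=1)   # 3 x (L-2)

    p = np.cross(v[:, :-1], v[:, 1:], axis=0)      # 3 x (L-1)
    q = np.cross(dv[:, :-1], dv[:, 1:], axis=0)    # 3 x (L-2)
    r = np.cross(ddv[:, :-1], ddv[:, 1:], axis=0)  # 3 x (L-3)

    rows = (
        _column_norms(v)[:lp],
        _column_norms(dv)[:lp],
        _column_norms(ddv)[:lp],
        _column_angles(v[:, :-1], v[:, 1:])[:lp],
        _column_angles(dv[:, :-1], dv[:, 1:])[:lp],
        _column_angles(ddv[:, :-1], ddv[:, 1:])[:lp],
        _column_angles(p[:, :-1], p[:, 1:])[:lp],
        _column_angles(q[:, :-1], q[:, 1:])[:lp],
        _column_angles(r[:, :-1], r[:, 1:])[:lp],
    )
    return np.vstack(rows)


def truncate_channels(channels: np.ndarray, n: int) -> np.ndarray:
    """Keep only the first ``n`` of the 9 heuristic channels, n in {3, 6, 9}."""
    if n not in (3, 6, 9):
        raise ValueError(f"n must be 3, 6 or 9, got {n}")
    return np.asarray(channels)[:n, :]
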