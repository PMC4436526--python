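"""Derived kinematic variables: arm joint angles, grip aperture, grip position.

Seven dependent variables summarize each person's movement: three joint
angles built from the shoulder (S), elbow (E) and wrist (W) markers, the
grip aperture (index-thumb distance), and the 3D grip position
(index-thumb midpoint).  All are samplewise, so trial windows index into
them unchanged.

The joint angles use an auxiliary origin point O = (x_S, y_S, z_E), so
that S->O is vertical:

* q1 = arccos((z_S - z_E) / |ES|): elevation of the upper arm from the
  vertical through the shoulder.
* q2 = arccos((y_S - y_E) / |EO|): direction of the shoulder->elbow
  displacement in the horizontal plane, measured against the y axis
  (|EO| uses x and y only).
* q3 = arccos((|SW|^2 - |ES|^2 - |EW|^2) / (2 |ES| |EW|)): elbow angle by
  the cosine rule on the S/E/W triangle.  Note this convention yields 0
  for a fully extended (collinear) arm and 90 for a right angle at the
  elbow — i.e. 180 minus the triangle's interior angle at E.

These are surface-marker estimates, not true joint-centre angles, and q3
ignores wrist rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Recording

#: Dependent-variable names in canonical order.
DV_NAMES = ("q1", "q2", "q3", "aperture", "grip_x", "grip_y", "grip_z")


@dataclass
class ArmAngles:
    q1: np.ndarray  # degrees
    q2: np.ndarray
    q3: np.ndarray
    n_degenerate: int = 0


def _clamped_arccos_deg(c: np.ndarray) -> np.ndarray:
    # Clamp for floating round-off at collinear configurations; anything
    # beyond ~1e-12 outside [-1, 1] indicates degenerate geometry and is
    # handled by the NaN masks upstream.
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def joint_angles(S: np.ndarray, E: np.ndarray, W: np.ndarray) -> ArmAngles:
    """Samplewise q1-q3 (degrees) from shoulder/elbow/wrist positions.

    Degenerate samples (zero-length ES, EW, or horizontal EO) yield NaN
    and are counted; a warning is raised if they exceed 1% of samples.
    """
    S, E, W = (np.atleast_2d(np.asarray(a, dtype=float)) for a in (S, E, W))
    if not (S.shape == E.shape == W.shape) or S.shape[1] != 3:
        raise ValueError("S, E, W must be (n, 3) arrays of equal length")
    es = np.linalg.norm(S - E, axis=1)
    ew = np.linalg.norm(W - E, axis=1)
    sw = np.linalg.norm(W - S, axis=1)
    eo_h = np.hypot(S[:, 0] - E[:, 0], S[:, 1] - E[:, 1])

    with np.errstate(divide="ignore", invalid="ignore"):
        q1 = _clamped_arccos_deg((S[:, 2] - E[:, 2]) / es)
        q2 = _clamped_arccos_deg((S[:, 1] - E[:, 1]) / eo_h)
        q3 = _clamped_arccos_deg((sw**2 - es**2 - ew**2) / (2 * es * ew))
    q1[es == 0] = np.nan
    q2[eo_h == 0] = np.nan
    q3[(es == 0) | (ew == 0)] = np.nan

    n_bad = int(np.isnan(q1).sum() + np.isnan(q2).sum() + np.isnan(q3).sum())
    if n_bad > 0.01 * 3 * len(S):
        warnings.warn(
            f"{n_bad} degenerate joint-angle samples (>1%)", stacklevel=2
        )
    return ArmAngles(q1, q2, q3, n_degenerate=n_bad)


def grip_aperture(index: np.ndarray, thumb: np.ndarray) -> np.ndarray:
    """Samplewise 3D index-thumb distance in mm."""
    index = np.atleast_2d(np.asarray(index, dtype=float))
    thumb = np.atleast_2d(np.asarray(thumb, dtype=float))
    if index.shape != thumb.shape:
        raise ValueError("index and thumb must have equal shapes")
    return np.linalg.norm(index - thumb, axis=1)


def grip_position(index: np.ndarray, thumb: np.ndarray) -> np.ndarray:
    """Samplewise index-thumb midpoint per axis (mm)."""
    index = np.atleast_2d(np.asarray(index, dtype=float))
    thumb = np.atleast_2d(np.asarray(thumb, dtype=float))
    if index.shape != thumb.shape:
        raise ValueError("index and thumb must have equal shapes")
    return (index + thumb) / 2.0


def derive_dvs(rec: Recording) -> pd.DataFrame:
    """All seven dependent variables for one (preprocessed) recording.

    Returns a DataFrame with columns ``q1, q2, q3, aperture, grip_x,
    grip_y, grip_z`` of exactly the recording's length.
    """
    angles = joint_angles(
        rec.position("shoulder"), rec.position("elbow"), rec.position("wrist")
    )
    index, thumb = rec.position("index"), rec.position("thumb")
    pos = grip_position(index, thumb)
    return pd.DataFrame(
        {
            "q1": angles.q1,
            "q2": angles.q2,
            "q3": angles.q3,
            "aperture": grip_aperture(index, thumb),
            "grip_x": pos[:, 0],
            "grip_y": pos[:, 1],
            "grip_z": pos[:, 2],
        }
    )
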