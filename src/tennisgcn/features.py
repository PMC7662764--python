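"""Active features: handcrafted movement and posture descriptors.

Alongside the learned graph-convolutional representation, the classifier is
fed a small knowledge-base vector per sample:

* movement -- per-joint mean speed and mean acceleration magnitude, from
  finite differences of the node trajectories;
* posture -- side lengths and interior angles of two body triangles, the
  lower one spanned by (left foot, spine, right foot) and the upper one by
  (left hand, head, right hand), time-averaged over the sample.

The resulting vector has length 2*V + 2*(3 + 3) = 50 for the 19-node
skeleton and is z-scored with training-split statistics before fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton_io import MotionSample

__all__ = [
    "ActiveFeatureVector",
    "LOWER_TRIANGLE",
    "UPPER_TRIANGLE",
    "joint_kinematics",
    "triangle_features",
    "active_features",
    "feature_matrix",
    "feature_names",
]

LOWER_TRIANGLE = ("foot_l", "spine_lower", "foot_r")
UPPER_TRIANGLE = ("hand_l", "head", "hand_r")


@dataclass(frozen=True)
class ActiveFeatureVector:
    """Fixed-length descriptor vector with stable component names."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.shape[0] != len(self.names):
            raise ValueError("values and names must have equal length")
        object.__setattr__(self, "values", v)


def joint_kinematics(s: MotionSample) -> tuple[np.ndarray, np.ndarray]:
    """Per-joint speed and acceleration magnitude series, shapes (V, T).

    Velocity is the central finite difference of position along time
    (one-sided at the ends); acceleration is the difference of the velocity.
    Units are channel units per frame and per frame squared.  Requires at
    least three frames.
    """
    C, V, T = s.shape
    if T < 3:
        raise ValueError(f"kinematics need T >= 3 frames, got {T}")
    vel = np.gradient(s.data, axis=2)          # (C, V, T)
    acc = np.gradient(vel, axis=2)
    speed = np.linalg.norm(vel, axis=0)        # (V, T)
    accel = np.linalg.norm(acc, axis=0)
    return speed, accel


def triangle_features(s: MotionSample, triple: tuple[str, str, str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame side lengths and interior angles of a node triangle.

    Sides are Euclidean; angles follow the law of cosines, with cosines
    clipped to [-1, 1] so collinear frames degrade to the limit angles
    {0, 0, pi} instead of failing.  Returns (sides, angles), each (T, 3);
    ``sides[:, i]`` is the side opposite vertex i and ``angles[:, i]`` the
    interior angle at vertex i.
    """
    if len(set(triple)) != 3:
        raise ValueError(f"triangle needs three distinct nodes, got {triple}")
    P = np.stack([s.node_series(n) for n in triple], axis=1)  # (T, 3, C)
    sides = np.stack(
        [
            np.linalg.norm(P[:, 1] - P[:, 2], axis=1),
            np.linalg.norm(P[:, 2] - P[:, 0], axis=1),
            np.linalg.norm(P[:, 0] - P[:, 1], axis=1),
        ],
        axis=1,
    )
    a, b, c = sides[:, 0], sides[:, 1], sides[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        cosA = np.clip((b**2 + c**2 - a**2) / (2 * b * c), -1.0, 1.0)
        cosB = np.clip((a**2 + c**2 - b**2) / (2 * a * c), -1.0, 1.0)
        cosC = np.clip((a**2 + b**2 - c**2) / (2 * a * b), -1.0, 1.0)
    angles = np.arccos(np.nan_to_num(np.stack([cosA, cosB, cosC], axis=1), nan=1.0))
    return sides, angles


def active_features(s: MotionSample) -> ActiveFeatureVector:
    """Concatenate time-averaged kinematics and both triangles' descriptors.

    Layout: per-joint mean speed (V), per-joint mean acceleration magnitude
    (V), then for each of the lower and upper triangles the three mean side
    lengths and three mean interior angles.
    """
    for needed in LOWER_TRIANGLE + UPPER_TRIANGLE:
        if needed not in s.node_names:
            raise ValueError(f"sample lacks canonical node {needed!r}")
    speed, accel = joint_kinematics(s)
    parts = [speed.mean(axis=1), accel.mean(axis=1)]
    for triple in (LOWER_TRIANGLE, UPPER_TRIANGLE):
        sides, angles = triangle_features(s, triple)
        parts.append(sides.mean(axis=0))
        parts.append(angles.mean(axis=0))
    return ActiveFeatureVector(np.concatenate(parts), feature_names(s.node_names))


def feature_names(node_names: tuple[str, ...]) -> tuple[str, ...]:
    names = [f"speed_{n}" for n in node_names] + [f"accel_{n}" for n in node_names]
    for tag, triple in (("lower", LOWER_TRIANGLE), ("upper", UPPER_TRIANGLE)):
        names += [f"{tag}_side_opp_{n}" for n in triple]
        names += [f"{tag}_angle_{n}" for n in triple]
    return tuple(names)


def feature_matrix(samples) -> np.ndarray:
    """Stack active-feature vectors of an iterable of samples, shape (N, 50)."""
    return np.stack([active_features(s).values for s in samples])
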