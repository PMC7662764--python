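"""Marker-level I/O and reduction to the 19-node skeleton.

A full-body optical capture uses 39 body markers (Plug-in-Gait placement)
plus 7 racket markers.  For classification this is redundant: clusters of
markers are collapsed to single graph nodes (e.g. the four head markers to
one interpolated head point, the racket to a handle node and a head node),
yielding the canonical 19-node skeleton.  This module reads marker data
(C3D or CSV), applies the reduction rules, projects to a 2-channel plane,
and assembles fixed-length classified samples from the three stroke phases
(preparation, shot, after-shot).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import c3dio
from .stgraph import CANONICAL_NODE_NAMES

__all__ = [
    "MarkerSequence",
    "NodeSequence",
    "MotionSample",
    "ReductionRules",
    "PHASES",
    "default_reduction_rules",
    "read_c3d",
    "read_marker_csv",
    "write_marker_csv",
    "reduce_markers",
    "project_to_plane",
    "canonicalize_handedness",
    "assemble_sample",
]

PHASES = ("preparation", "shot", "after_shot", "none")
CLASSES = ("forehand", "backhand", "no_shot")
_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class MarkerSequence:
    """Raw labelled marker trajectories.

    ``positions`` has shape (T, M, 3) in millimetres, ordered as
    ``marker_names``.  All frames carry the same marker set by construction.
    """

    marker_names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)
    frame_rate: float = 100.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 3:
            raise ValueError(f"positions must be (T, M, 3), got {pos.shape}")
        if pos.shape[0] < 1:
            raise ValueError("a marker sequence needs at least one frame")
        if pos.shape[1] != len(self.marker_names):
            raise ValueError("marker_names length must match positions")
        object.__setattr__(self, "positions", pos)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def marker(self, name: str) -> np.ndarray:
        return self.positions[:, self.marker_names.index(name), :]


@dataclass(frozen=True)
class NodeSequence:
    """Reduced per-frame node positions, (T, 19, k) with k = 3 or 2.

    ``axis_names`` names the retained world axes; ``phase_label`` is one of
    preparation / shot / after_shot / none and ``class_label`` (if known) the
    stroke class the phase belongs to.
    """

    node_names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)
    axis_names: tuple[str, ...] = ("x", "y", "z")
    phase_label: str = "none"
    class_label: str | None = None
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[1] != len(self.node_names):
            raise ValueError(f"positions must be (T, {len(self.node_names)}, k), got {pos.shape}")
        if pos.shape[2] != len(self.axis_names):
            raise ValueError("axis_names must match the coordinate dimension")
        if self.phase_label not in PHASES:
            raise ValueError(f"unknown phase label {self.phase_label!r}")
        object.__setattr__(self, "positions", pos)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def node(self, name: str) -> np.ndarray:
        return self.positions[:, self.node_names.index(name), :]


@dataclass(frozen=True)
class MotionSample:
    """One classified sample: a (C, V, T) attribute tensor plus annotations.

    Default dimensions are C=2 coordinate channels, V=19 nodes, T=14 frames.
    ``phase_boundaries`` holds the first frame index of the shot and
    after-shot thirds in the resampled timeline.
    """

    data: np.ndarray = field(repr=False)
    node_names: tuple[str, ...] = CANONICAL_NODE_NAMES
    channel_names: tuple[str, ...] = ("x", "z")
    label: str | None = None
    phase_boundaries: tuple[int, int] | None = None
    provenance: tuple = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"data must be (C, V, T), got {data.shape}")
        if data.shape[1] != len(self.node_names):
            raise ValueError("node dimension must match node_names")
        if data.shape[0] != len(self.channel_names):
            raise ValueError("channel dimension must match channel_names")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def node_series(self, name: str) -> np.ndarray:
        """(T, C) trajectory of one node."""
        return self.data[:, self.node_names.index(name), :].T


@dataclass(frozen=True)
class ReductionRules:
    """Mapping from source markers to canonical nodes.

    Multi-source nodes take the arithmetic per-frame mean of their sources;
    the racket head averages its head-rim markers and the four skull markers
    interpolate to a single head point.
    """

    racket_handle_source: str
    racket_head_sources: tuple[str, ...]
    head_sources: tuple[str, ...]
    body_map: dict[str, tuple[str, ...]]

    def full_map(self) -> dict[str, tuple[str, ...]]:
        out = dict(self.body_map)
        out["head"] = self.head_sources
        out["racket_handle"] = (self.racket_handle_source,)
        out["racket_head"] = self.racket_head_sources
        return out


#: Plug-in-Gait body marker names used by the default rules.
PIG_BODY_MARKERS = (
    "LFHD", "RFHD", "LBHD", "RBHD",
    "C7", "T10", "CLAV", "STRN", "RBAK",
    "LSHO", "LUPA", "LELB", "LFRM", "LWRA", "LWRB", "LFIN",
    "RSHO", "RUPA", "RELB", "RFRM", "RWRA", "RWRB", "RFIN",
    "LASI", "RASI", "LPSI", "RPSI",
    "LTHI", "LKNE", "LTIB", "LANK", "LHEE", "LTOE",
    "RTHI", "RKNE", "RTIB", "RANK", "RHEE", "RTOE",
)

#: Seven racket markers: four around the head rim, three along the handle.
RACKET_MARKERS = (
    "RKT_TOP", "RKT_LEFT", "RKT_RIGHT", "RKT_HEADBOT",
    "RKT_HANDTOP", "RKT_HANDMID", "RKT_HANDBOT",
)

ALL_MARKERS = PIG_BODY_MARKERS + RACKET_MARKERS


def default_reduction_rules() -> ReductionRules:
    """46 capture markers -> 19 canonical nodes."""
    return ReductionRules(
        racket_handle_source="RKT_HANDBOT",
        racket_head_sources=("RKT_TOP", "RKT_LEFT", "RKT_RIGHT", "RKT_HEADBOT"),
        head_sources=("LFHD", "RFHD", "LBHD", "RBHD"),
        body_map={
            "neck": ("C7",),
            "spine_upper": ("CLAV", "STRN"),
            "spine_lower": ("T10",),
            "pelvis": ("LASI", "RASI", "LPSI", "RPSI"),
            "shoulder_l": ("LSHO",),
            "elbow_l": ("LELB",),
            "hand_l": ("LWRA", "LWRB", "LFIN"),
            "shoulder_r": ("RSHO",),
            "elbow_r": ("RELB",),
            "hand_r": ("RWRA", "RWRB", "RFIN"),
            "hip_l": ("LASI", "LPSI"),
            "knee_l": ("LKNE",),
            "foot_l": ("LANK", "LHEE", "LTOE"),
            "hip_r": ("RASI", "RPSI"),
            "knee_r": ("RKNE",),
            "foot_r": ("RANK", "RHEE", "RTOE"),
        },
    )


def _check_gaps(names, positions, path) -> None:
    bad = np.isnan(positions).any(axis=2)  # (T, M)
    if bad.any():
        m = int(np.argmax(bad.any(axis=0)))
        frames = np.flatnonzero(bad[:, m])
        raise ValueError(
            f"{path}: marker {names[m]!r} has a gap (invalid samples) over frames "
            f"{frames[0]}..{frames[-1]}; fill gaps upstream before reading"
        )


def read_c3d(path: str | Path, subject_id: str = "") -> MarkerSequence:
    """Read labelled marker trajectories from a C3D file (positions in mm).

    Rejects files with marker gaps (runs of invalid samples), naming the
    marker and frame span; gap filling belongs to the capture pipeline.
    """
    names, xyz, rate = c3dio.read_c3d_raw(path)
    _check_gaps(names, xyz, path)
    return MarkerSequence(tuple(names), xyz, frame_rate=rate, subject_id=subject_id)


def write_marker_csv(seq: MarkerSequence, path: str | Path) -> None:
    """CSV fallback format: one row per frame, columns ``<marker>_x,_y,_z``."""
    cols = {}
    for m, name in enumerate(seq.marker_names):
        for a, ax in enumerate(_AXES):
            cols[f"{name}_{ax}"] = seq.positions[:, m, a]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_marker_csv(path: str | Path, frame_rate: float = 100.0, subject_id: str = "") -> MarkerSequence:
    df = pd.read_csv(path)
    names = []
    for col in df.columns:
        if col.endswith("_x"):
            names.append(col[:-2])
    if not names:
        raise ValueError(f"{path}: no '<marker>_x' columns found")
    pos = np.stack(
        [np.column_stack([df[f"{n}_{ax}"].to_numpy() for ax in _AXES]) for n in names],
        axis=1,
    )
    _check_gaps(names, pos, path)
    return MarkerSequence(tuple(names), pos, frame_rate=frame_rate, subject_id=subject_id)


def reduce_markers(
    seq: MarkerSequence,
    rules: ReductionRules | None = None,
    phase_label: str = "none",
    class_label: str | None = None,
) -> NodeSequence:
    """Collapse marker clusters to the canonical 19-node skeleton.

    Every multi-source node is the per-frame arithmetic mean of its source
    markers; frame count is preserved.  Raises ``ValueError`` naming the
    first missing source marker.
    """
    rules = rules or default_reduction_rules()
    mapping = rules.full_map()
    for node in CANONICAL_NODE_NAMES:
        if node not in mapping or not mapping[node]:
            raise ValueError(f"reduction rules give no source markers for node {node!r}")
    nodes = np.empty((seq.n_frames, len(CANONICAL_NODE_NAMES), 3))
    for i, node in enumerate(CANONICAL_NODE_NAMES):
        for src in mapping[node]:
            if src not in seq.marker_names:
                raise ValueError(f"source marker {src!r} (node {node!r}) missing from input")
        idx = [seq.marker_names.index(src) for src in mapping[node]]
        nodes[:, i, :] = seq.positions[:, idx, :].mean(axis=1)
    return NodeSequence(
        CANONICAL_NODE_NAMES,
        nodes,
        axis_names=_AXES,
        phase_label=phase_label,
        class_label=class_label,
        frame_rate=seq.frame_rate,
    )


def project_to_plane(seq: NodeSequence, plane: tuple[str, str] = ("x", "z")) -> NodeSequence:
    """Retain two world axes, giving 2-channel node attributes.

    Idempotent when the sequence already carries exactly the requested axes.
    """
    if tuple(seq.axis_names) == tuple(plane):
        return seq
    if len(plane) != 2 or len(set(plane)) != 2:
        raise ValueError(f"plane must be two distinct axes, got {plane}")
    try:
        idx = [seq.axis_names.index(ax) for ax in plane]
    except ValueError:
        raise ValueError(f"plane {plane} not available in axes {seq.axis_names}") from None
    return replace(seq, positions=seq.positions[:, :, idx], axis_names=tuple(plane))


def canonicalize_handedness(seq: NodeSequence, handedness: str = "right", lateral_axis: str = "y") -> NodeSequence:
    """Mirror a left-handed subject so the dominant hand is canonical-right.

    Negates the lateral world axis and swaps left/right node rows; a
    right-handed sequence is returned unchanged.
    """
    if handedness == "right":
        return seq
    if handedness != "left":
        raise ValueError(f"handedness must be 'left' or 'right', got {handedness!r}")
    pos = seq.positions.copy()
    if lateral_axis in seq.axis_names:
        pos[:, :, seq.axis_names.index(lateral_axis)] *= -1.0
    perm = []
    for name in seq.node_names:
        if name.endswith("_l"):
            perm.append(seq.node_names.index(name[:-2] + "_r"))
        elif name.endswith("_r"):
            perm.append(seq.node_names.index(name[:-2] + "_l"))
        else:
            perm.append(seq.node_names.index(name))
    return replace(seq, positions=pos[:, perm, :])


def _resample_indices(n: int, T: int) -> np.ndarray:
    """Nearest-frame uniform resampling map from n source frames to T."""
    return np.minimum((((np.arange(T) + 0.5) * n) / T).astype(int), n - 1)


def assemble_sample(
    prep: NodeSequence,
    shot: NodeSequence,
    after: NodeSequence,
    T: int = 14,
    plane: tuple[str, str] = ("x", "z"),
    normalize: bool = True,
    provenance: tuple = (),
) -> MotionSample:
    """Concatenate the three stroke phases into one T-frame sample.

    The phases are concatenated in order, uniformly resampled to exactly
    ``T`` frames (nearest-frame), projected to ``plane`` and, when
    ``normalize`` is set, centred per frame on the pelvis node and scaled by
    the frame-0 pelvis-neck distance so absolute position and body size do
    not leak into the class label.  Phases of different stroke classes are
    rejected.
    """
    phases = (prep, shot, after)
    for p in phases:
        if p.n_frames < 1:
            raise ValueError("empty phase")
        if tuple(p.node_names) != tuple(prep.node_names):
            raise ValueError("phases must share node order")
    labels = {p.class_label for p in phases if p.class_label is not None}
    if len(labels) > 1:
        raise ValueError(f"phases mix stroke classes: {sorted(labels)}")
    label = labels.pop() if labels else None

    seqs = [project_to_plane(p, plane) if p.positions.shape[2] == 3 else p for p in phases]
    concat = np.concatenate([p.positions for p in seqs], axis=0)
    n = concat.shape[0]
    idx = _resample_indices(n, T)
    data = concat[idx]  # (T, V, 2)

    n1, n2 = seqs[0].n_frames, seqs[1].n_frames
    shot_start = int(np.searchsorted(idx, n1))
    after_start = int(np.searchsorted(idx, n1 + n2))

    if normalize:
        names = list(prep.node_names)
        pelvis = data[:, names.index("pelvis"), :]
        data = data - pelvis[:, None, :]
        scale = np.linalg.norm(
            seqs[0].positions[0, names.index("neck"), :]
            - seqs[0].positions[0, names.index("pelvis"), :]
        )
        if scale <= 0:
            raise ValueError("degenerate pose: pelvis and neck coincide at frame 0")
        data = data / scale

    return MotionSample(
        data=np.transpose(data, (2, 1, 0)),  # (C, V, T)
        node_names=tuple(prep.node_names),
        channel_names=tuple(plane),
        label=label,
        phase_boundaries=(shot_start, after_start),
        provenance=provenance,
    )


def node_sequence_to_csv(seq: NodeSequence) -> str:
    """Node positions as CSV text in canonical node order."""
    cols = {}
    for i, name in enumerate(seq.node_names):
        for a, ax in enumerate(seq.axis_names):
            cols[f"{name}_{ax}"] = seq.positions[:, i, a]
    buf = io.StringIO()
    pd.DataFrame(cols).to_csv(buf, index=False)
    return buf.getvalue()
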