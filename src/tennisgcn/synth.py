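"""Synthetic three-class tennis-motion generator.

The study data (ten coaches performing forehands, backhands and running
without shots, captured optically) is private, so this module generates a
labelled stand-in with the same structure: 19-node skeleton sequences in
three classes with composition 348 / 354 / 378, each sample assembled from
three independently drawn phase instances (preparation, shot, after-shot)
of its own class and resampled to T = 14 frames at 10 Hz.

Kinematics are articulated, not arbitrary curves: limbs are rigid two-link
chains posed by exact inverse kinematics around a walking/running trunk.
Classes differ in the racket-arm swing -- the forehand sweeps from behind
and low to front and high while the hand drifts from the dominant side
across the body; the backhand starts cross-body and high and finishes low
on the dominant side; the no-shot class carries the racket with only a small
oscillation while running.  Noise has two components: per-node Gaussian
jitter (magnitude set by the committed calibration, in units of the
pelvis-neck distance) and sparse spike outliers emulating the occlusion and
mislabeling artifacts of optical capture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .skeleton_io import (
    CLASSES,
    MarkerSequence,
    MotionSample,
    NodeSequence,
    assemble_sample,
    canonicalize_handedness,
)
from .stgraph import CANONICAL_NODE_NAMES

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "pose_template",
    "generate_sample",
    "generate_dataset",
    "markers_from_nodes",
    "samples_to_array",
    "default_noise_sd",
]

_IDX = {name: i for i, name in enumerate(CANONICAL_NODE_NAMES)}


def _calibration() -> dict:
    text = resources.files("tennisgcn").joinpath("data/calibration.json").read_text()
    return json.loads(text)


def default_noise_sd() -> float:
    """Calibrated Gaussian jitter magnitude (see scripts/calibrate.py)."""
    return float(_calibration()["noise_sd"])


def default_class_separation() -> float:
    """Calibrated forehand/backhand swing separation (see scripts/calibrate.py)."""
    return float(_calibration()["class_separation"])


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic benchmark.

    ``noise_sd`` is the Gaussian jitter standard deviation as a fraction of
    body scale (pelvis-neck distance); ``None`` loads the committed
    calibrated value.  ``outlier_frac`` node-frames receive an additional
    uniform spike of up to ``outlier_scale`` body scales.  ``stroke_var``
    scales the correlated stroke-to-stroke swing variation (0 disables it,
    making same-class samples identical up to noise and subject size);
    ``class_separation`` scales the forehand/backhand swing difference and
    defaults to the committed calibrated value.
    """

    class_counts: tuple[int, int, int] = (348, 354, 378)  # forehand, backhand, no_shot
    phase_frames: tuple[int, int, int] = (5, 5, 4)
    T: int = 14
    plane: tuple[str, str] = ("x", "z")
    noise_sd: float | None = None
    outlier_frac: float = 0.02
    outlier_scale: float = 2.0
    subject_sd: float = 0.04
    stroke_var: float = 1.0
    class_separation: float | None = None
    left_handed_frac: float = 0.1
    phase_pool_size: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.class_counts):
            raise ValueError("class counts must be >= 1")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.class_separation is not None and self.class_separation <= 0:
            raise ValueError("class_separation must be > 0")

    def resolved_noise_sd(self) -> float:
        return default_noise_sd() if self.noise_sd is None else self.noise_sd

    def resolved_class_separation(self) -> float:
        return (default_class_separation() if self.class_separation is None
                else self.class_separation)


@dataclass
class SyntheticDataset:
    samples: list[MotionSample]
    config: GeneratorConfig

    @property
    def labels(self) -> np.ndarray:
        return np.array([CLASSES.index(s.label) for s in self.samples])

    def class_count(self, label: str) -> int:
        return sum(1 for s in self.samples if s.label == label)


# ---------------------------------------------------------------- kinematics

def _two_link(root: np.ndarray, target: np.ndarray, L1: float, L2: float,
              bend: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact two-link inverse kinematics: returns (mid joint, end effector).

    The target is clamped radially into the reachable annulus so segment
    lengths are always exactly L1 and L2 (rigid skeleton).
    """
    delta = target - root
    d = np.linalg.norm(delta)
    lo, hi = abs(L1 - L2) + 1e-3, L1 + L2 - 1e-3
    if d < 1e-9:
        delta = np.array([0.0, 0.0, -1.0])
        d = 1.0
    dc = np.clip(d, lo, hi)
    u = delta / d
    end = root + dc * u
    a = (L1**2 - L2**2 + dc**2) / (2 * dc)
    h = np.sqrt(max(L1**2 - a**2, 0.0))
    perp = bend - np.dot(bend, u) * u
    n = np.linalg.norm(perp)
    perp = perp / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])
    return root + a * u + h * perp, end


def _swing_angle(class_label: str, s: float, g: float, sep: float) -> tuple[float, float]:
    """(swing angle from vertical, lateral direction component) of the racket hand.

    Forehand and backhand share a common midline swing; ``sep`` scales their
    symmetric deviation from it, so sep -> 0 makes the two strokes coincide
    while sep = 1 gives fully distinct swings (forehand rising from behind
    and low to front and high, drifting across the body; backhand mirrored).
    The no-shot class is an oscillatory racket carry while running.
    """
    if class_label == "no_shot":
        return 0.25 * np.sin(2 * np.pi * (g + 0.5)), -0.15
    if class_label == "forehand":
        kappa = 1.0
    elif class_label == "backhand":
        kappa = -1.0
    else:
        raise ValueError(f"unknown class label {class_label!r}")
    psi = (-0.125 + 0.775 * s) + kappa * sep * (0.625 + 0.125 * s)
    y = kappa * sep * (-0.25 + 0.175 * (s + 1.0))
    return psi, y


def _apply_swing_mod(psi: float, y: float, mod: dict | None) -> tuple[float, float]:
    if mod is None:
        return psi, y
    return psi * mod.get("amp_scale", 1.0) + mod.get("psi_offset", 0.0), y + mod.get("y_offset", 0.0)


def _phase_s(phase: str, u: float) -> float:
    """Swing progress s in [-1, 1] within a phase (u in [0, 1])."""
    if phase == "preparation":
        return -u
    if phase == "shot":
        return -1.0 + 2.0 * u
    if phase == "after_shot":
        return 1.0 - 0.6 * u
    if phase == "none":
        return 0.0
    raise ValueError(f"unknown phase {phase!r}")


def pose_template(
    class_label: str,
    phase: str,
    progress: float,
    subject_scale: float = 1.0,
    gait_amplitude: float | None = None,
    gait_offset: float = 0.0,
    swing_mod: dict | None = None,
    lean: float = 0.0,
    class_separation: float = 1.0,
) -> np.ndarray:
    """Deterministic articulated 19-node pose, shape (19, 3), millimetres.

    ``progress`` runs 0..1 through the phase; the gait clock ``g`` advances
    with it so running continues across phases.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}")
    ph_order = {"preparation": 0.0, "shot": 1.0, "after_shot": 2.0, "none": 0.0}
    if phase not in ph_order:
        raise ValueError(f"unknown phase {phase!r}")
    g = (ph_order[phase] + progress) / 3.0 + gait_offset
    s = _phase_s(phase if class_label != "no_shot" else "none", progress)

    S = subject_scale
    pose = np.zeros((19, 3))
    pelvis = np.array([lean, 0.0, 930.0 * S])
    pose[_IDX["pelvis"]] = pelvis
    pose[_IDX["spine_lower"]] = pelvis + S * np.array([lean * 0.3, 0, 140.0])
    pose[_IDX["spine_upper"]] = pose[_IDX["spine_lower"]] + S * np.array([lean * 0.3, 0, 160.0])
    neck = pose[_IDX["spine_upper"]] + S * np.array([0, 0, 140.0])
    pose[_IDX["neck"]] = neck
    pose[_IDX["head"]] = neck + S * np.array([0, 0, 180.0])

    hip_l = pelvis + S * np.array([0, 95.0, 0])
    hip_r = pelvis + S * np.array([0, -95.0, 0])
    pose[_IDX["hip_l"]], pose[_IDX["hip_r"]] = hip_l, hip_r
    amp = (160.0 if class_label == "no_shot" else 70.0) if gait_amplitude is None else gait_amplitude
    L_leg = 430.0 * S
    for side, hip, off in (("l", hip_l, 0.0), ("r", hip_r, 0.5)):
        phase_leg = 2 * np.pi * (g * 2.0 + off)
        foot_target = hip + np.array([
            S * amp * np.sin(phase_leg),
            0.0,
            -(2 * L_leg) * 0.97 + S * 30.0 * max(0.0, np.cos(phase_leg)),
        ])
        knee, foot = _two_link(hip, foot_target, L_leg, L_leg, np.array([1.0, 0.0, 0.0]))
        pose[_IDX[f"knee_{side}"]], pose[_IDX[f"foot_{side}"]] = knee, foot

    sh_l = neck + S * np.array([0, 180.0, -30.0])
    sh_r = neck + S * np.array([0, -180.0, -30.0])
    pose[_IDX["shoulder_l"]], pose[_IDX["shoulder_r"]] = sh_l, sh_r
    L1, L2 = 300.0 * S, 270.0 * S

    # non-dominant (left) arm: gentle counter-swing
    psi_nd = 0.35 * np.sin(2 * np.pi * (g * 2.0))
    d_nd = np.array([np.sin(psi_nd), 0.12, -np.cos(psi_nd)])
    d_nd /= np.linalg.norm(d_nd)
    elbow_l, hand_l = _two_link(sh_l, sh_l + 0.85 * (L1 + L2) * d_nd, L1, L2,
                                np.array([0.0, 1.0, 0.2]))
    pose[_IDX["elbow_l"]], pose[_IDX["hand_l"]] = elbow_l, hand_l

    # dominant (right) arm: the class-defining racket swing
    psi, ylat = _apply_swing_mod(*_swing_angle(class_label, s, g, class_separation), swing_mod)
    d_dom = np.array([np.sin(psi), ylat, -np.cos(psi)])
    d_dom /= np.linalg.norm(d_dom)
    elbow_r, hand_r = _two_link(sh_r, sh_r + 0.92 * (L1 + L2) * d_dom, L1, L2,
                                np.array([0.0, -1.0, 0.2]))
    pose[_IDX["elbow_r"]], pose[_IDX["hand_r"]] = elbow_r, hand_r

    # racket rigidly extends the forearm
    fore = hand_r - elbow_r
    fore /= np.linalg.norm(fore)
    pose[_IDX["racket_handle"]] = hand_r + 90.0 * S * fore
    pose[_IDX["racket_head"]] = hand_r + 380.0 * S * fore
    return pose


# ----------------------------------------------------------------- sampling

def _instance_params(cfg: GeneratorConfig, class_idx: int, phase_idx: int, instance: int):
    """Deterministic per-pool-instance variation (the 'subset element')."""
    rng = np.random.default_rng([cfg.seed, 7919, class_idx, phase_idx, instance])
    return {
        # whole-trajectory stroke-to-stroke variation: the dominant source of
        # within-class spread, correlated across the frames of a phase
        "swing_mod": {
            "amp_scale": 1.0 + 0.30 * cfg.stroke_var * rng.standard_normal(),
            "psi_offset": 0.35 * cfg.stroke_var * rng.standard_normal(),
            "y_offset": 0.15 * cfg.stroke_var * rng.standard_normal(),
        },
        "gait_offset": 0.10 * cfg.stroke_var * rng.standard_normal(),
        "lean": 25.0 * cfg.stroke_var * rng.standard_normal(),
        "time_warp": 0.08 * cfg.stroke_var * rng.standard_normal(),
    }


def _phase_sequence(class_label: str, phase: str, n_frames: int, cfg: GeneratorConfig,
                    inst: dict, subject_scale: float) -> NodeSequence:
    frames = np.empty((n_frames, 19, 3))
    for fi in range(n_frames):
        u = fi / (n_frames - 1) if n_frames > 1 else 0.0
        u = float(np.clip(u + inst["time_warp"] * u * (1 - u), 0.0, 1.0))
        frames[fi] = pose_template(
            class_label,
            phase,
            u,
            subject_scale=subject_scale,
            gait_offset=inst["gait_offset"],
            swing_mod=inst["swing_mod"],
            lean=inst["lean"],
            class_separation=cfg.resolved_class_separation(),
        )
    return NodeSequence(
        CANONICAL_NODE_NAMES, frames, phase_label=phase if phase != "none" else "none",
        class_label=class_label,
    )


def generate_sample(class_label: str, cfg: GeneratorConfig, rng: np.random.Generator) -> MotionSample:
    """Draw one labelled sample: three random phase instances of the class,
    assembled to T frames, plus calibrated noise.

    Phase instances are drawn independently within the class (forehand and
    backhand phases are never mixed); the no-shot class draws all three
    thirds from its single running pool.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}")
    class_idx = CLASSES.index(class_label)
    subject_scale = 1.0 + cfg.subject_sd * rng.standard_normal()
    left_handed = rng.random() < cfg.left_handed_frac

    phases = (("preparation", "shot", "after_shot") if class_label != "no_shot"
              else ("none", "none", "none"))
    seqs = []
    provenance = []
    for phase_idx, phase in enumerate(phases):
        instance = int(rng.integers(cfg.phase_pool_size))
        inst = _instance_params(cfg, class_idx, phase_idx, instance)
        seq = _phase_sequence(class_label, phase, cfg.phase_frames[phase_idx], cfg,
                              inst, subject_scale)
        if left_handed:
            # record as a left-handed subject, then canonicalize back
            mirrored = canonicalize_handedness(seq, "left")  # mirror produces lefty view
            seq = canonicalize_handedness(mirrored, "left")
        seqs.append(seq)
        provenance.append((class_label, phase, instance))

    sample = assemble_sample(seqs[0], seqs[1], seqs[2], T=cfg.T, plane=cfg.plane,
                             provenance=tuple(provenance))
    data = sample.data.copy()
    sd = cfg.resolved_noise_sd()
    if sd > 0:
        data += rng.normal(0.0, sd, size=data.shape)
    if cfg.outlier_frac > 0:
        C, V, T = data.shape
        spikes = rng.random((V, T)) < cfg.outlier_frac
        data[:, spikes] += rng.uniform(-cfg.outlier_scale, cfg.outlier_scale,
                                       size=(C, int(spikes.sum())))
    return MotionSample(
        data=data,
        node_names=sample.node_names,
        channel_names=sample.channel_names,
        label=class_label,
        phase_boundaries=sample.phase_boundaries,
        provenance=sample.provenance,
    )


def generate_dataset(cfg: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate the full benchmark dataset (1080 samples by default).

    Deterministic under a fixed config: two runs with the same seed produce
    byte-identical sample tensors.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    samples: list[MotionSample] = []
    for label, count in zip(CLASSES, cfg.class_counts):
        for _ in range(count):
            samples.append(generate_sample(label, cfg, rng))
    return SyntheticDataset(samples=samples, config=cfg)


def samples_to_array(samples) -> np.ndarray:
    """Stack MotionSamples into an (N, C, V, T) tensor."""
    return np.stack([s.data for s in samples]).astype(np.float32)


# ------------------------------------------------------- marker-level fixtures

_MARKER_OFFSETS: dict[str, tuple[str, tuple[float, float, float]]] = {
    # marker -> (node it decorates, offset in mm); offsets of each node's
    # source cluster sum to zero so reduction recovers the node exactly.
    "LFHD": ("head", (60, 40, 20)), "RFHD": ("head", (60, -40, 20)),
    "LBHD": ("head", (-60, 40, -20)), "RBHD": ("head", (-60, -40, -20)),
    "C7": ("neck", (0, 0, 0)),
    "CLAV": ("spine_upper", (60, 0, 30)), "STRN": ("spine_upper", (-60, 0, -30)),
    "T10": ("spine_lower", (0, 0, 0)),
    "LSHO": ("shoulder_l", (0, 0, 0)), "RSHO": ("shoulder_r", (0, 0, 0)),
    "LELB": ("elbow_l", (0, 0, 0)), "RELB": ("elbow_r", (0, 0, 0)),
    "LWRA": ("hand_l", (20, 25, 0)), "LWRB": ("hand_l", (20, -25, 0)),
    "LFIN": ("hand_l", (-40, 0, 0)),
    "RWRA": ("hand_r", (20, 25, 0)), "RWRB": ("hand_r", (20, -25, 0)),
    "RFIN": ("hand_r", (-40, 0, 0)),
    "LASI": ("hip_l", (70, 0, 10)), "LPSI": ("hip_l", (-70, 0, -10)),
    "RASI": ("hip_r", (70, 0, 10)), "RPSI": ("hip_r", (-70, 0, -10)),
    "LKNE": ("knee_l", (0, 0, 0)), "RKNE": ("knee_r", (0, 0, 0)),
    "LANK": ("foot_l", (0, 20, 30)), "LHEE": ("foot_l", (-60, -10, -10)),
    "LTOE": ("foot_l", (60, -10, -20)),
    "RANK": ("foot_r", (0, -20, 30)), "RHEE": ("foot_r", (-60, 10, -10)),
    "RTOE": ("foot_r", (60, 10, -20)),
    # markers unused by the reduction rules, placed for completeness
    "RBAK": ("spine_upper", (-90, -60, 40)),
    "LUPA": ("elbow_l", (0, 40, 120)), "RUPA": ("elbow_r", (0, -40, 120)),
    "LFRM": ("hand_l", (0, 30, 120)), "RFRM": ("hand_r", (0, -30, 120)),
    "LTHI": ("knee_l", (40, 50, 200)), "RTHI": ("knee_r", (40, -50, 200)),
    "LTIB": ("knee_l", (30, 40, -200)), "RTIB": ("knee_r", (30, -40, -200)),
    "RKT_TOP": ("racket_head", (0, 0, 130)), "RKT_HEADBOT": ("racket_head", (0, 0, -130)),
    "RKT_LEFT": ("racket_head", (0, 110, 0)), "RKT_RIGHT": ("racket_head", (0, -110, 0)),
    "RKT_HANDTOP": ("racket_handle", (0, 0, 60)),
    "RKT_HANDMID": ("racket_handle", (0, 0, 30)),
    "RKT_HANDBOT": ("racket_handle", (0, 0, 0)),
}


def markers_from_nodes(nodes: NodeSequence, frame_rate: float = 100.0,
                       subject_id: str = "synthetic") -> MarkerSequence:
    """Synthesize the 46-marker capture view of a 19-node sequence.

    Each node's source-marker cluster is laid out with zero-sum offsets, so
    applying the default reduction rules recovers the node positions exactly
    (a round-trip oracle for the reader and the reduction).
    """
    if nodes.positions.shape[2] != 3:
        raise ValueError("marker synthesis needs 3D node positions")
    names = tuple(_MARKER_OFFSETS)
    T = nodes.n_frames
    out = np.empty((T, len(names), 3))
    for m, name in enumerate(names):
        node, off = _MARKER_OFFSETS[name]
        out[:, m, :] = nodes.node(node) + np.asarray(off)
    return MarkerSequence(names, out, frame_rate=frame_rate, subject_id=subject_id)
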