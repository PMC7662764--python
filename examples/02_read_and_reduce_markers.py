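"""Round-trip marker data through C3D and reduce it to the skeleton.

A capture session records 39 body markers (Plug-in-Gait) plus 7 racket
markers; the classifier works on 19 reduced nodes.  Here a synthetic stroke
provides the marker data.
"""

import tempfile
from pathlib import Path

import numpy as np

from tennisgcn import c3dio, read_c3d, reduce_markers, project_to_plane
from tennisgcn.synth import GeneratorConfig, markers_from_nodes, _instance_params, _phase_sequence

cfg = GeneratorConfig(class_counts=(1, 1, 1), noise_sd=0.0, seed=0)
nodes = _phase_sequence("forehand", "shot", 10, cfg, _instance_params(cfg, 0, 1, 0), 1.0)
markers = markers_from_nodes(nodes)
print(f"synthesized capture: {len(markers.marker_names)} markers x {markers.n_frames} frames")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "stroke.c3d"
    c3dio.write_c3d(path, list(markers.marker_names), markers.positions, frame_rate=100.0)
    back = read_c3d(path)
    err = np.abs(back.positions - markers.positions).max()
    print(f"C3D round trip: {path.stat().st_size} bytes, max error {err:.2e} mm")

reduced = reduce_markers(back)
print(f"reduced to {reduced.positions.shape[1]} nodes "
      f"(recovery error {np.abs(reduced.positions - nodes.positions).max():.2e} mm)")

planar = project_to_plane(reduced, ("x", "z"))
print(f"sagittal projection: {planar.positions.shape} (frames, nodes, channels)")
# The racket head travels front/up during a forehand shot phase:
head = planar.node("racket_head")
print(f"racket head x: {head[0, 0]:.0f} -> {head[-1, 0]:.0f} mm, "
      f"z: {head[0, 1]:.0f} -> {head[-1, 1]:.0f} mm")
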