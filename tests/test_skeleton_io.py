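"""C3D reading, marker reduction, projection and sample assembly."""

import numpy as np
import pytest

from tennisgcn import c3dio
from tennisgcn.skeleton_io import (
    MarkerSequence,
    NodeSequence,
    assemble_sample,
    canonicalize_handedness,
    default_reduction_rules,
    project_to_plane,
    read_c3d,
    read_marker_csv,
    reduce_markers,
    write_marker_csv,
)
from tennisgcn.stgraph import CANONICAL_NODE_NAMES
from tennisgcn.skeleton_io import ALL_MARKERS
from tennisgcn.synth import GeneratorConfig, markers_from_nodes, _instance_params, _phase_sequence


@pytest.fixture(scope="module")
def node_seq():
    cfg = GeneratorConfig(class_counts=(1, 1, 1), noise_sd=0.0, seed=0)
    inst = _instance_params(cfg, 0, 1, 0)
    return _phase_sequence("forehand", "shot", 6, cfg, inst, 1.0)


@pytest.fixture(scope="module")
def marker_seq(node_seq):
    return markers_from_nodes(node_seq)


class TestC3DReader:
    def test_roundtrip_identity(self, marker_seq, tmp_path):
        path = tmp_path / "fixture.c3d"
        c3dio.write_c3d(path, list(marker_seq.marker_names), marker_seq.positions, 120.0)
        back = read_c3d(path)
        assert back.marker_names == marker_seq.marker_names
        assert back.n_frames == marker_seq.n_frames
        assert back.frame_rate == pytest.approx(120.0)
        # float32 storage round trip
        np.testing.assert_allclose(back.positions, marker_seq.positions, atol=1e-3)

    def test_46_markers_survive(self, marker_seq, tmp_path):
        path = tmp_path / "full.c3d"
        c3dio.write_c3d(path, list(marker_seq.marker_names), marker_seq.positions)
        back = read_c3d(path)
        assert len(back.marker_names) == 46
        assert set(back.marker_names) == set(ALL_MARKERS)

    def test_gap_rejected_with_marker_and_span(self, marker_seq, tmp_path):
        pos = marker_seq.positions.copy()
        pos[2:4, 5, :] = np.nan  # gap on marker index 5, frames 2..3
        path = tmp_path / "gappy.c3d"
        c3dio.write_c3d(path, list(marker_seq.marker_names), pos)
        name = marker_seq.marker_names[5]
        with pytest.raises(ValueError, match=f"{name}.*2..3"):
            read_c3d(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_c3d(tmp_path / "absent.c3d")

    def test_not_a_c3d(self, tmp_path):
        bad = tmp_path / "junk.c3d"
        bad.write_bytes(b"\x00" * 2048)
        with pytest.raises(ValueError, match="magic"):
            read_c3d(bad)

    def test_csv_fallback_roundtrip(self, marker_seq, tmp_path):
        path = tmp_path / "markers.csv"
        write_marker_csv(marker_seq, path)
        back = read_marker_csv(path, frame_rate=marker_seq.frame_rate)
        assert back.marker_names == marker_seq.marker_names
        np.testing.assert_allclose(back.positions, marker_seq.positions, rtol=1e-12)


class TestReduceMarkers:
    def test_nineteen_nodes_always(self, marker_seq):
        nodes = reduce_markers(marker_seq)
        assert nodes.positions.shape[1] == 19
        assert nodes.node_names == CANONICAL_NODE_NAMES
        assert nodes.n_frames == marker_seq.n_frames

    def test_recovers_synthesized_nodes_exactly(self, node_seq, marker_seq):
        """Marker clusters have zero-sum offsets, so the mean reduction
        inverts the synthesis exactly."""
        nodes = reduce_markers(marker_seq)
        np.testing.assert_allclose(nodes.positions, node_seq.positions, atol=1e-9)

    def test_coincident_head_markers(self, marker_seq):
        pos = marker_seq.positions.copy()
        p = np.array([1.0, 2.0, 3.0])
        for name in ("LFHD", "RFHD", "LBHD", "RBHD"):
            pos[:, marker_seq.marker_names.index(name), :] = p
        nodes = reduce_markers(MarkerSequence(marker_seq.marker_names, pos))
        np.testing.assert_allclose(nodes.node("head"), np.tile(p, (marker_seq.n_frames, 1)))

    def test_racket_head_is_square_center(self, marker_seq):
        pos = marker_seq.positions.copy()
        corners = {
            "RKT_TOP": (1, 0, 1), "RKT_HEADBOT": (-1, 0, -1),
            "RKT_LEFT": (-1, 0, 1), "RKT_RIGHT": (1, 0, -1),
        }
        for name, c in corners.items():
            pos[:, marker_seq.marker_names.index(name), :] = c
        nodes = reduce_markers(MarkerSequence(marker_seq.marker_names, pos))
        np.testing.assert_allclose(nodes.node("racket_head"), 0.0, atol=1e-12)

    def test_missing_source_marker_named(self, marker_seq):
        names = tuple(n for n in marker_seq.marker_names if n != "C7")
        idx = [marker_seq.marker_names.index(n) for n in names]
        short = MarkerSequence(names, marker_seq.positions[:, idx, :])
        with pytest.raises(ValueError, match="C7"):
            reduce_markers(short)

    def test_translation_equivariance(self, marker_seq):
        t = np.array([10.0, -20.0, 5.0])
        shifted = MarkerSequence(marker_seq.marker_names, marker_seq.positions + t)
        n0 = reduce_markers(marker_seq)
        n1 = reduce_markers(shifted)
        np.testing.assert_allclose(n1.positions, n0.positions + t, atol=1e-9)


class TestProjection:
    def test_axis_selection(self, node_seq):
        p = project_to_plane(node_seq, ("x", "z"))
        np.testing.assert_array_equal(p.positions, node_seq.positions[:, :, [0, 2]])
        assert p.axis_names == ("x", "z")

    def test_idempotent_on_2d(self, node_seq):
        p = project_to_plane(node_seq, ("x", "z"))
        again = project_to_plane(p, ("x", "z"))
        np.testing.assert_array_equal(again.positions, p.positions)

    def test_projection_never_grows_norm(self, node_seq):
        p = project_to_plane(node_seq, ("y", "z"))
        assert np.all(
            np.linalg.norm(p.positions, axis=2) <= np.linalg.norm(node_seq.positions, axis=2) + 1e-12
        )

    def test_invalid_plane(self, node_seq):
        with pytest.raises(ValueError):
            project_to_plane(node_seq, ("x", "x"))
        with pytest.raises(ValueError):
            project_to_plane(node_seq, ("x", "w"))


class TestHandedness:
    def test_mirror_is_involution(self, node_seq):
        twice = canonicalize_handedness(canonicalize_handedness(node_seq, "left"), "left")
        np.testing.assert_allclose(twice.positions, node_seq.positions)

    def test_mirror_swaps_sides_and_flips_lateral(self, node_seq):
        m = canonicalize_handedness(node_seq, "left")
        left_hand = node_seq.node("hand_l")
        np.testing.assert_allclose(
            m.node("hand_r"), left_hand * np.array([1, -1, 1]), atol=1e-12
        )


class TestAssembleSample:
    def make_phase(self, n, phase, label="forehand", value=None, rng=None):
        if value is not None:
            pos = np.full((n, 19, 3), float(value))
            pos[:, CANONICAL_NODE_NAMES.index("neck"), 2] += 450.0  # nondegenerate scale
        else:
            pos = rng.normal(size=(n, 19, 3)) * 10
            pos[:, CANONICAL_NODE_NAMES.index("neck"), 2] += 450.0
        return NodeSequence(CANONICAL_NODE_NAMES, pos, phase_label=phase, class_label=label)

    def test_default_length_and_boundaries(self, rng):
        s = assemble_sample(
            self.make_phase(5, "preparation", rng=rng),
            self.make_phase(5, "shot", rng=rng),
            self.make_phase(4, "after_shot", rng=rng),
        )
        assert s.shape == (2, 19, 14)
        assert s.phase_boundaries == (5, 10)

    def test_constant_pose_gives_identical_frames(self):
        s = assemble_sample(
            self.make_phase(5, "preparation", value=1.0),
            self.make_phase(5, "shot", value=1.0),
            self.make_phase(4, "after_shot", value=1.0),
        )
        assert np.allclose(s.data, s.data[:, :, :1])

    def test_every_frame_appears_at_double_length(self, rng):
        phases = [
            self.make_phase(5, "preparation", rng=rng),
            self.make_phase(5, "shot", rng=rng),
            self.make_phase(4, "after_shot", rng=rng),
        ]
        s = assemble_sample(*phases, T=28, normalize=False)
        concat = np.concatenate([project_to_plane(p, ("x", "z")).positions for p in phases])
        # nearest-frame oracle: every source frame appears exactly twice
        expected = concat[np.repeat(np.arange(14), 2)]
        np.testing.assert_allclose(np.transpose(s.data, (2, 1, 0)), expected)

    @pytest.mark.parametrize("lengths", [(1, 1, 1), (2, 7, 3), (20, 20, 20)])
    def test_output_length_always_T(self, lengths, rng):
        s = assemble_sample(
            self.make_phase(lengths[0], "preparation", rng=rng),
            self.make_phase(lengths[1], "shot", rng=rng),
            self.make_phase(lengths[2], "after_shot", rng=rng),
        )
        assert s.shape[2] == 14

    def test_mixed_classes_rejected(self, rng):
        with pytest.raises(ValueError, match="mix"):
            assemble_sample(
                self.make_phase(5, "preparation", label="forehand", rng=rng),
                self.make_phase(5, "shot", label="backhand", rng=rng),
                self.make_phase(4, "after_shot", label="forehand", rng=rng),
            )

    def test_normalization_centers_pelvis(self, rng):
        s = assemble_sample(
            self.make_phase(5, "preparation", rng=rng),
            self.make_phase(5, "shot", rng=rng),
            self.make_phase(4, "after_shot", rng=rng),
        )
        pelvis = s.data[:, CANONICAL_NODE_NAMES.index("pelvis"), :]
        np.testing.assert_allclose(pelvis, 0.0, atol=1e-12)
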