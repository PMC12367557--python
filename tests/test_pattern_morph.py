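"""Segmentation, signed distance maps and pattern interpolation."""

import numpy as np
import pytest

from mimicaxis import (
    ColouredMesh,
    align_segments,
    align_to,
    interpolate_pattern,
    interpolate_segment_colours,
    make_banded_ellipsoid,
    segment_colours,
    signed_distance_map,
)
from mimicaxis.pattern_morph import PatternField, PatternError, SegmentationDegenerate
from mimicaxis.synthetic_fixtures import BandedEllipsoidParams, stripe_function

from conftest import brute_force_hop_distances


def _field(colours, labels=None, distance=None):
    return PatternField(
        labels=labels if labels is not None else [1, 2],
        segment_colours=colours,
        signed_distance=distance,
    )


def strip_mesh(rows=6, cols=10, boundary=5):
    """Flat triangulated strip with a straight vertical label boundary."""
    xs, ys = np.meshgrid(np.arange(cols), np.arange(rows), indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(rows * cols)])
    faces = []
    for i in range(cols - 1):
        for j in range(rows - 1):
            v = i * rows + j
            faces.append([v, v + rows, v + rows + 1])
            faces.append([v, v + rows + 1, v + 1])
    labels = np.where(verts[:, 0] < boundary, 1, 2)
    palette = np.array([[255, 220, 0], [30, 30, 30]])
    mesh = ColouredMesh(verts, np.array(faces), palette[labels - 1])
    return mesh, labels


class TestSegmentation:
    def test_two_exact_colours_recovered(self, two_tone_mesh):
        """Exactly two colours force the clustering; yellow is segment 1."""
        field = segment_colours(two_tone_mesh.mesh)
        np.testing.assert_array_equal(field.labels, two_tone_mesh.true_labels)
        np.testing.assert_array_equal(field.segment_colours[0], (255, 220, 0))
        np.testing.assert_array_equal(field.segment_colours[1], (30, 30, 30))

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_medians_near_truth(self, seed):
        """Gaussian colour noise (sd 8): medians within 4 units/channel."""
        fix = make_banded_ellipsoid(
            BandedEllipsoidParams(colour_noise_sd=8.0, seed=seed)
        )
        field = segment_colours(fix.mesh)
        truth = np.array([fix.params.colour_1, fix.params.colour_2], dtype=float)
        assert np.abs(field.segment_colours - truth).max() < 4.0

    def test_uniform_colour_is_degenerate(self):
        mesh = ColouredMesh(
            np.random.default_rng(0).normal(size=(10, 3)),
            [[0, 1, 2]],
            [[100, 100, 100]] * 10,
        )
        with pytest.raises(SegmentationDegenerate):
            segment_colours(mesh)


class TestSignedDistance:
    def test_boundary_vertices_have_magnitude_one(self, small_pair):
        ea, _, _ = small_pair
        field = signed_distance_map(segment_colours(ea.mesh), ea.mesh)
        d = field.signed_distance
        assert np.abs(d).min() == 1
        assert ((d > 0) == (field.labels == 1)).all()

    def test_strip_mesh_distance_counts_rows(self):
        """Three columns from a straight boundary -> magnitude 3."""
        mesh, labels = strip_mesh(rows=6, cols=10, boundary=5)
        field = signed_distance_map(
            PatternField(labels=labels, segment_colours=[[255, 220, 0], [30, 30, 30]]),
            mesh,
        )
        # column 2 is 3 edge hops from the nearest column-5 (label 2) vertex
        col2 = np.where(mesh.vertices[:, 0] == 2)[0]
        assert (field.signed_distance[col2] == 3).all()

    def test_matches_brute_force_oracle(self, small_pair):
        """Multi-source BFS equals per-vertex BFS shortest paths (<=500 verts)."""
        ea, eb, _ = small_pair
        for mesh in (ea.mesh, eb.mesh):
            assert mesh.n_vertices <= 500
            field = signed_distance_map(segment_colours(mesh), mesh)
            all_dist = brute_force_hop_distances(mesh)
            for v in range(mesh.n_vertices):
                opposite = np.where(field.labels != field.labels[v])[0]
                expected = min(all_dist[v][u] for u in opposite)
                assert abs(field.signed_distance[v]) == expected

    def test_disconnected_graph_reports_components(self):
        mesh, labels = strip_mesh(rows=2, cols=3, boundary=2)
        # add an isolated triangle far away
        extra = ColouredMesh(
            np.vstack([mesh.vertices, [[50, 50, 0], [51, 50, 0], [50, 51, 0]]]),
            np.vstack([mesh.faces, [[6, 7, 8]]]),
            np.vstack([mesh.vertex_colours, [[1, 2, 3]] * 3]),
        )
        field = PatternField(
            labels=np.append(labels, [1, 2, 2]),
            segment_colours=[[255, 220, 0], [30, 30, 30]],
        )
        with pytest.raises(PatternError, match="disconnected"):
            signed_distance_map(field, extra)


class TestAlignment:
    def test_colour_matching_pairs_like_with_like(self):
        a = _field([[255, 220, 0], [30, 30, 30]])
        b = _field([[80, 80, 80], [255, 160, 40]])  # dark grey first, orange second
        assert align_segments(a, b) == (2, 1)

    def test_identity_for_identical_and_tied_fields(self):
        a = _field([[255, 220, 0], [30, 30, 30]])
        assert align_segments(a, a) == (1, 2)
        # symmetric colours: both pairings tie, tie-break keeps identity
        tie_a = _field([[100, 100, 100], [120, 120, 120]])
        tie_b = _field([[110, 100, 100], [110, 120, 120]])
        assert align_segments(tie_a, tie_b) == (1, 2)

    def test_align_to_flips_labels_and_distances(self):
        b = _field(
            [[30, 30, 30], [255, 220, 0]],
            labels=[2, 1],
            distance=[-2, 1],
        )
        a = _field([[255, 220, 0], [30, 30, 30]])
        flipped = align_to(a, b)
        np.testing.assert_array_equal(flipped.labels, [1, 2])
        np.testing.assert_array_equal(flipped.signed_distance, [2, -1])
        np.testing.assert_array_equal(flipped.segment_colours[0], (255, 220, 0))


class TestInterpolation:
    def test_endpoint_recovery_bit_exact(self, small_fields):
        fa, fb = small_fields
        np.testing.assert_array_equal(interpolate_pattern(fa, fb, 0.0), fa.labels)
        np.testing.assert_array_equal(interpolate_pattern(fa, fb, 1.0), fb.labels)

    def test_midpoint_boundary_matches_analytic_mid_phase(self, medium_pair):
        """w=0.5 boundary within one edge of the mean-phase stripe."""
        ea, eb, _ = medium_pair
        fa = signed_distance_map(segment_colours(ea.mesh), ea.mesh)
        fb = align_to(fa, signed_distance_map(segment_colours(eb.mesh), eb.mesh))
        labels = interpolate_pattern(fa, fb, 0.5)
        mid_phase = (ea.params.band_phase + eb.params.band_phase) / 2.0
        params = BandedEllipsoidParams(band_phase=mid_phase)
        truth = stripe_function(params)(ea.mesh.vertices[:, 0])
        mid_field = signed_distance_map(
            PatternField(labels=truth, segment_colours=fa.segment_colours), ea.mesh
        )
        mismatched = labels != truth
        # a mismatch is tolerable only right on the analytic boundary
        assert np.abs(mid_field.signed_distance[mismatched]).max() <= 1

    def test_label_changes_monotone_in_w(self, small_fields):
        """D_w is linear in w, so each vertex flips label at most once."""
        fa, fb = small_fields
        sweep = np.stack(
            [interpolate_pattern(fa, fb, w) for w in np.linspace(-0.5, 1.5, 41)]
        )
        flips = (np.diff(sweep, axis=0) != 0).sum(axis=0)
        assert flips.max() <= 1

    def test_vertex_count_mismatch_rejected(self, small_fields):
        fa, _ = small_fields
        short = PatternField(
            labels=fa.labels[:-1],
            segment_colours=fa.segment_colours,
            signed_distance=fa.signed_distance[:-1],
        )
        with pytest.raises(PatternError):
            interpolate_pattern(fa, short, 0.5)

    def test_segment_colour_arithmetic_and_clamp(self):
        a = _field([[200, 180, 0], [30, 30, 30]])
        b = _field([[240, 200, 40], [10, 10, 10]])
        np.testing.assert_allclose(
            interpolate_segment_colours(a, b, 0.5)[0], (220, 190, 20)
        )
        np.testing.assert_allclose(interpolate_segment_colours(a, b, 0.0), a.segment_colours)
        extrapolated = interpolate_segment_colours(a, b, 1.5)
        np.testing.assert_allclose(extrapolated[0], (255, 210, 60))  # R clamped
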